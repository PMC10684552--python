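# Methods

This note documents the models behind `bovscan`, the defaults that matter,
the synthetic-data generator's assumptions, and the numerical choices made
where the design was genuinely open.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model and coordinates

A `HaplotypePanel` is a 2N × S matrix of phased biallelic haplotypes
(0 = reference allele, 1 = alternate), with 1-based site positions as in
VCF.  All intervals — windows, gene records, ancestry tracts, candidate
regions — are 0-based half-open (BED convention); conversion happens only
at I/O boundaries.  Multiallelic VCF records are dropped with a logged
count.  Records with missing genotype calls are dropped at read time: the
intended input is an imputed, phased call set, so missingness is an edge
case, and excluding whole sites keeps every downstream estimator's sample
size constant per site.  Unphased heterozygous calls do not abort reading,
but the panel is marked unphased and the EHH-family statistics refuse it;
frequency statistics still work.

For RFMix `.msp.tsv` input, tract boundaries are taken directly from the
file's `spos`/`epos` columns (physical bp), and runs of constant ancestry
across consecutive rows are merged per haplotype.  How marker-interval
edges should be mapped to bp (marker positions vs. midpoints) is a
convention the upstream tool owns; consuming its printed intervals
verbatim keeps the filter reproducible from the file alone.

## Windowed frequency statistics

* **π** per site is 2p̂(1−p̂)·n/(n−1) over the population's n haplotypes
  (equal to the mean pairwise difference); the window value divides the
  site sum by the window length in bp, matching the per-bp convention of
  the standard windowed-diversity tools.
* **FST** uses the Weir–Cockerham (1984) variance components a (among
  populations), b (among individuals within populations), c (within
  individuals), computed from diploid genotypes reconstructed by pairing
  each sample's two haplotype rows.  Windows combine by ratio of sums
  Σa / Σ(a+b+c) — the "weighted" convention — rather than a mean of
  per-site ratios, which is noisy at low-information sites.  Negative
  window values are reported as computed.  A Hudson estimator is available
  for sensitivity checks; it is never the default.
* **PBS** for target T against reference R and outgroup O is
  (T(F_TR) + T(F_TO) − T(F_RO))/2 with T(x) = −ln(1−x).  FST inputs are
  clamped to [0, 1−10⁻⁶] first so the branch length stays finite at fixed
  differences.  PBS against a *pool* of references is supported by giving
  the pooled label; running separate PBS per reference is equally valid
  and the choice is the caller's.
* Windows with fewer than `min_snps` SNPs (default 10) are undefined (NaN)
  and are never selected by any rule.

**Selection rules.**  `top_fraction` selects the ⌈q·n⌉ most extreme
defined windows (default q = 0.01), including all ties at the threshold;
being rank-based it is invariant under monotone transforms.  The Z-test
rule standardizes window values against the genome-wide mean and SD and
takes the one-sided upper tail, p < 0.005 by default, on raw window values
(not log-transformed — the raw scale is what the window statistics are
computed on, and the rule is a ranking device, not an inference).  For
statistics whose signal is a *low* value (the π-ratio in the swept
population), the sign is flipped before standardization.  Candidates are
the windows selected by *every* configured statistic, merged into
nonoverlapping regions.

## Haplotype statistics

EHH at marker m for an allele class is Σ_g C(n_g,2)/C(n,2) over groups of
haplotypes identical from the core to m (the core site's own alleles are
part of the identity).  The curve starts at the core with EHH = 1 and is
truncated at the first marker below the cutoff (that marker is included in
the integral), at a gap larger than the maximum, or at the chromosome end.
iHH is the trapezoidal integral over physical distance in bp (no genetic
map is assumed), both directions summed.

* **iHS**: ln(iHH_ancestral / iHH_derived) at polarized sites with MAF
  ≥ 0.05, standardized within 50 derived-allele-frequency bins of 2%.
  Ancestral states come from an outgroup fixed at the site (the buffalo
  convention); sites where the outgroup segregates are skipped.
* **XP-EHH**: ln(iHH_A / iHH_B) with each population's full haplotype set
  as the allele class, standardized in a single global bin; the windowed
  summary is the *mean* standardized score per window.
* Defaults — cutoff 0.05, maximum gap 200 kb, MAF 0.05, bin width 2% —
  follow the widely used selection-scan tooling; all are configurable.
  One deliberate difference: cores whose curve truncates at a large gap
  are *kept and flagged* rather than silently dropped, so every score in
  the output is auditable; filtering on the flag reproduces the stricter
  behavior.

## Gene-flow statistics

* **D** (ABBA–BABA) from population allele frequencies p₁..p₄:
  Σ[(1−p₁)p₂p₃(1−p₄) − p₁(1−p₂)p₃(1−p₄)] over the same sums' total, i.e.
  the frequency-weighted count of discordant patterns polarized by the
  outgroup.  Standard errors come from a delete-one block jackknife over
  contiguous genomic blocks (default 5 Mb; the block count is reported so
  users can judge SE stability — fewer than 3 blocks yields no Z).
* **f3(C; A, B)**: mean over sites of (p_C−p_A)(p_C−p_B) −
  p_C(1−p_C)/(n_C−1), the second term removing the finite-sample bias of
  p_C²; jackknife as for D.
* **U20/U50**: per-window count of SNPs where some allele is fixed among
  the *sampled* donor haplotypes (donors are typically 4–8 animals, so
  fixation is sample-level by construction), strictly below 1% in the
  source population and strictly above 20% (U20) or 50% (U50) in the
  target.  Both alleles are candidates at a site; a site contributes at
  most one count.  Threshold comparisons are strict at x and y and exact
  equality at w = 1.

## The ILS tract filter

A haplotype segment shared between cattle and a donor species through
incomplete lineage sorting (ancestral polymorphism) is broken by
recombination on both branches; its length is modeled as Gamma with shape
2 and rate 1/L, where L = 1/(r·t) is the expected shared-segment length
given per-bp per-generation recombination rate r and summed branch length
t in generations.  "Rate 1/L" (scale = L) is the reading consistent with
an expected segment length of L; the alternative (scale = 1/L) would give
mean 2/L and contradict it — the closed-form survival
e^(−m/L)(1 + m/L), tested on a 1,000-point grid, pins the choice down.
The default L = 206.52 bp is the documented value for the cattle/banteng
comparison; r and t are not separately published, so L is a direct model
input.  A tract of length m is retained iff its ILS survival probability
is below α (default 0.05), i.e. m ≳ 4.744·L.  Under the null, the
retained fraction converges to α — a calibration the acceptance suite
measures with 100,000 simulated lengths.

Ancestry proportions divide each sample's total retained tract length
(both haplotypes) by twice the genome length; tracts within a haplotype
are assumed disjoint, as local-ancestry callers emit them.

## Synthetic data: what it emulates and what it does not

The generator draws an ancestral frequency p ~ Beta(0.8, 0.8) per site
(mildly U-shaped spectrum) and population frequencies from the
Balding–Nichols model Beta(p(1−F)/F, (1−p)(1−F)/F), so a population's
expected frequency is p with variance F·p(1−p) and the expected
Weir–Cockerham FST between two populations is ≈ F.  Haplotypes are
i.i.d. Bernoulli per site.  This was chosen over a coalescent simulator
precisely because it gives the estimators closed-form expectations for
calibration, with no external data dependency.

Consequences to keep in mind: the base model has **no linkage
disequilibrium**, so EHH decays immediately off-core under the null and
every haplotype signal in a fixture comes from planted structure (shared
sweep haplotypes, copied donor segments).  Passing recovery tests
demonstrates that the estimators respond to the signal classes they
target, not that their power matches real genomes with background LD,
recombination-rate variation or demography.  Deep donor divergence is
emulated by a large-F Balding–Nichols draw plus donor-private fixed sites
at a configurable per-bp density — a stand-in for phylogenetic distance,
adequate for the U statistic's "donor fixed, absent in source" regime.

Planted signals: `plant_sweep` copies one core haplotype over a fraction
β of a population's haplotypes inside a region (a completed/ongoing hard
sweep); `plant_introgression` copies donor segments with Exponential
lengths into recipient haplotypes, either independently per haplotype or
— with `carrier_fraction` — the same interval into a chosen fraction of
haplotypes, which is the regime an adaptive-introgression scan detects
(per-haplotype placement leaves every tract at negligible population
frequency).  All truth is recorded and written alongside the fixture.

## Benchmark conditions

The calibration and recovery experiments (in `bovscan.benchmarks`, run by
both `tests/test_acceptance.py` and `scripts/acceptance.py`) use a 10 Mb
contig with 20,000 sites (one SNP per 500 bp):

* FST calibration: 2 × 50 diploids, F ∈ {0, 0.15}.
* Sweep recovery: 25 + 25 diploids at F = 0.15 (the indicine/taurine
  differentiation scale) plus a 2-diploid F = 0.9 outgroup for
  polarization; one sweep, β = 0.95, 100 kb.
* Introgression recovery: source/target at F = 0.02 (closely related
  indicine groups), a 4-diploid F = 0.6 donor with private fixed sites at
  2·10⁻⁴ per bp, a 2-diploid outgroup; 20 planted tracts of mean 300 kb
  at carrier fraction 0.3 (≈ 15–20% donor ancestry in the target — a
  strong but not unrealistic pulse for a recovery benchmark).  The D
  jackknife uses 500 kb blocks here (20 blocks on 10 Mb), the scaled-down
  analogue of the 5 Mb default on a full genome.
* ILS calibration: 100,000 Gamma(2, rate 1/206.52) lengths.

These sizes keep the full suite within a few minutes on one core while
leaving each window ~40 SNPs, enough for stable window statistics.

## Known limitations

* No genetic-map support: iHH integrates over physical distance.
* nSL/XP-nSL and composite-likelihood (CLR) scans are out of scope, as is
  local-ancestry inference itself — tracts are consumed, not inferred.
* The D statistic uses the frequency (ABBA−BABA) form polarized by the
  outgroup's reference-allele weight; sites where the outgroup carries
  the alternate allele contribute with weight 1−p₄ only.
* `maf_filter` uses the pooled frequency across all samples, as in the
  standard pre-processing chain; per-population filters can be composed
  from `site_mask`.
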