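# bovscan

Selection-scan and adaptive-introgression toolkit for multi-population
bovine genome panels.

Cattle comprise two domestic subspecies — humpless taurine and humped
indicine (zebu) — plus wild relatives (banteng, gaur, buffalo) that
hybridize with them.  Two questions drive much of bovine population
genomics: *which genomic regions were under positive selection* as indicine
cattle adapted to hot semi-arid and hot humid environments, and *which
regions entered the indicine gene pool by introgression* from other bovine
species.  `bovscan` implements the full windowed-scan workflow for both
questions on phased VCF panels, together with a synthetic-data generator
so every stage can be validated against planted ground truth without a
multi-hundred-genome dataset.

## Statistics implemented

**Selection scans** (50 kb windows, 20 kb steps by default):

- nucleotide diversity θπ per bp and the θπ ratio between populations
  (a sweep depresses diversity in the selected population);
- Weir–Cockerham (1984) F<sub>ST</sub> by ratio of variance-component
  sums, with a Hudson estimator option;
- the population branch statistic
  PBS = (T<sub>TR</sub> + T<sub>TO</sub> − T<sub>RO</sub>)/2 with
  T = −ln(1 − F<sub>ST</sub>), isolating the target population's branch;
- EHH / iHH / iHS (standardized in 2% derived-allele-frequency bins) and
  XP-EHH (standardized genome-wide, averaged per window);
- candidate selection by top-quantile (top 1%) or one-sided Z-test
  (p < 0.005) rules, intersection across statistics, merging to
  nonoverlapping regions, and GFF3 gene annotation.

**Gene-flow statistics**:

- the ABBA–BABA D statistic from population allele frequencies with a
  delete-one block-jackknife standard error and Z score;
- the outgroup f3 statistic with finite-sample bias correction;
- the adaptive-introgression U statistic: per-window counts of SNPs fixed
  in a donor (e.g. banteng), rare (< 1%) in a non-introgressed source
  (e.g. South Asian indicine) and common (> 20% for U20, > 50% for U50)
  in the target (e.g. East Asian indicine);
- an incomplete-lineage-sorting (ILS) filter for local-ancestry tracts: a
  segment shared through ancestral polymorphism has length
  ~ Gamma(shape 2, rate 1/L) with L = 1/(r·t); a tract of length m is
  kept only when its ILS survival probability e^(−m/L)(1 + m/L) is below
  α = 0.05 (default L = 206.52 bp for the cattle/banteng comparison);
- per-sample and per-population donor-ancestry fractions and regional
  haplotype frequency tables.

**Synthetic data**: Balding–Nichols panels (population frequency
~ Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral frequency p), planted
hard sweeps, planted donor tracts with recorded truth, and ILS-distributed
tract lengths — all deterministic given a seed.

## Worked example

Simulate a 500 kb two-population panel with one planted sweep, scan it,
and recover the sweep:

```python
import numpy as np
from bovscan import diversity, make_windows
from bovscan.synthetic import SimConfig, simulate_panel, plant_sweep

config = SimConfig(
    contig_length=500_000, n_sites=1_500,
    populations=[dict(label="IND", n_diploid=12, F=0.15),
                 dict(label="TAU", n_diploid=12, F=0.15)],
    seed=5,
)
panel, truth = simulate_panel(config)
popmap = config.popmap()
panel, _ = plant_sweep(panel, popmap, ("chr1", 200_000, 260_000),
                       "IND", beta=0.95, seed=7)

grid = make_windows({"chr1": 500_000}, 50_000, 20_000)
fst = diversity.fst_windowed(panel, popmap, "IND", "TAU", grid, min_snps=5)
best = grid.windows[int(np.nanargmax(fst.values))]
print("genome mean FST:", round(float(np.nanmean(fst.values)), 3))
print("peak FST window:", best, "value:", round(float(np.nanmax(fst.values)), 3))
```

```
genome mean FST: 0.201
peak FST window: ('chr1', 200000, 250000) value: 0.543
```

The genome-wide mean windowed F<sub>ST</sub> (~0.2) tracks the simulated
drift (F = 0.15 in each population against the shared ancestor; on a toy
panel this small the estimate is noticeably noisy — the 20,000-site
calibration in `scripts/acceptance.py` lands close to 0.15), and
the peak window is the planted sweep: the core haplotype carried to
frequency 0.95 in IND drives the allele-frequency divergence far above the
background.

The same workflow is available from the shell:

```bash
bovscan simulate --config plan.yaml --out fixture/
bovscan scan-diversity --config scan.yaml
bovscan scan-haplotype --config scan.yaml
bovscan scan-introgression --config scan.yaml
bovscan filter-tracts --tracts tracts.bed --length-l 206.52 --alpha 0.05 --out kept.bed
```

All outputs are TSV/BED with `#` headers recording the tool version,
configuration hash and seed; identical configuration and seed reproduce
outputs byte for byte.

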