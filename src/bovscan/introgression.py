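"""Gene-flow statistics and the incomplete-lineage-sorting tract filter.

Implements the frequency-based ABBA-BABA D statistic with delete-one block
jackknife, the outgroup f3 statistic with its sample-size bias correction,
the U-statistic window scan for adaptive introgression (donor-fixed alleles
rare in a source population but common in the target), ancestry-fraction
summaries over local-ancestry tracts, and the Gamma survival model that
separates genuine introgressed tracts from short segments expected under
incomplete lineage sorting.

The ILS null says a segment shared through ancestral polymorphism has
length distributed Gamma(shape 2, rate 1/L) with L = 1/(r*t): r the per-bp
per-generation recombination rate and t the summed branch length (in
generations) separating the two species.  A tract of length m is kept only
when its probability under that null, the survival function
e^(-m/L) (1 + m/L), falls below the retention threshold alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diversity import WindowStats
from .panel import HaplotypePanel, PopulationMap, TractSet, WindowGrid

#: Expected shared-ancestral-segment length (bp) used in the cattle/banteng
#: comparison; a direct model input since r and t are not published separately.
DEFAULT_L_BP = 206.52


def expected_tract_length(r: float, t: float) -> float:
    """Expected ILS segment length L = 1/(r*t) in bp."""
    if r <= 0 or t <= 0:
        raise ValueError("r and t must be positive")
    return 1.0 / (r * t)


def ils_survival(m, L: float = DEFAULT_L_BP):
    """P(ILS segment length >= m) = 1 - GammaCDF(m; shape 2, rate 1/L).

    Equals the closed form e^(-m/L) (1 + m/L).
    """
    m = np.asarray(m, dtype=float)
    if (m < 0).any():
        raise ValueError("m must be >= 0")
    if L <= 0:
        raise ValueError("L must be positive")
    out = sps.gamma.sf(m, a=2.0, scale=L)
    return float(out) if out.ndim == 0 else out


@dataclass
class IlsModel:
    """Gamma survival model for ILS tract lengths.

    Either give ``r`` and ``t`` (then L = 1/(r*t)), or give ``L`` directly
    when only the expected length is known.
    """

    r: float | None = None
    t: float | None = None
    L: float | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.r is not None and self.t is not None:
            L = expected_tract_length(self.r, self.t)
            if self.L is None:
                self.L = L
            elif abs(self.L - L) > 1e-9 * L:
                raise ValueError("L inconsistent with 1/(r*t)")
        if self.L is None:
            raise ValueError("need either L or both r and t")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")

    def survival(self, m) -> np.ndarray | float:
        return ils_survival(m, self.L)


def filter_tracts(
    tracts: TractSet, model: IlsModel
) -> tuple[TractSet, pd.DataFrame]:
    """Retain tracts too long to be plausible ILS.

    A tract of length m is retained iff survival(m) < alpha.  Returns the
    retained set and a one-row report with counts and length summaries.
    """
    lengths = tracts.lengths.astype(float)
    if len(lengths):
        keep = model.survival(lengths) < model.alpha
    else:
        keep = np.zeros(0, dtype=bool)
    retained = tracts.subset(keep)
    removed = lengths[~keep] if len(lengths) else lengths

    def _summary(x: np.ndarray) -> tuple[float, float]:
        return (float(np.mean(x)), float(np.median(x))) if len(x) else (np.nan, np.nan)

    mean_in, med_in = _summary(lengths)
    mean_keep, med_keep = _summary(lengths[keep] if len(lengths) else lengths)
    mean_rm, med_rm = _summary(removed)
    report = pd.DataFrame(
        [
            dict(
                n_input=len(tracts),
                n_retained=int(keep.sum()),
                n_removed=int((~keep).sum()),
                L=model.L,
                alpha=model.alpha,
                mean_length_input=mean_in,
                median_length_input=med_in,
                mean_length_retained=mean_keep,
                median_length_retained=med_keep,
                mean_length_removed=mean_rm,
                median_length_removed=med_rm,
            )
        ]
    )
    return retained, report


# ---------------------------------------------------------------------------
# D and f3
# ---------------------------------------------------------------------------


@dataclass
class DResult:
    d: float
    abba: float
    baba: float
    se: float | None
    z: float | None
    n_blocks: int


def _pop_freqs(
    panel: HaplotypePanel, popmap: PopulationMap, pops: list[str]
) -> np.ndarray:
    return np.array(
        [panel.alt_frequency(popmap.haplotype_rows(panel, p)) for p in pops]
    )


def _genome_blocks(panel: HaplotypePanel, block_size: int) -> np.ndarray:
    """Assign each site to a contiguous genomic block of ``block_size`` bp."""
    ids = np.zeros(panel.n_sites, dtype=np.int64)
    next_id = 0
    for contig in panel.contigs:
        m = panel.contig == contig
        local = (panel.pos[m] - 1) // block_size
        _, inv = np.unique(local, return_inverse=True)
        ids[m] = inv + next_id
        next_id = ids[m].max() + 1 if m.any() else next_id
    return ids


def _block_jackknife(num: np.ndarray, den: np.ndarray, blocks: np.ndarray):
    """Delete-one-block jackknife SE of a ratio-of-sums estimate."""
    labels = np.unique(blocks)
    n_blocks = len(labels)
    if n_blocks < 3:
        return None, n_blocks
    total_num, total_den = num.sum(), den.sum()
    est = []
    for lab in labels:
        m = blocks == lab
        d = total_den - den[m].sum()
        if d == 0:
            return None, n_blocks
        est.append((total_num - num[m].sum()) / d)
    est = np.asarray(est)
    se = np.sqrt((n_blocks - 1) / n_blocks * ((est - est.mean()) ** 2).sum())
    return float(se), n_blocks


def d_statistic(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    block_size: int = 5_000_000,
) -> DResult:
    """Frequency-based ABBA-BABA D for the tree ((P1, P2), P3), outgroup.

    D > 0 indicates excess allele sharing between P2 and P3.  The standard
    error comes from a delete-one block jackknife over contiguous genomic
    blocks; Z = D / SE is reported when at least 3 blocks exist.
    """
    if len({p1, p2, p3, outgroup}) != 4:
        raise ValueError("the four populations must be distinct")
    f1, f2, f3_, f4 = _pop_freqs(panel, popmap, [p1, p2, p3, outgroup])
    abba = (1 - f1) * f2 * f3_ * (1 - f4)
    baba = f1 * (1 - f2) * f3_ * (1 - f4)
    num, den = abba - baba, abba + baba
    total_den = den.sum()
    if total_den == 0:
        return DResult(np.nan, 0.0, 0.0, None, None, 0)
    d = num.sum() / total_den
    se, n_blocks = _block_jackknife(num, den, _genome_blocks(panel, block_size))
    z = d / se if se else None
    return DResult(
        d=float(d),
        abba=float(abba.sum()),
        baba=float(baba.sum()),
        se=se,
        z=z,
        n_blocks=n_blocks,
    )


@dataclass
class F3Result:
    f3: float
    se: float | None
    z: float | None
    n_blocks: int


def f3_statistic(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    c: str,
    a: str,
    b: str,
    block_size: int = 5_000_000,
) -> F3Result:
    """f3(C; A, B) with the finite-sample bias correction for C.

    Per site: (pC - pA)(pC - pB) - pC(1 - pC)/(nC - 1), averaged over sites
    (nC = number of C haplotypes).  Significantly negative values indicate C
    is admixed between sources related to A and B.
    """
    rows_c = popmap.haplotype_rows(panel, c)
    n_c = len(rows_c)
    if n_c < 2:
        raise ValueError("population C needs >= 2 haplotypes for bias correction")
    pc = panel.alt_frequency(rows_c)
    pa = panel.alt_frequency(popmap.haplotype_rows(panel, a))
    pb = panel.alt_frequency(popmap.haplotype_rows(panel, b))
    per_site = (pc - pa) * (pc - pb) - pc * (1 - pc) / (n_c - 1)
    ones = np.ones_like(per_site)
    value = per_site.mean()
    se, n_blocks = _block_jackknife(
        per_site, ones, _genome_blocks(panel, block_size)
    )
    z = value / se if se else None
    return F3Result(f3=float(value), se=se, z=z, n_blocks=n_blocks)


# ---------------------------------------------------------------------------
# U statistic
# ---------------------------------------------------------------------------


@dataclass
class UStatConfig:
    """Thresholds of the adaptive-introgression U statistic.

    A SNP counts when some allele is at frequency exactly ``w`` among the
    sampled donor haplotypes (default fixed), strictly below ``x`` in the
    source population, and strictly above ``y`` in the target (0.20 for
    U20, 0.50 for U50).
    """

    w: float = 1.0
    x: float = 0.01
    y: float = 0.20

    def __post_init__(self) -> None:
        if not 0 <= self.x < self.y <= self.w <= 1:
            raise ValueError("need 0 <= x < y <= w <= 1")


def u_statistic_windows(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    source: str,
    target: str,
    donor: str,
    grid: WindowGrid,
    config: UStatConfig | None = None,
) -> WindowStats:
    """Per-window count of SNPs matching the U-statistic condition.

    Both alleles are candidates at each site; a site contributes at most
    one count.  Donor fixation is fixation among the sampled donor
    haplotypes.
    """
    config = config or UStatConfig()
    f_src = panel.alt_frequency(popmap.haplotype_rows(panel, source))
    f_tgt = panel.alt_frequency(popmap.haplotype_rows(panel, target))
    f_don = panel.alt_frequency(popmap.haplotype_rows(panel, donor))
    hit = np.zeros(panel.n_sites, dtype=bool)
    for f_d, f_s, f_t in (
        (f_don, f_src, f_tgt),  # alt allele
        (1 - f_don, 1 - f_src, 1 - f_tgt),  # ref allele
    ):
        hit |= (f_d == config.w) & (f_s < config.x) & (f_t > config.y)
    values = np.zeros(len(grid))
    n_snps = np.zeros(len(grid), dtype=np.int64)
    for w, (contig, start, end) in enumerate(grid):
        idx = panel.sites_in_interval(contig, start, end)
        n_snps[w] = len(idx)
        values[w] = float(hit[idx].sum())
    y_tag = int(round(config.y * 100))
    return WindowStats(grid, values, n_snps, name=f"u{y_tag}")


# ---------------------------------------------------------------------------
# ancestry summaries
# ---------------------------------------------------------------------------


def ancestry_proportions(
    tracts: TractSet,
    contig_lengths: dict[str, int],
    popmap: PopulationMap,
) -> tuple[pd.Series, pd.Series]:
    """Donor ancestry fraction per sample and population.

    Per sample: total tract length over both haplotypes divided by twice the
    genome length.  Per population: mean over that population's samples
    (samples with no tracts contribute 0).
    """
    genome = float(sum(contig_lengths.values()))
    if genome <= 0:
        raise ValueError("empty contig length table")
    df = tracts.df
    for row in df.itertuples(index=False):
        if row.contig not in contig_lengths:
            raise ValueError(f"tract contig {row.contig!r} not in contig lengths")
        if row.end > contig_lengths[row.contig]:
            raise ValueError(
                f"tract {row.contig}:{row.start}-{row.end} beyond contig end"
            )
    samples = [s for s, _ in popmap.items()]
    per_sample = pd.Series(0.0, index=pd.Index(samples, name="sample"))
    if len(df):
        sums = (df["end"] - df["start"]).groupby(df["sample"]).sum()
        for s, tot in sums.items():
            if s not in per_sample.index:
                raise ValueError(f"tract sample {s!r} not in population map")
            per_sample[s] = tot / (2.0 * genome)
    pops = pd.Series({s: p for s, p in popmap.items()})
    per_pop = per_sample.groupby(pops).mean()
    per_pop.index.name = "population"
    return per_sample, per_pop


def haplotype_frequency_map(
    panel: HaplotypePanel,
    region: tuple[str, int, int],
    popmap: PopulationMap,
) -> pd.DataFrame:
    """Relative frequency of each distinct haplotype string per population.

    Rows are distinct 0/1 haplotype strings over the region's sites, columns
    are populations; each column sums to 1.
    """
    contig, start, end = region
    cols = panel.sites_in_interval(contig, start, end)
    if len(cols) == 0:
        raise ValueError(f"region {region} contains no sites")
    out: dict[str, pd.Series] = {}
    for pop in popmap.populations:
        rows = popmap.haplotype_rows(panel, pop)
        strings = [
            "".join(map(str, panel.haplotypes[r, cols].tolist())) for r in rows
        ]
        counts = pd.Series(strings).value_counts()
        out[pop] = counts / counts.sum()
    df = pd.DataFrame(out).fillna(0.0)
    df.index.name = "haplotype"
    return df.sort_index()
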