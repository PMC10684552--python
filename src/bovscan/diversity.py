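"""Frequency-based windowed statistics: pi, pi-ratio, FST, PBS, and the
candidate-window selection rules (top-quantile and Z-test).

Window combination follows the ratio-of-sums ("weighted") convention for
FST and a per-bp denominator for pi, matching the defaults of the standard
command-line tools for these statistics.  Windows with fewer SNPs than a
configurable minimum are reported as undefined (NaN) and never selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import HaplotypePanel, PopulationMap, WindowGrid, merge_windows


@dataclass
class WindowStats:
    """Per-window values of one statistic on a shared window grid."""

    grid: WindowGrid
    values: np.ndarray  # NaN where undefined
    n_snps: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_snps = np.asarray(self.n_snps, dtype=np.int64)
        if len(self.values) != len(self.grid) or len(self.n_snps) != len(self.grid):
            raise ValueError("value arrays must match the window grid length")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["n_snps"] = self.n_snps
        df[self.name or "value"] = self.values
        return df


def _check_same_grid(a: WindowStats, b: WindowStats) -> None:
    if a.grid.windows != b.grid.windows:
        raise ValueError("window grids do not match")


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


def site_pi(panel: HaplotypePanel, rows: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity 2*p*(1-p)*n/(n-1) over haplotype rows.

    Equals the average pairwise difference between the n haplotypes.
    """
    n = len(rows)
    if n < 2:
        raise ValueError("need >= 2 haplotypes for pi")
    p = panel.haplotypes[rows].mean(axis=0)
    return 2.0 * p * (1.0 - p) * n / (n - 1.0)


def windowed_pi(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    population: str,
    grid: WindowGrid,
    min_snps: int = 0,
) -> WindowStats:
    """Windowed pi per bp: sum of per-site pi over window length."""
    rows = popmap.haplotype_rows(panel, population)
    pi = site_pi(panel, rows)
    values = np.full(len(grid), np.nan)
    n_snps = np.zeros(len(grid), dtype=np.int64)
    for w, (contig, start, end) in enumerate(grid):
        idx = panel.sites_in_interval(contig, start, end)
        n_snps[w] = len(idx)
        if len(idx) >= min_snps:
            values[w] = pi[idx].sum() / (end - start)
    return WindowStats(grid, values, n_snps, name=f"pi_{population}")


def pi_ratio(pi_a: WindowStats, pi_b: WindowStats) -> WindowStats:
    """Elementwise pi_a / pi_b; undefined where pi_b is 0 or either is NaN."""
    _check_same_grid(pi_a, pi_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = pi_a.values / pi_b.values
    values[pi_b.values == 0] = np.nan
    return WindowStats(
        pi_a.grid,
        values,
        np.minimum(pi_a.n_snps, pi_b.n_snps),
        name=f"{pi_a.name}_over_{pi_b.name}",
    )


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------


def _pop_site_summaries(panel: HaplotypePanel, rows_per_pop: list[np.ndarray]):
    """Per population: diploid count, alt frequency, observed het frequency."""
    ns, ps, hs = [], [], []
    for rows in rows_per_pop:
        if len(rows) < 2 or len(rows) % 2:
            raise ValueError("each population needs >= 1 diploid (2 haplotypes/sample)")
        h = panel.haplotypes[rows]
        a0 = h[0::2]
        a1 = h[1::2]
        ns.append(a0.shape[0])
        ps.append(h.mean(axis=0))
        hs.append((a0 != a1).mean(axis=0))
    return np.array(ns, dtype=float), np.array(ps, dtype=float), np.array(hs, dtype=float)


def wc_components(
    panel: HaplotypePanel, popmap: PopulationMap, populations: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site variance components (a, b, c).

    a is the among-population component, b the among-individual-within-
    population component, c the within-individual component; per-site
    FST = a / (a + b + c), windowed FST = sum(a) / sum(a + b + c).
    """
    rows_per_pop = [popmap.haplotype_rows(panel, p) for p in populations]
    n, p, h = _pop_site_summaries(panel, rows_per_pop)  # (r, S) each except n (r,)
    r = float(len(populations))
    if r < 2:
        raise ValueError("need >= 2 populations")
    n = n[:, None]
    n_bar = n.mean(axis=0)  # scalar -> (1,) broadcast over sites
    n_c = (r * n_bar - (n**2).sum(axis=0) / (r * n_bar)) / (r - 1.0)
    p_bar = (n * p).sum(axis=0) / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1.0) * n_bar)
    h_bar = (n * h).sum(axis=0) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1.0))
        * (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar)
        - s2 * (r - 1.0) / r
        - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    return a, b, c


def hudson_components(
    panel: HaplotypePanel, popmap: PopulationMap, populations: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Hudson estimator per-site numerator and denominator (two populations)."""
    if len(populations) != 2:
        raise ValueError("Hudson estimator is defined for two populations")
    rows_per_pop = [popmap.haplotype_rows(panel, p) for p in populations]
    m = np.array([len(r) for r in rows_per_pop], dtype=float)  # haploid sizes
    p = np.array([panel.haplotypes[r].mean(axis=0) for r in rows_per_pop])
    p1, p2 = p
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (m[0] - 1.0)
        - p2 * (1 - p2) / (m[1] - 1.0)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst_windowed(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    grid: WindowGrid,
    estimator: str = "weir-cockerham",
    min_snps: int = 10,
) -> WindowStats:
    """Windowed FST between two populations by ratio of sums.

    Negative window values (no between-population variance in excess of
    sampling noise) are reported as computed, not clipped.
    """
    if estimator == "weir-cockerham":
        a, b, c = wc_components(panel, popmap, [pop_a, pop_b])
        num, den = a, a + b + c
    elif estimator == "hudson":
        num, den = hudson_components(panel, popmap, [pop_a, pop_b])
    else:
        raise ValueError(f"unknown FST estimator {estimator!r}")
    values = np.full(len(grid), np.nan)
    n_snps = np.zeros(len(grid), dtype=np.int64)
    for w, (contig, start, end) in enumerate(grid):
        idx = panel.sites_in_interval(contig, start, end)
        n_snps[w] = len(idx)
        if len(idx) < min_snps:
            continue
        d = den[idx].sum()
        if d != 0:
            values[w] = num[idx].sum() / d
    return WindowStats(grid, values, n_snps, name=f"fst_{pop_a}_{pop_b}")


def site_fst(
    panel: HaplotypePanel, popmap: PopulationMap, pop_a: str, pop_b: str
) -> np.ndarray:
    """Per-site Weir-Cockerham FST a/(a+b+c); NaN where both pops monomorphic."""
    a, b, c = wc_components(panel, popmap, [pop_a, pop_b])
    den = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den != 0, a / den, np.nan)


# ---------------------------------------------------------------------------
# PBS
# ---------------------------------------------------------------------------

_FST_CLAMP_HI = 1.0 - 1e-6


def _branch_transform(fst: np.ndarray) -> np.ndarray:
    clamped = np.clip(fst, 0.0, _FST_CLAMP_HI)
    return -np.log(1.0 - clamped)


def pbs(
    fst_tr: WindowStats, fst_to: WindowStats, fst_ro: WindowStats
) -> WindowStats:
    """Population branch statistic of the target population T.

    PBS = (T(F_TR) + T(F_TO) - T(F_RO)) / 2 with T(x) = -ln(1-x), where R is
    the reference and O the outgroup; FST values are clamped to
    [0, 1 - 1e-6] before the log transform so the branch length is finite.
    Undefined wherever any component window is undefined.
    """
    _check_same_grid(fst_tr, fst_to)
    _check_same_grid(fst_tr, fst_ro)
    values = (
        _branch_transform(fst_tr.values)
        + _branch_transform(fst_to.values)
        - _branch_transform(fst_ro.values)
    ) / 2.0
    values[~(fst_tr.defined & fst_to.defined & fst_ro.defined)] = np.nan
    n_snps = np.minimum(
        np.minimum(fst_tr.n_snps, fst_to.n_snps), fst_ro.n_snps
    )
    return WindowStats(fst_tr.grid, values, n_snps, name="pbs")


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------


def empirical_pvalues_z(values: np.ndarray, direction: str = "high") -> np.ndarray:
    """One-sided Z-test p-values against the genome-wide window distribution.

    Values are standardized over defined windows; p is the upper-tail normal
    probability.  ``direction="low"`` flips the sign first, for statistics
    where the signal is a low value (e.g. the pi-ratio in a swept
    population).
    """
    values = np.asarray(values, dtype=float)
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    x = -values if direction == "low" else values.copy()
    defined = ~np.isnan(x)
    if defined.sum() < 2:
        raise ValueError("need >= 2 defined windows")
    mean = x[defined].mean()
    sd = x[defined].std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance across windows; Z-test undefined")
    p = np.full(values.shape, np.nan)
    p[defined] = sps.norm.sf((x[defined] - mean) / sd)
    return p


def top_fraction(
    values: np.ndarray, q: float = 0.01, direction: str = "high"
) -> np.ndarray:
    """Boolean mask of the most extreme ceil(q * n_defined) windows.

    Ties at the threshold value are all included; undefined windows are
    never selected.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    values = np.asarray(values, dtype=float)
    x = -values if direction == "low" else values
    defined = ~np.isnan(x)
    n_def = int(defined.sum())
    sel = np.zeros(values.shape, dtype=bool)
    if n_def == 0:
        return sel
    k = int(np.ceil(q * n_def))
    threshold = np.sort(x[defined])[::-1][k - 1]
    sel[defined] = x[defined] >= threshold
    return sel


def intersect_candidates(
    grid: WindowGrid, selections: list[np.ndarray]
) -> list[tuple[str, int, int]]:
    """Windows selected by every method, merged to nonoverlapping regions."""
    if not selections:
        raise ValueError("no selections given")
    joint = np.logical_and.reduce([np.asarray(s, dtype=bool) for s in selections])
    chosen = [w for w, keep in zip(grid, joint) if keep]
    if not chosen:
        return []
    return merge_windows(chosen)
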