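"""Extended-haplotype-homozygosity statistics on phased panels.

EHH at a marker m for an allele class is the probability that two randomly
drawn class haplotypes are identical at every site from the core to m:
sum over identity groups g of C(n_g, 2) / C(n, 2).  iHH integrates the EHH
curve over physical distance (trapezoid rule, bp); iHS is the log-ratio of
ancestral and derived iHH standardized within derived-allele-frequency
bins; XP-EHH is the log-ratio between two populations (whole population as
the allele class) standardized genome-wide.

Defaults (EHH cutoff 0.05, 200 kb maximum marker gap, MAF >= 0.05 for
iHS cores, 2% frequency bins) follow the common selection-scan tooling.
Curves that truncate at a large gap are kept but flagged rather than
dropped, so the contribution of every core is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import UNKNOWN, HaplotypePanel, Polarization, PopulationMap, WindowGrid
from .diversity import WindowStats

EHH_CUTOFF = 0.05
MAX_GAP_BP = 200_000


@dataclass
class EhhCurve:
    """EHH decay curve around one core site for one allele class."""

    core_index: int
    core_pos: int
    n_carriers: int
    left_pos: np.ndarray  # positions walking away from the core (descending)
    left_ehh: np.ndarray
    right_pos: np.ndarray
    right_ehh: np.ndarray
    left_truncation: str  # "cutoff" | "gap" | "chrom_end"
    right_truncation: str


def _group_codes(column: np.ndarray, groups: np.ndarray) -> np.ndarray:
    _, inv = np.unique(groups * 2 + column, return_inverse=True)
    return inv


def _homozygosity(groups: np.ndarray) -> float:
    _, counts = np.unique(groups, return_counts=True)
    n = groups.size
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _extend(
    h: np.ndarray,
    pos: np.ndarray,
    core: int,
    lo: int,
    hi: int,
    direction: int,
    cutoff: float,
    max_gap: int,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Walk from the core in one direction, splitting identity groups.

    h is the (n_carriers, S) matrix, [lo, hi] the inclusive site-index range
    of the core's contig.  The first marker with EHH below ``cutoff`` is
    included, then the walk stops.
    """
    groups = _group_codes(h[:, core], np.zeros(h.shape[0], dtype=np.int64))
    out_pos, out_ehh = [], []
    j = core
    reason = "chrom_end"
    while True:
        j += direction
        if j < lo or j > hi:
            break
        if abs(int(pos[j]) - int(pos[j - direction])) > max_gap:
            reason = "gap"
            break
        groups = _group_codes(h[:, j], groups)
        e = _homozygosity(groups)
        out_pos.append(int(pos[j]))
        out_ehh.append(e)
        if e < cutoff:
            reason = "cutoff"
            break
    return np.asarray(out_pos), np.asarray(out_ehh), reason


def ehh(
    panel: HaplotypePanel,
    rows: np.ndarray,
    core_index: int,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP_BP,
) -> EhhCurve:
    """EHH curve for the allele class given by haplotype ``rows``.

    ``rows`` typically holds the carriers of one core allele within a
    population (iHS) or the whole population (XP-EHH).  Grouping includes
    the core site itself; the curve starts at the core with EHH = 1.
    """
    if not panel.phased:
        raise ValueError("EHH requires a phased panel")
    rows = np.asarray(rows, dtype=np.intp)
    if rows.size < 2:
        raise ValueError("EHH needs >= 2 carrier haplotypes")
    contig = panel.contig[core_index]
    block = np.flatnonzero(panel.contig == contig)
    lo, hi = int(block[0]), int(block[-1])
    h = panel.haplotypes[rows]
    lp, le, lt = _extend(h, panel.pos, core_index, lo, hi, -1, cutoff, max_gap)
    rp, re, rt = _extend(h, panel.pos, core_index, lo, hi, +1, cutoff, max_gap)
    return EhhCurve(
        core_index=core_index,
        core_pos=int(panel.pos[core_index]),
        n_carriers=int(rows.size),
        left_pos=lp,
        left_ehh=le,
        right_pos=rp,
        right_ehh=re,
        left_truncation=lt,
        right_truncation=rt,
    )


def ihh(curve: EhhCurve) -> float:
    """Trapezoidal integral of the EHH curve over bp, both directions summed."""
    total = 0.0
    for pos, vals in ((curve.left_pos, curve.left_ehh), (curve.right_pos, curve.right_ehh)):
        prev_pos, prev_ehh = curve.core_pos, 1.0
        for p, e in zip(pos, vals):
            total += abs(int(p) - int(prev_pos)) * (e + prev_ehh) / 2.0
            prev_pos, prev_ehh = p, e
    return total


@dataclass
class ScoreTable:
    """Per-site haplotype scores (iHS or XP-EHH) with inclusion flags."""

    df: pd.DataFrame  # site, contig, pos, freq, raw, std, included, flag
    statistic: str
    normalization: str

    @property
    def included(self) -> pd.DataFrame:
        return self.df[self.df["included"]]


def _site_table(records: list[dict], statistic: str, normalization: str) -> ScoreTable:
    cols = ["site", "contig", "pos", "freq", "raw", "std", "included", "flag"]
    df = pd.DataFrame(records, columns=cols)
    return ScoreTable(df=df, statistic=statistic, normalization=normalization)


def ihs(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    population: str,
    polarization: Polarization,
    min_maf: float = 0.05,
    n_bins: int = 50,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP_BP,
) -> ScoreTable:
    """Integrated-haplotype score per polarized site.

    Raw score = ln(iHH_ancestral / iHH_derived); a completed sweep of the
    derived allele gives a strongly negative score.  Standardization is
    within derived-allele-frequency bins (default 50 bins of 2%).  Sites
    with unknown ancestral state, MAF below ``min_maf``, fewer than two
    carriers of either allele, or a zero iHH are excluded.
    """
    if not panel.phased:
        raise ValueError("iHS requires a phased panel")
    rows = popmap.haplotype_rows(panel, population)
    h = panel.haplotypes[rows]
    records = []
    for j in range(panel.n_sites):
        anc = polarization.state[j]
        if anc == UNKNOWN:
            continue
        der = 1 - anc
        daf = float((h[:, j] == der).mean())
        rec = dict(
            site=j,
            contig=panel.contig[j],
            pos=int(panel.pos[j]),
            freq=daf,
            raw=np.nan,
            std=np.nan,
            included=False,
            flag="",
        )
        if min(daf, 1 - daf) < min_maf:
            rec["flag"] = "maf"
            records.append(rec)
            continue
        anc_rows = rows[h[:, j] == anc]
        der_rows = rows[h[:, j] == der]
        if len(anc_rows) < 2 or len(der_rows) < 2:
            rec["flag"] = "carriers"
            records.append(rec)
            continue
        c_anc = ehh(panel, anc_rows, j, cutoff, max_gap)
        c_der = ehh(panel, der_rows, j, cutoff, max_gap)
        ihh_a, ihh_d = ihh(c_anc), ihh(c_der)
        if ihh_a == 0 or ihh_d == 0:
            rec["flag"] = "zero_ihh"
            records.append(rec)
            continue
        gap = "gap" in (
            c_anc.left_truncation,
            c_anc.right_truncation,
            c_der.left_truncation,
            c_der.right_truncation,
        )
        rec["raw"] = float(np.log(ihh_a / ihh_d))
        rec["included"] = True
        rec["flag"] = "gap_truncated" if gap else ""
        records.append(rec)

    table = _site_table(records, "ihs", f"{n_bins} derived-frequency bins")
    df = table.df
    inc = df["included"].to_numpy()
    if inc.any():
        bins = np.clip(
            (df.loc[inc, "freq"].to_numpy() * n_bins).astype(int), 0, n_bins - 1
        )
        raw = df.loc[inc, "raw"].to_numpy()
        std = np.full(raw.shape, np.nan)
        keep = np.ones(raw.shape, dtype=bool)
        for b in np.unique(bins):
            m = bins == b
            if m.sum() < 2 or raw[m].std(ddof=0) == 0:
                keep[m] = False
                continue
            std[m] = (raw[m] - raw[m].mean()) / raw[m].std(ddof=0)
        idx = df.index[inc]
        df.loc[idx, "std"] = std
        df.loc[idx[~keep], "included"] = False
        df.loc[idx[~keep], "flag"] = "bin"
    return table


def window_prop_abs_ihs(
    table: ScoreTable, grid: WindowGrid, threshold: float = 2.0
) -> WindowStats:
    """Per window: fraction of scored sites with |standardized iHS| >= threshold."""
    df = table.included
    pos0 = df["pos"].to_numpy() - 1  # 0-based
    contigs = df["contig"].to_numpy()
    hits = np.abs(df["std"].to_numpy()) >= threshold
    values = np.full(len(grid), np.nan)
    n_snps = np.zeros(len(grid), dtype=np.int64)
    for w, (contig, start, end) in enumerate(grid):
        m = (contigs == contig) & (pos0 >= start) & (pos0 < end)
        n = int(m.sum())
        n_snps[w] = n
        if n:
            values[w] = hits[m].mean()
    return WindowStats(grid, values, n_snps, name="prop_abs_ihs")


def xpehh(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    min_maf: float = 0.0,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP_BP,
) -> ScoreTable:
    """Cross-population EHH score per site, standardized genome-wide.

    Raw score = ln(iHH_A / iHH_B) with the full haplotype panel of each
    population as the allele class; positive standardized scores mean
    longer haplotypes (ongoing/recent sweep) in population A.
    """
    if not panel.phased:
        raise ValueError("XP-EHH requires a phased panel")
    rows_a = popmap.haplotype_rows(panel, pop_a)
    rows_b = popmap.haplotype_rows(panel, pop_b)
    pooled = np.concatenate([rows_a, rows_b])
    records = []
    for j in range(panel.n_sites):
        freq = float(panel.haplotypes[pooled, j].mean())
        rec = dict(
            site=j,
            contig=panel.contig[j],
            pos=int(panel.pos[j]),
            freq=freq,
            raw=np.nan,
            std=np.nan,
            included=False,
            flag="",
        )
        if min(freq, 1 - freq) < min_maf:
            rec["flag"] = "maf"
            records.append(rec)
            continue
        c_a = ehh(panel, rows_a, j, cutoff, max_gap)
        c_b = ehh(panel, rows_b, j, cutoff, max_gap)
        ihh_a, ihh_b = ihh(c_a), ihh(c_b)
        if ihh_a == 0 or ihh_b == 0:
            rec["flag"] = "zero_ihh"
            records.append(rec)
            continue
        gap = "gap" in (
            c_a.left_truncation,
            c_a.right_truncation,
            c_b.left_truncation,
            c_b.right_truncation,
        )
        rec["raw"] = float(np.log(ihh_a / ihh_b))
        rec["included"] = True
        rec["flag"] = "gap_truncated" if gap else ""
        records.append(rec)

    table = _site_table(records, "xpehh", "single global bin")
    df = table.df
    inc = df["included"].to_numpy()
    if inc.any():
        raw = df.loc[inc, "raw"].to_numpy()
        sd = raw.std(ddof=0)
        if sd == 0:
            df.loc[inc, "std"] = 0.0
        else:
            df.loc[inc, "std"] = (raw - raw.mean()) / sd
    return table


def windowed_mean_score(table: ScoreTable, grid: WindowGrid) -> WindowStats:
    """Mean standardized score per window (the windowed XP-EHH summary)."""
    df = table.included
    pos0 = df["pos"].to_numpy() - 1
    contigs = df["contig"].to_numpy()
    std = df["std"].to_numpy()
    values = np.full(len(grid), np.nan)
    n_snps = np.zeros(len(grid), dtype=np.int64)
    for w, (contig, start, end) in enumerate(grid):
        m = (contigs == contig) & (pos0 >= start) & (pos0 < end)
        n = int(m.sum())
        n_snps[w] = n
        if n:
            values[w] = std[m].mean()
    return WindowStats(grid, values, n_snps, name=f"mean_{table.statistic}")
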