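"""Core data model: phased haplotype panels, population maps, windows, genes, tracts.

Coordinate conventions
----------------------
Variant site positions are stored 1-based, as in VCF.  Every interval object
(windows, gene records, ancestry tracts, merged candidate regions) is 0-based
half-open, as in BED.  Conversion between the two happens only at I/O
boundaries and in the single helper :func:`sites_in_interval`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

UNKNOWN = -1  # ancestral state code for sites the outgroup does not polarize


class PanelError(ValueError):
    """Raised when panel data violates a structural invariant."""


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotype matrix over variant sites.

    Attributes
    ----------
    contig : array of str, per site
    pos : array of int, 1-based positions, strictly increasing within a contig
    ref, alt : arrays of allele strings
    haplotypes : (2N, S) int8 matrix, 0 = ref allele, 1 = alt allele.
        Rows 2*i and 2*i+1 are the two haplotypes of sample ``samples[i]``.
    samples : sequence of N sample ids
    phased : whether rows are true haplotypes; haplotype statistics
        (EHH family) refuse unphased panels.
    contig_lengths : optional contig -> length (bp) map
    """

    contig: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray
    samples: list[str]
    phased: bool = True
    contig_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.contig = np.asarray(self.contig, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.samples = list(self.samples)
        if self.haplotypes.ndim != 2:
            raise PanelError("haplotype matrix must be 2-D")
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise PanelError(
                f"matrix has {self.haplotypes.shape[0]} rows for "
                f"{len(self.samples)} samples (need exactly 2 per sample)"
            )
        if self.haplotypes.shape[1] != self.pos.shape[0]:
            raise PanelError("matrix column count does not match site count")
        if self.haplotypes.size and not np.isin(self.haplotypes, (0, 1)).all():
            raise PanelError("haplotype entries must be 0 or 1 (biallelic, no missing)")
        for ctg in dict.fromkeys(self.contig):
            p = self.pos[self.contig == ctg]
            if p.size > 1 and not (np.diff(p) > 0).all():
                i = int(np.flatnonzero(np.diff(p) <= 0)[0])
                raise PanelError(
                    f"positions not strictly increasing on {ctg} near {p[i + 1]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def contigs(self) -> list[str]:
        return list(dict.fromkeys(self.contig))

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise PanelError(f"sample {sample!r} not in panel") from None

    def haplotype_rows(self, samples: Iterable[str]) -> np.ndarray:
        """Row indices of the haplotypes belonging to ``samples``."""
        rows = []
        for s in samples:
            i = self.sample_index(s)
            rows.extend((2 * i, 2 * i + 1))
        return np.asarray(rows, dtype=np.intp)

    def site_mask(self, mask: np.ndarray) -> "HaplotypePanel":
        """New panel restricted to sites where ``mask`` is True (order kept)."""
        mask = np.asarray(mask, dtype=bool)
        return HaplotypePanel(
            contig=self.contig[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            haplotypes=self.haplotypes[:, mask],
            samples=self.samples,
            phased=self.phased,
            contig_lengths=self.contig_lengths,
        )

    def sites_in_interval(self, contig: str, start: int, end: int) -> np.ndarray:
        """Site indices with 0-based position in the half-open [start, end)."""
        return np.flatnonzero(
            (self.contig == contig) & (self.pos - 1 >= start) & (self.pos - 1 < end)
        )

    def alt_frequency(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Alt-allele frequency per site over the given haplotype rows."""
        h = self.haplotypes if rows is None else self.haplotypes[rows]
        return h.mean(axis=0)

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            contig=self.contig.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            haplotypes=self.haplotypes.copy(),
            samples=list(self.samples),
            phased=self.phased,
            contig_lengths=dict(self.contig_lengths) if self.contig_lengths else None,
        )


class PopulationMap:
    """Mapping from sample id to population label."""

    def __init__(self, mapping: Mapping[str, str]):
        if not mapping:
            raise PanelError("population map is empty")
        self._map = dict(mapping)

    def __getitem__(self, sample: str) -> str:
        return self._map[sample]

    def __contains__(self, sample: str) -> bool:
        return sample in self._map

    def __len__(self) -> int:
        return len(self._map)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self._map.values()))

    def samples(self, population: str) -> list[str]:
        out = [s for s, p in self._map.items() if p == population]
        if not out:
            raise PanelError(f"population {population!r} has no samples")
        return out

    def haplotype_rows(self, panel: HaplotypePanel, population: str) -> np.ndarray:
        return panel.haplotype_rows(self.samples(population))

    def validate_against(self, panel: HaplotypePanel) -> None:
        missing = [s for s in self._map if s not in panel.samples]
        if missing:
            raise PanelError(f"mapped samples absent from panel: {missing[:5]}")

    def items(self):
        return self._map.items()


@dataclass
class Polarization:
    """Per-site ancestral state: 0 (ref ancestral), 1 (alt ancestral), -1 unknown."""

    state: np.ndarray

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.int8)
        if not np.isin(self.state, (0, 1, UNKNOWN)).all():
            raise PanelError("polarization states must be 0, 1 or -1")

    @property
    def known(self) -> np.ndarray:
        return self.state != UNKNOWN


@dataclass
class WindowGrid:
    """Sliding windows (contig, start, end), 0-based half-open."""

    windows: list[tuple[str, int, int]]
    size: int
    step: int

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.windows, columns=["contig", "start", "end"])


@dataclass
class GeneRecord:
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    name: str


@dataclass
class GeneSet:
    genes: list[GeneRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


TRACT_COLUMNS = ["contig", "start", "end", "sample", "hap", "donor", "prob"]


class TractSet:
    """Per-haplotype local-ancestry segments with a donor label.

    Backed by a DataFrame with columns contig, start, end (0-based half-open),
    sample, hap (0 or 1), donor, prob.  Zero-length tracts are dropped.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=TRACT_COLUMNS)
        df = df.copy()
        if "prob" not in df.columns:
            df["prob"] = 1.0
        missing = [c for c in TRACT_COLUMNS if c not in df.columns]
        if missing:
            raise PanelError(f"tract table missing columns: {missing}")
        df = df[TRACT_COLUMNS].reset_index(drop=True)
        if len(df):
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            df["hap"] = df["hap"].astype(np.int64)
            if (df["end"] < df["start"]).any():
                raise PanelError("tract with end < start")
            if not df["hap"].isin((0, 1)).all():
                raise PanelError("tract hap index must be 0 or 1")
            n0 = len(df)
            df = df[df["end"] > df["start"]].reset_index(drop=True)
            if len(df) < n0:
                logger.warning("dropped %d zero-length tracts", n0 - len(df))
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def subset(self, mask) -> "TractSet":
        return TractSet(self.df[np.asarray(mask, dtype=bool)])


# ---------------------------------------------------------------------------
# interval / frequency operations
# ---------------------------------------------------------------------------


def maf_filter(
    panel: HaplotypePanel, popmap: PopulationMap | None = None, min_maf: float = 0.01
) -> HaplotypePanel:
    """Drop sites with overall minor-allele frequency below ``min_maf``.

    Frequency is computed over all haplotypes in the panel; ``popmap`` is
    accepted for interface symmetry but does not change the pooled frequency.
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    if min_maf == 0 or panel.n_sites == 0:
        return panel
    p = panel.alt_frequency()
    keep = np.minimum(p, 1 - p) >= min_maf
    return panel.site_mask(keep)


def polarize_by_outgroup(
    panel: HaplotypePanel, popmap: PopulationMap, outgroup: str
) -> Polarization:
    """Ancestral allele = the allele fixed in the outgroup; unknown otherwise."""
    rows = popmap.haplotype_rows(panel, outgroup)
    h = panel.haplotypes[rows]
    state = np.full(panel.n_sites, UNKNOWN, dtype=np.int8)
    state[(h == 0).all(axis=0)] = 0
    state[(h == 1).all(axis=0)] = 1
    return Polarization(state)


def make_windows(
    contig_lengths: Mapping[str, int],
    size: int = 50_000,
    step: int = 20_000,
    keep_tail: bool = False,
) -> WindowGrid:
    """Sliding-window grid: ``size`` bp windows advanced by ``step`` bp.

    By default only windows fully inside the contig are emitted; with
    ``keep_tail`` one truncated terminal window is appended per contig so the
    union of windows covers every base.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if not 0 < step <= size:
        raise ValueError("step must satisfy 0 < step <= size")
    windows: list[tuple[str, int, int]] = []
    for contig, length in contig_lengths.items():
        start = 0
        last_end = 0
        while start + size <= length:
            windows.append((contig, start, start + size))
            last_end = start + size
            start += step
        if keep_tail and last_end < length:
            windows.append((contig, start, length))
    return WindowGrid(windows=windows, size=size, step=step)


def merge_windows(
    windows: Iterable[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Merge overlapping/adjacent intervals into sorted disjoint regions."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in windows:
        by_contig.setdefault(contig, []).append((int(start), int(end)))
    merged: list[tuple[str, int, int]] = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:  # overlap or abut
                cur_e = max(cur_e, e)
            else:
                merged.append((contig, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((contig, cur_s, cur_e))
    return merged


def annotate_regions(
    regions: Iterable[tuple[str, int, int]], genes: GeneSet
) -> list[tuple[tuple[str, int, int], list[str]]]:
    """Genes whose interval intersects each region by at least 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if g.end > g.start:
            trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g.name)
    out = []
    known_contigs = set(trees)
    for region in regions:
        contig, start, end = region
        if contig not in known_contigs:
            logger.warning("region contig %s absent from annotation", contig)
            out.append((region, []))
            continue
        hits = sorted(
            {iv.data for iv in trees[contig].overlap(start, end)},
        )
        out.append((region, hits))
    return out
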