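"""Synthetic multi-population haplotype panels with recorded ground truth.

The generator draws ancestral allele frequencies from a Beta law and
population frequencies from the Balding-Nichols model, then plants hard
sweeps (a core haplotype copied over a fraction of a population) and
donor-introgression tracts (donor segments copied into recipient
haplotypes).  Balding-Nichols was chosen over a full coalescent because it
gives the Weir-Cockerham estimator a closed-form expectation (mean FST ~ F),
which calibration tests exploit.  The base model has no linkage
disequilibrium: LD enters only through planted sweeps and tracts, so
haplotype-homozygosity nulls are analytic (EHH decays immediately off-core).

ILS tract lengths follow the Gamma(shape 2, rate 1/L) law with
L = 1/(r*t), the expected length of a segment shared by incomplete lineage
sorting between species whose branches sum to t generations at
per-bp recombination rate r.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .panel import (
    TRACT_COLUMNS,
    HaplotypePanel,
    PopulationMap,
    TractSet,
)


@dataclass
class PopulationSpec:
    """One simulated population.

    F is the Balding-Nichols drift parameter in [0, 1): the population's
    allele frequency at a site with ancestral frequency p is drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F), so E[freq] = p and Var = F p(1-p).
    ``private_fixed_density`` plants additional sites (per bp) fixed for the
    alt allele in this population and absent everywhere else, emulating the
    private variation of a deeply diverged donor species.
    """

    label: str
    n_diploid: int
    F: float = 0.0
    private_fixed_density: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.F < 1:
            raise ValueError("F must be in [0, 1)")
        if self.n_diploid < 1:
            raise ValueError("n_diploid must be >= 1")


@dataclass
class SimConfig:
    """Parameters of a synthetic panel.

    Defaults give a 10 Mb contig at one SNP per 500 bp with a mildly
    U-shaped ancestral frequency spectrum Beta(0.8, 0.8).
    """

    contig: str = "chr1"
    contig_length: int = 10_000_000
    n_sites: int = 20_000
    populations: list[PopulationSpec] = field(default_factory=list)
    beta_a: float = 0.8
    beta_b: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.populations = [
            PopulationSpec(**p) if isinstance(p, dict) else p for p in self.populations
        ]
        if self.contig_length < 1 or self.n_sites < 1:
            raise ValueError("contig_length and n_sites must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    def popmap(self) -> PopulationMap:
        mapping = {}
        for spec in self.populations:
            for i in range(spec.n_diploid):
                mapping[f"{spec.label}_{i}"] = spec.label
        return PopulationMap(mapping)


@dataclass
class SweepTruth:
    contig: str
    start: int
    end: int
    population: str
    core_frequency: float


@dataclass
class SimTruth:
    """Ground truth recorded by the generator for recovery tests."""

    config: SimConfig
    sweeps: list[SweepTruth] = field(default_factory=list)
    tracts: TractSet = field(default_factory=TractSet)


def simulate_panel(config: SimConfig) -> tuple[HaplotypePanel, SimTruth]:
    """Draw a phased panel under the Balding-Nichols model.

    Deterministic given ``config.seed``.  Sites are placed uniformly at
    random (without replacement) on the contig; haplotypes are i.i.d.
    Bernoulli draws from each population's site frequency.
    """
    rng = np.random.default_rng(config.seed)
    if not config.populations:
        raise ValueError("config.populations is empty")

    n_priv = {
        spec.label: int(round(spec.private_fixed_density * config.contig_length))
        for spec in config.populations
    }
    total_sites = config.n_sites + sum(n_priv.values())
    if total_sites > config.contig_length:
        raise ValueError("more sites than base pairs")
    pos = np.sort(
        rng.choice(config.contig_length, size=total_sites, replace=False)
    ).astype(np.int64) + 1  # 1-based
    # assign which sites are private to which population
    kind = np.zeros(total_sites, dtype=np.int64)  # 0 = shared BN site
    priv_labels = [spec.label for spec in config.populations if n_priv[spec.label]]
    if priv_labels:
        idx = rng.permutation(total_sites)
        offset = 0
        for k, label in enumerate(priv_labels, start=1):
            take = n_priv[label]
            kind[idx[offset : offset + take]] = k
            offset += take

    p_anc = rng.beta(config.beta_a, config.beta_b, size=total_sites)
    hap_blocks = []
    for spec in config.populations:
        if spec.F > 0:
            a = p_anc * (1 - spec.F) / spec.F
            b = (1 - p_anc) * (1 - spec.F) / spec.F
            p_pop = rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))
        else:
            p_pop = p_anc
        h = (
            rng.random((2 * spec.n_diploid, total_sites)) < p_pop[None, :]
        ).astype(np.int8)
        hap_blocks.append(h)

    # overwrite private sites: fixed alt in owner, ref elsewhere
    for k, label in enumerate(priv_labels, start=1):
        mask = kind == k
        for spec, h in zip(config.populations, hap_blocks):
            h[:, mask] = 1 if spec.label == label else 0

    haplotypes = np.vstack(hap_blocks)
    samples = [
        f"{spec.label}_{i}"
        for spec in config.populations
        for i in range(spec.n_diploid)
    ]
    panel = HaplotypePanel(
        contig=np.full(total_sites, config.contig, dtype=object),
        pos=pos,
        ref=np.full(total_sites, "A", dtype=object),
        alt=np.full(total_sites, "G", dtype=object),
        haplotypes=haplotypes,
        samples=samples,
        phased=True,
        contig_lengths={config.contig: config.contig_length},
    )
    return panel, SimTruth(config=config)


def plant_sweep(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    region: tuple[str, int, int],
    population: str,
    beta: float,
    seed: int,
    truth: SimTruth | None = None,
) -> tuple[HaplotypePanel, SweepTruth]:
    """Plant a hard sweep: copy one core haplotype over a fraction ``beta``
    of the population's haplotypes inside ``region`` (0-based half-open).

    Returns a modified copy of the panel and the truth record (also appended
    to ``truth`` when given).
    """
    if not 0.5 < beta <= 1:
        raise ValueError("core frequency beta must be in (0.5, 1]")
    contig, start, end = region
    length = (panel.contig_lengths or {}).get(contig)
    if start < 0 or (length is not None and end > length) or end <= start:
        raise ValueError(f"sweep region {region} outside contig")
    rng = np.random.default_rng(seed)
    rows = popmap.haplotype_rows(panel, population)
    cols = panel.sites_in_interval(contig, start, end)
    out = panel.copy()
    core_row = rng.choice(rows)
    n_carriers = int(np.floor(beta * len(rows)))
    carriers = rng.choice(rows, size=n_carriers, replace=False)
    core = panel.haplotypes[core_row, cols]
    for r in carriers:
        out.haplotypes[r, cols] = core
    rec = SweepTruth(
        contig=contig, start=start, end=end, population=population, core_frequency=beta
    )
    if truth is not None:
        truth.sweeps.append(rec)
    return out, rec


def plant_introgression(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    recipient: str,
    donor: str,
    mean_length: float,
    tracts_per_haplotype: int,
    seed: int,
    carrier_fraction: float | None = None,
    truth: SimTruth | None = None,
) -> tuple[HaplotypePanel, TractSet]:
    """Copy donor segments into recipient haplotypes and record the truth.

    Tract lengths are Exponential with mean ``mean_length``; start positions
    are uniform on the contig.  By default each recipient haplotype receives
    ``tracts_per_haplotype`` independent tracts.  With ``carrier_fraction``
    set, ``tracts_per_haplotype`` intervals are sampled once and each is
    copied (from a single donor haplotype) into that fraction of recipient
    haplotypes, giving the tract an appreciable population frequency — the
    regime an adaptive-introgression scan is meant to detect.
    """
    if recipient == donor:
        raise ValueError("recipient and donor populations must differ")
    if mean_length <= 0:
        raise ValueError("mean_length must be positive")
    rng = np.random.default_rng(seed)
    rec_rows = popmap.haplotype_rows(panel, recipient)
    don_rows = popmap.haplotype_rows(panel, donor)
    rec_samples = popmap.samples(recipient)
    contig = panel.contigs[0]
    length = (panel.contig_lengths or {contig: int(panel.pos.max())})[contig]
    out = panel.copy()
    records = []

    def _copy(row: int, start: int, end: int, donor_row: int) -> None:
        cols = out.sites_in_interval(contig, start, end)
        out.haplotypes[row, cols] = panel.haplotypes[donor_row, cols]
        i = int(np.flatnonzero(rec_rows == row)[0])
        records.append(
            dict(
                contig=contig,
                start=start,
                end=end,
                sample=rec_samples[i // 2],
                hap=i % 2,
                donor=donor,
                prob=1.0,
            )
        )

    if carrier_fraction is not None:
        if not 0 < carrier_fraction <= 1:
            raise ValueError("carrier_fraction must be in (0, 1]")
        n_car = max(1, int(np.ceil(carrier_fraction * len(rec_rows))))
        for _ in range(tracts_per_haplotype):
            tlen = max(1, int(round(rng.exponential(mean_length))))
            start = int(rng.integers(0, max(1, length - tlen)))
            donor_row = int(rng.choice(don_rows))
            for row in rng.choice(rec_rows, size=n_car, replace=False):
                _copy(int(row), start, start + tlen, donor_row)
    else:
        for row in rec_rows:
            for _ in range(tracts_per_haplotype):
                tlen = max(1, int(round(rng.exponential(mean_length))))
                start = int(rng.integers(0, max(1, length - tlen)))
                _copy(int(row), start, start + tlen, int(rng.choice(don_rows)))

    tracts = TractSet(pd.DataFrame(records, columns=TRACT_COLUMNS))
    if truth is not None:
        if len(truth.tracts.df):
            truth.tracts = TractSet(pd.concat([truth.tracts.df, tracts.df]))
        else:
            truth.tracts = TractSet(tracts.df)
    return out, tracts


def simulate_ils_lengths(L: float, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` tract lengths from the ILS null law Gamma(shape 2, rate 1/L).

    The mean is 2L (shape/rate).
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.gamma(shape=2.0, scale=L, size=n)


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------


def write_fixture_bundle(
    panel: HaplotypePanel, truth: SimTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write ``panel.vcf``, ``truth_sweeps.bed``, ``truth_tracts.bed``,
    ``popmap.tsv`` and ``config.yaml`` so a run can be reproduced from disk."""
    from . import panel_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_meta = [f"bovscan_seed={truth.config.seed}"]
    paths = {
        "vcf": outdir / "panel.vcf",
        "sweeps": outdir / "truth_sweeps.bed",
        "tracts": outdir / "truth_tracts.bed",
        "popmap": outdir / "popmap.tsv",
        "config": outdir / "config.yaml",
    }
    panel_io.write_vcf(panel, paths["vcf"], meta=seed_meta)
    with paths["sweeps"].open("w") as fh:
        fh.write(f"#{seed_meta[0]}\n#contig\tstart\tend\tpopulation\tcore_frequency\n")
        for s in truth.sweeps:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.population}\t{s.core_frequency:g}\n")
    panel_io.write_tracts_bed(truth.tracts, paths["tracts"], meta=seed_meta)
    panel_io.write_popmap(truth.config.popmap(), paths["popmap"])
    paths["config"].write_text(yaml.safe_dump(truth.config.to_dict(), sort_keys=False))
    return paths


def read_fixture_config(path: str | Path) -> SimConfig:
    return SimConfig.from_dict(yaml.safe_load(Path(path).read_text()))
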