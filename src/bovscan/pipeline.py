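"""End-to-end scan orchestration with deterministic seeds and TSV/BED outputs.

Every output file starts with ``#`` metadata lines naming the tool version,
the configuration hash and the seed, so a run is reproducible from its
outputs alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, diversity, haplotype, introgression, panel_io, synthetic
from .config import ConfigError, ScanConfig
from .panel import (
    HaplotypePanel,
    PopulationMap,
    annotate_regions,
    maf_filter,
    make_windows,
    polarize_by_outgroup,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A named pipeline stage failed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _meta(config: ScanConfig, extra: list[str] | None = None) -> list[str]:
    lines = [
        f"bovscan_version={__version__}",
        f"config_hash={config.digest()}",
        f"seed={config.seed}",
    ]
    return lines + (extra or [])


def _write_tsv(df: pd.DataFrame, path: Path, meta: list[str]) -> None:
    with path.open("w") as fh:
        for line in meta:
            fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def _load_inputs(config: ScanConfig) -> tuple[HaplotypePanel, PopulationMap]:
    panel = panel_io.read_phased_vcf(config.vcf)
    popmap = panel_io.read_popmap(config.popmap)
    popmap.validate_against(panel)
    if config.maf > 0:
        panel = maf_filter(panel, popmap, config.maf)
    return panel, popmap


def _grid_for(panel: HaplotypePanel, config: ScanConfig):
    lengths = panel.contig_lengths or {
        c: int(panel.pos[panel.contig == c].max()) for c in panel.contigs
    }
    return make_windows(
        lengths, size=config.window_size, step=config.step, keep_tail=config.keep_tail
    )


def run_selection_scan(config: ScanConfig) -> dict:
    """Windowed selection scan: compute the configured statistics, select
    candidate windows per statistic, intersect across statistics, merge,
    and annotate with genes when a GFF is configured.

    Returns a dict with the combined window table, the merged candidate
    regions, per-region gene lists, and the output paths written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        panel, popmap = _load_inputs(config)
    except (panel_io.FormatError, FileNotFoundError):
        raise
    except Exception as e:  # structural problems surface as input errors
        raise StageError("load_inputs", e) from e
    grid = _grid_for(panel, config)

    table = grid.to_frame()
    selections: dict[str, np.ndarray] = {}

    def _apply_rule(name: str, values: np.ndarray, direction: str) -> None:
        if config.selection_rule == "top":
            sel = diversity.top_fraction(values, config.top_q, direction)
            table[f"{name}_selected"] = sel
        else:
            p = diversity.empirical_pvalues_z(values, direction)
            sel = ~np.isnan(p) & (p < config.p_threshold)
            table[f"{name}_p"] = p
            table[f"{name}_selected"] = sel
        selections[name] = sel

    stats = list(config.statistics)
    try:
        # pi underlies the ratio and is always reported
        pi_a = diversity.windowed_pi(panel, popmap, config.pop_a, grid)
        pi_b = diversity.windowed_pi(panel, popmap, config.pop_b, grid)
        table["n_snps"] = pi_a.n_snps
        table[f"pi_{config.pop_a}"] = pi_a.values
        table[f"pi_{config.pop_b}"] = pi_b.values
        if "pi_ratio" in stats:
            ratio = diversity.pi_ratio(pi_a, pi_b)
            table["pi_ratio"] = ratio.values
            _apply_rule("pi_ratio", ratio.values, config.pi_ratio_direction)
        if "fst" in stats:
            fst = diversity.fst_windowed(
                panel, popmap, config.pop_a, config.pop_b, grid, min_snps=config.min_snps
            )
            table["fst"] = fst.values
            _apply_rule("fst", fst.values, "high")
        if "pbs" in stats:
            if not config.pbs_outgroup:
                raise ConfigError("pbs requested but pbs_outgroup not set")
            f_tr = diversity.fst_windowed(
                panel, popmap, config.pop_a, config.pop_b, grid, min_snps=config.min_snps
            )
            f_to = diversity.fst_windowed(
                panel, popmap, config.pop_a, config.pbs_outgroup, grid,
                min_snps=config.min_snps,
            )
            f_ro = diversity.fst_windowed(
                panel, popmap, config.pop_b, config.pbs_outgroup, grid,
                min_snps=config.min_snps,
            )
            pbs = diversity.pbs(f_tr, f_to, f_ro)
            table["pbs"] = pbs.values
            _apply_rule("pbs", pbs.values, "high")
    except ConfigError:
        raise
    except Exception as e:
        raise StageError("diversity_scan", e) from e

    try:
        if "xpehh" in stats:
            xp = haplotype.xpehh(panel, popmap, config.pop_a, config.pop_b)
            xp_win = haplotype.windowed_mean_score(xp, grid)
            table["xpehh_mean"] = xp_win.values
            _apply_rule("xpehh", xp_win.values, "high")
        if "ihs" in stats:
            pop = config.ihs_population or config.pop_a
            if not config.polarize_outgroup:
                raise ConfigError("ihs requested but polarize_outgroup not set")
            pol = polarize_by_outgroup(panel, popmap, config.polarize_outgroup)
            scores = haplotype.ihs(panel, popmap, pop, pol)
            prop = haplotype.window_prop_abs_ihs(
                scores, grid, config.abs_ihs_threshold
            )
            table["prop_abs_ihs"] = prop.values
            _apply_rule("ihs", prop.values, "high")
    except ConfigError:
        raise
    except Exception as e:
        raise StageError("haplotype_scan", e) from e

    regions = (
        diversity.intersect_candidates(grid, list(selections.values()))
        if selections
        else []
    )
    gene_lists = []
    if config.gff:
        try:
            genes = panel_io.read_gff3(config.gff)
        except Exception as e:
            raise StageError("annotate", e) from e
        gene_lists = annotate_regions(regions, genes)

    meta = _meta(config, [f"statistics={','.join(stats)}"])
    paths = {"windows": outdir / "selection_windows.tsv",
             "candidates": outdir / "candidate_regions.bed"}
    _write_tsv(table, paths["windows"], meta)
    panel_io.write_bed(regions, paths["candidates"], meta=meta)
    if config.gff:
        paths["genes"] = outdir / "candidate_genes.tsv"
        rows = [
            dict(contig=r[0], start=r[1], end=r[2], genes=",".join(gs))
            for r, gs in gene_lists
        ]
        _write_tsv(
            pd.DataFrame(rows, columns=["contig", "start", "end", "genes"]),
            paths["genes"],
            meta,
        )
    _write_manifest(config, outdir, paths)
    return dict(table=table, regions=regions, gene_lists=gene_lists, paths=paths)


def run_introgression_scan(config: ScanConfig) -> dict:
    """U-statistic windows, D and f3 reports, the ILS tract filter, and
    ancestry proportions, as configured."""
    for name in ("source_pop", "target_pop", "donor_pop"):
        if not getattr(config, name):
            raise ConfigError(f"introgression scan requires {name}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, popmap = _load_inputs(config)
    grid = _grid_for(panel, config)
    meta = _meta(config, ["u_alleles=both (at most one count per site)"])
    paths: dict[str, Path] = {}
    out: dict = {}

    try:
        table = grid.to_frame()
        for y, col in ((config.u_y20, "u20"), (config.u_y50, "u50")):
            ucfg = introgression.UStatConfig(w=config.u_w, x=config.u_x, y=y)
            ws = introgression.u_statistic_windows(
                panel, popmap, config.source_pop, config.target_pop,
                config.donor_pop, grid, ucfg,
            )
            table["n_snps"] = ws.n_snps
            table[col] = ws.values.astype(int)
        paths["u_windows"] = outdir / "u_windows.tsv"
        _write_tsv(table, paths["u_windows"], meta)
        out["u_windows"] = table
    except Exception as e:
        raise StageError("u_statistic", e) from e

    try:
        rows = []
        if config.d_outgroup:
            d = introgression.d_statistic(
                panel, popmap, config.source_pop, config.target_pop,
                config.donor_pop, config.d_outgroup, config.block_size,
            )
            rows.append(
                dict(statistic="D", configuration=(
                    f"(({config.source_pop},{config.target_pop}),"
                    f"{config.donor_pop});{config.d_outgroup}"),
                    value=d.d, se=d.se, z=d.z, n_blocks=d.n_blocks)
            )
            out["d"] = d
        f3 = introgression.f3_statistic(
            panel, popmap, config.target_pop, config.source_pop,
            config.donor_pop, config.block_size,
        )
        rows.append(
            dict(statistic="f3", configuration=(
                f"{config.target_pop};{config.source_pop},{config.donor_pop}"),
                value=f3.f3, se=f3.se, z=f3.z, n_blocks=f3.n_blocks)
        )
        out["f3"] = f3
        paths["gene_flow"] = outdir / "gene_flow.tsv"
        _write_tsv(pd.DataFrame(rows), paths["gene_flow"], meta)
    except Exception as e:
        raise StageError("gene_flow", e) from e

    if config.tracts:
        try:
            tracts = panel_io.read_tracts(config.tracts, config.tract_dialect)
            model = introgression.IlsModel(L=config.ils_L, alpha=config.ils_alpha)
            retained, report = introgression.filter_tracts(tracts, model)
            lengths = panel.contig_lengths or {
                c: int(panel.pos[panel.contig == c].max()) for c in panel.contigs
            }
            per_sample, per_pop = introgression.ancestry_proportions(
                retained, lengths, popmap
            )
            paths["filtered_tracts"] = outdir / "filtered_tracts.bed"
            paths["filter_report"] = outdir / "ils_filter_report.tsv"
            paths["ancestry"] = outdir / "ancestry_proportions.tsv"
            panel_io.write_tracts_bed(retained, paths["filtered_tracts"], meta=meta)
            _write_tsv(report, paths["filter_report"], meta)
            anc = per_sample.rename("fraction").reset_index()
            anc["population"] = [popmap[s] for s in anc["sample"]]
            _write_tsv(anc, paths["ancestry"], meta)
            out.update(tract_report=report, ancestry=(per_sample, per_pop))
        except panel_io.FormatError:
            raise
        except Exception as e:
            raise StageError("tract_filter", e) from e

    _write_manifest(config, outdir, paths)
    out["paths"] = paths
    return out


def _write_manifest(config: ScanConfig, outdir: Path, paths: dict) -> None:
    manifest = dict(
        bovscan_version=__version__,
        config_hash=config.digest(),
        seed=config.seed,
        outputs=sorted(str(p) for p in paths.values()),
        config=config.to_dict(),
    )
    (outdir / "run_manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=False)
    )


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


@dataclass
class SimulationPlan:
    """A panel configuration plus planted sweeps and introgression pulses."""

    panel: synthetic.SimConfig
    sweeps: list[dict] = field(default_factory=list)
    introgression: list[dict] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationPlan":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict) or "panel" not in d:
            raise ConfigError(f"{path}: simulation plan needs a 'panel' section")
        return cls(
            panel=synthetic.SimConfig.from_dict(d["panel"]),
            sweeps=d.get("sweeps", []),
            introgression=d.get("introgression", []),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            dict(
                panel=self.panel.to_dict(),
                sweeps=self.sweeps,
                introgression=self.introgression,
            ),
            sort_keys=False,
        )


def run_simulation(plan: SimulationPlan, outdir: str | Path) -> dict[str, Path]:
    """Simulate a panel, plant the configured signals, write the fixture
    bundle (VCF + truth BEDs + popmap + config).  Deterministic per seed."""
    panel, truth = synthetic.simulate_panel(plan.panel)
    popmap = plan.panel.popmap()
    for k, spec in enumerate(plan.sweeps):
        panel, _ = synthetic.plant_sweep(
            panel,
            popmap,
            region=tuple(spec["region"]),
            population=spec["population"],
            beta=float(spec.get("beta", 0.95)),
            seed=int(spec.get("seed", plan.panel.seed + 1000 + k)),
            truth=truth,
        )
    for k, spec in enumerate(plan.introgression):
        panel, _ = synthetic.plant_introgression(
            panel,
            popmap,
            recipient=spec["recipient"],
            donor=spec["donor"],
            mean_length=float(spec.get("mean_length", 300_000)),
            tracts_per_haplotype=int(spec.get("tracts_per_haplotype", 1)),
            seed=int(spec.get("seed", plan.panel.seed + 2000 + k)),
            carrier_fraction=spec.get("carrier_fraction"),
            truth=truth,
        )
    return synthetic.write_fixture_bundle(panel, truth, outdir)
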