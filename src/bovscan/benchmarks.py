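"""Simulation benchmarks: fixed study conditions with recorded truth.

Each function builds a synthetic panel under documented conditions, runs
the relevant scan end-to-end, and returns the measured quantities.  These
are the package's calibration and recovery experiments; the test suite and
the acceptance script both run them, so the numbers they report are always
recomputed, never stored.

Conditions (chosen once, see docs/methods.md):

* FST calibration: two populations of 50 diploids, 20,000 sites on 10 Mb,
  Balding-Nichols F in {0, 0.15} for both populations.
* Sweep recovery: indicine-like vs taurine-like pool (F = 0.15 each,
  25 diploids each) plus a small drifted outgroup for polarization; one
  hard sweep (core frequency 0.95) over 100 kb of a 10 Mb contig.
* Introgression recovery: source and target populations that are closely
  related (F = 0.02, 25 diploids each), a deeply drifted donor of
  4 diploids (F = 0.6) with private fixed sites at 2e-4 per bp, and a
  2-diploid outgroup (F = 0.9); 20 donor tracts of mean 300 kb copied into
  30% of target haplotypes.
* ILS filter calibration: 100,000 lengths from Gamma(shape 2,
  rate 1/206.52 bp), retention threshold alpha = 0.05.
"""

from __future__ import annotations

import numpy as np

from . import diversity, haplotype, introgression
from .panel import make_windows, merge_windows, polarize_by_outgroup
from .synthetic import SimConfig, plant_introgression, plant_sweep, simulate_panel

CONTIG_LENGTH = 10_000_000
N_SITES = 20_000
WINDOW, STEP = 50_000, 20_000


def _grid():
    return make_windows({"chr1": CONTIG_LENGTH}, WINDOW, STEP)


def fst_calibration(seed: int, F: float, n_diploid: int = 50) -> dict:
    """Genome-mean windowed Weir-Cockerham FST on a two-population
    Balding-Nichols panel with drift parameter ``F`` in both populations.

    The estimator's expectation is ~F, which this measures.
    """
    config = SimConfig(
        contig_length=CONTIG_LENGTH,
        n_sites=N_SITES,
        populations=[
            dict(label="A", n_diploid=n_diploid, F=F),
            dict(label="B", n_diploid=n_diploid, F=F),
        ],
        seed=seed,
    )
    panel, _ = simulate_panel(config)
    fst = diversity.fst_windowed(panel, config.popmap(), "A", "B", _grid())
    return dict(
        mean_windowed_fst=float(np.nanmean(fst.values)),
        n_windows=int(fst.defined.sum()),
        F=F,
    )


def sweep_benchmark(seed: int) -> dict:
    """Plant one hard sweep and measure its recovery by every scan statistic.

    Returns recovery indicators: whether sweep-overlapping windows reach the
    top 1% of FST and the low 1% tail of the pi-ratio, whether the maximal
    windowed mean XP-EHH window overlaps the sweep, and the |iHS| >= 2
    proportion inside vs outside the sweep.
    """
    sweep_region = ("chr1", 5_000_000, 5_100_000)
    config = SimConfig(
        contig_length=CONTIG_LENGTH,
        n_sites=N_SITES,
        populations=[
            dict(label="IND", n_diploid=25, F=0.15),
            dict(label="TAU", n_diploid=25, F=0.15),
            dict(label="BUF", n_diploid=2, F=0.9),
        ],
        seed=seed,
    )
    panel, truth = simulate_panel(config)
    popmap = config.popmap()
    panel, _ = plant_sweep(
        panel, popmap, sweep_region, "IND", beta=0.95, seed=seed + 1, truth=truth
    )
    grid = _grid()
    overlap = np.array(
        [s < sweep_region[2] and e > sweep_region[1] for _, s, e in grid]
    )

    fst = diversity.fst_windowed(panel, popmap, "IND", "TAU", grid)
    pi_i = diversity.windowed_pi(panel, popmap, "IND", grid)
    pi_t = diversity.windowed_pi(panel, popmap, "TAU", grid)
    ratio = diversity.pi_ratio(pi_i, pi_t)
    top_fst = diversity.top_fraction(fst.values, 0.01, "high")
    low_ratio = diversity.top_fraction(ratio.values, 0.01, "low")

    xp = haplotype.xpehh(panel, popmap, "IND", "TAU")
    xp_win = haplotype.windowed_mean_score(xp, grid)
    best_xp = int(np.nanargmax(xp_win.values))

    pol = polarize_by_outgroup(panel, popmap, "BUF")
    scores = haplotype.ihs(panel, popmap, "IND", pol)
    prop = haplotype.window_prop_abs_ihs(scores, grid)

    return dict(
        n_sweep_windows=int(overlap.sum()),
        fst_top1_sweep_windows=int((top_fst & overlap).sum()),
        pi_ratio_low1_sweep_windows=int((low_ratio & overlap).sum()),
        xpehh_argmax_overlaps_sweep=bool(overlap[best_xp]),
        prop_abs_ihs_sweep=float(np.nanmean(prop.values[overlap])),
        prop_abs_ihs_genome=float(np.nanmean(prop.values[~overlap])),
        null_abs_ihs_ge2_fraction=float(
            (np.abs(scores.included["std"]) >= 2).mean()
        ),
    )


def introgression_benchmark(seed: int) -> dict:
    """Plant donor tracts and measure U20 window recovery and D Z-scores.

    The D statistic is computed both before (null) and after (flow) the
    tracts are planted, with a 500 kb block jackknife (20 blocks on 10 Mb).
    """
    config = SimConfig(
        contig_length=CONTIG_LENGTH,
        n_sites=N_SITES,
        populations=[
            dict(label="SAI", n_diploid=25, F=0.02),
            dict(label="EAI", n_diploid=25, F=0.02),
            dict(label="BAN", n_diploid=4, F=0.6, private_fixed_density=2e-4),
            dict(label="BUF", n_diploid=2, F=0.9),
        ],
        seed=seed,
    )
    panel0, truth = simulate_panel(config)
    popmap = config.popmap()
    d_null = introgression.d_statistic(
        panel0, popmap, "SAI", "EAI", "BAN", "BUF", block_size=500_000
    )
    panel, _ = plant_introgression(
        panel0,
        popmap,
        recipient="EAI",
        donor="BAN",
        mean_length=300_000,
        tracts_per_haplotype=20,
        seed=seed + 1,
        carrier_fraction=0.3,
        truth=truth,
    )
    d_flow = introgression.d_statistic(
        panel, popmap, "SAI", "EAI", "BAN", "BUF", block_size=500_000
    )
    grid = _grid()
    u20 = introgression.u_statistic_windows(
        panel, popmap, "SAI", "EAI", "BAN", grid, introgression.UStatConfig(y=0.20)
    )
    truth_regions = merge_windows(
        [(r.contig, r.start, r.end) for r in truth.tracts.df.itertuples()]
    )
    overlap = np.array(
        [
            any(c == tc and s < te and e > ts for tc, ts, te in truth_regions)
            for c, s, e in grid
        ]
    )
    mean_len = float(truth.tracts.lengths.mean())
    return dict(
        u20_recovery=float((u20.values[overlap] > 0).mean()),
        u20_purity=float((u20.values[~overlap] == 0).mean()),
        d_z_flow=float(d_flow.z),
        d_z_null=float(d_null.z),
        d_flow=float(d_flow.d),
        d_null=float(d_null.d),
        n_truth_windows=int(overlap.sum()),
        mean_planted_tract_length=mean_len,
    )


def ils_calibration(seed: int, L: float = 206.52, n: int = 100_000) -> dict:
    """Draw ILS null lengths and measure the filter's retention fraction at
    alpha = 0.05 and the empirical survival at m = L (expected 2/e)."""
    from .synthetic import simulate_ils_lengths

    lengths = simulate_ils_lengths(L, n, seed)
    model = introgression.IlsModel(L=L, alpha=0.05)
    retained = model.survival(lengths) < model.alpha
    return dict(
        retained_fraction=float(retained.mean()),
        empirical_survival_at_L=float((lengths >= L).mean()),
        mean_length=float(lengths.mean()),
        expected_mean=2 * L,
    )
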