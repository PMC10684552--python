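"""EHH-family statistics: combinatorial cases, integrals, standardization."""

import numpy as np
import pandas as pd
import pytest

from bovscan import haplotype as hap
from bovscan.panel import Polarization, PopulationMap, make_windows

ALL = np.arange(4)


def small_panel(panel_factory, rng, columns, positions):
    """Panel from an explicit (haplotype x site) allele matrix."""
    h = np.asarray(columns, dtype=np.int8)
    return panel_factory(rng, haplotypes=h, positions=positions)


class TestEhh:
    def test_two_two_split_at_first_flank(self, rng, panel_factory):
        # 4 carriers all share the core; flanking marker splits them 2|2
        h = [
            [1, 0],
            [1, 0],
            [1, 1],
            [1, 1],
        ]
        panel = small_panel(panel_factory, rng, h, [1_000, 2_000])
        curve = hap.ehh(panel, ALL, core_index=0)
        assert curve.right_ehh[0] == pytest.approx(1 / 3)
        assert curve.left_pos.size == 0  # core is the first marker

    def test_identical_carriers_stay_at_one(self, rng, panel_factory):
        h = np.ones((4, 5), dtype=np.int8)
        panel = small_panel(panel_factory, rng, h, [10, 20, 30, 40, 50])
        curve = hap.ehh(panel, ALL, core_index=2)
        assert (curve.left_ehh == 1).all() and (curve.right_ehh == 1).all()
        assert curve.left_truncation == "chrom_end"
        assert curve.right_truncation == "chrom_end"

    def test_requires_two_carriers(self, rng, panel_factory):
        panel = panel_factory(rng, n_samples=2, n_sites=3)
        with pytest.raises(ValueError, match="2 carrier"):
            hap.ehh(panel, np.array([0]), 1)

    def test_monotone_nonincreasing_on_random_panels(self, rng, panel_factory):
        for seed in range(5):
            local = np.random.default_rng(seed)
            panel = panel_factory(local, n_samples=6, n_sites=40, p=0.5)
            curve = hap.ehh(panel, np.arange(12), core_index=20, cutoff=0.0)
            for e in (curve.left_ehh, curve.right_ehh):
                assert (np.diff(np.concatenate([[1.0], e])) <= 1e-12).all()

    def test_gap_truncates_curve(self, rng, panel_factory):
        h = np.ones((4, 3), dtype=np.int8)
        panel = small_panel(panel_factory, rng, h, [1_000, 2_000, 300_000])
        curve = hap.ehh(panel, ALL, core_index=1, max_gap=200_000)
        assert curve.right_truncation == "gap"
        assert curve.right_pos.size == 0

    def test_unphased_panel_rejected(self, rng, panel_factory):
        panel = panel_factory(rng, n_samples=3, n_sites=5)
        panel.phased = False
        with pytest.raises(ValueError, match="phased"):
            hap.ehh(panel, np.arange(6), 2)


class TestIhh:
    def test_rectangle_area(self, rng, panel_factory):
        h = np.ones((4, 3), dtype=np.int8)
        panel = small_panel(panel_factory, rng, h, [10_000, 20_000, 30_000])
        curve = hap.ehh(panel, ALL, core_index=1)
        # EHH is 1 for 10,000 bp on each side
        assert hap.ihh(curve) == pytest.approx(20_000.0)

    def test_single_trapezoid_when_first_marker_breaches_cutoff(self, rng, panel_factory):
        # 2|2 split gives EHH = 1/3 < cutoff 0.5: one trapezoid per side
        h = [
            [0, 1, 0],
            [0, 1, 0],
            [1, 1, 1],
            [1, 1, 1],
        ]
        panel = small_panel(panel_factory, rng, h, [500, 1_500, 4_500])
        curve = hap.ehh(panel, ALL, core_index=1, cutoff=0.5)
        assert curve.left_truncation == "cutoff"
        assert curve.right_truncation == "cutoff"
        expect = 1_000 * (1 + 1 / 3) / 2 + 3_000 * (1 + 1 / 3) / 2
        assert hap.ihh(curve) == pytest.approx(expect)

    def test_zero_when_no_flanks(self, rng, panel_factory):
        h = np.ones((4, 1), dtype=np.int8)
        panel = small_panel(panel_factory, rng, h, [42])
        assert hap.ihh(hap.ehh(panel, ALL, 0)) == 0.0


def _mirror_panel(panel_factory, rng):
    """Ancestral and derived carrier classes with identical flank patterns."""
    flank = np.array(
        [[0, 1, 0], [1, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=np.int8
    )
    core_anc = np.zeros((4, 1), dtype=np.int8)
    core_der = np.ones((4, 1), dtype=np.int8)
    left = np.vstack([flank, flank])
    right = np.vstack([flank, flank])
    core = np.vstack([core_anc, core_der])
    h = np.hstack([left, core, right])
    return panel_factory(rng, haplotypes=h, positions=[100, 200, 300, 400, 500, 600, 700])


class TestIhs:
    def test_mirror_classes_give_zero_raw_score(self, rng, panel_factory):
        panel = _mirror_panel(panel_factory, rng)
        popmap = PopulationMap({s: "pop" for s in panel.samples})
        pol = Polarization(np.zeros(panel.n_sites, dtype=np.int8))
        table = hap.ihs(panel, popmap, "pop", pol, min_maf=0.05, cutoff=0.0)
        core = table.df[table.df["pos"] == 400].iloc[0]
        assert core["raw"] == pytest.approx(0.0, abs=1e-12)

    def test_bin_standardization_moments(self, rng, panel_factory):
        panel = panel_factory(rng, n_samples=20, n_sites=300, p=0.5, length=3_000_000)
        popmap = PopulationMap({s: "pop" for s in panel.samples})
        pol = Polarization(np.zeros(panel.n_sites, dtype=np.int8))
        table = hap.ihs(panel, popmap, "pop", pol, n_bins=5)
        df = table.included
        bins = np.clip((df["freq"].to_numpy() * 5).astype(int), 0, 4)
        for b in np.unique(bins):
            scores = df["std"].to_numpy()[bins == b]
            assert abs(scores.mean()) < 1e-12
            assert scores.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_sample_relabeling(self, rng, panel_factory):
        panel = panel_factory(rng, n_samples=10, n_sites=80, p=0.5, length=500_000)
        pol = Polarization(np.zeros(panel.n_sites, dtype=np.int8))
        popmap = PopulationMap({s: "pop" for s in panel.samples})
        t1 = hap.ihs(panel, popmap, "pop", pol)
        perm = rng.permutation(panel.n_samples)
        rows = np.concatenate([[2 * i, 2 * i + 1] for i in perm])
        shuffled = panel_factory(
            rng, haplotypes=panel.haplotypes[rows], positions=panel.pos
        )
        t2 = hap.ihs(shuffled, PopulationMap({s: "pop" for s in shuffled.samples}),
                     "pop", pol)
        assert np.allclose(
            t1.df["raw"].to_numpy(), t2.df["raw"].to_numpy(), equal_nan=True
        )

    def test_unknown_ancestral_state_skipped(self, rng, panel_factory):
        panel = panel_factory(rng, n_samples=6, n_sites=10, p=0.5)
        state = np.zeros(10, dtype=np.int8)
        state[::2] = -1
        popmap = PopulationMap({s: "pop" for s in panel.samples})
        table = hap.ihs(panel, popmap, "pop", Polarization(state))
        assert set(table.df["site"]) == set(range(1, 10, 2))


class TestWindowPropAbsIhs:
    def _table(self, std_scores, positions):
        df = pd.DataFrame(
            dict(
                site=range(len(std_scores)),
                contig=["chr1"] * len(std_scores),
                pos=positions,
                freq=0.5,
                raw=std_scores,
                std=std_scores,
                included=True,
                flag="",
            )
        )
        return hap.ScoreTable(df, "ihs", "test")

    def test_direct_count(self):
        scores = [0.1] * 9 + [2.5, -2.0, 3.1]  # 3 of 12 beyond threshold
        table = self._table(scores, list(range(1, 13)))
        grid = make_windows({"chr1": 20}, 20, 20)
        ws = hap.window_prop_abs_ihs(table, grid, 2.0)
        assert ws.values[0] == pytest.approx(0.25)
        assert ws.n_snps[0] == 12

    def test_empty_window_undefined_and_bounded(self):
        table = self._table([0.5, 2.5], [1, 2])
        grid = make_windows({"chr1": 200}, 100, 100)
        ws = hap.window_prop_abs_ihs(table, grid)
        assert 0 <= ws.values[0] <= 1
        assert np.isnan(ws.values[1])


class TestXpehh:
    def test_identical_populations_score_zero(self, rng, panel_factory):
        block = (rng.random((10, 30)) < 0.5).astype(np.int8)
        panel = panel_factory(rng, haplotypes=np.vstack([block, block]), n_sites=30)
        popmap = PopulationMap(
            {s: ("a" if i < 5 else "b") for i, s in enumerate(panel.samples)}
        )
        table = hap.xpehh(panel, popmap, "a", "b")
        raw = table.included["raw"].to_numpy()
        assert np.allclose(raw, 0.0, atol=1e-12)

    def test_global_normalization_moments(self, rng, panel_factory):
        panel = panel_factory(rng, n_samples=12, n_sites=120, p=0.5, length=1_000_000)
        popmap = PopulationMap(
            {s: ("a" if i < 6 else "b") for i, s in enumerate(panel.samples)}
        )
        table = hap.xpehh(panel, popmap, "a", "b")
        std = table.included["std"].to_numpy()
        assert abs(std.mean()) < 1e-12
        assert std.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_windowed_mean_matches_direct_average(self, rng, panel_factory):
        panel = panel_factory(rng, n_samples=8, n_sites=60, p=0.5, length=100_000)
        popmap = PopulationMap(
            {s: ("a" if i < 4 else "b") for i, s in enumerate(panel.samples)}
        )
        table = hap.xpehh(panel, popmap, "a", "b")
        grid = make_windows({"chr1": 100_000}, 50_000, 20_000)
        ws = hap.windowed_mean_score(table, grid)
        df = table.included
        for w, (_, start, end) in enumerate(grid):
            m = (df["pos"] - 1 >= start) & (df["pos"] - 1 < end)
            if m.any():
                assert ws.values[w] == pytest.approx(df.loc[m, "std"].mean())
            else:
                assert np.isnan(ws.values[w])
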