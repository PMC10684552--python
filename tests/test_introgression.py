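"""Gene-flow statistics and the ILS tract filter against oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from bovscan import introgression as intro
from bovscan.panel import PopulationMap, TractSet, make_windows

import _oracles


def four_pop_panel(panel_factory, rng, n_sites=40, per_pop=4, length=5_000_000):
    panel = panel_factory(
        rng, n_samples=4 * per_pop, n_sites=n_sites, p=0.4, length=length
    )
    labels = ["P1", "P2", "P3", "OUT"]
    popmap = PopulationMap(
        {s: labels[i // per_pop] for i, s in enumerate(panel.samples)}
    )
    return panel, popmap


class TestDStatistic:
    def test_symmetric_p1_p2_gives_zero(self, rng, panel_factory):
        panel, _ = four_pop_panel(panel_factory, rng)
        block = panel.haplotypes[:8]
        h = np.vstack([block, block, panel.haplotypes[16:]])
        panel2 = panel_factory(rng, haplotypes=h, positions=panel.pos)
        popmap = PopulationMap(
            {s: ["P1", "P2", "P3", "OUT"][i // 4] for i, s in enumerate(panel2.samples)}
        )
        res = intro.d_statistic(panel2, popmap, "P1", "P2", "P3", "OUT")
        assert res.d == pytest.approx(0.0, abs=1e-15)

    def test_pure_abba_single_site(self, rng, panel_factory):
        h = np.array([[0]] * 4 + [[1]] * 4 + [[1]] * 4 + [[0]] * 4, dtype=np.int8)
        panel = panel_factory(rng, haplotypes=h, positions=[100])
        popmap = PopulationMap(
            {s: ["P1", "P2", "P3", "OUT"][i // 2] for i, s in enumerate(panel.samples)}
        )
        res = intro.d_statistic(panel, popmap, "P1", "P2", "P3", "OUT")
        assert res.d == pytest.approx(1.0)
        assert res.z is None  # a single block gives no jackknife

    def test_matches_jackknife_oracle(self, rng, panel_factory):
        panel, popmap = four_pop_panel(panel_factory, rng, n_sites=50)
        block_size = 1_000_000  # 5 blocks over the 5 Mb contig
        res = intro.d_statistic(
            panel, popmap, "P1", "P2", "P3", "OUT", block_size=block_size
        )
        freqs = np.array(
            [
                panel.alt_frequency(popmap.haplotype_rows(panel, p))
                for p in ("P1", "P2", "P3", "OUT")
            ]
        )
        blocks = (panel.pos - 1) // block_size
        d, se = _oracles.d_jackknife_oracle(freqs, blocks)
        assert res.d == pytest.approx(d, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        assert res.z == pytest.approx(d / se, abs=1e-8)
        assert -1 <= res.d <= 1

    def test_duplicate_populations_rejected(self, rng, panel_factory):
        panel, popmap = four_pop_panel(panel_factory, rng)
        with pytest.raises(ValueError):
            intro.d_statistic(panel, popmap, "P1", "P1", "P3", "OUT")


class TestF3:
    def test_matches_oracle(self, rng, panel_factory):
        panel, popmap = four_pop_panel(panel_factory, rng, n_sites=50)
        res = intro.f3_statistic(panel, popmap, "P3", "P1", "P2", block_size=1_000_000)
        pc = panel.alt_frequency(popmap.haplotype_rows(panel, "P3"))
        pa = panel.alt_frequency(popmap.haplotype_rows(panel, "P1"))
        pb = panel.alt_frequency(popmap.haplotype_rows(panel, "P2"))
        value, se = _oracles.f3_oracle(pc, pa, pb, 8, (panel.pos - 1) // 1_000_000)
        assert res.f3 == pytest.approx(value, abs=1e-12)
        assert res.se == pytest.approx(se, abs=1e-12)

    def test_symmetric_in_sources(self, rng, panel_factory):
        panel, popmap = four_pop_panel(panel_factory, rng)
        r1 = intro.f3_statistic(panel, popmap, "P3", "P1", "P2")
        r2 = intro.f3_statistic(panel, popmap, "P3", "P2", "P1")
        assert r1.f3 == pytest.approx(r2.f3, abs=1e-15)

    def test_admixed_target_is_negative(self, rng, panel_factory):
        # diverged sources: A all-ref-biased, B all-alt-biased; C = 50/50 mix
        n_sites = 400
        a = (rng.random((10, n_sites)) < 0.1).astype(np.int8)
        b = (rng.random((10, n_sites)) < 0.9).astype(np.int8)
        c = np.vstack([a[:5], b[:5]])
        panel = panel_factory(rng, haplotypes=np.vstack([a, b, c]), n_sites=n_sites)
        popmap = PopulationMap(
            {s: ["A", "B", "C"][i // 5] for i, s in enumerate(panel.samples)}
        )
        res = intro.f3_statistic(panel, popmap, "C", "A", "B")
        assert res.f3 < 0

    def test_unadmixed_target_near_zero(self, rng, panel_factory):
        # all three populations drawn from the same frequencies
        p = rng.uniform(0.1, 0.9, size=2_000)
        h = (rng.random((30, 2_000)) < p).astype(np.int8)
        panel = panel_factory(rng, haplotypes=h, n_sites=2_000, length=10_000_000)
        popmap = PopulationMap(
            {s: ["A", "B", "C"][i // 5] for i, s in enumerate(panel.samples)}
        )
        res = intro.f3_statistic(panel, popmap, "C", "A", "B", block_size=2_000_000)
        assert abs(res.f3) < 4 * res.se


class TestUStatistic:
    def _panel(self, panel_factory, rng, target_freqs):
        """10 source, 10 target, 5 donor diploids; donor fixed alt everywhere;
        source fixed ref; target frequency per site as given."""
        n_sites = len(target_freqs)
        src = np.zeros((20, n_sites), dtype=np.int8)
        tgt = np.zeros((20, n_sites), dtype=np.int8)
        for j, f in enumerate(target_freqs):
            tgt[: int(round(f * 20)), j] = 1
        don = np.ones((10, n_sites), dtype=np.int8)
        panel = panel_factory(
            rng,
            haplotypes=np.vstack([src, tgt, don]),
            positions=np.arange(1, n_sites + 1) * 100,
            length=100_000,
        )
        popmap = PopulationMap(
            {
                s: ("SRC" if i < 10 else "TGT" if i < 20 else "DON")
                for i, s in enumerate(panel.samples)
            }
        )
        return panel, popmap

    def test_direct_counts_u20_u50(self, rng, panel_factory):
        freqs = [0.30, 0.30, 0.30, 0.60, 0.60]
        panel, popmap = self._panel(panel_factory, rng, freqs)
        grid = make_windows({"chr1": 100_000}, 100_000, 100_000)
        u20 = intro.u_statistic_windows(
            panel, popmap, "SRC", "TGT", "DON", grid, intro.UStatConfig(y=0.20)
        )
        u50 = intro.u_statistic_windows(
            panel, popmap, "SRC", "TGT", "DON", grid, intro.UStatConfig(y=0.50)
        )
        assert u20.values[0] == 5
        assert u50.values[0] == 2

    def test_boundary_frequency_excluded(self, rng, panel_factory):
        panel, popmap = self._panel(panel_factory, rng, [0.20])
        grid = make_windows({"chr1": 100_000}, 100_000, 100_000)
        u20 = intro.u_statistic_windows(
            panel, popmap, "SRC", "TGT", "DON", grid, intro.UStatConfig(y=0.20)
        )
        assert u20.values[0] == 0  # strict inequality at y

    def test_no_donor_fixed_sites_gives_zero(self, rng, panel_factory):
        panel = panel_factory(rng, n_samples=12, n_sites=30, p=0.5)
        popmap = PopulationMap(
            {s: ["SRC", "TGT", "DON"][i // 4] for i, s in enumerate(panel.samples)}
        )
        f_don = panel.alt_frequency(popmap.haplotype_rows(panel, "DON"))
        assume_unfixed = ((f_don > 0) & (f_don < 1)).all()
        grid = make_windows({"chr1": 100_000}, 100_000, 100_000)
        u = intro.u_statistic_windows(panel, popmap, "SRC", "TGT", "DON", grid)
        if assume_unfixed:
            assert u.values[0] == 0

    def test_matches_per_site_oracle(self, rng, panel_factory):
        panel = panel_factory(rng, n_samples=15, n_sites=50, p=0.15, length=50_000)
        popmap = PopulationMap(
            {s: ["SRC", "TGT", "DON"][i // 5] for i, s in enumerate(panel.samples)}
        )
        grid = make_windows({"chr1": 50_000}, 25_000, 25_000)
        cfg = intro.UStatConfig(x=0.15, y=0.30)
        u = intro.u_statistic_windows(panel, popmap, "SRC", "TGT", "DON", grid, cfg)
        for w, (_, start, end) in enumerate(grid):
            oracle = _oracles.u_count_oracle(
                panel, popmap, "SRC", "TGT", "DON", start, end, x=0.15, y=0.30
            )
            assert u.values[w] == oracle

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            intro.UStatConfig(x=0.5, y=0.3)


class TestIlsModel:
    def test_expected_length_arithmetic(self):
        assert intro.expected_tract_length(1e-8, 500_000) == pytest.approx(200.0)
        assert intro.expected_tract_length(2e-8, 500_000) < 200.0  # monotone in r
        assert intro.expected_tract_length(1e-8, 1_000_000) < 200.0  # monotone in t
        with pytest.raises(ValueError):
            intro.expected_tract_length(0.0, 1.0)

    def test_expected_length_against_independent_evaluation(self):
        import math

        for r, t in [(1e-8, 484_212.0), (9.3e-9, 520_617.0)]:
            expect = math.exp(-(math.log(r) + math.log(t)))
            assert intro.expected_tract_length(r, t) == pytest.approx(
                expect, rel=1e-12
            )

    def test_survival_closed_form_on_grid(self):
        L = 206.52
        m = np.linspace(0, 20 * L, 1_000)
        closed = np.exp(-m / L) * (1 + m / L)
        assert np.abs(intro.ils_survival(m, L) - closed).max() < 1e-9

    def test_survival_reference_points(self):
        assert intro.ils_survival(0.0, 206.52) == 1.0
        assert intro.ils_survival(206.52, 206.52) == pytest.approx(
            2 / np.e, abs=1e-9
        )
        with pytest.raises(ValueError):
            intro.ils_survival(-1.0, 206.52)

    def test_retention_boundary_near_4p74_L(self):
        # survival(x*L) = 0.05 at x solving e^-x (1+x) = 0.05
        x = brentq(lambda v: np.exp(-v) * (1 + v) - 0.05, 1, 20, xtol=1e-12)
        assert x == pytest.approx(4.7439, abs=1e-4)
        L = 206.52
        m_star = x * L
        assert m_star == pytest.approx(979.7, abs=0.5)
        model = intro.IlsModel(L=L, alpha=0.05)
        assert model.survival(m_star + 0.01) < 0.05 < model.survival(m_star - 0.01)

    def test_model_from_r_and_t_consistency(self):
        model = intro.IlsModel(r=1e-8, t=500_000)
        assert model.L == pytest.approx(200.0)
        with pytest.raises(ValueError, match="inconsistent"):
            intro.IlsModel(r=1e-8, t=500_000, L=300.0)


class TestFilterTracts:
    def _tracts(self, lengths):
        df = pd.DataFrame(
            dict(
                contig="chr1",
                start=np.arange(len(lengths)) * 100_000,
                end=np.arange(len(lengths)) * 100_000 + np.asarray(lengths),
                sample="EAI_0",
                hap=0,
                donor="BAN",
                prob=1.0,
            )
        )
        return TractSet(df)

    def test_short_removed_long_retained(self):
        model = intro.IlsModel(L=206.52, alpha=0.05)
        retained, report = intro.filter_tracts(self._tracts([10, 5_000]), model)
        assert retained.df["end"].tolist() == [105_000]
        assert report.loc[0, "n_removed"] == 1
        assert report.loc[0, "n_retained"] == 1

    def test_alpha_one_retains_all(self):
        model = intro.IlsModel(L=206.52, alpha=1.0)
        retained, report = intro.filter_tracts(self._tracts([1, 10, 100]), model)
        assert len(retained) == 3

    def test_report_conserves_counts(self):
        lengths = [10, 200, 900, 1200, 5000, 30]
        model = intro.IlsModel(L=206.52, alpha=0.05)
        retained, report = intro.filter_tracts(self._tracts(lengths), model)
        assert (
            report.loc[0, "n_retained"] + report.loc[0, "n_removed"]
            == report.loc[0, "n_input"]
            == len(lengths)
        )
        assert len(retained) == report.loc[0, "n_retained"]


class TestAncestryProportions:
    def test_no_tracts_gives_zero(self):
        popmap = PopulationMap({"a": "EAI"})
        per_sample, per_pop = intro.ancestry_proportions(
            TractSet(), {"chr1": 1_000_000}, popmap
        )
        assert per_sample["a"] == 0.0
        assert per_pop["EAI"] == 0.0

    def test_half_covered_single_haplotype(self):
        df = pd.DataFrame(
            dict(contig=["chr1"], start=[0], end=[1_000_000], sample=["a"],
                 hap=[0], donor=["BAN"], prob=[1.0])
        )
        popmap = PopulationMap({"a": "EAI", "b": "EAI"})
        per_sample, per_pop = intro.ancestry_proportions(
            TractSet(df), {"chr1": 1_000_000}, popmap
        )
        assert per_sample["a"] == pytest.approx(0.5)
        assert per_pop["EAI"] == pytest.approx(0.25)

    def test_matches_bitmap_oracle(self, rng):
        samples = ["s0", "s1", "s2"]
        rows = []
        for s in samples:
            for hap in (0, 1):
                cursor = 0
                while cursor < 9_000 and rng.random() < 0.8:
                    start = cursor + int(rng.integers(0, 500))
                    end = start + int(rng.integers(1, 800))
                    rows.append(
                        dict(contig="c", start=start, end=min(end, 10_000),
                             sample=s, hap=hap, donor="BAN", prob=1.0)
                    )
                    cursor = end + int(rng.integers(1, 300))
        tracts = TractSet(pd.DataFrame(rows))
        popmap = PopulationMap({s: "EAI" for s in samples})
        per_sample, _ = intro.ancestry_proportions(tracts, {"c": 10_000}, popmap)
        oracle = _oracles.ancestry_bitmap_oracle(tracts.df, {"c": 10_000}, samples)
        for s in samples:
            assert per_sample[s] == pytest.approx(oracle[s], abs=1e-12)

    def test_tract_beyond_contig_rejected(self):
        df = pd.DataFrame(
            dict(contig=["c"], start=[0], end=[2_000], sample=["a"], hap=[0],
                 donor=["BAN"], prob=[1.0])
        )
        with pytest.raises(ValueError, match="beyond"):
            intro.ancestry_proportions(
                TractSet(df), {"c": 1_000}, PopulationMap({"a": "EAI"})
            )


class TestHaplotypeFrequencyMap:
    def test_monomorphic_region(self, rng, panel_factory):
        h = np.zeros((8, 4), dtype=np.int8)
        panel = panel_factory(rng, haplotypes=h, positions=[10, 20, 30, 40])
        popmap = PopulationMap(
            {s: ("x" if i < 2 else "y") for i, s in enumerate(panel.samples)}
        )
        df = intro.haplotype_frequency_map(panel, ("chr1", 0, 100), popmap)
        assert df.shape == (1, 2)
        assert (df.loc["0000"] == 1.0).all()

    def test_frequencies_sum_to_one_and_match_counting(self, rng, panel_factory):
        panel = panel_factory(rng, n_samples=6, n_sites=4, p=0.5, length=1_000)
        popmap = PopulationMap(
            {s: ("x" if i < 3 else "y") for i, s in enumerate(panel.samples)}
        )
        df = intro.haplotype_frequency_map(panel, ("chr1", 0, 1_000), popmap)
        assert np.allclose(df.sum(axis=0), 1.0)
        # exhaustive count for population x
        rows = popmap.haplotype_rows(panel, "x")
        strings = ["".join(map(str, panel.haplotypes[r].tolist())) for r in rows]
        for s in set(strings):
            assert df.loc[s, "x"] == pytest.approx(strings.count(s) / len(strings))

    def test_empty_region_rejected(self, rng, panel_factory):
        panel = panel_factory(rng, n_samples=2, positions=[500])
        with pytest.raises(ValueError, match="no sites"):
            intro.haplotype_frequency_map(
                panel, ("chr1", 600, 700), PopulationMap({s: "x" for s in panel.samples})
            )
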