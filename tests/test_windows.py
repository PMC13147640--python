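import numpy as np
import pandas as pd
import pytest

import rohscan as rs
from conftest import make_matrix, make_single_chrom
from oracles import pairwise_pi


class TestMakeWindows:
    def test_sliding_starts_and_truncation(self):
        layout = make_single_chrom(np.array([0]), chrom_len=100_000)
        win = rs.make_windows(layout, 50_000, 20_000)
        assert win["start"].tolist() == [0, 20_000, 40_000, 60_000, 80_000]
        assert win["end"].tolist() == [50_000, 70_000, 90_000, 100_000, 100_000]

    def test_tiling_when_step_equals_size(self):
        layout = make_single_chrom(np.array([0]), chrom_len=100_000)
        win = rs.make_windows(layout, 20_000, 20_000)
        assert (win["end"] - win["start"]).tolist() == [20_000] * 5
        assert (win["start"].iloc[1:].to_numpy()
                == win["end"].iloc[:-1].to_numpy()).all()

    def test_chromosome_shorter_than_window(self):
        layout = make_single_chrom(np.array([0]), chrom_len=30_000)
        win = rs.make_windows(layout, 50_000, 20_000)
        assert win[["start", "end"]].values.tolist() == [[0, 30_000], [20_000, 30_000]]

    def test_invalid_parameters_rejected(self):
        layout = make_single_chrom(np.array([0]), chrom_len=100_000)
        with pytest.raises(ValueError):
            rs.make_windows(layout, 0, 10)
        with pytest.raises(ValueError, match="step"):
            rs.make_windows(layout, 10_000, 20_000)

    def test_interior_site_falls_in_three_windows(self):
        # 50 kb / 20 kb: ceil(50/20) = 3 covering windows away from edges
        layout = make_single_chrom(np.array([0]), chrom_len=1_000_000)
        win = rs.make_windows(layout)
        site = 500_123
        n_cover = ((win["start"] <= site) & (site < win["end"])).sum()
        assert n_cover == 3


class TestWindowSummarize:
    def _win(self):
        return pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 50_000}])

    def test_proportion_of_extreme_ihs(self):
        sites = pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(10) * 1000,
            "value": [2.5, -2.1] + [0.5] * 8})
        tab = rs.window_summarize(sites, self._win(), "prop_ihs")
        assert tab["value"].iloc[0] == pytest.approx(0.2)

    def test_sparse_window_dropped_for_prop_ihs_only(self):
        sites = pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(9) * 1000, "value": [3.0] * 9})
        assert rs.window_summarize(sites, self._win(), "prop_ihs").empty
        kept = rs.window_summarize(sites, self._win(), "max_clr")
        assert len(kept) == 1

    def test_max_clr(self):
        sites = pd.DataFrame({"chrom": "chr1", "pos": [0, 1000, 2000],
                              "value": [1.2, 7.5, 3.3]})
        tab = rs.window_summarize(sites, self._win(), "max_clr")
        assert tab["value"].iloc[0] == 7.5

    def test_unsorted_table_rejected(self):
        sites = pd.DataFrame({"chrom": "chr1", "pos": [2000, 0],
                              "value": [1.0, 2.0]})
        with pytest.raises(ValueError, match="sorted"):
            rs.window_summarize(sites, self._win(), "max_clr")

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            rs.window_summarize(pd.DataFrame(columns=["chrom", "pos", "value"]),
                                self._win(), "bogus")


class TestPiWindows:
    def test_monomorphic_window_is_zero(self):
        gm = make_matrix(make_single_chrom(np.arange(5) * 1000,
                                           chrom_len=50_000),
                         np.zeros((3, 5), dtype=np.int8))
        win = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 50_000}])
        tab = rs.pi_windows(gm, ["s0", "s1", "s2"], win)
        assert tab["value"].iloc[0] == 0.0

    def test_single_site_plug_in_value(self):
        # one site, p = 0.5 from 4 alleles: (4/3 * 0.5) / 50 kb
        gm = make_matrix(make_single_chrom(np.array([100]), chrom_len=50_000),
                         np.array([[1], [1]], dtype=np.int8))
        win = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 50_000}])
        tab = rs.pi_windows(gm, ["s0", "s1"], win)
        assert tab["value"].iloc[0] == pytest.approx((4 / 3 * 0.5) / 50_000)
        # and the pairwise-difference oracle agrees
        assert tab["value"].iloc[0] == pytest.approx(
            pairwise_pi(gm.calls, [100], 0, 50_000))

    def test_identical_individuals_have_zero_pi(self):
        row = np.array([0, 2, 0, 2, 2], dtype=np.int8)
        gm = make_matrix(make_single_chrom(np.arange(5) * 1000,
                                           chrom_len=50_000),
                         np.vstack([row, row]))
        win = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 50_000}])
        assert rs.pi_windows(gm, ["s0", "s1"], win)["value"].iloc[0] == 0.0

    def test_matches_pairwise_oracle_on_random_panels(self, rng):
        for _ in range(5):
            m = int(rng.integers(5, 50))
            n = int(rng.integers(2, 6))
            pos = np.sort(rng.choice(50_000, size=m, replace=False))
            calls = rng.choice(np.array([0, 1, 2, -1], dtype=np.int8),
                               size=(n, m), p=[.4, .3, .2, .1])
            gm = make_matrix(make_single_chrom(pos, chrom_len=60_000), calls)
            win = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 30_000},
                                {"chrom": "chr1", "start": 30_000,
                                 "end": 60_000}])
            tab = rs.pi_windows(gm, [f"s{i}" for i in range(n)], win)
            for row in tab.itertuples(index=False):
                assert row.value == pytest.approx(
                    pairwise_pi(calls, pos, row.start, row.end), abs=1e-12)

    def test_single_individual_rejected(self):
        gm = make_matrix(make_single_chrom(np.array([0]), chrom_len=1000),
                         np.array([[1]], dtype=np.int8))
        with pytest.raises(ValueError, match="2 individuals"):
            rs.pi_windows(gm, ["s0"],
                          pd.DataFrame([{"chrom": "chr1", "start": 0,
                                         "end": 1000}]))


class TestRetainWindows:
    def _table(self, values, statistic="max_clr"):
        n = len(values)
        return pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(n) * 20_000,
            "end": np.arange(n) * 20_000 + 50_000,
            "statistic": statistic,
            "value": values,
            "n_snps": 20,
        })

    def test_upper_tail_quantile_rule(self, rng):
        vals = rng.normal(size=2000)
        annotated, _ = rs.retain_windows(self._table(vals), alpha=0.01)
        from scipy import stats as ss
        z_crit = ss.norm.ppf(0.99)
        got = annotated["retained"].to_numpy()
        want = annotated["z"].to_numpy() > z_crit
        assert (got == want).all()

    def test_lower_tail_for_pi(self):
        vals = np.concatenate([np.full(50, 1.0), [0.0]])
        vals = vals + np.linspace(0, 0.01, 51)  # break exact ties
        annotated, retained = rs.retain_windows(
            self._table(vals, statistic="pi"), alpha=0.01)
        assert annotated["retained"].iloc[50]
        assert len(retained) == 1

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            rs.retain_windows(self._table(np.ones(50)))

    def test_retained_intervals_are_merged_maximal(self, rng):
        vals = rng.normal(size=500)
        vals[100:104] = 10.0  # consecutive overlapping extreme windows
        _, retained = rs.retain_windows(self._table(vals), alpha=0.01)
        covering = retained[(retained["start"] <= 100 * 20_000)
                            & (retained["end"] >= 103 * 20_000 + 50_000)]
        assert len(covering) == 1


class TestOverlapReport:
    def _hot(self, rows):
        hot = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                          "peak_freq", "min_p", "n_snps"])
        return rs.HotspotResult("g", 0.5, 0.01, hot, pd.DataFrame())

    def _layout(self):
        return make_single_chrom(np.arange(0, 1000, 10), chrom_len=1000)

    def test_intersection_counts_as_support(self):
        hr = self._hot([("chr1", 100, 200, 0.9, 0.001, 10)])
        ret = {"ihs": pd.DataFrame([{"chrom": "chr1", "start": 150,
                                     "end": 250}])}
        rep = rs.overlap_report(hr, ret, self._layout())
        assert rep["per_hotspot"]["n_methods"].iloc[0] == 1

    def test_half_open_touch_is_not_support(self):
        hr = self._hot([("chr1", 100, 200, 0.9, 0.001, 10)])
        ret = {"ihs": pd.DataFrame([{"chrom": "chr1", "start": 200,
                                     "end": 300}])}
        rep = rs.overlap_report(hr, ret, self._layout())
        assert rep["per_hotspot"]["n_methods"].iloc[0] == 0
        assert rep["pct_snps_ge1"] == 0.0

    def test_two_methods_counted(self):
        hr = self._hot([("chr1", 100, 200, 0.9, 0.001, 10)])
        ret = {"ihs": pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 150}]),
               "clr": pd.DataFrame([{"chrom": "chr1", "start": 120,
                                     "end": 500}])}
        rep = rs.overlap_report(hr, ret, self._layout())
        assert rep["per_hotspot"]["n_methods"].iloc[0] == 2
        assert rep["pct_snps_ge1"] == 100.0
        assert 0 < rep["pct_snps_ge2"] <= 100.0

    def test_fractions_invariant_to_splitting_intervals(self):
        hr = self._hot([("chr1", 100, 300, 0.9, 0.001, 20)])
        whole = {"m": pd.DataFrame([{"chrom": "chr1", "start": 100,
                                     "end": 300}])}
        split = {"m": pd.DataFrame([{"chrom": "chr1", "start": 100, "end": 200},
                                    {"chrom": "chr1", "start": 200,
                                     "end": 300}])}
        r1 = rs.overlap_report(hr, whole, self._layout())
        r2 = rs.overlap_report(hr, split, self._layout())
        assert r1["pct_snps_ge1"] == r2["pct_snps_ge1"]
        assert r1["pct_snps_ge2"] == r2["pct_snps_ge2"]
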