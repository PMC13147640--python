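import numpy as np
import pandas as pd
import pytest

import rohscan as rs
from conftest import make_single_chrom


def seg(sid, start, end, chrom="chr1"):
    return rs.ROHSegment(sid, chrom, start, end, max(2, (end - start) // 1000))


class TestCoverage:
    def test_single_carrier_track(self, toy_layout):
        segs = [seg("a", 100_000, 200_001)]
        tr = rs.coverage(segs, toy_layout, ("g", ["a"]))
        freq = tr.freqs["chr1"]
        pos = toy_layout.positions("chr1")
        inside = (pos >= 100_000) & (pos < 200_001)
        assert (freq[inside] == 1.0).all()
        assert (freq[~inside] == 0.0).all()

    def test_shared_segment_frequency(self, toy_layout):
        segs = [seg("a", 0, 50_000), seg("b", 0, 50_000)]
        tr = rs.coverage(segs, toy_layout, ("g", ["a", "b", "c", "d"]))
        assert tr.freqs["chr1"][0] == 0.5

    def test_no_segments_all_zero(self, toy_layout):
        tr = rs.coverage([], toy_layout, ("g", ["a", "b"]))
        assert all((v == 0).all() for v in tr.counts.values())

    def test_individual_counted_once_despite_overlap(self, toy_layout):
        segs = [seg("a", 0, 100_000), seg("a", 50_000, 150_000)]
        tr = rs.coverage(segs, toy_layout, ("g", ["a"]))
        assert tr.counts["chr1"].max() == 1

    def test_empty_group_rejected(self, toy_layout):
        with pytest.raises(ValueError, match="no individuals"):
            rs.coverage([], toy_layout, ("g", []))


class TestPermutationNull:
    def test_no_freedom_whole_chromosome_segment(self):
        layout = make_single_chrom(np.arange(0, 1000, 10), chrom_len=1000)
        segs = [seg("a", 0, 1000)]
        null = rs.permute_null(segs, layout, ("g", ["a"]), n_perm=50, seed=0)
        assert (null.max_freqs == 1.0).all()

    def test_no_segments_all_zero(self, toy_layout):
        null = rs.permute_null([], toy_layout, ("g", ["a"]), n_perm=20, seed=0)
        assert (null.max_freqs == 0.0).all()

    def test_deterministic_under_seed(self, toy_layout):
        segs = [seg("a", 0, 200_000), seg("b", 300_000, 500_000)]
        g = ("g", ["a", "b"])
        n1 = rs.permute_null(segs, toy_layout, g, n_perm=100, seed=4)
        n2 = rs.permute_null(segs, toy_layout, g, n_perm=100, seed=4)
        n3 = rs.permute_null(segs, toy_layout, g, n_perm=100, seed=5)
        assert np.array_equal(n1.max_freqs, n2.max_freqs)
        assert not np.array_equal(n1.max_freqs, n3.max_freqs)

    def test_matches_exhaustive_enumeration_toy(self):
        """2 individuals, 10 bp segments, 100 bp chromosome, SNP per bp."""
        layout = make_single_chrom(np.arange(100), chrom_len=100)
        segs = [seg("i1", 0, 10), seg("i2", 50, 60)]
        null = rs.permute_null(segs, layout, ("g", ["i1", "i2"]),
                               n_perm=20_000, seed=1)
        # exhaustive: both starts uniform on 0..90; max = 1.0 iff overlap
        p_overlap = sum(
            1 for a in range(91) for b in range(91)
            if a < b + 10 and b < a + 10
        ) / 91 ** 2
        observed = (null.max_freqs == 1.0).mean()
        assert set(np.unique(null.max_freqs)) == {0.5, 1.0}
        assert abs(observed - p_overlap) < 4 * np.sqrt(p_overlap * (1 - p_overlap) / 20_000)

    def test_oversized_segment_rejected(self):
        layout = make_single_chrom(np.arange(100), chrom_len=100)
        with pytest.raises(ValueError, match="longer than chromosome"):
            rs.permute_null([seg("a", 0, 101)], layout, ("g", ["a"]), 10, 0)

    def test_conservation_of_counts_and_lengths(self, toy_layout):
        """Redistribution preserves per-individual counts and lengths.

        Verified structurally: the null is built from (individual,
        length) pairs only, so we check a permuted placement drawn the
        same way the null draws it.
        """
        rng = np.random.default_rng(0)
        segs = [seg("a", 0, 200_000), seg("a", 500_000, 800_000),
                seg("b", 0, 100_000)]
        by_ind = {}
        for s in segs:
            by_ind.setdefault((s.sample_id, s.chrom), []).append(s.length_bp)
        # draw placements as the permutation does
        for (sid, chrom), lens in by_ind.items():
            L = toy_layout.lengths[chrom]
            starts = [int(rng.integers(0, L - ln + 1)) for ln in lens]
            placed = [(st, st + ln) for st, ln in zip(starts, lens)]
            assert len(placed) == len(lens)
            assert sorted(e - s for s, e in placed) == sorted(lens)
            assert all(0 <= s < e <= L for s, e in placed)


class TestCallHotspots:
    def _toy(self):
        layout = make_single_chrom(np.arange(0, 1000, 10), chrom_len=1000)
        return layout

    def test_degenerate_whole_chromosome_not_called(self):
        # observed = null = 1.0 everywhere: strict inequality calls nothing
        layout = self._toy()
        segs = [seg("a", 0, 1000)]
        obs = rs.coverage(segs, layout, ("g", ["a"]))
        null = rs.permute_null(segs, layout, ("g", ["a"]), n_perm=100, seed=0)
        res = rs.call_hotspots(obs, null)
        assert res.threshold_freq == 1.0
        assert res.hotspots.empty

    def test_adjacency_rule_two_hotspots(self, toy_layout):
        obs = rs.coverage([], toy_layout, ("g", ["a"]))
        # hand-build observed counts: two separated significant islands
        obs.counts["chr1"][10:13] = 1
        obs.counts["chr1"][50:52] = 1
        null = rs.NullMaxDistribution("g", 100, np.full(100, 0.4))
        res = rs.call_hotspots(obs, null)
        assert len(res.hotspots) == 2
        first = res.hotspots.iloc[0]
        pos = toy_layout.positions("chr1")
        assert first["start"] == pos[10] and first["end"] == pos[12] + 1

    def test_gap_bridging_merges_nearby_runs(self, toy_layout):
        obs = rs.coverage([], toy_layout, ("g", ["a"]))
        obs.counts["chr1"][10:12] = 1
        obs.counts["chr1"][14:16] = 1
        null = rs.NullMaxDistribution("g", 100, np.full(100, 0.4))
        assert len(rs.call_hotspots(obs, null).hotspots) == 2
        bridged = rs.call_hotspots(obs, null, merge_gap_bp=50_000)
        assert len(bridged.hotspots) == 1

    def test_threshold_is_order_statistic(self):
        null = rs.NullMaxDistribution("g", 100, np.arange(1, 101) / 100.0)
        # ceil(0.99 * 100) = 99th order statistic = 0.99
        assert rs.fwer_threshold(null, alpha=0.01) == pytest.approx(0.99)
        assert rs.fwer_threshold(null, alpha=0.05) == pytest.approx(0.95)

    def test_threshold_monotone_and_hotspots_shrink(self, toy_layout):
        obs = rs.coverage([], toy_layout, ("g", ["a", "b"]))
        obs.counts["chr1"][20:30] = 2
        rng = np.random.default_rng(3)
        null = rs.NullMaxDistribution("g", 500, rng.uniform(0.2, 0.9, 500))
        thrs = [rs.fwer_threshold(null, a) for a in (0.2, 0.1, 0.05, 0.01)]
        assert all(b >= a for a, b in zip(thrs, thrs[1:]))
        n_hot = [len(rs.call_hotspots(obs, null, alpha=a).hotspots)
                 for a in (0.2, 0.01)]
        assert n_hot[0] >= n_hot[1]

    def test_empirical_p_uses_plus_one_correction(self, toy_layout):
        obs = rs.coverage([], toy_layout, ("g", ["a"]))
        obs.counts["chr1"][0] = 1  # freq 1.0
        null = rs.NullMaxDistribution("g", 99, np.full(99, 0.5))
        res = rs.call_hotspots(obs, null)
        snp0 = res.snp_table.iloc[0]
        assert snp0["p_fwer"] == pytest.approx(1.0 / 100.0)  # never zero
        zero_snp = res.snp_table.iloc[5]
        assert zero_snp["p_fwer"] == pytest.approx(1.0)

    def test_alpha_out_of_range_rejected(self):
        null = rs.NullMaxDistribution("g", 10, np.zeros(10))
        with pytest.raises(ValueError, match="alpha"):
            rs.fwer_threshold(null, alpha=0.0)

    def test_planted_island_recovered_exactly(self):
        """A 90%-carried island is called; nothing called elsewhere."""
        rng = np.random.default_rng(11)
        L, spacing = 30_000_000, 10_000
        layout = make_single_chrom(np.arange(0, L, spacing), chrom_len=L)
        island = (10_000_000, 10_500_000)
        flank = 100_000
        segs = []
        for i in range(30):
            lens = np.exp(rng.normal(np.log(800_000), 0.4, 8)).astype(np.int64)
            lens = np.minimum(lens, L)
            starts = rng.integers(0, L - lens + 1)
            segs += [seg(f"i{i}", int(s0), int(s0 + ln))
                     for s0, ln in zip(starts, lens)]
        for i in rng.choice(30, 27, replace=False):
            segs.append(seg(f"i{i}", island[0] - flank, island[1] + flank))
        members = [f"i{i}" for i in range(30)]
        obs = rs.coverage(segs, layout, ("g", members))
        null = rs.permute_null(segs, layout, ("g", members), n_perm=1000,
                               seed=12)
        res = rs.call_hotspots(obs, null)
        hot = res.hotspots
        assert ((hot["start"] < island[1]) & (island[0] < hot["end"])).any()
        assert not ((hot["end"] <= island[0] - flank - spacing)
                    | (hot["start"] >= island[1] + flank + spacing)).any()


class TestRegionOverlap:
    def test_containment_counts_carrier(self, toy_layout):
        segs = [seg("a", 100_000, 300_000)]
        regions = pd.DataFrame([{"chrom": "chr1", "start": 150_000,
                                 "end": 200_000}])
        tab = rs.region_overlap_frequency(segs, {"g": ["a", "b"]}, regions)
        assert tab["freq"].iloc[0] == 0.5

    def test_half_open_touch_is_no_overlap(self, toy_layout):
        segs = [seg("a", 100_000, 200_000)]
        regions = pd.DataFrame([{"chrom": "chr1", "start": 200_000,
                                 "end": 250_000}])
        tab = rs.region_overlap_frequency(segs, {"g": ["a"]}, regions)
        assert tab["freq"].iloc[0] == 0.0

    def test_empty_region_set(self, toy_layout):
        tab = rs.region_overlap_frequency([], {"g": ["a"]},
                                          pd.DataFrame(columns=["chrom",
                                                                "start",
                                                                "end"]))
        assert tab.empty

    def test_malformed_interval_rejected(self):
        regions = pd.DataFrame([{"chrom": "chr1", "start": 10, "end": 10}])
        with pytest.raises(ValueError, match="malformed"):
            rs.region_overlap_frequency([], {"g": ["a"]}, regions)
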