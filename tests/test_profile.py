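"""Track aggregation, coverage filtering, promoter/metagene summaries, ranking."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import imprintscreen as im
from imprintscreen import (
    MethylomeTrack,
    ScreenConfig,
    TranscriptModel,
    aggregate_per_cpg,
    filter_coverage,
    metagene_matrix,
    promoter_mean_methylation,
    rank_by_methylation_ratio,
)
from conftest import make_read


def brute_force_tally(reads):
    tally = {}
    for r in reads:
        for p, s in r.cpg_calls:
            m, u = tally.get(p, (0, 0))
            tally[p] = (m + (s == "M"), u + (s == "U"))
    return tally


def track_as_dict(track):
    return {
        int(p): (int(m), int(u))
        for p, m, u in zip(track.positions, track.n_meth, track.n_unmeth)
    }


class TestAggregate:
    def test_small_tally(self):
        reads = [
            make_read("r1", [100], ["M"]),
            make_read("r2", [100], ["M"]),
            make_read("r3", [100], ["U"]),
        ]
        track = aggregate_per_cpg(reads)
        assert track_as_dict(track) == {100: (2, 1)}
        assert track.ratios[0] == pytest.approx(2 / 3)

    def test_empty(self):
        assert len(aggregate_per_cpg([])) == 0

    def test_mixed_samples_rejected(self):
        reads = [make_read("r1", [1], ["M"], sample_id="a"),
                 make_read("r2", [1], ["M"], sample_id="b")]
        with pytest.raises(ValueError, match="mix sample_ids"):
            aggregate_per_cpg(reads)

    def test_matches_brute_force_on_simulation(self, rng):
        cfg = im.SimConfig(seed=11, n_cpgs=300, depth=30)
        pos, _, _ = im.simulate_locus(cfg)
        maps = im.simulate_diploid_methylome(pos, [], 0.4)
        reads = im.simulate_bisulfite_reads(maps, pos, cfg, "s", n_reads=10_000)
        assert track_as_dict(aggregate_per_cpg(reads)) == brute_force_tally(reads)

    @given(st.lists(
        st.lists(st.tuples(st.integers(0, 50), st.booleans()),
                 max_size=8, unique_by=lambda c: c[0]),
        max_size=20))
    def test_oracle_equivalence_property(self, call_lists):
        reads = [
            make_read(f"r{i}", [p for p, _ in sorted(calls)],
                      ["M" if m else "U" for _, m in sorted(calls)])
            for i, calls in enumerate(call_lists) if calls
        ]
        assert track_as_dict(aggregate_per_cpg(reads)) == brute_force_tally(reads)


class TestFilterCoverage:
    def _track(self):
        return MethylomeTrack("s", np.array([10, 20, 30, 40]),
                              np.array([1, 1, 2, 2]), np.array([0, 1, 1, 2]))

    def test_min_cov_three(self):
        kept = filter_coverage(self._track(), 3)
        assert list(kept.positions) == [30, 40]

    def test_min_cov_one_is_identity(self):
        t = self._track()
        assert list(filter_coverage(t, 1).positions) == list(t.positions)

    def test_all_below_threshold(self):
        assert len(filter_coverage(self._track(), 10)) == 0

    def test_idempotent(self):
        once = filter_coverage(self._track(), 3)
        twice = filter_coverage(once, 3)
        assert list(once.positions) == list(twice.positions)


class TestPromoterMean:
    def test_unweighted_mean(self):
        track = MethylomeTrack("s", np.array([900, 1000, 1100]),
                               np.array([1, 2, 3]), np.array([4, 3, 2]))
        t = TranscriptModel("t", "g", "chr1", "+", 1000, 3000)
        assert promoter_mean_methylation(track, t, 2000) == pytest.approx(0.4)

    def test_overlapping_promoters_share_value(self):
        track = MethylomeTrack("s", np.array([1000, 1500]),
                               np.array([3, 1]), np.array([1, 3]))
        t1 = TranscriptModel("t1", "g", "chr1", "+", 1200, 4000)
        t2 = TranscriptModel("t2", "g", "chr1", "+", 1300, 4000)
        assert promoter_mean_methylation(track, t1, 2000) == \
            promoter_mean_methylation(track, t2, 2000)

    def test_empty_window_undefined(self):
        track = MethylomeTrack("s", np.array([10_000]), np.array([1]), np.array([1]))
        t = TranscriptModel("t", "g", "chr1", "+", 1000, 2000)
        assert promoter_mean_methylation(track, t, 500) is None


class TestMetagene:
    def test_uniform_track(self):
        pos = np.arange(0, 40_000, 10)
        track = MethylomeTrack("s", pos, np.full(pos.size, 7), np.full(pos.size, 3))
        t = TranscriptModel("t", "g", "chr1", "+", 15_000, 25_000)
        row = metagene_matrix(track, [t], flank=10_000).iloc[0]
        assert np.allclose(row.to_numpy(dtype=float), 0.7)

    def test_gene_body_higher_than_flanks(self):
        cfg = im.SimConfig(seed=13, n_cpgs=3000, depth=15)
        pos, _, _ = im.simulate_locus(cfg, origin=20_000)
        t = TranscriptModel("t", "g", "chrSim", "+",
                            int(pos[1000]), int(pos[2000]))
        body = im.ImprintSpec(im.Region("chrSim", t.tss, t.tes), 0.8, 0.8)
        maps = im.simulate_diploid_methylome(pos, [body], 0.05)
        track = filter_coverage(
            aggregate_per_cpg(im.simulate_bisulfite_reads(maps, pos, cfg, "s")), 3)
        row = metagene_matrix(track, [t], flank=10_000)
        body_cols = [c for c in row.columns if c.startswith("body")]
        flank_cols = [c for c in row.columns if not c.startswith("body")]
        assert np.nanmean(row[body_cols]) > np.nanmean(row[flank_cols])

    def test_minus_strand_mirrors_plus(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(0, 50_000, 2), 4000, replace=False))
        meth = rng.integers(0, 10, pos.size)
        track = MethylomeTrack("s", pos, meth, 10 - meth)
        plus = TranscriptModel("p", "g", "chr1", "+", 18_000, 31_000)
        minus = TranscriptModel("m", "g", "chr1", "-", 31_000, 18_000)
        mirror_pos = 49_999 - pos[::-1]
        mirror = MethylomeTrack("s", mirror_pos, meth[::-1], (10 - meth)[::-1])
        plus_on_mirror = TranscriptModel(
            "pm", "g", "chr1", "+", 50_000 - 31_000, 50_000 - 18_000)
        a = metagene_matrix(track, [minus], flank=10_000).to_numpy(dtype=float)
        b = metagene_matrix(mirror, [plus_on_mirror], flank=10_000).to_numpy(dtype=float)
        np.testing.assert_allclose(a, b, equal_nan=True)


class TestRanking:
    def _means(self, pa, cn):
        # one transcript, one sample per group
        return {"PA1": pa}, {"CN1": cn}

    def test_ratio_arithmetic(self):
        pa, cn = self._means({"t": 0.9}, {"t": 0.45})
        df = rank_by_methylation_ratio(pa, cn)
        assert df.loc[0, "ratio"] == pytest.approx((0.9 + 0.01) / (0.45 + 0.01))
        assert len(df) == 1

    def test_ratio_one_excluded(self):
        pa, cn = self._means({"t": 0.5}, {"t": 0.5})
        assert len(rank_by_methylation_ratio(pa, cn)) == 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="at least one sample"):
            rank_by_methylation_ratio({}, {"CN1": {}})

    def test_planted_signal_recovery_and_order_invariance(self, rng):
        tids = [f"t{i:03d}" for i in range(200)]
        planted = {"t005", "t050", "t100", "t150", "t199"}
        pa1, pa2, cn1, cn2 = {}, {}, {}, {}
        for tid in tids:
            base = rng.uniform(0.02, 0.08)
            if tid in planted:
                pa1[tid] = rng.uniform(0.85, 0.95)
                pa2[tid] = rng.uniform(0.85, 0.95)
                cn1[tid] = rng.uniform(0.4, 0.5)
                cn2[tid] = rng.uniform(0.4, 0.5)
            else:
                pa1[tid] = pa2[tid] = cn1[tid] = cn2[tid] = base
        df = rank_by_methylation_ratio({"PA1": pa1, "PA2": pa2},
                                       {"CN1": cn1, "CN2": cn2})
        assert set(df["transcript_id"]) == planted
        # re-sorted by PA replicate-1 mean, descending
        assert list(df["pa1_mean"]) == sorted(df["pa1_mean"], reverse=True)
        # input order invariance
        shuffled = dict(reversed(list(pa1.items())))
        df2 = rank_by_methylation_ratio({"PA1": shuffled, "PA2": pa2},
                                        {"CN1": cn1, "CN2": cn2})
        pd.testing.assert_frame_equal(df, df2)

    def test_undefined_means_excluded(self):
        pa = {"PA1": {"a": 0.9, "b": None}}
        cn = {"CN1": {"a": 0.1, "b": 0.1}}
        df = rank_by_methylation_ratio(pa, cn)
        assert list(df["transcript_id"]) == ["a"]
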