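import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dhmscan.coverage import BinnedTrack, bin_track
from dhmscan.scan import (DifferentialMarkModel, ScanParams, call_dhmrs,
                          fold_change_filter, local_background,
                          merge_candidates, paired_bin_test,
                          poisson_enrich_windows, poisson_pvalue,
                          region_fold_change, seed_extend_scan)
from _oracles import (merge_oracle, poisson_upper_tail_series, scan_oracle,
                      union_intervals)
from conftest import track_from_values


def binned(values, bin_size=100):
    values = {c: np.asarray(v, dtype=float) for c, v in values.items()}
    sizes = {c: len(v) * bin_size for c, v in values.items()}
    return BinnedTrack(bin_size=bin_size, chrom_sizes=sizes, values=values)


class TestPairedBinTest:
    def test_identical_values_give_p_one(self, rng):
        v = rng.normal(10, 2, size=5)
        assert paired_bin_test(v, v) == 1.0

    def test_constant_nonzero_difference_gives_p_zero(self):
        assert paired_bin_test([1, 2, 3, 4, 5], [3, 4, 5, 6, 7]) == 0.0

    def test_matches_reference_paired_t(self):
        a = [10, 12, 9, 11, 10]
        b = [20, 25, 19, 22, 21]
        expected = stats.ttest_rel(b, a).pvalue
        assert paired_bin_test(a, b) == pytest.approx(expected, abs=1e-10)

    def test_matches_reference_on_random_pairs(self, rng):
        for _ in range(20):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            assert paired_bin_test(a, b) == pytest.approx(
                stats.ttest_rel(b, a).pvalue, abs=1e-10)

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            paired_bin_test([1, 2], [1, 2, 3])

    def test_welch_variant(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 10)
        assert paired_bin_test(a, b, test="welch") == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue, abs=1e-10)


class TestSeedExtendScan:
    def test_equal_tracks_give_no_candidates(self):
        v = np.full(300, 7.0)
        assert len(seed_extend_scan(binned({"c": v}), binned({"c": v}))) == 0

    def test_single_offset_stretch_recovered_exactly(self, rng):
        a = rng.normal(100, 10, size=200)
        b = a.copy()
        b[40:60] += 1000.0
        cand = seed_extend_scan(binned({"c": a}), binned({"c": b}))
        assert len(cand) == 1
        assert (cand["start"].iloc[0], cand["end"].iloc[0]) == (4000, 6000)
        assert cand["scan_p"].iloc[0] <= 0.01

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle_on_noise_plus_spikes(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        a = rng.gamma(4.0, 25.0, size=n)
        b = rng.gamma(4.0, 25.0, size=n)
        b[100:120] *= 4.0
        b[300:306] *= 3.0
        cand = seed_extend_scan(binned({"c": a}), binned({"c": b}))
        expected = union_intervals(scan_oracle(a, b))
        got = [(s // 100, e // 100) for s, e in
               zip(cand["start"], cand["end"])]
        assert got == expected

    def test_per_seed_stretch_capped_at_fifty_bins(self):
        # 60 differential bins: the oracle's individual stretches obey the
        # cap, and the scan's union equals the oracle union
        rng = np.random.default_rng(5)
        a = rng.normal(100, 5, size=100)
        b = a.copy()
        b[10:70] += 1000.0
        stretches = scan_oracle(a, b)
        assert stretches and all(e - s <= 50 for s, e, _ in stretches)
        cand = seed_extend_scan(binned({"c": a}), binned({"c": b}))
        got = [(s // 100, e // 100) for s, e in zip(cand["start"], cand["end"])]
        assert got == union_intervals(stretches)

    def test_scan_p_invariant_under_common_positive_scaling(self, rng):
        a = rng.gamma(4.0, 25.0, size=300)
        b = rng.gamma(4.0, 25.0, size=300)
        b[50:70] *= 4
        c1 = seed_extend_scan(binned({"c": a}), binned({"c": b}))
        c2 = seed_extend_scan(binned({"c": a * 7.5}), binned({"c": b * 7.5}))
        pd.testing.assert_frame_equal(c1, c2)


class TestFoldChange:
    @pytest.mark.parametrize("ma,mb,kept", [
        (10.0, 25.0, True),    # (25+1)/(10+1) = 2.36
        (10.0, 15.0, False),   # 16/11 = 1.45
        (0.0, 5.0, True),      # pseudocount: 6/1 = 6
    ])
    def test_pseudocount_ratio_rule(self, ma, mb, kept):
        assert (region_fold_change(ma, mb, 1.0) >= 2.0) is kept

    def test_filter_annotates_means_from_track(self):
        a = track_from_values({"c": np.full(1000, 10.0)})
        b = track_from_values({"c": np.full(1000, 25.0)})
        regions = pd.DataFrame([("c", 0, 500, 0.001)],
                               columns=["chrom", "start", "end", "scan_p"])
        out = fold_change_filter(regions, a, b)
        assert len(out) == 1
        assert out["mean_a"].iloc[0] == pytest.approx(10.0)
        assert out["fold_change"].iloc[0] == pytest.approx(26 / 11)


class TestMerge:
    def test_gap_below_threshold_merges(self):
        df = pd.DataFrame([("c", 0, 200, 0.01), ("c", 900, 1000, 0.001)],
                          columns=["chrom", "start", "end", "scan_p"])
        out = merge_candidates(df)
        assert out.iloc[0][["start", "end"]].tolist() == [0, 1000]
        assert out["scan_p"].iloc[0] == 0.001

    def test_gap_at_threshold_does_not_merge(self):
        df = pd.DataFrame([("c", 0, 200, 0.01), ("c", 1300, 1400, 0.01)],
                          columns=["chrom", "start", "end", "scan_p"])
        assert len(merge_candidates(df)) == 2

    def test_matches_fixed_point_oracle(self, rng):
        s = rng.integers(0, 50_000, size=50)
        ivs = [(int(a), int(a + w)) for a, w in
               zip(s, rng.integers(100, 3000, size=50))]
        df = pd.DataFrame([("c", a, b, 0.5) for a, b in ivs],
                          columns=["chrom", "start", "end", "scan_p"])
        out = merge_candidates(df)
        assert list(zip(out["start"], out["end"])) == merge_oracle(ivs, 1000)

    def test_idempotent(self, rng):
        s = np.sort(rng.integers(0, 100_000, size=30))
        df = pd.DataFrame([("c", int(a), int(a) + 500, 0.5) for a in s],
                          columns=["chrom", "start", "end", "scan_p"])
        once = merge_candidates(df)
        pd.testing.assert_frame_equal(merge_candidates(once), once)
        gaps = once["start"].to_numpy()[1:] - once["end"].to_numpy()[:-1]
        assert (gaps >= 1000).all()


class TestLocalBackground:
    def _track(self, starts):
        return track_from_values({"c": np.zeros(len(starts))},
                                 starts={"c": np.asarray(starts, np.int32)})

    def test_uniform_rate_recovered(self, rng):
        starts = (rng.random(20_000) < 0.2).astype(np.int32)
        track = self._track(starts)
        lam = local_background(track, "c", 5000, 5200)
        assert lam == pytest.approx(starts[100:10_100].sum() / 10_000)

    def test_window_clipped_at_chromosome_start(self):
        starts = np.ones(12_000, dtype=np.int32)
        lam = local_background(self._track(starts), "c", 0, 200)
        # centre 100 -> nominal [-4900, 5100) -> clipped [0, 5100)
        assert lam == pytest.approx(1.0)

    def test_region_wider_than_extent_is_its_own_background(self):
        starts = np.zeros(30_000, dtype=np.int32)
        starts[12_000:13_000] = 1
        lam = local_background(self._track(starts), "c", 11_000, 26_000)
        assert lam == pytest.approx(1000 / 15_000)


class TestPoissonEnrichment:
    def test_zero_count_never_enriched(self):
        assert poisson_pvalue(0, 5.0) == 1.0

    def test_upper_tail_matches_series_oracle(self):
        assert poisson_pvalue(20, 10.0) == pytest.approx(
            poisson_upper_tail_series(20, 10.0), abs=1e-12)

    def test_zero_rate_conventions(self):
        assert poisson_pvalue(1, 0.0) == 0.0
        assert poisson_pvalue(0, 0.0) == 1.0

    def test_window_detection_against_hand_computed_tail(self):
        starts = np.zeros(20_000, dtype=np.int32)
        starts[5000:5100] = 1          # 100 starts in one window
        track = track_from_values({"c": np.zeros(20_000)},
                                  starts={"c": starts})
        lam_bp = 0.05
        ok, table = poisson_enrich_windows(track, "c", 4000, 6000, lam_bp,
                                           alpha=1e-5)
        assert ok
        best = table.loc[table["count"].idxmax()]
        assert best["count"] == 100
        assert best["p"] == pytest.approx(
            poisson_upper_tail_series(100, 5.0), rel=1e-9)
        # a uniform region at the background rate is not enriched
        ok2, _ = poisson_enrich_windows(track, "c", 10_000, 12_000, lam_bp,
                                        alpha=1e-5)
        assert not ok2


class TestCallDhmrs:
    def test_identical_tracks_give_empty_set(self, smoke_experiment):
        t = smoke_experiment["tracks"][1]
        out = call_dhmrs(t, t, "punctate")
        assert len(out) == 0

    def test_swapping_tracks_flips_direction(self, smoke_experiment):
        t1, t2 = (smoke_experiment["tracks"][c] for c in (1, 2))
        ab = call_dhmrs(t1, t2, "punctate")
        ba = call_dhmrs(t2, t1, "punctate")
        pd.testing.assert_frame_equal(ab[["chrom", "start", "end"]],
                                      ba[["chrom", "start", "end"]])
        assert (ab["direction"] != ba["direction"]).all()
        np.testing.assert_allclose(ab["fold_change"], ba["fold_change"])

    def test_emitted_records_satisfy_contract(self, smoke_experiment):
        t1, t2 = (smoke_experiment["tracks"][c] for c in (1, 2))
        out = call_dhmrs(t1, t2, "punctate")
        assert len(out) > 0
        assert (out["fold_change"] >= 2.0).all()
        assert (out["enriched_a"] | out["enriched_b"]).all()
        assert (out["end"] > out["start"]).all()

    def test_unknown_mark_class_is_an_error(self, smoke_experiment):
        t = smoke_experiment["tracks"][1]
        with pytest.raises(ValueError, match="mark_class"):
            call_dhmrs(t, t, "sharp")

    def test_model_results_summary_reports_stages(self, smoke_experiment):
        t1, t2 = (smoke_experiment["tracks"][c] for c in (1, 2))
        res = DifferentialMarkModel(t1, t2, "punctate").fit()
        assert set(res.stage_counts) == {"candidates", "fold_pass", "merged",
                                         "enriched"}
        text = res.summary()
        assert "DHMRs" in text and "stage survivors" in text
        assert res.n_dhmrs == res.stage_counts["enriched"]

    def test_strict_both_mode_is_no_less_selective(self, smoke_experiment):
        t1, t2 = (smoke_experiment["tracks"][c] for c in (1, 2))
        default = call_dhmrs(t1, t2, "punctate")
        strict = call_dhmrs(t1, t2, "punctate",
                            ScanParams(enrich_mode="both"))
        assert len(strict) <= len(default)
        if len(strict):
            assert (strict["enriched_a"] & strict["enriched_b"]).all()


class TestScanParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ScanParams(seed_bins=10, max_bins=5)
        with pytest.raises(ValueError):
            ScanParams(scan_alpha=1.5)

    def test_mark_alpha_resolution(self):
        p = ScanParams()
        assert p.resolve_alpha("punctate") == 1e-5
        assert p.resolve_alpha("broad") == 1e-3
        assert ScanParams(enrich_alpha=0.01).resolve_alpha("broad") == 0.01
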