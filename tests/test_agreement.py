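import numpy as np
import pandas as pd
import pytest

from conftest import T0, make_ethogram
from oracles import brute_force_anova_ms, brute_force_icc_a1
from sowlying import (BoutTable, DegenerateMatrixError, ParameterError,
                      ValidationError, build_ratings, icc_agreement,
                      merge_transitional_sitting)

FIXTURE_6X2 = np.array([[1, 2], [3, 4], [5, 6], [7, 8], [9, 10], [11, 12]],
                       dtype=float)


class TestMergeTransitionalSitting:
    def test_sitting_between_lying_joins_one_rest_bout(self):
        eth = make_ethogram([("lying", 0, 60), ("sitting", 60, 90),
                             ("lying", 90, 150)])
        merged = merge_transitional_sitting(eth)
        assert len(merged) == 1
        assert merged.bouts["duration_s"].iloc[0] == 150.0
        assert merged.bouts["behavior"].iloc[0] == "rest"
        assert merged.source == "ethogram_merged"

    def test_isolated_sitting_stays_upright(self):
        eth = make_ethogram([("sitting", 100, 220)])
        assert len(merge_transitional_sitting(eth)) == 0

    def test_sitting_before_lying_down(self):
        eth = make_ethogram([("sitting", 0, 20), ("lying", 20, 620)])
        merged = merge_transitional_sitting(eth)
        assert len(merged) == 1
        assert merged.bouts["duration_s"].iloc[0] == 620.0

    def test_sitting_before_standing_up(self):
        eth = make_ethogram([("lying", 0, 600), ("sitting", 600, 640)])
        merged = merge_transitional_sitting(eth)
        assert len(merged) == 1
        assert merged.bouts["duration_s"].iloc[0] == 640.0

    def test_gap_beyond_tolerance_breaks_chain(self):
        eth = make_ethogram([("lying", 0, 60), ("lying", 120, 300)])
        merged = merge_transitional_sitting(eth, adjacency_tolerance=1.0)
        assert len(merged) == 2
        merged_wide = merge_transitional_sitting(eth, adjacency_tolerance=60.0)
        assert len(merged_wide) == 1

    def test_never_more_bouts_never_less_rest_than_raw(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            events, t = [], 0
            while t < 80000:
                t += int(rng.integers(60, 1200))
                d = int(rng.integers(30, 2000))
                beh = "sitting" if rng.random() < 0.4 else "lying"
                events.append((beh, t, min(t + d, 86000)))
                t += d
                if t >= 86000:
                    break
            eth = make_ethogram(events)
            raw = BoutTable.from_ethogram(eth)
            merged = merge_transitional_sitting(eth)
            assert len(merged) <= len(raw)
            assert merged.total_seconds() >= raw.total_seconds()


class TestBuildRatings:
    def windows(self, n=5):
        return [(f"w{i}", T0 + pd.Timedelta(days=i), T0 + pd.Timedelta(days=i + 1))
                for i in range(n)]

    def bouts_on_days(self, days, start_h=10, dur_s=3600):
        return BoutTable.from_records("sow1", [
            {"behavior": "lying",
             "start": T0 + pd.Timedelta(days=d, hours=start_h),
             "stop": T0 + pd.Timedelta(days=d, hours=start_h, seconds=dur_s)}
            for d in days])

    def test_identical_tables_give_identical_columns(self):
        b = self.bouts_on_days(range(5))
        m = build_ratings(b, b, self.windows())
        assert (m["video"] == m["sensor"]).all()

    def test_video_only_window(self):
        video = self.bouts_on_days([0])
        sensor = BoutTable.empty("sow1")
        m = build_ratings(video, sensor, self.windows(1), measure="lying_seconds")
        assert tuple(m.iloc[0]) == (3600.0, 0.0)

    def test_measure_switch_preserves_row_set(self):
        video = self.bouts_on_days(range(5))
        sensor = self.bouts_on_days(range(5), start_h=11)
        m1 = build_ratings(video, sensor, self.windows())
        m2 = build_ratings(video, sensor, self.windows(), measure="lying_seconds")
        assert list(m1.index) == list(m2.index)
        assert not m1.equals(m2)

    def test_low_coverage_windows_dropped(self):
        b = self.bouts_on_days(range(5))
        coverage = [(T0 + pd.Timedelta(days=1), T0 + pd.Timedelta(days=5))]
        m = build_ratings(b, b, self.windows(), sensor_coverage=coverage)
        assert len(m) == 4  # day 0 has zero sensor coverage -> dropped

    def test_unknown_measure_rejected(self):
        b = self.bouts_on_days([0])
        with pytest.raises(ParameterError):
            build_ratings(b, b, self.windows(1), measure="bouts_per_hour")


class TestICC:
    def test_fixture_matches_definitional_oracle(self):
        res = icc_agreement(FIXTURE_6X2)
        expect = brute_force_icc_a1(FIXTURE_6X2.tolist())
        assert res.estimate == pytest.approx(expect, rel=1e-10)
        assert res.estimate == pytest.approx(28.0 / 29.0, rel=1e-12)
        msr, msc, mse = brute_force_anova_ms(FIXTURE_6X2.tolist())
        assert res.ms_rows == pytest.approx(msr, rel=1e-12)
        assert res.ms_cols == pytest.approx(msc, rel=1e-12)
        assert res.ms_error == pytest.approx(mse, abs=1e-12)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_identical_columns_give_one(self):
        col = np.arange(8, dtype=float)
        res = icc_agreement(np.column_stack([col, col]))
        assert res.estimate == pytest.approx(1.0, abs=1e-12)

    def test_large_offset_tiny_row_variance_is_near_zero(self):
        col = np.array([0.0, 0.01, 0.02, 0.005, 0.015, 0.01])
        x = np.column_stack([col, col + 100.0])
        res = icc_agreement(x)
        assert abs(res.estimate) < 0.01
        assert res.estimate == pytest.approx(brute_force_icc_a1(x.tolist()),
                                             abs=1e-10)

    def test_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(2, 51))
            k = int(rng.integers(2, 5))
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), (n, k))
            res = icc_agreement(x)
            expect = brute_force_icc_a1(x.tolist())
            assert res.estimate == pytest.approx(expect, rel=1e-10, abs=1e-12)

    def test_location_scale_and_permutation_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(3, 1, (15, 2)) + rng.normal(0, 1, (15, 1))
        base = icc_agreement(x)
        shifted = icc_agreement(x + 123.4)
        scaled = icc_agreement(x * 7.5)
        permuted = icc_agreement(x[rng.permutation(15)])
        for other in (shifted, scaled, permuted):
            assert other.estimate == pytest.approx(base.estimate, rel=1e-9)
            assert other.ci_low == pytest.approx(base.ci_low, rel=1e-6)
            assert other.ci_high == pytest.approx(base.ci_high, rel=1e-6)

    def test_matches_published_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        x = rng.normal(10, 3, (12, 2)) + rng.normal(0, 2, (12, 1))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["video", "sensor"], 12),
            "score": x.ravel()})
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="score").set_index("Type")
        for form, row in (("A,1", "ICC(A,1)"), ("C,1", "ICC(C,1)")):
            res = icc_agreement(x, form=form)
            assert res.estimate == pytest.approx(ref.loc[row, "ICC"], rel=1e-9)
            lo, hi = ref.loc[row, "CI95"]
            assert res.ci_low == pytest.approx(lo, abs=5e-3)
            assert res.ci_high == pytest.approx(hi, abs=5e-3)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateMatrixError):
            icc_agreement(np.full((5, 2), 3.0))
        with pytest.raises(ValidationError):
            icc_agreement(np.array([[1.0, 2.0]]))
        with pytest.raises(ValidationError):
            icc_agreement(np.array([[1.0], [2.0]]))
        with pytest.raises(ParameterError):
            icc_agreement(FIXTURE_6X2, form="B,2")

    def test_rows_with_missing_cells_dropped(self):
        x = np.vstack([FIXTURE_6X2, [np.nan, 5.0]])
        res = icc_agreement(x)
        assert res.n == 6
        assert res.estimate == pytest.approx(28.0 / 29.0, rel=1e-12)

    def test_summary_mentions_form_and_ci(self):
        text = icc_agreement(FIXTURE_6X2).summary()
        assert "ICC(A,1)" in text and "95% CI" in text
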