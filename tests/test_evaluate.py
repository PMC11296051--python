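import numpy as np
import pandas as pd
import pytest

from pcedetect.dives import Dive, detect_dives
from pcedetect.evaluate import (EvalConfig, dive_counts, dive_level_metrics,
                                phase_distribution, pointwise_metrics,
                                predicted_event_centers, regress_counts)
from pcedetect.simulate import SimConfig, simulate_trip


def _dive(start, end, kind="regular"):
    return Dive(dive_id=0, start_idx=start, end_idx=end, max_depth_m=10.0,
                duration_s=(end - start) / 25.0, kind=kind,
                descent_end_idx=start + (end - start) // 4,
                ascent_start_idx=end - (end - start) // 4)


class TestDiveCounts:
    def test_sixteen_predicted_samples_is_two_events(self):
        n = 500
        depth = np.full(n, 5.0)
        pred = np.zeros(n, dtype=np.uint8)
        pred[120:136] = 1
        labels = np.zeros(n, dtype=np.uint8)
        df = dive_counts(pred, labels, [_dive(100, 400)], depth)
        assert df.loc[0, "predicted"] == pytest.approx(2.0)
        assert df.loc[0, "predicted_int"] == 2

    def test_empty_dive_counts_zero(self):
        n = 300
        df = dive_counts(np.zeros(n, np.uint8), np.zeros(n, np.uint8),
                         [_dive(50, 250)], np.full(n, 5.0))
        assert df.loc[0, "observed"] == 0.0
        assert df.loc[0, "predicted"] == 0.0

    def test_shallow_samples_count_for_neither(self):
        n = 300
        depth = np.full(n, 5.0)
        depth[100:110] = 0.3  # briefly above the 0.4 m threshold mid-dive
        v = np.zeros(n, np.uint8)
        v[100:116] = 1
        df = dive_counts(v, v, [_dive(50, 250)], depth)
        assert df.loc[0, "observed_points"] == 6
        assert df.loc[0, "predicted_points"] == 6

    def test_observed_equals_planted_event_count(self):
        cfg = SimConfig(trip_duration_s=900, seed=31)
        series, events, _ = simulate_trip(cfg, "b0")
        dives = detect_dives(series)
        df = dive_counts(np.zeros(len(series), np.uint8), series.label,
                         dives, series.depth)
        in_dive_events = [e for e in events if e.phase != "surface"]
        assert df["observed"].sum() == pytest.approx(len(in_dive_events))


class TestRegression:
    def test_identity_prediction(self):
        df = pd.DataFrame({"observed": [0, 1, 2, 5, 9.0]})
        df["predicted"] = df["observed"]
        slope, intercept, r2 = regress_counts(df)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_doubling_prediction(self):
        df = pd.DataFrame({"observed": [0, 1, 2, 5.0]})
        df["predicted"] = 2 * df["observed"]
        slope, _, r2 = regress_counts(df)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_small_table_matches_normal_equations(self):
        obs = np.array([1.0, 4.0, 2.0, 7.0, 5.0])
        prd = np.array([2.0, 5.0, 1.0, 8.0, 4.0])
        df = pd.DataFrame({"observed": obs, "predicted": prd})
        # hand OLS via the normal equations
        sxx = ((obs - obs.mean()) ** 2).sum()
        sxy = ((obs - obs.mean()) * (prd - prd.mean())).sum()
        slope_hand = sxy / sxx
        intercept_hand = prd.mean() - slope_hand * obs.mean()
        r2_hand = sxy ** 2 / (sxx * ((prd - prd.mean()) ** 2).sum())
        slope, intercept, r2 = regress_counts(df)
        assert slope == pytest.approx(slope_hand, rel=1e-12)
        assert intercept == pytest.approx(intercept_hand, rel=1e-12)
        assert r2 == pytest.approx(r2_hand, rel=1e-12)

    def test_zero_variance_is_a_named_error(self):
        df = pd.DataFrame({"observed": [2.0, 2.0], "predicted": [1.0, 3.0]})
        with pytest.raises(ValueError, match="zero variance"):
            regress_counts(df)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        obs = rng.poisson(5, 40).astype(float)
        prd = obs + rng.normal(0, 1, 40)
        df = pd.DataFrame({"observed": obs, "predicted": prd})
        perm = df.sample(frac=1, random_state=1).reset_index(drop=True)
        assert regress_counts(df) == pytest.approx(regress_counts(perm))


class TestDiveLevelMetrics:
    def _table(self, obs, prd):
        return pd.DataFrame({
            "observed_points": [8 * o for o in obs],
            "predicted_int": prd,
        })

    def test_perfect_predictions(self):
        m = dive_level_metrics(self._table([1, 0, 3, 0], [1, 0, 3, 0]))
        assert m["accuracy"] == 1.0
        assert m["sensitivity"] == 1.0
        assert m["false_positive_rate"] == 0.0

    def test_all_predicted_foraging_half_truly(self):
        m = dive_level_metrics(self._table([1, 1, 0, 0], [1, 2, 1, 1]))
        assert m["accuracy"] == 0.5
        assert m["sensitivity"] == 0.5  # TP / (TP + FP), as used in the field
        assert m["false_positive_rate"] == 1.0  # FP / observed positives

    def test_no_predicted_foraging_flags_undefined(self):
        m = dive_level_metrics(self._table([0, 0], [0, 0]))
        assert m["sensitivity"] is None
        assert m["false_positive_rate"] is None
        assert m["accuracy"] == 1.0


class TestPointwiseMetrics:
    def test_identical_vectors_are_perfect(self):
        n = 1000
        v = np.zeros(n, np.uint8)
        v[300:308] = 1
        m = pointwise_metrics(v, v, [_dive(250, 750)])
        assert m["accuracy"] == 1.0
        assert m["false_positive_rate"] == 0.0

    def test_small_shift_is_forgiven_by_1s_bins(self):
        n = 1000
        labels = np.zeros(n, np.uint8)
        labels[300:308] = 1  # bin 2 of the dive starting at 250
        pred = np.zeros(n, np.uint8)
        pred[312:320] = 1  # 12 samples (0.48 s) later, same 1 s bin
        m = pointwise_metrics(labels, pred, [_dive(250, 750)])
        assert m["accuracy"] == 1.0
        assert m["sensitivity"] == 1.0

    def test_disjoint_vectors_have_zero_sensitivity(self):
        n = 1000
        labels = np.zeros(n, np.uint8)
        labels[300:308] = 1
        pred = np.zeros(n, np.uint8)
        pred[500:508] = 1
        m = pointwise_metrics(labels, pred, [_dive(250, 750)])
        assert m["sensitivity"] == 0.0
        assert m["recall_conventional"] == 0.0


class TestPhaseDistribution:
    def test_all_bottom_events(self):
        d = _dive(100, 500)
        centers = [d.descent_end_idx + 5, d.ascent_start_idx - 5]
        out = phase_distribution(centers, [d])
        assert out["bottom"] == 1.0
        assert out["surface"] == out["descent"] == out["ascent"] == 0.0

    def test_empty_event_list_is_flagged(self):
        out = phase_distribution([], [_dive(0, 100)])
        assert out["empty"]
        assert sum(out[p] for p in ("surface", "descent", "bottom",
                                    "ascent")) == 0.0

    def test_generator_mix_recovered_through_detected_dives(self):
        cfg = SimConfig(trip_duration_s=2400, seed=33)
        series, events, _ = simulate_trip(cfg, "b0")
        dives = detect_dives(series)
        out = phase_distribution([e.sample_index for e in events], dives)
        n = len(events)
        for phase, p in (("bottom", 0.83), ("ascent", 0.12)):
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(out[phase] - p) < 4 * sd + 0.02

    def test_events_outside_any_dive_are_surface(self):
        out = phase_distribution([5, 600], [_dive(100, 500)])
        assert out["surface"] == 1.0


def test_predicted_event_centers():
    v = np.zeros(50, np.uint8)
    v[10:18] = 1
    v[30:34] = 1
    np.testing.assert_array_equal(predicted_event_centers(v), [13, 31])
    assert predicted_event_centers(np.zeros(10, np.uint8)).size == 0
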