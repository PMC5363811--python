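import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import chronoluc as cl
from chronoluc.errors import AnalysisError
from conftest import make_traceset


def brute_force_window_mean(t, y, i, half=12.0):
    """Independent oracle: plain mean of all samples within +-half hours."""
    mask = (t >= t[i] - half) & (t <= t[i] + half)
    return np.mean(y[mask])


class TestDetrend:
    def test_constant_trace_detrends_to_ones(self):
        t = np.arange(0, 72.5, 0.5)
        ts = make_traceset(t, {"w": np.full(t.size, 7.0)})
        dts = cl.detrend_moving_average(ts)
        np.testing.assert_allclose(dts.well("w"), 1.0, rtol=1e-12)

    def test_cosine_detrends_to_unit_mean_oscillation(self):
        # a 24 h window averages a 24 h cosine to its offset, so the interior
        # detrended values are 1 + (a/m) cos(...)
        t = np.arange(0, 120.025, 0.05)
        m, a = 10.0, 3.0
        y = m + a * np.cos(2 * np.pi * t / 24.0)
        ts = make_traceset(t, {"w": y})
        dts = cl.detrend_moving_average(ts)
        interior = ~dts.edge_mask["w"].to_numpy()
        expected = 1 + (a / m) * np.cos(2 * np.pi * t / 24.0)
        np.testing.assert_allclose(dts.well("w")[interior], expected[interior], atol=1e-3)

    def test_interior_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        t = np.arange(0, 60.25, 0.25)
        y = rng.uniform(1.0, 100.0, t.size)
        ts = make_traceset(t, {"w": y})
        dts = cl.detrend_moving_average(ts)
        got = dts.well("w")
        for i in range(0, t.size, 7):
            expected = y[i] / brute_force_window_mean(t, y, i)
            assert got[i] == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 120))
        t = np.cumsum(rng.uniform(0.2, 2.0, n))
        y = rng.lognormal(2.0, 1.0, n)
        if np.max(np.diff(t)) > 6.0:
            t = np.linspace(0, 50, n)
        ts = make_traceset(t, {"w": y})
        got = cl.detrend_moving_average(ts).well("w")
        expected = np.array(
            [y[i] / brute_force_window_mean(t, y, i) for i in range(n)]
        )
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_edge_points_masked(self):
        t = np.arange(0, 48.5, 0.5)
        ts = make_traceset(t, {"w": np.linspace(1, 2, t.size)})
        dts = cl.detrend_moving_average(ts)
        mask = dts.edge_mask["w"].to_numpy()
        assert mask[0] and mask[-1]
        assert not mask[t.size // 2]

    def test_nonpositive_counts_error_names_well_and_time(self):
        t = np.arange(0, 48.5, 0.5)
        y = np.full(t.size, 5.0)
        y[10] = 0.0
        ts = make_traceset(t, {"bad_well": y})
        with pytest.raises(AnalysisError, match="bad_well.*t=5.0"):
            cl.detrend_moving_average(ts)

    def test_coarse_grid_rejected(self):
        t = np.arange(0, 96, 8.0)
        ts = make_traceset(t, {"w": np.full(t.size, 5.0)})
        with pytest.raises(AnalysisError, match="coarse"):
            cl.detrend_moving_average(ts)

    def test_wells_with_missing_values_skipped_and_reported(self):
        t = np.arange(0, 48.5, 0.5)
        y = np.full(t.size, 5.0)
        y2 = y.copy()
        y2[3] = np.nan
        ts = make_traceset(t, {"ok": y, "gappy": y2})
        dts = cl.detrend_moving_average(ts)
        assert dts.wells == ["ok"]
        assert dts.skipped_wells == ("gappy",)


class TestNormalizeAtTime:
    def test_hand_example(self):
        ts = make_traceset([0.0, 1.0], {"w": [50.0, 25.0]})
        out, skipped = cl.normalize_at_time(ts, 0.0)
        np.testing.assert_allclose(out.well("w"), [100.0, 50.0])
        assert skipped == []

    def test_reference_at_maximum_bounds_trace_at_100(self, cosine_ts):
        out, _ = cl.normalize_at_time(cosine_ts, 24.0)  # a cosine peak
        assert np.all(out.well("w1") <= 100.0 + 1e-9)

    def test_idempotent(self, cosine_ts):
        once, _ = cl.normalize_at_time(cosine_ts, 30.0)
        twice, _ = cl.normalize_at_time(once, 30.0)
        np.testing.assert_allclose(once.well("w1"), twice.well("w1"), rtol=1e-12)

    def test_zero_reference_skips_well_with_report(self):
        ts = make_traceset([0.0, 1.0], {"w": [0.0, 5.0], "v": [2.0, 4.0]})
        out, skipped = cl.normalize_at_time(ts, 0.0)
        assert skipped == ["w"]
        assert out.wells == ["v"]

    def test_reference_is_last_sample_at_or_before_time(self):
        ts = make_traceset([0.0, 1.0, 2.0], {"w": [10.0, 20.0, 40.0]})
        out, _ = cl.normalize_at_time(ts, 1.7)  # -> sample at t=1
        np.testing.assert_allclose(out.well("w"), [50.0, 100.0, 200.0])


class TestNormalizeToKthPeak:
    def _damped(self):
        t = np.arange(0, 120.5, 0.5)
        y = 10.0 + 5.0 * np.exp(-0.004 * t) * np.cos(2 * np.pi * t / 24.0)
        return make_traceset(
            t, {"w": y}, {"w": {"strain_label": "WT"}}
        )

    def test_equal_peaks_all_scale_to_100(self):
        t = np.arange(0, 120.5, 0.5)
        y = 10.0 + 5.0 * np.cos(2 * np.pi * t / 24.0)
        ts = make_traceset(t, {"w": y}, {"w": {"strain_label": "WT"}})
        out, skipped = cl.normalize_to_kth_peak(ts, k=3)
        assert skipped == []
        # every cosine peak has the same height, so all scale to 100
        assert out.well("w").max() == pytest.approx(100.0, rel=1e-9)

    def test_damped_trace_first_peak_above_third(self):
        out, _ = cl.normalize_to_kth_peak(self._damped(), k=3)
        t, y = out.time_h, out.well("w")
        # detectable peaks sit near 24, 48, 72, ...; the third (~72 h) is
        # scaled to 100, so the less-damped first one must exceed it
        third = y[np.abs(t - 72.0) <= 2.0].max()
        first = y[np.abs(t - 24.0) <= 2.0].max()
        assert third == pytest.approx(100.0, rel=1e-3)
        assert first > 100.0

    def test_flat_trace_group_skipped(self):
        t = np.arange(0, 120.5, 0.5)
        ts = make_traceset(t, {"w": np.full(t.size, 3.0)}, {"w": {"strain_label": "flat"}})
        out, skipped = cl.normalize_to_kth_peak(ts, k=3)
        assert skipped == ["flat"] or skipped == [("flat",)]
        assert out.n_wells == 0


class TestAggregateReplicates:
    def test_hand_mean_and_sd(self):
        ts = make_traceset(
            [0.0],
            {"a": [2.0], "b": [4.0]},
            {"a": {"strain_label": "WT"}, "b": {"strain_label": "WT"}},
        )
        agg = cl.aggregate_replicates(ts, ["strain_label"])
        assert agg.loc[0, "mean"] == pytest.approx(3.0)
        assert agg.loc[0, "sd"] == pytest.approx(np.sqrt(2.0))
        assert agg.loc[0, "n"] == 2

    def test_singleton_group_sd_zero_and_flagged(self):
        ts = make_traceset([0.0, 1.0], {"a": [2.0, 3.0]}, {"a": {"strain_label": "WT"}})
        agg = cl.aggregate_replicates(ts, ["strain_label"])
        assert (agg["sd"] == 0.0).all()
        assert agg["singleton"].all()

    def test_identical_replicates_sd_zero(self):
        ts = make_traceset(
            [0.0, 1.0],
            {"a": [2.0, 3.0], "b": [2.0, 3.0]},
            {"a": {"strain_label": "WT"}, "b": {"strain_label": "WT"}},
        )
        agg = cl.aggregate_replicates(ts, ["strain_label"])
        assert (agg["sd"] == 0.0).all()
        assert not agg["singleton"].any()

    def test_permutation_invariant_in_well_order(self):
        rng = np.random.default_rng(0)
        t = np.arange(4.0)
        vals = {f"w{i}": rng.uniform(1, 9, 4) for i in range(5)}
        meta = {w: {"strain_label": "WT"} for w in vals}
        a = cl.aggregate_replicates(make_traceset(t, vals, meta), ["strain_label"])
        rev = dict(reversed(list(vals.items())))
        b = cl.aggregate_replicates(make_traceset(t, rev, meta), ["strain_label"])
        pd.testing.assert_frame_equal(a, b)

    def test_empty_traceset_rejected(self):
        with pytest.raises(AnalysisError):
            cl.aggregate_replicates(make_traceset([], {}), ["strain_label"])
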