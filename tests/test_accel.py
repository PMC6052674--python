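"""ODBA computation, calibration, and temporal/thermal aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from terrapath import accel
from terrapath.accel import AccBurst, Calibration

from conftest import make_burst


def naive_odba(samples, rate, window=None):
    """Independent per-sample brute-force ODBA (pure python loops)."""
    n = len(samples)
    if window is None:
        w = None
    else:
        w = int(round(window * rate))
    total = 0.0
    for i in range(n):
        s = 0.0
        for ax in range(3):
            if w is None:
                m = sum(samples[j][ax] for j in range(n)) / n
            else:
                lo = max(0, i - (w - 1) // 2)
                hi = min(n, i + w // 2 + 1)
                m = sum(samples[j][ax] for j in range(lo, hi)) / (hi - lo)
            s += abs(samples[i][ax] - m)
        total += s
    return total / n


class TestCalibration:
    def test_identity(self):
        b = make_burst(np.random.default_rng(0).normal(0, 0.1, (30, 3)),
                       calibration=Calibration(np.zeros(3), np.ones(3)))
        out = accel.apply_calibration(b)
        np.testing.assert_array_equal(out.samples, b.samples)

    def test_offset_shifts_axis_exactly(self):
        samples = np.zeros((10, 3))
        b = make_burst(samples,
                       calibration=Calibration([0.05, 0.0, 0.0], np.ones(3)))
        out = accel.apply_calibration(b)
        np.testing.assert_allclose(out.samples[:, 0], -0.05)
        np.testing.assert_array_equal(out.samples[:, 1:], 0.0)

    def test_missing_calibration_names_device(self):
        b = make_burst(np.zeros((10, 3)), individual="T07")
        with pytest.raises(ValueError, match="T07"):
            accel.apply_calibration(b)

    def test_zero_gain_rejected(self):
        with pytest.raises(ValueError, match="gain"):
            Calibration(np.zeros(3), [1.0, 0.0, 1.0])

    def test_pure_offset_miscalibration_leaves_odba_invariant(self, rng):
        # a constant per-axis offset is absorbed by the full-burst static
        # estimate, so ODBA of the miscalibrated burst equals the truth
        true = rng.normal(0, 0.05, (300, 3)) + [0, 0, 1.0]
        shifted = true + [0.08, -0.03, 0.12]
        odba_true = accel.compute_odba(make_burst(true))
        odba_shifted = accel.compute_odba(make_burst(shifted))
        assert odba_shifted == pytest.approx(odba_true, abs=1e-12)


class TestOdba:
    def test_constant_signal_is_zero(self):
        b = make_burst(np.tile([0.0, 0.0, 1.0], (300, 1)))
        assert accel.compute_odba(b) == 0.0

    def test_alternating_axis_forced_value(self):
        # x alternates +/-0.1 g about a constant mean; full-burst window
        x = np.where(np.arange(300) % 2 == 0, 0.1, -0.1)
        samples = np.column_stack([x + 0.2, np.zeros(300), np.ones(300)])
        assert accel.compute_odba(make_burst(samples)) == pytest.approx(0.1, abs=1e-15)

    @pytest.mark.parametrize("window", [None, 2.0, 5.0])
    def test_matches_naive_oracle(self, window, rng):
        samples = rng.normal(0, 0.1, (60, 3)) + [0, 0, 1.0]
        b = make_burst(samples, rate=10.0)
        expected = naive_odba(samples.tolist(), 10.0, window)
        assert accel.compute_odba(b, window=window) == pytest.approx(
            expected, abs=1e-12
        )

    def test_linear_scaling_of_dynamic_component(self, rng):
        static = np.array([0.0, 0.0, 1.0])
        dyn = rng.normal(0, 0.05, (200, 3))
        dyn -= dyn.mean(axis=0)  # exactly zero-mean dynamic part
        base = accel.compute_odba(make_burst(static + dyn))
        for c in (2.0, -3.0, 0.5):
            scaled = accel.compute_odba(make_burst(static + c * dyn))
            assert scaled == pytest.approx(abs(c) * base, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            accel.compute_odba(make_burst(np.empty((0, 3))))
        with pytest.raises(ValueError, match="2 samples"):
            accel.compute_odba(make_burst(np.zeros((30, 3))), window=0.05)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([None, 1.0]))
    def test_nonnegative(self, seed, window):
        samples = np.random.default_rng(seed).normal(0, 0.2, (40, 3))
        assert accel.compute_odba(make_burst(samples), window=window) >= 0.0


class TestAggregation:
    def _records(self, rng, n=1000):
        ts = pd.Timestamp("2015-06-01 07:00") + pd.to_timedelta(
            rng.integers(0, 4 * 12 * 6, n) * 10, unit="min"
        )
        return pd.DataFrame(
            {
                "individual": rng.choice(["T01", "T02", "T03"], n),
                "timestamp": ts,
                "odba": rng.gamma(2.0, 0.01, n),
                "body_temp": rng.uniform(12, 30, n),
                "hour": pd.DatetimeIndex(ts).hour,
            }
        )

    def test_single_and_equal_value_hours(self):
        ts = pd.to_datetime(["2015-06-01 08:05", "2015-06-01 09:05",
                             "2015-06-01 09:25"])
        rec = pd.DataFrame(
            {"individual": "T01", "timestamp": ts, "odba": [0.02, 0.05, 0.05],
             "hour": ts.hour}
        )
        out = accel.hourly_mean_odba(rec)
        assert len(out) == 2
        assert out.loc[out["hour"] == 8, "mean_odba"].item() == 0.02
        assert out.loc[out["hour"] == 9, "mean_odba"].item() == 0.05
        assert out.loc[out["hour"] == 9, "n_bursts"].item() == 2

    def test_hourly_mean_matches_groupby_oracle(self, rng):
        rec = self._records(rng)
        out = accel.hourly_mean_odba(rec)
        # dict-based brute force
        sums, counts = {}, {}
        for _, r in rec.iterrows():
            key = (r["individual"], r["timestamp"].date(), r["timestamp"].hour)
            sums[key] = sums.get(key, 0.0) + r["odba"]
            counts[key] = counts.get(key, 0) + 1
        assert len(out) == len(sums)
        for _, r in out.iterrows():
            key = (r["individual"], r["date"], r["hour"])
            assert r["mean_odba"] == pytest.approx(sums[key] / counts[key])
            assert r["n_bursts"] == counts[key]

    def test_temperature_bins_hand_computed(self):
        rec = pd.DataFrame(
            {
                "individual": "T01",
                "timestamp": pd.to_datetime(["2015-06-01 08:00"] * 5),
                "odba": [0.02, 0.04, 0.03, 0.10, 0.20],
                "body_temp": [20.4, 20.2, 19.6, 24.8, 25.3],
                "hour": 8,
            }
        )
        out = accel.bin_by_temperature(rec).set_index("temp_bin")
        # 20.4, 20.2, 19.6 -> bin 20; 24.8, 25.3 -> bin 25
        assert list(out.index) == [20, 25]
        assert out.loc[20, "mean_odba"] == pytest.approx(0.03)
        assert out.loc[20, "se_odba"] == pytest.approx(0.01 / np.sqrt(3))
        assert out.loc[25, "mean_odba"] == pytest.approx(0.15)
        assert out.loc[25, "se_odba"] == pytest.approx(
            np.std([0.10, 0.20], ddof=1) / np.sqrt(2)
        )

    def test_single_record_bin_has_zero_se(self):
        rec = pd.DataFrame(
            {"individual": "T01",
             "timestamp": [pd.Timestamp("2015-06-01 08:00")],
             "odba": [0.05], "body_temp": [20.4], "hour": [8]}
        )
        out = accel.bin_by_temperature(rec)
        assert out["temp_bin"].item() == 20
        assert out["se_odba"].item() == 0.0

    def test_bin_counts_conserve_records(self, rng):
        rec = self._records(rng)
        rec.loc[rec.index[:100], "body_temp"] = np.nan
        out = accel.bin_by_temperature(rec)
        assert out["n"].sum() == rec["body_temp"].notna().sum()

    def test_all_missing_temperature_errors(self):
        rec = pd.DataFrame(
            {"individual": "T01",
             "timestamp": [pd.Timestamp("2015-06-01 08:00")],
             "odba": [0.05], "body_temp": [np.nan], "hour": [8]}
        )
        with pytest.raises(ValueError, match="body temperature"):
            accel.bin_by_temperature(rec)


def test_body_temperature_join_within_tolerance(rng):
    bursts = [make_burst(rng.normal(0, 0.05, (30, 3)), ts="2015-06-01 08:00"),
              make_burst(rng.normal(0, 0.05, (30, 3)), ts="2015-06-01 12:00")]
    body = pd.DataFrame(
        {
            "individual": "T01",
            "timestamp": pd.to_datetime(
                ["2015-06-01 08:01", "2015-06-01 11:00"]
            ),
            "body_temp_c": [21.5, 28.0],
        }
    )
    rec = accel.odba_records(bursts, body)
    # 08:00 matches the reading 60 s away; 12:00 has nothing within 150 s
    assert rec.loc[rec["hour"] == 8, "body_temp"].item() == 21.5
    assert np.isnan(rec.loc[rec["hour"] == 12, "body_temp"].item())
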