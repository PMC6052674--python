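"""Dead reckoning, step geometry, movement-mode clustering, subsampling."""

import numpy as np
import pandas as pd
import pytest

from terrapath import paths, synth


def random_path(rng, n=50):
    return np.cumsum(rng.normal(0, 5, (n, 2)), axis=0)


def angle_oracle(xy):
    """Brute-force turning angles via dot products, degrees in [0, 180]."""
    out = []
    for i in range(1, len(xy) - 1):
        u = xy[i] - xy[i - 1]
        v = xy[i + 1] - xy[i]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            out.append(np.nan)
            continue
        c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
        out.append(np.degrees(np.arccos(c)))
    return np.array(out)


class TestThreadToPath:
    def test_due_north_and_east(self):
        pts = paths.thread_to_path((0.0, 0.0), [10.0], [0.0])
        np.testing.assert_allclose(pts[-1], [0.0, 10.0], atol=1e-12)
        pts = paths.thread_to_path((0.0, 0.0), [10.0], [90.0])
        np.testing.assert_allclose(pts[-1], [10.0, 0.0], atol=1e-12)

    def test_round_trip_inverse_geometry(self, rng):
        d = rng.uniform(0.01, 30.0, 40)
        b = rng.uniform(0.0, 360.0 - 1e-9, 40)
        pts = paths.thread_to_path((5.0, -3.0), d, b)
        seg = np.diff(pts, axis=0)
        d2 = np.hypot(seg[:, 0], seg[:, 1])
        b2 = np.degrees(np.arctan2(seg[:, 0], seg[:, 1])) % 360.0
        np.testing.assert_allclose(d2, d, atol=1e-9)
        np.testing.assert_allclose(b2, b, atol=1e-9)

    def test_concatenation_composes_displacements(self, rng):
        d = rng.uniform(0, 10, 20)
        b = rng.uniform(0, 360 - 1e-9, 20)
        whole = paths.thread_to_path((0, 0), d, b)
        first = paths.thread_to_path((0, 0), d[:11], b[:11])
        second = paths.thread_to_path(first[-1], d[11:], b[11:])
        np.testing.assert_allclose(
            np.vstack([first, second[1:]]), whole, atol=1e-9
        )

    def test_bad_bearing_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 360\)"):
            paths.thread_to_path((0, 0), [1.0], [361.0])
        with pytest.raises(ValueError, match="non-negative"):
            paths.thread_to_path((0, 0), [-1.0], [10.0])


class TestComputeSteps:
    def test_collinear_and_reversal(self):
        straight = paths.compute_steps(np.array([[0, 0], [1, 1], [2, 2.0]]))
        assert straight["turn_angle"].iloc[1] == pytest.approx(0.0, abs=1e-12)
        back = paths.compute_steps(np.array([[0, 0], [1, 0], [0, 0.0]]))
        assert back["turn_angle"].iloc[1] == pytest.approx(180.0, abs=1e-12)

    def test_counts(self, rng):
        xy = random_path(rng, 37)
        steps = paths.compute_steps(xy)
        assert len(steps) == 36
        assert steps["turn_angle"].notna().sum() == 35

    def test_matches_dot_product_oracle(self, rng):
        xy = random_path(rng)
        steps = paths.compute_steps(xy)
        np.testing.assert_allclose(
            steps["turn_angle"].to_numpy()[1:], angle_oracle(xy), atol=1e-9
        )
        np.testing.assert_allclose(
            steps["step_length"].to_numpy(),
            np.hypot(*np.diff(xy, axis=0).T),
            atol=1e-12,
        )

    def test_duplicate_points_give_missing_angles(self):
        xy = np.array([[0, 0], [1, 0], [1, 0], [2, 0.0]])
        steps = paths.compute_steps(xy)
        assert steps["step_length"].iloc[1] == 0.0
        assert steps["turn_angle"].iloc[1:3].isna().all()


def two_mode_steps(rng, n=400):
    """Synthetic steps from two well-separated generating modes."""
    ext = rng.random(n) < 0.5
    length = np.where(
        ext,
        np.exp(rng.normal(np.log(0.7), 0.3, n)),
        np.exp(rng.normal(np.log(5.0), 0.3, n)),
    )
    angle = np.clip(
        np.where(ext, rng.normal(150, 15, n), rng.normal(15, 10, n)), 0, 180
    )
    steps = pd.DataFrame({"step_length": length, "turn_angle": angle})
    steps.loc[0, "turn_angle"] = np.nan  # first step has no angle
    truth = np.where(ext, "extensive", "intensive")
    return steps, truth


class TestClassifyModes:
    def test_label_convention_and_partition(self, rng):
        steps, _ = two_mode_steps(rng)
        out, summary = paths.classify_modes(steps, seed=0)
        assert summary.mean_angle_extensive >= summary.mean_angle_intensive
        n_angles = steps["turn_angle"].notna().sum()
        assert summary.n_extensive + summary.n_intensive == n_angles
        assert summary.n_unassigned == len(steps) - n_angles

    def test_recovery_of_generating_modes(self, rng):
        steps, truth = two_mode_steps(rng)
        out, _ = paths.classify_modes(steps, seed=0)
        ok = out["turn_angle"].notna()
        agree = (out.loc[ok, "mode"].to_numpy() == truth[ok.to_numpy()]).mean()
        assert agree >= 0.90

    def test_order_invariance_with_fixed_seed(self, rng):
        steps, _ = two_mode_steps(rng)
        out1, _ = paths.classify_modes(steps, seed=3)
        perm = rng.permutation(len(steps))
        out2, _ = paths.classify_modes(
            steps.iloc[perm].reset_index(drop=True), seed=3
        )
        restored = out2.set_index(pd.Index(perm)).sort_index()
        assert (restored["mode"].to_numpy() == out1["mode"].to_numpy()).all()

    def test_hierarchical_alternative(self, rng):
        steps, truth = two_mode_steps(rng)
        out, _ = paths.classify_modes(steps, seed=0, method="hierarchical")
        ok = out["turn_angle"].notna()
        agree = (out.loc[ok, "mode"].to_numpy() == truth[ok.to_numpy()]).mean()
        assert agree >= 0.90

    def test_too_few_steps_rejected(self):
        steps = pd.DataFrame({"step_length": [1.0], "turn_angle": [np.nan]})
        with pytest.raises(ValueError, match="at least 2"):
            paths.classify_modes(steps)


class TestSubsample:
    def _fine(self, rng, n=73):
        t = pd.Timestamp("2015-06-01 07:00") + pd.to_timedelta(
            np.arange(n) * 10, unit="min"
        )
        xy = random_path(rng, n)
        return pd.DataFrame(
            {"individual": "T01", "timestamp": t, "x": xy[:, 0], "y": xy[:, 1]}
        )

    def test_native_interval_is_identity(self, rng):
        pts = self._fine(rng)
        out = paths.subsample(pts, pd.Timedelta(minutes=10))
        pd.testing.assert_frame_equal(out, pts)

    def test_path_length_shrinks_under_subsampling(self, rng):
        pts = self._fine(rng)
        fine_len = paths.compute_steps(pts)["step_length"].sum()
        coarse = paths.subsample(pts, pd.Timedelta(hours=1))
        coarse_len = paths.compute_steps(coarse)["step_length"].sum()
        assert coarse_len <= fine_len + 1e-9

    def test_endpoints_kept(self, rng):
        pts = self._fine(rng, n=75)  # last point off the hourly grid
        out = paths.subsample(pts, pd.Timedelta(hours=1))
        assert out["timestamp"].iloc[0] == pts["timestamp"].iloc[0]
        assert out["timestamp"].iloc[-1] == pts["timestamp"].iloc[-1]

    def test_bad_interval(self, rng):
        with pytest.raises(ValueError, match="positive"):
            paths.subsample(self._fine(rng), 0)

    def test_coarser_sampling_inflates_intensive_fraction(self):
        # the resolution-bias direction: hourly sampling of a two-mode
        # path looks straighter (more "intensive") than the fine path,
        # and measured turning angles do not increase
        cfg = synth.SynthConfig(seed=2, days=10)
        frac, ang = {}, {}
        for label, interval in (("fine", None), ("hourly", pd.Timedelta(hours=1))):
            parts = []
            for i in range(6):
                fine, _ = synth.simulate_track(
                    cfg, f"T{i:02d}", rng=np.random.default_rng(100 + i)
                )
                pts = fine[["individual", "timestamp", "x", "y"]]
                if interval is not None:
                    pts = paths.subsample(pts, interval)
                parts.append(paths.compute_steps(pts.reset_index(drop=True)))
            steps = pd.concat(parts, ignore_index=True)
            labelled, summary = paths.classify_modes(steps, seed=0)
            frac[label] = summary.n_intensive / (
                summary.n_intensive + summary.n_extensive
            )
            ang[label] = labelled["turn_angle"].mean()
        assert frac["hourly"] > frac["fine"]
        assert ang["hourly"] <= ang["fine"]


class TestModeOdbaCompare:
    def _steps(self, odbas, modes):
        n = len(odbas)
        ts = pd.Timestamp("2015-06-01 08:00") + pd.to_timedelta(
            np.arange(n), unit="h"
        )
        steps = pd.DataFrame(
            {"individual": "T01", "timestamp": ts, "mode": modes,
             "step_length": 1.0, "turn_angle": 10.0}
        )
        hourly = pd.DataFrame(
            {"individual": "T01", "date": ts.date, "hour": ts.hour,
             "mean_odba": odbas}
        )
        return steps, hourly

    def test_identical_groups_give_zero_t(self):
        steps, hourly = self._steps(
            [0.02] * 6, ["extensive"] * 3 + ["intensive"] * 3
        )
        out = paths.mode_odba_compare(steps, hourly)
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_matches_hand_computed_student_t(self):
        a = np.array([0.05, 0.06, 0.04])
        b = np.array([0.02, 0.03, 0.025])
        steps, hourly = self._steps(
            np.concatenate([a, b]), ["extensive"] * 3 + ["intensive"] * 3
        )
        out = paths.mode_odba_compare(steps, hourly)
        sp2 = ((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4.0
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert out["t"] == pytest.approx(t_hand, rel=1e-12)
        assert out["df"] == 4

    def test_small_mode_rejected(self):
        steps, hourly = self._steps(
            [0.02] * 3, ["extensive", "intensive", "intensive"]
        )
        with pytest.raises(ValueError, match="at least 2"):
            paths.mode_odba_compare(steps, hourly)
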