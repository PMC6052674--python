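"""Mixture fitting and active/inactive burst classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from sklearn.mixture import GaussianMixture

from terrapath import activity
from terrapath.activity import DegenerateDataError, MixtureFit


def sample_mixture(rng, n, mu_a, s_a, mu_b, s_b, w):
    active = rng.random(n) < w
    x = np.where(active, rng.normal(mu_a, s_a, n), rng.normal(mu_b, s_b, n))
    return x, active


def em_oracle_labels(values, seed=0):
    """Independent EM fit; returns active labels (lower-mean component)."""
    gm = GaussianMixture(2, n_init=5, random_state=seed).fit(values.reshape(-1, 1))
    post = gm.predict_proba(values.reshape(-1, 1))
    a = int(np.argmin(gm.means_.ravel()))
    return post[:, a] > 0.5, gm


class TestTransform:
    @pytest.mark.parametrize(
        "odba,expected", [(1.0, 1.0), (0.001, 10.0), (0.008, 5.0)]
    )
    def test_known_values(self, odba, expected):
        assert activity.transform_odba(odba) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="undefined"):
            activity.transform_odba(0.0)
        with pytest.raises(ValueError):
            activity.transform_odba(np.array([0.01, -0.2]))

    def test_strictly_decreasing(self):
        x = np.linspace(0.001, 1.4, 100)
        assert np.all(np.diff(activity.transform_odba(x)) < 0)

    def test_floor_replaces_zeros_by_half_min_positive(self):
        out = activity.floor_positive(np.array([0.0, 0.004, 0.01]))
        np.testing.assert_allclose(out, [0.002, 0.004, 0.01])


class TestFitMixture:
    def test_parameter_recovery_and_em_agreement(self, rng):
        x, truth = sample_mixture(rng, 2000, 3.0, 0.5, 7.0, 0.8, 0.5)
        fit = activity.fit_mixture(x, "T01", seed=1)
        assert fit.converged
        assert fit.mu_a == pytest.approx(3.0, abs=0.1)
        assert fit.mu_b == pytest.approx(7.0, abs=0.1)
        assert fit.sigma_a == pytest.approx(0.5, abs=0.15)
        assert fit.sigma_b == pytest.approx(0.8, abs=0.15)
        assert fit.weight == pytest.approx(0.5, abs=0.1)
        # independent EM oracle agrees on nearly all labels
        rec = pd.DataFrame(
            {"individual": "T01", "odba": x**-3.0,
             "timestamp": pd.Timestamp("2015-06-01 08:00")}
        )
        nls_labels = activity.classify_bursts(fit, rec)["state"] == "active"
        em_labels, _ = em_oracle_labels(x)
        assert (nls_labels.to_numpy() == em_labels).mean() >= 0.98

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateDataError):
            activity.fit_mixture(np.full(100, 5.0))

    def test_too_few_values(self):
        with pytest.raises(DegenerateDataError, match="at least"):
            activity.fit_mixture(np.arange(10.0))

    def test_single_component_flags_boundary(self, rng):
        x = rng.normal(5.0, 0.6, 500)  # mixing weight effectively 1
        fit = activity.fit_mixture(x, "T01", seed=3)
        assert fit.boundary or not fit.converged

    def test_mixture_density_integrates_to_one(self, rng):
        x, _ = sample_mixture(rng, 1000, 3.0, 0.5, 7.0, 0.8, 0.3)
        fit = activity.fit_mixture(x, "T01", seed=2)
        total, _ = integrate.quad(
            lambda v: activity.mixture_pdf(v, fit), -20, 30, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_as_printed_mode_integrates_to_two(self, rng):
        x, _ = sample_mixture(rng, 1000, 3.0, 0.5, 7.0, 0.8, 0.5)
        fit = activity.fit_mixture(x, "T01", seed=2, mode="as-printed")
        total, _ = integrate.quad(
            lambda v: activity.mixture_pdf(v, fit), -20, 30, limit=200
        )
        assert total == pytest.approx(2.0, abs=1e-6)


def _fit(mu_a=3.0, s_a=0.5, mu_b=7.0, s_b=0.5, w=0.5, mode="weighted"):
    return MixtureFit(
        individual="T01", mu_a=mu_a, sigma_a=s_a, mu_b=mu_b, sigma_b=s_b,
        weight=w, converged=True, sse=0.0, n=100, mode=mode,
    )


class TestClassify:
    def test_midpoint_tie_breaks_to_inactive(self):
        # mu chosen so odba -> transform round-trips exactly in floats,
        # making p_active exactly 0.5 at the midpoint
        fit = _fit(mu_a=1.0, mu_b=3.0, s_a=0.5, s_b=0.5)
        mid = (fit.mu_a + fit.mu_b) / 2.0
        rec = pd.DataFrame(
            {"odba": [mid**-3.0],
             "timestamp": [pd.Timestamp("2015-06-01 08:00")]}
        )
        out = activity.classify_bursts(fit, rec)
        assert out["p_active"].item() == pytest.approx(0.5, abs=1e-12)
        assert out["state"].item() == "inactive"

    def test_at_active_mean_probability_near_one(self):
        fit = _fit()
        rec = pd.DataFrame(
            {"odba": [fit.mu_a**-3.0],
             "timestamp": [pd.Timestamp("2015-06-01 08:00")]}
        )
        out = activity.classify_bursts(fit, rec)
        assert out["p_active"].item() > 0.999

    def test_unconverged_fit_refused(self):
        fit = MixtureFit(
            individual="T01", mu_a=3.0, sigma_a=0.5, mu_b=7.0, sigma_b=0.5,
            weight=0.5, converged=False, sse=1.0, n=100,
        )
        rec = pd.DataFrame(
            {"odba": [0.02], "timestamp": [pd.Timestamp("2015-06-01 08:00")]}
        )
        with pytest.raises(ValueError, match="converge"):
            activity.classify_bursts(fit, rec)

    def test_p_active_monotone_between_means(self):
        fit = _fit(s_a=0.5, s_b=0.9, w=0.3)
        grid = np.linspace(fit.mu_a, fit.mu_b, 200)
        p = activity.p_active(fit, grid)
        assert np.all(np.diff(p) <= 1e-12)

    def test_induced_odba_threshold_separates_ranges(self, rng):
        # active and inactive ODBA ranges must come out disjoint,
        # mirroring the pooled two-range split reported for field data
        x, _ = sample_mixture(rng, 2000, 3.0, 0.5, 7.0, 0.8, 0.35)
        fit = activity.fit_mixture(x, "T01", seed=4)
        rec = pd.DataFrame(
            {"odba": x**-3.0,
             "timestamp": pd.Timestamp("2015-06-01 08:00")}
        )
        out = activity.classify_bursts(fit, rec)
        act = out.loc[out["state"] == "active", "odba"]
        inact = out.loc[out["state"] == "inactive", "odba"]
        assert act.min() > inact.max()


class TestActivityProportion:
    def _labels(self, states, hour=8):
        n = len(states)
        return pd.DataFrame(
            {
                "individual": "T01",
                "timestamp": pd.Timestamp(f"2015-06-01 {hour:02d}:00")
                + pd.to_timedelta(np.arange(n) * 10, unit="min"),
                "state": states,
            }
        )

    def test_exact_ratio(self):
        out = activity.activity_proportion(
            self._labels(["active"] * 3 + ["inactive"] * 3)
        )
        assert out["prop_active"].item() == 0.5

    def test_zero_active(self):
        out = activity.activity_proportion(self._labels(["inactive"] * 6))
        assert out["prop_active"].item() == 0.0

    def test_matches_counting_oracle(self, rng):
        ts = pd.Timestamp("2015-06-01 07:00") + pd.to_timedelta(
            rng.integers(0, 12 * 6 * 4, 1000) * 10, unit="min"
        )
        labels = pd.DataFrame(
            {
                "individual": rng.choice(["T01", "T02"], 1000),
                "timestamp": ts,
                "state": rng.choice(["active", "inactive"], 1000),
            }
        )
        out = activity.activity_proportion(labels)
        counts = {}
        for _, r in labels.iterrows():
            key = (r["individual"], r["timestamp"].date(), r["timestamp"].hour)
            a, n = counts.get(key, (0, 0))
            counts[key] = (a + (r["state"] == "active"), n + 1)
        assert len(out) == len(counts)
        for _, r in out.iterrows():
            a, n = counts[(r["individual"], r["date"], r["hour"])]
            assert r["n_active"] == a and r["n_bursts"] == n
            assert r["prop_active"] == a / n
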