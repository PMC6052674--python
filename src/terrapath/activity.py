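"""Active/inactive classification of acceleration bursts.

The working assumption is that pooled per-burst ODBA values of one
individual are a two-state mixture: a power transform x = ODBA^(-1/3)
makes each state approximately Gaussian on the transformed scale, so
the pooled transformed values follow a two-component Gaussian mixture.
Because the transform is strictly decreasing, the component with the
LOWER transformed mean is the HIGHER-ODBA (active) state.

The mixture is fitted per individual by non-linear least squares
against an empirical density (histogram by default), each burst is then
assigned the posterior probability of the active component, and hourly
activity is the exact fraction of active bursts in the hour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DegenerateDataError",
    "MixtureFit",
    "transform_odba",
    "floor_positive",
    "fit_mixture",
    "mixture_pdf",
    "classify_bursts",
    "activity_proportion",
]


class DegenerateDataError(ValueError):
    """Raised when the data cannot identify a two-component mixture."""


@dataclass(frozen=True)
class MixtureFit:
    """Per-individual two-Gaussian mixture on the transformed ODBA scale.

    Component a (``mu_a < mu_b``) is the active state: a low
    transformed mean corresponds to high ODBA.  ``weight`` is the
    mixing proportion of component a.  In ``as-printed`` mode the two
    components carry equal unit weights (the summed pdf integrates to
    2; kept only for compatibility) and ``weight`` is reported as 0.5.
    """

    individual: str
    mu_a: float
    sigma_a: float
    mu_b: float
    sigma_b: float
    weight: float
    converged: bool
    sse: float
    n: int
    boundary: bool = False
    mode: str = "weighted"

    def __post_init__(self):
        if not (self.sigma_a > 0 and self.sigma_b > 0):
            raise ValueError("component SDs must be positive")
        if not (0.0 < self.weight < 1.0):
            raise ValueError("mixing weight must lie strictly in (0, 1)")
        if not self.mu_a < self.mu_b:
            raise ValueError("components must be ordered mu_a < mu_b")


def transform_odba(odba):
    """Power transform x = ODBA^(-1/3); strictly decreasing, undefined at 0.

    Raises on non-positive input; use :func:`floor_positive` first if
    calibrated data may contain zeros.
    """
    x = np.asarray(odba, dtype=float)
    if np.any(x <= 0):
        raise ValueError("transform undefined for ODBA <= 0; floor values first")
    out = x ** (-1.0 / 3.0)
    return float(out) if np.isscalar(odba) else out


def floor_positive(odba):
    """Replace non-positive ODBA values by half the smallest positive value."""
    x = np.asarray(odba, dtype=float)
    pos = x[x > 0]
    if pos.size == 0:
        raise ValueError("no positive ODBA values to define a floor")
    return np.where(x > 0, x, 0.5 * pos.min())


def mixture_pdf(x, fit: MixtureFit):
    """Density of the fitted mixture at transformed values ``x``.

    In ``as-printed`` mode this is the equal-unit-weight sum of the two
    component pdfs (it integrates to 2, not 1).
    """
    pa = stats.norm.pdf(x, fit.mu_a, fit.sigma_a)
    pb = stats.norm.pdf(x, fit.mu_b, fit.sigma_b)
    if fit.mode == "as-printed":
        return pa + pb
    return fit.weight * pa + (1.0 - fit.weight) * pb


def _empirical_density(values: np.ndarray, how: str):
    if how == "histogram":
        dens, edges = np.histogram(values, bins="fd", density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers, dens
    if how == "kde":
        kde = stats.gaussian_kde(values)
        grid = np.linspace(values.min(), values.max(), 256)
        return grid, kde(grid)
    raise ValueError(f"unknown density estimator {how!r}")


def _model_density(theta, x, mode):
    m1, m2, ls1, ls2, lw = theta
    s1, s2 = np.exp(ls1), np.exp(ls2)
    p1 = stats.norm.pdf(x, m1, s1)
    p2 = stats.norm.pdf(x, m2, s2)
    if mode == "as-printed":
        return p1 + p2
    w = 1.0 / (1.0 + np.exp(-lw))
    return w * p1 + (1.0 - w) * p2


def fit_mixture(
    values,
    individual: str = "",
    *,
    init=None,
    min_n: int = 50,
    mode: str = "weighted",
    density: str = "histogram",
    max_restarts: int = 20,
    seed: int = 0,
) -> MixtureFit:
    """Fit the two-Gaussian mixture to one individual's transformed values
    by non-linear least squares against an empirical density.

    Parameters
    ----------
    values : transformed ODBA values (one individual)
    init : optional (mu_a, mu_b, sigma_a, sigma_b, weight) starting point
    mode : "weighted" (proper mixture, default) or "as-printed"
        (equal unit weights; compatibility only)
    density : "histogram" (Freedman-Diaconis bins, default) or "kde"

    Raises
    ------
    DegenerateDataError for near-constant data or n below ``min_n``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < min_n:
        raise DegenerateDataError(f"need at least {min_n} values, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if np.std(v) < 1e-8 * max(1.0, abs(np.mean(v))):
        raise DegenerateDataError("values are (near-)constant; mixture unidentifiable")

    x, dens = _empirical_density(v, density)

    med = np.median(v)
    lo, hi = v[v <= med], v[v > med]
    pooled_sd = max(np.std(v) / 2.0, 1e-3)
    if init is not None:
        m1, m2, s1, s2, w = (
            init[0],
            init[1],
            init[2],
            init[3],
            init[4] if len(init) > 4 else 0.5,
        )
    else:
        m1, m2 = np.mean(lo), np.mean(hi)
        s1 = s2 = pooled_sd
        w = 0.5
    theta0 = np.array([m1, m2, np.log(s1), np.log(s2), np.log(w / (1 - w))])

    rng = np.random.default_rng(seed)
    best = None
    start = theta0
    for attempt in range(max_restarts + 1):
        try:
            res = optimize.least_squares(
                lambda th: _model_density(th, x, mode) - dens,
                start,
                method="lm",
                max_nfev=5000,
            )
        except Exception:
            res = None
        if res is not None and np.all(np.isfinite(res.x)):
            sse = float(2.0 * res.cost)
            # a converged fit always beats an unconverged one; among
            # converged (or among unconverged) fits, lower SSE wins
            key = (not res.success, sse)
            if best is None or key < (not best[0].success, best[1]):
                best = (res, sse)
            if res.success:
                break
        # perturbed restart
        span = v.max() - v.min()
        start = theta0 + rng.normal(0, 1, 5) * np.array(
            [0.2 * span, 0.2 * span, 0.5, 0.5, 1.0]
        )

    if best is None:
        raise RuntimeError("mixture fit failed on all restarts")
    res, sse = best
    m1, m2, ls1, ls2, lw = res.x
    s1, s2 = float(np.exp(ls1)), float(np.exp(ls2))
    w = 0.5 if mode == "as-printed" else float(1.0 / (1.0 + np.exp(-lw)))
    if m1 > m2:
        m1, m2, s1, s2, w = m2, m1, s2, s1, 1.0 - w
    w = float(np.clip(w, 1e-6, 1 - 1e-6))
    s1, s2 = max(s1, 1e-9), max(s2, 1e-9)
    # flag solutions at/near the boundary of identifiability: a vanishing
    # component, or separation below ~2 pooled SDs (the classic condition
    # under which a two-Gaussian mixture is effectively unimodal)
    pooled = np.sqrt((s1**2 + s2**2) / 2.0)
    boundary = w < 0.05 or w > 0.95 or (m2 - m1) < 2.0 * pooled
    return MixtureFit(
        individual=individual,
        mu_a=float(m1),
        sigma_a=s1,
        mu_b=float(m2),
        sigma_b=s2,
        weight=w,
        converged=bool(res.success),
        sse=sse,
        n=int(v.size),
        boundary=bool(boundary),
        mode=mode,
    )


def p_active(fit: MixtureFit, transformed):
    """Posterior probability of the active (low transformed mean) component."""
    x = np.asarray(transformed, dtype=float)
    la = stats.norm.logpdf(x, fit.mu_a, fit.sigma_a)
    lb = stats.norm.logpdf(x, fit.mu_b, fit.sigma_b)
    if fit.mode == "as-printed":
        wa = wb = 0.5
    else:
        wa, wb = fit.weight, 1.0 - fit.weight
    la = la + np.log(wa)
    lb = lb + np.log(wb)
    m = np.maximum(la, lb)
    pa = np.exp(la - m)
    return pa / (pa + np.exp(lb - m))


def classify_bursts(fit: MixtureFit, records: pd.DataFrame) -> pd.DataFrame:
    """Label each burst active/inactive by mixture posterior.

    ``records`` needs an ``odba`` column; zeros are floored before the
    transform.  The label is active iff p_active > 0.5 (an exact tie is
    inactive — the conservative, deterministic choice).  Classification
    uses only this individual's fit, never pooled data.
    """
    if not fit.converged:
        raise ValueError(f"mixture fit for {fit.individual!r} did not converge")
    out = records.copy()
    x = transform_odba(floor_positive(out["odba"].to_numpy()))
    out["transformed"] = x
    out["p_active"] = p_active(fit, x)
    out["state"] = np.where(out["p_active"] > 0.5, "active", "inactive")
    return out


def activity_proportion(labels: pd.DataFrame) -> pd.DataFrame:
    """Hourly proportion of active bursts per individual x date x hour.

    ``prop_active`` is exactly n_active / n_bursts.
    """
    df = labels.copy()
    df["date"] = df["timestamp"].dt.date
    df["hour"] = df["timestamp"].dt.hour
    df["active"] = (df["state"] == "active").astype(int)
    g = (
        df.groupby(["individual", "date", "hour"], sort=True)["active"]
        .agg(n_active="sum", n_bursts="size")
        .reset_index()
    )
    g["prop_active"] = g["n_active"] / g["n_bursts"]
    return g
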