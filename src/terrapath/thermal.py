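"""Thermal performance curves (TPC) for activity as a function of body
temperature.

Activity (mean ODBA) is binned at whole degrees Celsius; a set of
candidate curves — constant, quadratic, Gaussian, skewed Gaussian, and
cubic regression splines of increasing flexibility — is fitted to the
binned means by least squares and ranked by the small-sample-corrected
least-squares AIC (AICc), n*ln(SSE/n) + 2k + 2k(k+1)/(n-k-1) — the
correction matters here because candidate flexibility (up to 8
parameters) is large relative to the couple of dozen one-degree bins a
field season yields.  The winning curve gives the thermal optimum
(argmax) and the performance breadth: the contiguous temperature
interval around the optimum where predicted performance stays at or
above a fraction (default 80%) of the maximum.  A flat, wide breadth is
the signature of a thermal generalist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import interpolate, optimize, special

__all__ = ["TpcFit", "BreadthResult", "fit_tpc", "performance_breadth", "CANDIDATES"]


@dataclass(frozen=True)
class TpcFit:
    name: str
    params: np.ndarray
    aic: float
    predict: Callable[[np.ndarray], np.ndarray]
    candidates: pd.DataFrame  # model, k, aic, delta_aic (NaN when skipped)
    temp_range: tuple[float, float]


@dataclass(frozen=True)
class BreadthResult:
    level: float
    t_opt: float
    lo: float
    hi: float


def _fit_constant(t, y, w):
    c = float(np.average(y, weights=w))
    return np.array([c]), lambda x: np.full(np.shape(x), c, dtype=float)


def _fit_quadratic(t, y, w):
    coef = np.polyfit(t, y, 2, w=np.sqrt(w))
    return coef, lambda x: np.polyval(coef, np.asarray(x, dtype=float))


# both peaked families carry a baseline offset so that every candidate
# family is closed under affine rescaling of the response (this makes
# the AIC ranking invariant to units of the activity measure)


def _gauss(x, a, t0, w, c):
    return c + a * np.exp(-((x - t0) ** 2) / (2.0 * w**2))


def _fit_gaussian(t, y, w):
    a0 = max(float(np.max(y) - np.min(y)), 1e-9)
    t0 = float(t[np.argmax(y)])
    w0 = max((t.max() - t.min()) / 4.0, 0.5)
    popt, _ = optimize.curve_fit(
        _gauss, t, y, p0=[a0, t0, w0, float(np.min(y))],
        sigma=1.0 / np.sqrt(w), maxfev=10000
    )
    return np.asarray(popt), lambda x: _gauss(np.asarray(x, dtype=float), *popt)


def _skewgauss(x, a, t0, w, s, c):
    z = (x - t0) / w
    return c + a * np.exp(-(z**2) / 2.0) * (1.0 + special.erf(s * z / np.sqrt(2.0)))


def _fit_skewgauss(t, y, w):
    a0 = max(float(np.max(y) - np.min(y)), 1e-9)
    t0 = float(t[np.argmax(y)])
    w0 = max((t.max() - t.min()) / 4.0, 0.5)
    popt, _ = optimize.curve_fit(
        _skewgauss, t, y, p0=[a0, t0, w0, 0.1, float(np.min(y))],
        sigma=1.0 / np.sqrt(w), maxfev=20000
    )
    return np.asarray(popt), lambda x: _skewgauss(np.asarray(x, dtype=float), *popt)


def _fit_bspline(df):
    def fit(t, y, w):
        k = 3
        n_interior = df - (k + 1)
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(t, qs)
        else:
            interior = np.array([])
        knots = np.concatenate(
            [[t.min()] * (k + 1), interior, [t.max()] * (k + 1)]
        )
        dm = interpolate.BSpline.design_matrix(t, knots, k).toarray()
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(dm * sw[:, None], y * sw, rcond=None)

        def predict(x):
            x = np.clip(np.asarray(x, dtype=float), t.min(), t.max())
            return interpolate.BSpline.design_matrix(x, knots, k).toarray() @ coef

        return coef, predict

    return fit


#: candidate name -> (parameter count k, fitter(t, y, w) -> (params, predict))
CANDIDATES: dict[str, tuple[int, Callable]] = {
    "constant": (1, _fit_constant),
    "quadratic": (3, _fit_quadratic),
    "gaussian": (4, _fit_gaussian),
    "skew_gaussian": (5, _fit_skewgauss),
    "bspline_df4": (4, _fit_bspline(4)),
    "bspline_df6": (6, _fit_bspline(6)),
    "bspline_df8": (8, _fit_bspline(8)),
}


def fit_tpc(bins: pd.DataFrame, candidates: dict | None = None) -> TpcFit:
    """Fit all candidate curves to temperature-binned mean ODBA and keep
    the lowest-AIC model, with the usual parsimony convention: models
    within 2 AIC units of the minimum carry essentially equal support,
    so the fewest-parameter model among them is selected.

    ``bins`` follows the temperature-bin schema (temp_bin, mean_odba);
    candidates with more parameters than ``n - 2`` bins are skipped,
    and candidates that fail to converge are dropped with a warning.
    """
    cand = CANDIDATES if candidates is None else candidates
    t = bins["temp_bin"].to_numpy(dtype=float)
    y = bins["mean_odba"].to_numpy(dtype=float)
    # bin means are heteroscedastic (few records in edge bins), so fits
    # and the SSE entering the AIC are inverse-variance weighted by the
    # per-bin record count; weights are normalised to mean 1
    if "n" in bins.columns:
        w = bins["n"].to_numpy(dtype=float)
        w = w / w.mean()
    else:
        w = np.ones_like(y)
    n = t.size
    max_k = max(k for k, _ in cand.values())
    if n < max_k + 2:
        # per-candidate identifiability is still enforced below; this is
        # only a guard against absurdly small inputs
        if n < 3:
            raise ValueError("need at least 3 temperature bins")

    rows = []
    fits = {}
    for name, (k, fitter) in cand.items():
        if n < k + 2:
            rows.append((name, k, np.nan, "skipped (too few bins)"))
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                params, predict = fitter(t, y, w)
            resid = y - predict(t)
            if not np.all(np.isfinite(resid)):
                raise RuntimeError("non-finite predictions")
            sse = float(np.sum(w * resid**2))
            aic = (
                n * np.log(max(sse, 1e-300) / n)
                + 2.0 * k
                + 2.0 * k * (k + 1) / (n - k - 1)
            )
            rows.append((name, k, aic, ""))
            fits[name] = (params, predict, aic, k)
        except Exception as exc:  # dropped candidate, not fatal
            warnings.warn(f"TPC candidate {name!r} failed: {exc}", stacklevel=2)
            rows.append((name, k, np.nan, f"failed: {exc}"))
    if not fits:
        raise RuntimeError("no TPC candidate converged")

    # models within 2 AIC units of the minimum have essentially equal
    # support; among those, prefer the most parsimonious (fewest k)
    aic_min = min(f[2] for f in fits.values())
    near = {nm: f for nm, f in fits.items() if f[2] <= aic_min + 2.0}
    best_name = min(near, key=lambda nm: (near[nm][3], near[nm][2]))
    params, predict, aic, _ = fits[best_name]
    table = pd.DataFrame(rows, columns=["model", "k", "aic", "note"])
    table["delta_aic"] = table["aic"] - np.nanmin(table["aic"].to_numpy())
    return TpcFit(
        name=best_name,
        params=np.asarray(params, dtype=float),
        aic=float(aic),
        predict=predict,
        candidates=table,
        temp_range=(float(t.min()), float(t.max())),
    )


def performance_breadth(fit: TpcFit, level: float = 0.8) -> BreadthResult:
    """Thermal optimum and performance breadth of a fitted TPC.

    Evaluates the curve on a 0.1 degC grid over the observed range;
    t_opt is the argmax, the breadth is the maximal contiguous interval
    containing t_opt where the curve stays >= level * maximum.
    """
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    lo, hi = fit.temp_range
    grid = np.arange(lo, hi + 1e-9, 0.1)
    pred = np.asarray(fit.predict(grid), dtype=float)
    if not np.all(np.isfinite(pred)):
        raise ValueError("fitted curve produced non-finite predictions")
    imax = int(np.argmax(pred))
    thresh = level * pred[imax]
    above = pred >= thresh - 1e-12
    i0 = imax
    while i0 > 0 and above[i0 - 1]:
        i0 -= 1
    i1 = imax
    while i1 < len(grid) - 1 and above[i1 + 1]:
        i1 += 1
    return BreadthResult(
        level=level,
        t_opt=float(grid[imax]),
        lo=float(grid[i0]),
        hi=float(grid[i1]),
    )
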