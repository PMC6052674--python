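"""Environmental determinants of movement and activity.

Linear mixed models (random intercept per individual, ML fit via
statsmodels MixedLM) relate hourly responses — natural-log hourly
displacement, mean hourly ODBA — to weather covariates; each model is
tested against the intercept-plus-random-effect null with a likelihood
ratio test, and summarised by the variance-partition coefficients of
determination:

    r2_marginal    = var_fixed / (var_fixed + var_group + var_resid)
    r2_conditional = (var_fixed + var_group) / (var_fixed + var_group + var_resid)

where var_fixed is the population variance of the fixed-effect linear
predictor.  Backward-stepwise deletion removes the least significant
term while the AIC does not worsen (an alpha-threshold mode is also
available).  Hourly activity proportions are modelled as a binomial
random-intercept GLMM fitted by Gauss-Hermite quadrature maximum
likelihood, with the r2 computed on the latent (logit) scale using the
standard logistic residual variance pi^2/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "ModelResult",
    "fit_mixed",
    "backward_stepwise",
    "fit_activity_logistic",
    "precip_contrast",
]


@dataclass(frozen=True)
class ModelResult:
    response: str
    terms: tuple[str, ...]
    fixed_effects: pd.DataFrame  # term, estimate, ci_low, ci_high, p
    re_var: float
    resid_var: float
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    r2_marginal: float
    r2_conditional: float
    n: int
    loglik: float
    aic: float
    singular: bool = False
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if np.isfinite(self.r2_marginal) and np.isfinite(self.r2_conditional):
            assert -1e-9 <= self.r2_marginal <= self.r2_conditional <= 1 + 1e-9, (
                "variance-partition r2 must satisfy 0 <= r2m <= r2c <= 1"
            )


def _r2_parts(var_fixed, var_group, var_resid):
    tot = var_fixed + var_group + var_resid
    return float(var_fixed / tot), float((var_fixed + var_group) / tot)


def _fit_lmm(data: pd.DataFrame, response: str, terms, group: str):
    rhs = " + ".join(terms) if terms else "1"
    model = smf.mixedlm(f"{response} ~ {rhs}", data, groups=data[group])
    # gradient methods can stall at the zero-variance boundary; accept
    # the first converged finite fit, else the best finite one seen
    best = None
    last_exc = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "powell", "nm"):
            try:
                res = model.fit(reml=False, method=method, maxiter=1000)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if not np.isfinite(res.llf):
                last_exc = RuntimeError(f"non-finite log-likelihood ({method})")
                continue
            if res.converged:
                return model, res
            if best is None or res.llf > best.llf:
                best = res
    if best is not None:
        return model, best
    raise RuntimeError(f"mixed-model fit failed: {last_exc}")


def fit_mixed(
    data: pd.DataFrame,
    response: str,
    terms,
    group: str = "individual",
) -> ModelResult:
    """Linear mixed model with a random intercept per ``group``, fitted by
    maximum likelihood, plus a likelihood-ratio test against the
    intercept-only (random effect retained) null.

    ``data`` must contain the response, all covariate columns and the
    grouping column; rows with missing values are dropped.
    """
    terms = list(terms)
    cols = [response, group] + terms
    df = data[cols].dropna().reset_index(drop=True)
    if df[group].nunique() < 2:
        raise ValueError("need at least 2 groups for a random intercept")

    model, res = _fit_lmm(df, response, terms, group)
    _, res0 = _fit_lmm(df, response, [], group)

    lrt = max(0.0, 2.0 * (res.llf - res0.llf))
    lrt_df = len(terms)
    lrt_p = float(stats.chi2.sf(lrt, lrt_df)) if lrt_df > 0 else float("nan")

    fe = res.fe_params
    X = model.exog
    var_fixed = float(np.var(X @ fe.to_numpy()))
    var_group = float(np.asarray(res.cov_re)[0, 0])
    var_resid = float(res.scale)
    r2m, r2c = _r2_parts(var_fixed, var_group, var_resid)

    ci = res.conf_int(alpha=0.05)
    rows = []
    for name in fe.index:
        rows.append(
            (
                name,
                float(fe[name]),
                float(ci.loc[name, 0]),
                float(ci.loc[name, 1]),
                float(res.pvalues[name]),
            )
        )
    fixed = pd.DataFrame(rows, columns=["term", "estimate", "ci_low", "ci_high", "p"])

    singular = var_group < 1e-8 * max(var_resid, 1e-12)
    flags = []
    if singular:
        flags.append("singular: group variance estimated at (near) zero")
    if not res.converged:
        flags.append("optimizer did not report convergence")

    k = len(fe) + 2  # fixed effects + group variance + residual variance
    return ModelResult(
        response=response,
        terms=tuple(terms),
        fixed_effects=fixed,
        re_var=var_group,
        resid_var=var_resid,
        lrt_stat=float(lrt),
        lrt_df=lrt_df,
        lrt_p=lrt_p,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n=len(df),
        loglik=float(res.llf),
        aic=float(-2.0 * res.llf + 2.0 * k),
        singular=bool(singular),
        flags=tuple(flags),
    )


def backward_stepwise(
    data: pd.DataFrame,
    response: str,
    terms,
    group: str = "individual",
    *,
    criterion: str = "aic",
    alpha: float = 0.05,
    fitter=fit_mixed,
):
    """Backward deletion: repeatedly drop the least significant term.

    criterion="aic" (default): the drop is accepted while it does not
    increase the AIC.  criterion="p": drop while the largest p-value
    exceeds ``alpha``.  Deterministic given the data.  Returns
    (retained terms, ModelResult of the final model).
    """
    if criterion not in ("aic", "p"):
        raise ValueError("criterion must be 'aic' or 'p'")
    current_terms = list(terms)
    current = fitter(data, response, current_terms, group)
    while current_terms:
        pvals = current.fixed_effects.set_index("term")["p"]
        pvals = pvals.drop("Intercept", errors="ignore")
        worst = pvals.idxmax()
        if criterion == "p" and pvals[worst] <= alpha:
            break
        candidate_terms = [t for t in current_terms if t != worst]
        candidate = fitter(data, response, candidate_terms, group)
        if criterion == "aic" and candidate.aic > current.aic + 1e-9:
            break
        current_terms, current = candidate_terms, candidate
    return current_terms, current


# ---------------------------------------------------------------------------
# binomial random-intercept GLMM by Gauss-Hermite quadrature ML


def _glmm_negll(params, y, n, X, group_idx, n_groups, nodes, weights):
    beta = params[:-1]
    sigma = np.exp(params[-1])
    eta0 = X @ beta
    # (obs, node) linear predictor with scaled random effect
    eta = eta0[:, None] + (np.sqrt(2.0) * sigma) * nodes[None, :]
    ll_obs = y[:, None] * eta - n[:, None] * np.logaddexp(0.0, eta)
    ll_group = np.zeros((n_groups, nodes.size))
    np.add.at(ll_group, group_idx, ll_obs)
    ll_group = ll_group + np.log(weights / np.sqrt(np.pi))[None, :]
    return -float(special.logsumexp(ll_group, axis=1).sum())


def _fit_binom_glmm(y, n, X, group_idx, n_groups, n_nodes=25):
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    # starting values from the no-random-effect GLM
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(
            np.column_stack([y, n - y]), X, family=sm.families.Binomial()
        ).fit()
    x0 = np.concatenate([glm.params, [np.log(0.5)]])
    args = (y, n, X, group_idx, n_groups, nodes, weights)
    res = optimize.minimize(
        _glmm_negll, x0, args=args, method="BFGS",
        options={"maxiter": 500, "gtol": 1e-6},
    )
    if not res.success:
        res2 = optimize.minimize(
            _glmm_negll, res.x, args=args, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if res2.fun <= res.fun:
            res = res2
    return res, args


def fit_activity_logistic(
    data: pd.DataFrame,
    terms,
    group: str = "individual",
    events: str = "n_active",
    trials: str = "n_bursts",
) -> ModelResult:
    """Binomial random-intercept GLMM for hourly activity proportions.

    events/trials columns give the number of active bursts and the
    number of bursts per hour.  Fixed effects are ``terms``; a random
    intercept per ``group`` is integrated out by 25-node Gauss-Hermite
    quadrature and the likelihood maximised numerically.  The LRT is
    against the intercept-plus-random-effect null; r2 values are on the
    latent scale (logistic residual variance pi^2/3).

    Degenerate data (all hours fully active, or fully inactive) and
    apparent separation (unbounded coefficients) are flagged, not
    hidden.
    """
    terms = list(terms)
    cols = [events, trials, group] + terms
    df = data[cols].dropna().reset_index(drop=True)
    y = df[events].to_numpy(dtype=float)
    n = df[trials].to_numpy(dtype=float)
    if np.any(y > n) or np.any(n <= 0):
        raise ValueError("events must satisfy 0 <= events <= trials, trials > 0")
    groups, group_idx = np.unique(df[group], return_inverse=True)
    if groups.size < 2:
        raise ValueError("need at least 2 groups for a random intercept")

    flags = []
    if np.all(y == n):
        flags.append("degenerate: every hour fully active")
    elif np.all(y == 0):
        flags.append("degenerate: every hour fully inactive")
    if flags:
        fixed = pd.DataFrame(
            {"term": ["Intercept"] + terms, "estimate": np.nan,
             "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}
        )
        return ModelResult(
            response=f"{events}/{trials}", terms=tuple(terms), fixed_effects=fixed,
            re_var=float("nan"), resid_var=float(np.pi**2 / 3),
            lrt_stat=float("nan"), lrt_df=len(terms), lrt_p=float("nan"),
            r2_marginal=float("nan"), r2_conditional=float("nan"),
            n=len(df), loglik=float("nan"), aic=float("nan"),
            singular=True, flags=tuple(flags),
        )

    X = np.column_stack([np.ones(len(df))] + [df[t].to_numpy(dtype=float) for t in terms])
    res, args = _fit_binom_glmm(y, n, X, group_idx, groups.size)
    X0 = X[:, :1]
    res0, _ = _fit_binom_glmm(y, n, X0, group_idx, groups.size)

    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))
    if np.any(np.abs(beta) > 20):
        flags.append("possible separation: unbounded coefficient estimate")

    # Wald covariance from the numerical Hessian of the negative loglik
    try:
        H = approx_hess(res.x, _glmm_negll, args=args)
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:-1], 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(beta.size, np.nan)
        flags.append("Hessian not invertible; Wald CIs unavailable")
    zcrit = stats.norm.ppf(0.975)
    pvals = 2.0 * stats.norm.sf(np.abs(beta) / np.where(se > 0, se, np.nan))
    fixed = pd.DataFrame(
        {
            "term": ["Intercept"] + terms,
            "estimate": beta,
            "ci_low": beta - zcrit * se,
            "ci_high": beta + zcrit * se,
            "p": pvals,
        }
    )

    ll, ll0 = -res.fun, -res0.fun
    lrt = max(0.0, 2.0 * (ll - ll0))
    lrt_df = len(terms)
    lrt_p = float(stats.chi2.sf(lrt, lrt_df)) if lrt_df else float("nan")

    var_fixed = float(np.var(X @ beta))
    var_group = sigma**2
    var_resid = float(np.pi**2 / 3.0)
    r2m, r2c = _r2_parts(var_fixed, var_group, var_resid)

    k = beta.size + 1
    return ModelResult(
        response=f"{events}/{trials}",
        terms=tuple(terms),
        fixed_effects=fixed,
        re_var=var_group,
        resid_var=var_resid,
        lrt_stat=float(lrt),
        lrt_df=lrt_df,
        lrt_p=lrt_p,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n=len(df),
        loglik=float(ll),
        aic=float(-2.0 * ll + 2.0 * k),
        singular=sigma**2 < 1e-8,
        flags=tuple(flags),
    )


def precip_contrast(values, flag, *, log_transform: bool = False) -> dict:
    """Two-sample Student's t-test of a response with vs without
    precipitation.  Group means are reported on the original scale even
    when the test runs on the natural-log scale.
    """
    v = np.asarray(values, dtype=float)
    f = np.asarray(flag).astype(bool)
    wet, dry = v[f], v[~f]
    if wet.size < 2 or dry.size < 2:
        raise ValueError("each precipitation group needs at least 2 values")
    tw, td = wet, dry
    if log_transform:
        if np.any(wet <= 0) or np.any(dry <= 0):
            raise ValueError("log transform requires positive values")
        tw, td = np.log(wet), np.log(dry)
    if np.var(tw) == 0 and np.var(td) == 0 and tw.mean() == td.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(tw, td, equal_var=True)
    return {
        "mean_precip": float(wet.mean()),
        "mean_no_precip": float(dry.mean()),
        "n_precip": int(wet.size),
        "n_no_precip": int(dry.size),
        "t": float(t),
        "df": int(wet.size + dry.size - 2),
        "p": float(p),
    }
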