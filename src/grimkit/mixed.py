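"""Linear mixed-effects models of the orbital tightening score.

Three random-intercept models quantify the injection (intervention) effect
on the per-video orbital tightening (OT) score:

* **Model I** — between-treatments, all data at day resolution. Fixed part:
  treatment x intervention plus day and its interactions with treatment and
  intervention (reference levels Oil / pre / day 1). Random intercepts for
  animal identity and for day nested in week (week and week:day components).
* **Model II** — within CCl4, weeks 1-4 (baseline excluded: the intervention
  factor is undefined in week 0). Fixed part week x intervention (reference
  week 1 / pre); random intercept per animal.
* **Model III** — as II for the Oil control arm.

Estimation is restricted maximum likelihood (REML) via statsmodels'
``MixedLM``; variance components are reported in response units together
with the intra-class correlation ICC = sum(tau) / (sum(tau) + sigma^2).
Confidence intervals and p-values use Satterthwaite degrees of freedom
computed from the REML surface (normal approximation as fallback); this
approximates, but is not identical to, the Kenward-Roger small-sample
correction. Coefficient point estimates are unaffected by the df method.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import norm, t as t_dist

from grimkit.io import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "MODEL_SPECS",
    "fit_model",
    "variance_decomposition",
    "coefficient_table",
]

_TREAT = "C(treatment, Treatment('Oil'))"
_IV = "C(intervention, Treatment('pre'))"
_WEEK = "C(week, Treatment(1))"


@dataclass(frozen=True)
class ModelSpec:
    """Formula, random-effect structure and data filter of one model."""

    id: str
    fixed: str
    #: variance-component design: name -> patsy formula (crossed intercepts);
    #: empty dict means a plain fixed-effects (OLS) model
    random: dict[str, str]
    data_filter: Callable[[pd.DataFrame], pd.DataFrame]
    description: str = ""


def _filter_all(df: pd.DataFrame) -> pd.DataFrame:
    return df


def _filter_ccl4(df: pd.DataFrame) -> pd.DataFrame:
    return df[(df["treatment"] == "CCl4") & (df["week"] >= 1)]


def _filter_oil(df: pd.DataFrame) -> pd.DataFrame:
    return df[(df["treatment"] == "Oil") & (df["week"] >= 1)]


MODEL_SPECS: dict[str, ModelSpec] = {
    "I": ModelSpec(
        id="I",
        fixed=(
            f"ot_score ~ {_TREAT} * {_IV} + C(day) "
            f"+ C(day):{_TREAT} + C(day):{_IV}"
        ),
        random={
            "animal": "0 + C(animal_id)",
            "week": "0 + C(week)",
            "week:day": "0 + C(week):C(day)",
        },
        data_filter=_filter_all,
        description="between-treatments, day resolution, day nested in week",
    ),
    "II": ModelSpec(
        id="II",
        fixed=f"ot_score ~ {_WEEK} * {_IV}",
        random={"animal": "0 + C(animal_id)"},
        data_filter=_filter_ccl4,
        description="within-CCl4, weeks 1-4",
    ),
    "III": ModelSpec(
        id="III",
        fixed=f"ot_score ~ {_WEEK} * {_IV}",
        random={"animal": "0 + C(animal_id)"},
        data_filter=_filter_oil,
        description="within-Oil, weeks 1-4",
    ),
}


@dataclass
class MixedModelFit:
    """REML fit summary: coefficients, variance components, ICC."""

    model_id: str
    coefficients: pd.DataFrame  # term, beta, se, ci_low, ci_high, p, df
    variance_components: dict[str, float]
    sigma2: float
    icc: float
    variance_shares: dict[str, float]  # percent of total, incl. 'residual'
    estimator: str
    df_method: str
    n_obs: int
    converged: bool
    boundary: bool
    loglike: float


_CLEAN = re.compile(r"C\((\w+)[^\[]*\)\[T\.([^\]]+)\]")


def _clean_term(term: str) -> str:
    return _CLEAN.sub(lambda m: f"{m.group(1)}[{m.group(2)}]", term)


def _reml_loglike(
    theta: np.ndarray, y: np.ndarray, X: np.ndarray, Z: list[np.ndarray]
) -> float:
    """Profiled REML log-likelihood at variance parameters (tau..., sigma2)."""
    *taus, sigma2 = theta
    n = len(y)
    V = sigma2 * np.eye(n)
    for tau, Zk in zip(taus, Z):
        if tau > 0:
            V += tau * (Zk @ Zk.T)
    L = np.linalg.cholesky(V)
    logdet_v = 2.0 * np.log(np.diag(L)).sum()
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, Vi_X.T @ y)
    r = y - X @ beta
    quad = r @ np.linalg.solve(V, r)
    return -0.5 * (logdet_v + logdet_x + quad)


def _gls_cov(
    theta: np.ndarray, X: np.ndarray, Z: list[np.ndarray]
) -> np.ndarray:
    *taus, sigma2 = theta
    n = X.shape[0]
    V = sigma2 * np.eye(n)
    for tau, Zk in zip(taus, Z):
        if tau > 0:
            V += tau * (Zk @ Zk.T)
    return np.linalg.inv(X.T @ np.linalg.solve(V, X))


def _satterthwaite_dfs(
    y: np.ndarray,
    X: np.ndarray,
    Z: list[np.ndarray],
    taus: np.ndarray,
    sigma2: float,
    boundary_tol: float = 1e-6,
) -> np.ndarray | None:
    """Per-coefficient Satterthwaite df from the REML surface.

    df_j = 2 Var(beta_j)^2 / (g' A g) with g the gradient of Var(beta_j)
    w.r.t. the free variance parameters and A their asymptotic covariance
    (inverse negative numeric Hessian of the REML log-likelihood).
    Components at the tau >= 0 boundary are held fixed. Returns None when
    the Hessian is not usable (caller falls back to the normal
    approximation).
    """
    theta = np.append(taus, sigma2)
    free = [k for k, tau in enumerate(taus) if tau > boundary_tol]
    free.append(len(theta) - 1)  # sigma2 always free
    if not free:
        return None
    steps = np.maximum(1e-4, 1e-3 * np.abs(theta))

    def ll(t: np.ndarray) -> float:
        return _reml_loglike(np.maximum(t, 0.0), y, X, Z)

    m = len(free)
    H = np.empty((m, m))
    for a, i in enumerate(free):
        for b, j in enumerate(free[: a + 1]):
            hi, hj = steps[i], steps[j]
            if i == j:
                f0 = ll(theta)
                tp, tm = theta.copy(), theta.copy()
                tp[i] += hi
                tm[i] -= hi
                H[a, a] = (ll(tp) - 2 * f0 + ll(tm)) / hi**2
            else:
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[i] += hi
                tpp[j] += hj
                tpm[i] += hi
                tpm[j] -= hj
                tmp[i] -= hi
                tmp[j] += hj
                tmm[i] -= hi
                tmm[j] -= hj
                H[a, b] = H[b, a] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (
                    4 * hi * hj
                )
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(A)) or np.any(np.diag(A) <= 0):
        return None
    # gradient of each Var(beta_j) w.r.t. the free parameters
    p = X.shape[1]
    grads = np.zeros((p, m))
    for a, i in enumerate(free):
        h = steps[i]
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] = max(tm[i] - h, 0.0)
        cp = np.diag(_gls_cov(tp, X, Z))
        cm = np.diag(_gls_cov(tm, X, Z))
        grads[:, a] = (cp - cm) / (tp[i] - tm[i])
    var_beta = np.diag(_gls_cov(theta, X, Z))
    denom = np.einsum("pa,ab,pb->p", grads, A, grads)
    with np.errstate(divide="ignore", invalid="ignore"):
        dfs = 2.0 * var_beta**2 / denom
    dfs = np.where(np.isfinite(dfs) & (dfs > 0), dfs, np.inf)
    return np.minimum(dfs, 1e6)


def _fit_ols(spec: ModelSpec, df: pd.DataFrame) -> MixedModelFit:
    """Fixed-effects-only fallback: exact least squares with t inference."""
    model = smf.ols(spec.fixed, data=df)
    res = model.fit()
    dfs = np.full(len(res.params), res.df_resid)
    ci = res.conf_int()
    coef = pd.DataFrame(
        {
            "term": [_clean_term(t) for t in res.params.index],
            "beta": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p": res.pvalues.to_numpy(),
            "df": dfs,
        }
    )
    sigma2 = float(res.mse_resid)
    return MixedModelFit(
        model_id=spec.id,
        coefficients=coef,
        variance_components={},
        sigma2=sigma2,
        icc=0.0,
        variance_shares={"residual": 100.0},
        estimator="OLS",
        df_method="exact",
        n_obs=int(res.nobs),
        converged=True,
        boundary=False,
        loglike=float(res.llf),
    )


def fit_model(
    ds: Dataset, spec: ModelSpec | str, df_method: str = "satterthwaite"
) -> MixedModelFit:
    """Fit one model specification by REML.

    ``df_method`` is ``"satterthwaite"`` (default) or ``"normal"``. Boundary
    fits (a variance component estimated at zero) are returned with
    ``boundary=True`` rather than raised.
    """
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    if df_method not in ("satterthwaite", "normal"):
        raise ValueError(f"unknown df_method {df_method!r}")
    data = spec.data_filter(ds.records).copy()
    if data.empty:
        raise ValueError(f"model {spec.id}: no data after filtering")
    if not spec.random:
        return _fit_ols(spec, data)

    data["_one"] = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            spec.fixed,
            data,
            groups=data["_one"],
            vc_formula=spec.random,
            re_formula="0",
        )
        res = model.fit(reml=True, method=["powell", "lbfgs"], maxiter=5000)

    vc_names = list(model.exog_vc.names)
    taus = {name: float(v) for name, v in zip(vc_names, res.vcomp)}
    # report in the spec's declared order
    taus = {name: taus[name] for name in spec.random if name in taus}
    sigma2 = float(res.scale)
    boundary = any(tau < 1e-8 for tau in taus.values())

    y = np.asarray(model.endog, dtype=float)
    X = np.asarray(model.exog, dtype=float)
    Z = []
    for name in taus:
        idx = vc_names.index(name)
        cols = np.concatenate(
            [np.asarray(m, dtype=float) for m in model.exog_vc.mats[idx]], axis=0
        )
        Z.append(cols)
    theta = np.append(list(taus.values()), sigma2)
    cov_beta = _gls_cov(theta, X, Z)
    se = np.sqrt(np.diag(cov_beta))
    beta = res.fe_params.to_numpy()

    dfs = None
    if df_method == "satterthwaite":
        try:
            dfs = _satterthwaite_dfs(y, X, Z, np.array(list(taus.values())), sigma2)
        except np.linalg.LinAlgError:
            dfs = None
        if dfs is None:
            logger.warning(
                "model %s: Satterthwaite df unavailable, using normal approximation",
                spec.id,
            )
    used_method = "satterthwaite" if dfs is not None else "normal"
    if dfs is None:
        dfs = np.full(len(beta), np.inf)
    tstat = beta / se
    with np.errstate(invalid="ignore"):
        p = np.where(
            np.isinf(dfs),
            2 * norm.sf(np.abs(tstat)),
            2 * t_dist.sf(np.abs(tstat), dfs),
        )
        crit = np.where(np.isinf(dfs), norm.ppf(0.975), t_dist.ppf(0.975, dfs))
    coef = pd.DataFrame(
        {
            "term": [_clean_term(t) for t in res.fe_params.index],
            "beta": beta,
            "se": se,
            "ci_low": beta - crit * se,
            "ci_high": beta + crit * se,
            "p": p,
            "df": dfs,
        }
    )
    total = sum(taus.values()) + sigma2
    shares = {name: 100.0 * tau / total for name, tau in taus.items()}
    shares["residual"] = 100.0 * sigma2 / total
    return MixedModelFit(
        model_id=spec.id,
        coefficients=coef,
        variance_components=taus,
        sigma2=sigma2,
        icc=sum(taus.values()) / total,
        variance_shares=shares,
        estimator="REML",
        df_method=used_method,
        n_obs=len(y),
        converged=bool(res.converged),
        boundary=boundary,
        loglike=float(res.llf),
    )


def variance_decomposition(fit: MixedModelFit) -> dict[str, float]:
    """Percent variance shares per random term plus the residual, and ICC."""
    out = dict(fit.variance_shares)
    out["icc"] = fit.icc
    return out


def coefficient_table(fit: MixedModelFit) -> pd.DataFrame:
    """Coefficient rows ordered intercept, main effects, interactions."""
    if fit.coefficients.empty:
        raise ValueError("empty fit: no coefficients")
    df = fit.coefficients.copy()

    def order(term: str) -> tuple[int, str]:
        if term == "Intercept":
            return (0, term)
        return (2 if ":" in term else 1, term)

    df["_key"] = df["term"].map(order)
    df = df.sort_values("_key").drop(columns="_key").reset_index(drop=True)
    df["sign"] = np.sign(df["beta"]).astype(int)
    df["significant"] = df["p"] < 0.05
    return df
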