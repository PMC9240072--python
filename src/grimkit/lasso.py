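"""L1-penalized coefficient ranking of the grimace criteria.

The five FAU scores are strongly collinear, so ordinary regression
coefficients of the average picture score on the criteria are unstable. The
LASSO (elastic-net mixing alpha = 1) shrinks and selects: the average
picture score is regressed on the five per-video FAU scores and their
interactions with week (numeric, 1-4) and intervention (post indicator),
separately per treatment arm, with 10-fold cross-validation over a
descending penalty grid. Coefficients are reported at the one-standard-error
penalty — the most parsimonious model whose CV error is within one SE of the
minimum — on standardized predictors so magnitudes are comparable.

Week 0 is excluded: the intervention factor is undefined at baseline and
would make the design rank-deficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from grimkit.io import FAUS, Dataset

__all__ = ["LassoFit", "build_design", "fit_lasso_cv", "rank_coefficients"]


@dataclass
class LassoFit:
    """Cross-validated LASSO fit summary for one treatment arm."""

    treatment: str
    lambda_grid: np.ndarray
    lambda_min: float
    lambda_1se: float
    coefficients: dict[str, float]
    cv_mean: np.ndarray
    cv_se: np.ndarray
    folds: int
    seed: int
    n_obs: int
    dropped_columns: list[str] = field(default_factory=list)


def build_design(
    ds: Dataset, treatment: str, week_numeric: bool = True
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Response and standardized predictor matrix for one treatment arm.

    Predictors: the five FAU scores, FAU x week and FAU x post-intervention
    interactions (15 columns with numeric week). All columns are centered
    and scaled to unit sample SD (ddof=1). Constant columns are dropped with
    a warning. Returns ``(y, X, names)``.
    """
    df = ds.records
    df = df[(df["treatment"] == treatment) & (df["week"] >= 1)]
    # the response is undefined for videos without a single fully scored image
    n_undefined = int(df["avg_picture_score"].isna().sum())
    if n_undefined:
        warnings.warn(
            f"dropped {n_undefined} video(s) without a complete picture score",
            stacklevel=2,
        )
        df = df[df["avg_picture_score"].notna()]
    if df.empty:
        raise ValueError(f"no records for treatment {treatment!r} in weeks 1-4")
    y = df["avg_picture_score"].to_numpy(dtype=float)
    post = (df["intervention"] == "post").astype(float).to_numpy()
    cols: dict[str, np.ndarray] = {}
    for f in FAUS:
        score = df[f"{f}_score"].to_numpy(dtype=float)
        cols[f] = score
        if week_numeric:
            cols[f"{f}:week"] = score * df["week"].to_numpy(dtype=float)
        else:
            for w in sorted(df["week"].unique())[1:]:
                cols[f"{f}:week{w}"] = score * (df["week"] == w).to_numpy(dtype=float)
        cols[f"{f}:post"] = score * post
    names, dropped, mats = [], [], []
    for name, col in cols.items():
        sd = col.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            dropped.append(name)
            continue
        names.append(name)
        mats.append((col - col.mean()) / sd)
    if dropped:
        warnings.warn(f"dropped constant predictor column(s): {dropped}", stacklevel=2)
    if not names:
        raise ValueError("no non-constant predictors remain")
    return y, np.column_stack(mats), names


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int, eps: float) -> np.ndarray:
    n = len(y)
    lam_max = np.abs(X.T @ (y - y.mean())).max() / n
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * eps, n_lambda)


def fit_lasso_cv(
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str],
    treatment: str = "",
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    grid_eps: float = 1e-4,
) -> LassoFit:
    """K-fold cross-validated LASSO path with the one-SE rule.

    The grid runs from the smallest penalty that zeroes every coefficient
    down by ``grid_eps``. Per fold the full path is fit on the training
    split and scored on the held-out split; ``lambda_1se`` is the largest
    penalty whose mean CV MSE is within one standard error (across folds) of
    the minimum. Coefficients are refit on all data at ``lambda_1se``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError(f"need at least {folds} observations, got {n}")
    if n < 2 * folds:
        raise ValueError(f"need >= {2 * folds} observations for {folds}-fold CV")
    lambdas = _lambda_grid(X, y, n_lambda, grid_eps)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_mse = np.empty((folds, len(lambdas)))
    for k, (tr, te) in enumerate(kf.split(X)):
        _, coefs, _ = lasso_path(X[tr], y[tr], alphas=lambdas)
        # lasso_path centers nothing; include intercept via training means
        inter = y[tr].mean() - X[tr].mean(axis=0) @ coefs
        pred = X[te] @ coefs + inter
        fold_mse[k] = ((pred - y[te, None]) ** 2).mean(axis=0)
    cv_mean = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(cv_mean))
    lam_min = float(lambdas[i_min])
    threshold = cv_mean[i_min] + cv_se[i_min]
    ok = np.flatnonzero(cv_mean <= threshold)
    lam_1se = float(lambdas[ok.min()])  # grid is descending: first = largest
    model = Lasso(alpha=lam_1se, fit_intercept=True, max_iter=100_000, tol=1e-10)
    model.fit(X, y)
    coefficients = {name: float(b) for name, b in zip(names, model.coef_)}
    return LassoFit(
        treatment=treatment,
        lambda_grid=lambdas,
        lambda_min=lam_min,
        lambda_1se=lam_1se,
        coefficients=coefficients,
        cv_mean=cv_mean,
        cv_se=cv_se,
        folds=folds,
        seed=seed,
        n_obs=n,
    )


def rank_coefficients(fit: LassoFit) -> list[tuple[str, float]]:
    """Nonzero coefficients ordered by |beta| descending, ties alphabetical."""
    nonzero = [(name, b) for name, b in fit.coefficients.items() if b != 0.0]
    return sorted(nonzero, key=lambda nb: (-abs(nb[1]), nb[0]))


def fit_treatment(ds: Dataset, treatment: str, folds: int = 10, seed: int = 0) -> LassoFit:
    """Convenience: build the design for one arm and cross-validate."""
    y, X, names = build_design(ds, treatment)
    fit = fit_lasso_cv(y, X, names, treatment=treatment, folds=folds, seed=seed)
    return fit
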