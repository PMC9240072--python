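"""Severity classes, contingency statistics, bootstrap medians, correlations.

The per-video orbital tightening score (0-16 scale) is discretized into
welfare severity classes — mild (< 3), moderate (3-6 inclusive), severe
(> 6) — and counted per treatment x intervention cell. Class distributions
are compared with Pearson chi-square tests (no continuity correction) and
pairwise class post-hocs with multiplicity adjustment; group contrasts use
the Mann-Whitney test with the rank-based effect size r; central tendencies
of the skewed, tied score distributions are summarized as bootstrap medians
with percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import lgamma
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from grimkit.io import FAUS, Dataset
from grimkit.mobps import EffectSizeResult, effect_size

__all__ = [
    "SEVERITY_LABELS",
    "BootstrapEstimate",
    "classify",
    "classify_scores",
    "severity_counts",
    "chi_square",
    "fisher_exact_2xc",
    "posthoc_pairwise",
    "mann_whitney_contrast",
    "bootstrap_median",
    "correlation_matrix",
    "normality_check",
]

SEVERITY_LABELS: tuple[str, ...] = ("mild", "moderate", "severe")
_INTERVENTION_ORDER = ("bsl", "pre", "post")


def classify(score: float) -> str:
    """Severity class of one aggregated score: <3 mild, 3-6 moderate, >6 severe."""
    if score < 0 or not np.isfinite(score):
        raise ValueError(f"score must be a non-negative real, got {score}")
    if score < 3:
        return "mild"
    if score <= 6:
        return "moderate"
    return "severe"


def classify_scores(scores: Sequence[float]) -> pd.Categorical:
    """Vectorized :func:`classify` preserving the class order."""
    arr = np.asarray(scores, dtype=float)
    if (arr < 0).any() or not np.isfinite(arr).all():
        bad = np.flatnonzero((arr < 0) | ~np.isfinite(arr))[0]
        raise ValueError(f"score must be a non-negative real (position {bad})")
    labels = np.where(arr < 3, "mild", np.where(arr <= 6, "moderate", "severe"))
    return pd.Categorical(labels, categories=list(SEVERITY_LABELS), ordered=True)


def severity_counts(ds: Dataset, score_column: str = "ot_score") -> pd.DataFrame:
    """Counts per (treatment, intervention) x severity class.

    Rows are ordered Oil before CCl4 and bsl/pre/post within treatment;
    columns mild/moderate/severe. The grand total equals the record count.
    """
    df = ds.records
    if df.empty:
        idx = pd.MultiIndex.from_product(
            [[], []], names=["treatment", "intervention"]
        )
        return pd.DataFrame(columns=list(SEVERITY_LABELS), index=idx, dtype=int)
    cls = classify_scores(df[score_column])
    table = (
        pd.crosstab([df["treatment"], df["intervention"]], cls)
        .reindex(columns=list(SEVERITY_LABELS), fill_value=0)
    )
    order = [
        (t, i)
        for t in ("Oil", "CCl4")
        for i in _INTERVENTION_ORDER
        if (t, i) in table.index
    ]
    table = table.loc[order]
    table.index.names = ["treatment", "intervention"]
    table.columns.name = "severity"
    return table.astype(int)


def chi_square(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction.

    Returns ``(statistic, df, p)``. Zero marginals are rejected by name
    because expected counts would vanish.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("table must be two-dimensional")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    if (row_sums == 0).any():
        raise ValueError(f"zero marginal in row {int(np.argmax(row_sums == 0))}")
    if (col_sums == 0).any():
        raise ValueError(f"zero marginal in column {int(np.argmax(col_sums == 0))}")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(dof), float(p)


def _log_multinom(counts: np.ndarray) -> float:
    n = counts.sum()
    return lgamma(n + 1) - sum(lgamma(c + 1) for c in counts)


def fisher_exact_2xc(table: np.ndarray) -> float:
    """Exact conditional (Fisher-Freeman-Halton) p for a 2 x C table.

    Enumerates all first rows compatible with the margins; the p-value sums
    the multivariate hypergeometric probabilities of tables no more probable
    than the observed one.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape[0] != 2:
        raise ValueError("fisher_exact_2xc expects exactly 2 rows")
    col = arr.sum(axis=0)
    r1 = int(arr.sum(axis=1)[0])
    n = int(arr.sum())
    log_denom = _log_multinom(np.array([r1, n - r1]))  # log C(n, r1)

    def log_prob(first_row: np.ndarray) -> float:
        return (
            sum(_log_multinom(np.array([x, c - x])) for x, c in zip(first_row, col))
            - log_denom
        )

    obs = log_prob(arr[0])
    c = len(col)

    total = 0.0

    def recurse(j: int, remaining: int, row: list[int]) -> None:
        nonlocal total
        if j == c - 1:
            if remaining <= col[j]:
                lp = log_prob(np.array(row + [remaining]))
                if lp <= obs + 1e-9:
                    total += np.exp(lp)
            return
        lo = max(0, remaining - int(col[j + 1 :].sum()))
        hi = min(col[j], remaining)
        for x in range(lo, hi + 1):
            recurse(j + 1, remaining - x, row + [x])

    recurse(0, r1, [])
    return float(min(total, 1.0))


def posthoc_pairwise(
    counts: pd.DataFrame, adjust: str = "fdr"
) -> pd.DataFrame:
    """Pairwise severity-class comparisons within one treatment's table.

    ``counts`` is the interventions x classes sub-table of one treatment.
    For each class pair the 2 x interventions sub-table is tested by Pearson
    chi-square without continuity correction; adjusted p-values
    (``fdr`` = Benjamini-Hochberg, or ``holm`` / ``bonferroni``) derive from
    those. Cells with small expected counts are flagged (``low_expected``)
    and an exact conditional p (``p_exact``) is reported alongside as a
    sensitivity check; it does not enter the adjustment.
    """
    from statsmodels.stats.multitest import multipletests

    methods = {"fdr": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}
    if adjust not in methods:
        raise ValueError(f"unknown adjustment {adjust!r}; use {sorted(methods)}")
    rows = []
    for a, b in combinations(counts.columns, 2):
        sub = counts[[a, b]].T.to_numpy(dtype=float)  # 2 x interventions
        keep = sub.sum(axis=0) > 0
        sub = sub[:, keep]
        expected = np.outer(sub.sum(axis=1), sub.sum(axis=0)) / sub.sum()
        stat, dof, p = chi_square(sub)
        rows.append(
            {
                "pair": f"{a}/{b}",
                "statistic": stat,
                "df": dof,
                "p_raw": p,
                "low_expected": bool((expected < 5).any()),
                "p_exact": fisher_exact_2xc(sub.astype(int)),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method=methods[adjust])[1]
    out["method"] = adjust
    return out


def mann_whitney_contrast(
    ds: Dataset,
    group_a: Mapping[str, object],
    group_b: Mapping[str, object],
    score_column: str = "ot_score",
) -> tuple[EffectSizeResult, dict]:
    """Two-sided Mann-Whitney contrast between two record selections.

    Selectors map column names to a value or collection of values, e.g.
    ``{"treatment": "CCl4", "week": 0}`` vs
    ``{"treatment": "CCl4", "week": 1, "intervention": "post"}``.
    Returns the effect summary and a provenance record of the selections.
    """

    def select(sel: Mapping[str, object], name: str) -> pd.Series:
        mask = pd.Series(True, index=ds.records.index)
        for colname, value in sel.items():
            col = ds.records[colname]
            if isinstance(value, (list, tuple, set, frozenset)):
                mask &= col.isin(list(value))
            else:
                mask &= col == value
        if not mask.any():
            raise ValueError(f"selector {name} ({dict(sel)}) selects no records")
        return ds.records.loc[mask, score_column]

    x = select(group_a, "group_a")
    y = select(group_b, "group_b")
    res = effect_size(x, y)
    provenance = {
        "group_a": dict(group_a),
        "group_b": dict(group_b),
        "score_column": score_column,
        "n_a": len(x),
        "n_b": len(y),
    }
    return res, provenance


@dataclass(frozen=True)
class BootstrapEstimate:
    """Bootstrap median with percentile 95% confidence interval."""

    median: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def bootstrap_median(
    sample: Sequence[float], n_boot: int = 10_000, seed: int = 0
) -> BootstrapEstimate:
    """Median and percentile 95% CI from ``n_boot`` resamples.

    The point estimate is the median of the bootstrap distribution, which by
    construction lies inside the percentile interval.
    """
    arr = np.asarray(sample, dtype=float)
    if arr.size == 0:
        raise ValueError("sample must be non-empty")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    medians = np.median(arr[idx], axis=1)
    lo, mid, hi = np.percentile(medians, [2.5, 50.0, 97.5])
    return BootstrapEstimate(
        median=float(mid), ci_low=float(lo), ci_high=float(hi),
        n_boot=n_boot, seed=seed,
    )


def correlation_matrix(
    ds: Dataset, treatment: str, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise correlations of the five FAU scores, pooled over time.

    Constant columns yield NaN rows/columns (undefined correlation) with a
    unit diagonal kept for defined columns.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    df = ds.records[ds.records["treatment"] == treatment]
    if len(df) < 3:
        raise ValueError(f"need >= 3 records for treatment {treatment!r}")
    cols = [f"{f}_score" for f in FAUS]
    corr = df[cols].corr(method=method)
    corr.index = corr.columns = list(FAUS)
    return corr


def normality_check(sample: Sequence[float]) -> tuple[float, pd.DataFrame]:
    """Shapiro-Wilk p-value and ordered quantile pairs for a Q-Q plot."""
    arr = np.asarray(sample, dtype=float)
    if not 3 <= arr.size <= 5000:
        raise ValueError(f"sample size {arr.size} outside [3, 5000]")
    if np.ptp(arr) == 0:
        raise ValueError("constant sample: normality undefined")
    stat_p = stats.shapiro(arr).pvalue
    (theo, ordered), _ = stats.probplot(arr, dist="norm")
    qq = pd.DataFrame({"theoretical": theo, "observed": ordered})
    return float(stat_p), qq
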