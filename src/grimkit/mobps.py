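"""Coalition effect-size ranking of FAU subsets with Shapley attribution.

The "mining on best parameter search" idea: for every non-empty subset of
the five facial action units, form the composite score (sum of the subset's
per-video scores), measure how well it separates the pre- from the
post-intervention condition with a size- and tie-robust effect size, and
normalize to the best subset. Each criterion's contribution to a subset is
attributed by the Shapley value of the restricted coalition game — the
average marginal gain in the measure over all orderings in which the
criterion can join the subset. With five players the 2^5 = 32 coalitions are
enumerated exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from grimkit.io import FAUS, Dataset

__all__ = [
    "ContrastSpec",
    "EffectSizeResult",
    "CoalitionImportance",
    "effect_size",
    "coalition_measure",
    "coalition_values",
    "shapley_attribution",
    "rank_combinations",
]


@dataclass(frozen=True)
class EffectSizeResult:
    """Mann-Whitney effect summary in the first-sample (R-style) convention.

    ``statistic_w`` counts pairs where the first sample exceeds the second
    (ties counted half); ``z`` is the tie-corrected normal approximation
    without continuity correction; ``r = |z| / sqrt(n1 + n2)``;
    ``cliffs_delta`` is the signed dominance (#x>y - #x<y) / (n1*n2).
    """

    statistic_w: float
    z: float
    r: float
    cliffs_delta: float
    p: float
    n1: int
    n2: int


def effect_size(
    x: Sequence[float], y: Sequence[float], kind: str = "r"
) -> EffectSizeResult:
    """Rank-based effect size of two independent samples.

    ``kind`` only selects which statistic downstream callers treat as the
    measure; the full result is always computed. When both samples are
    constant and equal the variance vanishes and z (hence r) is defined as 0.
    """
    if kind not in ("r", "cliffs_delta"):
        raise ValueError(f"unknown effect size kind {kind!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    w = r1 - n1 * (n1 + 1) / 2.0  # = #{x>y} + 0.5 * #ties
    mean_w = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var_w <= 0:
        z = 0.0
    else:
        z = (w - mean_w) / math.sqrt(var_w)
    r = abs(z) / math.sqrt(n)
    delta = (2.0 * w - n1 * n2) / (n1 * n2)
    p = 2.0 * norm.sf(abs(z)) if var_w > 0 else 1.0
    return EffectSizeResult(
        statistic_w=float(w),
        z=float(z),
        r=float(r),
        cliffs_delta=float(delta),
        p=float(p),
        n1=n1,
        n2=n2,
    )


@dataclass(frozen=True)
class ContrastSpec:
    """Definition of the two groups an effect size compares.

    The default is the study's core question: pre- vs post-injection videos
    within the CCl4 arm over the treatment weeks. ``treatment=None`` pools
    both arms.
    """

    group1: str = "pre"
    group2: str = "post"
    treatment: str | None = "CCl4"
    weeks: tuple[int, ...] = (1, 2, 3, 4)

    def split(self, records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        df = records[records["week"].isin(self.weeks)]
        if self.treatment is not None:
            df = df[df["treatment"] == self.treatment]
        g1 = df[df["intervention"] == self.group1]
        g2 = df[df["intervention"] == self.group2]
        for name, g in (("group1", g1), ("group2", g2)):
            if g.empty:
                raise ValueError(f"contrast {self}: {name} selects no records")
        return g1, g2


@dataclass(frozen=True)
class CoalitionImportance:
    """One scored FAU subset: measure, normalized strength, member shares."""

    subset: tuple[str, ...]
    M: float
    M_rel: float
    member_weights: Mapping[str, float] = field(default_factory=dict)


def coalition_measure(
    ds: Dataset,
    subset: Iterable[str],
    contrast: ContrastSpec | None = None,
    kind: str = "r",
) -> float:
    """Effect-size measure M of one FAU subset's composite score."""
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    unknown = [f for f in subset if f not in FAUS]
    if unknown:
        raise ValueError(f"unknown FAU label(s) {unknown}")
    contrast = contrast or ContrastSpec()
    g1, g2 = contrast.split(ds.records)
    cols = [f"{f}_score" for f in subset]
    res = effect_size(g1[cols].sum(axis=1), g2[cols].sum(axis=1), kind=kind)
    return res.r if kind == "r" else abs(res.cliffs_delta)


def coalition_values(
    ds: Dataset, contrast: ContrastSpec | None = None, kind: str = "r"
) -> dict[frozenset, float]:
    """Measure M for all 31 non-empty subsets, plus v(empty) = 0."""
    v: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, len(FAUS) + 1):
        for subset in combinations(FAUS, size):
            v[frozenset(subset)] = coalition_measure(ds, subset, contrast, kind)
    return v


def shapley_attribution(
    v: Mapping[frozenset, float], players: Sequence[str] = FAUS
) -> dict[str, float]:
    """Exact Shapley values of a coalition game given on every subset.

    phi_i = sum over S not containing i of |S|! (n-|S|-1)! / n! *
    (v(S+i) - v(S)). Requires v on all 2^n subsets with v(empty) = 0.
    """
    players = tuple(players)
    n = len(players)
    fact = [math.factorial(k) for k in range(n + 1)]
    for size in range(n + 1):
        for subset in combinations(players, size):
            if frozenset(subset) not in v:
                raise KeyError(f"missing coalition value for subset {subset}")
    phi: dict[str, float] = {}
    for i in players:
        others = [p for p in players if p != i]
        total = 0.0
        for size in range(n):
            weight = fact[size] * fact[n - size - 1] / fact[n]
            for subset in combinations(others, size):
                s = frozenset(subset)
                total += weight * (v[s | {i}] - v[s])
        phi[i] = total
    return phi


def rank_combinations(
    ds: Dataset,
    contrast: ContrastSpec | None = None,
    kind: str = "r",
) -> pd.DataFrame:
    """Score and rank all 31 FAU subsets; attribute members by Shapley value.

    Returns a DataFrame sorted by descending normalized measure ``M_rel``
    (ties broken by smaller subset, then label order). ``weight_<fau>``
    columns hold each member's Shapley share of its subset's own sub-game,
    normalized to sum to 1 within the subset (NaN for non-members; all-zero
    sub-games get equal shares).
    """
    if ds.records.empty:
        raise ValueError("empty dataset")
    v = coalition_values(ds, contrast, kind)
    m_max = max(val for key, val in v.items() if key)
    entries: list[CoalitionImportance] = []
    for size in range(1, len(FAUS) + 1):
        for subset in combinations(FAUS, size):
            key = frozenset(subset)
            sub_v = {
                frozenset(t): v[frozenset(t)]
                for r in range(size + 1)
                for t in combinations(subset, r)
            }
            phi = shapley_attribution(sub_v, players=subset)
            total = sum(phi.values())  # = v(subset) by efficiency
            if total > 0:
                weights = {f: phi[f] / total for f in subset}
            else:
                weights = {f: 1.0 / size for f in subset}
            entries.append(
                CoalitionImportance(
                    subset=subset,
                    M=v[key],
                    M_rel=v[key] / m_max if m_max > 0 else 0.0,
                    member_weights=weights,
                )
            )
    rows = []
    for e in entries:
        row = {
            "subset": "+".join(e.subset),
            "size": len(e.subset),
            "M": e.M,
            "M_rel": e.M_rel,
        }
        for f in FAUS:
            row[f"weight_{f}"] = e.member_weights.get(f, np.nan)
        rows.append(row)
    out = pd.DataFrame(rows)
    out = out.sort_values(
        by=["M_rel", "size", "subset"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return out
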