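"""Shared fixtures: synthetic study datasets generated once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from grimkit.io import FAUS, aggregate_videos
from grimkit.simulate import GeneratorConfig, simulate


@pytest.fixture(scope="session")
def sim_images():
    """One default-preset simulation: (per-image scores, ground truth)."""
    return simulate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def paper_ds(sim_images):
    """Aggregated per-video dataset of the default synthetic study."""
    images, _ = sim_images
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return aggregate_videos(images, mode="scaled_sum")


@pytest.fixture()
def tiny_images():
    """Hand-built image table: one video, 8 frames, constant scores."""
    rows = []
    for i in range(8):
        rows.append(
            {
                "animal_id": "A01",
                "treatment": "Oil",
                "week": 1,
                "day": 1,
                "intervention": "pre",
                "ot": 1,
                "nb": 0,
                "cb": 0,
                "ep": 0,
                "wc": 0,
            }
        )
    return pd.DataFrame(rows)


def make_random_game(rng: np.random.Generator) -> dict[frozenset, float]:
    """A random 5-player coalition value function with v(empty) = 0."""
    from itertools import combinations

    v = {frozenset(): 0.0}
    for size in range(1, 6):
        for subset in combinations(FAUS, size):
            v[frozenset(subset)] = float(rng.uniform(0, 10))
    return v


def shapley_bruteforce(v: dict[frozenset, float], players=FAUS) -> dict[str, float]:
    """Oracle: average marginal contribution over all |N|! orderings."""
    from itertools import permutations

    phi = dict.fromkeys(players, 0.0)
    perms = list(permutations(players))
    for order in perms:
        seen: frozenset = frozenset()
        for p in order:
            phi[p] += v[seen | {p}] - v[seen]
            seen = seen | {p}
    return {p: phi[p] / len(perms) for p in players}


def mannwhitney_bruteforce(x, y) -> float:
    """Oracle: W = #{x_i > y_j} + 0.5 #ties by direct pair enumeration."""
    w = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                w += 1.0
            elif xi == yj:
                w += 0.5
    return w
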