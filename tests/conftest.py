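"""Shared fixtures: hand-built networks and small model-ready frames."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from egosmoke import Alter, Ego, EgoNetwork


def make_network(
    n: int,
    edges: list[tuple[int, int]] = (),
    statuses: list[str | None] | None = None,
    ego_id: str = "e0",
    **ego_kwargs,
) -> EgoNetwork:
    """Build an ego network with alters a00..a{n-1} and integer edge pairs."""
    statuses = statuses or ["non_smoker"] * n
    alters = [Alter(alter_id=f"a{i:02d}", smoking_raw=statuses[i]) for i in range(n)]
    ties = {frozenset((f"a{i:02d}", f"a{j:02d}")) for i, j in edges}
    return EgoNetwork(ego=Ego(ego_id=ego_id, **ego_kwargs), alters=alters, ties=ties)


def random_network(rng: np.random.Generator, n_max: int = 12) -> EgoNetwork:
    """A random graph with random smoking statuses, for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < rng.uniform(0.1, 0.9)]
    levels = ["smoker", "occasional_smoker", "former_smoker",
              "non_smoker", "never_smoker"]
    statuses = [levels[rng.integers(0, 5)] for _ in range(n)]
    return make_network(n, edges, statuses)


@pytest.fixture
def worked_example_network() -> EgoNetwork:
    """25 alters, 9 smokers; focal smoker a00 tied to 4 smoker neighbours."""
    statuses = ["smoker"] * 9 + ["non_smoker"] * 16
    edges = [(0, i) for i in range(1, 5)]
    # some background ties among the rest so the graph is not a bare star
    edges += [(5, 6), (9, 10), (11, 12), (12, 13)]
    return make_network(25, edges, statuses)


@pytest.fixture
def glmm_fixture() -> pd.DataFrame:
    """Fixed 3-ego × 4-alter dataset for quadrature-vs-grid checks."""
    return pd.DataFrame({
        "ego_id": ["e1"] * 4 + ["e2"] * 4 + ["e3"] * 4,
        "y": [1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 0],
        "x": [0.5, -1.2, 0.3, 2.0, -0.7, 0.1, 1.5, -2.0, 0.0, 0.9, -0.4, 1.1],
    })


def grid_loglik(records: pd.DataFrame, beta, sigma_u: float,
                outcome: str = "y", terms=("x",), group: str = "ego_id",
                width: float = 12.0, points: int = 200_001) -> float:
    """Dense-grid (trapezoid) marginal log-likelihood — independent oracle."""
    from scipy.special import expit

    beta = np.asarray(beta, float)
    u = np.linspace(-width * sigma_u, width * sigma_u, points)
    total = 0.0
    for _, g in records.groupby(group):
        X = np.column_stack([np.ones(len(g))] +
                            [g[t].to_numpy(float) for t in terms])
        eta = (X @ beta)[:, None] + u[None, :]
        p = expit(eta)
        y = g[outcome].to_numpy(float)[:, None]
        lik = np.prod(np.where(y == 1, p, 1 - p), axis=0)
        dens = np.exp(-(u ** 2) / (2 * sigma_u ** 2)) / (
            sigma_u * np.sqrt(2 * np.pi))
        total += np.log(np.trapezoid(lik * dens, u))
    return float(total)
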