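"""Structural measures of the alter–alter graph.

All measures are computed on the undirected, unweighted alter–alter graph
with the ego excluded and isolates retained:

* density — realized fraction of the n(n−1)/2 possible ties;
* component count — connected components, isolates counting as one each;
* Freeman degree centralization — Σ_i (d_max − d_i) / ((n−1)(n−2)),
  1 for a star, 0 for any degree-regular graph;
* per-alter normalized degree d_i/(n−1) and betweenness normalized by
  (n−1)(n−2)/2 pairs.

Degenerate graphs (fewer than 2 alters for density, fewer than 3 for
centralization) return 0 with a logged warning instead of raising, so that
descriptive tables never abort on a tiny network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network_model import EgoNetwork

__all__ = [
    "NetworkMetrics",
    "density",
    "count_components",
    "degree_centralization",
    "alter_centralities",
    "network_metrics",
    "zscore",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkMetrics:
    """Network-level structure plus per-alter centralities for one ego."""

    ego_id: str
    n_alters: int
    density: float
    n_components: int
    degree_centralization: float
    degree_norm: dict[str, float]
    betweenness_norm: dict[str, float]


def density(net: EgoNetwork) -> float:
    n = net.n_alters
    if n < 2:
        log.warning("ego %s: density undefined for n=%d, returning 0",
                    net.ego.ego_id, n)
        return 0.0
    return len(net.ties) / (n * (n - 1) / 2)


def count_components(net: EgoNetwork) -> int:
    """Connected components of the alter–alter graph; isolates count."""
    return nx.number_connected_components(net.graph())


def degree_centralization(net: EgoNetwork) -> float:
    """Freeman degree centralization of the alter–alter graph."""
    n = net.n_alters
    if n < 3:
        log.warning("ego %s: centralization undefined for n=%d, returning 0",
                    net.ego.ego_id, n)
        return 0.0
    degrees = np.array([d for _, d in net.graph().degree()], dtype=float)
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def alter_centralities(net: EgoNetwork) -> tuple[dict[str, float], dict[str, float]]:
    """Per-alter normalized degree and betweenness; isolates get (0, 0)."""
    g = net.graph()
    n = net.n_alters
    if n <= 1:
        return ({a.alter_id: 0.0 for a in net.alters},
                {a.alter_id: 0.0 for a in net.alters})
    deg = {v: d / (n - 1) for v, d in g.degree()}
    # networkx normalizes by 2/((n-1)(n-2)) for undirected graphs, which is
    # exactly the pair normalization wanted here.
    btw = (nx.betweenness_centrality(g, normalized=True) if n >= 3
           else {v: 0.0 for v in g})
    return deg, btw


def network_metrics(net: EgoNetwork) -> NetworkMetrics:
    deg, btw = alter_centralities(net)
    return NetworkMetrics(
        ego_id=net.ego.ego_id,
        n_alters=net.n_alters,
        density=density(net),
        n_components=count_components(net),
        degree_centralization=degree_centralization(net),
        degree_norm=deg,
        betweenness_norm=btw,
    )


def zscore(values, *, name: str = "variable") -> np.ndarray:
    """Standardize to mean 0, sd 1 over the pooled non-missing sample.

    Missing values (NaN) propagate.  A constant vector (zero spread) or
    fewer than two observed values raises ``ValueError`` naming the
    variable, since a z-score is then meaningless.
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise ValueError(f"zscore({name}): need >= 2 non-missing values")
    mu, sd = obs.mean(), obs.std(ddof=1)
    if sd == 0:
        raise ValueError(f"zscore({name}): zero spread (constant vector)")
    return (x - mu) / sd
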