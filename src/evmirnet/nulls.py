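"""Randomized-network null models for topological statistics.

Observed centralities are compared against degree-preserving randomizations
of the network: repeated double-edge swaps — replace edges (a,b),(c,d) by
(a,d),(c,b) — each accepted only if it creates no self-loop or duplicate
edge and, for bipartite graphs, keeps both endpoints on their side.  The
degree sequence (and bipartite partition) is conserved exactly, so any
excess of an observed centrality over the null distribution reflects
*wiring* structure beyond what the degrees impose.

Empirical tail probabilities use the rank estimator p = (r + 1)/(n + 1),
which is never exactly zero and is uniform under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd

from . import topology

logger = logging.getLogger(__name__)

__all__ = [
    "rewire_degree_preserving",
    "null_distribution",
    "empirical_pvalue",
    "NullSummary",
    "MEASURES",
]


@dataclass
class RewireLog:
    attempted: int = 0
    accepted: int = 0
    rejected: int = 0


def rewire_degree_preserving(
    net: nx.Graph, n_swaps: int | None = None, seed: int = 0
) -> tuple[nx.Graph, RewireLog]:
    """Degree-preserving randomization by double-edge swaps.

    ``n_swaps`` counts *attempts* (default 10x the edge count), so runtime
    is predictable; rejected attempts (self-loop, duplicate edge, or
    bipartite side violation) leave the graph unchanged.  Bipartiteness is
    detected from a ``bipartite`` node attribute when present.
    """
    g = net.copy()
    m = g.number_of_edges()
    if m < 2:
        logger.warning("graph has %d edge(s); rewiring returns it unchanged", m)
        return g, RewireLog()
    if n_swaps is None:
        n_swaps = 10 * m
    if n_swaps < 1:
        raise ValueError(f"n_swaps must be >= 1, got {n_swaps}")

    sides = nx.get_node_attributes(g, "bipartite")
    bip = len(sides) == g.number_of_nodes() and len(set(sides.values())) == 2
    rng = np.random.default_rng(seed)
    edges = [tuple(e) for e in g.edges]
    if bip:
        # orient every edge left -> right so swaps pair like sides
        left_side = min(set(sides.values()))
        edges = [(a, b) if sides[a] == left_side else (b, a) for a, b in edges]
    log = RewireLog()
    for _ in range(n_swaps):
        log.attempted += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            log.rejected += 1
            continue
        a, b = edges[i]
        c, d = edges[j]
        if bip:
            new1, new2 = (a, d), (c, b)
        else:
            # choose one of the two pairings at random for uniformity
            if rng.integers(2):
                c, d = d, c
            new1, new2 = (a, d), (c, b)
        if new1[0] == new1[1] or new2[0] == new2[1]:
            log.rejected += 1
            continue
        if g.has_edge(*new1) or g.has_edge(*new2):
            log.rejected += 1
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(*new1)
        g.add_edge(*new2)
        edges[i], edges[j] = new1, new2
        log.accepted += 1
    return g, log


def _measure_degree(net: nx.Graph) -> dict[str, float]:
    return {v: float(d) for v, d in net.degree}


def _measure_bridging(net: nx.Graph) -> dict[str, float]:
    _, brc = topology.bridging(net)
    return brc


MEASURES: dict[str, Callable[[nx.Graph], dict[str, float]]] = {
    "degree": _measure_degree,
    "betweenness": topology.betweenness,
    "bridging": _measure_bridging,
    "centroid": topology.centroid,
}


@dataclass
class NullSummary:
    """Observed values and their degree-preserving null distribution."""

    measure: str
    observed: dict[str, float]
    null_values: pd.DataFrame = field(repr=False)  # replicate x node
    scheme: str
    seed: int
    n_random: int
    n_swaps: int | None

    def empirical_p(self, tail: str = "upper") -> dict[str, float]:
        return {
            v: empirical_pvalue(self.observed[v], self.null_values[v].to_numpy(), tail)
            for v in self.null_values.columns
        }

    def quantiles(self, q: float) -> dict[str, float]:
        return self.null_values.quantile(q).to_dict()

    def tidy(self) -> pd.DataFrame:
        long = self.null_values.reset_index(names="replicate").melt(
            id_vars="replicate", var_name="node", value_name="value"
        )
        long.insert(1, "measure", self.measure)
        return long


def null_distribution(
    net: nx.Graph,
    measure: str,
    n_random: int = 40,
    seed: int = 0,
    n_swaps: int | None = None,
) -> NullSummary:
    """Evaluate ``measure`` on ``n_random`` degree-preserving rewirings.

    Replicate r uses seed ``seed + r`` so individual replicates are
    reproducible in isolation.
    """
    if n_random < 1:
        raise ValueError(f"n_random must be >= 1, got {n_random}")
    if measure not in MEASURES:
        raise ValueError(
            f"unknown measure {measure!r}; registered measures: {sorted(MEASURES)}"
        )
    fn = MEASURES[measure]
    observed = {k: float(v) for k, v in fn(net).items()}
    nodes = sorted(observed, key=str)
    rows = np.empty((n_random, len(nodes)))
    for r in range(n_random):
        rewired, _ = rewire_degree_preserving(net, n_swaps=n_swaps, seed=seed + r)
        vals = fn(rewired)
        rows[r] = [vals[v] for v in nodes]
    null_df = pd.DataFrame(rows, columns=nodes)
    null_df.index.name = "replicate"
    return NullSummary(
        measure=measure,
        observed=observed,
        null_values=null_df,
        scheme="degree_preserving_double_edge_swap",
        seed=seed,
        n_random=n_random,
        n_swaps=n_swaps,
    )


def empirical_pvalue(observed: float, null_values: np.ndarray, tail: str = "upper") -> float:
    """Rank-based empirical p-value, p = (r + 1)/(n + 1)."""
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("null sample is empty")
    if tail == "upper":
        r = int(np.sum(null_values >= observed))
    elif tail == "lower":
        r = int(np.sum(null_values <= observed))
    elif tail == "two-sided":
        center = float(np.median(null_values))
        r = int(np.sum(np.abs(null_values - center) >= abs(observed - center)))
    else:
        raise ValueError(f"tail must be upper|lower|two-sided, got {tail}")
    return (r + 1) / (null_values.size + 1)
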