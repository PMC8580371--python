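"""PPI network construction, Betweenness / Bridging / Centroid centralities,
and consensus hub selection.

Edges of the protein-protein interaction table are filtered on their
evidence-channel scores (defaults: experiments > 0.0031, databases > 0.36,
retained when at least one configured channel passes).  On the resulting
simple undirected graph three node centralities are computed:

* **Betweenness** C_B(v): number of shortest paths between unordered node
  pairs passing through v as an interior node, fractionally weighted when
  several shortest paths exist.  Unnormalized, endpoints excluded.
* **Bridging centrality** BrC(v) = C_B(v) x BCoef(v), with the bridging
  coefficient BCoef(v) = (1/deg v) / sum_{u in N(v)} 1/deg(u) — large for
  nodes whose neighbourhood is better connected than themselves, i.e.
  nodes sitting between modules.
* **Centroid centrality** C_cen(v) = min_{w != v} [gamma_v(w) - gamma_w(v)],
  where gamma_v(w) counts the nodes strictly closer to v than to w; positive
  only for nodes near the topological centre of their component.

A node is a *hub* when its centrality strictly exceeds the network-wide mean
— by default simultaneously for all three measures (consensus rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "filter_ppi_edges",
    "graph_from_edges",
    "betweenness",
    "bridging",
    "centroid",
    "centrality_report",
    "select_hubs",
    "crosslink_hubs",
    "HubSet",
]

DEFAULT_PPI_THRESHOLDS = {"experiments": 0.0031, "databases": 0.36}


def filter_ppi_edges(
    edges: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    mode: str = "union",
) -> pd.DataFrame:
    """Filter PPI edges on evidence-channel scores.

    An edge is retained when its score strictly exceeds the channel
    threshold in at least one configured channel (``mode="union"``, the
    default) or in every configured channel (``mode="intersection"``).
    Self-loops are dropped and endpoints canonicalized (protein_a <
    protein_b); duplicate edges keep the maximum score per channel.
    """
    if thresholds is None:
        thresholds = dict(DEFAULT_PPI_THRESHOLDS)
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be union|intersection, got {mode}")
    channels = [c for c in edges.columns if c not in ("protein_a", "protein_b")]
    unknown = set(thresholds) - set(channels)
    if unknown:
        raise ValueError(
            f"unknown channel(s) {sorted(unknown)}; available channels: {sorted(channels)}"
        )
    out = edges.copy()
    # canonicalize and drop loops
    a = out["protein_a"].astype(str)
    b = out["protein_b"].astype(str)
    swap = a > b
    out["protein_a"] = a.where(~swap, b)
    out["protein_b"] = b.where(~swap, a)
    out = out[out["protein_a"] != out["protein_b"]]
    out = out.groupby(["protein_a", "protein_b"], as_index=False).max()

    passing = [out[ch] > thr for ch, thr in thresholds.items()]
    combined = np.logical_or.reduce(passing) if mode == "union" else np.logical_and.reduce(passing)
    return out.loc[combined].reset_index(drop=True)


def graph_from_edges(edges: pd.DataFrame) -> nx.Graph:
    """Simple undirected graph from a (canonicalized) PPI edge table."""
    g = nx.Graph()
    g.add_edges_from(zip(edges["protein_a"], edges["protein_b"]))
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def betweenness(net: nx.Graph) -> dict[str, float]:
    """Unnormalized betweenness, each unordered pair counted once,
    endpoints excluded (Brandes accumulation)."""
    return nx.betweenness_centrality(net, normalized=False)


def bridging(net: nx.Graph, cb: dict[str, float] | None = None) -> tuple[dict[str, float], dict[str, float]]:
    """Bridging coefficient and bridging centrality per node.

    BCoef(v) = (1/deg v) / sum over neighbours u of 1/deg(u);
    BrC(v) = C_B(v) * BCoef(v).  Isolated nodes get BCoef = 0 (logged).
    """
    if cb is None:
        cb = betweenness(net)
    bcoef: dict[str, float] = {}
    brc: dict[str, float] = {}
    for v in net.nodes:
        d = net.degree(v)
        if d == 0:
            logger.info("isolated node %r assigned bridging coefficient 0", v)
            bcoef[v] = 0.0
        else:
            denom = sum(1.0 / net.degree(u) for u in net.neighbors(v))
            bcoef[v] = (1.0 / d) / denom
        brc[v] = cb[v] * bcoef[v]
    return bcoef, brc


def centroid(net: nx.Graph) -> dict[str, float]:
    """Centroid centrality, computed within each connected component.

    C_cen(v) = min over w != v in v's component of gamma_v(w) - gamma_w(v),
    where gamma_v(w) = #{u outside {v, w} : d(u, v) < d(u, w)}.  Nodes in
    singleton components get 0.
    """
    out: dict[str, float] = {}
    for comp in nx.connected_components(net):
        nodes = sorted(comp)
        n = len(nodes)
        if n == 1:
            out[nodes[0]] = 0.0
            continue
        sub = net.subgraph(nodes)
        index = {v: i for i, v in enumerate(nodes)}
        dist = np.zeros((n, n))
        for v, lengths in nx.all_pairs_shortest_path_length(sub):
            i = index[v]
            for u, d in lengths.items():
                dist[index[u], i] = d
        # closer[v, w] = #{u : d(u,v) < d(u,w)}; u = v always contributes 1
        # (d(v,v)=0 < d(v,w)) and u = w never does, so
        # gamma_v(w) = closer[v, w] - 1 and the -1 cancels in the difference.
        closer = (dist[:, :, None] < dist[:, None, :]).sum(axis=0)
        f = (closer - closer.T).astype(float)
        np.fill_diagonal(f, np.inf)
        vals = f.min(axis=1)
        for v, val in zip(nodes, vals):
            out[v] = float(val)
    return out


def centrality_report(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness, bridging (coefficient and centrality)
    and centroid value, as a DataFrame indexed by node."""
    cb = betweenness(net)
    bcoef, brc = bridging(net, cb)
    cc = centroid(net)
    nodes = sorted(net.nodes)
    return pd.DataFrame(
        {
            "degree": [net.degree(v) for v in nodes],
            "betweenness": [cb[v] for v in nodes],
            "bridging_coef": [bcoef[v] for v in nodes],
            "bridging": [brc[v] for v in nodes],
            "centroid": [cc[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


@dataclass
class HubSet:
    hubs: list[str]
    required: tuple[str, ...]
    mode: str
    means: dict[str, float]
    passes: pd.DataFrame = field(repr=False)
    crosslink: dict[str, int] | None = None


def select_hubs(
    report: pd.DataFrame,
    required: tuple[str, ...] = ("betweenness", "bridging", "centroid"),
    mode: str = "all",
) -> HubSet:
    """Select hub nodes: centrality strictly above the network-wide mean.

    ``mode="all"`` (consensus, default) requires every centrality in
    ``required`` to exceed its mean; ``mode="any"`` requires at least one.
    """
    if report.empty:
        raise ValueError("centrality report is empty")
    if mode not in ("all", "any"):
        raise ValueError(f"mode must be all|any, got {mode}")
    missing = [c for c in required if c not in report.columns]
    if missing:
        raise ValueError(f"centralities {missing} absent from report")
    means = {c: float(report[c].mean()) for c in required}
    passes = pd.DataFrame({c: report[c] > means[c] for c in required})
    agg = passes.all(axis=1) if mode == "all" else passes.any(axis=1)
    return HubSet(
        hubs=sorted(report.index[agg]),
        required=tuple(required),
        mode=mode,
        means=means,
        passes=passes,
    )


def crosslink_hubs(hubset: HubSet, bipartite_net: nx.Graph) -> HubSet:
    """Annotate each hub with the number of miRNAs targeting it, i.e. its
    degree in the miRNA-target bipartite network (0 when absent)."""
    hubset.crosslink = {
        h: (bipartite_net.degree(h) if h in bipartite_net else 0) for h in hubset.hubs
    }
    return hubset
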