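"""miRNA-target bipartite network over the DE transcript list, and the
enrichment statistics comparing up- versus down-regulated targets.

The interaction table (validated miRNA-target records, optionally scored) is
first reduced to the top-scoring fraction within each source database, then
restricted to targets present in the differential-expression list; the
resulting unique (miRNA, target) pairs form an undirected bipartite graph.
Transcript degree (number of distinct miRNAs targeting it) is compared
between up- and down-regulated transcripts by a classical two-sample
Student's t-test, with a label-permutation test as its nonparametric twin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_top_percent",
    "build_bipartite",
    "degree_report",
    "student_t",
    "enrichment_stats",
    "label_permutation_test",
    "EnrichmentResult",
    "mirna_nodes",
    "target_nodes",
]

MIRNA_SIDE = 0
TARGET_SIDE = 1


def filter_top_percent(interactions: pd.DataFrame, pct: float = 20.0) -> pd.DataFrame:
    """Keep, within each source, the records in the top ``pct`` percent by score.

    The cutoff rank is ceil(pct/100 * n_scored); every record tied with the
    boundary score is retained.  Records without a score (NaN, or a missing
    score column) are retained unconditionally — they correspond to curated
    entries a score filter should not discard.
    """
    if not 0.0 < pct <= 100.0:
        raise ValueError(f"pct must lie in (0, 100], got {pct}")
    if "score" not in interactions.columns or interactions.empty:
        return interactions.copy()
    keep = np.ones(len(interactions), dtype=bool)
    scores = interactions["score"].to_numpy(dtype=float)
    scored = np.isfinite(scores)
    for source, idx in interactions.groupby("source").indices.items():
        idx = np.asarray(idx)
        s_idx = idx[scored[idx]]
        n = s_idx.size
        if n == 0:
            continue
        k = math.ceil(pct / 100.0 * n)
        boundary = np.sort(scores[s_idx])[::-1][k - 1]
        keep[s_idx] = scores[s_idx] >= boundary
    return interactions.loc[keep].reset_index(drop=True)


def build_bipartite(
    mirnas: set[str] | list[str],
    de: pd.DataFrame,
    interactions: pd.DataFrame,
    direction_filter: str = "both",
) -> nx.Graph:
    """Build the miRNA-target bipartite graph restricted to DE transcripts.

    Edges are the unique (miRNA, target) pairs among ``interactions`` whose
    miRNA is in ``mirnas`` and whose target appears in the DE table (within
    ``direction_filter``: "up", "down" or "both"); records duplicated across
    sources collapse to a single edge.  miRNAs without any retained target
    stay in the graph as degree-0 nodes; transcripts enter only via edges.
    """
    if direction_filter not in ("up", "down", "both"):
        raise ValueError(f"direction_filter must be up|down|both, got {direction_filter}")
    if len(mirnas) == 0:
        raise ValueError("mirnas must be non-empty")
    de_keep = de if direction_filter == "both" else de[de["direction"] == direction_filter]
    targets_allowed = set(de_keep["transcript"])
    mirna_set = set(mirnas)

    g = nx.Graph()
    g.add_nodes_from(sorted(mirna_set), bipartite=MIRNA_SIDE)
    if not interactions.empty:
        mask = interactions["mirna"].isin(mirna_set) & interactions["target"].isin(
            targets_allowed
        )
        pairs = {
            (m, t)
            for m, t in zip(
                interactions.loc[mask, "mirna"], interactions.loc[mask, "target"]
            )
        }
        for m, t in sorted(pairs):
            g.add_node(t, bipartite=TARGET_SIDE)
            g.add_edge(m, t)
    return g


def mirna_nodes(net: nx.Graph) -> list[str]:
    return sorted(n for n, d in net.nodes(data=True) if d["bipartite"] == MIRNA_SIDE)


def target_nodes(net: nx.Graph) -> list[str]:
    return sorted(n for n, d in net.nodes(data=True) if d["bipartite"] == TARGET_SIDE)


def degree_report(net: nx.Graph, side: str = "mirna", min_degree: int = 0) -> pd.DataFrame:
    """Nodes of one side with degree strictly above ``min_degree``.

    Ordered descending by degree, lexicographic within ties.  This is the
    "most connected" report: e.g. miRNAs targeting the largest number of DE
    transcripts, or transcripts targeted by the most miRNAs.
    """
    if side not in ("mirna", "target"):
        raise ValueError(f"side must be mirna|target, got {side}")
    nodes = mirna_nodes(net) if side == "mirna" else target_nodes(net)
    rows = [(n, net.degree(n)) for n in nodes if net.degree(n) > min_degree]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["node", "degree"])


def student_t(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, int, float]:
    """Classical equal-variance two-sample t-test.

    Returns (t, df, two-sided p) with df = n_a + n_b - 2.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs >= 2 observations (got {a.size}, {b.size})")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 <= 0.0:
        raise ValueError("pooled variance is zero; t statistic undefined")
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


@dataclass
class EnrichmentResult:
    """Up- versus down-regulated target-degree comparison."""

    mean_degree_up: float
    mean_degree_down: float
    ratio: float | None
    t_stat: float | None
    df: int | None
    p_value: float | None
    permutation_p: float | None = None
    mirna_up_fraction: pd.DataFrame | None = field(default=None, repr=False)
    mean_up_fraction: float | None = None
    coverage_count: int = 0
    coverage_fraction: float = 0.0
    n_up: int = 0
    n_down: int = 0
    degenerate: bool = False


def _degrees_by_direction(
    net: nx.Graph, de: pd.DataFrame, include_zero_degree: bool = True
) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    deg = pd.Series(
        {t: net.degree(t) if t in net else 0 for t in de["transcript"]}, dtype=float
    )
    if not include_zero_degree:
        deg = deg[deg > 0]
    direction = de.set_index("transcript")["direction"]
    up = deg[direction.loc[deg.index] == "up"].to_numpy()
    down = deg[direction.loc[deg.index] == "down"].to_numpy()
    return up, down, deg


def enrichment_stats(
    net: nx.Graph,
    de: pd.DataFrame,
    min_mirna_degree: int = 2,
    include_zero_degree: bool = True,
) -> EnrichmentResult:
    """Compute the full enrichment summary of the bipartite network.

    Per-transcript degree (distinct targeting miRNAs) is grouped by DE
    direction; DE transcripts without any interaction count with degree 0
    unless ``include_zero_degree`` is False.  Alongside the mean-degree
    ratio and Student's t-test, reports the per-miRNA fraction of targets
    that are upregulated — averaged over miRNAs with total degree strictly
    above ``min_mirna_degree`` (default 2, i.e. more than two targets) — and
    the coverage (DE transcripts targeted by at least one miRNA).
    """
    up, down, _ = _degrees_by_direction(net, de, include_zero_degree)
    de_set = set(de["transcript"])
    covered = sum(1 for t in target_nodes(net) if net.degree(t) > 0 and t in de_set)
    coverage_fraction = covered / len(de_set) if de_set else 0.0

    up_targets = set(de.loc[de["direction"] == "up", "transcript"])
    rows = []
    for m in mirna_nodes(net):
        d = net.degree(m)
        n_up_t = sum(1 for t in net.neighbors(m) if t in up_targets)
        rows.append((m, d, n_up_t / d if d else np.nan))
    frac = pd.DataFrame(rows, columns=["mirna", "degree", "up_fraction"])
    qualifying = frac[frac["degree"] > min_mirna_degree]
    mean_up_fraction = (
        float(qualifying["up_fraction"].mean()) if not qualifying.empty else None
    )

    if up.size < 2 or down.size < 2:
        return EnrichmentResult(
            mean_degree_up=float(up.mean()) if up.size else float("nan"),
            mean_degree_down=float(down.mean()) if down.size else float("nan"),
            ratio=None,
            t_stat=None,
            df=None,
            p_value=None,
            mirna_up_fraction=frac,
            mean_up_fraction=mean_up_fraction,
            coverage_count=covered,
            coverage_fraction=coverage_fraction,
            n_up=int(up.size),
            n_down=int(down.size),
            degenerate=True,
        )
    mean_up, mean_down = float(up.mean()), float(down.mean())
    ratio = mean_up / mean_down if mean_down > 0 else None
    try:
        t, df, p = student_t(up, down)
    except ValueError:
        t = df = p = None  # zero pooled variance
    return EnrichmentResult(
        mean_degree_up=mean_up,
        mean_degree_down=mean_down,
        ratio=ratio,
        t_stat=t,
        df=df,
        p_value=p,
        mirna_up_fraction=frac,
        mean_up_fraction=mean_up_fraction,
        coverage_count=covered,
        coverage_fraction=coverage_fraction,
        n_up=int(up.size),
        n_down=int(down.size),
        degenerate=t is None,
    )


def label_permutation_test(
    net: nx.Graph,
    de: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    include_zero_degree: bool = True,
) -> float:
    """Empirical p-value for the up/down mean-degree difference.

    Up/down labels are shuffled over transcripts (group sizes preserved) and
    the absolute mean-degree difference recomputed; p = (r + 1)/(n_perm + 1)
    with r the number of permutations at least as extreme as observed.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    up, down, deg = _degrees_by_direction(net, de, include_zero_degree)
    observed = abs(up.mean() - down.mean())
    values = deg.to_numpy()
    n_up = up.size
    rng = np.random.default_rng(seed)
    r = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        diff = abs(perm[:n_up].mean() - perm[n_up:].mean())
        if diff >= observed - 1e-12:
            r += 1
    return (r + 1) / (n_perm + 1)
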