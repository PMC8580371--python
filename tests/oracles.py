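"""Independent brute-force oracles used by the test suite.

These deliberately use naive enumeration (plain BFS + explicit path
enumeration, triple loops over the definition) so they share no code path
with the implementations they check.
"""

from __future__ import annotations

from collections import deque


def adjacency(edges) -> dict:
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def bfs_dist(adj: dict, s) -> dict:
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def all_shortest_paths(adj: dict, s, t) -> list[list]:
    """Every shortest s-t path, by layered enumeration."""
    dist = bfs_dist(adj, s)
    if t not in dist:
        return []
    paths = [[s]]
    for step in range(dist[t]):
        paths = [
            p + [v]
            for p in paths
            for v in adj[p[-1]]
            if dist.get(v) == step + 1
        ]
    return [p for p in paths if p[-1] == t]


def brute_betweenness(nodes, edges) -> dict:
    """Unnormalized betweenness: sum over unordered pairs of the fraction
    of shortest paths passing through each interior node."""
    adj = adjacency(edges)
    cb = {v: 0.0 for v in nodes}
    nl = sorted(nodes)
    for i, s in enumerate(nl):
        for t in nl[i + 1 :]:
            paths = all_shortest_paths(adj, s, t) if s in adj and t in adj else []
            if not paths:
                continue
            sigma = len(paths)
            for v in nl:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                cb[v] += through / sigma
    return cb


def brute_bridging_coef(nodes, edges) -> dict:
    adj = adjacency(edges)
    out = {}
    for v in nodes:
        nbrs = adj.get(v, set())
        if not nbrs:
            out[v] = 0.0
            continue
        out[v] = (1.0 / len(nbrs)) / sum(1.0 / len(adj[u]) for u in nbrs)
    return out


def brute_centroid(nodes, edges) -> dict:
    """Centroid value from the definition: C(v) = min_w [gamma_v(w) - gamma_w(v)],
    gamma_v(w) = #{u outside {v,w} in the same component: d(u,v) < d(u,w)}."""
    adj = adjacency(edges)
    dists = {v: bfs_dist(adj, v) if v in adj else {v: 0} for v in nodes}
    out = {}
    for v in nodes:
        comp = set(dists[v])
        others = [w for w in comp if w != v]
        if not others:
            out[v] = 0.0
            continue
        best = None
        for w in others:
            gamma_vw = sum(
                1 for u in comp if u not in (v, w) and dists[v][u] < dists[w][u]
            )
            gamma_wv = sum(
                1 for u in comp if u not in (v, w) and dists[w][u] < dists[v][u]
            )
            f = gamma_vw - gamma_wv
            best = f if best is None else min(best, f)
        out[v] = float(best)
    return out


def straight_line_global_mean(ct_rows: dict, ct_max: float) -> dict:
    """Element-wise recomputation of global-mean normalization.

    ``ct_rows`` maps miRNA -> list of Ct per subject (detected panel only);
    returns miRNA -> list of relative values (None where not amplifying).
    """
    n_subj = len(next(iter(ct_rows.values())))
    rel = {m: [None] * n_subj for m in ct_rows}
    for s in range(n_subj):
        present = [m for m in ct_rows if ct_rows[m][s] < ct_max]
        gm = sum(ct_rows[m][s] for m in present) / len(present)
        for m in present:
            rel[m][s] = gm - ct_rows[m][s]
    return rel
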