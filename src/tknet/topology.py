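"""Key-node topology: degree, bipartite betweenness centrality (BiBC), and
the random-network null ensemble used to judge whether a hub could occur by
chance.

BiBC of a node v is the sum, over all pairs (s, t) with s in one node group
(e.g. microbes) and t in the other (host parameters), of the fraction of
shortest s-t paths that pass through v. It is computed with a
Brandes-style dependency accumulation restricted to cross-group pairs and
left unnormalized (a raw path-fraction count); pairs in different
components contribute nothing.

The null model draws uniform random simple graphs G(n, m) with exactly the
real network's node and edge counts, reassigns the two group labels at
random with the real group sizes, and records each random network's best
node, giving an empirical density of (degree, BiBC) extremes against which
the real hubs are compared via an upper-tail probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "bibc",
    "node_topology",
    "rank_key_nodes",
    "pareto_frontier",
    "erdos_renyi_gnm",
    "null_ensemble",
    "NullEnsembleDensity",
    "powerlaw_degree_fit",
]


def _adjacency(graph: nx.Graph) -> tuple[list[str], dict, list[list[int]]]:
    nodes = list(graph.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    for u, v in graph.edges:
        adj[idx[u]].append(idx[v])
        adj[idx[v]].append(idx[u])
    return nodes, idx, adj


def _bibc_accumulate(adj: list[list[int]], sources: list[int], targets: set[int]) -> np.ndarray:
    """Brandes dependency accumulation restricted to cross-group pairs."""
    n = len(adj)
    bc = np.zeros(n)
    for s in sources:
        # BFS shortest-path DAG from s
        sigma = [0.0] * n
        dist = [-1] * n
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma[s] = 1.0
        dist[s] = 0
        order: list[int] = [s]
        head = 0
        while head < len(order):
            v = order[head]
            head += 1
            dv = dist[v]
            sv = sigma[v]
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dv + 1
                    order.append(w)
                if dist[w] == dv + 1:
                    sigma[w] += sv
                    preds[w].append(v)
        delta = [0.0] * n
        for w in reversed(order):
            coeff = delta[w]
            if w in targets and w != s:
                coeff += 1.0
            coeff /= sigma[w]
            for v in preds[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    return bc


def bibc(
    graph: nx.Graph,
    group1,
    group2,
    normalized: bool = False,
) -> pd.Series:
    """Bipartite betweenness centrality of every node.

    ``group1`` and ``group2`` are disjoint node collections; each node v
    scores the summed fraction of shortest paths between cross-group pairs
    (s in group1, t in group2, s != v != t) passing through v. With
    ``normalized=True`` the score is divided by the number of cross-group
    pairs.
    """
    g1, g2 = list(group1), list(group2)
    overlap = set(g1) & set(g2)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    missing = (set(g1) | set(g2)) - set(graph.nodes)
    if missing:
        raise ValueError(f"group members not in graph: {sorted(missing)[:5]}")
    nodes, idx, adj = _adjacency(graph)
    a = [idx[u] for u in g1]
    b = [idx[u] for u in g2]
    if len(a) <= len(b):
        sources, targets = a, set(b)
    else:
        sources, targets = b, set(a)
    bc = _bibc_accumulate(adj, sources, targets)
    if normalized and g1 and g2:
        bc = bc / (len(g1) * len(g2))
    return pd.Series(bc, index=pd.Index(nodes, name="node_id"), name="bibc")


def node_topology(graph: nx.Graph, group1, group2, normalized: bool = False) -> pd.DataFrame:
    """Per-node degree and BiBC."""
    b = bibc(graph, group1, group2, normalized=normalized)
    deg = pd.Series(dict(graph.degree), name="degree").reindex(b.index)
    return pd.DataFrame({"degree": deg.astype(int), "bibc": b})


def rank_key_nodes(topology: pd.DataFrame, restrict_to=None) -> pd.DataFrame:
    """Nodes ordered by BiBC (descending), ties broken by degree then id.

    ``restrict_to`` limits the ranking to a node subset (e.g. ASVs only).
    Adds a ``pareto`` column marking the (degree, BiBC) Pareto frontier.
    """
    top = topology if restrict_to is None else topology.loc[[n for n in restrict_to if n in topology.index]]
    # stable sort from id order so equal (bibc, degree) rows end up id-ordered
    out = top.loc[sorted(top.index)].sort_values(
        by=["bibc", "degree"], ascending=[False, False], kind="mergesort"
    )
    out = out.copy()
    out["pareto"] = pareto_frontier(out)
    return out


def pareto_frontier(topology: pd.DataFrame) -> pd.Series:
    """Boolean mask of nodes not dominated in (degree, bibc) by any other
    node (strictly better in one coordinate, at least as good in the other)."""
    deg = topology["degree"].to_numpy(dtype=float)
    bib = topology["bibc"].to_numpy(dtype=float)
    n = len(topology)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        dominated = (
            ((deg >= deg[i]) & (bib >= bib[i]) & ((deg > deg[i]) | (bib > bib[i])))
        ).any()
        mask[i] = not dominated
    return pd.Series(mask, index=topology.index, name="pareto")


def _gnm_edge_indices(n: int, m: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    max_m = n * (n - 1) // 2
    if m > max_m:
        raise ValueError(f"m={m} exceeds the {max_m} possible edges on {n} nodes")
    if m < 0 or n < 1:
        raise ValueError("need n >= 1 and m >= 0")
    iu, iv = np.triu_indices(n, k=1)
    pick = rng.choice(max_m, size=m, replace=False)
    return iu[pick], iv[pick]


def erdos_renyi_gnm(n: int, m: int, seed: int | np.random.Generator = 0) -> nx.Graph:
    """Uniform random simple graph with exactly ``n`` nodes and ``m`` edges
    (no self- or multi-edges); fully seeded."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u, v = _gnm_edge_indices(n, m, rng)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(u.tolist(), v.tolist()))
    return g


@dataclass
class NullEnsembleDensity:
    """Empirical distribution of the best node's (degree, BiBC) over a
    random-graph ensemble."""

    n: int
    m: int
    group_sizes: tuple[int, int]
    count: int
    seed: int
    max_bibc_pairs: np.ndarray  # (count, 2): degree, bibc of each network's max-BiBC node
    max_degree_pairs: np.ndarray  # (count, 2): degree, bibc of each network's max-degree node
    bins: int = 50

    def density(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """2D histogram (frequencies summing to 1) of the max-BiBC pairs on a
        (degree, bibc) grid; returns (hist, degree_edges, bibc_edges)."""
        deg = self.max_bibc_pairs[:, 0]
        bib = self.max_bibc_pairs[:, 1]
        dmax = int(deg.max()) if len(deg) else 0
        degree_edges = np.arange(0, dmax + 2) - 0.5
        bibc_edges = np.linspace(0.0, max(bib.max(), 1e-9), self.bins + 1)
        hist, _, _ = np.histogram2d(deg, bib, bins=[degree_edges, bibc_edges])
        return hist / hist.sum(), degree_edges, bibc_edges

    def tail_probability(self, degree: float, bibc_value: float) -> float:
        """P(degree >= d AND BiBC >= b) for the best node of a random
        network, by empirical counting."""
        hits = (self.max_bibc_pairs[:, 0] >= degree) & (self.max_bibc_pairs[:, 1] >= bibc_value)
        return float(hits.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "max_bibc_degree": self.max_bibc_pairs[:, 0],
                "max_bibc_bibc": self.max_bibc_pairs[:, 1],
                "max_degree_degree": self.max_degree_pairs[:, 0],
                "max_degree_bibc": self.max_degree_pairs[:, 1],
            }
        )


def null_ensemble(
    n: int,
    m: int,
    group_sizes: tuple[int, int],
    count: int = 10_000,
    seed: int = 0,
    bins: int = 50,
) -> NullEnsembleDensity:
    """Generate ``count`` G(n, m) random graphs, reassign the two group
    labels uniformly at random with the given sizes, and record each
    network's extreme nodes.

    Per network the summary node is the maximum-BiBC node (ties broken by
    higher degree); the maximum-degree node (ties by higher BiBC) is recorded
    alongside.
    """
    g1, g2 = group_sizes
    if g1 < 1 or g2 < 1 or g1 + g2 > n:
        raise ValueError(f"invalid group sizes {group_sizes} for n={n}")
    rng = np.random.default_rng(seed)
    max_bibc = np.empty((count, 2))
    max_deg = np.empty((count, 2))
    for it in range(count):
        u, v = _gnm_edge_indices(n, m, rng)
        adj: list[list[int]] = [[] for _ in range(n)]
        deg = np.zeros(n, dtype=int)
        for a, b in zip(u.tolist(), v.tolist()):
            adj[a].append(b)
            adj[b].append(a)
            deg[a] += 1
            deg[b] += 1
        labels = rng.permutation(n)
        ga, gb = labels[:g1].tolist(), labels[g1 : g1 + g2].tolist()
        if len(ga) <= len(gb):
            sources, targets = ga, set(gb)
        else:
            sources, targets = gb, set(ga)
        bc = _bibc_accumulate(adj, sources, targets)
        i = int(np.lexsort((-deg, -bc))[0])
        max_bibc[it] = (deg[i], bc[i])
        j = int(np.lexsort((-bc, -deg))[0])
        max_deg[it] = (deg[j], bc[j])
    return NullEnsembleDensity(
        n=n,
        m=m,
        group_sizes=(g1, g2),
        count=count,
        seed=seed,
        max_bibc_pairs=max_bibc,
        max_degree_pairs=max_deg,
        bins=bins,
    )


def powerlaw_degree_fit(graph: nx.Graph | pd.Series) -> tuple[float, float]:
    """Least-squares power-law fit of the degree histogram.

    Regresses log(count of nodes with degree k) on log k over the positive
    degrees with nonzero counts (isolated nodes are ignored); returns
    (slope, R^2). Requires at least three distinct positive degrees.
    """
    if isinstance(graph, nx.Graph):
        degrees = np.array([d for _, d in graph.degree], dtype=int)
    else:
        degrees = np.asarray(graph, dtype=int)
    degrees = degrees[degrees >= 1]
    ks, counts = np.unique(degrees, return_counts=True)
    if ks.size < 3:
        raise ValueError("need at least 3 distinct positive degrees for a power-law fit")
    lx = np.log(ks.astype(float))
    ly = np.log(counts.astype(float))
    slope, intercept = np.polyfit(lx, ly, 1)
    fitted = slope * lx + intercept
    ss_res = float(((ly - fitted) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(r2)
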