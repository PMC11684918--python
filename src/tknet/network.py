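"""Sign-consistent Spearman correlation network over the treated group.

Nodes are the differentially responding ASVs and host parameters. For every
unordered node pair, Spearman correlations are computed within each
experiment's treated (WD_Ch) samples and on the pooled treated samples; an
edge is kept only if

1. the per-experiment correlations agree in (nonzero) sign,
2. the pooled correlation p-value is below the edge threshold (0.05), and
3. the causality filter passes: the pooled correlation sign equals the
   product of the two endpoints' fold-change signs (an edge whose sign
   contradicts how its endpoints moved between conditions is treated as a
   correlation inequality and removed).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .netgraph import NetworkEdge, NetworkNode, TranskingdomNetwork

__all__ = [
    "spearman_rho",
    "pairwise_spearman",
    "causality_filter",
    "build_edges",
    "assemble_network",
]


def spearman_rho(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with pairwise deletion of missing values.

    p-value from the t-distribution approximation with n-2 df; with
    ``exact=True`` (small n only) an exact permutation p is computed instead.
    Raises for constant input, where rho is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    if exact:
        if x.size > 8:
            raise ValueError("exact permutation p only supported for n <= 8")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = abs(np.corrcoef(rx, perm)[0, 1])
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    return float(rho), float(p)


def _rank_columns(mat: np.ndarray) -> np.ndarray:
    # mat: features x samples; rank within each row
    return np.apply_along_axis(stats.rankdata, 1, mat)


def pairwise_spearman(data: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and t-approximation p for the rows of ``data``
    (features x samples). Missing values are deleted pairwise; constant rows
    yield NaN against every partner.
    """
    mat = data.to_numpy(dtype=float)
    n_feat, n_samp = mat.shape
    if n_samp < 3:
        raise ValueError("need at least 3 samples")
    if not np.isnan(mat).any():
        ranks = _rank_columns(mat)
        sd = ranks.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.corrcoef(ranks)
        rho[sd == 0, :] = np.nan
        rho[:, sd == 0] = np.nan
        p = _t_approx_p(rho, n_samp)
    else:
        rho = np.full((n_feat, n_feat), np.nan)
        p = np.full((n_feat, n_feat), np.nan)
        for i in range(n_feat):
            rho[i, i], p[i, i] = 1.0, 0.0
            for j in range(i + 1, n_feat):
                try:
                    r, pv = spearman_rho(mat[i], mat[j])
                except ValueError:
                    continue
                rho[i, j] = rho[j, i] = r
                p[i, j] = p[j, i] = pv
    ids = data.index
    return pd.DataFrame(rho, index=ids, columns=ids), pd.DataFrame(p, index=ids, columns=ids)


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0 - 1e-15, 0.0, p)
    p = np.where(np.isnan(rho), np.nan, p)
    np.fill_diagonal(p, 0.0)
    return p


def causality_filter(rho_sign: float, fc_sign_a: int, fc_sign_b: int) -> bool:
    """Pass iff the correlation sign equals the product of the endpoints'
    fold-change signs; zero fold-change signs fail."""
    if fc_sign_a == 0 or fc_sign_b == 0:
        return False
    return bool(np.sign(rho_sign) == fc_sign_a * fc_sign_b)


def build_edges(
    data_by_exp: dict[int, pd.DataFrame],
    fc_sign: pd.Series,
    edge_p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Edge candidates for every unordered node pair.

    ``data_by_exp`` maps experiment -> (nodes x treated-samples) frame; the
    pooled correlation is computed on the column-concatenated frames.
    ``fc_sign`` gives each node's fold-change sign for the causality filter.
    Returns one row per pair with per-filter pass flags and the conjunction
    in ``kept``.
    """
    exps = sorted(data_by_exp)
    if len(exps) < 2:
        raise ValueError("need at least two experiments")
    index = data_by_exp[exps[0]].index
    for e in exps[1:]:
        if not index.equals(data_by_exp[e].index):
            raise ValueError("experiments disagree on node set")
    for e in exps:
        if data_by_exp[e].shape[1] < 3:
            raise ValueError(f"experiment {e} has fewer than 3 treated samples")
    pooled = pd.concat([data_by_exp[e] for e in exps], axis=1)
    rho_e = {e: pairwise_spearman(data_by_exp[e])[0] for e in exps}
    rho_p, p_p = pairwise_spearman(pooled)

    rows = []
    ids = list(index)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            r1 = float(rho_e[exps[0]].at[a, b])
            r2 = float(rho_e[exps[1]].at[a, b])
            rp = float(rho_p.at[a, b])
            pp = float(p_p.at[a, b])
            if math.isnan(r1) or math.isnan(r2) or math.isnan(rp):
                continue  # undefined correlation (constant node) is excluded
            sign_ok = np.sign(r1) == np.sign(r2) != 0
            p_ok = pp < edge_p_threshold
            cause_ok = causality_filter(np.sign(rp), int(fc_sign.get(a, 0)), int(fc_sign.get(b, 0)))
            rows.append(
                {
                    "node_a": a,
                    "node_b": b,
                    "rho_exp1": r1,
                    "rho_exp2": r2,
                    "rho_pooled": rp,
                    "p_pooled": pp,
                    "sign_consistent": bool(sign_ok),
                    "p_threshold": bool(p_ok),
                    "causality": bool(cause_ok),
                    "kept": bool(sign_ok and p_ok and cause_ok),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "node_a",
            "node_b",
            "rho_exp1",
            "rho_exp2",
            "rho_pooled",
            "p_pooled",
            "sign_consistent",
            "p_threshold",
            "causality",
            "kept",
        ],
    )


def assemble_network(
    nodes: pd.DataFrame,
    edges: pd.DataFrame,
) -> tuple[TranskingdomNetwork, set[str]]:
    """Build the transkingdom network from node metadata and kept edges.

    ``nodes``: frame indexed by node id with columns ``kind``, ``fc_sign``
    and optionally ``mean_abundance``. ``edges``: output of
    :func:`build_edges` (only rows with ``kept`` are added). Returns the
    network and its main (largest) connected component.
    """
    net = TranskingdomNetwork()
    for nid, row in nodes.iterrows():
        ma = row.get("mean_abundance")
        net.add_node(
            NetworkNode(
                id=str(nid),
                kind=str(row["kind"]),
                fc_sign=int(row["fc_sign"]),
                mean_abundance=None if ma is None or (isinstance(ma, float) and math.isnan(ma)) else float(ma),
            )
        )
    if len(edges):
        for _, e in edges[edges["kept"]].iterrows():
            net.add_edge(
                NetworkEdge(
                    node_a=str(e["node_a"]),
                    node_b=str(e["node_b"]),
                    rho_pooled=float(e["rho_pooled"]),
                    p_pooled=float(e["p_pooled"]),
                    rho_sign_exp1=int(np.sign(e["rho_exp1"])),
                    rho_sign_exp2=int(np.sign(e["rho_exp2"])),
                )
            )
    return net, net.main_component()
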