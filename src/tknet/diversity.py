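"""Alpha and beta diversity: Shannon index, observed features, Bray-Curtis
dissimilarity, principal-coordinates analysis, and ANOSIM.

ANOSIM follows Clarke's formulation: R = (mean rank of between-group
dissimilarities - mean rank of within-group dissimilarities) / (M/2), ranks
taken over all M = n(n-1)/2 dissimilarities with ties averaged, and the
p-value estimated from seeded label permutations with the add-one estimator
(1 + #{R_perm >= R_obs}) / (n_perm + 1).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis, pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "shannon_index",
    "observed_features",
    "bray_curtis",
    "distance_matrix",
    "alpha_diversity_table",
    "pcoa",
    "anosim",
]


def shannon_index(abundances, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over nonzero proportions.

    Natural log by default; pass ``base`` for another logarithm base.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot compute Shannon index of an all-zero sample")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def observed_features(abundances) -> int:
    """Number of strictly positive entries (observed richness)."""
    x = np.asarray(abundances, dtype=float)
    return int((x > 0).sum())


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    if x.sum() + y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_braycurtis(x, y))


def distance_matrix(t, metric: str = "braycurtis") -> pd.DataFrame:
    """Pairwise sample dissimilarity matrix of a count table (samples are
    columns of ``t``)."""
    x = t.values().T
    d = squareform(pdist(x, metric=metric))
    return pd.DataFrame(d, index=t.sample_ids, columns=t.sample_ids)


def alpha_diversity_table(t, base: float | None = None) -> pd.DataFrame:
    """Per-sample Shannon index and observed-feature count."""
    rows = {
        s: {
            "shannon": shannon_index(t.data[s].to_numpy(), base=base),
            "observed_features": observed_features(t.data[s].to_numpy()),
        }
        for s in t.sample_ids
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def pcoa(d: pd.DataFrame, n_axes: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical metric scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and keeps the axes with positive
    eigenvalues. Returns (coordinates, fraction of variance per axis); the
    variance fractions are taken over the positive eigenvalues only. Each
    axis's sign is fixed so its largest-magnitude coordinate is positive.
    """
    dm = np.asarray(d, dtype=float)
    n = dm.shape[0]
    if dm.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-10, 1e-10 * abs(evals[0]))
    if not pos.any():
        raise ValueError("no positive eigenvalues; degenerate distance matrix")
    evals_pos = evals[pos]
    coords = evecs[:, pos] * np.sqrt(evals_pos)
    for a in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, a]))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    if n_axes is not None:
        coords = coords[:, :n_axes]
        evals_pos = evals_pos[:n_axes]
    frac = evals_pos / evals[pos].sum()
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(n)
    return pd.DataFrame(coords, index=index, columns=cols), frac


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(
    d: pd.DataFrame,
    labels,
    n_perm: int = 999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """ANOSIM R statistic and permutation p-value.

    ``labels`` gives one group per sample (aligned with the matrix order);
    every group must have at least two members and there must be at least two
    groups.
    """
    dm = np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    n = dm.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than two members")

    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm[iu])
    within_obs = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranks, within_obs)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        within = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, within) >= r_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return r_obs, p
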