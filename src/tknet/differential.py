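"""Cross-experiment differential testing and response-group classification.

Every feature (ASV or host parameter) must change in the same fold-change
direction in both independent experiments before it can be called
significant; consistent features are then tested by a Mann-Whitney U test on
the pooled samples, with Benjamini-Hochberg control across the tested set.
Host parameters use a one-tailed test in the shared fold-change direction at
FDR 0.05; ASVs use a two-tailed test at FDR 0.1.

The response-group classifier assigns each ASV to one of three patterns over
the ND / WD / WD_Ch comparisons: ``reversed`` (shifted by the Western diet
and moved back by cholestyramine), ``treatment_only`` (shifted only under
treatment), or ``diet_only`` (shifted by diet regardless of treatment).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .tables import CountTable, HostTable, SampleMetadata

__all__ = [
    "mann_whitney_u",
    "bh_fdr",
    "fisher_combined",
    "comparison_stats",
    "test_with_consistency",
    "classify_response_groups",
    "family_differential",
    "COMPARISONS",
]

#: standard comparisons, each as (numerator group, reference group)
COMPARISONS = {
    "WDvsND": ("WD", "ND"),
    "ChvsWD": ("WD_Ch", "WD"),
    "ChvsND": ("WD_Ch", "ND"),
}

_ALTERNATIVES = {"two": "two-sided", "greater": "greater", "less": "less"}


def mann_whitney_u(x, y, tail: str = "two") -> tuple[float, float]:
    """Mann-Whitney U test of ``x`` against ``y``.

    U counts pairs with x_i > y_j plus half the ties. The p-value is exact
    (full enumeration) when the combined sample size is at most 20 and there
    are no ties, otherwise the normal approximation with tie and continuity
    corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if tail not in _ALTERNATIVES:
        raise ValueError(f"tail must be one of {sorted(_ALTERNATIVES)}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative=_ALTERNATIVES[tail], method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_combined(pvals) -> float:
    """Fisher's combined probability: X^2 = -2 sum(ln p_i) ~ chi-square(2k)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any():
        raise ValueError("p-values must be in (0, 1]; clip zeros upstream")
    if (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    x2 = -2.0 * np.log(p).sum()
    return float(chi2.sf(x2, 2 * p.size))


def _group_arrays(
    data: pd.DataFrame, meta: SampleMetadata, group: str, experiment: int | None = None
) -> pd.DataFrame:
    cols = [s for s in meta.samples(experiment=experiment, group=group) if s in data.columns]
    if not cols:
        where = f"experiment {experiment}" if experiment is not None else "the data"
        raise ValueError(f"group {group!r} has no samples in {where}")
    return data[cols]


def comparison_stats(
    data: pd.DataFrame,
    meta: SampleMetadata,
    comparison: tuple[str, str],
    tail: str = "two",
) -> pd.DataFrame:
    """Per-feature cross-experiment statistics for one group comparison.

    Computes each experiment's fold-change sign from group means, the
    consistency flag (equal nonzero signs), and the pooled Mann-Whitney U
    and p for consistent features. ``tail='auto'`` tests one-tailed in the
    shared fold-change direction (the host-parameter convention); inconsistent
    features get p = q = NaN and are never significant.
    """
    a, b = comparison
    exps = meta.experiments
    if len(exps) < 2:
        raise ValueError("need at least two experiments")
    signs = {}
    for e in exps:
        ma = _group_arrays(data, meta, a, e).mean(axis=1)
        mb = _group_arrays(data, meta, b, e).mean(axis=1)
        signs[e] = np.sign(ma - mb)
    sign_frame = pd.DataFrame(signs)
    consistent = (sign_frame.nunique(axis=1) == 1) & (sign_frame.iloc[:, 0] != 0)

    xa = _group_arrays(data, meta, a).to_numpy()
    xb = _group_arrays(data, meta, b).to_numpy()
    u = np.full(len(data), np.nan)
    p = np.full(len(data), np.nan)
    cons = consistent.to_numpy()
    shared = sign_frame.iloc[:, 0].to_numpy()
    for i in range(len(data)):
        if not cons[i]:
            continue
        if tail == "auto":
            t = "greater" if shared[i] > 0 else "less"
        else:
            t = tail
        xi = xa[i][~np.isnan(xa[i])]
        yi = xb[i][~np.isnan(xb[i])]
        u[i], p[i] = mann_whitney_u(xi, yi, tail=t)

    out = pd.DataFrame(
        {
            "fc_sign_exp1": sign_frame[exps[0]].astype(int),
            "fc_sign_exp2": sign_frame[exps[1]].astype(int),
            "consistent": consistent,
            "direction": np.where(cons, shared, 0).astype(int),
            "u_statistic": u,
            "p": p,
        },
        index=data.index,
    )
    out["comparison"] = f"{a}vs{b}"
    return out


def test_with_consistency(
    table: CountTable | HostTable,
    meta: SampleMetadata,
    comparison: tuple[str, str] = ("WD_Ch", "WD"),
    tail: str | None = None,
    fdr_level: float | None = None,
) -> pd.DataFrame:
    """Differential records with BH-FDR over the consistent features.

    ASV tables default to a two-tailed test at FDR 0.1; host tables to a
    one-tailed test in the shared fold-change direction at FDR 0.05.
    """
    is_host = isinstance(table, HostTable)
    if tail is None:
        tail = "auto" if is_host else "two"
    if fdr_level is None:
        fdr_level = 0.05 if is_host else 0.1
    stats = comparison_stats(table.data, meta, comparison, tail=tail)
    stats["q"] = np.nan
    tested = stats.index[stats["consistent"]]
    if len(tested):
        stats.loc[tested, "q"] = bh_fdr(stats.loc[tested, "p"].to_numpy())
    stats["significant"] = stats["consistent"] & (stats["q"] < fdr_level)
    return stats


def classify_response_groups(
    stats_wd_nd: pd.DataFrame,
    stats_ch_wd: pd.DataFrame,
    stats_ch_nd: pd.DataFrame,
    p_threshold: float = 0.1,
) -> pd.Series:
    """Three-way response-group labels from the three comparison statistics.

    A comparison counts as significant for a feature when its fold-change
    direction is consistent across experiments and the pooled two-tailed
    p-value is below ``p_threshold``.
    """
    idx = stats_wd_nd.index
    for other, name in ((stats_ch_wd, "ChvsWD"), (stats_ch_nd, "ChvsND")):
        if not idx.equals(other.index):
            raise ValueError(f"comparison {name} covers a different feature set")

    def sig(s: pd.DataFrame) -> pd.Series:
        return s["consistent"] & (s["p"] < p_threshold)

    sig_wn, sig_cw, sig_cn = sig(stats_wd_nd), sig(stats_ch_wd), sig(stats_ch_nd)
    dir_wn = stats_wd_nd["direction"]
    dir_cw = stats_ch_wd["direction"]
    dir_cn = stats_ch_nd["direction"]

    labels = pd.Series("none", index=idx, dtype=object, name="response_group")
    reversed_mask = sig_wn & sig_cw & (dir_cw == -dir_wn)
    treatment_mask = ~sig_wn & sig_cn & sig_cw & (dir_cn == dir_cw)
    diet_mask = sig_wn & sig_cn & (dir_wn == dir_cn) & ~sig_cw
    labels[reversed_mask] = "reversed"
    labels[treatment_mask & (labels == "none")] = "treatment_only"
    labels[diet_mask & (labels == "none")] = "diet_only"
    return labels


def family_differential(
    family_by_exp: dict[int, CountTable],
    meta: SampleMetadata,
    comparison: tuple[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Family-level meta-analysis across experiments.

    Each experiment is tested separately with a two-tailed Mann-Whitney U
    test on relative abundances; families with consistent fold-change
    direction have their per-experiment p-values combined by Fisher's method.
    Families absent from one experiment are skipped with a warning.
    """
    a, b = comparison
    exps = sorted(family_by_exp)
    if len(exps) < 2:
        raise ValueError("need at least two experiments")
    common = set(family_by_exp[exps[0]].feature_ids)
    universe = set()
    for e in exps:
        ids = set(family_by_exp[e].feature_ids)
        universe |= ids
        common &= ids
    skipped = universe - common
    if skipped:
        warnings.warn(f"skipping {len(skipped)} family(ies) absent from an experiment", stacklevel=2)

    rows = []
    for fam in sorted(common):
        per_p, per_sign = [], []
        for e in exps:
            data = family_by_exp[e].data
            xa = _group_arrays(data, meta, a, e).loc[fam].to_numpy()
            xb = _group_arrays(data, meta, b, e).loc[fam].to_numpy()
            _, p = mann_whitney_u(xa, xb, tail="two")
            per_p.append(p)
            per_sign.append(np.sign(xa.mean() - xb.mean()))
        consistent = len(set(per_sign)) == 1 and per_sign[0] != 0
        combined = fisher_combined(np.clip(per_p, 1e-300, 1.0)) if consistent else np.nan
        rows.append(
            {
                "family": fam,
                "p_exp1": per_p[0],
                "p_exp2": per_p[1],
                "fc_sign_exp1": int(per_sign[0]),
                "fc_sign_exp2": int(per_sign[1]),
                "consistent": consistent,
                "combined_p": combined,
                "significant": bool(consistent and all(p < alpha for p in per_p)),
            }
        )
    return pd.DataFrame(rows).set_index("family")
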