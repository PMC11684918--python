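"""Normalization and filtering chain for ASV and host tables.

The ASV path is fixed by the scale tags: raw counts are relativized per
million within each experiment, filtered to the minimal set of high-abundance
features covering 99.95% of cumulative abundance, intersected across
experiments, and quantile normalized. A second, heatmap-oriented path takes
raw counts to per-sample relative abundances divided by each feature's mean.
Host parameters are median-normalized per experiment so the two experiments
can be pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CountTable, HostTable, SampleMetadata, Scale

__all__ = [
    "NormalizationTrace",
    "relativize_per_million",
    "cumulative_abundance_filter",
    "intersect_common_features",
    "quantile_normalize",
    "relativize_and_mean_normalize",
    "median_normalize_host",
    "aggregate_to_family",
    "normalize_asv_pair",
]

MILLION = 1_000_000.0


@dataclass
class NormalizationTrace:
    """Ordered provenance of preprocessing steps."""

    steps: list[dict] = field(default_factory=list)

    def record(self, operation: str, params: dict, features_in: int, features_out: int) -> None:
        self.steps.append(
            {
                "operation": operation,
                "params": params,
                "features_in": features_in,
                "features_out": features_out,
            }
        )

    def to_list(self) -> list[dict]:
        return list(self.steps)


def relativize_per_million(t: CountTable, trace: NormalizationTrace | None = None) -> CountTable:
    """Scale each sample to a total of one million."""
    if t.scale is not Scale.raw_counts:
        raise ValueError(f"relativize_per_million expects raw counts, got scale={t.scale.value}")
    totals = t.data.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total count")
    out = t.data.div(totals, axis=1) * MILLION
    if trace is not None:
        trace.record("relativize_per_million", {}, t.shape[0], t.shape[0])
    return t.with_data(out, Scale.per_million)


def cumulative_abundance_filter(
    t: CountTable, threshold: float = 0.9995, trace: NormalizationTrace | None = None
) -> tuple[CountTable, list[str]]:
    """Keep the minimal prefix of features, ranked by total abundance across
    all samples (descending, ties by feature id), whose cumulative share of
    total abundance reaches ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if t.shape[0] == 0:
        raise ValueError("empty table")
    totals = t.data.sum(axis=1)
    grand = float(totals.sum())
    if grand <= 0:
        raise ValueError("table has zero total abundance")
    order = sorted(totals.index, key=lambda f: (-totals[f], f))
    cum = 0.0
    kept: list[str] = []
    for f in order:
        kept.append(f)
        cum += float(totals[f])
        if cum / grand >= threshold - 1e-12:
            break
    filtered = t.subset_features(kept)
    if trace is not None:
        trace.record("cumulative_abundance_filter", {"threshold": threshold}, t.shape[0], len(kept))
    return filtered, kept


def intersect_common_features(kept_exp1: list[str], kept_exp2: list[str]) -> list[str]:
    """Features passing the abundance filter in both experiments, ordered by
    the experiment-1 ranking. Empty intersections warn rather than fail."""
    s2 = set(kept_exp2)
    common = [f for f in kept_exp1 if f in s2]
    if not common:
        warnings.warn("no features are common to both experiments", stacklevel=2)
    return common


def quantile_normalize(t: CountTable, trace: NormalizationTrace | None = None) -> CountTable:
    """Classical quantile normalization: every sample is mapped onto the
    cross-sample mean of order statistics; tied values within a sample get
    the mean of the reference values at the tied positions."""
    if t.scale is not Scale.per_million:
        raise ValueError(f"quantile_normalize expects per-million scale, got {t.scale.value}")
    x = t.values()
    n_feat, n_samp = x.shape
    if n_samp <= 1:
        out = t.data.copy()
    else:
        reference = np.sort(x, axis=0).mean(axis=1)
        qn = np.empty_like(x)
        for j in range(n_samp):
            col = x[:, j]
            order = np.argsort(col, kind="stable")
            assigned = reference.copy()
            sorted_vals = col[order]
            # average reference values over runs of tied observations
            start = 0
            for end in range(1, n_feat + 1):
                if end == n_feat or sorted_vals[end] != sorted_vals[start]:
                    if end - start > 1:
                        assigned[start:end] = reference[start:end].mean()
                    start = end
            qn[order, j] = assigned
        out = pd.DataFrame(qn, index=t.data.index, columns=t.data.columns)
    if trace is not None:
        trace.record("quantile_normalize", {}, n_feat, n_feat)
    return t.with_data(out, Scale.quantile_normalized)


def relativize_and_mean_normalize(t: CountTable, trace: NormalizationTrace | None = None) -> CountTable:
    """Heatmap preprocessing: per-sample relative proportions, then each
    feature divided by its mean across all samples (zero-mean features are
    set to zero with a warning)."""
    if t.scale is not Scale.raw_counts:
        raise ValueError(f"expected raw counts, got scale={t.scale.value}")
    totals = t.data.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total count")
    rel = t.data.div(totals, axis=1)
    means = rel.mean(axis=1)
    zero_rows = means.index[means == 0]
    if len(zero_rows):
        warnings.warn(f"{len(zero_rows)} feature(s) with zero mean set to 0", stacklevel=2)
    safe = means.replace(0.0, np.nan)
    out = rel.div(safe, axis=0).fillna(0.0)
    if trace is not None:
        trace.record("relativize_and_mean_normalize", {}, t.shape[0], t.shape[0])
    return t.with_data(out, Scale.mean_normalized)


def median_normalize_host(h: HostTable, meta: SampleMetadata) -> HostTable:
    """Divide each parameter by its within-experiment median so experiments
    become poolable; requires strictly positive medians."""
    if h.normalized:
        raise ValueError("host table is already median-normalized")
    out = h.data.copy()
    for exp in meta.experiments:
        cols = [s for s in meta.samples(experiment=exp) if s in out.columns]
        if not cols:
            continue
        med = out[cols].median(axis=1, skipna=True)
        bad = med.index[(med <= 0) | med.isna()]
        if len(bad):
            raise ValueError(f"parameter {bad[0]!r} has non-positive median in experiment {exp}")
        out[cols] = out[cols].div(med, axis=0)
    return HostTable(out, h.info.copy(), normalized=True)


def aggregate_to_family(t: CountTable, tax, rank: str = "family") -> CountTable:
    """Sum feature rows by taxonomic label at ``rank``; features without an
    assignment are pooled into ``"Unassigned"``. Column sums are preserved."""
    labels = [tax.rank_label(f, rank) for f in t.feature_ids]
    out = t.data.groupby(pd.Index(labels, name=rank)).sum()
    return CountTable(out, scale=t.scale)


def normalize_asv_pair(
    counts_by_exp: dict[int, CountTable],
    threshold: float = 0.9995,
    trace: NormalizationTrace | None = None,
) -> tuple[dict[int, CountTable], list[str]]:
    """Run the full ASV chain on each experiment: per-million relativization,
    cumulative-abundance filtering, cross-experiment intersection, quantile
    normalization. Returns the per-experiment quantile-normalized tables
    (restricted to the common features) and the common feature list."""
    exps = sorted(counts_by_exp)
    if len(exps) < 2:
        raise ValueError("need at least two experiments")
    rel = {e: relativize_per_million(counts_by_exp[e], trace) for e in exps}
    kept: dict[int, list[str]] = {}
    for e in exps:
        _, kept[e] = cumulative_abundance_filter(rel[e], threshold, trace)
    common = kept[exps[0]]
    for e in exps[1:]:
        common = intersect_common_features(common, kept[e])
    out = {e: quantile_normalize(rel[e].subset_features(common), trace) for e in exps}
    return out, common
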