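"""Core data containers and TSV readers/writers.

All tabular data is exchanged as UTF-8 tab-separated text. Feature tables
(microbial counts, host parameters) are stored features x samples; sample
metadata is one row per sample. Count tables carry a ``scale`` tag recording
which normalisation has been applied, and the preprocessing operations refuse
inputs on the wrong scale, so the pipeline order cannot silently be violated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Scale",
    "SampleMetadata",
    "CountTable",
    "TaxonomyTable",
    "HostTable",
    "TableFormatError",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


class TableFormatError(ValueError):
    """Raised when an input table violates the expected layout."""


class Group(str, enum.Enum):
    """Experimental groups: normal diet, Western diet, WD + cholestyramine."""

    ND = "ND"
    WD = "WD"
    WD_Ch = "WD_Ch"


#: accepted free-text spellings for each group label
DEFAULT_GROUP_ALIASES: Mapping[str, str] = {
    "ND": "ND",
    "WD": "WD",
    "WD_CH": "WD_Ch",
    "WD+CH": "WD_Ch",
    "WDCH": "WD_Ch",
    "WD_CHOL": "WD_Ch",
    "WD+CHOL": "WD_Ch",
}


class Scale(str, enum.Enum):
    """Normalisation state of a :class:`CountTable`."""

    raw_counts = "raw_counts"
    per_million = "per_million"
    quantile_normalized = "quantile_normalized"
    per_sample_relative = "per_sample_relative"
    mean_normalized = "mean_normalized"


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise TableFormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations: experiment (1 or 2) and treatment group."""

    frame: pd.DataFrame  # index sample_id; columns: experiment (int), group (str)

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "sample")
        bad = set(self.frame["group"]) - {g.value for g in Group}
        if bad:
            raise TableFormatError(f"unknown group labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def experiments(self) -> list[int]:
        return sorted(self.frame["experiment"].unique())

    def samples(self, experiment: int | None = None, group: str | Group | None = None) -> list[str]:
        """Sample ids matching the given experiment and/or group."""
        sel = pd.Series(True, index=self.frame.index)
        if experiment is not None:
            sel &= self.frame["experiment"] == experiment
        if group is not None:
            sel &= self.frame["group"] == (group.value if isinstance(group, Group) else group)
        return list(self.frame.index[sel])

    @classmethod
    def read_tsv(cls, path: str | Path, group_aliases: Mapping[str, str] | None = None) -> "SampleMetadata":
        df = _read_tsv(path)
        required = {"experiment", "group"}
        if not required <= set(df.columns):
            raise TableFormatError(
                f"{path}: metadata needs columns {sorted(required)}, got {list(df.columns)}"
            )
        aliases = dict(DEFAULT_GROUP_ALIASES)
        if group_aliases:
            aliases.update({k.upper(): v for k, v in group_aliases.items()})
        df = df.copy()
        df["group"] = [aliases.get(str(g).upper(), str(g)) for g in df["group"]]
        df["experiment"] = df["experiment"].astype(int)
        return cls(df[["experiment", "group"]])

    def write_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class CountTable:
    """Feature x sample abundance matrix with a normalisation-scale tag."""

    data: pd.DataFrame  # index feature_id, columns sample_id, float values
    scale: Scale = Scale.raw_counts

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "feature")
        _check_unique(self.data.columns, "sample")
        if self.data.isna().any().any():
            raise TableFormatError("count table contains missing values")
        if (self.data.to_numpy() < 0).any():
            raise TableFormatError("count table contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, scale: Scale) -> "CountTable":
        return CountTable(data=data, scale=scale)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        ids = [s for s in sample_ids if s in self.data.columns]
        return replace(self, data=self.data[ids])

    def subset_features(self, feature_ids: Iterable[str]) -> "CountTable":
        ids = list(feature_ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise KeyError(f"features not in table: {sorted(missing)}")
        return replace(self, data=self.data.loc[ids])

    @classmethod
    def read_tsv(cls, path: str | Path, scale: Scale = Scale.raw_counts) -> "CountTable":
        df = _read_tsv(path)
        try:
            df = df.astype(float)
        except ValueError as exc:
            loc = _locate_non_numeric(df)
            raise TableFormatError(f"{path}: non-numeric cell at {loc}") from exc
        return cls(df, scale=scale)

    def write_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class TaxonomyTable:
    """Feature id -> ordered lineage (kingdom..genus, possibly truncated)."""

    frame: pd.DataFrame  # index feature_id, columns a prefix of RANKS

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "feature")

    def lineage(self, feature_id: str) -> tuple[str, ...]:
        row = self.frame.loc[feature_id]
        return tuple(str(v) for v in row if isinstance(v, str) and v)

    def rank_label(self, feature_id: str, rank: str = "family") -> str:
        """Taxon at ``rank`` for a feature, or ``"Unassigned"``."""
        if feature_id not in self.frame.index or rank not in self.frame.columns:
            return "Unassigned"
        val = self.frame.at[feature_id, rank]
        return str(val) if isinstance(val, str) and val else "Unassigned"

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxonomyTable":
        df = _read_tsv(path, numeric=False)
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class HostTable:
    """Host parameters (metabolic phenotypes and gene expression) per sample.

    Values live on the natural (strictly positive) measurement scale; missing
    measurements are allowed and encoded as NaN, and are dropped pairwise in
    correlations.
    """

    data: pd.DataFrame  # index parameter_id, columns sample_id
    info: pd.DataFrame  # index parameter_id; columns: kind {phenotype, gene}, tissue (str or "")
    normalized: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "parameter")
        if not self.data.index.equals(self.info.index):
            raise TableFormatError("host value and info tables disagree on parameter ids")
        bad = set(self.info["kind"]) - {"phenotype", "gene"}
        if bad:
            raise TableFormatError(f"unknown host parameter kinds: {sorted(bad)}")

    @property
    def parameter_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def kind(self, parameter_id: str) -> str:
        return str(self.info.at[parameter_id, "kind"])

    def subset_samples(self, sample_ids: Iterable[str]) -> "HostTable":
        ids = [s for s in sample_ids if s in self.data.columns]
        return replace(self, data=self.data[ids])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "HostTable":
        df = _read_tsv(path, numeric=False)
        meta_cols = [c for c in ("kind", "tissue") if c in df.columns]
        if "kind" not in meta_cols:
            raise TableFormatError(f"{path}: host table needs a 'kind' column")
        info = df[meta_cols].copy()
        if "tissue" not in info.columns:
            info["tissue"] = ""
        info["tissue"] = info["tissue"].fillna("")
        vals = df.drop(columns=meta_cols)
        try:
            vals = vals.astype(float)
        except ValueError as exc:
            raise TableFormatError(f"{path}: non-numeric host value: {exc}") from exc
        return cls(vals, info[["kind", "tissue"]])

    def write_tsv(self, path: str | Path) -> None:
        out = pd.concat([self.info, self.data], axis=1)
        out.index.name = "parameter_id"
        out.to_csv(path, sep="\t")


def _read_tsv(path: str | Path, numeric: bool = True) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise TableFormatError(f"{path}: no data rows")
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise TableFormatError(f"{path}: duplicate id {dup[0]!r}")
    dupc = df.columns[df.columns.duplicated()]
    if len(dupc):
        raise TableFormatError(f"{path}: duplicate column {dupc[0]!r}")
    return df


def _locate_non_numeric(df: pd.DataFrame) -> str:
    for j, col in enumerate(df.columns):
        for i, v in enumerate(df[col]):
            try:
                float(v)
            except (TypeError, ValueError):
                return f"row {df.index[i]!r}, column {col!r} (value {v!r})"
    return "unknown position"
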