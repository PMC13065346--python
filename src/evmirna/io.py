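"""Reading and writing of count matrices, metadata and annotation tables.

Count files are tab-separated text: one header row of sample IDs, first
column header ``miRNA``, integer counts. Metadata is a two-column table
(sample, group). Annotations are two columns (feature, chromosome location).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, MetadataError

FEATURE_COLUMN = "miRNA"

_ARM_SUFFIXES = ("-5p", "-3p")


def normalize_feature_id(name: str) -> str:
    """Trim whitespace and lower-case the species prefix (``hsa-``).

    miRBase IDs are otherwise case-sensitive (``hsa-miR-21-5p`` vs
    ``hsa-let-7a-5p``), so only the prefix is normalized.
    """
    name = name.strip()
    head, sep, tail = name.partition("-")
    if sep and head.isalpha() and len(head) <= 4:
        return head.lower() + sep + tail
    return name


def has_arm_suffix(name: str) -> bool:
    return name.endswith(_ARM_SUFFIXES)


def strip_arm_suffix(name: str) -> str:
    return name[:-3] if has_arm_suffix(name) else name


@dataclass
class CountMatrix:
    """Integer feature-by-sample counts plus a sample-to-group mapping."""

    counts: pd.DataFrame  # features x samples, int64
    groups: pd.Series  # index: sample IDs, values: group labels

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise DataFormatError(f"duplicate feature IDs: {list(dupes)[:5]}")
        if self.counts.columns.has_duplicates:
            raise DataFormatError("duplicate sample IDs in count matrix")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise DataFormatError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise DataFormatError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise MetadataError(f"samples missing from metadata: {missing}")
        self.groups = self.groups.loc[self.counts.columns]

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def group_names(self) -> list[str]:
        """Group labels in first-appearance (sample) order."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def write(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = FEATURE_COLUMN
        out.to_csv(path, sep="\t")


@dataclass
class RawCountFile:
    """A count file from one alignment pipeline, before harmonization."""

    path: str
    counts: pd.DataFrame  # features x samples, int64
    locations: pd.Series | None = field(default=None)  # feature -> chrom location

    def __post_init__(self) -> None:
        if self.counts.columns.has_duplicates:
            raise DataFormatError(f"{self.path}: duplicate sample IDs")
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise DataFormatError(f"{self.path}: duplicate feature IDs: {list(dupes)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise DataFormatError(f"{self.path}: negative counts")


def _read_count_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"count file not found: {path}")
    if path.stat().st_size == 0:
        raise DataFormatError(f"empty count file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise DataFormatError(f"{path}: no sample columns")
    df.index = pd.Index([normalize_feature_id(str(f)) for f in df.index], name=FEATURE_COLUMN)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise DataFormatError(f"{path}: duplicate feature IDs: {list(dupes)[:5]}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()][0]
            raise DataFormatError(f"{path}: non-numeric count for {bad!r} in sample {col!r}")
        if not np.allclose(vals, np.round(vals)):
            raise DataFormatError(f"{path}: non-integer counts in sample {col!r}")
        if (vals < 0).any():
            raise DataFormatError(f"{path}: negative counts in sample {col!r}")
    return df.astype(np.int64)


def read_metadata(path: str | Path) -> pd.Series:
    """Read a (sample, group) table; returns sample -> group."""
    path = Path(path)
    if not path.exists():
        raise MetadataError(f"metadata file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise MetadataError(f"{path}: expected at least two columns (sample, group)")
    sample_col, group_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        raise MetadataError(f"{path}: duplicate sample IDs")
    return pd.Series(df[group_col].values, index=df[sample_col].values, name="group")


def read_annotations(path: str | Path) -> pd.Series:
    """Read a (feature, chromosome location) table; returns feature -> location."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: expected two columns (feature, location)")
    feats = [normalize_feature_id(f) for f in df.iloc[:, 0]]
    return pd.Series(df.iloc[:, 1].values, index=feats, name="location")


def read_counts(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a count file plus metadata into a validated :class:`CountMatrix`."""
    df = _read_count_table(path)
    groups = read_metadata(metadata_path)
    return CountMatrix(df, groups)


def read_raw_counts(path: str | Path, annotation_path: str | Path | None = None) -> RawCountFile:
    """Read one pipeline dialect file (no metadata required yet)."""
    df = _read_count_table(path)
    locations = read_annotations(annotation_path) if annotation_path else None
    return RawCountFile(str(path), df, locations)


def make_count_matrix(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series | Sequence[str],
) -> CountMatrix:
    """Build a CountMatrix from an in-memory frame and per-sample groups."""
    if isinstance(groups, pd.Series):
        g = groups
    elif isinstance(groups, Mapping):
        g = pd.Series(dict(groups))
    else:
        g = pd.Series(list(groups), index=counts.columns)
    return CountMatrix(counts, g)
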