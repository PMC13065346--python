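"""Detection-set partitioning across groups and per-group abundance ranking."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import CountMatrix

DETECTION_RULES = ("any_replicate_nonzero", "all_replicates_nonzero", "min_total")


def detection_flags(
    matrix: CountMatrix, rule: str = "any_replicate_nonzero", min_total: int = 1
) -> pd.DataFrame:
    """Boolean features x groups table: is the feature detected in the group?

    Rules: ``any_replicate_nonzero`` (default), ``all_replicates_nonzero``,
    ``min_total`` (group total count >= ``min_total``).
    """
    if rule not in DETECTION_RULES:
        raise ConfigurationError(f"unknown detection rule {rule!r}; choose from {DETECTION_RULES}")
    flags = {}
    for g in matrix.group_names:
        sub = matrix.counts[matrix.samples_of(g)]
        if rule == "any_replicate_nonzero":
            flags[g] = (sub > 0).any(axis=1)
        elif rule == "all_replicates_nonzero":
            flags[g] = (sub > 0).all(axis=1)
        else:
            flags[g] = sub.sum(axis=1) >= min_total
    return pd.DataFrame(flags)


@dataclass
class DetectionPartition:
    """Assignment of each detected feature to its exact subset of groups."""

    rule: str
    group_names: list[str]
    cells: dict[tuple[str, ...], list[str]]  # subset (canonical order) -> features

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def cell(self, *groups: str) -> list[str]:
        key = tuple(g for g in self.group_names if g in set(groups))
        return self.cells.get(key, [])

    def group_total(self, group: str) -> int:
        """Number of features detected in ``group`` (any cell containing it)."""
        return sum(len(v) for key, v in self.cells.items() if group in key)

    def exclusive(self, group: str) -> list[str]:
        return self.cells.get((group,), [])

    def summary(self) -> dict:
        return {
            "rule": self.rule,
            "union_size": self.union_size,
            "group_totals": {g: self.group_total(g) for g in self.group_names},
            "exclusive": {g: len(self.exclusive(g)) for g in self.group_names},
            "cells": {"+".join(k): sorted(v) for k, v in sorted(self.cells.items())},
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def detect_partition(
    matrix: CountMatrix, rule: str = "any_replicate_nonzero", min_total: int = 1
) -> DetectionPartition:
    """Partition detected features into the cells of the multi-group Venn."""
    flags = detection_flags(matrix, rule, min_total)
    groups = matrix.group_names
    cells: dict[tuple[str, ...], list[str]] = {}
    arr = flags.to_numpy()
    for i, feat in enumerate(flags.index):
        members = tuple(g for g, on in zip(groups, arr[i]) if on)
        if not members:
            continue
        cells.setdefault(members, []).append(feat)
    label = rule if rule != "min_total" else f"min_total>={min_total}"
    return DetectionPartition(rule=label, group_names=list(groups), cells=cells)


@dataclass
class AbundanceRanking:
    """Per-group top-k features by mean CPM, with cross-group flags."""

    k: int
    tables: dict[str, pd.DataFrame]  # group -> (feature, mean_cpm, sd_cpm) sorted
    common_abundant: set[str] = field(default_factory=set)  # top-k in every group
    uniquely_abundant: dict[str, set[str]] = field(default_factory=dict)  # group -> features

    def top_features(self, group: str) -> list[str]:
        return list(self.tables[group]["feature"])

    def is_abundant(self, feature: str, group: str) -> bool:
        return feature in set(self.tables[group]["feature"])


def rank_abundance(
    cpm_matrix: pd.DataFrame, groups: pd.Series, k: int = 20
) -> AbundanceRanking:
    """Rank features by mean CPM within each group.

    Ties break lexicographically by feature ID (smaller ID first), making
    rankings deterministic. ``common_abundant`` features sit in every group's
    top-k; ``uniquely_abundant`` features sit in exactly one group's.
    """
    if k <= 0:
        raise ConfigurationError("k must be a positive integer")
    order: dict[str, None] = {}
    for g in groups:
        order.setdefault(g, None)
    group_names = list(order)

    tables: dict[str, pd.DataFrame] = {}
    for g in group_names:
        samples = [s for s in cpm_matrix.columns if groups[s] == g]
        sub = cpm_matrix[samples]
        stats = pd.DataFrame(
            {
                "feature": cpm_matrix.index,
                "mean_cpm": sub.mean(axis=1).to_numpy(),
                "sd_cpm": sub.std(axis=1, ddof=1).to_numpy() if len(samples) > 1 else np.nan,
            }
        )
        stats = stats[stats["mean_cpm"] > 0]
        stats = stats.sort_values(
            by=["mean_cpm", "feature"], ascending=[False, True], kind="mergesort"
        ).head(k)
        tables[g] = stats.reset_index(drop=True)

    membership = {g: set(t["feature"]) for g, t in tables.items()}
    every = set.intersection(*membership.values()) if membership else set()
    unique: dict[str, set[str]] = {}
    for g in group_names:
        others = set().union(*(membership[h] for h in group_names if h != g)) if len(group_names) > 1 else set()
        unique[g] = membership[g] - others
    return AbundanceRanking(k=k, tables=tables, common_abundant=every, uniquely_abundant=unique)
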