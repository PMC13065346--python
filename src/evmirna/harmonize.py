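"""Merge count files from two alignment pipelines into one matrix.

Rules: features absent from one file but counted in the other are zero-filled
on the missing side; a feature lacking its -3p/-5p arm suffix in the primary
file is renamed to the arm that is the sole expressed form in the reference
file, provided chromosome annotations do not conflict; otherwise it is logged
as unresolved and excluded. Harmonization never alters a numeric count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MetadataError
from .io import CountMatrix, RawCountFile, has_arm_suffix, make_count_matrix


@dataclass
class HarmonizationLog:
    """Audit trail of renames, zero-fills and exclusions."""

    zero_filled_primary: list[str] = field(default_factory=list)
    zero_filled_reference: list[str] = field(default_factory=list)
    renamed: list[dict] = field(default_factory=list)  # {old, new, evidence}
    unresolved: list[dict] = field(default_factory=list)  # {feature, reason}

    def to_dict(self) -> dict:
        return {
            "zero_filled_primary": self.zero_filled_primary,
            "zero_filled_reference": self.zero_filled_reference,
            "renamed": self.renamed,
            "unresolved": self.unresolved,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _location(locations: pd.Series | None, feature: str) -> str | None:
    if locations is None or feature not in locations.index:
        return None
    val = locations[feature]
    return None if pd.isna(val) else str(val)


def _resolve_armless(
    feature: str,
    reference: RawCountFile,
    primary_locations: pd.Series | None,
    log: HarmonizationLog,
) -> str | None:
    """Return the resolved arm name for an arm-less feature, or None."""
    candidates = [
        arm
        for arm in (feature + "-5p", feature + "-3p")
        if arm in reference.counts.index and reference.counts.loc[arm].sum() > 0
    ]
    if len(candidates) != 1:
        reason = "no expressed arm in reference" if not candidates else "both arms expressed in reference"
        log.unresolved.append({"feature": feature, "reason": reason})
        return None
    arm = candidates[0]
    loc_primary = _location(primary_locations, feature)
    loc_arm = _location(reference.locations, arm)
    if loc_primary is not None and loc_arm is not None and loc_primary != loc_arm:
        log.unresolved.append(
            {"feature": feature, "reason": f"chromosome mismatch: {loc_primary} vs {loc_arm}"}
        )
        return None
    evidence = "sole-expressed-arm"
    if loc_primary is not None and loc_arm is not None:
        evidence += "+chromosome-match"
    log.renamed.append({"old": feature, "new": arm, "evidence": evidence})
    return arm


def harmonize_counts(
    primary: RawCountFile,
    reference: RawCountFile,
    groups: pd.Series | None = None,
) -> tuple[CountMatrix, HarmonizationLog]:
    """Merge two pipeline dialect files into a rectangular count matrix.

    ``primary`` may carry arm-stripped feature names; ``reference`` is the
    pipeline whose expressed arms and chromosome annotations decide renames.
    ``groups`` maps every sample in either file to its group label; when
    omitted, each sample is placed in its own group.
    """
    log = HarmonizationLog()

    overlap = set(primary.counts.columns) & set(reference.counts.columns)
    if overlap:
        raise MetadataError(f"sample IDs present in both files: {sorted(overlap)[:5]}")

    pri = primary.counts.copy()
    rename_map: dict[str, str] = {}
    for feat in pri.index:
        if has_arm_suffix(feat):
            continue
        arm = _resolve_armless(feat, reference, primary.locations, log)
        if arm is not None and arm not in pri.index:
            rename_map[feat] = arm
    unresolved_names = {u["feature"] for u in log.unresolved}
    # arm-less features that resolved to a name already present in the primary
    # file cannot be merged without double counting; treat as unresolved
    for feat in list(pri.index):
        if has_arm_suffix(feat) or feat in rename_map or feat in unresolved_names:
            continue
        log.unresolved.append({"feature": feat, "reason": "resolved arm already present in primary"})
        log.renamed = [r for r in log.renamed if r["old"] != feat]
        unresolved_names.add(feat)
    pri = pri.drop(index=[f for f in unresolved_names if f in pri.index])
    pri = pri.rename(index=rename_map)

    ref = reference.counts
    union = list(pri.index) + [f for f in ref.index if f not in set(pri.index)]
    merged = pd.DataFrame(0, index=pd.Index(union, name="miRNA"), columns=list(pri.columns) + list(ref.columns), dtype=np.int64)
    merged.loc[pri.index, pri.columns] = pri
    merged.loc[ref.index, ref.columns] = ref.to_numpy()

    pri_set = set(pri.index)
    ref_set = set(ref.index)
    log.zero_filled_primary = sorted(f for f in union if f not in pri_set)
    log.zero_filled_reference = sorted(f for f in union if f not in ref_set)

    if groups is None:
        groups = pd.Series({s: s for s in merged.columns})
    missing = [s for s in merged.columns if s not in groups.index]
    if missing:
        raise MetadataError(f"samples missing from metadata: {missing}")
    matrix = make_count_matrix(merged, groups.loc[merged.columns])
    return matrix, log
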