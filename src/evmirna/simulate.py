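"""Synthetic negative-binomial count matrices with known ground truth.

Emulates a 4-subtype EV small-RNA design (CM, CF, HCMVEC, Mac with 3/3/3/4
replicates by default): feature-specific log-scale baselines and NB
dispersions, heterogeneous library sizes, optional single-group effects,
structural zeros, and two pipeline file dialects for harmonization tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .io import (
    CountMatrix,
    RawCountFile,
    has_arm_suffix,
    make_count_matrix,
    strip_arm_suffix,
)

DEFAULT_GROUPS = ("CM", "CF", "HCMVEC", "Mac")
DEFAULT_SIZES = (3, 3, 3, 4)


@dataclass
class SimConfig:
    """Parameters of the count simulator.

    The NB parameterization is variance = mu + alpha * mu**2, matching the
    differential-expression module. Each differentially expressed feature
    receives a signed log2 effect in exactly one group.
    """

    n_features: int = 500
    group_names: tuple[str, ...] = DEFAULT_GROUPS
    group_sizes: tuple[int, ...] = DEFAULT_SIZES
    baseline_logmean_range: tuple[float, float] = (float(np.log(5.0)), float(np.log(2000.0)))
    dispersion_range: tuple[float, float] = (0.05, 0.6)
    de_fraction: float = 0.0
    effect_log2fc: float = 2.0
    structural_zero_fraction: float = 0.0
    libsize_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0
    both_arm_fraction: float = 0.2  # hairpins emitting both -5p and -3p arms

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ConfigurationError("n_features must be positive")
        if len(self.group_names) != len(self.group_sizes):
            raise ConfigurationError("group_names and group_sizes must have equal length")
        if len(self.group_names) < 1:
            raise ConfigurationError("at least one group required")
        if any(n <= 0 for n in self.group_sizes):
            raise ConfigurationError("group_sizes must be positive")
        for name, rng in (
            ("baseline_logmean_range", self.baseline_logmean_range),
            ("dispersion_range", self.dispersion_range),
            ("libsize_range", self.libsize_range),
        ):
            lo, hi = rng
            if lo > hi:
                raise ConfigurationError(f"{name}: lower bound exceeds upper bound")
        for name, frac in (
            ("de_fraction", self.de_fraction),
            ("structural_zero_fraction", self.structural_zero_fraction),
            ("both_arm_fraction", self.both_arm_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.dispersion_range[0] < 0:
            raise ConfigurationError("dispersion must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = [float(v) if isinstance(v, float) else v for v in val]
            elif isinstance(val, float):
                data[key] = float(val)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in (
            "group_names",
            "group_sizes",
            "baseline_logmean_range",
            "dispersion_range",
            "libsize_range",
        ):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class TruthTable:
    """Ground truth for a simulated matrix."""

    effects: pd.DataFrame  # feature, group, log2fc
    structural_zeros: pd.DataFrame  # feature, zero_groups (comma-joined)
    baselines: pd.Series = field(repr=False, default=None)  # natural-log feature means
    dispersions: pd.Series = field(repr=False, default=None)
    libsizes: pd.Series = field(repr=False, default=None)

    def write(self, path: str | Path) -> None:
        self.effects.to_csv(path, sep="\t", index=False)


def _feature_names(n: int, both_arm_fraction: float, rng: np.random.Generator) -> list[str]:
    """miRBase-style names; some hairpins contribute both arms."""
    names: list[str] = []
    hairpin = 0
    while len(names) < n:
        hairpin += 1
        base = f"hsa-miR-{1000 + hairpin}"
        if rng.random() < both_arm_fraction and len(names) + 2 <= n:
            names.append(base + "-5p")
            names.append(base + "-3p")
        else:
            arm = "-5p" if rng.random() < 0.7 else "-3p"
            names.append(base + arm)
    return names


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB with variance = mean + alpha * mean**2 (Poisson when alpha == 0)."""
    out = np.zeros_like(mean, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        a = alpha[~pois]
        mu = mean[~pois]
        size = 1.0 / a
        p = size / (size + mu)
        out[~pois] = rng.negative_binomial(size, p)
    return out


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, TruthTable]:
    """Draw an integer count matrix plus its ground-truth table.

    Counts for feature i, sample j are NB with mean
    ``libsize_j * exp(baseline_i) * 2**effect`` where the effect applies only
    in the affected group. Structural-zero cells are exactly zero. The same
    config (including seed) yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    groups = list(config.group_names)
    sizes = list(config.group_sizes)

    features = _feature_names(n, config.both_arm_fraction, rng)
    sample_ids: list[str] = []
    sample_groups: list[str] = []
    for g, k in zip(groups, sizes):
        for r in range(1, k + 1):
            sample_ids.append(f"{g}_{r}")
            sample_groups.append(g)
    n_samples = len(sample_ids)

    lo, hi = config.baseline_logmean_range
    baselines = rng.uniform(lo, hi, size=n)
    alo, ahi = config.dispersion_range
    alphas = rng.uniform(alo, ahi, size=n)
    llo, lhi = config.libsize_range
    libsizes = rng.uniform(llo, lhi, size=n_samples)

    # signed single-group effects
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    de_groups = rng.integers(0, len(groups), size=n_de)
    de_signs = rng.choice([-1.0, 1.0], size=n_de)
    log2fc = np.zeros((n, len(groups)))
    for idx, gi, sign in zip(de_idx, de_groups, de_signs):
        log2fc[idx, gi] = sign * config.effect_log2fc

    # structural zeros: each chosen feature silenced in a strict non-empty subset
    n_zero = int(round(config.structural_zero_fraction * n))
    zero_idx = rng.choice(n, size=n_zero, replace=False) if n_zero else np.array([], dtype=int)
    zero_mask = np.zeros((n, len(groups)), dtype=bool)
    for idx in zero_idx:
        if len(groups) < 2:
            break
        k = int(rng.integers(1, len(groups)))  # 1 .. G-1 groups silenced
        silenced = rng.choice(len(groups), size=k, replace=False)
        zero_mask[idx, silenced] = True

    group_of_sample = np.array([groups.index(g) for g in sample_groups])
    mean = (
        libsizes[None, :]
        * np.exp(baselines)[:, None]
        * np.exp2(log2fc[:, group_of_sample])
    )
    counts = _nb_draw(rng, mean, np.broadcast_to(alphas[:, None], mean.shape).copy())
    counts[zero_mask[:, group_of_sample]] = 0

    counts_df = pd.DataFrame(counts, index=pd.Index(features, name="miRNA"), columns=sample_ids)
    matrix = make_count_matrix(counts_df, pd.Series(sample_groups, index=sample_ids))

    effects = pd.DataFrame(
        {
            "feature": [features[i] for i in de_idx],
            "group": [groups[gi] for gi in de_groups],
            "log2fc": de_signs * config.effect_log2fc,
        }
    )
    zeros = pd.DataFrame(
        {
            "feature": [features[i] for i in zero_idx],
            "zero_groups": [
                ",".join(groups[gi] for gi in np.flatnonzero(zero_mask[i])) for i in zero_idx
            ],
        }
    )
    truth = TruthTable(
        effects=effects,
        structural_zeros=zeros,
        baselines=pd.Series(baselines, index=features),
        dispersions=pd.Series(alphas, index=features),
        libsizes=pd.Series(libsizes, index=sample_ids),
    )
    return matrix, truth


def plant_marker(
    matrix: CountMatrix,
    group: str,
    feature_name: str = "hsa-miR-9999-5p",
    mean_count: float = 3000.0,
    dispersion: float = 0.2,
    seed: int = 0,
) -> CountMatrix:
    """Insert one abundant, group-exclusive NB feature into a matrix.

    The planted feature draws NB counts (variance = mu + alpha*mu^2) in
    ``group`` and is exactly zero everywhere else — a positive control the
    key-miRNA filter should recover for that group.
    """
    if group not in matrix.group_names:
        raise ConfigurationError(f"unknown group {group!r}")
    if feature_name in matrix.features:
        raise ConfigurationError(f"feature {feature_name!r} already present")
    rng = np.random.default_rng(seed)
    row = np.zeros(len(matrix.samples), dtype=np.int64)
    cols = [i for i, s in enumerate(matrix.samples) if s in set(matrix.samples_of(group))]
    mu = np.full(len(cols), mean_count)
    row[cols] = _nb_draw(rng, mu, np.full(len(cols), dispersion))
    counts = pd.concat(
        [
            matrix.counts,
            pd.DataFrame([row], index=pd.Index([feature_name], name="miRNA"), columns=matrix.samples),
        ]
    )
    return make_count_matrix(counts, matrix.groups)


def _hairpin_locations(features: list[str], rng: np.random.Generator) -> dict[str, str]:
    """Deterministic per-hairpin chromosome locations; arms share the locus."""
    locs: dict[str, str] = {}
    for f in features:
        base = strip_arm_suffix(f)
        if base not in locs:
            chrom = int(rng.integers(1, 23))
            start = int(rng.integers(10_000, 100_000_000))
            locs[base] = f"chr{chrom}:{start}-{start + 80}"
    return locs


def emit_dialects(
    matrix: CountMatrix,
    strip_arm_fraction: float = 0.3,
    drop_fraction: float = 0.05,
    seed: int = 0,
    reference_group: str | None = None,
) -> tuple[RawCountFile, RawCountFile, pd.Series]:
    """Split a matrix into two pipeline dialect files plus annotations.

    Dialect A (the "primary" pipeline) carries every group except
    ``reference_group`` (default: the last group); a fraction of its features
    lose their -3p/-5p suffix and a fraction are dropped outright. Dialect B
    (the "reference" pipeline) carries the remaining group's samples with
    intact names. The annotation series maps every emitted feature name
    (arm-stripped aliases included) to a chromosome location shared by the
    arms of a hairpin.
    """
    for name, frac in (("strip_arm_fraction", strip_arm_fraction), ("drop_fraction", drop_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ConfigurationError(f"{name} must lie in [0, 1]")
    groups = matrix.group_names
    if reference_group is None:
        reference_group = groups[-1]
    if reference_group not in groups:
        raise ConfigurationError(f"unknown reference group {reference_group!r}")

    rng = np.random.default_rng(seed)
    ref_samples = matrix.samples_of(reference_group)
    pri_samples = [s for s in matrix.samples if s not in ref_samples]

    features = list(matrix.features)
    locs = _hairpin_locations(features, rng)

    pri = matrix.counts[pri_samples].copy()
    n = len(features)
    n_drop = int(round(drop_fraction * n))
    drop_idx = set(rng.choice(n, size=n_drop, replace=False).tolist()) if n_drop else set()
    keep = [f for i, f in enumerate(features) if i not in drop_idx]
    pri = pri.loc[keep]

    armful = [f for f in keep if has_arm_suffix(f)]
    n_strip = int(round(strip_arm_fraction * len(armful)))
    strip_set = (
        set(rng.choice(len(armful), size=n_strip, replace=False).tolist()) if n_strip else set()
    )
    rename = {armful[i]: strip_arm_suffix(armful[i]) for i in strip_set}
    # a stripped name may collide with its sibling arm's stripped name; keep
    # the collision (summing would break count conservation) by renaming only
    # the first occurrence and leaving later ones intact
    seen: set[str] = set()
    final_rename: dict[str, str] = {}
    for old, new in rename.items():
        if new in seen or new in pri.index:
            continue
        seen.add(new)
        final_rename[old] = new
    pri = pri.rename(index=final_rename)

    ref = matrix.counts[ref_samples].copy()

    ann_names: dict[str, str] = {}
    for f in features:
        ann_names[f] = locs[strip_arm_suffix(f)]
    for new in final_rename.values():
        ann_names[new] = locs[new]
    annotations = pd.Series(ann_names, name="location")

    file_a = RawCountFile("dialect_a", pri, annotations.reindex(pri.index))
    file_b = RawCountFile("dialect_b", ref, annotations.reindex(ref.index))
    return file_a, file_b, annotations
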