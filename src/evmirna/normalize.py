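"""CPM, median-of-ratios size factors, log transform and PCA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NormalizationError, StatisticalError
from .io import CountMatrix


def cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million miRNA reads, no pseudocount.

    value(i, j) = count(i, j) / total(j) * 1e6.
    """
    totals = matrix.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise NormalizationError(f"all-zero sample column(s): {list(zero.index)}")
    return matrix.counts / totals * 1e6


@dataclass
class NormalizationResult:
    """Median-of-ratios size factors and the normalized/log matrices."""

    size_factors: pd.Series  # per sample, geometric mean 1
    normalized: pd.DataFrame  # count / size factor
    log2: pd.DataFrame  # log2(normalized + 1)
    reference_features: pd.Index  # all-nonzero features used for the median

    def group_means(self, matrix: CountMatrix) -> pd.DataFrame:
        """Per-group mean normalized count (features x groups)."""
        cols = {}
        for g in matrix.group_names:
            cols[g] = self.normalized[matrix.samples_of(g)].mean(axis=1)
        return pd.DataFrame(cols)


def size_factors(matrix: CountMatrix) -> NormalizationResult:
    """Median-of-ratios normalization over an all-nonzero reference set.

    The pseudo-reference is the per-feature geometric mean across samples,
    restricted to features with no zero count. Size factors are rescaled so
    their geometric mean is exactly 1, which leaves ratios between samples
    untouched but fixes the overall scale.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise NormalizationError(
            "median-of-ratios reference set is empty (no feature is nonzero in "
            "every sample); consider CPM normalization instead"
        )
    ref_counts = counts[all_nonzero]
    log_geo = np.log(ref_counts).mean(axis=1)
    ratios = np.log(ref_counts) - log_geo[:, None]
    log_s = np.median(ratios, axis=0)
    log_s = log_s - log_s.mean()  # geometric mean of size factors -> 1
    s = pd.Series(np.exp(log_s), index=matrix.samples, name="size_factor")
    normalized = matrix.counts / s
    return NormalizationResult(
        size_factors=s,
        normalized=normalized,
        log2=np.log2(normalized + 1.0),
        reference_features=matrix.features[all_nonzero],
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray  # non-increasing, sums to 1

    def to_dict(self) -> dict:
        return {
            "scores": {s: list(map(float, row)) for s, row in self.scores.iterrows()},
            "variance_fraction": [float(v) for v in self.variance_fraction],
        }


def pca(logmatrix: pd.DataFrame) -> PCAResult:
    """PCA with samples as observations and features centered, not scaled.

    Constant features are dropped first. Components are ordered by explained
    variance; fractions are normalized over all retained components.
    """
    if logmatrix.shape[1] < 2:
        raise StatisticalError("PCA requires at least 2 samples")
    x = logmatrix.T  # samples x features
    keep = x.std(axis=0, ddof=0) > 0
    x = x.loc[:, keep]
    if x.shape[1] == 0:
        raise StatisticalError("all features are constant across samples")
    centered = x - x.mean(axis=0)
    u, svals, _ = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    n_comp = min(x.shape[0] - 1, x.shape[1])
    u, svals = u[:, :n_comp], svals[:n_comp]
    var = svals**2
    total = var.sum()
    if total == 0:
        raise StatisticalError("zero total variance")
    scores = pd.DataFrame(
        u * svals,
        index=logmatrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    return PCAResult(scores=scores, variance_fraction=var / total)
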