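"""All-pairwise negative-binomial Wald differential expression with BH FDR.

Counts are modeled as NB with variance = mu + alpha * mu**2. Per-feature
dispersions come from a method-of-moments estimate on size-factor-normalized
counts, shrunk 50/50 (on the log scale) toward a mean-dispersion trend fitted
by robust regression, and floored. Group means are compared with a Wald
statistic whose standard error follows from the NB variance of the group-mean
estimator (delta method on the log2 ratio, with a small pseudo-mass to keep
zero means finite). No outlier replacement and no independent filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, EvmirnaError
from .io import CountMatrix
from .normalize import NormalizationResult

DISPERSION_FLOOR = 1e-8
PSEUDO_MASS = 0.5  # added to group means inside the log2 ratio

DE_COLUMNS = ["feature", "baseMean", "log2FC", "SE", "stat", "pvalue", "FDR"]


@dataclass
class DispersionEstimate:
    """Per-feature dispersion with its method-of-moments and trend parts."""

    moments: pd.Series  # raw MoM value (may be <= 0 before flooring)
    trend: pd.Series  # fitted trend value at the feature's mean
    final: pd.Series  # shrunken, floored value used for testing

    def __post_init__(self) -> None:
        assert (self.final >= DISPERSION_FLOOR).all()


def _fit_trend(mean_counts: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Robust log-log regression of dispersion on mean normalized count.

    Only features with a positive MoM estimate inform the fit; Huber weights
    keep outlying features from dragging the trend. Falls back to the median
    dispersion when too few features are usable.
    """
    usable = (alpha_mom > 0) & (mean_counts > 0)
    if usable.sum() < 10:
        fallback = np.median(alpha_mom[usable]) if usable.any() else 0.1
        return np.full_like(mean_counts, max(fallback, DISPERSION_FLOOR))
    x = np.log(mean_counts[usable])
    y = np.log(alpha_mom[usable])
    import statsmodels.api as sm

    design = sm.add_constant(x)
    fit = sm.RLM(y, design, M=sm.robust.norms.HuberT()).fit()
    b0, b1 = fit.params
    logm = np.log(np.maximum(mean_counts, 1e-8))
    return np.exp(b0 + b1 * logm)


def estimate_dispersions(
    matrix: CountMatrix, norm: NormalizationResult
) -> DispersionEstimate:
    """Method-of-moments dispersions pooled across groups, trend-shrunken.

    On normalized counts y_ij = K_ij / s_j with group mean q_g, the NB model
    gives E[(y - q)^2] ~= q / s_j + alpha * q^2, so a pooled within-group
    variance yields alpha ~= (s2 - xi * qbar) / qbar^2 with xi the mean
    inverse size factor (the classic rough estimator).
    """
    y = norm.normalized.to_numpy(dtype=float)
    s = norm.size_factors.to_numpy(dtype=float)
    groups = matrix.groups.to_numpy()
    labels = matrix.group_names

    n, m = y.shape
    ss = np.zeros(n)
    df = 0
    qbar = np.zeros(n)
    for g in labels:
        cols = np.flatnonzero(groups == g)
        sub = y[:, cols]
        qg = sub.mean(axis=1)
        ss += ((sub - qg[:, None]) ** 2).sum(axis=1)
        df += len(cols) - 1
    if df <= 0:
        raise DesignError("dispersion estimation needs at least one group with >= 2 replicates")
    s2 = ss / df
    qbar = y.mean(axis=1)
    xi = float(np.mean(1.0 / s))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(qbar > 0, (s2 - xi * qbar) / np.maximum(qbar, 1e-300) ** 2, 0.0)

    alpha_trend = np.clip(_fit_trend(qbar, alpha_mom), DISPERSION_FLOOR, None)
    # non-positive MoM estimates carry no usable signal; they collapse onto
    # the trend instead of being floored (flooring would fake near-Poisson
    # precision and inflate the Wald statistic)
    clipped = np.where(alpha_mom > 0, alpha_mom, alpha_trend)
    final = np.exp(0.5 * np.log(clipped) + 0.5 * np.log(alpha_trend))
    final = np.clip(final, DISPERSION_FLOOR, None)
    idx = matrix.features
    return DispersionEstimate(
        moments=pd.Series(alpha_mom, index=idx),
        trend=pd.Series(alpha_trend, index=idx),
        final=pd.Series(final, index=idx),
    )


def _pair_table(
    features: pd.Index,
    base_mean: np.ndarray,
    q_a: np.ndarray,
    q_b: np.ndarray,
    var_a: np.ndarray,
    var_b: np.ndarray,
    df: float,
) -> pd.DataFrame:
    ln2 = np.log(2.0)
    qa = q_a + PSEUDO_MASS
    qb = q_b + PSEUDO_MASS
    lfc = np.log2(qa / qb)
    se = np.sqrt(var_a / (qa**2) + var_b / (qb**2)) / ln2
    both_zero = (q_a == 0) & (q_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, lfc / se, 0.0)
    # t reference with the dispersion-estimation df (n - G): the SE rests on
    # a variance estimated from few replicates, and a normal reference is
    # measurably anti-conservative at n ~ 3 per group
    pval = 2.0 * sps.t.sf(np.abs(stat), df)
    lfc[both_zero] = 0.0
    stat[both_zero] = 0.0
    pval[both_zero] = 1.0
    se[both_zero] = np.nan
    table = pd.DataFrame(
        {
            "feature": features,
            "baseMean": base_mean,
            "log2FC": lfc,
            "SE": se,
            "stat": stat,
            "pvalue": np.clip(pval, 0.0, 1.0),
        }
    )
    table["FDR"] = adjust_fdr(table["pvalue"].to_numpy())
    return table


def fit_pairwise(
    matrix: CountMatrix,
    norm: NormalizationResult,
    dispersions: DispersionEstimate | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """NB Wald tests for every unordered group pair, BH-adjusted per pair.

    Size factors must come from the full matrix (all groups at once). The
    returned dict maps (A, B) — in group order — to a table whose log2FC is
    A relative to B.
    """
    labels = matrix.group_names
    group_cols = {g: np.flatnonzero(matrix.groups.to_numpy() == g) for g in labels}
    for g, cols in group_cols.items():
        if len(cols) < 2:
            raise DesignError(f"group {g!r} has fewer than 2 replicates")
    if dispersions is None:
        dispersions = estimate_dispersions(matrix, norm)

    y = norm.normalized.to_numpy(dtype=float)
    s = norm.size_factors.to_numpy(dtype=float)
    alpha = dispersions.final.to_numpy(dtype=float)
    base_mean = y.mean(axis=1)

    q: dict[str, np.ndarray] = {}
    var_q: dict[str, np.ndarray] = {}
    for g, cols in group_cols.items():
        qg = y[:, cols].mean(axis=1)
        # Var(qhat_g) = (1/n^2) * sum_j (q/s_j + alpha q^2) under the NB model
        inv_s = (1.0 / s[cols]).sum()
        n_g = len(cols)
        var_q[g] = (qg * inv_s + alpha * qg**2 * n_g) / n_g**2
        q[g] = qg

    df = len(matrix.samples) - len(labels)
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for a, b in combinations(labels, 2):
        out[(a, b)] = _pair_table(matrix.features, base_mean, q[a], q[b], var_q[a], var_q[b], df)
    return out


def adjust_fdr(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up; output is monotone-enforced, same order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise EvmirnaError("adjust_fdr expects a 1-D array")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise EvmirnaError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def pair_lfc(
    tables: dict[tuple[str, str], pd.DataFrame], group: str, other: str
) -> pd.DataFrame:
    """Table for (group vs other), orienting log2FC so + favors ``group``."""
    if (group, other) in tables:
        return tables[(group, other)]
    if (other, group) in tables:
        t = tables[(other, group)].copy()
        t["log2FC"] = -t["log2FC"]
        t["stat"] = -t["stat"]
        return t
    raise EvmirnaError(f"no DE table for pair ({group}, {other})")


def summarize_pairs(
    tables: dict[tuple[str, str], pd.DataFrame], alpha: float = 0.05
) -> dict[str, dict[str, int]]:
    """Per-pair counts of up/down features at FDR < alpha."""
    out = {}
    for (a, b), t in tables.items():
        sig = t["FDR"] < alpha
        out[f"{a}_vs_{b}"] = {
            "up": int((sig & (t["log2FC"] > 0)).sum()),
            "down": int((sig & (t["log2FC"] < 0)).sum()),
            "tested": int(len(t)),
        }
    return out
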