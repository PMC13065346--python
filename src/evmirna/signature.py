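"""Tissue-specificity index tau and the three-criteria key-miRNA filter.

tau = sum_i (1 - x_i / x_max) / (N - 1) over N group means: 0 for a uniform
profile, 1 for single-group expression. A feature is "key" for a subtype when
it is abundant (top-k mean CPM there), upregulated (significantly up vs at
least one other subtype) and enriched (tau above threshold, or linear fold
change above threshold in enough pairwise comparisons).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import AbundanceRanking
from .diffexp import pair_lfc
from .errors import ConfigurationError, EvmirnaError


def compute_tau(group_means: np.ndarray | list[float]) -> float:
    """Specificity index of one expression profile across N >= 2 groups."""
    x = np.asarray(group_means, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise EvmirnaError("tau needs a 1-D profile over at least 2 groups")
    if (x < 0).any():
        raise EvmirnaError("tau requires non-negative group means")
    xmax = x.max()
    if xmax == 0:
        raise EvmirnaError("tau is undefined for an all-zero profile")
    return float((1.0 - x / xmax).sum() / (len(x) - 1))


def tau_table(group_means: pd.DataFrame) -> pd.DataFrame:
    """Per-feature tau over a features x groups table of mean normalized counts.

    Features whose maximum group mean is zero get tau = NaN (flagged
    undefined, excluded from enrichment calls downstream).
    """
    x = group_means.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise EvmirnaError("tau needs at least 2 groups")
    if (x < 0).any():
        raise EvmirnaError("tau requires non-negative group means")
    xmax = x.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        xhat = x / xmax[:, None]
    tau = (1.0 - xhat).sum(axis=1) / (x.shape[1] - 1)
    tau = np.where(xmax > 0, tau, np.nan)
    out = group_means.copy()
    out["x_max"] = xmax
    out["tau"] = tau
    return out


@dataclass
class Thresholds:
    """Filter thresholds of the key-miRNA classifier."""

    k: int = 20
    alpha: float = 0.05
    tau_thresh: float = 0.7
    fc_thresh: float = 5.0
    m: int = 2
    require_significant_fc: bool = True  # FDR < alpha in the >= m comparisons

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0.0 <= self.tau_thresh <= 1.0:
            raise ConfigurationError("tau_thresh must lie in [0, 1]")
        if self.fc_thresh <= 1.0:
            raise ConfigurationError("fc_thresh must exceed 1")
        if self.m < 1:
            raise ConfigurationError("m must be >= 1")


def consensus_upregulated(
    tables: dict[tuple[str, str], pd.DataFrame],
    subtype: str,
    others: list[str],
    alpha: float = 0.05,
) -> set[str]:
    """Features significantly up in ``subtype`` against every other group."""
    result: set[str] | None = None
    for other in others:
        t = pair_lfc(tables, subtype, other)
        up = set(t.loc[(t["FDR"] < alpha) & (t["log2FC"] > 0), "feature"])
        result = up if result is None else result & up
    if result is None:
        raise EvmirnaError("consensus requires at least one other group")
    return result


def classify_key(
    ranking: AbundanceRanking,
    tables: dict[tuple[str, str], pd.DataFrame],
    taus: pd.DataFrame,
    groups: list[str],
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Apply the abundance/upregulation/enrichment filter per (feature, subtype).

    Returns one row per subtype for every feature in that subtype's top-k
    list, with the three criterion flags, tau, the best favoring fold change,
    the final ``key`` call and the ``consensus_upregulated`` flag.
    """
    th = thresholds or Thresholds()
    log2_fc_thresh = np.log2(th.fc_thresh)
    tau_by_feature = taus["tau"]

    rows = []
    consensus: dict[str, set[str]] = {}
    for g in groups:
        others = [h for h in groups if h != g]
        consensus[g] = consensus_upregulated(tables, g, others, th.alpha) if others else set()
        per_pair = {h: pair_lfc(tables, g, h).set_index("feature") for h in others}
        for feature in ranking.top_features(g):
            up_pairs = 0
            fc_pairs = 0
            best_lfc = -np.inf
            for h, t in per_pair.items():
                if feature not in t.index:
                    continue
                lfc = float(t.at[feature, "log2FC"])
                fdr = float(t.at[feature, "FDR"])
                sig_up = fdr < th.alpha and lfc > 0
                if sig_up:
                    up_pairs += 1
                big_fc = lfc > log2_fc_thresh and (not th.require_significant_fc or fdr < th.alpha)
                if big_fc:
                    fc_pairs += 1
                best_lfc = max(best_lfc, lfc)
            tau = float(tau_by_feature.get(feature, np.nan))
            upregulated = up_pairs >= 1
            enriched = (not np.isnan(tau) and tau > th.tau_thresh) or fc_pairs >= th.m
            rows.append(
                {
                    "feature": feature,
                    "subtype": g,
                    "abundant": True,  # rows are drawn from the top-k list
                    "upregulated": upregulated,
                    "enriched": enriched,
                    "tau": tau,
                    "best_log2FC": best_lfc if np.isfinite(best_lfc) else np.nan,
                    "n_up_pairs": up_pairs,
                    "n_fc_pairs": fc_pairs,
                    "key": upregulated and enriched,
                    "consensus_upregulated": feature in consensus[g],
                }
            )
    return pd.DataFrame(rows)


def write_consensus_sets(
    tables: dict[tuple[str, str], pd.DataFrame],
    groups: list[str],
    path: str | Path,
    alpha: float = 0.05,
) -> dict[str, list[str]]:
    sets = {
        g: sorted(consensus_upregulated(tables, g, [h for h in groups if h != g], alpha))
        for g in groups
    }
    Path(path).write_text(json.dumps(sets, indent=2))
    return sets
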