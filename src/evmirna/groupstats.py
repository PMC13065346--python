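"""Assumption-driven statistical test routing for grouped measurements.

Multi-group data goes to one-way ANOVA + Tukey when per-group normality
passes and spreads are homogeneous, to Brown-Forsythe/Welch ANOVA +
Dunnett T3 when normality passes but spreads differ, and to Kruskal-Wallis +
Dunn otherwise. Two-group data on a log-candidate scale goes to a lognormal
t / lognormal Welch / Mann-Whitney cascade; dimensionless indices use the
same cascade on the raw scale with an unpaired t at the top.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

from .errors import ConfigurationError, EvmirnaError, StatisticalError

MULTI_ROUTES = ("anova_tukey", "welch_bf_dunnettT3", "kruskal_dunn")
TWO_ROUTES = ("unpaired_t", "welch_t", "lognormal_t", "lognormal_welch", "mann_whitney")
ROUTES = MULTI_ROUTES + TWO_ROUTES

SHAPIRO_MIN_N = 3


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class MeasurementTable:
    """Long-format grouped observations plus design and scale hints."""

    data: pd.DataFrame  # columns: sample, group, value
    design: str  # "multi_group" | "two_group"
    scale_hint: str = "raw"  # "raw" | "lognormal_candidate" | "dimensionless_index"

    def __post_init__(self) -> None:
        required = {"sample", "group", "value"}
        if not required.issubset(self.data.columns):
            raise ConfigurationError(f"measurement table needs columns {sorted(required)}")
        if self.design not in ("multi_group", "two_group"):
            raise ConfigurationError(f"unknown design {self.design!r}")
        if self.scale_hint not in ("raw", "lognormal_candidate", "dimensionless_index"):
            raise ConfigurationError(f"unknown scale_hint {self.scale_hint!r}")
        vals = self.data["value"].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise EvmirnaError("measurement values must be finite")
        counts = self.data.groupby("group").size()
        if len(counts) < 2:
            raise ConfigurationError("need at least 2 groups")
        if self.design == "two_group" and len(counts) != 2:
            raise ConfigurationError("two_group design requires exactly 2 groups")
        if (counts < 2).any():
            small = list(counts[counts < 2].index)
            raise ConfigurationError(f"groups with fewer than 2 observations: {small}")

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.data["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def values_of(self, group: str) -> np.ndarray:
        return self.data.loc[self.data["group"] == group, "value"].to_numpy(dtype=float)

    @classmethod
    def read(cls, path: str | Path, design: str, scale_hint: str = "raw") -> "MeasurementTable":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.strip().lower() for c in df.columns]
        return cls(df, design, scale_hint)


@dataclass
class AssumptionReport:
    """Shapiro-Wilk / spread-test p-values and the derived predicates."""

    alpha: float
    shapiro_raw: dict[str, float]  # group -> p (NaN when n < 3)
    shapiro_log: dict[str, float]
    spread_test: str  # "brown_forsythe" | "f_test"
    spread_p_raw: float
    spread_p_log: float
    insufficient_n: list[str] = field(default_factory=list)

    @property
    def normality_pass(self) -> bool:
        ps = list(self.shapiro_raw.values())
        return bool(ps) and all(not math.isnan(p) and p >= self.alpha for p in ps)

    @property
    def lognormality_pass(self) -> bool:
        ps = list(self.shapiro_log.values())
        return bool(ps) and all(not math.isnan(p) and p >= self.alpha for p in ps)

    @property
    def equal_sd(self) -> bool:
        return self.spread_p_raw >= self.alpha

    @property
    def equal_sd_log(self) -> bool:
        return self.spread_p_log >= self.alpha

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "shapiro_raw": self.shapiro_raw,
            "shapiro_log": self.shapiro_log,
            "spread_test": self.spread_test,
            "spread_p_raw": self.spread_p_raw,
            "spread_p_log": self.spread_p_log,
            "insufficient_n": self.insufficient_n,
            "normality_pass": self.normality_pass,
            "lognormality_pass": self.lognormality_pass,
            "equal_sd": self.equal_sd,
            "equal_sd_log": self.equal_sd_log,
        }


def _shapiro_p(values: np.ndarray) -> float:
    if len(values) < SHAPIRO_MIN_N or np.ptp(values) == 0:
        return float("nan")
    return float(sps.shapiro(values).pvalue)


def _f_test_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided variance-ratio F test (larger variance in the numerator)."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb > va:
        a, b = b, a
        va, vb = vb, va
    if vb == 0:
        return 0.0
    f = va / vb
    dfn, dfd = len(a) - 1, len(b) - 1
    return float(min(1.0, 2.0 * sps.f.sf(f, dfn, dfd)))


def assess_assumptions(table: MeasurementTable, alpha: float = 0.05) -> AssumptionReport:
    """Per-group Shapiro-Wilk on raw and log scales plus a spread test.

    The spread test is Brown-Forsythe (Levene with median centering) for
    multi-group designs and the variance-ratio F test for two groups. Groups
    with fewer than 3 observations make Shapiro-Wilk inapplicable; they are
    flagged and the corresponding normality predicate fails.
    """
    groups = table.group_names
    raw = {g: table.values_of(g) for g in groups}

    log_needed = table.scale_hint == "lognormal_candidate"
    logs: dict[str, np.ndarray] = {}
    for g, vals in raw.items():
        if (vals <= 0).any():
            if log_needed:
                bad = table.data.loc[
                    (table.data["group"] == g) & (table.data["value"] <= 0), "sample"
                ].iloc[0]
                raise EvmirnaError(
                    f"non-positive value for sample {bad!r} in group {g!r} on a log route"
                )
            logs[g] = np.array([])
        else:
            logs[g] = np.log(vals)

    shapiro_raw = {g: _shapiro_p(v) for g, v in raw.items()}
    shapiro_log = {g: (_shapiro_p(v) if len(v) else float("nan")) for g, v in logs.items()}
    insufficient = [g for g, v in raw.items() if len(v) < SHAPIRO_MIN_N]

    if table.design == "multi_group":
        spread_test = "brown_forsythe"
        spread_p_raw = float(sps.levene(*raw.values(), center="median").pvalue)
        if all(len(v) for v in logs.values()):
            spread_p_log = float(sps.levene(*logs.values(), center="median").pvalue)
        else:
            spread_p_log = float("nan")
    else:
        spread_test = "f_test"
        a, b = (raw[g] for g in groups)
        spread_p_raw = _f_test_p(a, b)
        if all(len(logs[g]) for g in groups):
            spread_p_log = _f_test_p(*(logs[g] for g in groups))
        else:
            spread_p_log = float("nan")

    return AssumptionReport(
        alpha=alpha,
        shapiro_raw=shapiro_raw,
        shapiro_log=shapiro_log,
        spread_test=spread_test,
        spread_p_raw=spread_p_raw,
        spread_p_log=spread_p_log,
        insufficient_n=insufficient,
    )


def select_route(report: AssumptionReport, design: str, scale_hint: str = "raw") -> str:
    """Deterministic mapping from assumption predicates to a named route."""
    if design == "multi_group":
        if report.normality_pass:
            return "anova_tukey" if report.equal_sd else "welch_bf_dunnettT3"
        return "kruskal_dunn"
    if design != "two_group":
        raise ConfigurationError(f"unknown design {design!r}")
    if scale_hint == "lognormal_candidate":
        if report.lognormality_pass:
            return "lognormal_t" if report.equal_sd_log else "lognormal_welch"
        return "mann_whitney"
    # raw scale (dimensionless indices included)
    if report.normality_pass:
        return "unpaired_t" if report.equal_sd else "welch_t"
    return "mann_whitney"


# --- route implementations ---------------------------------------------------


def _smm_sf(t: float, k: int, df: float) -> float:
    """Survival function of the studentized maximum modulus SMM(k, df).

    M = max_i |Z_i| / (chi_df / sqrt(df)) with independent Z_i; used for
    Dunnett T3 adjusted p-values.
    """
    if t <= 0:
        return 1.0

    chi_scaled = sps.chi(df, scale=1.0 / math.sqrt(df))

    def integrand(u: float) -> float:
        return (2.0 * sps.norm.cdf(t * u) - 1.0) ** k * chi_scaled.pdf(u)

    cdf, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return float(min(1.0, max(0.0, 1.0 - cdf)))


def _check_variance(raw: dict[str, np.ndarray], route: str) -> None:
    degenerate = [g for g, v in raw.items() if np.var(v, ddof=1) == 0]
    if degenerate:
        raise StatisticalError(
            f"zero-variance group(s) {degenerate} are degenerate for route {route!r}"
        )


def _welch_anova_p(groups: list[np.ndarray]) -> float:
    n = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    var = np.array([g.var(ddof=1) for g in groups])
    w = n / var
    mw = (w * means).sum() / w.sum()
    k = len(groups)
    num = ((w * (means - mw) ** 2).sum()) / (k - 1)
    lam = (3.0 / (k**2 - 1)) * ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    f = num / (1 + 2 * lam * (k - 2) / 3.0)
    df2 = 1.0 / lam
    return float(sps.f.sf(f, k - 1, df2))


def _brown_forsythe_anova_p(groups: list[np.ndarray]) -> float:
    """Brown-Forsythe F* ANOVA (unequal-variance correction of the F test)."""
    n = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    var = np.array([g.var(ddof=1) for g in groups])
    grand = (n * means).sum() / n.sum()
    num = (n * (means - grand) ** 2).sum()
    denom_terms = (1 - n / n.sum()) * var
    denom = denom_terms.sum()
    f = num / denom
    c = denom_terms / denom
    df2 = 1.0 / ((c**2 / (n - 1)).sum())
    return float(sps.f.sf(f, len(groups) - 1, df2))


@dataclass
class RouteResult:
    route: str
    omnibus_p: float | None  # NaN-free; None for two-group routes
    omnibus_detail: dict = field(default_factory=dict)
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)  # pair, p_adj, stars

    def to_dict(self) -> dict:
        return {
            "route": self.route,
            "omnibus_p": self.omnibus_p,
            "omnibus_detail": self.omnibus_detail,
            "posthoc": self.posthoc.to_dict(orient="records"),
        }


def _posthoc_frame(rows: list[tuple[str, str, float]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"group_a": a, "group_b": b, "p_adj": p, "stars": significance_stars(p)}
            for a, b, p in rows
        ]
    )


def _dunn_posthoc(raw: dict[str, np.ndarray]) -> list[tuple[str, str, float]]:
    """Dunn's rank-based z tests with tie correction, Bonferroni-adjusted."""
    groups = list(raw)
    all_vals = np.concatenate([raw[g] for g in groups])
    ranks = sps.rankdata(all_vals)
    n_total = len(all_vals)
    mean_rank: dict[str, float] = {}
    pos = 0
    for g in groups:
        k = len(raw[g])
        mean_rank[g] = ranks[pos : pos + k].mean()
        pos += k
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for a, b in combinations(groups, 2):
        se = math.sqrt(var_base * (1.0 / len(raw[a]) + 1.0 / len(raw[b])))
        z = abs(mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * sps.norm.sf(z) * n_pairs)
        rows.append((a, b, float(p)))
    return rows


def run_comparison(table: MeasurementTable, route: str) -> RouteResult:
    """Execute a named route: omnibus test plus all-pairs post hoc table."""
    if route not in ROUTES:
        raise ConfigurationError(f"unknown route {route!r}; choose from {ROUTES}")
    groups = table.group_names
    raw = {g: table.values_of(g) for g in groups}
    if route in MULTI_ROUTES and table.design != "multi_group":
        raise ConfigurationError(f"route {route!r} requires a multi_group design")
    if route in TWO_ROUTES and len(groups) != 2:
        raise ConfigurationError(f"route {route!r} requires exactly 2 groups")

    if route.startswith("lognormal"):
        for g, vals in raw.items():
            if (vals <= 0).any():
                raise EvmirnaError(f"non-positive value in group {g!r} on a log route")
        work = {g: np.log(v) for g, v in raw.items()}
    else:
        work = raw

    if route == "anova_tukey":
        _check_variance(work, route)
        omnibus = float(sps.f_oneway(*work.values()).pvalue)
        res = sps.tukey_hsd(*work.values())
        rows = [
            (groups[i], groups[j], float(res.pvalue[i, j]))
            for i, j in combinations(range(len(groups)), 2)
        ]
        return RouteResult(route, omnibus, {"test": "one-way ANOVA"}, _posthoc_frame(rows))

    if route == "welch_bf_dunnettT3":
        _check_variance(work, route)
        vals = list(work.values())
        welch_p = _welch_anova_p(vals)
        bf_p = _brown_forsythe_anova_p(vals)
        n_pairs = len(groups) * (len(groups) - 1) // 2
        rows = []
        for a, b in combinations(groups, 2):
            xa, xb = work[a], work[b]
            va, vb = xa.var(ddof=1) / len(xa), xb.var(ddof=1) / len(xb)
            t = abs(xa.mean() - xb.mean()) / math.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (len(xa) - 1) + vb**2 / (len(xb) - 1))
            rows.append((a, b, _smm_sf(t, n_pairs, df)))
        return RouteResult(
            route,
            welch_p,
            {"welch_anova_p": welch_p, "brown_forsythe_anova_p": bf_p},
            _posthoc_frame(rows),
        )

    if route == "kruskal_dunn":
        omnibus = float(sps.kruskal(*work.values()).pvalue)
        return RouteResult(route, omnibus, {"test": "Kruskal-Wallis"}, _posthoc_frame(_dunn_posthoc(work)))

    # two-group routes
    a, b = groups
    xa, xb = work[a], work[b]
    if route in ("unpaired_t", "lognormal_t"):
        _check_variance(work, route)
        p = float(sps.ttest_ind(xa, xb, equal_var=True).pvalue)
    elif route in ("welch_t", "lognormal_welch"):
        _check_variance(work, route)
        p = float(sps.ttest_ind(xa, xb, equal_var=False).pvalue)
    else:  # mann_whitney
        p = float(sps.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
    return RouteResult(route, None, {"p": p}, _posthoc_frame([(a, b, p)]))


def analyze(table: MeasurementTable, alpha: float = 0.05) -> dict:
    """Assess assumptions, select the route, run it; JSON-ready report."""
    report = assess_assumptions(table, alpha)
    route = select_route(report, table.design, table.scale_hint)
    result = run_comparison(table, route)
    return {"assumptions": report.to_dict(), "route": route, "result": result.to_dict()}


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))
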