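import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from evmirna.errors import ConfigurationError, EvmirnaError, StatisticalError
from evmirna.groupstats import (
    AssumptionReport,
    MeasurementTable,
    ROUTES,
    _smm_sf,
    analyze,
    assess_assumptions,
    run_comparison,
    select_route,
    significance_stars,
)


def long_table(groups_to_values, design, scale_hint="raw"):
    rows = []
    for g, vals in groups_to_values.items():
        for i, v in enumerate(vals):
            rows.append({"sample": f"{g}_{i}", "group": g, "value": v})
    return MeasurementTable(pd.DataFrame(rows), design, scale_hint)


def gaussian_fixture(n_groups=4, n=10, sd=1.0, seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    return {
        f"g{i}": rng.normal(i * shift, sd, size=n).tolist() for i in range(n_groups)
    }


def report(normal=True, lognormal=True, equal=True, alpha=0.05):
    p_pass, p_fail = 0.5, 0.001
    sp = p_pass if equal else p_fail
    return AssumptionReport(
        alpha=alpha,
        shapiro_raw={"a": p_pass if normal else p_fail, "b": p_pass if normal else p_fail},
        shapiro_log={"a": p_pass if lognormal else p_fail, "b": p_pass if lognormal else p_fail},
        spread_test="f_test",
        spread_p_raw=sp,
        spread_p_log=sp,
    )


class TestMeasurementTable:
    def test_requires_two_groups(self):
        with pytest.raises(ConfigurationError):
            long_table({"a": [1, 2, 3]}, "multi_group")

    def test_two_group_design_enforced(self):
        with pytest.raises(ConfigurationError):
            long_table({"a": [1, 2], "b": [1, 2], "c": [1, 2]}, "two_group")

    def test_min_two_per_group(self):
        with pytest.raises(ConfigurationError):
            long_table({"a": [1.0], "b": [1, 2]}, "two_group")

    def test_nonfinite_rejected(self):
        with pytest.raises(EvmirnaError):
            long_table({"a": [1.0, float("inf")], "b": [1, 2]}, "two_group")


class TestAssessAssumptions:
    def test_matches_scipy_oracle(self):
        """Fixed-seed Gaussian fixture vs direct scipy computation."""
        vals = gaussian_fixture(n_groups=2, n=10, seed=4)
        table = long_table(vals, "two_group")
        rep = assess_assumptions(table)
        for g in vals:
            assert rep.shapiro_raw[g] == pytest.approx(
                sps.shapiro(np.array(vals[g])).pvalue
            )
        a, b = (np.array(vals[g]) for g in vals)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        f = max(va, vb) / min(va, vb)
        dfn = len(a) - 1
        p_oracle = min(1.0, 2 * sps.f.sf(f, dfn, dfn))
        assert rep.spread_p_raw == pytest.approx(p_oracle)

    def test_multi_group_uses_brown_forsythe(self):
        vals = gaussian_fixture(n_groups=3, n=8, seed=5)
        rep = assess_assumptions(long_table(vals, "multi_group"))
        arrays = [np.array(v) for v in vals.values()]
        assert rep.spread_test == "brown_forsythe"
        assert rep.spread_p_raw == pytest.approx(
            sps.levene(*arrays, center="median").pvalue
        )

    def test_identical_groups_equal_sd(self):
        vals = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
        rep = assess_assumptions(long_table(vals, "two_group"))
        assert rep.equal_sd

    def test_insufficient_n_fails_normality(self):
        vals = {"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0, 2.5]}
        rep = assess_assumptions(long_table(vals, "two_group"))
        assert "a" in rep.insufficient_n
        assert math.isnan(rep.shapiro_raw["a"])
        assert not rep.normality_pass

    def test_nonpositive_value_on_log_route_errors(self):
        vals = {"a": [1.0, 0.0, 2.0], "b": [1.0, 2.0, 3.0]}
        with pytest.raises(EvmirnaError, match="non-positive"):
            assess_assumptions(long_table(vals, "two_group", "lognormal_candidate"))


class TestSelectRoute:
    @pytest.mark.parametrize(
        "normal,equal,expected",
        [
            (True, True, "anova_tukey"),
            (True, False, "welch_bf_dunnettT3"),
            (False, True, "kruskal_dunn"),
            (False, False, "kruskal_dunn"),
        ],
    )
    def test_multi_group_mapping(self, normal, equal, expected):
        assert select_route(report(normal=normal, equal=equal), "multi_group") == expected

    @pytest.mark.parametrize(
        "lognormal,equal,expected",
        [
            (True, True, "lognormal_t"),
            (True, False, "lognormal_welch"),
            (False, True, "mann_whitney"),
            (False, False, "mann_whitney"),
        ],
    )
    def test_two_group_lognormal_mapping(self, lognormal, equal, expected):
        rep = report(lognormal=lognormal, equal=equal)
        assert select_route(rep, "two_group", "lognormal_candidate") == expected

    @pytest.mark.parametrize(
        "normal,equal,expected",
        [
            (True, True, "unpaired_t"),
            (True, False, "welch_t"),
            (False, True, "mann_whitney"),
            (False, False, "mann_whitney"),
        ],
    )
    def test_two_group_raw_mapping(self, normal, equal, expected):
        rep = report(normal=normal, equal=equal)
        assert select_route(rep, "two_group", "dimensionless_index") == expected

    def test_total_over_all_predicates(self):
        """Every predicate combination maps to a valid route (exhaustive)."""
        for normal, lognormal, equal in itertools.product([True, False], repeat=3):
            rep = report(normal=normal, lognormal=lognormal, equal=equal)
            for design, hints in (
                ("multi_group", ["raw"]),
                ("two_group", ["raw", "lognormal_candidate", "dimensionless_index"]),
            ):
                for hint in hints:
                    assert select_route(rep, design, hint) in ROUTES


class TestRunComparison:
    def test_posthoc_covers_all_pairs(self):
        vals = gaussian_fixture(n_groups=4, n=6, seed=7)
        res = run_comparison(long_table(vals, "multi_group"), "anova_tukey")
        assert len(res.posthoc) == 6  # C(4,2)

    def test_anova_tukey_matches_scipy_oracle(self):
        vals = gaussian_fixture(n_groups=4, n=8, seed=8, shift=0.8)
        res = run_comparison(long_table(vals, "multi_group"), "anova_tukey")
        arrays = [np.array(v) for v in vals.values()]
        assert res.omnibus_p == pytest.approx(sps.f_oneway(*arrays).pvalue, abs=1e-6)
        oracle = sps.tukey_hsd(*arrays)
        names = list(vals)
        for _, row in res.posthoc.iterrows():
            i, j = names.index(row["group_a"]), names.index(row["group_b"])
            assert row["p_adj"] == pytest.approx(oracle.pvalue[i, j], abs=1e-6)

    def test_lognormal_t_log_equivariance(self):
        """lognormal_t on a*exp(z) equals unpaired_t on z."""
        rng = np.random.default_rng(9)
        za, zb = rng.normal(0, 1, 8), rng.normal(0.7, 1, 8)
        log_vals = {"a": za.tolist(), "b": zb.tolist()}
        exp_vals = {"a": (2.0 * np.exp(za)).tolist(), "b": (2.0 * np.exp(zb)).tolist()}
        p_log = run_comparison(
            long_table(exp_vals, "two_group", "lognormal_candidate"), "lognormal_t"
        ).posthoc["p_adj"][0]
        p_raw = run_comparison(long_table(log_vals, "two_group"), "unpaired_t").posthoc[
            "p_adj"
        ][0]
        # the a=2.0 scale shifts log values by a constant, which cancels
        assert p_log == pytest.approx(p_raw, abs=1e-12)

    def test_mann_whitney_matches_scipy(self):
        vals = gaussian_fixture(n_groups=2, n=9, seed=10, shift=1.0)
        res = run_comparison(long_table(vals, "two_group"), "mann_whitney")
        a, b = (np.array(v) for v in vals.values())
        assert res.posthoc["p_adj"][0] == pytest.approx(
            sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
        )

    def test_kruskal_dunn_structure(self):
        vals = gaussian_fixture(n_groups=3, n=7, seed=11, shift=2.0)
        res = run_comparison(long_table(vals, "multi_group"), "kruskal_dunn")
        arrays = [np.array(v) for v in vals.values()]
        assert res.omnibus_p == pytest.approx(sps.kruskal(*arrays).pvalue)
        assert len(res.posthoc) == 3
        assert res.posthoc["p_adj"].between(0, 1).all()

    def test_welch_bf_dunnett_t3(self):
        rng = np.random.default_rng(12)
        vals = {
            "a": rng.normal(0, 0.5, 8).tolist(),
            "b": rng.normal(1.5, 3.0, 8).tolist(),
            "c": rng.normal(0, 1.0, 8).tolist(),
        }
        res = run_comparison(long_table(vals, "multi_group"), "welch_bf_dunnettT3")
        assert 0 <= res.omnibus_p <= 1
        assert "brown_forsythe_anova_p" in res.omnibus_detail
        assert len(res.posthoc) == 3
        assert res.posthoc["p_adj"].between(0, 1).all()

    def test_zero_variance_group_rejected(self):
        vals = {"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0, 3.0]}
        with pytest.raises(StatisticalError):
            run_comparison(long_table(vals, "two_group"), "unpaired_t")

    def test_unknown_route_rejected(self):
        vals = gaussian_fixture(n_groups=2, n=4)
        with pytest.raises(ConfigurationError):
            run_comparison(long_table(vals, "two_group"), "bogus_route")

    def test_stars(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.5) == "ns"


class TestSMM:
    def test_matches_monte_carlo(self):
        """SMM tail probability vs direct simulation."""
        rng = np.random.default_rng(13)
        k, df = 3, 10
        z = np.abs(rng.standard_normal((200_000, k))).max(axis=1)
        s = np.sqrt(rng.chisquare(df, 200_000) / df)
        m = z / s
        for t in (1.5, 2.5, 3.5):
            mc = (m > t).mean()
            assert _smm_sf(t, k, df) == pytest.approx(mc, abs=0.01)

    def test_monotone_in_t(self):
        ps = [_smm_sf(t, 6, 8) for t in (0.5, 1.5, 2.5, 3.5)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestNullCalibration:
    @pytest.mark.parametrize("route", ["anova_tukey", "unpaired_t"])
    def test_parametric_null_rejection_rate(self, route):
        rng = np.random.default_rng(14)
        n_sim, rejections = 400, 0
        n_groups = 4 if route == "anova_tukey" else 2
        design = "multi_group" if route == "anova_tukey" else "two_group"
        for _ in range(n_sim):
            vals = {f"g{i}": rng.normal(0, 1, 6).tolist() for i in range(n_groups)}
            res = run_comparison(long_table(vals, design), route)
            p = res.omnibus_p if res.omnibus_p is not None else res.posthoc["p_adj"][0]
            rejections += p < 0.05
        rate = rejections / n_sim
        margin = 2.576 * math.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < margin + 0.005


class TestAnalyze:
    def test_end_to_end_json_ready(self):
        import json

        vals = gaussian_fixture(n_groups=4, n=8, seed=15)
        out = analyze(long_table(vals, "multi_group"))
        assert out["route"] in ROUTES
        json.dumps(out, default=float)  # serializable
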