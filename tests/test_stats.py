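"""Gated group comparisons, post hoc tests, correlation and power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from glenostab.stats import (
    StatsError,
    build_report,
    compare_variability,
    correlate,
    dunn_test,
    gate_and_compare,
    observed_power,
)


class TestGateAndCompare:
    def test_three_identical_groups_null(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        res = gate_and_compare({"A": vals, "B": vals, "C": vals})
        assert res.omnibus_p > 0.99

    def test_large_shift_detected(self, rng):
        base = rng.normal(0, 1, 10)
        res = gate_and_compare(
            {"A": rng.normal(0, 1, 10), "B": rng.normal(0, 1, 10), "C": base + 5.0}
        )
        assert res.omnibus_p < 0.001
        assert res.test_used == "anova"
        assert all(p.method == "holm-sidak" for p in res.pairwise)

    def test_heavy_tails_route_to_kruskal(self):
        rng = np.random.default_rng(42)
        groups = {k: rng.standard_cauchy(15) * 10 for k in "ABC"}
        res = gate_and_compare(groups)
        assert any(p <= 0.05 for p in res.shapiro_p.values())
        assert res.test_used == "kruskal"
        assert all(p.method == "dunn-bonferroni" for p in res.pairwise)

    def test_unequal_variance_routes_nonparametric(self, rng):
        groups = {
            "A": rng.normal(0, 1, 12),
            "B": rng.normal(0, 1, 12),
            "C": rng.normal(0, 10, 12),
        }
        res = gate_and_compare(groups)
        assert res.brown_forsythe_p <= 0.05
        assert res.test_used == "kruskal"

    def test_adjusted_p_at_least_raw(self, rng):
        groups = {k: rng.normal(i * 0.5, 1, 10) for i, k in enumerate("ABCD")}
        res = gate_and_compare(groups)
        for pw in res.pairwise:
            assert pw.adjusted_p >= pw.raw_p - 1e-12

    def test_too_small_group_rejected(self):
        with pytest.raises(StatsError):
            gate_and_compare({"A": [1.0], "B": [1.0, 2.0]})


class TestDunn:
    def test_two_group_dunn_matches_kruskal(self, rng):
        """For two groups Dunn's z^2 equals the Kruskal-Wallis H statistic,
        so the raw p values agree (chi2_1 vs squared-normal)."""
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 9)
        raw = dunn_test({"A": a, "B": b})[0].raw_p
        _, kw_p = sps.kruskal(a, b)
        assert raw == pytest.approx(kw_p, rel=1e-9)

    def test_bonferroni_adjustment_formula(self, rng):
        groups = {k: rng.normal(0, 1, 8) for k in "ABC"}
        res = dunn_test(groups)
        for pw in res:
            assert pw.adjusted_p == pytest.approx(min(1.0, pw.raw_p * len(res)))


class TestVariability:
    def test_null_groups_usually_not_rejected(self, rng):
        rejections = 0
        for _ in range(50):
            groups = {k: rng.normal(0, 1, 10) for k in "ABC"}
            if compare_variability(groups).omnibus_p <= 0.05:
                rejections += 1
        assert rejections <= 10  # ~alpha-level behaviour

    def test_matches_scipy_brown_forsythe(self, rng):
        groups = {"A": rng.normal(0, 1, 10), "B": rng.normal(0, 4, 10)}
        res = compare_variability(groups)
        _, p = sps.levene(groups["A"], groups["B"], center="median")
        assert res.omnibus_p == pytest.approx(p)

    def test_inflated_group_detected_with_decent_power(self, rng):
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            groups = {
                "A": rng.normal(0, 1, 10),
                "B": rng.normal(0, 1, 10),
                "C": rng.normal(0, 4, 10),
            }
            if compare_variability(groups).omnibus_p <= 0.05:
                hits += 1
        assert hits / n_sim > 0.6

    def test_constant_groups_degenerate(self):
        with pytest.warns(UserWarning):
            res = compare_variability({"A": np.ones(5), "B": np.ones(5)})
        assert res.omnibus_p == 1.0


class TestCorrelate:
    def test_perfect_decreasing_line(self):
        x = {"G": np.arange(10.0)}
        y = {"G": -2.0 * np.arange(10.0) + 3.0}
        r, p = correlate(x, y)["G"]
        assert r == pytest.approx(-1.0)
        assert p < 1e-8

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            correlate({"G": np.ones(5)}, {"G": np.arange(5.0)})

    def test_short_group_rejected(self):
        with pytest.raises(StatsError):
            correlate({"G": np.arange(2.0)}, {"G": np.arange(2.0)})


class TestObservedPower:
    def test_zero_effect_power_near_alpha(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        power = observed_power({"A": vals, "B": vals, "C": vals})
        assert power == pytest.approx(0.05, abs=0.01)

    def test_huge_effect_power_near_one(self, rng):
        groups = {
            "A": rng.normal(0, 1, 10),
            "B": rng.normal(10, 1, 10),
            "C": rng.normal(20, 1, 10),
        }
        assert observed_power(groups) > 0.99

    def test_zero_residual_variance_warns_power_one(self):
        with pytest.warns(UserWarning):
            power = observed_power({"A": np.ones(5), "B": np.full(5, 2.0)})
        assert power == 1.0

    def test_matches_monte_carlo_power(self, rng):
        """Noncentral-F power at the fixture's effect size agrees with a
        brute-force simulation at the same means and pooled SD."""
        means, sd, n = (0.0, 1.2, 0.0), 1.0, 10
        fixture = {
            k: rng.normal(mu, sd, n) for k, mu in zip("ABC", means)
        }
        analytic = observed_power(fixture)
        # oracle: resample at the *sample* means/SD of the fixture
        mus = [v.mean() for v in fixture.values()]
        pooled = np.sqrt(np.mean([v.var(ddof=1) for v in fixture.values()]))
        hits = 0
        n_sim = 1500
        for _ in range(n_sim):
            sim = [rng.normal(mu, pooled, n) for mu in mus]
            if sps.f_oneway(*sim).pvalue <= 0.05:
                hits += 1
        rate = hits / n_sim
        ci = 1.96 * np.sqrt(rate * (1 - rate) / n_sim)
        assert abs(analytic - rate) < ci + 0.03


class TestBuildReport:
    @staticmethod
    def _cohort(rng, n=8, groups=("Reference", "MA", "BIO")):
        rows = []
        for g in groups:
            for i in range(n):
                rows.append(
                    {
                        "specimen_id": f"{g}-{i}",
                        "group": g,
                        "correction_deg": 0 if g == "Reference" else (10 if i < n // 2 else 20),
                        "subchondral_bmd": rng.normal(220, 30),
                        "vault_bmd": rng.normal(400, 40),
                        "global_bmd": rng.normal(370, 40),
                        "subchondral_bvtv": rng.uniform(0.4, 0.8),
                        "vault_bvtv": rng.uniform(0.5, 0.9),
                        "global_bvtv": rng.uniform(0.6, 0.9),
                        "micromotion_pre_um": rng.normal(45, 10),
                        "micromotion_post_um": rng.normal(60, 12),
                        "micromotion_delta_um": rng.normal(15, 5),
                        "rotation_pre_deg": rng.normal(0.1, 0.02),
                        "rotation_post_deg": rng.normal(0.12, 0.02),
                        "rotation_delta_deg": rng.normal(0.02, 0.01),
                    }
                )
        return pd.DataFrame(rows)

    def test_density_table_schema(self, rng):
        tables = build_report(self._cohort(rng))
        density = tables["density"]
        assert len(density) == 6  # three BMD + three BV/TV variables
        for g in ("Reference", "MA", "BIO"):
            assert f"{g}_mean" in density.columns
            assert f"{g}_sd" in density.columns
        assert "BIO_vs_MA_p" in density.columns or "MA_vs_BIO_p" in density.columns
        assert "omnibus_p" in density.columns

    def test_single_group_descriptives_only(self, rng):
        tables = build_report(self._cohort(rng, groups=("Reference",)))
        assert "omnibus_p" not in tables["density"].columns
        assert tables["correlation"].empty or "pearson_r" in tables["correlation"]

    def test_deterministic_for_same_cohort(self, rng):
        cohort = self._cohort(rng)
        t1 = build_report(cohort.copy())
        t2 = build_report(cohort.copy())
        for name in t1:
            pd.testing.assert_frame_equal(t1[name], t2[name])

    def test_empty_cohort_rejected(self):
        with pytest.raises(StatsError):
            build_report(pd.DataFrame())
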