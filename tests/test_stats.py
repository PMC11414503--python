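"""Regressions, rank statistics, subject aggregation, consistency report."""

import numpy as np
import pandas as pd
import pytest

from plaquemorph.cohort import CohortSpec, make_cohort
from plaquemorph.stats import (
    compare_groups,
    consistency_report,
    describe,
    fit_linear,
    fit_power,
    levene,
    scheirer_ray_hare,
    spearman,
    subject_summary,
)


class TestFitLinear:
    def test_exact_line(self):
        x = np.arange(1.0, 11.0)
        res = fit_linear(x, 2 * x + 1)
        assert res.b == pytest.approx(2.0, abs=1e-12)
        assert res.a == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_null_relationship(self, rng):
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        assert fit_linear(x, y).r_squared < 0.01

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(1, 10, size=17)
        y = rng.normal(3 * x - 2, 1.5)
        res = fit_linear(x, y)
        # closed-form normal equations
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.a == pytest.approx(beta[0], abs=1e-10)
        assert res.b == pytest.approx(beta[1], abs=1e-10)
        resid = y - X @ beta
        r2 = 1 - (resid @ resid) / np.sum((y - y.mean()) ** 2)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear(np.ones(5), np.arange(5.0))


class TestFitPower:
    def test_exact_power_recovery(self):
        x = np.linspace(1, 9, 20)
        res = fit_power(x, 2.0 * x**1.5)
        assert res.a == pytest.approx(2.0, rel=1e-6)
        assert res.b == pytest.approx(1.5, rel=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_sphere_family_two_thirds_exponent(self):
        r = np.linspace(1, 10, 25)
        vol = 4 / 3 * np.pi * r**3
        area = 4 * np.pi * r**2
        res = fit_power(vol, area)
        assert res.b == pytest.approx(2 / 3, abs=0.01)
        assert res.r_squared >= 0.999

    def test_multiplicative_noise_power_beats_linear(self):
        wins = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = np.exp(rng.normal(5.2, 0.85, size=112))
            y = 0.5 * x**1.5 * np.exp(rng.normal(0, 0.25, size=112))
            if fit_power(x, y).r_squared >= fit_linear(x, y).r_squared:
                wins += 1
        assert wins / n_seeds >= 0.90

    def test_nonpositive_input_named(self):
        with pytest.raises(ValueError, match="indices \\[2\\]"):
            fit_power(np.array([1.0, 2.0, -1.0, 3.0]), np.array([1.0, 2, 3, 4]))


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        up = spearman(x, x**3 + 1)
        assert up.rho == pytest.approx(1.0)
        assert up.label == "strong"
        down = spearman(x, -x)
        assert down.rho == pytest.approx(-1.0)

    def test_ties_match_midrank_pearson_oracle(self, rng):
        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(0, 4, size=30).astype(float) + 0.5 * x
        res = spearman(x, y)
        # brute-force: Pearson correlation of midranks
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(oracle, abs=1e-12)

    def test_label_boundary_strictly_greater(self):
        from plaquemorph.stats import CorrelationResult

        assert CorrelationResult(rho=0.5, p_value=0.001, n=40).label == "none"
        assert CorrelationResult(rho=0.51, p_value=0.001, n=40).label == "significant"
        assert CorrelationResult(rho=0.8, p_value=0.001, n=40).label == "significant"
        assert CorrelationResult(rho=0.81, p_value=0.001, n=40).label == "strong"
        assert CorrelationResult(rho=0.9, p_value=0.2, n=4).label == "none"

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        base = spearman(x, y)
        trans = spearman(np.exp(x), y**3)
        assert trans.rho == pytest.approx(base.rho, abs=1e-12)


class TestDescribe:
    def test_normal_small_sample_mean_sd(self):
        d = describe([1.0, 2.0, 3.0, 4.0, 5.0])
        assert d["normality_test"] == "shapiro_wilk"
        assert d["format"] == "mean_sd"
        assert d["text"] == "3.00 ± 1.58"

    def test_skewed_sample_median_iqr(self, rng):
        x = np.exp(rng.normal(0, 1.5, size=45))
        d = describe(x)
        assert d["format"] == "median_iqr"

    def test_large_sample_uses_ks_gate(self, rng):
        d = describe(rng.normal(10, 2, size=51))
        assert d["normality_test"] == "kolmogorov_smirnov"


class TestCompareGroups:
    def test_identical_groups_nonsignificant(self, rng):
        g = np.concatenate([np.zeros(20), np.ones(20)])
        x = np.tile(rng.normal(5, 1, size=20), 2)
        res = compare_groups(x, g)
        assert res.p_value > 0.9

    def test_u_statistic_matches_pair_counting(self, rng):
        x1 = rng.normal(0, 1, size=8)
        x2 = np.round(rng.normal(0.5, 1, size=7), 1)
        x = np.concatenate([x1, x2])
        g = np.array([0] * 8 + [1] * 7)
        res = compare_groups(x, g)
        if res.test_used == "mann_whitney":
            u = sum(
                1.0 if a > b else (0.5 if a == b else 0.0) for a in x1 for b in x2
            )
            assert res.statistic == pytest.approx(u, abs=1e-10)

    def test_one_skewed_group_forces_mann_whitney(self, rng):
        skew = np.exp(rng.normal(0, 2, size=30))
        norm = rng.normal(5, 1, size=30)
        res = compare_groups(
            np.concatenate([skew, norm]), np.array(["a"] * 30 + ["b"] * 30)
        )
        assert res.test_used == "mann_whitney"

    def test_more_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            compare_groups(np.arange(9.0), np.array([0, 1, 2] * 3))


class TestLevene:
    def test_equal_variance_null(self, rng):
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(5, 1, 200)])
        g = np.array([0] * 200 + [1] * 200)
        assert levene(x, g) > 0.05

    def test_detects_variance_ratio_100(self):
        detected = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.normal(0, 1, 50), rng.normal(0, 10, 50)])
            g = np.array([0] * 50 + [1] * 50)
            detected += levene(x, g) < 0.05
        assert detected >= 49

    def test_matches_textbook_formula(self):
        # fixed 2x5 table; classic Levene with centre = mean
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0, 2.0, 2.5, 3.0, 3.5, 4.0])
        g = np.array([0] * 5 + [1] * 5)
        z = np.abs(x - np.array([x[:5].mean()] * 5 + [x[5:].mean()] * 5))
        zbar = z.mean()
        zg = [z[:5].mean(), z[5:].mean()]
        num = 5 * ((zg[0] - zbar) ** 2 + (zg[1] - zbar) ** 2) / (2 - 1)
        den = (np.sum((z[:5] - zg[0]) ** 2) + np.sum((z[5:] - zg[1]) ** 2)) / (10 - 2)
        from scipy.stats import f

        p_oracle = float(f.sf(num / den, 1, 8))
        assert levene(x, g) == pytest.approx(p_oracle, abs=1e-10)


def _srh_oracle(y, a, b):
    """Rank-transform + sequential ANOVA via statsmodels, coded separately."""
    import statsmodels.api as sm
    from scipy.stats import chi2, rankdata
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"r": rankdata(y), "A": pd.Categorical(a), "B": pd.Categorical(b)})
    model = ols("r ~ C(A) + C(B) + C(A):C(B)", df).fit()
    tab = sm.stats.anova_lm(model, typ=1)
    n = len(df)
    ss_total = np.sum((df["r"] - df["r"].mean()) ** 2)
    ms_total = ss_total / (n - 1)
    H = tab["sum_sq"][:3].to_numpy() / ms_total
    dfs = tab["df"][:3].to_numpy()
    p = chi2.sf(H, dfs)
    return H, p


class TestScheirerRayHare:
    def test_degenerate_identical_values(self):
        res = scheirer_ray_hare(
            np.ones(12), np.repeat([0, 1], 6), np.tile([0, 1, 2], 4)
        )
        assert res.H_A == res.H_B == res.H_interaction == 0.0
        assert res.p_A == res.p_B == res.p_interaction == 1.0

    def test_additive_a_effect_dominates(self):
        rng = np.random.default_rng(3)
        a = np.repeat([0, 1], 20)
        b = np.tile([0, 1], 20)
        y = 5.0 * a + rng.normal(0, 1, size=40)
        res = scheirer_ray_hare(y, a, b)
        assert res.H_A > res.H_B
        assert res.H_A > res.H_interaction
        assert res.p_A < 0.001

    def test_matches_independent_decomposition(self, rng):
        # fixed 12-observation unbalanced-ish table with ties
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0, 5.0, 9.0])
        a = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        b = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        res = scheirer_ray_hare(y, a, b)
        H, p = _srh_oracle(y, a, b)
        assert res.H_A == pytest.approx(H[0], abs=1e-10)
        assert res.H_B == pytest.approx(H[1], abs=1e-10)
        assert res.H_interaction == pytest.approx(H[2], abs=1e-10)
        assert res.p_A == pytest.approx(p[0], abs=1e-10)
        assert res.df_A == 2 and res.df_B == 1 and res.df_interaction == 2

    def test_ss_decomposition_sums_to_total(self, rng):
        y = rng.normal(size=30)
        a = rng.integers(0, 3, size=30)
        b = rng.integers(0, 2, size=30)
        res = scheirer_ray_hare(y, a, b)
        total = res.ss["A"] + res.ss["B"] + res.ss["interaction"] + res.ss["within"]
        assert total == pytest.approx(res.ss["total"], abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        y = rng.normal(size=24)
        a = rng.integers(0, 2, size=24)
        b = rng.integers(0, 3, size=24)
        r1 = scheirer_ray_hare(y, a, b)
        r2 = scheirer_ray_hare(np.exp(y), a, b)
        assert r2.H_A == pytest.approx(r1.H_A, abs=1e-10)
        assert r2.H_interaction == pytest.approx(r1.H_interaction, abs=1e-10)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError, match="2 levels"):
            scheirer_ray_hare(np.arange(8.0), np.zeros(8), np.tile([0, 1], 4))


class TestSubjectSummary:
    def test_single_plaque(self):
        p = pd.DataFrame({"volume_mm3": [100.0], "surface_area_mm2": [120.0]})
        s = subject_summary(p, None)
        assert s.TPV == s.MPV == 100.0
        assert s.TPSA == s.MPSA == 120.0
        assert s.PVSARmax == s.PVSARmean == s.PVSARmin == s.PVSARm == pytest.approx(0.8333, abs=1e-4)
        assert s.TCV == s.RTVCP == 0.0

    def test_two_plaques(self):
        p = pd.DataFrame(
            {"volume_mm3": [100.0, 50.0], "surface_area_mm2": [120.0, 80.0]}
        )
        s = subject_summary(p)
        assert s.TPV == 150.0 and s.MPV == 100.0
        assert s.PVSARmin == pytest.approx(0.625)
        assert s.PVSARm == pytest.approx(0.8333, abs=1e-4)

    def test_matches_naive_reaggregation(self, rng):
        plaques, covs, _ = make_cohort(CohortSpec(n_subjects=8, seed=4))
        for sid, grp in plaques.groupby("subject_id"):
            calcs = pd.DataFrame(
                {
                    "volume_mm3": grp["calc_volume_mm3"],
                    "surface_area_mm2": grp["calc_surface_area_mm2"],
                }
            )
            s = subject_summary(grp, calcs)
            v = grp["volume_mm3"].to_numpy()
            sa = grp["surface_area_mm2"].to_numpy()
            assert s.TPV == pytest.approx(v.sum(), rel=1e-12)
            assert s.MPSA == pytest.approx(sa.max(), rel=1e-12)
            assert s.RTVCP == pytest.approx(grp["calc_volume_mm3"].sum() / v.sum(), rel=1e-12)
            assert s.PVSARm == pytest.approx((v / sa)[np.argmax(v)], rel=1e-12)
            assert s.PVSARmin <= s.PVSARmean <= s.PVSARmax
        assert s.MPV <= s.TPV

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no plaques"):
            subject_summary(pd.DataFrame(columns=["volume_mm3", "surface_area_mm2"]))


class TestConsistencyReport:
    def test_structure_counts(self):
        plaques, covs, _ = make_cohort(CohortSpec(n_subjects=20, seed=2))
        from plaquemorph.pipeline import subject_table_from_plaques

        subjects = subject_table_from_plaques(plaques)
        report = consistency_report(plaques, subjects, covs)
        assert len(report["pairwise_fits"]) == 15
        assert len(report["calcification_fits"]) == 4
        assert "vsar_fit" in report
        assert report["n_tests"] > 0

    def test_scaled_clone_family_all_strong(self):
        # exact similarity family: every pair follows an exact power law
        base_v = 50.0
        scales = np.linspace(1.0, 3.0, 20)
        plaques = pd.DataFrame(
            {
                "subject_id": np.arange(20) // 2,
                "side": ["left", "right"] * 10,
                "volume_mm3": base_v * scales**3,
                "surface_area_mm2": 70.0 * scales**2,
                "length_mm": 8.0 * scales,
                "surface_distance_mm": 10.0 * scales,
                "max_cross_area_mm2": 20.0 * scales**2,
                "max_cross_diameter_mm": 5.0 * scales,
                "calc_volume_mm3": 5.0 * scales**3,
                "calc_surface_area_mm2": 15.0 * scales**2,
            }
        )
        from plaquemorph.pipeline import subject_table_from_plaques

        report = consistency_report(plaques, subject_table_from_plaques(plaques))
        for entry in report["pairwise_fits"]:
            assert entry["significant"]
            assert entry["power"].r_squared == pytest.approx(1.0, abs=1e-6)

    def test_missing_columns_listed(self):
        with pytest.raises(ValueError, match="missing columns"):
            consistency_report(
                pd.DataFrame({"volume_mm3": [1.0]}), pd.DataFrame(), None
            )

    def test_null_covariates_rarely_significant(self):
        # zero-linkage covariates at n=40: the significance label
        # (rho > 0.5) should essentially never fire
        hits = 0
        trials = 0
        for seed in range(20):
            spec = CohortSpec(
                n_subjects=40,
                covariate_rank_corr={"TG": 0.0, "TC": 0.0},
                seed=seed,
            )
            plaques, covs, _ = make_cohort(spec)
            from plaquemorph.pipeline import subject_table_from_plaques

            report = consistency_report(
                plaques, subject_table_from_plaques(plaques), covs
            )
            for cov, row in report["covariate_spearman"].items():
                for f, res in row.items():
                    trials += 1
                    hits += res.label != "none"
        assert hits / trials < 0.10
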