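"""Group tests, effect sizes, FDR, adjustment, regression and mediation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aslhemo.cohort_stats import (adjust_age_sex, bh_fdr, cohen_d,
                                  cohen_d_from_samples, compare_groups,
                                  correlate, fit_regression, mann_whitney_r,
                                  mediate_bootstrap, phi_2x2, prepare_cohort)
from aslhemo.exceptions import DomainError


class TestCohenD:
    def test_equal_means_zero(self):
        assert cohen_d(10.0, 2.0, 30, 10.0, 3.0, 40) == 0.0

    def test_translation_invariance(self):
        d1 = cohen_d(10.0, 2.0, 30, 12.0, 3.0, 40)
        d2 = cohen_d(110.0, 2.0, 30, 112.0, 3.0, 40)
        assert d1 == pytest.approx(d2)

    def test_matches_definition_on_samples(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 1.2, 50)
        d = cohen_d_from_samples(a, b)
        pooled = np.sqrt((39 * a.var(ddof=1) + 49 * b.var(ddof=1)) / 88)
        assert d == pytest.approx((b.mean() - a.mean()) / pooled)

    def test_zero_pooled_sd_undefined(self):
        with pytest.raises(DomainError):
            cohen_d(1.0, 0.0, 10, 1.0, 0.0, 10)


class TestCompareGroups:
    def test_identical_samples_degenerate(self):
        res = compare_groups([2.0] * 5, [2.0] * 6)
        assert res.p_raw == 1.0 and res.effect_value == 0.0

    def test_normal_samples_use_t_with_brute_force_statistic(self, rng):
        a = rng.normal(50, 5, 40)
        b = rng.normal(53, 5, 35)
        res = compare_groups(a, b)
        assert res.test == "t"
        n1, n2 = len(a), len(b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert res.statistic == pytest.approx(t_hand)
        assert res.effect_name == "cohen_d"

    def test_skewed_samples_use_mann_whitney_with_hand_z(self, rng):
        a = rng.exponential(1.0, 45)
        b = rng.exponential(1.8, 40)
        res = compare_groups(a, b)
        assert res.test == "mann_whitney"
        # brute-force z from the rank-sum definition (no ties here)
        n1, n2 = len(a), len(b)
        ranks = stats.rankdata(np.concatenate([a, b]))
        u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        z = (u1 - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert res.effect_value == pytest.approx(abs(z) / np.sqrt(n1 + n2))

    def test_tied_data_effect_uses_tie_correction(self):
        a = [1, 1, 2, 2, 3, 3]
        b = [2, 2, 3, 3, 4, 4]
        r, z = mann_whitney_r(a, b)
        assert 0 < r < 1

    def test_detects_group_gap_at_study_scale(self, rng):
        """Groups simulated at the gray-matter CBF summary statistics
        (54.06 +/- 7.78, n=89 vs 42.52 +/- 7.13, n=42) are separated
        essentially always at alpha = 0.05."""
        rejections = 0
        for _ in range(200):
            sca = rng.normal(54.06, 7.78, 89)
            ctl = rng.normal(42.52, 7.13, 42)
            res = compare_groups(sca, ctl)
            rejections += res.p_raw < 0.05
        assert rejections >= 199

    def test_too_small_groups(self):
        with pytest.raises(DomainError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPhi:
    def test_independent_table_is_zero(self):
        assert phi_2x2([[20, 20], [10, 10]], continuity=False).phi == \
            pytest.approx(0.0)

    def test_matches_exhaustive_chi_square(self):
        table = np.array([[12, 5], [7, 16]], dtype=float)
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        chi2 = ((table - expected) ** 2 / expected).sum()
        res = phi_2x2(table, continuity=False)
        assert res.chi2 == pytest.approx(chi2)
        assert res.phi == pytest.approx(np.sqrt(chi2 / n))

    def test_zero_margin_undefined(self):
        with pytest.raises(DomainError):
            phi_2x2([[0, 0], [5, 7]])


class TestBhFdr:
    def test_equally_spaced_example(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    @staticmethod
    def step_up_oracle(p):
        """Textbook BH step-up: p_(i) * m / i, cumulative min from the top."""
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p, kind="stable")
        scaled = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        return out

    def test_matches_oracle_on_random_families(self, rng):
        for _ in range(20):
            n = rng.integers(1, 30)
            p = rng.random(n)
            fam = rng.integers(0, 3, n)
            got = bh_fdr(p, fam)
            for label in np.unique(fam):
                idx = fam == label
                assert np.allclose(got[idx], self.step_up_oracle(p[idx]))
            assert np.all(got >= p) and np.all(got <= 1)

    def test_rejects_invalid_p(self):
        with pytest.raises(DomainError):
            bh_fdr([0.5, 1.2])


class TestAdjustAgeSex:
    def test_uncorrelated_variable_nearly_unchanged(self, rng):
        n = 500
        age = rng.uniform(8, 28, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = rng.normal(10, 1, n)
        adj = adjust_age_sex(y, age, sex)
        assert np.corrcoef(adj, y)[0, 1] > 0.98
        assert adj.mean() == pytest.approx(y.mean())

    def test_pure_age_effect_removed(self, rng):
        age = rng.uniform(8, 28, 100)
        sex = rng.integers(0, 2, 100).astype(float)
        y = 2.0 * age
        adj = adjust_age_sex(y, age, sex)
        assert np.allclose(adj, y.mean())

    def test_matches_normal_equations(self, rng):
        n = 80
        age = rng.uniform(8, 28, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = 1.5 * age - 3.0 * sex + rng.normal(0, 1, n)
        adj = adjust_age_sex(y, age, sex)
        X = np.column_stack([np.ones(n), age, sex])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(adj, y - X @ beta + y.mean())


class TestCorrelate:
    def test_identity_is_perfect(self, rng):
        x = rng.normal(0, 1, 50)
        res = correlate(x, x)
        assert res.r == pytest.approx(1.0)

    def test_monotone_transform_preserves_spearman(self, rng):
        x = rng.exponential(1, 60)            # skewed -> Spearman gate
        y = rng.exponential(1, 60) + 0.5 * x
        r1 = correlate(x, y)
        r2 = correlate(np.log(x), y)
        assert r1.method == "spearman"
        assert r2.r == pytest.approx(r1.r)

    def test_matches_rank_based_brute_force(self, rng):
        x = rng.exponential(1, 40)
        y = x ** 2 + rng.exponential(0.5, 40)
        res = correlate(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        assert res.r == pytest.approx(np.corrcoef(rx, ry)[0, 1])


class TestFitRegression:
    def make_df(self, rng, n=80, noise=0.0):
        df = pd.DataFrame({
            "x1": rng.normal(0, 1, n),
            "x2": rng.normal(5, 2, n),
            "x3": rng.integers(0, 2, n).astype(float),
        })
        df["y"] = 2.0 + 1.5 * df.x1 - 0.7 * df.x2 + 3.0 * df.x3
        if noise:
            df["y"] += rng.normal(0, noise, n)
        return df

    def test_exact_recovery_without_noise(self, rng):
        df = self.make_df(rng)
        res = fit_regression(df, "y", ["x1", "x2", "x3"])
        assert res.table.loc["x1", "b"] == pytest.approx(1.5)
        assert res.table.loc["x2", "b"] == pytest.approx(-0.7)
        assert res.table.loc["x3", "b"] == pytest.approx(3.0)

    def test_standardized_coefficients_scale_invariant(self, rng):
        df = self.make_df(rng, noise=1.0)
        res1 = fit_regression(df, "y", ["x1", "x2", "x3"])
        df2 = df.assign(x2=df.x2 * 10.0)
        res2 = fit_regression(df2, "y", ["x1", "x2", "x3"])
        assert res2.table.loc["x2", "beta"] == pytest.approx(
            res1.table.loc["x2", "beta"])
        assert res2.table.loc["x2", "p"] == pytest.approx(
            res1.table.loc["x2", "p"])

    def test_vif_and_partial_r_ranges(self, rng):
        df = self.make_df(rng, noise=2.0)
        res = fit_regression(df, "y", ["x1", "x2", "x3"])
        assert (res.table["vif"] >= 1.0).all()
        assert res.table["partial_r"].abs().le(1.0).all()

    def test_singular_design_names_collinear_columns(self, rng):
        df = self.make_df(rng, noise=1.0)
        df["x1_copy"] = df.x1
        with pytest.raises(DomainError, match="x1"):
            fit_regression(df, "y", ["x1", "x1_copy", "x2"])


class TestMediateBootstrap:
    def simulate(self, rng, n=300, a=0.5, b=0.4, direct=0.3, noise=1.0):
        x = rng.normal(0, 1, n)
        m = a * x + rng.normal(0, noise, n)
        y = direct * x + b * m + rng.normal(0, noise, n)
        return x, m, y

    def test_zero_b_path_ci_covers_zero(self, rng):
        x = rng.normal(0, 1, 200)
        m = 0.5 * x + rng.normal(0, 1, 200)
        y = 0.3 * x + rng.normal(0, 1, 200)   # mediator has no effect on y
        res = mediate_bootstrap(x, m, y, n_boot=500, seed=1)
        assert res.ci_low <= 0.0 <= res.ci_high
        assert abs(res.indirect) < 0.1

    def test_large_sample_recovers_planted_paths(self, rng):
        x, m, y = self.simulate(rng, n=2000, noise=0.3)
        res = mediate_bootstrap(x, m, y, n_boot=500, seed=2)
        assert res.indirect == pytest.approx(0.20, abs=0.03)
        assert res.ci_low <= 0.20 <= res.ci_high
        assert res.proportion_mediated == pytest.approx(0.4, abs=0.08)
        # for nested linear models the effects decompose exactly
        assert res.direct + res.indirect == pytest.approx(res.total, rel=1e-9)

    def test_deterministic_given_seed(self, rng):
        x, m, y = self.simulate(rng)
        r1 = mediate_bootstrap(x, m, y, n_boot=200, seed=7)
        r2 = mediate_bootstrap(x, m, y, n_boot=200, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert np.array_equal(r1.boot_indirect, r2.boot_indirect)

    def test_point_estimates_match_independent_package(self, rng):
        pg = pytest.importorskip("pingouin")
        x, m, y = self.simulate(rng, n=250)
        res = mediate_bootstrap(x, m, y, n_boot=200, seed=3)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        ref = pg.mediation_analysis(data=df, x="x", m="m", y="y",
                                    n_boot=200, seed=3).set_index("path")
        assert res.a_path == pytest.approx(ref.loc["m ~ X", "coef"])
        assert res.total == pytest.approx(ref.loc["Total", "coef"])
        assert res.direct == pytest.approx(ref.loc["Direct", "coef"])
        assert res.indirect == pytest.approx(ref.loc["Indirect", "coef"])

    def test_covariates_change_the_paths(self, rng):
        n = 200
        c = rng.normal(0, 1, n)
        x = c + rng.normal(0, 1, n)
        m = 0.5 * x + c + rng.normal(0, 0.5, n)
        y = 0.4 * m + rng.normal(0, 0.5, n)
        plain = mediate_bootstrap(x, m, y, n_boot=100, seed=4)
        adj = mediate_bootstrap(x, m, y, covariates=c, n_boot=100, seed=4)
        assert plain.a_path != pytest.approx(adj.a_path, rel=1e-3)

    def test_validation(self, rng):
        x, m, y = self.simulate(rng, n=30)
        with pytest.raises(DomainError):
            mediate_bootstrap(x[:10], m[:10], y[:10])
        with pytest.raises(DomainError):
            mediate_bootstrap(x, np.zeros_like(m), y)


class TestPrepareCohort:
    def test_group_mean_substitution_and_cao2(self):
        df = pd.DataFrame({
            "group": ["SCA"] * 4 + ["control"] * 4,
            "hemoglobin": [8.0, 9.0, np.nan, 10.0, 13.0, 13.5, 14.0, np.nan],
            "oxygen_saturation": [0.97, np.nan, 0.96, 0.98, 0.98, 0.99,
                                  np.nan, 0.97],
        })
        out = prepare_cohort(df)
        assert out.loc[2, "hemoglobin"] == pytest.approx(9.0)
        assert out.loc[7, "hemoglobin"] == pytest.approx(13.5)
        assert out.loc[1, "oxygen_saturation"] == pytest.approx(0.97)
        expected = 1.34 * 9.0 * 0.96 + 0.3
        assert out.loc[2, "cao2"] == pytest.approx(expected)
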