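"""Inference layer: permutation tests, bootstrap, effect sizes, Bayes
factors, RIN, similarity, matching, windows, models, and mediation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bisensory.stats import (bayes_factor, bootstrap_ci, hedges_g,
                             match_participants, mediation,
                             moving_window_compare, partial_correlation,
                             permutation_test, rin_transform,
                             similarity_matrices)


class TestPermutationTest:
    def test_identical_groups_not_significant(self):
        x = np.tile(np.arange(10.0), (2, 1)).T
        res = permutation_test(x[:, :1], x[:, :1] + 0.0, n_perm=500, seed=0)
        assert res.p_perm[0] > 0.5

    def test_single_variable_tmax_equals_uncorrected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.3, 1, (25, 1))
        a = permutation_test(x, n_perm=2000, correction="tmax", seed=2)
        b = permutation_test(x, n_perm=2000, correction="none", seed=2)
        assert a.p_perm[0] == b.p_perm[0]

    def test_p_values_in_valid_range(self):
        rng = np.random.default_rng(3)
        res = permutation_test(rng.normal(2, 1, (20, 4)), n_perm=99, seed=4)
        assert (res.p_perm >= 1 / 100).all() and (res.p_perm <= 1).all()

    def test_two_sample_detects_shift(self):
        rng = np.random.default_rng(5)
        x = rng.normal(1.0, 1, (30, 1))
        y = rng.normal(0.0, 1, (30, 1))
        res = permutation_test(x, y, n_perm=1000, seed=6)
        assert res.p_perm[0] < 0.01

    def test_null_p_distribution_stochastically_uniform(self):
        """Under H0, P(p <= alpha) <= alpha (+MC error) for valid tests."""
        rng = np.random.default_rng(7)
        ps = [permutation_test(rng.standard_normal((12, 1)), n_perm=499,
                               seed=rng.integers(2 ** 31)).p_perm[0]
              for _ in range(600)]
        ps = np.asarray(ps)
        for alpha in (0.05, 0.1, 0.25):
            assert (ps <= alpha).mean() <= alpha + 2.5 * np.sqrt(
                alpha * (1 - alpha) / 600)

    def test_invalid_n_perm(self):
        with pytest.raises(ValueError):
            permutation_test(np.ones((5, 1)), n_perm=0)


class TestBootstrapCI:
    def test_constant_data_zero_width(self):
        lo, hi = bootstrap_ci(np.full(20, 3.3), np.mean, n_boot=100, seed=0)
        assert lo == hi == pytest.approx(3.3)

    def test_contains_truth_typically(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5, 2, 200)
        lo, hi = bootstrap_ci(x, np.mean, n_boot=999, seed=2)
        assert lo < 5.3 and hi > 4.7 and lo < hi

    def test_skewed_data_asymmetric_interval(self):
        """BCa shifts the interval toward the skew relative to the naive
        percentile interval."""
        rng = np.random.default_rng(3)
        x = rng.exponential(1.0, 60)
        lo, hi = bootstrap_ci(x, np.mean, n_boot=3999, seed=4)
        m = x.mean()
        assert (hi - m) > (m - lo)   # right-skewed: longer upper arm

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0, 2.0], np.mean)


class TestHedgesG:
    def test_identical_samples_zero(self):
        x = np.arange(10.0)
        g, _ = hedges_g(x, x, n_boot=0)
        assert g == pytest.approx(0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        g1, _ = hedges_g(x, y, n_boot=0)
        g2, _ = hedges_g(y, x, n_boot=0)
        assert g1 == pytest.approx(-g2)

    def test_calibration_against_population_d(self):
        """Median estimate over replicates sits within 0.05 of d = 0.5."""
        rng = np.random.default_rng(1)
        gs = [hedges_g(rng.normal(0.5, 1, 200), rng.normal(0, 1, 200),
                       n_boot=0)[0] for _ in range(300)]
        assert abs(np.median(gs) - 0.5) < 0.05

    def test_matches_reference_implementation(self):
        import pingouin as pg

        rng = np.random.default_rng(2)
        x, y = rng.normal(0.4, 1, 25), rng.normal(0, 1.2, 35)
        g, _ = hedges_g(x, y, n_boot=0)
        assert g == pytest.approx(pg.compute_effsize(x, y, eftype="hedges"),
                                  abs=1e-10)

    def test_zero_pooled_sd_flagged(self):
        with pytest.warns(UserWarning):
            g, ci = hedges_g(np.full(5, 1.0), np.full(5, 1.0), n_boot=0)
        assert np.isnan(g)


class TestBayesFactor:
    def test_zero_effect_favours_null(self):
        assert bayes_factor(t=0.0, nx=30, ny=30) > 1

    def test_monotone_decreasing_in_t(self):
        bfs = [bayes_factor(t=t, nx=25, ny=25) for t in (0.0, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(bfs, bfs[1:]))

    def test_large_effect_from_samples(self):
        rng = np.random.default_rng(0)
        bf01 = bayes_factor(rng.normal(1.5, 1, 40), rng.normal(0, 1, 40))
        assert bf01 < 1 / 3


class TestRIN:
    def test_monotone_and_centred(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(2, 101)
        z = rin_transform(x)
        assert (np.argsort(z) == np.argsort(x)).all()
        assert abs(z.mean()) < 1e-10

    def test_spearman_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(1, 80)
        y = x ** 2 + rng.normal(0, 0.5, 80)
        r0 = sps.spearmanr(x, y).statistic
        r1 = sps.spearmanr(rin_transform(x), rin_transform(y)).statistic
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            rin_transform(np.ones(10))


class TestSimilarityMatrices:
    def test_self_comparison_is_perfect(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0, 0.05, (30, 20))
        ages = rng.uniform(6, 20.9, 30)
        rmse, corr, trace = similarity_matrices(d, ages)
        # a subject compared with itself: rmse 0, corr 1; excluded from the
        # diagonal averages, so check the raw pairwise building block
        from numpy.testing import assert_allclose
        assert_allclose(np.sqrt(((d[0] - d[0]) ** 2).mean()), 0.0)
        assert np.isfinite(rmse[np.isfinite(rmse)]).all()
        assert (corr[np.isfinite(corr)] <= 1.0 + 1e-12).all()

    def test_lag_pushes_trace_above_diagonal(self):
        """Two groups whose difference functions follow the same age profile
        offset by ~5 years: the row-wise argmin sits ~2 bins above."""
        rng = np.random.default_rng(1)
        n = 120
        ages = rng.uniform(6, 20.9, n)
        groups = np.array(["NT", "ASD"])[rng.integers(0, 2, n)]
        shape = np.sin(np.linspace(0, np.pi, 20))
        eff_age = np.where(groups == "ASD", np.maximum(ages - 5, 6), ages)
        d = (0.02 * (eff_age[:, None] - 6) * shape[None, :]
             + rng.normal(0, 0.01, (n, 20)))
        rmse, corr, trace = similarity_matrices(d, ages, groups=groups)
        rows = np.arange(len(trace["rmse_argmin"]))
        used = (trace["rmse_argmin"] >= 0) & (rows >= 2)
        offset = (rows - trace["rmse_argmin"])[used].mean()
        assert offset >= 1.0


class TestMatching:
    def pool(self):
        return pd.DataFrame({
            "subject_id": [f"c{i}" for i in range(6)],
            "sex": ["F", "F", "M", "M", "F", "M"],
            "age_years": [8.0, 12.0, 8.0, 12.0, 20.0, 20.0],
            "piq": [100.0, 110.0, 100.0, 110.0, 120.0, 95.0],
        })

    def test_exact_duplicates_selected(self):
        cases = self.pool().copy()
        cases["subject_id"] = [f"x{i}" for i in range(6)]
        m = match_participants(cases, self.pool())
        assert (m["distance"] == 0).all()
        assert m["control_id"].is_unique

    def test_tie_broken_by_lower_id(self):
        pool = pd.DataFrame({
            "subject_id": ["c9", "c2"], "sex": ["M", "M"],
            "age_years": [10.0, 10.0], "piq": [100.0, 100.0]})
        case = pd.DataFrame({"subject_id": ["x0"], "sex": ["M"],
                             "age_years": [10.0], "piq": [100.0]})
        m = match_participants(case, pool)
        assert m["control_id"].iloc[0] == "c2"

    def test_no_same_sex_control_flagged(self):
        case = pd.DataFrame({"subject_id": ["x0"], "sex": ["F"],
                             "age_years": [10.0], "piq": [100.0]})
        pool = pd.DataFrame({"subject_id": ["c0"], "sex": ["M"],
                             "age_years": [10.0], "piq": [100.0]})
        m = match_participants(case, pool)
        assert m["control_id"].isna().all()

    def test_matching_beats_random_subsets_on_age(self):
        rng = np.random.default_rng(0)
        n_case, n_pool = 20, 80
        cases = pd.DataFrame({
            "subject_id": [f"x{i}" for i in range(n_case)],
            "sex": rng.choice(["F", "M"], n_case),
            "age_years": rng.uniform(6, 40, n_case),
            "piq": rng.normal(105, 12, n_case)})
        pool = pd.DataFrame({
            "subject_id": [f"c{i}" for i in range(n_pool)],
            "sex": rng.choice(["F", "M"], n_pool),
            "age_years": rng.uniform(6, 40, n_pool),
            "piq": rng.normal(105, 12, n_pool)})
        m = match_participants(cases, pool)
        matched = pool.set_index("subject_id").loc[m["control_id"].dropna()]
        gap_matched = abs(matched["age_years"].mean()
                          - cases["age_years"].mean())
        gaps_random = [abs(pool.sample(n_case, random_state=i)["age_years"]
                           .mean() - cases["age_years"].mean())
                       for i in range(100)]
        assert gap_matched < np.mean(gaps_random)


class TestMovingWindow:
    def test_step_larger_than_range_single_window(self):
        rng = np.random.default_rng(0)
        n = 40
        vals = pd.Series(rng.normal(0, 1, n))
        ages = pd.Series(rng.uniform(10, 16, n))
        grp = pd.Series(np.array(["NT", "ASD"])[rng.integers(0, 2, n)])
        win = moving_window_compare(vals, ages, grp, window=10.0, step=20.0,
                                    age_range=(10.0, 16.0), n_perm=200,
                                    n_boot=200, seed=1)
        assert len(win) == 1

    def test_identical_groups_no_significant_windows(self):
        rng = np.random.default_rng(1)
        n = 120
        ages = pd.Series(rng.uniform(6, 26, n))
        vals = pd.Series(rng.normal(0, 1, n))
        grp = pd.Series(np.array(["NT", "ASD"])[rng.integers(0, 2, n)])
        win = moving_window_compare(vals, ages, grp, n_perm=500, n_boot=200,
                                    seed=2)
        assert not win["significant"].any()
        assert win["bf01"].median() > 1


class TestPartialCorrelation:
    def test_variable_equal_to_covariate_gives_zero(self):
        rng = np.random.default_rng(0)
        c = rng.normal(0, 1, 50)
        x = rng.normal(0, 1, 50)
        r, p = partial_correlation(x, c + 1e-9 * rng.normal(size=50), c,
                                   n_perm=200, seed=1)
        assert abs(r) < 0.25 and p > 0.01

    def test_constant_covariate_equals_plain_correlation(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 40), rng.normal(0, 1, 40)
        r, _ = partial_correlation(x, y, np.full(40, 2.0), n_perm=100, seed=2)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_shared_variance_detected(self):
        rng = np.random.default_rng(2)
        c = rng.normal(0, 1, 80)
        latent = rng.normal(0, 1, 80)
        x = c + latent + rng.normal(0, 0.3, 80)
        y = 0.5 * c + latent + rng.normal(0, 0.3, 80)
        r, p = partial_correlation(x, y, c, n_perm=500, seed=3)
        assert r > 0.5 and p < 0.01

    def test_matches_reference_implementation(self):
        import pingouin as pg

        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(0, 1, 60),
                           "y": rng.normal(0, 1, 60),
                           "c": rng.normal(0, 1, 60)})
        df["y"] += 0.5 * df["x"] + 0.3 * df["c"]
        r, _ = partial_correlation(df.x, df.y, df.c, n_perm=50, seed=4)
        ref = pg.partial_corr(df, x="x", y="y", covar="c")["r"].iloc[0]
        assert r == pytest.approx(ref, abs=1e-6)


class TestMediation:
    def triple(self, rng, n=200, direct=0.4, indirect=0.5, noise=0.6):
        age = rng.normal(0, 1, n)
        med = indirect * age + rng.normal(0, noise, n)
        out = direct * age + 0.6 * med + rng.normal(0, noise, n)
        return age, med, out

    def test_path_algebra_identity(self):
        """a*b + c' = c exactly for the z-scored OLS system."""
        rng = np.random.default_rng(0)
        age, med, out = self.triple(rng)
        res = mediation(age, med, out, n_boot=200, seed=1)
        assert res.mediated_ab + res.path_c_prime == pytest.approx(
            res.path_c, abs=1e-10)

    def test_null_mediator_gives_direct_only(self):
        rng = np.random.default_rng(1)
        age = rng.normal(0, 1, 200)
        med = rng.normal(0, 1, 200)             # independent of age
        out = 0.6 * age + rng.normal(0, 0.6, 200)
        res = mediation(age, med, out, n_boot=500, seed=2)
        assert abs(res.mediated_ab) < 0.1
        assert res.p["c_prime"] < 0.05
        assert res.classification == "none"

    def test_full_mediation_classified(self):
        rng = np.random.default_rng(2)
        age = rng.normal(0, 1, 200)
        med = 0.7 * age + rng.normal(0, 0.5, 200)
        out = 0.8 * med + rng.normal(0, 0.5, 200)   # no direct path
        res = mediation(age, med, out, n_boot=500, seed=3)
        assert res.classification == "full"

    def test_partial_mediation_classified(self):
        rng = np.random.default_rng(3)
        age, med, out = self.triple(rng, n=300)
        res = mediation(age, med, out, n_boot=500, seed=4)
        assert res.classification == "partial"
        assert res.p["ab"] < 0.05 and res.p["c_prime"] < 0.05

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            mediation(np.ones(20), np.arange(20.0), np.arange(20.0),
                      n_boot=10)


class TestModels:
    def test_lmm_recovers_group_age_condition_signs(self, small_cohort):
        from bisensory.stats import fit_rt_lmm

        subjects, trials = small_cohort
        coefs, fit = fit_rt_lmm(trials[trials.rt_ms.notna()], subjects)
        assert coefs.loc["group_c", "coef"] > 0          # ASD slower
        assert coefs.loc["age_years", "coef"] < 0        # older faster
        # unisensory conditions slower than the AV reference
        cond_rows = [i for i in coefs.index if "condition" in i]
        assert all(coefs.loc[i, "coef"] > 0 for i in cond_rows)

    def test_ancova_detects_group_dependent_slope(self):
        from bisensory.stats import ancova_benefit_correlation

        rng = np.random.default_rng(0)
        rows = []
        for g, slope in (("young", 0.2), ("old", 1.0)):
            pred = rng.normal(0.1, 0.03, 60)
            emp = slope * pred + rng.normal(0, 0.01, 60)
            rows.append(pd.DataFrame({"pred": pred, "emp": emp, "grp": g}))
        d = pd.concat(rows)
        out = ancova_benefit_correlation(d["pred"], d["emp"], d["grp"])
        assert out["interaction_p"] < 0.01
        assert out["group_r"]["old"] > out["group_r"]["young"]

    def test_ancova_single_group_reduces_to_regression(self):
        from bisensory.stats import ancova_benefit_correlation

        rng = np.random.default_rng(1)
        pred = rng.normal(0.1, 0.03, 40)
        emp = 0.8 * pred + rng.normal(0, 0.02, 40)
        out = ancova_benefit_correlation(pred, emp, ["all"] * 40)
        assert out["p_slope"] < 0.01
        assert np.isnan(out["interaction_p"])
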