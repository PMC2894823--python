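"""OLS engine, t-tests, Bonferroni bookkeeping, filters and the GWAS loop."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, special

from cnvgwas import (
    AssociationConfig,
    CnvrGwas,
    PhenotypeTable,
    SubjectFilter,
    apply_filters,
    bonferroni_threshold,
    build_design_matrix,
    fit_ols,
    run_combined_snp_cnvr,
    run_gwas,
    simulate_null_gwas_inputs,
    t_test_pvalue,
)
from cnvgwas.errors import (
    CollinearityError,
    ConfigError,
    InsufficientDataError,
    MonomorphicRegionError,
)


def _phenos(data, ids=None):
    ids = ids or [f"S{i}" for i in range(len(next(iter(data.values()))))]
    return PhenotypeTable(pd.DataFrame(data, index=pd.Index(ids, name="subject_id")))


class TestFitOls:
    def test_exact_linear_fit_recovered(self):
        x = np.arange(5.0)
        X = np.column_stack([np.ones(5), x])
        y = 2.0 + 3.0 * x
        fit = fit_ols(X, y, ["intercept", "x"])
        assert fit.params == pytest.approx([2.0, 3.0], abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.bse == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_duplicated_column_raises_collinearity_naming_it(self):
        x = np.arange(6.0)
        X = np.column_stack([np.ones(6), x, x])
        with pytest.raises(CollinearityError) as err:
            fit_ols(X, x, ["intercept", "x", "x_copy"])
        assert err.value.columns  # a column is named

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            fit_ols(np.ones((2, 2)), np.ones(2))

    @given(st.integers(0, 999))
    def test_agrees_with_reference_least_squares(self, seed):
        """Independent oracle: statsmodels OLS on random well-conditioned data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        n, k = 50, 4
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
        beta = rng.normal(size=k)
        y = X @ beta + rng.normal(size=n)
        mine = fit_ols(X, y)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(mine.params, ref.params, rtol=1e-8)
        np.testing.assert_allclose(mine.bse, ref.bse, rtol=1e-8)
        assert mine.df_resid == int(ref.df_resid)


class TestTTestPvalue:
    def test_zero_effect_gives_one(self):
        assert t_test_pvalue(0.0, 0.3, 10) == 1.0

    def test_perfect_fit_degenerate_cases(self):
        assert t_test_pvalue(1.0, 0.0, 10) == 0.0
        assert t_test_pvalue(0.0, 0.0, 10) == 1.0

    def test_matches_quadrature_of_t_density(self):
        # independent oracle: numerically integrate the t density tail
        df = 10

        def density(x):
            c = special.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * special.gamma(df / 2))
            return c * (1 + x * x / df) ** (-(df + 1) / 2)

        tail, _ = integrate.quad(density, 2.0, np.inf)
        assert t_test_pvalue(2.0, 1.0, df) == pytest.approx(2 * tail, abs=1e-8)

    def test_invalid_df(self):
        with pytest.raises(ConfigError):
            t_test_pvalue(1.0, 1.0, 0)


class TestBonferroni:
    def test_direct_formula(self):
        assert bonferroni_threshold(0.05, 1000) == pytest.approx(5e-5)
        assert bonferroni_threshold(0.05, 1) == 0.05
        # at a genome-wide region count in the tens of thousands the cut-off
        # drops below 2e-6
        assert bonferroni_threshold(0.05, 25007) == pytest.approx(0.05 / 25007)

    def test_zero_tests_rejected(self):
        with pytest.raises(ConfigError):
            bonferroni_threshold(0.05, 0)


class TestSubjectFilters:
    def test_no_filters_keeps_everyone(self):
        phenos = _phenos({"sex": [1.0, 1.0, 2.0]})
        assert apply_filters(phenos, []) == ["S0", "S1", "S2"]

    def test_equality_filter(self):
        phenos = _phenos({"sex": [1.0, 1.0, 2.0]})
        assert apply_filters(phenos, [SubjectFilter.parse("sex==1")]) == ["S0", "S1"]

    def test_contradictory_filters_empty(self):
        phenos = _phenos({"x": [1.0, 2.0]})
        got = apply_filters(phenos, [SubjectFilter("x", "<", 0.0), SubjectFilter("x", ">", 0.0)])
        assert got == []

    def test_missing_value_never_satisfies(self):
        phenos = _phenos({"sex": [1.0, float("nan")]})
        assert apply_filters(phenos, [SubjectFilter("sex", "!=", 2.0)]) == ["S0"]

    def test_unknown_column_raises(self):
        phenos = _phenos({"sex": [1.0]})
        with pytest.raises(ConfigError, match="nope"):
            apply_filters(phenos, [SubjectFilter("nope", "==", 1.0)])

    def test_parse_rejects_garbage(self):
        with pytest.raises(ConfigError):
            SubjectFilter.parse("sex=male")


class TestDesignMatrix:
    def test_columns_and_shape(self):
        phenos = _phenos({"y": [1.0, 2, 3, 4, 5], "age": [30.0, 40, 50, 60, 70]})
        state = pd.Series([0.0, -1, 0, -1, 0], index=phenos.subject_ids)
        cfg = AssociationConfig(phenotype="y", covariates=("age",))
        X, y, names, used = build_design_matrix(state, phenos, cfg, phenos.subject_ids)
        assert X.shape == (5, 3)
        assert names == ("intercept", "state", "age")
        assert used == phenos.subject_ids

    def test_complete_case_drops_missing_covariate(self):
        phenos = _phenos({"y": [1.0, 2, 3, 4, 5],
                          "age": [30.0, np.nan, 50, 60, 70]})
        state = pd.Series([0.0, -1, 0, -1, 0], index=phenos.subject_ids)
        cfg = AssociationConfig(phenotype="y", covariates=("age",))
        X, y, _, used = build_design_matrix(state, phenos, cfg, phenos.subject_ids)
        assert X.shape == (4, 3) and "S1" not in used

    def test_monomorphic_state_flagged(self):
        phenos = _phenos({"y": [1.0, 2, 3]})
        state = pd.Series([0.0, 0.0, 0.0], index=phenos.subject_ids)
        cfg = AssociationConfig(phenotype="y")
        with pytest.raises(MonomorphicRegionError, match="monomorphic"):
            build_design_matrix(state, phenos, cfg, phenos.subject_ids)

    def test_phenotype_cannot_be_covariate(self):
        with pytest.raises(ConfigError):
            AssociationConfig(phenotype="y", covariates=("y",))


def _null_fit(n_subjects=60, n_regions=12, seed=0, **cfg_kw):
    states, phenos = simulate_null_gwas_inputs(n_subjects, n_regions, seed=seed)
    cfg = AssociationConfig(phenotype="y", **cfg_kw)
    return states, phenos, run_gwas(states.regions, states, phenos, cfg)


class TestRunGwas:
    def test_one_result_per_testable_region_sorted(self):
        states, _, res = _null_fit()
        assert res.m_tested + len(res.skipped) == len(states.regions)
        starts = [r.start_pos for r in res.results]
        assert starts == sorted(starts)

    def test_significance_flags_match_bonferroni_rule(self):
        _, _, res = _null_fit()
        thr = res.alpha / res.m_tested
        for r in res.results:
            assert r.significant == (r.p_value < thr)

    def test_changing_alpha_rescales_flags_without_refit(self):
        _, _, res = _null_fit()
        before = [(r.beta, r.se, r.p_value) for r in res.results]
        res.set_alpha(0.5)
        assert [(r.beta, r.se, r.p_value) for r in res.results] == before
        for r in res.results:
            assert r.significant == (r.p_value < 0.5 / res.m_tested)

    def test_subject_permutation_changes_no_statistic(self):
        states, phenos, res = _null_fit()
        rng = np.random.default_rng(3)
        perm = rng.permutation(phenos.subject_ids).tolist()
        phenos2 = PhenotypeTable(phenos.frame.loc[perm])
        res2 = run_gwas(states.regions, states, phenos2, AssociationConfig(phenotype="y"))
        assert [(r.region_id, r.beta, r.se, r.p_value) for r in res.results] == [
            (r.region_id, r.beta, r.se, r.p_value) for r in res2.results
        ]

    def test_filtered_out_subject_changes_no_statistic(self):
        states, phenos, res = _null_fit()
        extra = phenos.frame.copy()
        extra.loc["ZZZZ"] = [99.0]
        extra["keep"] = [1.0] * len(phenos.frame) + [0.0]
        phenos2 = PhenotypeTable(extra)
        res2 = run_gwas(
            states.regions, states, phenos2,
            AssociationConfig(phenotype="y", filters=(SubjectFilter("keep", "==", 1.0),)),
        )
        assert [(r.beta, r.p_value) for r in res.results] == [
            (r.beta, r.p_value) for r in res2.results
        ]

    def test_perfect_single_region_is_significant(self):
        states, phenos = simulate_null_gwas_inputs(30, 1, seed=5)
        y = -2.0 * states.frame.iloc[0].to_numpy()  # exact linear relation
        phenos = PhenotypeTable(pd.DataFrame({"y": y}, index=phenos.frame.index))
        res = run_gwas(states.regions, states, phenos, AssociationConfig(phenotype="y"))
        (r,) = res.results
        assert r.p_value == 0.0 and r.significant

    def test_summary_mentions_counts(self):
        _, _, res = _null_fit()
        text = res.summary()
        assert f"regions tested     : {res.m_tested}" in text


class TestCombinedSnpCnvr:
    def _setup(self, beta_dose=0.5, beta_state=0.5, n=300, seed=11):
        from cnvgwas import GenotypeTable, SnpMarker
        from cnvgwas.cnvr_detection import CnvrStateMatrix, SubCnvr

        rng = np.random.default_rng(seed)
        subjects = [f"S{i:03d}" for i in range(n)]
        state = -(rng.random(n) < 0.25).astype(float)
        dose = rng.binomial(2, 0.3, size=n).astype(float)
        y = beta_dose * dose + beta_state * state + rng.normal(size=n)
        region = SubCnvr(chromosome="1", start_pos=100, end_pos=5_000,
                         n_subjects=n,
                         carrier_ids=frozenset(s for s, v in zip(subjects, state) if v))
        frame = pd.DataFrame([state], index=pd.Index([region.region_id], name="region_id"),
                             columns=subjects)
        states = CnvrStateMatrix(frame=frame, regions=[region])
        genotypes = GenotypeTable(pd.DataFrame([dose], index=pd.Index(["m1"], name="marker_id"),
                                               columns=subjects))
        snp_map = [SnpMarker("m1", "1", 2_000)]
        phenos = PhenotypeTable(pd.DataFrame({"y": y}, index=pd.Index(subjects, name="subject_id")))
        return states, genotypes, phenos, snp_map

    def test_joint_model_recovers_both_effects(self):
        states, genotypes, phenos, snp_map = self._setup()
        results, skipped = run_combined_snp_cnvr(
            states.regions, states, genotypes, phenos,
            AssociationConfig(phenotype="y"), snp_map)
        (r,) = results
        assert skipped == []
        assert r.snp_beta == pytest.approx(0.5, abs=3 * r.snp_se)
        assert r.state_beta == pytest.approx(0.5, abs=3 * r.state_se)
        assert r.f_p < 1e-6 and r.f_df == 2

    def test_constant_state_reduces_to_snp_only_with_warning(self):
        states, genotypes, phenos, snp_map = self._setup(beta_state=0.0)
        states.frame.iloc[0, :] = 0.0
        with pytest.warns(UserWarning, match="SNP-only"):
            results, _ = run_combined_snp_cnvr(
                states.regions, states, genotypes, phenos,
                AssociationConfig(phenotype="y"), snp_map)
        (r,) = results
        assert r.state_beta is None and r.f_df == 1

    def test_region_without_genotyped_snps_skipped(self):
        states, genotypes, phenos, snp_map = self._setup()
        far_map = [m.__class__("m1", "1", 999_999) for m in snp_map]  # outside the span
        with pytest.raises(InsufficientDataError):
            run_combined_snp_cnvr(states.regions, states, genotypes, phenos,
                                  AssociationConfig(phenotype="y"), far_map)

    def test_null_joint_f_type_one_error_near_alpha(self):
        # 200 independent null (region, SNP) models; fraction with F-p < 0.05
        hits = 0
        total = 0
        for seed in range(200):
            states, genotypes, phenos, snp_map = self._setup(
                beta_dose=0.0, beta_state=0.0, n=120, seed=seed)
            results, _ = run_combined_snp_cnvr(
                states.regions, states, genotypes, phenos,
                AssociationConfig(phenotype="y"), snp_map)
            total += 1
            hits += results[0].f_p < 0.05
        assert 0.01 <= hits / total <= 0.10  # ~alpha within binomial noise
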