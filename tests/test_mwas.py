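"""Per-CpG regression against independent oracles, QC filters, inflation
diagnostic, and multiple-testing adjustment."""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from epimediate import (
    DegenerateInstrumentError,
    MethylationMatrix,
    SimParams,
    ValidationError,
    adjust_bh,
    adjust_bonferroni,
    filter_probes,
    fit_cpg,
    genomic_inflation,
    run_mwas,
    simulate_cohort,
)

N_TESTED_450K = 468_622  # autosomal post-QC probe count of a 450K-scale scan


def _normal_equations_oracle(y, X):
    """Closed-form OLS: solve X'X b = X'y, classical SE on column 1."""
    xtx = X.T @ X
    coef = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ coef
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(xtx)[1, 1])
    t = coef[1] / se
    p = 2 * stats.t.sf(abs(t), df)
    return coef[1], se, p


class TestFitCpg:
    def test_matches_normal_equations_on_random_designs(self, rng):
        for _ in range(50):
            n = int(rng.integers(12, 40))
            k = int(rng.integers(0, 4))
            dose = rng.binomial(2, 0.3, n).astype(float)
            if np.ptp(dose) == 0:
                dose[0] += 1
            C = rng.normal(size=(n, k)) if k else None
            y = rng.uniform(0.1, 0.9, n)
            r = fit_cpg(y, dose, covariates=C, outlier_iqr_k=None)
            X = np.column_stack([np.ones(n), dose] +
                                ([C] if C is not None else []))
            beta, se, p = _normal_equations_oracle(y, X)
            assert r.beta == pytest.approx(beta, rel=1e-8)
            assert r.se == pytest.approx(se, rel=1e-8)
            assert r.p == pytest.approx(p, rel=1e-8)

    def test_matches_statsmodels_with_missing_data(self, rng):
        n = 80
        dose = rng.binomial(2, 0.4, n).astype(float)
        C = rng.normal(size=(n, 2))
        y = 0.4 + 0.05 * dose + 0.02 * C[:, 0] + rng.normal(0, 0.03, n)
        y[[3, 17]] = np.nan
        dose[9] = np.nan
        r = fit_cpg(y, dose, covariates=C, outlier_iqr_k=None)
        mask = np.isfinite(y) & np.isfinite(dose)
        X = sm.add_constant(np.column_stack([dose[mask], C[mask]]))
        fit = sm.OLS(y[mask], X).fit()
        assert r.n == mask.sum()
        assert r.beta == pytest.approx(fit.params[1], rel=1e-10)
        assert r.se == pytest.approx(fit.bse[1], rel=1e-10)
        assert r.p == pytest.approx(fit.pvalues[1], rel=1e-10)

    def test_six_point_hand_computable_fixture(self):
        # one covariate, values chosen so the normal equations are exact
        dose = np.array([0.0, 0, 1, 1, 2, 2])
        cov = np.array([1.0, -1, 1, -1, 1, -1])
        y = np.array([0.30, 0.32, 0.35, 0.37, 0.40, 0.42])
        r = fit_cpg(y, dose, covariates=cov, outlier_iqr_k=None)
        X = np.column_stack([np.ones(6), dose, cov])
        beta, se, p = _normal_equations_oracle(y, X)
        assert r.beta == pytest.approx(beta, rel=1e-12)
        assert r.se == pytest.approx(se, rel=1e-12)

    def test_zero_effect_recovered_exactly_without_noise(self, rng):
        n = 40
        dose = rng.binomial(2, 0.5, n).astype(float)
        cov = rng.normal(size=n)
        y = 0.5 + 0.1 * cov  # methylation built only from the covariate
        r = fit_cpg(y, dose, covariates=cov, outlier_iqr_k=None)
        assert abs(r.beta) < 1e-12

    def test_planted_per_allele_effect_recovered(self, rng):
        n, effect = 2000, 0.241
        dose = rng.binomial(2, 0.4, n).astype(float)
        y = np.clip(0.2 + effect * dose + rng.normal(0, 0.25, n), 0.001, 0.999)
        r = fit_cpg(y, dose)
        assert abs(r.beta - effect) < 3 * r.se

    def test_constant_dose_is_degenerate(self):
        with pytest.raises(DegenerateInstrumentError):
            fit_cpg(np.random.default_rng(0).uniform(size=20), np.ones(20))

    def test_rank_deficient_design_rejected(self, rng):
        n = 30
        dose = rng.binomial(2, 0.4, n).astype(float)
        C = np.column_stack([dose, dose])  # collinear with instrument
        with pytest.raises(ValidationError, match="rank"):
            fit_cpg(rng.uniform(size=n), dose, covariates=C,
                    outlier_iqr_k=None)

    def test_outlier_sample_excluded_from_fit(self, rng):
        n = 60
        dose = rng.binomial(2, 0.4, n).astype(float)
        y = 0.5 + 0.01 * dose + rng.normal(0, 0.01, n)
        y[5] = 0.99  # far beyond 3xIQR
        r = fit_cpg(y, dose, outlier_iqr_k=3.0)
        assert r.n == n - 1
        r_off = fit_cpg(y, dose, outlier_iqr_k=None)
        assert r_off.n == n


class TestFilterProbes:
    def _meth(self, chroms, n_samples=4):
        n = len(chroms)
        return MethylationMatrix(
            sample_ids=[f"S{i}" for i in range(n_samples)],
            cpg_ids=[f"cg{j}" for j in range(n)],
            betas=np.full((n_samples, n), 0.5),
            chromosomes=chroms,
            positions=np.arange(1, n + 1) * 100,
            genes=["G"] * n,
        )

    def test_sex_chromosome_probes_removed(self):
        meth = self._meth(["1", "X", "2", "Y"] + ["3"] * 6)
        out = filter_probes(meth)
        assert out.n_cpgs == 8
        assert not any(out.sex_chromosome)

    def test_no_detection_matrix_applies_only_sex_filter(self):
        meth = self._meth(["1", "2", "3"])
        out = filter_probes(meth)
        assert out.cpg_ids == meth.cpg_ids

    def test_probe_failing_detection_in_one_sample_removed(self):
        meth = self._meth(["1", "2", "3"])
        det = np.zeros((4, 3))
        det[2, 1] = 0.2  # one sample above 0.05 at cg1
        out = filter_probes(meth, detection_p=det)
        assert out.cpg_ids == ["cg0", "cg2"]

    def test_all_probes_removed_is_error(self):
        meth = self._meth(["X", "Y"])
        with pytest.raises(ValidationError, match="every probe"):
            filter_probes(meth)


class TestGenomicInflation:
    def test_median_p_half_gives_unity(self):
        assert genomic_inflation([0.5, 0.5, 0.5]) == pytest.approx(1.0)

    def test_uniform_null_near_one(self, rng):
        p = rng.uniform(size=100_000)
        assert 0.98 < genomic_inflation(p) < 1.02

    def test_doubled_chi_square_doubles_lambda(self, rng):
        chi = rng.chisquare(1, size=100_000)
        p = stats.chi2.sf(2 * chi, 1)
        assert genomic_inflation(p) == pytest.approx(2.0, rel=0.03)

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            genomic_inflation([])
        with pytest.raises(ValidationError):
            genomic_inflation([0.0, 0.5])


class TestAdjustBH:
    def test_printed_top3_q_values_at_450k_scale(self):
        p = [1.71e-10, 1.22e-7, 3.18e-7]
        q = adjust_bh(p, n_tests=N_TESTED_450K)
        assert q[0] == pytest.approx(8.01e-5, rel=5e-3)
        assert round(q[1], 3) == 0.029
        assert round(q[2], 3) == 0.050

    def test_single_p_single_test(self):
        assert adjust_bh([0.03], n_tests=1)[0] == pytest.approx(0.03)

    def test_n_tests_smaller_than_p_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.1, 0.2], n_tests=1)

    @staticmethod
    def _exhaustive_oracle(p, n_tests):
        """q_i = min over ranks j >= rank(i) of p_(j)*n/j, by explicit loops."""
        order = sorted(range(len(p)), key=lambda i: p[i])
        q = [0.0] * len(p)
        for rank_pos, i in enumerate(order):
            best = min(
                p[order[j]] * n_tests / (j + 1)
                for j in range(rank_pos, len(p))
            )
            q[i] = min(1.0, best)
        return q

    def test_equals_exhaustive_oracle_on_all_permutations(self):
        base = [0.001, 0.01, 0.02, 0.04, 0.2, 0.9]
        for perm in itertools.permutations(base):
            np.testing.assert_allclose(
                adjust_bh(list(perm)),
                self._exhaustive_oracle(list(perm), len(perm)),
                rtol=1e-12,
            )

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=8),
           st.integers(min_value=0, max_value=10**6))
    def test_matches_oracle_and_is_monotone(self, p, extra):
        n_tests = len(p) + extra
        q = adjust_bh(p, n_tests=n_tests)
        np.testing.assert_allclose(q, self._exhaustive_oracle(p, n_tests),
                                   rtol=1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)  # q respects p ordering
        assert np.all(q >= np.asarray(p) - 1e-15)

    def test_agrees_with_statsmodels_when_denominator_matches(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=40)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adjust_bh(p), q_sm, rtol=1e-12)


class TestBonferroni:
    @pytest.mark.parametrize("p,expected", [
        (1.22e-7, 0.057), (3.18e-7, 0.149),
    ])
    def test_printed_values_at_450k_scale(self, p, expected):
        assert round(adjust_bonferroni(p, N_TESTED_450K), 3) == expected

    def test_capped_at_one(self):
        assert adjust_bonferroni(0.5, 10) == 1.0


class TestRunMwas:
    def test_planted_cpgs_are_the_fdr_hits(self):
        effects = {"cg_hit1": 2e-3, "cg_hit2": -2e-3, "cg_hit3": 1.5e-3}
        params = SimParams(n_samples=2000, n_cpgs=400,
                           responsive_cpg_effects=effects,
                           cis_snp_effects={}, theta_my={}, seed=21)
        cohort, _ = simulate_cohort(params)
        report = run_mwas(cohort, "rs_instr",
                          covariate_names=["mat_age", "mat_bmi", "batch1"])
        hits = {r.cpg_id for r in report.hits(0.05)}
        assert hits == set(effects)
        # strongly planted CpGs must occupy the top ranks
        assert {r.cpg_id for r in report.results[:3]} == set(effects)

    def test_single_cpg_adjustments_collapse_to_p(self):
        params = SimParams(n_samples=300, n_cpgs=1,
                           responsive_cpg_effects={"cg_only": 0.0},
                           cis_snp_effects={}, theta_my={}, seed=3)
        cohort, _ = simulate_cohort(params)
        report = run_mwas(cohort, "rs_instr")
        (r,) = report.results
        assert r.q_bh == pytest.approx(r.p)
        assert r.p_bonf == pytest.approx(r.p)

    def test_results_sorted_by_p_and_annotated(self, small_cohort):
        cohort, _ = small_cohort
        report = run_mwas(cohort, "rs_instr", covariate_names=["mat_age"])
        ps = [r.p for r in report.results]
        assert ps == sorted(ps)
        assert all(r.chromosome != "NA" for r in report.results)
        assert all(r.p_bonf >= r.p and r.q_bh >= r.p - 1e-15
                   for r in report.results)

    def test_external_test_count_scales_adjustments(self, small_cohort):
        cohort, _ = small_cohort
        rep_default = run_mwas(cohort, "rs_instr")
        rep_scaled = run_mwas(cohort, "rs_instr", total_tests=N_TESTED_450K)
        top_d = rep_default.results[0]
        top_s = rep_scaled.results[0]
        assert top_s.p == pytest.approx(top_d.p)
        assert top_s.p_bonf == pytest.approx(
            min(1.0, top_d.p * N_TESTED_450K), rel=1e-9)
        assert top_s.q_bh >= top_d.q_bh

    def test_unknown_instrument_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValidationError):
            run_mwas(cohort, "rs_not_there")
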