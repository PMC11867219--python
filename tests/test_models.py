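import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from conftest import random_cells
from fhburden.models import (CohortCells, ModelFit, fit_adjacent_categories, fit_model1,
                             fit_model2, fit_model3, fit_null, lrt, optimal_k,
                             run_gene_scan, wald_test)


def bernoulli_loglik(records: pd.DataFrame, eta: np.ndarray) -> float:
    """Independent evaluation of the carrier-status log-likelihood."""
    y = records["carrier"].to_numpy(float)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def numeric_ml_beta(cells: CohortCells, design_fn, p: int) -> np.ndarray:
    """Brute-force numeric maximization of the grouped likelihood."""
    patterns, successes, trials = cells.grouped()
    X = design_fn(patterns)

    def negll(beta):
        eta = X @ beta
        return -np.sum(successes * eta - trials * np.logaddexp(0.0, eta))

    res = minimize(negll, np.full(p, 0.1), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return res.x


class TestNullModel:
    def test_no_sex_effect_recovers_logit_carrier_frequency(self):
        counts = np.zeros((2, 2, 2, 2))
        # carrier frequency 0.1 in both sexes, no cases/FH
        counts[0, 0, 0] = [900, 100]
        counts[1, 0, 0] = [450, 50]
        fit = fit_null(CohortCells(counts))
        assert fit.params["sex"] == pytest.approx(0.0, abs=1e-8)
        assert fit.params["(intercept)"] == pytest.approx(math.log(0.1 / 0.9), abs=1e-8)

    def test_loglik_equals_direct_bernoulli_evaluation(self, rng):
        cells = random_cells(rng)
        fit = fit_null(cells)
        records = cells.to_records()
        eta = (fit.params["(intercept)"]
               + fit.params["sex"] * records["sex"].to_numpy(float))
        assert fit.loglik == pytest.approx(bernoulli_loglik(records, eta), abs=1e-8)

    def test_grouped_and_expanded_fits_agree(self, rng):
        cells = random_cells(rng, scale=200)
        grouped = fit_null(cells)
        expanded = fit_null(cells.to_records())
        assert np.allclose(grouped.params, expanded.params, atol=1e-8)
        assert grouped.loglik == pytest.approx(expanded.loglik, abs=1e-8)

    def test_constant_response_is_an_error(self):
        counts = np.zeros((2, 2, 2, 2))
        counts[:, :, :, 0] = 10
        with pytest.raises(ValueError, match="no-carrier"):
            fit_null(CohortCells(counts))


class TestModel1:
    def test_two_by_two_odds_ratio_is_cross_product_exactly(self):
        a, b, c, d = 40.0, 960.0, 15.0, 985.0  # carriers/non by case/control
        counts = np.zeros((2, 2, 2, 2))
        counts[0, 1, 0] = [b, a]
        counts[0, 0, 0] = [d, c]
        counts[1, 1, 0] = [b, a]  # same table in both sexes keeps sex estimable
        counts[1, 0, 0] = [d, c]
        fit = fit_model1(CohortCells(counts))
        assert math.exp(fit.beta1) == pytest.approx((a * d) / (b * c), abs=1e-10)

    def test_independence_gives_null_beta1_and_zero_lrt(self):
        counts = np.zeros((2, 2, 2, 2))
        for sex in (0, 1):
            for case in (0, 1):
                counts[sex, case, 0] = [1800, 200]
        cells = CohortCells(counts)
        m1 = fit_model1(cells)
        stat, df, p = lrt(m1, fit_null(cells))
        assert m1.beta1 == pytest.approx(0.0, abs=1e-7)
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert df == 1

    def test_matches_numeric_maximization_oracle(self, rng):
        cells = random_cells(rng)
        fit = fit_model1(cells)

        def design(patterns):
            return np.column_stack([np.ones(len(patterns)), patterns[:, 1], patterns[:, 0]])

        beta = numeric_ml_beta(cells, design, 3)
        assert np.allclose(fit.params[["(intercept)", "case", "sex"]], beta, atol=1e-4)

    def test_grouped_and_expanded_fits_agree(self, rng):
        cells = random_cells(rng, scale=150)
        assert np.allclose(fit_model1(cells).params,
                           fit_model1(cells.to_records()).params, atol=1e-8)


class TestModel2:
    def test_k_t_is_beta2_over_beta1(self, rng):
        cells = random_cells(rng)
        fit = fit_model2(cells)
        assert fit.k_T == pytest.approx(fit.params["fh"] / fit.params["case"])

    def test_all_zero_fh_column_is_an_error_naming_it(self, rng):
        counts = rng.integers(10, 500, size=(2, 2, 2, 2)).astype(float)
        counts[:, :, 1, :] = 0.0
        with pytest.raises(ValueError, match="fh"):
            fit_model2(CohortCells(counts))

    def test_lrt_against_null_has_two_df(self, rng):
        cells = random_cells(rng)
        _, df, _ = lrt(fit_model2(cells), fit_null(cells))
        assert df == 2


class TestModel3:
    def test_k_zero_is_exactly_model1(self, rng):
        cells = random_cells(rng)
        m1, m3 = fit_model1(cells), fit_model3(cells, k=0.0)
        assert np.allclose(m1.params.to_numpy(), m3.params.to_numpy(), atol=1e-8)
        assert m1.loglik == pytest.approx(m3.loglik, abs=1e-8)
        assert np.allclose(m1.cov.to_numpy(), m3.cov.to_numpy(), atol=1e-8)

    def test_k_one_equals_proxy_phenotype_when_case_and_fh_disjoint(self, rng):
        counts = rng.integers(20, 800, size=(2, 2, 2, 2)).astype(float)
        counts[:, 1, 1, :] = 0.0  # cases never report FH -> case+fh = max(case, fh)
        cells = CohortCells(counts)
        m3 = fit_model3(cells, k=1.0)
        records = cells.to_records()
        proxy = records.assign(case=np.maximum(records["case"], records["fh"]))
        m1_proxy = fit_model1(proxy)
        assert m3.beta1 == pytest.approx(m1_proxy.beta1, abs=1e-8)
        assert m3.loglik == pytest.approx(m1_proxy.loglik, abs=1e-8)

    def test_matches_numeric_maximization_oracle(self, rng):
        cells = random_cells(rng)
        fit = fit_model3(cells, k=0.5)

        def design(patterns):
            comp = patterns[:, 1] + 0.5 * patterns[:, 2]
            return np.column_stack([np.ones(len(patterns)), comp, patterns[:, 0]])

        beta = numeric_ml_beta(cells, design, 3)
        assert np.allclose(fit.params[["(intercept)", "case_k_fh", "sex"]],
                           beta, atol=1e-4)

    def test_constrained_loglik_never_exceeds_model2(self, rng):
        for _ in range(10):
            cells = random_cells(rng)
            for k in (0.0, 0.3, 0.5, 1.0):
                assert fit_model3(cells, k=k).loglik <= fit_model2(cells).loglik + 1e-9


class TestAgainstStatsmodels:
    def test_coefficients_covariance_match_glm(self, rng):
        import statsmodels.api as sm

        cells = random_cells(rng)
        fit = fit_model2(cells)
        patterns, successes, trials = cells.grouped()
        X = np.column_stack([np.ones(8), patterns[:, 1], patterns[:, 2],
                             patterns[:, 0]])
        glm = sm.GLM(np.column_stack([successes, trials - successes]), X,
                     family=sm.families.Binomial()).fit()
        assert np.allclose(fit.params[["(intercept)", "case", "fh", "sex"]],
                           glm.params, atol=1e-7)
        assert np.allclose(fit.cov.to_numpy(), glm.cov_params(), atol=1e-7)


class TestLrtWald:
    def test_statistic_is_twice_loglik_difference(self, rng):
        cells = random_cells(rng)
        null = fit_null(cells)
        m3 = fit_model3(cells, k=0.5)
        stat, df, p = lrt(m3, null)
        assert stat == pytest.approx(2.0 * (m3.loglik - null.loglik), abs=1e-10)
        assert df == 1 and 0.0 < p <= 1.0

    def test_equal_logliks_give_zero_statistic_p_one(self, rng):
        null = fit_null(random_cells(rng))
        alt = ModelFit(model="m1", params=null.params, cov=null.cov,
                       loglik=null.loglik, df=null.df + 1, n=null.n,
                       converged=True, separated=False, beta1_name="case")
        stat, df, p = lrt(alt, null)
        assert stat == 0.0 and p == 1.0

    def test_lrt_requires_matching_data(self, rng):
        c1, c2 = random_cells(rng), random_cells(rng)
        with pytest.raises(ValueError, match="different data"):
            lrt(fit_model1(c1), fit_null(c2))
        with pytest.raises(ValueError, match="nested null"):
            lrt(fit_model1(c1), fit_model2(c1))

    def test_lrt_invariant_to_covariate_scaling(self, rng):
        cells = random_cells(rng, scale=300)
        records = cells.to_records()
        records["age"] = rng.normal(50, 10, len(records))
        base = lrt(fit_model1(records, covariates=["age"]),
                   fit_null(records, covariates=["age"]))[0]
        records["age"] = (records["age"] - 50.0) / 10.0
        scaled = lrt(fit_model1(records, covariates=["age"]),
                     fit_null(records, covariates=["age"]))[0]
        assert base == pytest.approx(scaled, abs=1e-6)

    def test_wald_p_one_at_zero_estimate(self):
        counts = np.zeros((2, 2, 2, 2))
        for sex in (0, 1):
            for case in (0, 1):
                counts[sex, case, 0] = [900, 100]
        z, p, (lo, hi) = wald_test(fit_model1(CohortCells(counts)))
        assert p == pytest.approx(1.0, abs=1e-6)
        assert lo < 0 < hi

    def test_wald_and_lrt_agree_asymptotically(self, rng):
        # large balanced table with a genuine effect
        counts = np.zeros((2, 2, 2, 2))
        for sex in (0, 1):
            counts[sex, 0, 0] = [99000, 1000]
            counts[sex, 1, 0] = [49400, 600]
        cells = CohortCells(counts)
        m1 = fit_model1(cells)
        _, p_wald, _ = wald_test(m1)
        _, _, p_lrt = lrt(m1, fit_null(cells))
        assert abs(math.log10(p_wald) - math.log10(p_lrt)) < 1.0


class TestOptimalK:
    def test_small_effect_limit_is_one_half(self):
        assert optimal_k(1e-9) == 0.5
        assert optimal_k(1e-6) == pytest.approx(0.5, abs=1e-6)

    def test_closed_form_values(self):
        assert optimal_k(math.log(2)) == pytest.approx(math.log(1.5) / math.log(2), rel=1e-12)
        assert optimal_k(math.log(5)) == pytest.approx(math.log(3) / math.log(5), rel=1e-12)

    def test_strictly_increasing_in_beta1(self):
        grid = np.linspace(1e-4, math.log(5), 200)
        vals = [optimal_k(b) for b in grid]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] > 0.5


class TestAdjacentCategories:
    @staticmethod
    def _hwe_genotypes(rng, n, p_allele, beta1, beta3, pheno):
        """Draw G from the adjacent-categories model with HWE baseline odds."""
        q = p_allele
        base = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
        a = np.log(base[1] / base[0]), np.log(base[2] / base[1])
        eta = beta1 * pheno["case"].to_numpy() + beta3 * pheno["sex"].to_numpy()
        logw = np.stack([np.zeros(n), a[0] + eta, a[0] + a[1] + 2 * eta], axis=1)
        probs = np.exp(logw - logw.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        cdf = probs.cumsum(axis=1)
        return (u[:, None] > cdf).sum(axis=1)

    def test_missing_top_level_reduces_to_binary_logistic(self, rng):
        n = 2000
        pheno = pd.DataFrame({"sex": rng.integers(0, 2, n),
                              "case": rng.integers(0, 2, n),
                              "fh": rng.integers(0, 2, n)})
        g = rng.choice([0, 1], size=n, p=[0.9, 0.1])
        ac = fit_adjacent_categories(g, pheno, model="m1")
        binary = fit_model1(pheno.assign(carrier=g))
        assert ac.beta1 == pytest.approx(binary.beta1, abs=1e-8)

    def test_per_allele_log_or_recovery_under_hwe(self, rng):
        n = 400_000
        pheno = pd.DataFrame({"sex": rng.integers(0, 2, n),
                              "case": rng.integers(0, 2, n),
                              "fh": np.zeros(n, dtype=int)})
        g = self._hwe_genotypes(rng, n, 0.2, math.log(1.3), 0.05, pheno)
        fit = fit_adjacent_categories(g, pheno, model="m1")
        se = fit.se("case")
        assert fit.beta1 == pytest.approx(math.log(1.3), abs=4 * se)

    def test_null_generator_gives_calibrated_lrt(self, rng):
        # slopes zero in the generator: 2*(l1-l0) should look chi2(1)
        n = 5000
        stats_ = []
        for _ in range(200):
            pheno = pd.DataFrame({"sex": rng.integers(0, 2, n),
                                  "case": rng.integers(0, 2, n),
                                  "fh": np.zeros(n, dtype=int)})
            g = self._hwe_genotypes(rng, n, 0.3, 0.0, 0.0, pheno)
            alt = fit_adjacent_categories(g, pheno, model="m1")
            null = fit_adjacent_categories(g, pheno, model="null")
            stats_.append(lrt(alt, null)[0])
        stats_ = np.asarray(stats_)
        # chi2(1): mean 1, sd sqrt(2); check mean within 4 MC SEs
        assert abs(stats_.mean() - 1.0) < 4 * math.sqrt(2.0 / len(stats_))

    def test_single_level_is_an_error(self, rng):
        pheno = pd.DataFrame({"sex": [0, 1] * 5, "case": [0, 1] * 5,
                              "fh": [0] * 10})
        with pytest.raises(ValueError, match="2 observed levels"):
            fit_adjacent_categories(np.zeros(10, dtype=int), pheno, model="m1")


class TestGeneScan:
    def test_three_gene_scan_with_skip(self, rng):
        from fhburden.burden import BurdenVector
        from fhburden.simulate import SimulationConfig, generate_carriers, generate_cohort
        from fhburden.cohorts import load_proportions

        cfg = SimulationConfig(proportions=load_proportions("breast"), n=100_000,
                               reps=1, seed=7)
        cells = generate_cohort(cfg, 7)
        with_effect = generate_carriers(cells, 3.0, 0.5, cfg.alpha, cfg.beta3, 8)
        null_gene = generate_carriers(cells, 1.0, 0.5, cfg.alpha, cfg.beta3, 9)
        # expand one phenotype frame and two carrier vectors consistent with it
        pheno = with_effect.to_records().drop(columns="carrier")
        pheno.insert(0, "sample_id", [f"s{i}" for i in range(len(pheno))])
        g_effect = with_effect.to_records()["carrier"].to_numpy(bool)
        base_records = null_gene.to_records()
        pheno_cols = ["sex", "case", "fh"]
        assert base_records[pheno_cols].value_counts().to_dict() == \
            with_effect.to_records()[pheno_cols].value_counts().to_dict()
        g_null = base_records["carrier"].to_numpy(bool)
        carriers = {
            "EFFECT": BurdenVector("EFFECT", pheno["sample_id"].tolist(), g_effect),
            "NULL": BurdenVector("NULL", pheno["sample_id"].tolist(), g_null),
            "EMPTY": BurdenVector("EMPTY", pheno["sample_id"].tolist(),
                                  np.zeros(len(pheno), bool)),
        }
        table, skipped = run_gene_scan(carriers, pheno, model="m3", k=0.5)
        assert skipped == ["EMPTY"]
        assert set(table["gene"]) == {"EFFECT", "NULL"}
        effect_row = table.set_index("gene").loc["EFFECT"]
        assert effect_row["odds_ratio"] > 1.5
        assert effect_row["p_lrt"] < 1e-3
        assert (table["ci_low"] <= table["odds_ratio"]).all()
        assert (table["odds_ratio"] <= table["ci_high"]).all()

    def test_empty_gene_list(self):
        pheno = pd.DataFrame({"sample_id": ["a"], "sex": [0], "case": [0], "fh": [0]})
        table, skipped = run_gene_scan({}, pheno)
        assert table.empty and skipped == []
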