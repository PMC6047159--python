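import math

import numpy as np
import pytest

import milkgwas as mg
from milkgwas.association import variant_filters
from milkgwas.phenotypes import PhenotypeSpec


class TestNullFit:
    def test_intercept_only_residuals_sum_zero(self, rng):
        y = rng.normal(size=50)
        fit = mg.fit_null_model(y)
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-10)

    def test_residuals_orthogonal_and_leverage_sum(self, rng):
        X = rng.normal(size=(200, 3))
        y = rng.normal(size=200)
        fit = mg.fit_null_model(y, X)
        assert np.abs(fit.X.T @ fit.residuals).max() < 1e-8 * np.abs(y).max()
        assert fit.leverages.sum() == pytest.approx(4.0)  # intercept + 3

    def test_coefficients_match_normal_equations(self, rng):
        X = rng.normal(size=(120, 4))
        y = rng.normal(size=120)
        fit = mg.fit_null_model(y, X)
        Xd = np.column_stack([np.ones(120), X])
        expected = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        np.testing.assert_allclose(fit.coef, expected, atol=1e-10)

    def test_exact_fit_flagged_degenerate(self, rng):
        X = rng.normal(size=(30, 2))
        a = np.array([1.0, 2.0, -0.5])
        y = np.column_stack([np.ones(30), X]) @ a
        fit = mg.fit_null_model(y, X)
        assert fit.degenerate

    def test_rank_deficiency_names_columns(self, rng):
        import pandas as pd

        X = pd.DataFrame({"age": rng.normal(size=40)})
        X["age_copy"] = X["age"]
        with pytest.raises(ValueError, match="age_copy"):
            mg.fit_null_model(rng.normal(size=40), X)


class TestScoreTest:
    def test_hand_computed_example(self):
        """y=(1,2,3,4), intercept only, hard g=(0,0,1,1):
        U=1.6, V=0.8, S=3.2, beta=2 (the OLS slope)."""
        null = mg.fit_null_model(np.array([1.0, 2.0, 3.0, 4.0]))
        res = mg.score_test(null, mg.hard_to_triples(np.array([0, 0, 1, 1])))
        assert res.score == pytest.approx(1.6)
        assert res.information == pytest.approx(0.8)
        assert res.statistic == pytest.approx(3.2)
        assert res.beta == pytest.approx(2.0)
        assert res.direction == "+"

    @pytest.mark.parametrize("information", ["expected", "observed"])
    def test_hard_genotypes_reduce_to_ols_score_statistic(self, rng, information):
        """With degenerate triples both information variants coincide and
        equal the classical OLS score statistic to 1e-8 relative."""
        for _ in range(100):
            n = rng.integers(30, 120)
            X = rng.normal(size=(n, 2))
            y = rng.normal(size=n)
            g = rng.binomial(2, rng.uniform(0.1, 0.9), n).astype(float)
            if g.std() == 0:
                continue
            null = mg.fit_null_model(y, X)
            res = mg.score_test(
                null, mg.hard_to_triples(g.astype(int)), information=information
            )
            # OLS score statistic: n * squared partial correlation
            Xd = np.column_stack([np.ones(n), X])
            q, _ = np.linalg.qr(Xd)
            rg = g - q @ (q.T @ g)
            ry = y - q @ (q.T @ y)
            s_ols = n * (rg @ ry) ** 2 / ((rg @ rg) * (ry @ ry))
            assert res.statistic == pytest.approx(s_ols, rel=1e-8)

    def test_beta_equals_ols_slope_for_hard_genotypes(self, rng):
        n = 80
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        g = rng.binomial(2, 0.4, n)
        null = mg.fit_null_model(y, X)
        res = mg.score_test(null, mg.hard_to_triples(g))
        Xd = np.column_stack([np.ones(n), X, g])
        slope = np.linalg.lstsq(Xd, y, rcond=None)[0][-1]
        assert res.beta == pytest.approx(slope, rel=1e-8)

    def test_pure_prior_triples_untestable(self, rng):
        """Triples equal to the HWE prior carry no genotype signal: the
        expected dosage is constant, so V ~ 0 and the result is flagged."""
        n = 100
        y = rng.normal(size=n)
        null = mg.fit_null_model(y)
        t = np.tile(mg.hwe_prior(0.3), (n, 1))
        res = mg.score_test(null, t)
        assert not res.testable and np.isnan(res.p)

    def test_information_ordering_uncertain_below_hard(self, rng):
        """Genotype uncertainty cannot add information: V(posterior) <=
        V(true hard maternal genotypes) on matched simulations."""
        n = 800
        p = 0.3
        mother = rng.binomial(2, p, n)
        father = rng.binomial(2, p, n)
        infant = rng.binomial(1, mother / 2) + rng.binomial(1, father / 2)
        posterior, _ = mg.impute_cohort(infant[None, :], raf=[p])
        y = rng.normal(size=n)
        null = mg.fit_null_model(y)
        v_hard = mg.score_test(null, mg.hard_to_triples(mother)).information
        v_post = mg.score_test(null, posterior[0]).information
        assert v_post <= v_hard

    def test_power_ordering(self, rng):
        """Rejection rate: true maternal genotypes >= imputed posteriors
        >= pure-prior triples, at a fixed multiplicative effect."""
        from milkgwas.simulate import GeneticEffect

        reject = {"true": 0, "posterior": 0}
        n_rep = 40
        for rep in range(n_rep):
            cfg = mg.SimConfig(
                n_dyads=400,
                variants=[mg.Variant("1", 1, "A", "G", raf=0.3, snp_id="v")],
                seed=9000 + rep,
                genetic_effects=[GeneticEffect(0, "AA", 0.75)],
            )
            cohort, table = mg.simulate_study(cfg)
            y = np.log(table["AA"].to_numpy())
            null = mg.fit_null_model(y)
            posterior, _ = mg.impute_cohort(cohort.infant, raf=[0.3])
            r_true = mg.score_test(null, mg.hard_to_triples(cohort.maternal[0]))
            r_post = mg.score_test(null, posterior[0])
            reject["true"] += r_true.p < 0.05
            reject["posterior"] += r_post.p < 0.05
            prior = np.tile(mg.hwe_prior(0.3), (400, 1))
            assert not mg.score_test(null, prior).testable
        assert reject["true"] >= reject["posterior"]
        assert reject["posterior"] > 0

    def test_batch_matches_scalar(self, rng):
        n = 60
        y = rng.normal(size=n)
        null = mg.fit_null_model(y)
        stack = rng.dirichlet([1, 1, 1], size=(5, n))
        batch = mg.score_test_batch(null, stack)
        for i, res in enumerate(batch):
            single = mg.score_test(null, stack[i])
            assert res.statistic == pytest.approx(single.statistic, rel=1e-12)


def _hwe_oracle(n0, n1, n2):
    """Enumerate every genotype configuration with the same allele counts
    and sum the HWE-conditional probabilities <= the observed one."""
    n = n0 + n1 + n2
    na = 2 * n0 + n1  # copies of the first allele
    def prob(h):
        a0 = (na - h) // 2
        a2 = n - h - a0
        if a0 < 0 or a2 < 0 or (na - h) % 2:
            return 0.0
        return (
            math.factorial(n)
            / (math.factorial(a0) * math.factorial(h) * math.factorial(a2))
            * 2**h
            / math.comb(2 * n, na)
            * math.comb(2 * n - na, 0)  # normalisation handled below
        )
    weights = {h: prob(h) for h in range(0, min(na, 2 * n - na) + 1)}
    total = sum(weights.values())
    p_obs = weights[n1]
    return sum(w for w in weights.values() if w <= p_obs * (1 + 1e-12)) / total


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert mg.hwe_exact_test(3, 0, 0) == 1.0

    def test_two_sample_enumeration(self):
        # alleles: 2 of each; configurations h=0 (p 1/3) or h=2 (p 2/3)
        assert mg.hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)
        assert mg.hwe_exact_test(0, 2, 0) == pytest.approx(1.0)

    def test_agrees_with_enumeration_oracle_small_n(self):
        for n in range(1, 21):
            for n0 in range(n + 1):
                for n1 in range(n - n0 + 1):
                    n2 = n - n0 - n1
                    got = mg.hwe_exact_test(n0, n1, n2)
                    want = _hwe_oracle(n0, n1, n2)
                    assert got == pytest.approx(want, rel=1e-9), (n0, n1, n2)

    def test_extreme_departure_is_small(self):
        # all hets at a common variant is HWE-unlikely for large n
        assert mg.hwe_exact_test(0, 100, 0) < 1e-5

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            mg.hwe_exact_test(0, 0, 0)


class TestVariantFilters:
    def test_both_studies_common_kept(self):
        d = variant_filters([0.06, 0.06], [1.0, 1.0], [0.5, 0.5])
        assert d.keep

    def test_single_study_maf_rule(self):
        assert variant_filters([0.12, None], [1.0, None], [0.5, None]).keep
        assert not variant_filters([0.07, None], [1.0, None], [0.5, None]).keep

    def test_info_strict_vs_regional(self):
        strict = variant_filters([0.2, 0.2], [1.0, 0.95], [0.5, 0.5], mode="strict")
        regional = variant_filters([0.2, 0.2], [1.0, 0.95], [0.5, 0.5], mode="regional")
        assert not strict.keep and "info" in strict.reason
        assert regional.keep

    def test_hwe_filter(self):
        d = variant_filters([0.2, 0.2], [1.0, 1.0], [0.5, 1e-6])
        assert not d.keep and "HWE" in d.reason

    def test_absent_everywhere(self):
        assert not variant_filters([None], [None], [None]).keep


class TestReportEffect:
    def test_log_phenotype_multiplicative(self):
        spec = PhenotypeSpec("AA", "PUFA6", "log")
        rep = mg.report_effect(math.log(0.85), math.log(1.03), spec)
        assert rep.value == pytest.approx(0.85)
        assert rep.se == pytest.approx(1.03)

    def test_percent_per_major_allele(self):
        spec = PhenotypeSpec("AA", "PUFA6", "log")
        rep = mg.report_effect(math.log(0.85), 0.01, spec)
        assert rep.percent_per_major_allele == pytest.approx(
            (1 / 0.85 - 1) * 100, abs=1e-9
        )
        assert 17.0 < rep.percent_per_major_allele < 18.0

    def test_sqrt_ratio_standardisation(self):
        spec = PhenotypeSpec("PUFA6/PUFA3", "derived", "sqrt-ratio", s0=12.0)
        rep = mg.report_effect(-0.664, 0.1, spec)
        assert rep.value == pytest.approx(2 * math.sqrt(12) * -0.664, abs=1e-9)
        assert rep.value == pytest.approx(-4.60, abs=0.005)

    def test_increasing_effect_has_no_major_allele_percent(self):
        spec = PhenotypeSpec("LAU", "SFA", "log")
        assert mg.report_effect(math.log(1.84), 0.1, spec).percent_per_major_allele is None
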