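import itertools

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import integrate, stats as st

from soyepi import epistasis as epi
from soyepi.datatypes import PhenotypeVector
from tests.conftest import make_genotypes, make_phenotypes


class TestDirichletMultinomial:
    def test_single_observation_predictive(self):
        # one draw in one of 3 categories under a uniform prior: prob 1/3
        lp = epi.dm_log_marginal([1, 0, 0], epi.DirichletPrior(1.0))
        assert np.exp(lp) == pytest.approx(1 / 3)

    def test_two_in_same_category(self):
        # Gamma(3)/Gamma(5) * Gamma(3) = 1/6
        lp = epi.dm_log_marginal([2, 0, 0], 1.0)
        assert np.exp(lp) == pytest.approx(1 / 6)

    @pytest.mark.parametrize("n,k", [(1, 2), (2, 2), (3, 2), (4, 3)])
    def test_normalizes_over_ordered_sequences(self, n, k):
        total = 0.0
        for seq in itertools.product(range(k), repeat=n):
            counts = np.bincount(seq, minlength=k)
            total += np.exp(epi.dm_log_marginal(counts, 1.0))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            epi.dm_log_marginal([0, 0], 1.0)
        with pytest.raises(ValueError):
            epi.dm_log_marginal([1, 0], -1.0)
        with pytest.raises(ValueError):
            epi.DirichletPrior(0.0)


class TestGaussianMarginal:
    PRIOR = epi.GaussianCellPrior(mu0=45.0, kappa0=1.0, alpha0=2.0, beta0=25.0)

    def test_single_value_is_student_t_density(self):
        y = 50.0
        lp = epi.gaussian_log_marginal([[y]], self.PRIOR)
        scale = np.sqrt(
            self.PRIOR.beta0 * (self.PRIOR.kappa0 + 1)
            / (self.PRIOR.alpha0 * self.PRIOR.kappa0)
        )
        expected = st.t.logpdf(y, df=2 * self.PRIOR.alpha0, loc=self.PRIOR.mu0,
                               scale=scale)
        assert lp == pytest.approx(expected, abs=1e-10)

    def test_cells_are_independent(self):
        data = [48.0, 51.0, 44.5]
        one = epi.gaussian_log_marginal([data], self.PRIOR)
        two = epi.gaussian_log_marginal([data, data], self.PRIOR)
        assert two == pytest.approx(2 * one, abs=1e-10)

    def test_matches_numerical_integration(self):
        """Marginal of a 3-point cell agrees with direct quadrature of the
        Normal likelihood over the Normal-Inverse-Gamma prior."""
        ys = np.array([43.0, 46.0, 49.0])
        pr = self.PRIOR

        def integrand(mu, s2):
            lik = np.prod(st.norm.pdf(ys, mu, np.sqrt(s2)))
            prior = (
                st.invgamma.pdf(s2, pr.alpha0, scale=pr.beta0)
                * st.norm.pdf(mu, pr.mu0, np.sqrt(s2 / pr.kappa0))
            )
            return lik * prior

        val, _ = integrate.dblquad(
            integrand, 1.0, 400.0, lambda s2: 20.0, lambda s2: 70.0,
            epsabs=1e-12, epsrel=1e-10,
        )
        lp = epi.gaussian_log_marginal([ys], pr)
        assert lp == pytest.approx(np.log(val), abs=1e-4)

    def test_invalid_prior(self):
        with pytest.raises(ValueError):
            epi.GaussianCellPrior(mu0=0.0, kappa0=-1.0)


@pytest.fixture(scope="module")
def score_fixture():
    rng = np.random.default_rng(10)
    G = make_genotypes(rng.integers(0, 3, size=(80, 5)))
    y = make_phenotypes(G, rng.normal(45, 5, 80))
    return G, y


@pytest.fixture(scope="module")
def range_fixture():
    rng = np.random.default_rng(5)
    G = make_genotypes(rng.integers(0, 3, size=(100, 4)))
    y = make_phenotypes(G, rng.normal(45, 5, 100))
    return G, y


class TestPartitionScore:
    def test_all_background_decomposition(self, score_fixture):
        G, y = score_fixture
        score = epi.partition_log_score(np.zeros(5, dtype=int), G, y)
        prior = epi.GaussianCellPrior.from_phenotype(y.values)
        expected = epi.gaussian_log_marginal([y.values], prior)
        for j in range(5):
            counts = np.bincount(G.dosages[:, j], minlength=3)
            expected += epi.dm_log_marginal(counts, 1.0)
        assert score == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_block_relabeling(self, score_fixture):
        G, y = score_fixture
        a = epi.partition_log_score(np.array([2, 2, 0, 3, 3]), G, y)
        b = epi.partition_log_score(np.array([3, 3, 0, 2, 2]), G, y)
        assert a == pytest.approx(b, abs=1e-12)

    def test_singleton_dependency_equals_background(self, score_fixture):
        G, y = score_fixture
        a = epi.partition_log_score(np.array([2, 0, 0, 0, 0]), G, y)
        b = epi.partition_log_score(np.zeros(5, dtype=int), G, y)
        assert a == pytest.approx(b, abs=1e-12)

    def test_null_marker_in_associated_block_lowers_expected_score(self):
        """On average over simulations, promoting an independent marker into
        the phenotype block costs score at large n."""
        rng = np.random.default_rng(11)
        deltas = []
        for _ in range(20):
            G = make_genotypes(rng.integers(0, 3, size=(400, 3)))
            y = make_phenotypes(G, rng.normal(45, 5, 400))
            null = epi.partition_log_score(np.zeros(3, dtype=int), G, y)
            promoted = epi.partition_log_score(np.array([1, 0, 0]), G, y)
            deltas.append(promoted - null)
        assert np.mean(deltas) < 0

    def test_empty_candidate_set_is_error(self, score_fixture):
        G, y = score_fixture
        with pytest.raises(ValueError):
            epi.partition_log_score(
                np.zeros(0, dtype=int), G.dosages[:, :0], y.values
            )


class TestTwoLocusTest:
    def test_constant_phenotype_is_degenerate_with_p_one(self):
        rng = np.random.default_rng(0)
        G = make_genotypes(rng.integers(0, 3, size=(50, 2)))
        y = make_phenotypes(G, np.full(50, 45.0))
        res = epi.two_locus_test(G, y, 0, 1)
        assert res.degenerate
        assert res.p_value == 1.0

    def test_recovers_planted_product_coefficient(self):
        rng = np.random.default_rng(1)
        G = make_genotypes(rng.integers(0, 3, size=(200, 2)))
        ga, gb = G.dosages[:, 0].astype(float), G.dosages[:, 1].astype(float)
        y = make_phenotypes(G, 40 + 3.0 * ga * gb + rng.normal(0, 0.1, 200))
        res = epi.two_locus_test(G, y, 0, 1)
        assert res.p_value < 1e-10
        assert 2.9 <= res.coefficient <= 3.1

    def test_agrees_with_reference_linear_model(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            r = np.random.default_rng(seed)
            G = make_genotypes(r.integers(0, 3, size=(60, 2)))
            y = make_phenotypes(G, r.normal(45, 5, 60))
            res = epi.two_locus_test(G, y, 0, 1)
            ga, gb = G.dosages[:, 0].astype(float), G.dosages[:, 1].astype(float)
            X = sm.add_constant(np.column_stack([ga, gb, ga * gb]))
            fit = sm.OLS(y.values, X).fit()
            assert res.p_value == pytest.approx(fit.pvalues[3], abs=1e-8)
            assert res.coefficient == pytest.approx(fit.params[3], abs=1e-8)

    def test_collinear_markers_flagged(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=50)
        G = make_genotypes(np.column_stack([g, g]))
        y = make_phenotypes(G, rng.normal(45, 5, 50))
        res = epi.two_locus_test(G, y, 0, 1)
        assert res.degenerate
        assert np.isnan(res.p_value)

    def test_additive_null_interaction_p_is_uniform(self):
        """With purely additive effects the product-term p-value is uniform
        over replicates (KS at alpha = 0.01)."""
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(200):
            dosages = rng.integers(0, 3, size=(500, 2))
            G = make_genotypes(dosages)
            ga, gb = dosages[:, 0], dosages[:, 1]
            y = make_phenotypes(G, 45 + ga + gb + rng.normal(0, 2, 500))
            pvals.append(epi.two_locus_test(G, y, 0, 1).p_value)
        assert st.kstest(pvals, "uniform").pvalue > 0.01

    def test_monomorphic_marker_rejected(self):
        G = make_genotypes(np.column_stack([np.zeros(20, int),
                                            np.arange(20) % 3]))
        y = make_phenotypes(G, np.arange(20) + 30.0)
        with pytest.raises(ValueError, match="polymorphic"):
            epi.two_locus_test(G, y, 0, 1)


class TestPairwiseRange:
    def test_pair_group_has_min_equal_max(self, range_fixture):
        G, y = range_fixture
        pmin, pmax, tests = epi.pairwise_p_range([0, 1], G, y)
        assert pmin == pmax
        assert len(tests) == 1

    def test_triplet_evaluates_three_pairs(self, range_fixture):
        G, y = range_fixture
        pmin, pmax, tests = epi.pairwise_p_range([0, 1, 2], G, y)
        assert len(tests) == 3
        assert pmin <= pmax

    def test_group_of_one_is_error(self, range_fixture):
        G, y = range_fixture
        with pytest.raises(ValueError):
            epi.pairwise_p_range([0], G, y)


class TestMCMCInterface:
    def test_input_validation(self):
        rng = np.random.default_rng(6)
        G = make_genotypes(rng.integers(0, 3, size=(30, 4)))
        y = make_phenotypes(G, rng.normal(45, 5, 30))
        with pytest.raises(ValueError, match="burn-in"):
            epi.mcmc_search(G, y, iterations=100, burnin=100)
        G1 = G.subset_markers([0])
        with pytest.raises(ValueError, match="at least 2"):
            epi.mcmc_search(G1, y, iterations=100, burnin=10)

    def test_same_seed_reproduces_result(self):
        rng = np.random.default_rng(7)
        G = make_genotypes(rng.integers(0, 3, size=(60, 5)))
        y = make_phenotypes(G, rng.normal(45, 5, 60))
        a = epi.mcmc_search(G, y, iterations=3000, burnin=1000, seed=3)
        b = epi.mcmc_search(G, y, iterations=3000, burnin=1000, seed=3)
        assert a.block_posteriors == b.block_posteriors
        assert np.array_equal(a.final_state.assignment, b.final_state.assignment)

    def test_discrete_phenotype_mode_runs(self):
        rng = np.random.default_rng(8)
        G = make_genotypes(rng.integers(0, 3, size=(60, 4)))
        y = make_phenotypes(G, rng.normal(45, 5, 60))
        res = epi.mcmc_search(G, y, iterations=2000, burnin=500, seed=4,
                              phenotype_mode="discrete")
        assert res.n_retained == 1500
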