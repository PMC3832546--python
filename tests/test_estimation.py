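"""EM estimation of the three nested Poisson abundance models."""

import numpy as np
import pytest
from scipy import stats

from isodiff import (
    IsoformAbundanceModel,
    ReadCategoryTable,
    confidence_intervals,
    default_sim_gene,
    fit_model0,
    fit_model1,
    fit_model2,
    simulate_counts,
)
from isodiff.estimation import loglik

from conftest import optimizer_loglik, random_instance


def table(counts, rates, totals, cond="c1"):
    return ReadCategoryTable(
        condition_id=cond,
        counts=np.asarray(counts, dtype=float),
        rates=np.asarray(rates, dtype=float),
        isoform_totals=np.asarray(totals, dtype=float),
        total_reads_mapped=int(np.sum(counts)),
    )


class TestLoglik:
    def test_direct_substitution(self):
        t = table([3], [[1.0]], [1.0])
        assert loglik(np.array([1.0]), t) == pytest.approx(-1.0)  # 3·log1 − 1

    def test_zero_theta_zero_counts(self):
        t = table([1], [[1.0]], [1.0])
        t.counts[:] = 0  # no reads at all
        assert loglik(np.array([0.0]), t) == 0.0

    def test_zero_mean_with_reads_is_minus_inf(self):
        t = table([2, 3], [[1.0, 0.0], [0.0, 1.0]], [1.0, 1.0])
        assert loglik(np.array([0.0, 1.0]), t) == -np.inf

    def test_negative_theta_rejected(self):
        t = table([3], [[1.0]], [1.0])
        with pytest.raises(ValueError, match="non-negative"):
            loglik(np.array([-0.5]), t)

    def test_matches_poisson_pmf_up_to_constant(self):
        """Differences of the reduced log-likelihood equal differences of
        the exact Poisson log-pmf (the dropped log n! terms cancel)."""
        rng = np.random.default_rng(3)
        tables, _ = random_instance(rng, K=1, I=2, J=4)
        t = tables[0]

        def exact(theta):
            mu = t.rates @ theta
            return stats.poisson.logpmf(t.counts, mu).sum() - (
                t.isoform_totals @ theta - mu.sum()
            )

        th_a = np.array([1.3, 2.1])
        th_b = np.array([0.7, 3.9])
        assert loglik(th_a, t) - loglik(th_b, t) == pytest.approx(
            exact(th_a) - exact(th_b), abs=1e-9
        )


class TestFitModel2:
    def test_isoform_specific_closed_form(self):
        """With no read sharing the MLE is reads/total-rate per isoform."""
        t1 = table([6, 10], [[2.0, 0.0], [0.0, 4.0]], [3.0, 5.0])
        est = fit_model2([t1])
        assert est.theta[0] == pytest.approx([6 / 3.0, 10 / 5.0], rel=1e-8)

    def test_zero_reads_condition_gives_zero_vector(self):
        t_empty = ReadCategoryTable("c1", np.zeros(0), np.zeros((0, 2)), [3.0, 5.0], 0)
        est = fit_model2([t_empty])
        assert est.theta.tolist() == [[0.0, 0.0]]
        assert est.loglik == 0.0

    def test_em_matches_numerical_optimizer(self, sim_gene):
        """On simulated cassette-gene data the EM optimum agrees with a
        generic box-constrained optimizer to 1e-4 in log-likelihood."""
        rng = np.random.default_rng(7)
        theta = np.array([[8.0, 2.0], [2.0, 8.0]])
        tables = simulate_counts(theta, sim_gene, (50e6, 55e6), 50, rng)
        est = fit_model2(tables)
        oracle = optimizer_loglik(tables, model=2)
        assert est.loglik >= oracle - 1e-4 * abs(oracle)
        assert est.loglik == pytest.approx(oracle, rel=1e-4)


class TestFitModel0:
    def test_single_condition_equals_model2(self):
        rng = np.random.default_rng(11)
        tables, _ = random_instance(rng, K=1, I=2, J=4)
        e0 = fit_model0(tables)
        e2 = fit_model2(tables)
        assert e0.loglik == pytest.approx(e2.loglik, abs=1e-8)
        assert np.allclose(e0.theta, e2.theta, atol=1e-6)

    def test_identical_conditions_recover_single_condition_mle(self):
        rng = np.random.default_rng(12)
        tables, _ = random_instance(rng, K=1, I=2, J=5)
        t = tables[0]
        e_single = fit_model2([t])
        e0 = fit_model0([t, t])
        assert np.allclose(e0.theta_tilde, e_single.theta[0], rtol=1e-5, atol=1e-8)
        assert e0.loglik == pytest.approx(2 * e_single.loglik, rel=1e-8)


class TestFitModel1:
    def test_requires_two_conditions(self):
        t = table([3], [[1.0]], [1.0])
        with pytest.raises(ValueError, match="two conditions"):
            fit_model1([t])

    def test_tau_sums_to_K(self):
        rng = np.random.default_rng(13)
        tables, _ = random_instance(rng, K=3, I=2, J=5)
        e1 = fit_model1(tables)
        assert e1.tau.sum() == pytest.approx(3.0, abs=1e-9)

    def test_equal_conditions_reduce_to_model0(self):
        rng = np.random.default_rng(14)
        tables, _ = random_instance(rng, K=1, I=2, J=5)
        t = tables[0]
        e0 = fit_model0([t, t])
        e1 = fit_model1([t, t])
        assert e1.loglik == pytest.approx(e0.loglik, abs=1e-6)
        assert np.allclose(e1.tau, 1.0, atol=1e-4)

    def test_pure_fold_change_recovered(self, sim_gene):
        """Counts generated at θ₂ = 3·θ₁ give a τ̂ ratio near 3."""
        rng = np.random.default_rng(15)
        theta = np.vstack([[4.0, 4.0], [12.0, 12.0]])
        tables = simulate_counts(theta, sim_gene, (50e6, 50e6), 50, rng)
        e1 = fit_model1(tables)
        assert e1.tau[1] / e1.tau[0] == pytest.approx(3.0, rel=0.1)
        oracle = optimizer_loglik(tables, model=1)
        assert e1.loglik >= oracle - 1e-4
        assert e1.loglik == pytest.approx(oracle, rel=1e-6)

    def test_single_isoform_equals_model2(self):
        rng = np.random.default_rng(16)
        tables, _ = random_instance(rng, K=2, I=1, J=3)
        e1 = fit_model1(tables)
        e2 = fit_model2(tables)
        assert e1.loglik == pytest.approx(e2.loglik, abs=1e-6)
        assert e1.df == 2 and e2.df == 2  # I+K−1 == K·I when I = 1


class TestNestingAndMonotonicity:
    @pytest.mark.parametrize("seed", range(8))
    def test_loglik_nesting(self, seed):
        """l0 ≤ l1 ≤ l2 for every instance (models are nested)."""
        rng = np.random.default_rng(100 + seed)
        tables, _ = random_instance(rng)
        e0, e1, e2 = fit_model0(tables), fit_model1(tables), fit_model2(tables)
        assert e0.loglik <= e1.loglik + 1e-6
        assert e1.loglik <= e2.loglik + 1e-6

    @pytest.mark.parametrize("model", [0, 1])
    def test_em_loglik_nondecreasing(self, model):
        rng = np.random.default_rng(17)
        tables, _ = random_instance(rng, K=2, I=3, J=6)
        est = IsoformAbundanceModel(model=model).fit(tables).estimate_
        path = np.array(est.loglik_path)
        assert np.all(np.diff(path) >= -1e-9)

    def test_em_single_condition_path_monotone(self):
        rng = np.random.default_rng(18)
        tables, _ = random_instance(rng, K=1, I=3, J=6)
        est = fit_model2(tables)
        path = np.array(est.loglik_path)
        assert np.all(np.diff(path) >= -1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_all_models(self, seed):
        """EM optima match the generic optimizer within 1e-4 log-likelihood
        on small random instances."""
        rng = np.random.default_rng(200 + seed)
        tables, _ = random_instance(rng)
        for model, fit in ((0, fit_model0), (1, fit_model1), (2, fit_model2)):
            est = fit(tables)
            oracle = optimizer_loglik(tables, model=model, seed=seed)
            # EM must reach the optimizer's optimum; it may exceed it if
            # the generic optimizer under-converges on a ridge
            assert est.loglik >= oracle - 1e-4


class TestRateScalingInvariance:
    def test_scaling_rates_and_theta_inversely_preserves_means(self):
        """a→c·a with θ→θ/c leaves category means (hence counts' law)
        unchanged; fitted log-likelihoods shift only via the linear
        penalty identity."""
        rng = np.random.default_rng(19)
        tables, _ = random_instance(rng, K=2, I=2, J=4)
        c = 3.7
        scaled = [
            ReadCategoryTable(
                t.condition_id, t.counts.copy(), c * t.rates,
                c * t.isoform_totals, t.total_reads_mapped,
            )
            for t in tables
        ]
        e = fit_model2(tables)
        e_s = fit_model2(scaled)
        assert np.allclose(e_s.theta * c, e.theta, rtol=1e-6, atol=1e-9)
        # category means (c·a)·(θ/c) = a·θ and the penalty (c·a_tot)·(θ/c)
        # are both unchanged, so the fitted log-likelihood is identical
        assert e_s.loglik == pytest.approx(e.loglik, rel=1e-8)


class TestConfidenceIntervals:
    def test_poisson_closed_form(self):
        """One isoform, unit rate: the Wald interval is n ± z·√n."""
        n = 100
        t = table([n], [[1.0]], [1.0])
        est = fit_model2([t])
        ci = confidence_intervals(est, [t], level=0.95)["theta"]
        z = stats.norm.ppf(0.975)
        assert ci[0, 0, 0] == pytest.approx(n - z * np.sqrt(n), rel=1e-6)
        assert ci[0, 0, 1] == pytest.approx(n + z * np.sqrt(n), rel=1e-6)

    def test_zero_count_isoform_one_sided(self):
        t = table([8], [[2.0, 0.0]], [4.0, 3.0])
        est = fit_model2([t])
        assert est.theta[0, 1] == 0.0
        ci = confidence_intervals(est, [t], level=0.95)["theta"]
        assert ci[0, 1, 0] == 0.0
        assert ci[0, 1, 1] == pytest.approx(-np.log(0.05) / 3.0, rel=1e-9)

    def test_model1_intervals_cover_point_estimates(self):
        rng = np.random.default_rng(21)
        tables, _ = random_instance(rng, K=2, I=2, J=5)
        e1 = fit_model1(tables)
        ci = confidence_intervals(e1, tables, level=0.95)
        for i, th in enumerate(e1.theta_tilde):
            if th > 0 and np.isfinite(ci["theta_tilde"][i]).all():
                assert ci["theta_tilde"][i, 0] <= th <= ci["theta_tilde"][i, 1]
        for k, tv in enumerate(e1.tau):
            if np.isfinite(ci["tau"][k]).all():
                assert ci["tau"][k, 0] <= tv <= ci["tau"][k, 1]

    def test_coverage_near_nominal(self, sim_gene):
        """Wald intervals at moderate depth cover the true abundances at
        roughly the nominal 95% rate."""
        rng = np.random.default_rng(22)
        theta = np.array([[6.0, 4.0], [3.0, 7.0]])
        hits = 0
        total = 0
        for _ in range(120):
            tables = simulate_counts(theta, sim_gene, (50e6, 55e6), 50, rng)
            est = fit_model2(tables)
            ci = confidence_intervals(est, tables, level=0.95)["theta"]
            for k in range(2):
                for i in range(2):
                    if np.isfinite(ci[k, i]).all():
                        total += 1
                        hits += ci[k, i, 0] <= theta[k, i] <= ci[k, i, 1]
        assert total > 400
        assert 0.88 <= hits / total <= 0.99

    def test_bad_level_rejected(self):
        t = table([3], [[1.0]], [1.0])
        est = fit_model2([t])
        with pytest.raises(ValueError, match="level"):
            confidence_intervals(est, [t], level=1.5)
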