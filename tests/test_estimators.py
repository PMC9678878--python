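"""Estimator correctness: closed forms, recovery, coherence, intervals."""

import numpy as np
import pytest
from scipy import integrate

from gride.distributions import GrideLaw, lomax_predictive_pdf, sample_gride_ratio
from gride.errors import (
    BoundaryRatioError,
    InsufficientDataError,
    ParameterError,
)
from gride.estimators import (
    gride_loglik,
    gride_mle,
    gride_score,
    lb_estimator,
    mg_bayes,
    mg_mle,
    moment_estimator,
    twonn_bayes,
    twonn_ls,
    twonn_mle,
)
from gride.neighbors import (
    ConsecutiveRatios,
    NeighborTable,
    RatioSample,
    build_neighbor_table,
    consecutive_ratios,
    generalized_ratios,
)
from gride.synthetic_data import make_hypercube


def _ratio_sample(values, n1=1, n2=2):
    return RatioSample(values=np.asarray(values, dtype=float), n1=n1, n2=n2)


def _pareto_draws(d, n, seed):
    rng = np.random.default_rng(seed)
    return (1.0 - rng.random(n)) ** (-1.0 / d)


class TestTwoNNMle:
    def test_closed_form_hand_value(self):
        est = twonn_mle(_ratio_sample([np.e, np.e, np.e]))
        assert est.d_hat == pytest.approx(2.0 / 3.0)
        assert est.ci_low < est.d_hat < est.ci_high

    def test_recovers_pareto_shape(self):
        d, n = 3.0, 100_000
        est = twonn_mle(_ratio_sample(_pareto_draws(d, n, 0)))
        assert est.d_hat == pytest.approx(d, abs=3 * d / np.sqrt(n))

    def test_rejects_wrong_orders(self):
        with pytest.raises(ParameterError):
            twonn_mle(_ratio_sample([2.0, 3.0, 4.0], n1=2, n2=4))


class TestTwoNNLs:
    def test_exact_pareto_quantile_grid(self):
        d, n = 2.0, 1000
        i = np.arange(1, n + 1)
        mu = (1.0 - i / (n + 1)) ** (-1.0 / d)
        est = twonn_ls(_ratio_sample(mu), trim=0.90)
        assert est.d_hat == pytest.approx(d, rel=0.02)

    def test_top_point_always_dropped(self):
        # trim=1 must still exclude the empirical-CDF point at 1 (infinite ordinate)
        mu = (1.0 - np.arange(1, 101) / 101.0) ** (-1.0 / 3.0)
        est = twonn_ls(_ratio_sample(mu), trim=1.0)
        assert np.isfinite(est.d_hat)
        assert est.n_effective == 99

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            twonn_ls(_ratio_sample([1.1, 1.2, 1.3, 1.4]), trim=0.5)


class TestTwoNNBayes:
    def test_conjugate_update(self):
        post, est = twonn_bayes(_ratio_sample([np.e, np.e, np.e]), 1.0, 1.0)
        assert (post.shape, post.rate) == (4.0, 4.0)
        assert est.d_hat == pytest.approx(1.0)

    def test_posterior_concentrates(self):
        d = 4.0
        post, est = twonn_bayes(_ratio_sample(_pareto_draws(d, 50_000, 1)), 1.0, 1.0)
        assert est.d_hat == pytest.approx(d, rel=0.02)
        assert est.ci_high - est.ci_low < 0.2

    def test_predictive_density_normalized(self):
        post, _ = twonn_bayes(_ratio_sample(_pareto_draws(2.0, 500, 2)), 1.0, 1.0)
        val, _ = integrate.quad(
            lambda m: lomax_predictive_pdf(m, post), 1.0, np.inf, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-8)


class TestGrideMle:
    def test_consecutive_orders_closed_form(self):
        mu = _pareto_draws(2.5, 500, 3)
        est = gride_mle(_ratio_sample(mu, 1, 2))
        assert est.d_hat == pytest.approx(500 / np.log(mu).sum())

    def test_coherence_with_twonn(self):
        """gride(1,2) * (n-1)/n equals the unbiased TWO-NN MLE exactly."""
        mu = _pareto_draws(3.0, 777, 4)
        g = gride_mle(_ratio_sample(mu, 1, 2)).d_hat
        t = twonn_mle(_ratio_sample(mu, 1, 2)).d_hat
        assert g * 776 / 777 == pytest.approx(t, rel=1e-12)

    def test_recovery_at_high_orders(self):
        law = GrideLaw(d=2.0, n1=10, n2=20)
        mu = sample_gride_ratio(law, 10_000, rng=5)
        est = gride_mle(
            RatioSample(mu, 10, 20), bootstrap_reps=200, seed=11, level=0.95
        )
        boot_se = (est.ci_high - est.ci_low) / 4.0  # rough normal-scale width
        assert est.d_hat == pytest.approx(2.0, abs=3 * max(boot_se, 0.01))
        assert est.ci_low <= est.d_hat <= est.ci_high

    def test_score_zero_at_optimum(self):
        law = GrideLaw(d=5.0, n1=4, n2=9)
        rs = RatioSample(sample_gride_ratio(law, 2000, rng=6), 4, 9)
        est = gride_mle(rs)
        assert abs(gride_score(est.d_hat, rs)) < 1e-8 * rs.n

    def test_loglik_concavity_spot_check(self, rng):
        law = GrideLaw(d=3.0, n1=3, n2=8)
        rs = RatioSample(sample_gride_ratio(law, 500, rng=7), 3, 8)
        for d in rng.uniform(0.1, 50.0, size=50):
            h = 1e-4 * d
            second = (
                gride_loglik(d + h, rs) - 2 * gride_loglik(d, rs) + gride_loglik(d - h, rs)
            ) / h**2
            assert second < 0

    def test_boundary_ratio_rejected(self):
        with pytest.raises(BoundaryRatioError):
            gride_mle(_ratio_sample([1.0, 1.5, 2.0], 2, 5))

    def test_bootstrap_requires_seed(self):
        mu = _pareto_draws(2.0, 100, 8)
        with pytest.raises(ParameterError):
            gride_mle(_ratio_sample(mu, 1, 2), bootstrap_reps=10)


class TestMg:
    def test_reduces_to_twonn_at_L2(self):
        mu = _pareto_draws(2.0, 300, 9)
        cons = ConsecutiveRatios(values=mu[:, None], L=2)
        assert mg_mle(cons).d_hat == pytest.approx(
            twonn_mle(_ratio_sample(mu)).d_hat, rel=1e-12
        )

    def test_direct_substitution_value(self):
        # mu_{i,l} = exp(1/(l-1)): weighted log sum is n*(L-1) = 30, d = 29/30
        n, L = 10, 4
        mu = np.exp(1.0 / np.arange(1, L))[None, :].repeat(n, axis=0)
        est = mg_mle(ConsecutiveRatios(values=mu, L=L))
        assert est.d_hat == pytest.approx(29.0 / 30.0)
        assert est.n_effective == 30

    def test_bayes_matches_mle_asymptotically(self):
        rng = np.random.default_rng(10)
        d, n, L = 2.0, 4000, 5
        shapes = np.arange(1, L) * d
        mu = (1.0 - rng.random((n, L - 1))) ** (-1.0 / shapes)
        cons = ConsecutiveRatios(values=mu, L=L)
        post, est_b = mg_bayes(cons, 0.001, 0.001)
        assert est_b.d_hat == pytest.approx(mg_mle(cons).d_hat, rel=1e-3)

    def test_bayes_reduces_to_twonn_bayes_at_L2(self):
        mu = _pareto_draws(3.0, 200, 11)
        post_mg, _ = mg_bayes(ConsecutiveRatios(values=mu[:, None], L=2), 1.0, 1.0)
        post_2nn, _ = twonn_bayes(_ratio_sample(mu), 1.0, 1.0)
        assert post_mg.shape == post_2nn.shape
        assert post_mg.rate == pytest.approx(post_2nn.rate)

    def test_posterior_parameters_grow_with_L(self, random_table):
        _, table = random_table
        posts = [
            mg_bayes(consecutive_ratios(table, L), 1.0, 1.0)[0] for L in (2, 4, 8)
        ]
        assert posts[0].shape < posts[1].shape < posts[2].shape
        assert posts[0].rate < posts[1].rate < posts[2].rate


class TestLb:
    @staticmethod
    def _unit_statistic_table(n=20, kmax=8):
        # construct log-distances with sum_{j<k} log(r_k/r_j) = k-1 for all k
        a = np.zeros(kmax)
        for k in range(2, kmax + 1):
            a[k - 1] = 1.0 + a[: k - 1].sum() / (k - 1)
        dist = np.exp(a)[None, :].repeat(n, axis=0)
        return NeighborTable(distances=dist, indices=None)

    def test_unit_statistic_gives_one(self):
        table = self._unit_statistic_table()
        assert lb_estimator(table, 2, 8, corrected=False).d_hat == pytest.approx(1.0)
        assert lb_estimator(table, 2, 8, corrected=True).d_hat == pytest.approx(1.0)

    def test_single_term_corrected_is_pareto_mle(self, random_table):
        _, table = random_table
        est = lb_estimator(table, 2, 2, corrected=True)
        mu = generalized_ratios(table, 1, 2)
        assert est.d_hat == pytest.approx(table.n / np.log(mu.values).sum())

    def test_hypercube_recovery(self):
        x, _ = make_hypercube(n=2500, d=5, seed=11)
        table = build_neighbor_table(x, kmax=20)
        est = lb_estimator(table, 10, 20, corrected=True)
        assert est.d_hat == pytest.approx(5.0, rel=0.10)


class TestMomentEstimator:
    def test_pareto_mean_inversion(self):
        # sample mean exactly 2 with orders (1,2): Pareto mean d/(d-1) = 2 at d = 2
        est = moment_estimator(_ratio_sample([1.5, 2.5]))
        assert est.d_hat == pytest.approx(2.0, abs=1e-9)

    def test_mean_near_one_out_of_range(self):
        with pytest.raises(ParameterError):
            moment_estimator(_ratio_sample([1.0000001, 1.0000002]))

    def test_sampler_recovery(self):
        law = GrideLaw(d=4.0, n1=8, n2=16)
        mu = sample_gride_ratio(law, 10_000, rng=13)
        est = moment_estimator(RatioSample(mu, 8, 16))
        # delta-method scale: 3 MC standard errors on the mean, inflated
        # through the inverse slope; generous absolute bound
        assert est.d_hat == pytest.approx(4.0, abs=0.3)


class TestInvariances:
    def test_all_estimators_scale_invariant(self, rng):
        x = rng.standard_normal((200, 4))
        for factor in (0.01, 7.0):
            t1 = build_neighbor_table(x, kmax=10)
            t2 = build_neighbor_table(factor * x, kmax=10)
            a = twonn_mle(generalized_ratios(t1, 1, 2)).d_hat
            b = twonn_mle(generalized_ratios(t2, 1, 2)).d_hat
            assert a == pytest.approx(b, rel=1e-10)
            ga = gride_mle(generalized_ratios(t1, 3, 7)).d_hat
            gb = gride_mle(generalized_ratios(t2, 3, 7)).d_hat
            assert ga == pytest.approx(gb, rel=1e-8)
            ma = mg_mle(consecutive_ratios(t1, 6)).d_hat
            mb = mg_mle(consecutive_ratios(t2, 6)).d_hat
            assert ma == pytest.approx(mb, rel=1e-10)

    def test_serialization_roundtrip(self):
        est = twonn_mle(_ratio_sample(_pareto_draws(2.0, 100, 14)))
        record = est.to_dict()
        assert record["method"] == "twonn_mle"
        assert record["n_effective"] == 100
        import json

        assert json.loads(est.to_json())["d_hat"] == pytest.approx(est.d_hat)


class TestConsistency:
    @pytest.mark.parametrize("d", [2.0, 5.0])
    def test_gride_bias_vanishes_at_large_n(self, d):
        """On draws from the exact ratio law the MLE bias at n=1e5 is < 1% of d."""
        law = GrideLaw(d=d, n1=4, n2=8)
        mu = sample_gride_ratio(law, 100_000, rng=17)
        est = gride_mle(RatioSample(mu, 4, 8))
        assert abs(est.d_hat - d) < 0.01 * d
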