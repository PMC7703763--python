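import time

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from pseudoclust.likelihood import (
    ClusterCovParts,
    Hyperparameters,
    LikelihoodCache,
    NumericalError,
    block_logdet,
    block_quadform,
    cluster_cov_parts,
    cluster_marginal_loglik,
    crp_log_prior,
    joint_log_posterior,
    log_hyper_prior,
)

_LOG2PI = np.log(2 * np.pi)


def random_psd_parts(rng, T):
    def psd():
        W = rng.standard_normal((T, T + 2))
        return W @ W.T / (T + 2) + 0.1 * np.eye(T)

    return ClusterCovParts(A=psd(), B=psd())


def dense_block_cov(parts, n_c):
    return np.kron(np.eye(n_c), parts.A) + np.kron(np.ones((n_c, n_c)), parts.B)


def random_hyper(rng):
    return Hyperparameters(
        a=float(rng.uniform(0.5, 2.0)),
        L=float(rng.uniform(0.2, 1.0)),
        a1=float(rng.uniform(0.2, 0.9)),
        eps=float(rng.uniform(0.05, 0.5)),
        alpha=float(rng.uniform(0.3, 2.0)),
    )


class TestCovParts:
    def test_scalar_gene_level(self):
        h = Hyperparameters(a=1.0, L=1.0, a1=0.5, eps=0.1, alpha=1.0)
        parts = cluster_cov_parts(np.array([0.0]), h)
        np.testing.assert_allclose(parts.A, [[1.0]])  # 1*0.5 + 0.5

    def test_scalar_mean_level(self):
        h = Hyperparameters(a=1.0, L=2.0, a1=0.5, eps=0.5, alpha=1.0)
        parts = cluster_cov_parts(np.array([0.0]), h)
        np.testing.assert_allclose(parts.B, [[3.5]])  # 3 a^2 + eps

    def test_pure_signal_limit(self):
        h = Hyperparameters(a=1.0, L=1.0, a1=1 - 1e-12, eps=0.1, alpha=1.0)
        parts = cluster_cov_parts(np.array([0.0, 0.5]), h)
        # the white-noise diagonal term vanishes as a1 -> 1
        np.testing.assert_allclose(np.diag(parts.A), [1.0, 1.0], atol=1e-10)

    def test_invalid_hyper(self):
        for kwargs in (
            dict(a=-1.0),
            dict(L=0.0),
            dict(a1=1.0),
            dict(a1=0.0),
            dict(eps=-0.1),
            dict(alpha=0.0),
        ):
            full = dict(a=1.0, L=1.0, a1=0.5, eps=0.1, alpha=1.0)
            full.update(kwargs)
            with pytest.raises(ValueError):
                Hyperparameters(**full)


@pytest.mark.parametrize("n_c", [1, 2, 3, 5])
@pytest.mark.parametrize("T", [1, 3, 8])
def test_block_identities_match_dense_oracle(n_c, T, rng):
    """Block logdet/quadform equal dense Kronecker-assembled computation."""
    for _ in range(5):
        parts = random_psd_parts(rng, T)
        M = dense_block_cov(parts, n_c)
        Y = rng.standard_normal((n_c, T))
        y = Y.reshape(-1)
        sign, logdet = np.linalg.slogdet(M)
        assert sign > 0
        assert block_logdet(parts, n_c) == pytest.approx(logdet, rel=1e-8, abs=1e-8)
        expected_quad = y @ np.linalg.solve(M, y)
        assert block_quadform(Y, parts) == pytest.approx(expected_quad, rel=1e-8)


def test_block_logdet_single_gene(rng):
    parts = random_psd_parts(rng, 3)
    expected = np.linalg.slogdet(parts.A + parts.B)[1]
    assert block_logdet(parts, 1) == pytest.approx(expected, rel=1e-10)


def test_block_logdet_hand_example():
    # T=1, A=[2], B=[1], n_c=2: dense [[3,1],[1,3]] has determinant 8
    parts = ClusterCovParts(A=np.array([[2.0]]), B=np.array([[1.0]]))
    assert block_logdet(parts, 2) == pytest.approx(np.log(8.0), rel=1e-10)


def test_block_quadform_zero_data(rng):
    parts = random_psd_parts(rng, 4)
    assert block_quadform(np.zeros((3, 4)), parts) == 0.0


def test_block_quadform_single_gene(rng):
    parts = random_psd_parts(rng, 4)
    y = rng.standard_normal(4)
    expected = y @ np.linalg.solve(parts.A + parts.B, y)
    assert block_quadform(y[None, :], parts) == pytest.approx(expected, rel=1e-8)


def test_nonpositive_definite_raises():
    parts = ClusterCovParts(A=-np.eye(2), B=np.zeros((2, 2)))
    with pytest.raises(NumericalError):
        block_logdet(parts, 2)


class TestMarginalLoglik:
    def test_standard_normal_point(self):
        # n_c=1, T=1, y=0 and unit total variance: density of N(0,1) at 0
        # total variance A + B = a^2 + 3 a^2 + eps = 1 at a = 0.5
        h = Hyperparameters(a=0.5, L=1.0, a1=0.5, eps=1e-12, alpha=1.0)
        ll = cluster_marginal_loglik(np.zeros((1, 1)), np.array([0.0]), h)
        assert ll == pytest.approx(-0.5 * _LOG2PI, abs=1e-6)

    @pytest.mark.parametrize("n_c,T", [(1, 1), (2, 3), (3, 6)])
    def test_matches_dense_mvn(self, n_c, T, rng):
        tau = np.sort(rng.random(T))
        h = random_hyper(rng)
        Y = rng.standard_normal((n_c, T))
        parts = cluster_cov_parts(tau, h)
        M = dense_block_cov(parts, n_c)
        expected = multivariate_normal(np.zeros(n_c * T), M).logpdf(Y.reshape(-1))
        assert cluster_marginal_loglik(Y, tau, h) == pytest.approx(expected, rel=1e-8)

    def test_exchangeable_in_genes(self, rng):
        tau = np.sort(rng.random(5))
        h = random_hyper(rng)
        Y = rng.standard_normal((4, 5))
        base = cluster_marginal_loglik(Y, tau, h)
        for _ in range(3):
            perm = rng.permutation(4)
            assert cluster_marginal_loglik(Y[perm], tau, h) == pytest.approx(base, rel=1e-10)

    def test_noise_scale_peak_at_sample_variance(self, rng):
        """For pure white noise the likelihood peaks where the modelled
        noise variance matches the sample second moment (1-D grid search)."""
        y = rng.standard_normal(5) * 1.5
        sample_var = float(np.mean(y**2))
        grid = np.linspace(0.2 * sample_var, 3.0 * sample_var, 121)

        def ll(s2):
            parts = ClusterCovParts(A=s2 * np.eye(5), B=1e-10 * np.eye(5))
            return -0.5 * (
                block_quadform(y[None, :], parts) + block_logdet(parts, 1) + 5 * _LOG2PI
            )

        values = [ll(s2) for s2 in grid]
        assert grid[int(np.argmax(values))] == pytest.approx(sample_var, rel=0.05)

    def test_flat_cost_in_cluster_size(self, rng):
        """O(T^3 + n_c T^2) scaling: a 3000-gene cluster evaluates in well
        under a second, impossible under dense O((n_c T)^3) assembly."""
        tau = np.linspace(0, 1, 10)
        h = random_hyper(rng)
        Y = rng.standard_normal((3000, 10))
        start = time.perf_counter()
        cluster_marginal_loglik(Y, tau, h)
        assert time.perf_counter() - start < 1.0


def test_cache_matches_direct_evaluation(rng):
    tau = np.sort(rng.random(6))
    h = random_hyper(rng)
    Y = rng.standard_normal((5, 6))
    cache = LikelihoodCache(Y, tau, h)
    for members in ([0], [1, 3], [0, 2, 4], list(range(5))):
        direct = cluster_marginal_loglik(Y[members], tau, h)
        assert cache.loglik(members) == pytest.approx(direct, rel=1e-8)


class TestJointPosterior:
    def test_invariant_to_cluster_relabeling(self, rng):
        Y = rng.standard_normal((5, 6))
        h = random_hyper(rng)
        order = rng.permutation(6)
        labels = np.array([0, 1, 0, 2, 1])
        relabeled = np.array([2, 0, 2, 1, 0])
        assert joint_log_posterior(Y, order, labels, h) == pytest.approx(
            joint_log_posterior(Y, order, relabeled, h), rel=1e-12
        )

    def test_invariant_to_order_reversal(self, rng):
        Y = rng.standard_normal((4, 7))
        h = random_hyper(rng)
        order = rng.permutation(7)
        labels = np.array([0, 0, 1, 1])
        assert joint_log_posterior(Y, order, labels, h) == pytest.approx(
            joint_log_posterior(Y, order[::-1], labels, h), rel=1e-10
        )

    def test_a1_prior_is_beta_4_1(self):
        # the a1-dependence of the prior must match Beta(4,1): density 4 x^3
        base = dict(a=1.0, L=1.0, eps=0.1, alpha=1.0)
        lp_hi = log_hyper_prior(Hyperparameters(a1=0.999, **base))
        lp_lo = log_hyper_prior(Hyperparameters(a1=0.5, **base))
        expected = np.log(4 * 0.999**3) - np.log(4 * 0.5**3)
        assert lp_hi - lp_lo == pytest.approx(expected, rel=1e-10)

    def test_crp_prior_normalised_over_partitions(self):
        from conftest import set_partitions

        alpha = 1.7
        total = sum(
            np.exp(crp_log_prior([len(b) for b in p], alpha))
            for p in set_partitions(range(4))
        )
        assert total == pytest.approx(1.0, rel=1e-10)
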