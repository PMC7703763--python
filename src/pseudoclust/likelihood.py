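"""Collapsed marginal likelihood of a gene cluster under a hierarchical GP.

Each cluster owns a latent mean trajectory drawn from a GP with squared-
exponential covariance ``B = Sigma(tau, 3 a^2 + eps, L)``; the genes in the
cluster deviate from that mean by gene-level GP draws with covariance
``A = Sigma(tau, a^2 a1, 1) + a^2 (1 - a1) I`` (a smooth deviation plus white
noise; ``a1`` is the fraction of around-mean variation that is smooth signal
rather than noise).  Integrating the cluster mean out analytically, the
stacked data vector of a cluster with ``n_c`` genes is zero-mean Gaussian with
covariance ``I_{n_c} (x) A + J_{n_c} (x) B`` where ``J`` is the all-ones
matrix.  The block structure gives closed forms

    logdet = (n_c - 1) logdet(A) + logdet(A + n_c B)
    y' M^{-1} y = sum_j (y_j - ybar)' A^{-1} (y_j - ybar)
                  + n_c ybar' (A + n_c B)^{-1} ybar

so the cost per cluster is O(T^3) regardless of the cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.special import gammaln

from .kernels import squared_exponential_cov

__all__ = [
    "Hyperparameters",
    "ClusterCovParts",
    "NumericalError",
    "cluster_cov_parts",
    "block_logdet",
    "block_quadform",
    "cluster_marginal_loglik",
    "LikelihoodCache",
    "crp_log_prior",
    "log_hyper_prior",
    "joint_log_posterior",
]

_LOG2PI = np.log(2.0 * np.pi)

# DP concentration prior: Gamma with shape 2 and rate 4 (mean 1/2).
ALPHA_PRIOR_SHAPE = 2.0
ALPHA_PRIOR_RATE = 4.0
# Signal fraction prior Beta(4, 1): most around-mean variation is smooth.
A1_PRIOR_ALPHA = 4.0
A1_PRIOR_BETA = 1.0
# Weakly informative priors for the remaining hyperparameters:
# log a ~ N(0,1), log L ~ N(0,1), eps ~ Gamma(shape 1, rate 10).
EPS_PRIOR_RATE = 10.0


class NumericalError(RuntimeError):
    """A covariance matrix failed Cholesky factorisation even after jitter."""


@dataclass(frozen=True)
class Hyperparameters:
    """Model hyperparameters.

    a : overall amplitude; the gene-level marginal variance is a^2.
    L : length scale of the cluster-mean GP on the [0,1] pseudotime axis.
    a1 : in (0,1); fraction of around-mean variation that is smooth.
    eps : small positive offset in the cluster-mean scale 3 a^2 + eps.
    alpha : Dirichlet-process concentration.
    """

    a: float
    L: float
    a1: float
    eps: float
    alpha: float

    def __post_init__(self):
        if not (self.a > 0 and self.L > 0 and self.eps > 0 and self.alpha > 0):
            raise ValueError("a, L, eps and alpha must be positive")
        if not (0.0 < self.a1 < 1.0):
            raise ValueError("a1 must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class ClusterCovParts:
    """The two T x T blocks of a cluster covariance: gene-level A, mean-level B."""

    A: np.ndarray
    B: np.ndarray


def cluster_cov_parts(tau, hyper: Hyperparameters) -> ClusterCovParts:
    """Build the gene-level (A) and cluster-mean (B) covariance blocks."""
    tau = np.asarray(tau, dtype=float)
    a2 = hyper.a * hyper.a
    A = squared_exponential_cov(tau, a2 * hyper.a1, 1.0)
    A[np.diag_indices_from(A)] += a2 * (1.0 - hyper.a1)
    B = squared_exponential_cov(tau, 3.0 * a2 + hyper.eps, hyper.L)
    return ClusterCovParts(A=A, B=B)


def _jittered_cholesky(M: np.ndarray):
    """Cholesky, adding relative jitter only on failure (one 10x retry)."""
    T = M.shape[0]
    jitter = 1e-6 * np.trace(M) / T
    for factor in (0.0, 1.0, 10.0):
        try:
            return cho_factor(M + factor * jitter * np.eye(T), lower=True)
        except LinAlgError:
            continue
    raise NumericalError(
        f"covariance of size {T} not positive definite "
        f"(trace {np.trace(M):.3e}, jitter {jitter:.3e})"
    )


def _chol_logdet(chol) -> float:
    return 2.0 * float(np.sum(np.log(np.diag(chol[0]))))


def block_logdet(parts: ClusterCovParts, n_c: int) -> float:
    """log det of ``I_{n_c} (x) A + J_{n_c} (x) B`` in O(T^3)."""
    if n_c < 1:
        raise ValueError("n_c must be at least 1")
    cA = _jittered_cholesky(parts.A)
    cAB = _jittered_cholesky(parts.A + n_c * parts.B)
    return (n_c - 1) * _chol_logdet(cA) + _chol_logdet(cAB)


def block_quadform(Y_c: np.ndarray, parts: ClusterCovParts) -> float:
    """Quadratic form ``y' M^{-1} y`` for the block covariance, in O(T^3).

    ``Y_c`` has one row per gene in the cluster, columns ordered by the
    current cell order (the same ordering used to build ``parts``).
    """
    Y_c = np.atleast_2d(np.asarray(Y_c, dtype=float))
    n_c = Y_c.shape[0]
    ybar = Y_c.mean(axis=0)
    R = Y_c - ybar
    cA = _jittered_cholesky(parts.A)
    within = float(np.sum(R * cho_solve(cA, R.T).T))
    cAB = _jittered_cholesky(parts.A + n_c * parts.B)
    between = n_c * float(ybar @ cho_solve(cAB, ybar))
    return within + between


def cluster_marginal_loglik(Y_c: np.ndarray, tau, hyper: Hyperparameters) -> float:
    """Log marginal likelihood of a cluster's genes, mean integrated out.

    Equals the zero-mean multivariate-normal log density of ``vec(Y_c)``
    under covariance ``I (x) A + J (x) B``.
    """
    Y_c = np.atleast_2d(np.asarray(Y_c, dtype=float))
    parts = cluster_cov_parts(tau, hyper)
    n_c, T = Y_c.shape
    return -0.5 * (
        block_quadform(Y_c, parts) + block_logdet(parts, n_c) + n_c * T * _LOG2PI
    )


class LikelihoodCache:
    """Per-(order, hyperparameters) cache for fast cluster log-likelihoods.

    Precomputes the Cholesky factor of A, the solves ``A^{-1} y_j`` for every
    gene, and lazily caches factors of ``A + n B`` per occupied cluster size,
    so that the marginal log-likelihood of any gene subset costs O(T^2).
    """

    def __init__(self, Y_ordered: np.ndarray, tau, hyper: Hyperparameters):
        self.Y = np.asarray(Y_ordered, dtype=float)
        self.tau = np.asarray(tau, dtype=float)
        self.hyper = hyper
        self.n_genes, self.T = self.Y.shape
        self.parts = cluster_cov_parts(self.tau, hyper)
        self._cA = _jittered_cholesky(self.parts.A)
        self._logdetA = _chol_logdet(self._cA)
        # columns: A^{-1} y_j
        self._G = cho_solve(self._cA, self.Y.T)
        self._q = np.einsum("jt,tj->j", self.Y, self._G)
        self._AB = {}

    def _chol_AnB(self, n: int):
        entry = self._AB.get(n)
        if entry is None:
            chol = _jittered_cholesky(self.parts.A + n * self.parts.B)
            entry = (chol, _chol_logdet(chol))
            self._AB[n] = entry
        return entry

    def loglik(self, members) -> float:
        """Marginal log-likelihood of the cluster formed by ``members``."""
        idx = np.asarray(members, dtype=np.intp)
        n = idx.size
        if n == 0:
            return 0.0
        s = self.Y[idx].sum(axis=0)
        As = self._G[:, idx].sum(axis=1)
        within = float(self._q[idx].sum() - (s @ As) / n)
        cAB, ldAB = self._chol_AnB(n)
        between = float(s @ cho_solve(cAB, s)) / n
        logdet = (n - 1) * self._logdetA + ldAB
        return -0.5 * (within + between + logdet + n * self.T * _LOG2PI)

    def total_loglik(self, labels: np.ndarray) -> float:
        labels = np.asarray(labels)
        return float(
            sum(self.loglik(np.flatnonzero(labels == k)) for k in np.unique(labels))
        )


def crp_log_prior(cluster_sizes, alpha: float) -> float:
    """Log probability of a partition under the Chinese restaurant process."""
    sizes = np.asarray(cluster_sizes, dtype=float)
    if np.any(sizes < 1):
        raise ValueError("cluster sizes must be positive")
    n = sizes.sum()
    K = sizes.size
    return float(
        K * np.log(alpha)
        + np.sum(gammaln(sizes))
        + gammaln(alpha)
        - gammaln(alpha + n)
    )


def log_hyper_prior(hyper: Hyperparameters) -> float:
    """Joint log prior density of (a, L, a1, eps, alpha).

    a1 ~ Beta(4,1); alpha ~ Gamma(shape 2, rate 4); log a ~ N(0,1);
    log L ~ N(0,1); eps ~ Gamma(shape 1, rate 10).  Densities are with
    respect to the natural (untransformed) parameters.
    """
    la, lL = np.log(hyper.a), np.log(hyper.L)
    lp = 0.0
    # log a, log L standard normal; density in a-space includes 1/a Jacobian
    lp += -0.5 * (la * la + lL * lL) - _LOG2PI - la - lL
    # eps ~ Exponential(rate 10)
    lp += np.log(EPS_PRIOR_RATE) - EPS_PRIOR_RATE * hyper.eps
    # a1 ~ Beta(4, 1): density 4 x^3
    lp += np.log(A1_PRIOR_ALPHA) + (A1_PRIOR_ALPHA - 1.0) * np.log(hyper.a1)
    # alpha ~ Gamma(2, rate 4)
    lp += (
        ALPHA_PRIOR_SHAPE * np.log(ALPHA_PRIOR_RATE)
        - gammaln(ALPHA_PRIOR_SHAPE)
        + (ALPHA_PRIOR_SHAPE - 1.0) * np.log(hyper.alpha)
        - ALPHA_PRIOR_RATE * hyper.alpha
    )
    return float(lp)


def joint_log_posterior(Y: np.ndarray, order, labels, hyper: Hyperparameters) -> float:
    """Unnormalised joint log posterior of (order, partition, hyperparameters).

    Sum of the per-cluster marginal log-likelihoods, the CRP partition prior,
    and the hyperparameter priors; orders carry a uniform prior over
    permutations (a constant, omitted).
    """
    from .kernels import geodesic_pseudotime, validate_order

    Y = np.asarray(Y, dtype=float)
    labels = np.asarray(labels)
    order = validate_order(order, Y.shape[1])
    if labels.shape != (Y.shape[0],):
        raise ValueError("labels must assign one cluster per gene")
    tau = geodesic_pseudotime(Y, order)
    cache = LikelihoodCache(Y[:, order], tau, hyper)
    loglik = cache.total_loglik(labels)
    _, sizes = np.unique(labels, return_counts=True)
    return loglik + crp_log_prior(sizes, hyper.alpha) + log_hyper_prior(hyper)
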