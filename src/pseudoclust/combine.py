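"""Combining per-chain posterior similarity matrices.

Chains run on different cell subsamples produce PSMs of varying quality; four
combination strategies are provided:

``mean``
    element-wise unweighted arithmetic mean of the PSMs;
``DPM+PEAR`` / ``PY+PEAR``
    a weighted mean, with chain weights from a Dirichlet-process (or
    Pitman-Yor) mixture over genes with per-chain feature-selection
    indicators: chains whose PSM block is better explained by the shared
    partition than by a single component receive higher posterior inclusion,
    and the normalised inclusion probabilities are the weights;
``lmkk``
    localized multiple kernel k-means on the PSMs (each PSM is an admissible
    kernel), which learns per-gene, per-chain weights and yields a summary
    clustering directly.

For the first three, a summary clustering is extracted from the combined PSM
by the PEAR criterion.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import gammaln
from sklearn.cluster import KMeans

from .psm import SummaryClustering, pear, summary_clustering_pear, validate_psm

__all__ = [
    "mean_psm",
    "weighted_psm",
    "chain_weights_mixture",
    "lmkk_summary",
    "combine",
    "COMBINATION_METHODS",
]

logger = logging.getLogger(__name__)

COMBINATION_METHODS = ("mean", "DPM+PEAR", "PY+PEAR", "lmkk")
_METHOD_ALIASES = {
    "mean": "mean",
    "dpm+pear": "DPM+PEAR",
    "dpm-pear": "DPM+PEAR",
    "py+pear": "PY+PEAR",
    "py-pear": "PY+PEAR",
    "lmkk": "lmkk",
}


def _stack(psms) -> np.ndarray:
    psms = [np.asarray(p, dtype=float) for p in psms]
    if not psms:
        raise ValueError("need at least one PSM")
    shape = psms[0].shape
    if any(p.shape != shape for p in psms):
        raise ValueError("all PSMs must have the same dimensions and gene order")
    return np.stack(psms)


def mean_psm(psms) -> np.ndarray:
    """Element-wise unweighted mean; a convex combination of PSD matrices."""
    stacked = _stack(psms)
    out = stacked.mean(axis=0)
    np.fill_diagonal(out, 1.0)
    return out


def weighted_psm(psms, weights) -> np.ndarray:
    """Convex combination ``sum_m w_m PSM_m`` of the per-chain PSMs."""
    stacked = _stack(psms)
    w = np.asarray(weights, dtype=float)
    if w.shape != (stacked.shape[0],):
        raise ValueError("one weight per PSM required")
    if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be nonnegative and sum to 1")
    out = np.tensordot(np.clip(w, 0.0, None), stacked, axes=1)
    np.fill_diagonal(out, 1.0)
    return out


# --------------------------------------------------------------------------
# chain weighting via mixtures with feature selection
# --------------------------------------------------------------------------

def _gauss_marginal(n, s, ss, noise_var, prior_var):
    """Collapsed log marginal of n values per feature, N(mu, noise) mean-prior N(0, prior)."""
    denom = noise_var + n * prior_var
    return (
        -0.5 * n * np.log(2.0 * np.pi * noise_var)
        + 0.5 * np.log(noise_var / denom)
        - ss / (2.0 * noise_var)
        + prior_var * s * s / (2.0 * noise_var * denom)
    )


def chain_weights_mixture(
    psms,
    process: str = "DPM",
    rng=None,
    n_sweeps: int = 1000,
    discount: float = 0.25,
    noise_var: float = 0.04,
    prior_var: float = 0.25,
) -> np.ndarray:
    """Chain weights from a DP / Pitman-Yor mixture with feature selection.

    Genes are the observations; chain m contributes a feature block (the
    columns of its PSM, centred per feature).  A mixture over genes with a
    CRP (``process="DPM"``) or Pitman-Yor (``process="PY"``, discount d)
    partition prior is fitted by collapsed Gibbs sampling; each block carries
    a Bernoulli(1/2) inclusion indicator stating whether its features follow
    the cluster-specific means or one shared component.  The weight of chain
    m is its posterior inclusion frequency (second half of the sweeps),
    normalised across chains.  Deterministic given ``rng``.
    """
    stacked = _stack(psms)
    m, n_g, _ = stacked.shape
    if m < 2:
        raise ValueError("chain weighting requires at least two PSMs")
    if process not in ("DPM", "PY"):
        raise ValueError("process must be 'DPM' or 'PY'")
    d = float(discount) if process == "PY" else 0.0
    if not (0.0 <= d < 1.0):
        raise ValueError("discount must lie in [0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    # design matrix: one row per gene, blocks of centred PSM columns
    X = np.concatenate([stacked[i] - stacked[i].mean(axis=0) for i in range(m)], axis=1)
    D = X.shape[1]
    block = np.repeat(np.arange(m), n_g)

    z = np.zeros(n_g, dtype=np.intp)
    gamma = np.ones(m, dtype=bool)
    alpha = 1.0

    def block_logml(mask_features, labels):
        """Log marginal of the masked features under partition vs shared."""
        cols = X[:, mask_features]
        part = 0.0
        for k in np.unique(labels):
            sub = cols[labels == k]
            part += _gauss_marginal(
                sub.shape[0], sub.sum(axis=0), (sub**2).sum(axis=0), noise_var, prior_var
            ).sum()
        shared = _gauss_marginal(
            n_g, cols.sum(axis=0), (cols**2).sum(axis=0), noise_var, prior_var
        ).sum()
        return part, shared

    def py_alpha_logprior_term(a, K):
        # alpha-dependent part of the Pitman-Yor partition probability
        ks = np.arange(1, K)
        return float(np.sum(np.log(a + ks * d)) + gammaln(a + 1.0) - gammaln(a + n_g))

    inclusion = np.zeros(m)
    burn = n_sweeps // 2
    kept = 0
    for sweep in range(n_sweeps):
        feat_mask = gamma[block]
        Xi = X[:, feat_mask]
        # --- partition sweep (collapsed, on included features only) ---
        for i in range(n_g):
            labels_rest = np.delete(z, i)
            keys, counts = np.unique(labels_rest, return_counts=True)
            K = keys.size
            x = Xi[i]
            logw = np.empty(K + 1)
            for idx_k, (k, n_k) in enumerate(zip(keys, counts)):
                members = np.flatnonzero(labels_rest == k)
                members = members + (members >= i)  # undo the deletion shift
                s = Xi[members].sum(axis=0)
                post_var = prior_var * noise_var / (noise_var + n_k * prior_var)
                mu = prior_var * s / (noise_var + n_k * prior_var)
                pred_var = post_var + noise_var
                ll = -0.5 * np.sum(
                    np.log(2.0 * np.pi * pred_var) + (x - mu) ** 2 / pred_var
                )
                logw[idx_k] = np.log(n_k - d) + ll
            pred_var0 = prior_var + noise_var
            ll_new = -0.5 * np.sum(np.log(2.0 * np.pi * pred_var0) + x * x / pred_var0)
            logw[K] = np.log(alpha + d * K) + ll_new
            w = np.exp(logw - logw.max())
            choice = int(rng.choice(K + 1, p=w / w.sum()))
            z[i] = keys[choice] if choice < K else (keys.max() + 1 if K else 0)
        _, z = np.unique(z, return_inverse=True)

        # --- feature-selection indicators ---
        for b in range(m):
            part, shared = block_logml(block == b, z)
            log_bf = np.clip(part - shared, -700.0, 700.0)
            gamma[b] = rng.random() < 1.0 / (1.0 + np.exp(-log_bf))

        # --- concentration ---
        K = int(z.max()) + 1
        if process == "DPM":
            from .sampler import sample_alpha

            alpha = sample_alpha(alpha, K, n_g, rng)
        else:
            prop = alpha * np.exp(rng.normal(0.0, 0.3))
            log_ratio = (
                py_alpha_logprior_term(prop, K)
                - py_alpha_logprior_term(alpha, K)
                + 2.0 * (np.log(prop) - np.log(alpha))  # Gamma(2,4) prior + Jacobian
                - 4.0 * (prop - alpha)
            )
            if np.log(rng.random()) < log_ratio:
                alpha = prop

        if sweep >= burn:
            inclusion += gamma
            kept += 1

    inclusion /= max(kept, 1)
    if inclusion.sum() <= 0.0:
        logger.warning("no chain block selected in any sweep; falling back to uniform weights")
        return np.full(m, 1.0 / m)
    return inclusion / inclusion.sum()


# --------------------------------------------------------------------------
# localized multiple kernel k-means
# --------------------------------------------------------------------------

def _simplex_qp_diag(q: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Minimise ``0.5 q.theta^2 + g.theta`` over the probability simplex.

    ``q`` is the (nonnegative) diagonal of the Hessian.  The KKT conditions
    give ``theta_m = max(0, (lam - g_m) / q_m)`` with the dual ``lam`` fixed
    by the sum-to-one constraint; ``lam`` is found by bisection.
    """
    q = np.maximum(q, 1e-12)

    def total(lam):
        return np.sum(np.maximum(0.0, (lam - g) / q))

    lo = g.min()
    hi = g.max() + q.max()
    while total(hi) < 1.0:
        hi = 2.0 * hi - lo + 1.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if total(mid) < 1.0:
            lo = mid
        else:
            hi = mid
    theta = np.maximum(0.0, (hi - g) / q)
    return theta / theta.sum()


def lmkk_summary(
    psms,
    k: int,
    rng=None,
    max_iter: int = 100,
    tol: float = 1e-6,
    return_history: bool = False,
):
    """Localized multiple kernel k-means over per-chain PSM kernels.

    Alternates (i) a kernel k-means relaxation — the top-k eigenvectors H of
    the locally combined kernel ``K_theta(i,j) = sum_m theta_im theta_jm
    K_m(i,j)`` — with (ii) per-gene weight rows updated by an exact convex QP
    on the simplex.  The objective ``Tr((I - H H') K_theta)`` is non-
    increasing; iteration stops at relative change < ``tol`` or ``max_iter``.
    Returns hard labels (k-means++ seeded k-means in the embedding H) and the
    per-gene, per-chain weight matrix theta.
    """
    stacked = _stack(psms)
    for p in stacked:
        validate_psm(p)
    m, n_g, _ = stacked.shape
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    theta = np.full((n_g, m), 1.0 / m)
    prev_obj = np.inf
    history = []
    H = None
    for _ in range(max_iter):
        k_theta = np.einsum("im,jm,mij->ij", theta, theta, stacked)
        k_theta = 0.5 * (k_theta + k_theta.T)
        eigvals, eigvecs = np.linalg.eigh(k_theta)
        H = eigvecs[:, -k:]
        C = np.eye(n_g) - H @ H.T
        obj = float(np.sum(C * k_theta))
        history.append(obj)
        if prev_obj - obj < tol * max(1.0, abs(prev_obj)):
            prev_obj = obj
            break
        prev_obj = obj
        # per-gene simplex QPs (diagonal Hessian), one coordinate-descent pass
        for i in range(n_g):
            q = 2.0 * C[i, i] * stacked[:, i, i]
            g = 2.0 * np.einsum("j,mj,jm->m", C[i], stacked[:, i, :], theta) - (
                2.0 * C[i, i] * stacked[:, i, i] * theta[i]
            )
            try:
                theta[i] = _simplex_qp_diag(q, g)
            except (FloatingPointError, ValueError):  # pragma: no cover
                logger.warning("weight update failed for gene %d; keeping uniform row", i)
                theta[i] = np.full(m, 1.0 / m)

    seed = int(rng.integers(2**31 - 1))
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(H)
    if return_history:
        return labels, theta, history
    return labels, theta


def combine(
    psms,
    method: str = "mean",
    k_max: int | None = None,
    rng=None,
    linkage_method: str = "average",
    **weight_kwargs,
) -> SummaryClustering:
    """Combine per-chain PSMs into one summary clustering.

    ``mean``, ``DPM+PEAR`` and ``PY+PEAR`` build a (weighted) PSM and then
    apply the PEAR summary; ``lmkk`` scans k = 2..k_max and keeps the run
    whose labels maximise PEAR against the mean PSM.
    """
    canonical = _METHOD_ALIASES.get(method.lower())
    if canonical is None:
        raise ValueError(f"unknown combination method {method!r}; choose from {COMBINATION_METHODS}")
    stacked = _stack(psms)
    m, n_g, _ = stacked.shape
    if k_max is None:
        k_max = min(n_g - 1, 20)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    if canonical == "mean":
        P = mean_psm(stacked)
        sc = summary_clustering_pear(P, k_max, linkage_method)
        sc.chain_weights = np.full(m, 1.0 / m)
    elif canonical in ("DPM+PEAR", "PY+PEAR"):
        process = "DPM" if canonical.startswith("DPM") else "PY"
        weights = chain_weights_mixture(stacked, process=process, rng=rng, **weight_kwargs)
        P = weighted_psm(stacked, weights)
        sc = summary_clustering_pear(P, k_max, linkage_method)
        sc.chain_weights = weights
    else:  # lmkk
        P = mean_psm(stacked)
        best = None
        for k in range(2, max(k_max, 2) + 1):
            labels, theta = lmkk_summary(stacked, k, rng=rng)
            score = pear(labels, P)
            if best is None or score > best[0] + 1e-12:
                best = (score, labels, theta, k)
        score, labels, theta, k = best
        sc = SummaryClustering(
            labels=labels,
            pear_score=float(score),
            psm=P,
            chain_weights=theta.mean(axis=0) / theta.mean(axis=0).sum(),
            extras={"gene_chain_weights": theta, "k": k},
        )
    sc.method = canonical
    return sc
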