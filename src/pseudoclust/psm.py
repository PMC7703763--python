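"""Posterior similarity matrices and PEAR summary clusterings.

The posterior similarity matrix (PSM) records, for every pair of genes, the
fraction of posterior samples in which the two genes share a cluster.  It is
symmetric, has unit diagonal, and — being an average of partition indicator
matrices — is positive semidefinite, which also makes it an admissible kernel
for the multiple-kernel combination step.

A single summary clustering is extracted by hierarchical clustering on
``1 - PSM`` and choosing the dendrogram cut that maximises the posterior
expected adjusted Rand index (PEAR) against the PSM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "compute_psm",
    "validate_psm",
    "pear",
    "summary_clustering_pear",
    "SummaryClustering",
]


@dataclass
class SummaryClustering:
    """Hard labels plus the PSM (and optional chain weights) behind them."""

    labels: np.ndarray
    pear_score: float
    psm: np.ndarray | None = None
    chain_weights: np.ndarray | None = None
    method: str = "pear"
    extras: dict | None = None

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)


def compute_psm(trace_or_allocations) -> np.ndarray:
    """Co-clustering frequency matrix over genes from posterior samples.

    Accepts a :class:`~pseudoclust.sampler.Trace` or any iterable of label
    vectors.  Entry (i, j) is the fraction of samples with
    ``label_i == label_j``; the diagonal is exactly 1.
    """
    allocations = getattr(trace_or_allocations, "allocations", trace_or_allocations)
    allocations = np.atleast_2d(np.asarray(allocations))
    if allocations.size == 0:
        raise ValueError("need at least one allocation sample to build a PSM")
    n_samples, n_g = allocations.shape
    psm = np.zeros((n_g, n_g))
    for labels in allocations:
        psm += labels[:, None] == labels[None, :]
    psm /= n_samples
    np.fill_diagonal(psm, 1.0)
    return psm


def validate_psm(psm: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Check symmetry, unit diagonal, [0,1] entries and PSD up to ``tol``."""
    psm = np.asarray(psm, dtype=float)
    if psm.ndim != 2 or psm.shape[0] != psm.shape[1]:
        raise ValueError("PSM must be square")
    if not np.allclose(psm, psm.T, atol=tol):
        raise ValueError("PSM must be symmetric")
    if not np.allclose(np.diag(psm), 1.0, atol=tol):
        raise ValueError("PSM diagonal must be 1")
    if psm.min() < -tol or psm.max() > 1 + tol:
        raise ValueError("PSM entries must lie in [0, 1]")
    eigs = np.linalg.eigvalsh(psm)
    if eigs[0] < -tol * max(eigs[-1], 1.0):
        raise ValueError(f"PSM is not positive semidefinite (min eigenvalue {eigs[0]:.3e})")
    return psm


def pear(labels, psm: np.ndarray) -> float:
    """Posterior expected adjusted Rand index of ``labels`` against ``psm``.

    With I the co-clustering indicator of ``labels`` and pi the PSM entries,
    over unordered pairs:

        PEAR = (sum I pi - S_I S_pi / C) / ((S_I + S_pi) / 2 - S_I S_pi / C)

    where C is the number of pairs.  Equals the posterior mean of the
    adjusted Rand index between ``labels`` and the sampled partitions.
    Returns 0 when the denominator vanishes (no better than chance).
    """
    labels = np.asarray(labels)
    psm = np.asarray(psm, dtype=float)
    n_g = labels.size
    if psm.shape != (n_g, n_g):
        raise ValueError("labels length must match the PSM dimension")
    iu = np.triu_indices(n_g, k=1)
    ind = (labels[:, None] == labels[None, :])[iu].astype(float)
    pi = psm[iu]
    n_pairs = ind.size
    if n_pairs == 0:
        return 0.0
    s_i, s_pi = ind.sum(), pi.sum()
    cross = s_i * s_pi / n_pairs
    denom = 0.5 * (s_i + s_pi) - cross
    if denom == 0.0:
        return 0.0
    return float((ind @ pi - cross) / denom)


def summary_clustering_pear(
    psm: np.ndarray,
    k_max: int | None = None,
    linkage_method: str = "average",
) -> SummaryClustering:
    """Cut an average-linkage dendrogram of ``1 - PSM`` at the PEAR-optimal k.

    Every cut k = 1..k_max is scored by PEAR against the PSM; ties resolve to
    the smallest number of clusters.
    """
    psm = np.asarray(psm, dtype=float)
    n_g = psm.shape[0]
    if k_max is None:
        k_max = min(n_g - 1, 20)
    k_max = max(int(k_max), 1)
    dist = np.clip(1.0 - psm, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    best_labels, best_score = None, -np.inf
    for k in range(1, min(k_max, n_g) + 1):
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
        score = pear(labels, psm)
        if score > best_score + 1e-12:
            best_labels, best_score = labels, score
    return SummaryClustering(
        labels=best_labels, pear_score=float(best_score), psm=psm, method="pear"
    )
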