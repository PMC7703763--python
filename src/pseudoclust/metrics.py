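"""Partition agreement scores and across-chain convergence checks.

ARI, the Fowlkes-Mallows index and normalized mutual information all equal 1
for identical partitions; degenerate cases (no co-clustered pairs, zero
entropy) return 0 by convention with a warning.  Convergence of parallel
subsampled chains is judged on three criteria: the mean pairwise distance
between chain PSMs, the stability of the combined summary under leaving one
chain out, and the potential scale reduction of the log-posterior series.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import (
    adjusted_rand_score,
    fowlkes_mallows_score,
    normalized_mutual_info_score,
)

__all__ = [
    "adjusted_rand_index",
    "fowlkes_mallows",
    "normalized_mutual_info",
    "gelman_rubin",
    "ConvergenceReport",
    "convergence_report",
]


def _check_lengths(c1, c2):
    c1, c2 = np.asarray(c1), np.asarray(c2)
    if c1.shape != c2.shape or c1.ndim != 1:
        raise ValueError("partitions must be 1-D and of equal length")
    return c1, c2


def _pair_counts(labels: np.ndarray) -> float:
    """Number of co-clustered (unordered) pairs in a partition."""
    _, counts = np.unique(labels, return_counts=True)
    return float(np.sum(counts * (counts - 1) / 2))


def adjusted_rand_index(c1, c2) -> float:
    """Adjusted Rand index; 1 for identical partitions, ~0 at chance."""
    c1, c2 = _check_lengths(c1, c2)
    return float(adjusted_rand_score(c1, c2))


def fowlkes_mallows(c1, c2) -> float:
    """Fowlkes-Mallows index TP / sqrt((TP+FP)(TP+FN)) over gene pairs.

    Returns 0 (with a warning) when either partition has no co-clustered
    pairs, in which case the index is undefined.
    """
    c1, c2 = _check_lengths(c1, c2)
    if _pair_counts(c1) == 0 or _pair_counts(c2) == 0:
        warnings.warn("Fowlkes-Mallows undefined (a partition has no co-clustered pairs); returning 0")
        return 0.0
    return float(fowlkes_mallows_score(c1, c2))


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def normalized_mutual_info(c1, c2) -> float:
    """NMI with geometric-mean normalisation, natural logarithms.

    Returns 0 (with a warning) when either partition has zero entropy.
    """
    c1, c2 = _check_lengths(c1, c2)
    if _entropy(c1) == 0.0 or _entropy(c2) == 0.0:
        warnings.warn("NMI undefined (a partition has zero entropy); returning 0")
        return 0.0
    return float(normalized_mutual_info_score(c1, c2, average_method="geometric"))


def gelman_rubin(series_list) -> float:
    """Potential scale reduction factor across chains (floored at 1).

    The classic between/within variance ratio over whole chains; here the
    chains already differ in their cell subsamples, so the statistic asks
    whether their log-posterior levels agree, not whether a single chain is
    internally stationary.  Chains with (numerically) zero pooled variance
    give 1 by convention.
    """
    series = [np.asarray(s, dtype=float) for s in series_list]
    n = min(s.size for s in series)
    if n < 4:
        raise ValueError("need at least 4 samples per chain")
    chains = np.asarray([s[-n:] for s in series])
    chain_means = chains.mean(axis=1)
    chain_vars = chains.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W <= 1e-12 * max(1.0, abs(chain_means.mean())) ** 2 + 1e-300:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(max(1.0, np.sqrt(var_hat / W)))


@dataclass
class ConvergenceReport:
    """Across-chain convergence summary for subsampled chains."""

    mean_pairwise_psm_distance: float
    loo_ari_min: float
    per_chain_logpost_gr: float
    passed: bool
    thresholds: dict
    #: ARI of the full-combination summary against each leave-one-chain-out summary
    loo_ari: list = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


DEFAULT_THRESHOLDS = {"psm_distance": 0.1, "loo_ari": 0.8, "gelman_rubin": 1.1}


def convergence_report(
    traces,
    psms,
    combine_fn,
    thresholds: dict | None = None,
) -> ConvergenceReport:
    """Assess convergence across subsampled chains.

    ``combine_fn`` maps a list of PSMs to a summary labelling (or an object
    with a ``labels`` attribute); it is applied to all chains and to every
    leave-one-chain-out subset.
    """
    psms = [np.asarray(p, dtype=float) for p in psms]
    if len(psms) < 2:
        raise ValueError("convergence assessment requires at least two chains")
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)

    iu = np.triu_indices(psms[0].shape[0], k=1)
    dists = [
        np.mean(np.abs(psms[i][iu] - psms[j][iu]))
        for i in range(len(psms))
        for j in range(i + 1, len(psms))
    ]
    mean_dist = float(np.mean(dists))

    def labels_of(result):
        return np.asarray(getattr(result, "labels", result))

    full = labels_of(combine_fn(psms))
    loo_aris = []
    for leave in range(len(psms)):
        subset = [p for i, p in enumerate(psms) if i != leave]
        loo_aris.append(adjusted_rand_index(full, labels_of(combine_fn(subset))))
    loo_min = float(np.min(loo_aris))

    # Chains on identical cells have comparable log-posterior levels, so the
    # across-chain ratio applies; chains on different subsamples each target
    # their own posterior, so only within-chain stationarity is checked
    # (split halves of each chain), taking the worst chain.
    cell_sets = [getattr(t, "cell_indices", None) for t in traces]
    same_cells = all(
        c is None or np.array_equal(c, cell_sets[0]) for c in cell_sets
    )
    if same_cells:
        gr = gelman_rubin([t.log_post for t in traces])
    else:
        gr = max(
            gelman_rubin([t.log_post[: len(t.log_post) // 2],
                          t.log_post[len(t.log_post) // 2 :]])
            for t in traces
        )

    passed = (
        mean_dist <= thr["psm_distance"]
        and loo_min >= thr["loo_ari"]
        and gr <= thr["gelman_rubin"]
    )
    return ConvergenceReport(
        mean_pairwise_psm_distance=mean_dist,
        loo_ari_min=loo_min,
        per_chain_logpost_gr=gr,
        passed=bool(passed),
        thresholds=thr,
        loo_ari=[float(a) for a in loo_aris],
    )
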