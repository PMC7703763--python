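"""MCMC over cell orders, gene partitions and hyperparameters.

One iteration is: a Metropolis-Hastings move on the cell order (a mixture of
four symmetric permutation proposals), a collapsed Gibbs sweep over gene
allocations under the Chinese-restaurant-process prior, and random-walk
updates of the hyperparameters (with the concentration updated by the
standard two-step auxiliary-variable scheme).  Chains are reproducible
bit-for-bit from their seed.  For large cell numbers, parallel chains are run
on stratified subsamples of cells (equal numbers per capture time) and later
combined through their posterior similarity matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed

from .data import ExpressionData
from .kernels import geodesic_pseudotime
from .likelihood import (
    ALPHA_PRIOR_RATE,
    ALPHA_PRIOR_SHAPE,
    A1_PRIOR_ALPHA,
    A1_PRIOR_BETA,
    EPS_PRIOR_RATE,
    Hyperparameters,
    LikelihoodCache,
    NumericalError,
    crp_log_prior,
    log_hyper_prior,
)

__all__ = [
    "MCMCConfig",
    "ChainState",
    "Trace",
    "ORDER_MOVES",
    "propose_order",
    "mh_accept",
    "crp_gibbs_sweep",
    "sample_alpha",
    "sample_hyperparameters",
    "run_chain",
    "stratified_subsample",
    "run_subsampled_chains",
]

logger = logging.getLogger(__name__)

ORDER_MOVES = ("adjacent_swap", "segment_reversal", "single_relocation", "full_reversal")
_WALK_PARAMS = ("a", "L", "eps", "a1")


@dataclass
class MCMCConfig:
    """Settings for one chain and for parallel subsampled chains."""

    n_iter: int = 3000
    burn_in_fraction: float = 0.5
    thin: int = 5
    rng_seed: int = 0
    #: probabilities of (adjacent_swap, segment_reversal, single_relocation,
    #: full_reversal) order proposals
    move_probabilities: tuple = (0.4, 0.3, 0.25, 0.05)
    #: random-walk standard deviations on the log/logit scale
    step_sizes: dict = field(
        default_factory=lambda: {"a": 0.1, "L": 0.1, "eps": 0.1, "a1": 0.1}
    )
    n_chains: int = 4
    #: cells retained per capture time in each subsampled chain; None = all
    cells_per_capture: int | None = 10
    adapt_interval: int = 50

    def __post_init__(self):
        probs = np.asarray(self.move_probabilities, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("move_probabilities must be 4 nonnegative values summing to 1")
        if not (0.0 < self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must lie in (0, 1)")
        if self.n_iter < 0 or self.thin < 1 or self.n_chains < 1:
            raise ValueError("invalid iteration/thinning/chain counts")


@dataclass
class ChainState:
    """One MCMC state: order, allocation, hyperparameters, cached log posterior."""

    order: np.ndarray
    labels: np.ndarray
    hyper: Hyperparameters
    log_post: float


@dataclass
class Trace:
    """Post-burn-in, thinned samples from one chain."""

    allocations: np.ndarray  # (n_samples, n_genes)
    orders: np.ndarray  # (n_samples, T)
    hypers: np.ndarray  # (n_samples, 5): a, L, a1, eps, alpha
    log_post: np.ndarray  # (n_samples,)
    seed: int
    cell_indices: np.ndarray
    gene_ids: list | None = None

    hyper_names = ("a", "L", "a1", "eps", "alpha")

    @property
    def n_samples(self) -> int:
        return self.allocations.shape[0]


def propose_order(order, move_type: str, rng) -> tuple[np.ndarray, float]:
    """Propose a new permutation; all moves are symmetric (log ratio 0).

    With fewer than three cells only swap and reversal change anything
    meaningfully; the other moves degenerate to them.
    """
    o = np.asarray(order, dtype=np.intp).copy()
    T = o.size
    if move_type not in ORDER_MOVES:
        raise ValueError(f"unknown move type {move_type!r}")
    if move_type == "full_reversal" or T < 3:
        if move_type == "adjacent_swap" and T >= 2:
            i = int(rng.integers(T - 1))
            o[[i, i + 1]] = o[[i + 1, i]]
        else:
            o = o[::-1].copy()
        return o, 0.0
    if move_type == "adjacent_swap":
        i = int(rng.integers(T - 1))
        o[[i, i + 1]] = o[[i + 1, i]]
    elif move_type == "segment_reversal":
        i, j = np.sort(rng.choice(T, size=2, replace=False))
        o[i : j + 1] = o[i : j + 1][::-1]
    elif move_type == "single_relocation":
        i = int(rng.integers(T))
        k = int(rng.integers(T))
        elem = o[i]
        o = np.insert(np.delete(o, i), k, elem)
    return o, 0.0


def mh_accept(delta_log_post: float, log_proposal_ratio: float, rng) -> bool:
    """Metropolis-Hastings acceptance: u < exp(delta + log ratio)."""
    total = delta_log_post + log_proposal_ratio
    if total >= 0.0:
        return True
    if not np.isfinite(total):
        return False
    return np.log(rng.random()) < total


def crp_gibbs_sweep(labels, cache: LikelihoodCache, alpha: float, rng) -> np.ndarray:
    """One collapsed Gibbs pass over all genes.

    Each gene is removed from its cluster and reassigned: to an existing
    cluster ``c`` with probability proportional to ``n_c exp(delta_c)`` or to
    a fresh cluster with probability proportional to ``alpha exp(delta_new)``,
    where ``delta`` is the change in the summed cluster marginal
    log-likelihoods.  Labels are compacted to ``0..K-1`` on return.
    """
    labels = np.asarray(labels, dtype=np.intp).copy()
    n_g = labels.size
    clusters: dict[int, list] = {}
    for j, k in enumerate(labels):
        clusters.setdefault(int(k), []).append(j)
    logliks = {k: cache.loglik(m) for k, m in clusters.items()}
    for j in range(n_g):
        k_old = int(labels[j])
        clusters[k_old].remove(j)
        if clusters[k_old]:
            logliks[k_old] = cache.loglik(clusters[k_old])
        else:
            del clusters[k_old], logliks[k_old]
        keys = list(clusters)
        logw = np.empty(len(keys) + 1)
        cand = {}
        for i, k in enumerate(keys):
            cand[k] = cache.loglik(clusters[k] + [j])
            logw[i] = np.log(len(clusters[k])) + cand[k] - logliks[k]
        new_ll = cache.loglik([j])
        logw[-1] = np.log(alpha) + new_ll
        w = np.exp(logw - logw.max())
        choice = int(rng.choice(w.size, p=w / w.sum()))
        if choice < len(keys):
            k_new = keys[choice]
            clusters[k_new].append(j)
            logliks[k_new] = cand[k_new]
        else:
            k_new = max(clusters) + 1 if clusters else 0
            clusters[k_new] = [j]
            logliks[k_new] = new_ll
        labels[j] = k_new
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def sample_alpha(alpha: float, n_clusters: int, n_genes: int, rng) -> float:
    """Two-step auxiliary-variable update of the DP concentration.

    Under the Gamma(shape 2, rate 4) prior, draw the auxiliary
    ``eta ~ Beta(alpha+1, n)`` and then alpha from the induced two-component
    Gamma mixture (Escobar-West scheme).
    """
    eta = rng.beta(alpha + 1.0, n_genes)
    b = ALPHA_PRIOR_RATE - np.log(eta)
    odds = (ALPHA_PRIOR_SHAPE + n_clusters - 1.0) / (n_genes * b)
    if rng.random() < odds / (1.0 + odds):
        return float(rng.gamma(ALPHA_PRIOR_SHAPE + n_clusters, 1.0 / b))
    return float(rng.gamma(ALPHA_PRIOR_SHAPE + n_clusters - 1.0, 1.0 / b))


def _walk_prior_logdens(name: str, value: float) -> float:
    """Log target density of one walked hyperparameter on its transform scale.

    Combines the prior density in natural space with the Jacobian of the
    log (a, L, eps) or logit (a1) transform the random walk operates on.
    """
    if name == "a" or name == "L":
        lv = np.log(value)
        return -0.5 * lv * lv  # log value ~ N(0,1); constants cancel
    if name == "eps":
        return -EPS_PRIOR_RATE * value + np.log(value)  # Exp(10) prior + Jacobian
    if name == "a1":
        return (A1_PRIOR_ALPHA - 1.0) * np.log(value) + (A1_PRIOR_BETA - 1.0) * np.log1p(
            -value
        ) + np.log(value) + np.log1p(-value)
    raise ValueError(name)


def _perturb(name: str, value: float, step: float, rng) -> float:
    z = rng.normal(0.0, step)
    if name == "a1":
        logit = np.log(value) - np.log1p(-value) + z
        return float(1.0 / (1.0 + np.exp(-logit)))
    return float(value * np.exp(z))


def sample_hyperparameters(
    cache: LikelihoodCache,
    labels: np.ndarray,
    rng,
    step_sizes: dict,
):
    """Random-walk Metropolis updates of a, L, eps (log scale) and a1 (logit).

    Returns the updated cache (rebuilt on any acceptance), the total cluster
    log-likelihood under the final hyperparameters, and per-parameter
    acceptance flags.  The DP concentration is updated separately by
    :func:`sample_alpha` because the likelihood does not depend on it.
    """
    hyper = cache.hyper
    loglik = cache.total_loglik(labels)
    accepted = {}
    for name in _WALK_PARAMS:
        step = step_sizes.get(name, 0.1)
        current = getattr(hyper, name)
        proposal_value = _perturb(name, current, step, rng)
        if step == 0.0 or proposal_value == current:
            accepted[name] = True
            continue
        try:
            new_hyper = replace(hyper, **{name: proposal_value})
            new_cache = LikelihoodCache(cache.Y, cache.tau, new_hyper)
            new_loglik = new_cache.total_loglik(labels)
        except (NumericalError, ValueError):
            accepted[name] = False
            continue
        delta = (
            new_loglik
            + _walk_prior_logdens(name, proposal_value)
            - loglik
            - _walk_prior_logdens(name, current)
        )
        if mh_accept(delta, 0.0, rng):
            hyper, cache, loglik = new_hyper, new_cache, new_loglik
            accepted[name] = True
        else:
            accepted[name] = False
    return cache, loglik, accepted


def _initial_order(capture_times: np.ndarray, rng) -> np.ndarray:
    """Sort cells by capture time with a random shuffle within each stage."""
    order = []
    for stage in np.unique(capture_times):
        idx = np.flatnonzero(capture_times == stage)
        order.append(rng.permutation(idx))
    return np.concatenate(order)


def _initial_hyper(rng, data_sd: float | None = None) -> Hyperparameters:
    """Draw initial hyperparameters from their priors.

    The amplitude is moment-matched to the data instead: the marginal
    variance of an observation is about 4 a^2 (a^2 around the cluster mean
    plus 3 a^2 for the mean itself), so ``a = sd/2`` starts the random walk
    near the right scale rather than waiting for it to drift there.
    """
    a_init = float(np.exp(rng.normal()))
    if data_sd is not None and data_sd > 0:
        a_init = max(data_sd / 2.0, 1e-3)
    return Hyperparameters(
        a=a_init,
        L=float(np.exp(rng.normal())),
        a1=float(np.clip(rng.beta(A1_PRIOR_ALPHA, A1_PRIOR_BETA), 1e-4, 1.0 - 1e-4)),
        eps=float(rng.gamma(1.0, 1.0 / EPS_PRIOR_RATE) + 1e-6),
        alpha=float(rng.gamma(ALPHA_PRIOR_SHAPE, 1.0 / ALPHA_PRIOR_RATE) + 1e-6),
    )


def run_chain(data: ExpressionData, config: MCMCConfig, cell_indices=None) -> Trace:
    """Run one chain; deterministic given ``config.rng_seed``.

    ``cell_indices`` restricts the chain to a subset of cells (the stratified
    subsample); indices are recorded in the returned trace.
    """
    if cell_indices is None:
        cell_indices = np.arange(data.n_cells)
    cell_indices = np.asarray(cell_indices, dtype=np.intp)
    sub = data.subset_cells(cell_indices)
    Y, captures = sub.values, sub.capture_times
    n_g, T = Y.shape
    rng = np.random.default_rng(config.rng_seed)

    order = _initial_order(captures, rng)
    labels = np.zeros(n_g, dtype=np.intp)
    hyper = _initial_hyper(rng, data_sd=float(Y.std()))
    tau = geodesic_pseudotime(Y, order)
    cache = LikelihoodCache(Y[:, order], tau, hyper)
    loglik = cache.total_loglik(labels)

    burn_in = int(np.floor(config.burn_in_fraction * config.n_iter))
    step_sizes = dict(config.step_sizes)
    accept_counts = {name: 0 for name in _WALK_PARAMS}
    window = 0

    samples = {"allocations": [], "orders": [], "hypers": [], "log_post": []}
    move_probs = np.asarray(config.move_probabilities, dtype=float)

    for it in range(config.n_iter):
        # --- order move ---
        move = ORDER_MOVES[int(rng.choice(4, p=move_probs))]
        new_order, log_ratio = propose_order(order, move, rng)
        try:
            new_tau = geodesic_pseudotime(Y, new_order)
            new_cache = LikelihoodCache(Y[:, new_order], new_tau, hyper)
            new_loglik = new_cache.total_loglik(labels)
        except NumericalError as exc:  # pragma: no cover - defensive
            logger.warning("order proposal rejected after numerical failure: %s", exc)
        else:
            if mh_accept(new_loglik - loglik, log_ratio, rng):
                order, cache, loglik = new_order, new_cache, new_loglik

        # --- allocation sweep ---
        labels = crp_gibbs_sweep(labels, cache, hyper.alpha, rng)
        loglik = cache.total_loglik(labels)

        # --- hyperparameters ---
        cache, loglik, accepted = sample_hyperparameters(cache, labels, rng, step_sizes)
        hyper = cache.hyper
        n_clusters = int(labels.max()) + 1
        hyper = replace(hyper, alpha=sample_alpha(hyper.alpha, n_clusters, n_g, rng))
        cache.hyper = hyper
        for name, ok in accepted.items():
            accept_counts[name] += ok
        window += 1

        # diminishing step-size adaptation during burn-in, frozen afterwards
        if it < burn_in and window == config.adapt_interval:
            scale = min(0.5, 5.0 / np.sqrt(it + 1.0))
            for name in _WALK_PARAMS:
                rate = accept_counts[name] / window
                if rate > 0.40:
                    step_sizes[name] = min(step_sizes[name] * np.exp(scale), 10.0)
                elif rate < 0.25:
                    step_sizes[name] = max(step_sizes[name] * np.exp(-scale), 1e-3)
                accept_counts[name] = 0
            window = 0

        if it >= burn_in and (it - burn_in) % config.thin == 0:
            _, sizes = np.unique(labels, return_counts=True)
            log_post = loglik + crp_log_prior(sizes, hyper.alpha) + log_hyper_prior(hyper)
            samples["allocations"].append(labels.copy())
            samples["orders"].append(order.copy())
            samples["hypers"].append(
                [hyper.a, hyper.L, hyper.a1, hyper.eps, hyper.alpha]
            )
            samples["log_post"].append(log_post)

    n_s = len(samples["allocations"])
    return Trace(
        allocations=np.asarray(samples["allocations"], dtype=np.intp).reshape(n_s, n_g),
        orders=np.asarray(samples["orders"], dtype=np.intp).reshape(n_s, T),
        hypers=np.asarray(samples["hypers"], dtype=float).reshape(n_s, 5),
        log_post=np.asarray(samples["log_post"], dtype=float),
        seed=int(config.rng_seed),
        cell_indices=cell_indices,
        gene_ids=list(data.gene_ids),
    )


def stratified_subsample(capture_times, n_per_capture: int, rng) -> np.ndarray:
    """Sample ``n_per_capture`` cells uniformly without replacement per stage.

    Returned indices are sorted by capture time (then by index within stage).
    """
    capture_times = np.asarray(capture_times)
    picks = []
    for stage in np.unique(capture_times):
        pool = np.flatnonzero(capture_times == stage)
        if pool.size < n_per_capture:
            raise ValueError(
                f"capture time {stage} has {pool.size} cells; "
                f"cannot subsample {n_per_capture}"
            )
        picks.append(np.sort(rng.choice(pool, size=n_per_capture, replace=False)))
    return np.concatenate(picks)


def _one_subsampled_chain(data, config, subsample_seed, chain_seed, group_mask):
    rng = np.random.default_rng(subsample_seed)
    candidates = np.flatnonzero(group_mask)
    if config.cells_per_capture is None:
        idx = candidates
    else:
        local = stratified_subsample(
            data.capture_times[candidates], config.cells_per_capture, rng
        )
        idx = candidates[local]
    chain_cfg = replace(config, rng_seed=int(chain_seed))
    return run_chain(data, chain_cfg, cell_indices=idx)


def run_subsampled_chains(
    data: ExpressionData,
    config: MCMCConfig,
    cell_groups=None,
    n_jobs: int = 1,
) -> list[Trace]:
    """Run ``config.n_chains`` independent chains on stratified subsamples.

    Each chain receives its own subsample (``cells_per_capture`` cells per
    capture time, or all cells when None) and its own seed, both derived
    deterministically from ``config.rng_seed``.  When ``cell_groups`` is
    given (one label per cell, e.g. the cell line a cell came from), chains
    are assigned to groups round-robin and subsample only within their group,
    so separately collected datasets can each feed their own chains.
    """
    seed_rng = np.random.default_rng(config.rng_seed)
    seeds = seed_rng.integers(0, 2**31 - 1, size=(config.n_chains, 2))
    if cell_groups is None:
        masks = [np.ones(data.n_cells, dtype=bool)] * config.n_chains
    else:
        cell_groups = np.asarray(cell_groups)
        group_labels = np.unique(cell_groups)
        masks = [
            cell_groups == group_labels[m % group_labels.size]
            for m in range(config.n_chains)
        ]
    jobs = (
        delayed(_one_subsampled_chain)(data, config, seeds[m, 0], seeds[m, 1], masks[m])
        for m in range(config.n_chains)
    )
    return list(Parallel(n_jobs=n_jobs)(jobs))
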