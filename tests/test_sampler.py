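import numpy as np
import pytest

import pseudoclust as pc
from pseudoclust.likelihood import Hyperparameters, LikelihoodCache
from pseudoclust.sampler import (
    ORDER_MOVES,
    crp_gibbs_sweep,
    mh_accept,
    propose_order,
    sample_alpha,
    stratified_subsample,
)


class TestOrderMoves:
    def test_full_reversal(self, rng):
        new, ratio = propose_order([0, 1, 2], "full_reversal", rng)
        np.testing.assert_array_equal(new, [2, 1, 0])
        assert ratio == 0.0

    def test_adjacent_swap_positions(self):
        # position drawn first; force it with a seeded generator
        rng = np.random.default_rng(0)
        new, ratio = propose_order([0, 1, 2], "adjacent_swap", rng)
        assert ratio == 0.0
        assert sorted(new.tolist()) == [0, 1, 2]
        assert not np.array_equal(new, [0, 1, 2])

    @pytest.mark.parametrize("move", ["adjacent_swap", "segment_reversal", "full_reversal"])
    def test_swap_and_reversal_are_involutions(self, move):
        # the same seeded generator picks the same positions twice
        order = np.arange(5)
        for seed in range(20):
            once, _ = propose_order(order, move, np.random.default_rng(seed))
            twice, _ = propose_order(once, move, np.random.default_rng(seed))
            np.testing.assert_array_equal(twice, order)

    @pytest.mark.parametrize("move", ORDER_MOVES)
    @pytest.mark.parametrize("T", [2, 3, 7])
    def test_always_a_permutation(self, move, T):
        for seed in range(30):
            new, ratio = propose_order(np.arange(T), move, np.random.default_rng(seed))
            assert sorted(new.tolist()) == list(range(T))
            assert ratio == 0.0

    def test_unknown_move_rejected(self, rng):
        with pytest.raises(ValueError):
            propose_order(np.arange(4), "shuffle", rng)


class TestMHAcceptance:
    class _FixedU:
        def __init__(self, u):
            self.u = u

        def random(self):
            return self.u

    def test_zero_delta_always_accepts(self):
        assert mh_accept(0.0, 0.0, self._FixedU(0.999999))

    def test_minus_infinity_always_rejects(self):
        assert not mh_accept(-np.inf, 0.0, self._FixedU(1e-12))

    def test_acceptance_threshold(self):
        delta = np.log(0.5)
        assert mh_accept(delta, 0.0, self._FixedU(0.4))
        assert not mh_accept(delta, 0.0, self._FixedU(0.6))


class TestGibbsSweep:
    def test_single_gene_stays_in_one_cluster(self, rng):
        h = Hyperparameters(a=1.0, L=0.5, a1=0.5, eps=0.1, alpha=1.0)
        cache = LikelihoodCache(rng.standard_normal((1, 4)), np.linspace(0, 1, 4), h)
        labels = crp_gibbs_sweep(np.zeros(1, dtype=int), cache, 1.0, rng)
        np.testing.assert_array_equal(labels, [0])

    def test_vanishing_alpha_blocks_new_clusters(self, rng):
        h = Hyperparameters(a=1.0, L=0.5, a1=0.5, eps=0.1, alpha=1e-300)
        cache = LikelihoodCache(rng.standard_normal((5, 4)), np.linspace(0, 1, 4), h)
        labels = np.zeros(5, dtype=int)
        for _ in range(20):
            labels = crp_gibbs_sweep(labels, cache, 1e-300, rng)
            assert np.unique(labels).size == 1

    def test_small_instance_matches_enumeration(self, rng):
        """3-gene partition frequencies agree with the enumerated posterior."""
        from conftest import canonical_labels, partition_to_labels, set_partitions

        from pseudoclust.likelihood import crp_log_prior

        Y = rng.standard_normal((3, 5))
        tau = np.linspace(0, 1, 5)
        h = Hyperparameters(a=1.0, L=0.5, a1=0.7, eps=0.2, alpha=1.0)
        cache = LikelihoodCache(Y, tau, h)
        log_post = {}
        for blocks in set_partitions(range(3)):
            labels = partition_to_labels(blocks, 3)
            lp = sum(cache.loglik(b) for b in blocks) + crp_log_prior(
                [len(b) for b in blocks], h.alpha
            )
            log_post[canonical_labels(labels)] = lp
        mx = max(log_post.values())
        Z = sum(np.exp(v - mx) for v in log_post.values())
        exact = {k: np.exp(v - mx) / Z for k, v in log_post.items()}

        labels = np.zeros(3, dtype=int)
        counts = {}
        n_sweeps = 6000
        for _ in range(n_sweeps):
            labels = crp_gibbs_sweep(labels, cache, h.alpha, rng)
            key = canonical_labels(labels)
            counts[key] = counts.get(key, 0) + 1
        tv = 0.5 * sum(
            abs(exact.get(k, 0) - counts.get(k, 0) / n_sweeps)
            for k in set(exact) | set(counts)
        )
        assert tv < 0.05


def test_alpha_update_preserves_prior_when_uninformative():
    """With one gene the partition carries no information, so repeated
    concentration updates must leave the Gamma(2, rate 4) prior invariant."""
    rng = np.random.default_rng(123)
    alpha, draws = 0.5, []
    for _ in range(4000):
        alpha = sample_alpha(alpha, n_clusters=1, n_genes=1, rng=rng)
        draws.append(alpha)
    draws = np.asarray(draws)
    assert draws.mean() == pytest.approx(0.5, abs=0.05)  # shape/rate = 2/4
    assert draws.var() == pytest.approx(2 / 16, abs=0.05)


class TestStratifiedSubsample:
    def test_counts_and_ordering(self, rng):
        captures = np.repeat([1, 2, 3], 20)
        idx = stratified_subsample(captures, 10, rng)
        assert idx.size == 30
        for stage, lo, hi in [(1, 0, 20), (2, 20, 40), (3, 40, 60)]:
            assert np.sum((idx >= lo) & (idx < hi)) == 10
        np.testing.assert_array_equal(captures[idx], np.repeat([1, 2, 3], 10))

    def test_full_stage_is_identity(self, rng):
        captures = np.repeat([0, 1], 5)
        np.testing.assert_array_equal(
            stratified_subsample(captures, 5, rng), np.arange(10)
        )

    def test_insufficient_cells(self, rng):
        with pytest.raises(ValueError):
            stratified_subsample(np.repeat([0, 1], 4), 5, rng)

    def test_overlap_matches_hypergeometric_mean(self):
        # drawing 10 of 20 twice: expected overlap 10*10/20 = 5 per stage
        captures = np.repeat([1, 2, 3], 20)
        overlaps = []
        for seed in range(200):
            a = set(stratified_subsample(captures, 10, np.random.default_rng(seed)))
            b = set(stratified_subsample(captures, 10, np.random.default_rng(10_000 + seed)))
            overlaps.append(len(a & b))
        assert np.mean(overlaps) == pytest.approx(15.0, abs=1.0)


class TestRunChain:
    def test_empty_run(self, tiny_dataset):
        cfg = pc.MCMCConfig(n_iter=0, rng_seed=1, cells_per_capture=None)
        trace = pc.run_chain(tiny_dataset.data, cfg)
        assert trace.n_samples == 0

    def test_deterministic_given_seed(self, tiny_dataset):
        cfg = pc.MCMCConfig(n_iter=60, rng_seed=9, cells_per_capture=None)
        t1 = pc.run_chain(tiny_dataset.data, cfg)
        t2 = pc.run_chain(tiny_dataset.data, cfg)
        np.testing.assert_array_equal(t1.allocations, t2.allocations)
        np.testing.assert_array_equal(t1.orders, t2.orders)
        np.testing.assert_array_equal(t1.hypers, t2.hypers)
        np.testing.assert_array_equal(t1.log_post, t2.log_post)

    def test_single_cluster_data_yields_modal_k_one(self):
        design = pc.SimulationDesign(n_genes=6, n_clusters=1, n_cells=24, rng_seed=3)
        ds = pc.simulate_dataset(design)
        cfg = pc.MCMCConfig(n_iter=400, rng_seed=11, cells_per_capture=None)
        trace = pc.run_chain(ds.data.center_genes(), cfg)
        ks = [np.unique(a).size for a in trace.allocations]
        values, counts = np.unique(ks, return_counts=True)
        assert values[np.argmax(counts)] == 1

    def test_trace_shapes_consistent(self, short_trace, tiny_dataset):
        n = short_trace.n_samples
        assert n > 0
        assert short_trace.orders.shape == (n, tiny_dataset.data.n_cells)
        assert short_trace.hypers.shape == (n, 5)
        assert short_trace.log_post.shape == (n,)
        # labels are compacted to 0..K-1 in every sample
        for a in short_trace.allocations:
            k = np.unique(a)
            np.testing.assert_array_equal(k, np.arange(k.size))


class TestSubsampledChains:
    def test_chain_count_and_distinct_seeds(self, tiny_dataset):
        cfg = pc.MCMCConfig(n_iter=30, n_chains=4, cells_per_capture=4, rng_seed=2)
        traces = pc.run_subsampled_chains(tiny_dataset.data, cfg)
        assert len(traces) == 4
        assert len({t.seed for t in traces}) == 4
        for t in traces:
            assert t.cell_indices.size == 12  # 4 per each of 3 stages
            np.testing.assert_array_equal(
                tiny_dataset.data.capture_times[t.cell_indices], np.repeat([1, 2, 3], 4)
            )

    def test_single_full_chain_equivalent(self, tiny_dataset):
        cfg = pc.MCMCConfig(n_iter=30, n_chains=1, cells_per_capture=None, rng_seed=5)
        (trace,) = pc.run_subsampled_chains(tiny_dataset.data, cfg)
        assert trace.cell_indices.size == tiny_dataset.data.n_cells

    def test_per_group_subsampling(self, tiny_dataset):
        groups = np.where(np.arange(tiny_dataset.data.n_cells) % 2 == 0, "lineA", "lineB")
        cfg = pc.MCMCConfig(n_iter=20, n_chains=2, cells_per_capture=2, rng_seed=7)
        traces = pc.run_subsampled_chains(tiny_dataset.data, cfg, cell_groups=groups)
        assert set(groups[traces[0].cell_indices]) == {"lineA"}
        assert set(groups[traces[1].cell_indices]) == {"lineB"}


def test_posterior_order_mass_is_reversal_symmetric():
    """On a tiny instance the sampled order distribution must give an order
    and its reversal equal mass (the model cannot tell time's arrow)."""
    rng = np.random.default_rng(5)
    data = pc.ExpressionData(rng.standard_normal((2, 3)))
    cfg = pc.MCMCConfig(n_iter=6000, burn_in_fraction=0.2, thin=1, rng_seed=17,
                        cells_per_capture=None)
    trace = pc.run_chain(data, cfg)
    counts = {}
    for o in trace.orders:
        counts[tuple(o)] = counts.get(tuple(o), 0) + 1
    top = max(counts, key=counts.get)
    p_top = counts[top] / trace.n_samples
    p_rev = counts.get(tuple(reversed(top)), 0) / trace.n_samples
    assert abs(p_top - p_rev) < 0.06
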