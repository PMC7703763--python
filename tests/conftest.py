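"""Shared fixtures and small oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import pseudoclust as pc


def set_partitions(items):
    """Yield all set partitions of ``items`` (lists of blocks)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for p in set_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [[first] + p[i]] + p[i + 1 :]
        yield [[first]] + p


def canonical_labels(labels) -> tuple:
    """Relabel a partition by order of first appearance (canonical form)."""
    seen, out = {}, []
    for v in labels:
        if v not in seen:
            seen[v] = len(seen)
        out.append(seen[v])
    return tuple(out)


def partition_to_labels(blocks, n) -> np.ndarray:
    labels = np.empty(n, dtype=int)
    for k, block in enumerate(blocks):
        labels[block] = k
    return labels


def structured_psm(rng, n_genes=20, k=5, n_samples=50, flip=0.1) -> np.ndarray:
    """PSM from noisy samples around a fixed k-block partition."""
    base = np.arange(n_genes) % k
    samples = []
    for _ in range(n_samples):
        labels = base.copy()
        mask = rng.random(n_genes) < flip
        labels[mask] = rng.integers(k, size=int(mask.sum()))
        samples.append(labels)
    return pc.compute_psm(np.asarray(samples))


def noise_psm(rng, n_genes=20, k=5, n_samples=50) -> np.ndarray:
    """PSM from independent uniformly random allocations (no shared structure)."""
    return pc.compute_psm(rng.integers(k, size=(n_samples, n_genes)))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small, clearly separated dataset: 8 genes, 2 clusters, 24 cells."""
    design = pc.SimulationDesign(n_genes=8, n_clusters=2, n_cells=24, rng_seed=1)
    ds = pc.simulate_dataset(design)
    return pc.permute_within_capture(ds, np.random.default_rng(2))


@pytest.fixture(scope="session")
def short_trace(tiny_dataset):
    """One quick full-cell chain on the tiny dataset."""
    cfg = pc.MCMCConfig(n_iter=300, rng_seed=4, cells_per_capture=None)
    return pc.run_chain(tiny_dataset.data.center_genes(), cfg)
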