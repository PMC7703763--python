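"""Synthetic pseudotime-course data with known cluster structure.

The generator emulates the benchmark conditions the method is evaluated
under: a handful of latent cluster trajectories drawn from GPs over a uniform
pseudotime grid, gene-level GP deviations plus white noise around them, cells
binned into a few capture times (thirds of the trajectory at the defaults),
the true within-capture-time order destroyed by random permutation, and
optional random dropout of non-zero entries.  Deliberately the
parameterisation is *not* the hierarchical model used for inference: cluster
means are drawn directly from a single-level GP (squared-exponential,
Matérn-3/2 or linear, per design), so recovery tests are not circular.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .data import ExpressionData
from .kernels import linear_cov, matern32_cov, squared_exponential_cov

__all__ = [
    "SimulationDesign",
    "DropoutSpec",
    "LabeledDataset",
    "simulate_dataset",
    "permute_within_capture",
    "inject_dropout",
    "simulate_large",
]

_KERNELS = {
    "sqexp": lambda tau, scale, length: squared_exponential_cov(tau, scale, length),
    "matern32": lambda tau, scale, length: matern32_cov(tau, scale, length),
    "linear": lambda tau, scale, length: linear_cov(tau, scale, bias=0.1),
}


@dataclass(frozen=True)
class DropoutSpec:
    """Random dropout: zero out non-zero entries independently.

    Either a single global ``rate``, or per-gene-group rates (``gene_groups``
    assigns each gene a group label, ``group_rates`` maps label -> rate).
    ``protected_cells`` marks a cell subset whose dropout probability is
    multiplied by ``protected_factor`` (cells known to be less affected).
    """

    rate: float | None = None
    gene_groups: tuple | None = None
    group_rates: dict | None = None
    protected_cells: tuple | None = None
    protected_factor: float = 1.0

    def per_gene_rates(self, n_genes: int) -> np.ndarray:
        if self.rate is not None:
            rates = np.full(n_genes, float(self.rate))
        else:
            if self.gene_groups is None or self.group_rates is None:
                raise ValueError("need either a global rate or per-group rates")
            groups = np.asarray(self.gene_groups)
            if groups.shape != (n_genes,):
                raise ValueError("gene_groups must assign one group per gene")
            rates = np.array([float(self.group_rates[g]) for g in groups])
        if np.any(rates < 0) or np.any(rates > 1):
            raise ValueError("dropout rates must lie in [0, 1]")
        if not (0.0 <= self.protected_factor <= 1.0):
            raise ValueError("protected_factor must lie in [0, 1]")
        return rates


@dataclass(frozen=True)
class SimulationDesign:
    """Generative settings for one synthetic dataset.

    ``separability`` controls how distinct the cluster trajectories are:
    ``"high"`` draws large-amplitude means and enforces a minimum pairwise
    separation (clearly separated clusters); ``"low"`` draws overlapping
    low-amplitude means with more noise, so the cluster structure only
    emerges through the pseudotime ordering.
    """

    n_genes: int = 20
    n_clusters: int = 5
    n_cells: int = 60
    n_capture: int = 3
    kernel_family: str = "sqexp"
    separability: str = "high"
    dropout: DropoutSpec | None = None
    rng_seed: int = 0
    mean_scale: float = 9.0  # marginal variance of cluster-mean GPs ("high")
    mean_length: float = 0.25
    gene_scale: float = 0.09  # variance of smooth gene-level deviations
    gene_length: float = 0.3
    noise_sd: float = 0.2
    #: required ratio of min between-cluster mean distance to max gene
    #: deviation norm for "high"-separability designs
    separation_factor: float = 5.0

    def __post_init__(self):
        if self.n_genes < self.n_clusters or self.n_clusters < 1:
            raise ValueError("need at least one gene per cluster")
        if self.n_cells < 2 or self.n_capture < 1 or self.n_cells % self.n_capture:
            raise ValueError("n_cells must be a positive multiple of n_capture")
        if self.kernel_family not in _KERNELS:
            raise ValueError(f"kernel_family must be one of {sorted(_KERNELS)}")
        if self.separability not in ("high", "low"):
            raise ValueError("separability must be 'high' or 'low'")


@dataclass
class LabeledDataset:
    """Synthetic data plus its generative ground truth.

    ``true_order`` indexes columns of ``data.values`` such that
    ``values[:, true_order]`` restores the true pseudotime sequence.
    """

    data: ExpressionData
    true_labels: np.ndarray
    true_order: np.ndarray
    design: SimulationDesign = None
    #: cluster mean trajectories on the true pseudotime grid (k x n_cells)
    cluster_means: np.ndarray = None

    @property
    def capture_times(self) -> np.ndarray:
        return self.data.capture_times


def _draw_means(design: SimulationDesign, tau: np.ndarray, rng) -> np.ndarray:
    """Cluster mean trajectories; redrawn until separated for "high" designs."""
    kern = _KERNELS[design.kernel_family]
    scale = design.mean_scale if design.separability == "high" else 1.0
    if design.kernel_family == "linear":
        # a linear kernel has marginal variance scale * t^2, vanishing at the
        # trajectory start; inflate the amplitude so line trajectories spread
        # comparably to the stationary families
        scale = 9.0 * scale
    cov = kern(tau, scale, design.mean_length)
    chol_jitter = cov + 1e-8 * scale * np.eye(tau.size)
    L = np.linalg.cholesky(chol_jitter)
    return (L @ rng.standard_normal((tau.size, design.n_clusters))).T


def _assign_labels(design: SimulationDesign) -> np.ndarray:
    return np.arange(design.n_genes) % design.n_clusters


def simulate_dataset(design: SimulationDesign) -> LabeledDataset:
    """Generate one dataset; bit-reproducible from ``design.rng_seed``.

    Cells come out in true pseudotime order with capture times assigned in
    consecutive blocks; call :func:`permute_within_capture` to hide the
    within-stage order, and :func:`inject_dropout` to add technical zeros.
    """
    rng = np.random.default_rng(design.rng_seed)
    T = design.n_cells
    tau = np.linspace(0.0, 1.0, T)
    labels = _assign_labels(design)
    noise_sd = design.noise_sd if design.separability == "high" else 2.0 * design.noise_sd

    kern = _KERNELS[design.kernel_family]
    dev_cov = kern(tau, design.gene_scale, design.gene_length)
    dev_chol = np.linalg.cholesky(dev_cov + 1e-10 * np.eye(T))

    for _ in range(500):
        means = _draw_means(design, tau, rng)
        devs = (dev_chol @ rng.standard_normal((T, design.n_genes))).T
        noise = noise_sd * rng.standard_normal((design.n_genes, T))
        values = means[labels] + devs + noise
        if design.separability == "low" or design.n_clusters == 1:
            break
        # enforce clear separation: smallest between-mean distance must
        # dominate the largest total gene-level deviation
        diffs = means[:, None, :] - means[None, :, :]
        dist = np.linalg.norm(diffs, axis=2)
        min_sep = dist[np.triu_indices(design.n_clusters, k=1)].min()
        max_dev = np.linalg.norm(devs + noise, axis=1).max()
        if min_sep >= design.separation_factor * max_dev:
            break
    else:
        raise RuntimeError("could not draw sufficiently separated cluster means")

    capture = np.repeat(np.arange(1, design.n_capture + 1), T // design.n_capture)
    data = ExpressionData(
        values,
        gene_ids=[f"gene_{i}" for i in range(design.n_genes)],
        cell_ids=[f"cell_{i}" for i in range(T)],
        capture_times=capture,
    )
    return LabeledDataset(
        data=data,
        true_labels=labels,
        true_order=np.arange(T),
        design=design,
        cluster_means=means,
    )


def permute_within_capture(dataset: LabeledDataset, rng) -> LabeledDataset:
    """Shuffle cells independently within each capture time.

    The recorded ``true_order`` is updated so that indexing the permuted
    columns with it restores the true pseudotime sequence.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    capture = dataset.data.capture_times
    perm = np.arange(capture.size)
    for stage in np.unique(capture):
        idx = np.flatnonzero(capture == stage)
        perm[idx] = rng.permutation(idx)
    data = ExpressionData(
        dataset.data.values[:, perm],
        list(dataset.data.gene_ids),
        [dataset.data.cell_ids[i] for i in perm],
        capture[perm],
    )
    # new[:, argsort(perm)] == old; compose with the previous true order
    inverse = np.argsort(perm)
    new_true = inverse[dataset.true_order]
    return LabeledDataset(
        data=data,
        true_labels=dataset.true_labels.copy(),
        true_order=new_true,
        design=dataset.design,
        cluster_means=dataset.cluster_means,
    )


def inject_dropout(dataset: LabeledDataset, spec, rng=None) -> LabeledDataset:
    """Zero out non-zero entries independently at the specified rate(s).

    Entries that are already zero are never modified, and dimensions are
    preserved.  ``spec`` may be a float (global rate) or a
    :class:`DropoutSpec`.
    """
    if not isinstance(spec, DropoutSpec):
        spec = DropoutSpec(rate=float(spec))
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    values = dataset.data.values.copy()
    n_genes, n_cells = values.shape
    rates = spec.per_gene_rates(n_genes)
    rate_matrix = np.broadcast_to(rates[:, None], values.shape).copy()
    if spec.protected_cells is not None:
        rate_matrix[:, np.asarray(spec.protected_cells, dtype=np.intp)] *= spec.protected_factor
    mask = (values != 0.0) & (rng.random(values.shape) < rate_matrix)
    values[mask] = 0.0
    data = ExpressionData(
        values,
        list(dataset.data.gene_ids),
        list(dataset.data.cell_ids),
        dataset.data.capture_times.copy(),
    )
    return LabeledDataset(
        data=data,
        true_labels=dataset.true_labels.copy(),
        true_order=dataset.true_order.copy(),
        design=dataset.design,
        cluster_means=dataset.cluster_means,
    )


def simulate_large(
    design: SimulationDesign = None,
    n_cells: int = 9000,
    coarse_grid: int = 256,
    **kwargs,
) -> LabeledDataset:
    """Large-cell-number variant avoiding an n_cells x n_cells covariance.

    Cluster means and smooth gene deviations are drawn on a coarse pseudotime
    grid from a Matérn-3/2 (by default) GP and interpolated to the full grid
    with cubic splines; white noise is added pointwise.  Suitable for many
    thousands of cells, from which stratified subsamples feed the chains.
    """
    if design is None:
        design = SimulationDesign(kernel_family="matern32", **kwargs)
    design = replace(design, n_cells=int(n_cells))
    rng = np.random.default_rng(design.rng_seed)
    T = design.n_cells
    tau_full = np.linspace(0.0, 1.0, T)
    tau_coarse = np.linspace(0.0, 1.0, min(coarse_grid, T))
    labels = _assign_labels(design)
    noise_sd = design.noise_sd if design.separability == "high" else 2.0 * design.noise_sd

    kern = _KERNELS[design.kernel_family]
    scale = design.mean_scale if design.separability == "high" else 1.0
    mean_cov = kern(tau_coarse, scale, design.mean_length)
    mean_chol = np.linalg.cholesky(mean_cov + 1e-8 * scale * np.eye(tau_coarse.size))
    means_coarse = (mean_chol @ rng.standard_normal((tau_coarse.size, design.n_clusters))).T
    means = CubicSpline(tau_coarse, means_coarse, axis=1)(tau_full)

    dev_cov = kern(tau_coarse, design.gene_scale, design.gene_length)
    dev_chol = np.linalg.cholesky(dev_cov + 1e-10 * np.eye(tau_coarse.size))
    devs_coarse = (dev_chol @ rng.standard_normal((tau_coarse.size, design.n_genes))).T
    devs = CubicSpline(tau_coarse, devs_coarse, axis=1)(tau_full)

    values = means[labels] + devs
    # add noise in cell blocks to keep peak memory proportional to one block
    block = 2000
    for start in range(0, T, block):
        stop = min(start + block, T)
        values[:, start:stop] += noise_sd * rng.standard_normal(
            (design.n_genes, stop - start)
        )

    capture = np.repeat(np.arange(1, design.n_capture + 1), T // design.n_capture)
    data = ExpressionData(
        values,
        gene_ids=[f"gene_{i}" for i in range(design.n_genes)],
        cell_ids=[f"cell_{i}" for i in range(T)],
        capture_times=capture,
    )
    return LabeledDataset(
        data=data,
        true_labels=labels,
        true_order=np.arange(T),
        design=design,
        cluster_means=means,
    )
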