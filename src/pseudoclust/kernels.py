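"""Covariance functions and the order-to-pseudotime map.

Pseudotime lives on [0, 1].  A cell ordering is a permutation ``o`` of the
column indices of the expression matrix; it is mapped deterministically to a
pseudotime vector by accumulating Euclidean distances in expression space
between consecutive cells along the order and normalising the cumulative path
length to [0, 1].  Covariance builders return dense symmetric positive
semidefinite matrices evaluated at a pseudotime vector.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "squared_exponential_cov",
    "matern32_cov",
    "linear_cov",
    "geodesic_pseudotime",
    "validate_order",
]

_SQRT3 = np.sqrt(3.0)


def _check_positive(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0.0:
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")
    return value


def validate_order(perm, n_cells: int) -> np.ndarray:
    """Validate that ``perm`` is a permutation of ``0..n_cells-1``."""
    perm = np.asarray(perm, dtype=np.intp)
    if perm.shape != (n_cells,) or not np.array_equal(np.sort(perm), np.arange(n_cells)):
        raise ValueError("order must be a permutation of all cell indices")
    return perm


def squared_exponential_cov(tau, scale: float, length: float) -> np.ndarray:
    """Squared-exponential covariance ``scale * exp(-(t_j - t_i)^2 / (2 length^2))``.

    Parameters
    ----------
    tau : array-like
        Pseudotime vector of length T.
    scale : float
        Marginal variance (the diagonal value); must be positive.
    length : float
        Length scale on the pseudotime axis; must be positive.
    """
    scale = _check_positive(scale, "scale")
    length = _check_positive(length, "length")
    tau = np.asarray(tau, dtype=float)
    d = tau[None, :] - tau[:, None]
    cov = scale * np.exp(-(d * d) / (2.0 * length * length))
    return 0.5 * (cov + cov.T)


def matern32_cov(tau, scale: float, length: float) -> np.ndarray:
    """Matérn-3/2 covariance ``scale * (1 + sqrt(3) d / length) exp(-sqrt(3) d / length)``."""
    scale = _check_positive(scale, "scale")
    length = _check_positive(length, "length")
    tau = np.asarray(tau, dtype=float)
    r = _SQRT3 * np.abs(tau[None, :] - tau[:, None]) / length
    cov = scale * (1.0 + r) * np.exp(-r)
    return 0.5 * (cov + cov.T)


def linear_cov(tau, scale: float, bias: float = 0.0) -> np.ndarray:
    """Linear (dot-product) covariance ``bias + scale * t_i * t_j``."""
    scale = _check_positive(scale, "scale")
    bias = float(bias)
    if bias < 0.0:
        raise ValueError(f"bias must be nonnegative, got {bias!r}")
    tau = np.asarray(tau, dtype=float)
    return bias + scale * np.outer(tau, tau)


def geodesic_pseudotime(expression, order) -> np.ndarray:
    """Map a cell order to pseudotimes via cumulative path length.

    Consecutive pseudotime increments are proportional to the Euclidean
    distance in expression space (all genes) between neighbouring cells along
    the order; the cumulative path is normalised so that the first cell sits
    at pseudotime 0 and the last at 1.  A degenerate path of total length zero
    (all cells identical) falls back to a uniform grid.

    Parameters
    ----------
    expression : ndarray (n_genes, n_cells) or object with a ``values`` attribute
    order : permutation of the cell indices
    """
    X = getattr(expression, "values", expression)
    X = np.asarray(X, dtype=float)
    n_cells = X.shape[1]
    if n_cells < 2:
        raise ValueError("pseudotime requires at least two cells")
    order = validate_order(order, n_cells)
    path = X[:, order]
    steps = np.linalg.norm(np.diff(path, axis=1), axis=0)
    total = steps.sum()
    if total == 0.0:
        return np.linspace(0.0, 1.0, n_cells)
    tau = np.empty(n_cells)
    tau[0] = 0.0
    np.cumsum(steps / total, out=tau[1:])
    tau[-1] = 1.0
    return tau
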