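"""In-memory container for log-expression matrices with capture times."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionData"]


@dataclass
class ExpressionData:
    """A genes x cells matrix of pre-processed log-transformed expression.

    Rows are genes, columns are cells.  ``capture_times`` holds one integer
    experimental stage per cell; stages constrain chain initialisation and
    stratified subsampling but not the inferred ordering itself.
    """

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)
    capture_times: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D genes x cells matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        n_g, T = self.values.shape
        if not self.gene_ids:
            self.gene_ids = [f"gene_{i}" for i in range(n_g)]
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(T)]
        if len(self.gene_ids) != n_g or len(set(self.gene_ids)) != n_g:
            raise ValueError("gene_ids must be unique and match the row count")
        if len(self.cell_ids) != T or len(set(self.cell_ids)) != T:
            raise ValueError("cell_ids must be unique and match the column count")
        if self.capture_times is None:
            self.capture_times = np.zeros(T, dtype=int)
        self.capture_times = np.asarray(self.capture_times, dtype=int)
        if self.capture_times.shape != (T,):
            raise ValueError("capture_times must hold one integer stage per cell")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def center_genes(self) -> "ExpressionData":
        """Return a copy with every gene row mean-centred.

        The clustering model places a zero-mean GP on cluster trajectories,
        so expression should be centred per gene before inference.
        """
        centred = self.values - self.values.mean(axis=1, keepdims=True)
        return ExpressionData(
            centred, list(self.gene_ids), list(self.cell_ids), self.capture_times.copy()
        )

    def subset_cells(self, indices) -> "ExpressionData":
        indices = np.asarray(indices, dtype=np.intp)
        return ExpressionData(
            self.values[:, indices],
            list(self.gene_ids),
            [self.cell_ids[i] for i in indices],
            self.capture_times[indices],
        )
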