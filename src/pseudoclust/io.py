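"""Reading and writing the package's file formats.

Expression matrices travel as CSV/TSV with gene IDs in the first column and
cell IDs in the header; capture times as a two-column CSV mapping cell ID to
integer stage.  PSMs and label vectors are CSVs indexed by gene ID, traces
are gzip-compressed CSVs (one row per retained sample), run settings are
YAML, and ground truth / run metadata / convergence reports are JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ExpressionData
from .metrics import DEFAULT_THRESHOLDS
from .sampler import MCMCConfig, Trace

__all__ = [
    "read_expression",
    "write_expression",
    "read_psm",
    "write_psm",
    "read_labels",
    "write_labels",
    "read_truth",
    "write_truth",
    "RunConfig",
    "load_run_config",
    "save_run_config",
    "write_trace",
    "read_trace",
    "write_metadata",
]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_expression(matrix_path, capture_path=None, center: bool = True) -> ExpressionData:
    """Load a genes x cells matrix plus per-cell capture times.

    The matrix file must have a header row of cell IDs and gene IDs in the
    first column; the capture file maps ``cell_id -> capture`` (integer
    stage).  Per-gene mean-centering is applied by default, matching the
    zero-mean GP placed on cluster trajectories.
    """
    df = pd.read_csv(matrix_path, sep=_sep_for(matrix_path), index_col=0)
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = df.columns[np.flatnonzero(~np.isfinite(values).all(axis=0))[:3]]
        raise ValueError(f"non-numeric or non-finite expression entries (e.g. cells {list(bad)})")
    cell_ids = [str(c) for c in df.columns]
    gene_ids = [str(g) for g in df.index]

    if capture_path is None:
        capture_times = np.zeros(len(cell_ids), dtype=int)
    else:
        cap = pd.read_csv(capture_path, sep=_sep_for(capture_path))
        if cap.shape[1] < 2:
            raise ValueError("capture file needs columns: cell_id, capture")
        mapping = dict(zip(cap.iloc[:, 0].astype(str), cap.iloc[:, 1]))
        missing = [c for c in cell_ids if c not in mapping]
        if missing:
            raise ValueError(f"capture file is missing cells: {missing[:5]}")
        capture_times = np.array([int(mapping[c]) for c in cell_ids])

    data = ExpressionData(values, gene_ids, cell_ids, capture_times)
    return data.center_genes() if center else data


def write_expression(data: ExpressionData, matrix_path, capture_path=None) -> None:
    df = pd.DataFrame(data.values, index=data.gene_ids, columns=data.cell_ids)
    df.to_csv(matrix_path, sep=_sep_for(matrix_path))
    if capture_path is not None:
        pd.DataFrame(
            {"cell_id": data.cell_ids, "capture": data.capture_times}
        ).to_csv(capture_path, index=False)


def write_psm(psm: np.ndarray, gene_ids, path) -> None:
    pd.DataFrame(psm, index=gene_ids, columns=gene_ids).to_csv(path)


def read_psm(path):
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(g) for g in df.index]


def write_labels(labels, gene_ids, path) -> None:
    pd.DataFrame({"gene_id": gene_ids, "cluster": np.asarray(labels, dtype=int)}).to_csv(
        path, index=False
    )


def read_labels(path):
    df = pd.read_csv(path)
    return df["cluster"].to_numpy(dtype=int), [str(g) for g in df["gene_id"]]


def write_truth(dataset, path) -> None:
    """Serialise a synthetic dataset's ground truth (labels, order, design)."""
    design = dataset.design
    payload = {
        "true_labels": np.asarray(dataset.true_labels, dtype=int).tolist(),
        "true_order": np.asarray(dataset.true_order, dtype=int).tolist(),
        "gene_ids": list(dataset.data.gene_ids),
        "design": dataclasses.asdict(design) if design is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def read_truth(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    payload["true_labels"] = np.asarray(payload["true_labels"], dtype=int)
    payload["true_order"] = np.asarray(payload["true_order"], dtype=int)
    return payload


@dataclass
class RunConfig:
    """End-to-end settings: sampling plus combination and reporting."""

    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    method: str = "mean"
    k_max: int | None = None
    center_genes: bool = True
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self.mcmc)
        out["move_probabilities"] = list(self.mcmc.move_probabilities)
        out.update(
            method=self.method,
            k_max=self.k_max,
            center_genes=self.center_genes,
            thresholds=dict(self.thresholds),
        )
        return out


def load_run_config(path) -> RunConfig:
    """Parse a flat YAML file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    mcmc_fields = {f.name for f in dataclasses.fields(MCMCConfig)}
    extra_fields = {"method", "k_max", "center_genes", "thresholds"}
    unknown = set(raw) - mcmc_fields - extra_fields
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    mcmc_kwargs = {k: v for k, v in raw.items() if k in mcmc_fields}
    if "move_probabilities" in mcmc_kwargs:
        mcmc_kwargs["move_probabilities"] = tuple(mcmc_kwargs["move_probabilities"])
    cfg = RunConfig(mcmc=MCMCConfig(**mcmc_kwargs))
    for key in extra_fields - {"thresholds"}:
        if key in raw:
            setattr(cfg, key, raw[key])
    if "thresholds" in raw:
        cfg.thresholds.update(raw["thresholds"])
    return cfg


def save_run_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_trace(trace: Trace, directory) -> None:
    """Store one chain's samples as gzip-compressed CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(trace.allocations, columns=trace.gene_ids).to_csv(
        directory / "allocations.csv.gz", index=False
    )
    pd.DataFrame(trace.orders).to_csv(directory / "orders.csv.gz", index=False)
    pd.DataFrame(trace.hypers, columns=list(Trace.hyper_names)).to_csv(
        directory / "hypers.csv.gz", index=False
    )
    pd.DataFrame({"log_post": trace.log_post}).to_csv(
        directory / "log_post.csv.gz", index=False
    )
    with open(directory / "chain.json", "w") as fh:
        json.dump(
            {
                "seed": int(trace.seed),
                "cell_indices": np.asarray(trace.cell_indices, dtype=int).tolist(),
            },
            fh,
            indent=2,
        )


def read_trace(directory) -> Trace:
    directory = Path(directory)
    alloc = pd.read_csv(directory / "allocations.csv.gz")
    with open(directory / "chain.json") as fh:
        meta = json.load(fh)
    return Trace(
        allocations=alloc.to_numpy(dtype=np.intp),
        orders=pd.read_csv(directory / "orders.csv.gz").to_numpy(dtype=np.intp),
        hypers=pd.read_csv(directory / "hypers.csv.gz").to_numpy(dtype=float),
        log_post=pd.read_csv(directory / "log_post.csv.gz")["log_post"].to_numpy(),
        seed=int(meta["seed"]),
        cell_indices=np.asarray(meta["cell_indices"], dtype=np.intp),
        gene_ids=[str(g) for g in alloc.columns],
    )


def write_metadata(path, seed, config: RunConfig | None = None, **extra) -> None:
    """Record what produced an output directory (seed, config hash, versions)."""
    import numpy
    import scipy

    from . import __version__

    payload = {
        "package_version": __version__,
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
        "seed": int(seed) if seed is not None else None,
    }
    if config is not None:
        payload["config"] = config.to_dict()
        payload["config_hash"] = config_hash(config)
    payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
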