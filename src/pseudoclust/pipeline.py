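"""Convenience orchestration: chains -> PSMs -> combined summary."""

from __future__ import annotations

import numpy as np

from .combine import combine
from .data import ExpressionData
from .psm import compute_psm
from .sampler import MCMCConfig, run_subsampled_chains

__all__ = ["run_pipeline"]


def run_pipeline(
    data: ExpressionData,
    config: MCMCConfig,
    methods=("mean",),
    k_max: int | None = None,
    center: bool = True,
    cell_groups=None,
    n_jobs: int = 1,
):
    """Run subsampled chains and combine their PSMs with each method.

    Returns ``(summaries, traces, psms)`` where ``summaries`` maps method
    name to its :class:`~pseudoclust.psm.SummaryClustering`.  Combination
    seeds derive from ``config.rng_seed`` so the whole pipeline is
    reproducible.
    """
    if center:
        data = data.center_genes()
    traces = run_subsampled_chains(data, config, cell_groups=cell_groups, n_jobs=n_jobs)
    psms = [compute_psm(t) for t in traces]
    rng = np.random.default_rng(config.rng_seed + 1)
    summaries = {}
    for method in methods:
        summaries[method] = combine(psms, method=method, k_max=k_max, rng=rng)
    return summaries, traces, psms
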