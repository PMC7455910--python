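"""End-to-end fitting workflow: filter -> offsets -> priors -> per-gene
MCMC -> diagnostics -> contrasts -> BH adjustment.

Chains are summarized gene by gene and then discarded, so memory stays
flat in the number of genes; set ``save_chains`` to keep full chains in an
HDF5 container instead.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import (ConvergenceReport, chain_diagnostics,
                          flag_convergence, reports_to_frame)
from .inference import Contrast, GeneResult, adjust_results, summarize
from .io import (CountMatrix, ModelDesign, RunConfig, SampleMetadata,
                 build_design, results_to_frame)
from .preprocess import filter_low_expression, median_of_ratios_size_factors
from .priors import PriorSpec, default_priors
from .sampler import GenePrior, fit_gene


@dataclass
class FitResult:
    results: list[GeneResult]
    reports: list[ConvergenceReport]
    design: ModelDesign
    priors: PriorSpec
    kept_mask: np.ndarray
    counts: CountMatrix

    @property
    def results_frame(self) -> pd.DataFrame:
        return results_to_frame(self.results)

    @property
    def diagnostics_frame(self) -> pd.DataFrame:
        return reports_to_frame(self.reports)


def fit_workflow(
    counts: CountMatrix,
    metadata: SampleMetadata,
    fixed: str,
    contrasts: list[Contrast],
    random: str = "intercept",
    config: RunConfig | None = None,
    filter_min_samples: int | None = None,
    no_filter: bool = False,
    offsets: np.ndarray | None = None,
    priors: PriorSpec | None = None,
    save_chains: str | None = None,
    include_failed_in_bh: bool = False,
    min_accept: float = 0.10,
    geweke_alpha: float = 0.05,
) -> FitResult:
    """Fit the Bayesian NB mixed model to every gene.

    ``filter_min_samples`` is the m of the CPM>1-in-at-least-m-samples
    filter; when None it is left to the caller's chosen default (0 = keep
    all). Offsets default to natural-log median-of-ratios size factors
    computed on the *filtered* matrix.
    """
    config = config or RunConfig()
    if no_filter or not filter_min_samples:
        filtered, mask = counts, np.ones(counts.n_genes, dtype=bool)
    else:
        filtered, mask = filter_low_expression(counts, filter_min_samples)
    if offsets is None:
        offsets = median_of_ratios_size_factors(filtered).offsets
    design = build_design(metadata, fixed, random_spec=random, offsets=offsets)
    if priors is None:
        priors = default_priors(filtered, design, k=config.prior_k,
                                span=config.loess_span)

    h5 = None
    if save_chains is not None:
        import h5py

        h5 = h5py.File(save_chains, "w")

    def one(g: int):
        chains = fit_gene(filtered, g, design, priors, config)
        rep = chain_diagnostics(chains)
        res = summarize(chains, contrasts, converged=not chains.failed)
        return g, chains, rep, res

    results: list[GeneResult] = []
    reports: list[ConvergenceReport] = []
    gene_iter = range(filtered.n_genes)
    if config.n_workers > 1:
        pool = ThreadPoolExecutor(max_workers=config.n_workers)
        mapped = pool.map(one, gene_iter)
    else:
        pool = None
        mapped = map(one, gene_iter)
    try:
        for g, chains, rep, res in mapped:
            reports.append(rep)
            results.append(res)
            if h5 is not None:
                grp = h5.create_group(chains.gene_id)
                grp.create_dataset("beta", data=chains.beta)
                grp.create_dataset("log_alpha", data=chains.log_alpha)
                if chains.sigma2 is not None:
                    grp.create_dataset("sigma", data=chains.sigma2)
                if chains.b is not None:
                    grp.create_dataset("b", data=chains.b)
                grp.create_dataset("accept_beta", data=chains.accept_beta)
                grp.create_dataset("accept_alpha", data=chains.accept_alpha)
    finally:
        if pool is not None:
            pool.shutdown()
        if h5 is not None:
            h5.close()

    reports = flag_convergence(reports, min_accept=min_accept,
                               geweke_alpha=geweke_alpha)
    for rep, res in zip(reports, results):
        res.converged = not rep.failed
    results = adjust_results(results, include_failed=include_failed_in_bh)
    return FitResult(results=results, reports=reports, design=design,
                     priors=priors, kept_mask=mask, counts=filtered)
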