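"""Posterior inference: contrasts, contour probabilities, BH adjustment.

A contrast is a linear combination c'beta of the fixed-effect coefficients;
its posterior is summarized by the median and the 95% equal-tailed credible
interval of the draw-wise combination. Evidence against c'beta = 0 is the
contour probability

    p_c = min(1, 2 * (1/R) * #{ draws on the opposite side of 0 from the
                                posterior median })

the Bayesian analogue of a two-sided p-value. Across genes, contour
probabilities for a given contrast are adjusted with the Benjamini-Hochberg
step-up procedure. The resolution of p_c is 2/R, so a fully one-sided chain
reports exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .sampler import PosteriorChains


@dataclass
class Contrast:
    """Named linear combination of fixed-effect coefficients (tests c'beta=0)."""

    name: str
    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if self.c.ndim != 1 or not np.any(self.c != 0):
            raise ValueError(f"contrast {self.name!r} must be a nonzero vector")


def parse_contrast(name: str, spec, column_names: list[str]) -> Contrast:
    """Build a Contrast from an explicit coefficient vector or a symbolic
    sum/difference of design-column names, e.g. ``"group + group:time"``."""
    if isinstance(spec, str):
        c = np.zeros(len(column_names))
        expr = spec.replace("-", "+-")
        for term in expr.split("+"):
            term = term.strip()
            if not term:
                continue
            sign = 1.0
            if term.startswith("-"):
                sign, term = -1.0, term[1:].strip()
            matches = [i for i, col in enumerate(column_names)
                       if col == term or term in col]
            exact = [i for i, col in enumerate(column_names) if col == term]
            idx = exact if exact else matches
            if len(idx) != 1:
                raise ValueError(
                    f"contrast term {term!r} matches {len(idx)} design columns "
                    f"of {column_names}"
                )
            c[idx[0]] += sign
        return Contrast(name, c)
    return Contrast(name, np.asarray(spec, dtype=float))


def contrast_chain(chains: PosteriorChains, contrast: Contrast) -> np.ndarray:
    """Draw-wise values of c'beta."""
    if contrast.c.shape[0] != chains.beta.shape[1]:
        raise ValueError(
            f"contrast {contrast.name!r} has length {contrast.c.shape[0]}, "
            f"design has p={chains.beta.shape[1]}"
        )
    return chains.beta @ contrast.c


def contour_probability(samples: np.ndarray) -> float:
    """Twice the fraction of draws on the opposite side of 0 from the
    posterior median (capped at 1). Draws exactly at 0 never count.
    """
    samples = np.asarray(samples, dtype=float)
    R = samples.size
    if R < 100:
        warnings.warn(
            f"contour probability from only {R} draws; resolution is {2 / max(R, 1):.3g}",
            UserWarning,
            stacklevel=2,
        )
    med = float(np.median(samples))
    n_opp = int(np.sum(samples * med < 0))
    p_c = min(1.0, 2.0 * n_opp / R)
    # perfectly symmetric chains give p_c = 0 by the strict inequality;
    # surface the pathology rather than silently reporting strong evidence
    if abs(med) < 1e-12:
        lo = np.sum(samples < 0) / R
        hi = np.sum(samples > 0) / R
        if abs(lo - hi) < 2.0 / R and lo > 0:
            warnings.warn(
                "posterior median is numerically 0 with balanced tails; "
                "contour probability is degenerate",
                UserWarning,
                stacklevel=2,
            )
    return p_c


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    adj(i) = min_{j >= i} p_(j) * n / j over the ascending ordering,
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


@dataclass
class ContrastSummary:
    median: float
    ci_lower: float
    ci_upper: float
    contour_prob: float
    adj_contour_prob: float = np.nan


@dataclass
class GeneResult:
    gene_id: str
    contrasts: dict = field(default_factory=dict)  # name -> ContrastSummary
    converged: bool = True


def summarize(chains: PosteriorChains, contrasts: list[Contrast],
              converged: bool = True) -> GeneResult:
    """Per-contrast posterior median, 95% equal-tailed interval and contour
    probability for one gene; BH adjustment happens later across genes."""
    if chains.n_retained < 100:
        warnings.warn("fewer than 100 retained draws", UserWarning, stacklevel=2)
    res = GeneResult(gene_id=chains.gene_id, converged=converged)
    for con in contrasts:
        draws = contrast_chain(chains, con)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        res.contrasts[con.name] = ContrastSummary(
            median=float(np.median(draws)),
            ci_lower=float(lo),
            ci_upper=float(hi),
            contour_prob=contour_probability(draws),
        )
    return res


def adjust_results(results: list[GeneResult],
                   include_failed: bool = False) -> list[GeneResult]:
    """BH-adjust contour probabilities across genes, separately per contrast.

    Convergence failures are excluded from the adjustment pool by default
    and keep NaN adjusted values (the raw contour probability is still
    reported).
    """
    if not results:
        return results
    names = list(results[0].contrasts.keys())
    pool = [r for r in results if (r.converged or include_failed)]
    for name in names:
        raw = np.array([r.contrasts[name].contour_prob for r in pool])
        if raw.size:
            adj = bh_adjust(raw)
            for r, a in zip(pool, adj):
                r.contrasts[name].adj_contour_prob = float(a)
    return results
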