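"""Empirical prior construction for the Bayesian NB mixed model.

Each gene g gets independent priors

    beta_g   ~ MVN(M_g, T)
    log a_g  ~ N(A_g, B)
    sigma2_b ~ InvGamma(U, V)          (single random intercept, q = 1)

M_g has the log of the gene's mean raw count in its intercept element and
zeros elsewhere; T = diag(7^2) keeps the coefficient priors vague. The
dispersion prior shares information across genes: naive method-of-moments
dispersion estimates are regressed on mean log(CPM) with a local-quadratic
LOESS, A_g is the trend value at the gene's mean log(CPM), and the prior
variance B = (k*tau)^2 inflates the residual spread tau of the trend fit
by a factor k (default 2) because method-of-moments estimates ignore the
variance explained by the fixed and random effects and therefore
over-estimate the dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .io import CountMatrix, ModelDesign, ValidationError
from .preprocess import cpm

MIN_USABLE_GENES = 20
TAU_FLOOR = 0.1  # avoids a point-mass dispersion prior when the trend fits exactly


@dataclass
class DispersionTrend:
    mean_logcpm: np.ndarray           # per gene (all genes)
    naive_dispersion: np.ndarray      # per gene, NaN where undefined
    trend: Callable[[np.ndarray], np.ndarray]  # log-dispersion vs mean log(CPM)
    tau: float                        # residual SD of the genes entering the fit
    fit_range: tuple[float, float]


@dataclass
class PriorSpec:
    M: np.ndarray        # G x p prior means
    T: np.ndarray        # p x p prior covariance
    U: float | np.ndarray
    V: float
    A: np.ndarray        # per-gene prior mean of log dispersion
    B: float             # shared prior variance of log dispersion
    k: float
    trend: DispersionTrend | None = None


def mom_dispersion(counts: CountMatrix) -> np.ndarray:
    """Naive method-of-moments dispersion per gene.

    Counts are first scaled to the median library size; the estimate is
    (v_g - m_g) / m_g^2 with the sample variance (S-1 divisor). Values can
    legitimately be non-positive (under-dispersed genes); genes with zero
    mean return NaN.
    """
    if counts.n_samples < 2:
        raise ValidationError("method-of-moments dispersion needs >= 2 samples")
    lib = counts.counts.sum(axis=0).astype(float)
    scaled = counts.counts * (np.median(lib) / lib)[None, :]
    m = scaled.mean(axis=1)
    v = scaled.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = (v - m) / m**2
    est[m == 0] = np.nan
    return est


def _loess_quadratic(
    x: np.ndarray, y: np.ndarray, span: float, n_grid: int = 201
) -> tuple[np.ndarray, np.ndarray]:
    """Local quadratic regression with tricube weights on an evaluation grid.

    Returns (grid, fitted values at grid). The trend between grid points is
    recovered by linear interpolation; 201 points over the observed range
    make the interpolation error negligible relative to tau.
    """
    n = x.size
    k = max(3, int(np.ceil(span * n)))
    k = min(k, n)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return np.array([lo]), np.array([float(np.mean(y))])
    grid = np.linspace(lo, hi, n_grid)
    fitted = np.empty(n_grid)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        if k < n:
            idx = np.argpartition(d, k - 1)[:k]
        else:
            idx = np.arange(n)
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = float(np.mean(y[idx]))
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        xc = x[idx] - x0
        A = np.column_stack([np.ones(idx.size), xc, xc**2])
        Aw = A * w[:, None]
        coef, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ y[idx], rcond=None)
        fitted[i] = coef[0]
    return grid, fitted


def fit_dispersion_prior(
    mom: np.ndarray,
    mean_logcpm: np.ndarray,
    k: float = 2.0,
    span: float = 0.75,
) -> tuple[np.ndarray, float, DispersionTrend]:
    """Fit the log-dispersion trend and derive (A_g, B).

    Only genes with strictly positive method-of-moments estimates enter the
    LOESS fit of ln(dispersion) on mean log(CPM); every gene then receives
    A_g from the fitted trend at its own mean log(CPM), clamped to the
    fitted range outside it. B = (k * tau)^2 with tau the residual SD.
    """
    mom = np.asarray(mom, dtype=float)
    mean_logcpm = np.asarray(mean_logcpm, dtype=float)
    usable = np.isfinite(mom) & (mom > 0) & np.isfinite(mean_logcpm)
    if usable.sum() < MIN_USABLE_GENES:
        raise ValidationError(
            f"only {int(usable.sum())} genes with positive dispersion estimates "
            f"(need >= {MIN_USABLE_GENES}); set A and B manually"
        )
    x = mean_logcpm[usable]
    y = np.log(mom[usable])
    grid, fitted_grid = _loess_quadratic(x, y, span)
    lo, hi = float(grid[0]), float(grid[-1])

    def trend(xs: np.ndarray) -> np.ndarray:
        xs = np.clip(np.asarray(xs, dtype=float), lo, hi)
        return np.interp(xs, grid, fitted_grid)

    residuals = y - trend(x)
    tau = float(np.std(residuals, ddof=1)) if x.size > 1 else 0.0
    B = (k * max(tau, TAU_FLOOR)) ** 2
    A = trend(mean_logcpm)
    dt = DispersionTrend(
        mean_logcpm=mean_logcpm,
        naive_dispersion=mom,
        trend=trend,
        tau=tau,
        fit_range=(lo, hi),
    )
    return A, B, dt


def default_priors(
    counts: CountMatrix,
    design: ModelDesign,
    k: float = 2.0,
    span: float = 0.75,
    fixed_A: float | np.ndarray | None = None,
    fixed_B: float | None = None,
) -> PriorSpec:
    """Assemble the default prior specification for a filtered count matrix."""
    G, p = counts.n_genes, design.p
    mean_count = counts.counts.mean(axis=1)
    if np.any(mean_count <= 0):
        raise ValidationError(
            "gene with zero mean count; filter low-expression genes first"
        )
    M = np.zeros((G, p))
    M[:, 0] = np.log(mean_count)
    T = np.diag(np.full(p, 49.0))
    if design.q <= 1:
        U, V = 0.01, 0.01
    else:  # pragma: no cover - interface restricts q <= 1
        U, V = 1.0, design.q + 1

    trend = None
    if fixed_A is not None and fixed_B is not None:
        A = np.full(G, float(fixed_A)) if np.isscalar(fixed_A) else np.asarray(fixed_A)
        B = float(fixed_B)
    else:
        A_fit, B_fit, trend = fit_dispersion_prior(
            mom_dispersion(counts), mean_log_cpm(counts), k=k, span=span
        )
        A = A_fit if fixed_A is None else (
            np.full(G, float(fixed_A)) if np.isscalar(fixed_A) else np.asarray(fixed_A)
        )
        B = B_fit if fixed_B is None else float(fixed_B)
    return PriorSpec(M=M, T=T, U=U, V=V, A=A, B=B, k=k, trend=trend)


def mean_log_cpm(counts: CountMatrix) -> np.ndarray:
    """Per-gene log of the mean CPM across samples (finite post-filtering)."""
    return np.log(cpm(counts).mean(axis=1))
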