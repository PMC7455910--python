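"""Per-gene hybrid Metropolis-Hastings/Gibbs sampler for the Bayesian
negative binomial mixed model

    Y_s  ~ NB(mu_s, alpha),   Var(Y) = mu + alpha mu^2
    log mu_s = X_s beta + b_{subject(s)} + offset_s
    b_i  ~ N(0, sigma2_b)

with priors beta ~ MVN(M, T), log alpha ~ N(A, B) and sigma2_b inverse
gamma(U, V) (shape/scale convention: density proportional to
x^(-U-1) exp(-V/x)).

The regression block (beta, b) is updated jointly with a one-step weighted
least squares Gaussian proposal (Gamerman's scheme) and an asymmetric
Metropolis-Hastings correction; log alpha by an adaptive random walk;
sigma2_b by its exact inverse-gamma full conditional.

`run_chain` drives the compiled kernel in :mod:`nbmix._kernel`; the
functions `wls_proposal`, `mh_update_regression`, `rw_update_log_dispersion`
and `gibbs_update_sigma` are plain-numpy implementations of the individual
updates, used for single steps, didactic purposes and as test surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from concurrent.futures import ThreadPoolExecutor

import numpy as np
import scipy.stats as st

from . import _kernel
from .io import CountMatrix, ModelDesign, RunConfig, gene_seed
from .priors import PriorSpec


# ---------------------------------------------------------------------------
# Model pieces
# ---------------------------------------------------------------------------

def nb_loglik(y, mu, alpha):
    """Log pmf of the NB with mean ``mu`` and dispersion ``alpha``
    (Var = mu + alpha*mu^2), i.e. size r = 1/alpha, computed stably via
    log-gamma functions. Vectorized over any broadcastable arguments."""
    r = 1.0 / np.asarray(alpha, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return st.nbinom.logpmf(y, r, r / (r + mu))


@dataclass
class GenePrior:
    """Per-gene view of a PriorSpec."""

    M: np.ndarray   # p
    T: np.ndarray   # p x p
    U: float
    V: float
    A: float
    B: float

    @classmethod
    def from_spec(cls, prior: PriorSpec, g: int) -> "GenePrior":
        return cls(M=prior.M[g], T=prior.T, U=float(prior.U), V=float(prior.V),
                   A=float(prior.A[g]), B=float(prior.B))


@dataclass
class ChainState:
    """Current parameter values of one gene's chain."""

    beta: np.ndarray          # p
    b: np.ndarray | None      # I (None when q = 0)
    log_alpha: float
    sigma2: float             # random-intercept variance (ignored when q = 0)

    def theta(self) -> np.ndarray:
        if self.b is None:
            return np.asarray(self.beta, dtype=float)
        return np.concatenate([self.beta, self.b])


@dataclass
class PosteriorChains:
    """Retained (post burn-in) draws and per-iteration acceptance flags."""

    gene_id: str
    beta: np.ndarray          # R x p
    log_alpha: np.ndarray     # R
    sigma2: np.ndarray | None  # R (None when q = 0)
    b: np.ndarray | None      # thinned random-effect draws, if stored
    accept_beta: np.ndarray   # n_iter bools
    accept_alpha: np.ndarray  # n_iter bools
    n_burn: int
    failed: bool = False
    column_names: list | None = None

    @property
    def n_retained(self) -> int:
        return self.beta.shape[0]


def _linpred(design: ModelDesign, state: ChainState) -> np.ndarray:
    eta = design.X @ state.beta + design.offsets
    if state.b is not None and design.subject_index is not None:
        eta = eta + state.b[design.subject_index]
    return eta


def log_posterior(y, design: ModelDesign, state: ChainState,
                  prior: GenePrior) -> float:
    """Unnormalized log posterior of (beta, b) at fixed alpha, sigma2."""
    eta = _linpred(design, state)
    if np.any(np.abs(eta) > _kernel.ETA_MAX):
        return -np.inf
    mu = np.exp(eta)
    alpha = np.exp(state.log_alpha)
    ll = float(np.sum(nb_loglik(y, mu, alpha)))
    d = state.beta - prior.M
    lp = ll - 0.5 * d @ np.linalg.solve(prior.T, d)
    if state.b is not None:
        lp -= 0.5 * np.sum(state.b**2) / state.sigma2
    return lp


# ---------------------------------------------------------------------------
# Individual updates (numpy reference implementations)
# ---------------------------------------------------------------------------

def wls_proposal(y, design: ModelDesign, state: ChainState,
                 prior: GenePrior) -> tuple[np.ndarray, np.ndarray]:
    """One weighted-least-squares step from the current state.

    Returns (mean, covariance) of the Gaussian proposal for the stacked
    coefficient vector theta = (beta, b). With combined design
    C = [X | Z], eta = C theta + rho and mu = exp(eta), the working
    weights are w = mu / (1 + alpha mu), the working response is
    z = (eta - rho) + (y - mu)/mu, and

        cov  = (C' W C + P)^(-1)
        mean = cov (C' W z + P m0)

    where P is the block-diagonal prior precision and m0 = (M, 0).
    """
    S = design.n_samples
    I = design.n_subjects if design.q == 1 else 0
    C = design.X
    if I > 0:
        Z = np.zeros((S, I))
        Z[np.arange(S), design.subject_index] = 1.0
        C = np.hstack([design.X, Z])
    eta = C @ state.theta() + design.offsets
    mu = np.exp(np.clip(eta, -_kernel.ETA_MAX, _kernel.ETA_MAX))
    alpha = np.exp(state.log_alpha)
    w = mu / (1.0 + alpha * mu)
    z = (eta - design.offsets) + (y - mu) / mu
    Tinv = np.linalg.inv(prior.T)
    dim = C.shape[1]
    P = np.zeros((dim, dim))
    P[: design.p, : design.p] = Tinv
    if I > 0:
        P[design.p:, design.p:] = np.eye(I) / state.sigma2
    m0 = np.zeros(dim)
    m0[: design.p] = prior.M
    Qmat = C.T @ (w[:, None] * C) + P
    try:
        cov = np.linalg.inv(Qmat)
    except np.linalg.LinAlgError:
        Qmat = Qmat + 1e-8 * np.eye(dim)
        cov = np.linalg.inv(Qmat)
    mean = cov @ (C.T @ (w * z) + P @ m0)
    return mean, cov


def mh_update_regression(y, design: ModelDesign, state: ChainState,
                         prior: GenePrior,
                         rng: np.random.Generator) -> tuple[ChainState, bool]:
    """Joint MH update of (beta, b) with the asymmetric WLS proposal."""
    mean_c, cov_c = wls_proposal(y, design, state, prior)
    theta_p = rng.multivariate_normal(mean_c, cov_c, method="cholesky")
    p = design.p
    prop = ChainState(
        beta=theta_p[:p],
        b=theta_p[p:] if state.b is not None else None,
        log_alpha=state.log_alpha,
        sigma2=state.sigma2,
    )
    lp_prop = log_posterior(y, design, prop, prior)
    if not np.isfinite(lp_prop):
        return state, False
    lp_cur = log_posterior(y, design, state, prior)
    mean_p, cov_p = wls_proposal(y, design, prop, prior)
    logq_fwd = st.multivariate_normal.logpdf(theta_p, mean_c, cov_c)
    logq_rev = st.multivariate_normal.logpdf(state.theta(), mean_p, cov_p)
    log_ratio = (lp_prop + logq_rev) - (lp_cur + logq_fwd)
    if not np.isfinite(log_ratio):
        return state, False
    if np.log(rng.random()) < log_ratio:
        return prop, True
    return state, False


def rw_update_log_dispersion(y, design: ModelDesign, state: ChainState,
                             prior: GenePrior, step_sd: float,
                             rng: np.random.Generator) -> tuple[float, bool]:
    """Random-walk MH update of log(alpha); the Gaussian proposal is
    symmetric so only likelihood and prior terms enter the ratio."""
    if step_sd < 0:
        raise ValueError("step_sd must be >= 0")
    la = state.log_alpha
    la_p = la + step_sd * rng.standard_normal()
    mu = np.exp(np.clip(_linpred(design, state), -_kernel.ETA_MAX,
                        _kernel.ETA_MAX))
    ll_p = float(np.sum(nb_loglik(y, mu, np.exp(la_p))))
    ll_c = float(np.sum(nb_loglik(y, mu, np.exp(la))))
    lr = (ll_p - ll_c
          - 0.5 * (la_p - prior.A) ** 2 / prior.B
          + 0.5 * (la - prior.A) ** 2 / prior.B)
    if np.isfinite(lr) and np.log(rng.random()) < lr:
        return la_p, True
    return la, False


def gibbs_update_sigma(b: np.ndarray, U: float, V: float,
                       rng: np.random.Generator) -> float:
    """Exact inverse-gamma draw of the random-intercept variance.

    Full conditional: IG(shape U + I/2, scale V + sum(b^2)/2), under the
    shape/scale convention density ~ x^(-shape-1) exp(-scale/x).
    """
    b = np.asarray(b, dtype=float).ravel()
    shape = U + b.size / 2.0
    scale = V + 0.5 * float(np.sum(b**2))
    return scale / rng.gamma(shape, 1.0)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def _pregenerate(rng: np.random.Generator, n_iter: int, dim: int,
                 ig_shape: float, q: int):
    xi = rng.standard_normal((n_iter, dim))
    xi_d = rng.standard_normal(n_iter)
    u_reg = rng.random(n_iter)
    u_disp = rng.random(n_iter)
    gam = rng.gamma(ig_shape, 1.0, n_iter) if q == 1 else np.ones(n_iter)
    return xi, xi_d, u_reg, u_disp, gam


def run_chain(y, design: ModelDesign, prior: GenePrior, config: RunConfig,
              rng: np.random.Generator, gene_id: str = "gene",
              compiled: bool = True) -> PosteriorChains:
    """Run the full MCMC for one gene and return retained draws.

    All randomness is pre-generated from ``rng`` before the kernel runs, so
    a chain depends only on the generator's seed. ``compiled=False`` runs
    the identical algorithm through the kernel's pure-Python fallback.
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    I = design.n_subjects if design.q == 1 else 0
    dim = design.p + I
    ig_shape = float(prior.U) + I / 2.0
    xi, xi_d, u_reg, u_disp, gam = _pregenerate(
        rng, config.n_iter, dim, ig_shape, design.q
    )
    subj = (design.subject_index if I > 0
            else np.zeros(design.n_samples, dtype=np.int64))
    Tinv = np.linalg.inv(prior.T)
    fn = _kernel.run_chain_kernel if compiled else _kernel.run_chain_kernel.py_func
    (beta, la, s2, b, acc_b, acc_a, n_bad, _step) = fn(
        y, np.ascontiguousarray(design.X), subj, I,
        np.ascontiguousarray(design.offsets),
        np.ascontiguousarray(prior.M, dtype=np.float64),
        np.ascontiguousarray(Tinv), float(prior.A), float(prior.B),
        float(prior.U), float(prior.V),
        int(config.n_iter), int(config.n_burn),
        xi, xi_d, u_reg, u_disp, gam,
        float(config.step_sd_init), float(config.adapt_target),
        bool(config.save_random_effects), 10,
    )
    failed = n_bad > config.n_iter // 2
    return PosteriorChains(
        gene_id=gene_id,
        beta=beta,
        log_alpha=la,
        sigma2=s2 if I > 0 else None,
        b=b if (config.save_random_effects and I > 0) else None,
        accept_beta=acc_b.astype(bool),
        accept_alpha=acc_a.astype(bool),
        n_burn=config.n_burn,
        failed=failed,
        column_names=list(design.column_names),
    )


def fit_gene(counts: CountMatrix, g: int, design: ModelDesign,
             priors: PriorSpec, config: RunConfig,
             compiled: bool = True) -> PosteriorChains:
    gene_id = counts.gene_ids[g]
    rng = np.random.default_rng(gene_seed(config.master_seed, gene_id))
    return run_chain(
        counts.counts[g], design, GenePrior.from_spec(priors, g), config,
        rng, gene_id=gene_id, compiled=compiled,
    )


def fit_all_genes(counts: CountMatrix, design: ModelDesign,
                  priors: PriorSpec, config: RunConfig):
    """Fit every gene independently; per-gene seeded streams make the output
    a pure function of (inputs, master_seed), whatever ``n_workers`` is.

    A gene whose chain aborts yields a PosteriorChains with ``failed=True``;
    unexpected per-gene exceptions yield None and never abort the run.
    """
    def one(g: int):
        try:
            return fit_gene(counts, g, design, priors, config)
        except Exception:
            return None

    genes = range(counts.n_genes)
    if config.n_workers > 1:
        with ThreadPoolExecutor(max_workers=config.n_workers) as pool:
            return list(pool.map(one, genes))
    return [one(g) for g in genes]
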