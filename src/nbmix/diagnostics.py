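"""Chain-quality screening.

Two screens are applied to every gene's chain:

* acceptance rates of the two Metropolis blocks (regression coefficients
  and log dispersion) over the post burn-in iterations — the variance
  update is an exact Gibbs draw and is ignored;
* a Geweke mean-equality z-test comparing the first 20% of the retained
  draws to the final 50%, for every screened parameter (each fixed-effect
  coefficient, log alpha and, when present, log sigma2_b). The segment
  variances are long-run (autocorrelation-consistent) variances estimated
  with Geyer's initial monotone sequence of autocovariances; a naive
  independent-sample variance would reject stationary but autocorrelated
  chains wholesale.

Geweke p-values are BH-adjusted across genes separately per parameter. A
gene is flagged as a convergence failure when any acceptance rate falls
below 0.10 or any adjusted Geweke p-value falls below 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .inference import bh_adjust
from .sampler import PosteriorChains

MIN_ACCEPTANCE = 0.10
GEWEKE_ALPHA = 0.05
EARLY_FRAC = 0.20
LATE_FRAC = 0.50


def acceptance_rate(flags: np.ndarray) -> float:
    """Mean of per-iteration acceptance flags (pass the post burn-in slice)."""
    flags = np.asarray(flags)
    if flags.size == 0:
        raise ValueError("no iterations to compute an acceptance rate from")
    return float(np.mean(flags))


def long_run_variance(x: np.ndarray) -> float:
    """Long-run variance of a stationary chain (variance of the mean times n).

    Geyer's initial monotone sequence estimator: autocovariances are
    computed by FFT, summed in adjacent pairs while the pair sums stay
    positive and non-increasing. For iid input this reduces to (about) the
    ordinary variance; for autocorrelated chains it inflates the variance
    by the integrated autocorrelation time.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 0.0
    xc = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    if acov[0] <= 0:
        return 0.0
    # sigma2 = -gamma0 + 2 * sum of pair sums Gamma_m = gamma_2m + gamma_{2m+1},
    # truncated at the first nonpositive pair, each pair capped by the previous
    total = -acov[0]
    prev = np.inf
    for m in range(n // 2):
        g = acov[2 * m] + acov[2 * m + 1]
        if g <= 0:
            break
        g = min(g, prev)
        total += 2 * g
        prev = g
    return max(total, 0.0)


def geweke_test(chain: np.ndarray) -> tuple[float, float]:
    """Geweke z-test for equal means of the first 20% vs the last 50% of a
    retained chain, with autocorrelation-consistent segment variances;
    returns (z, two-sided normal p)."""
    chain = np.asarray(chain, dtype=float)
    R = chain.size
    if R < 100:
        warnings.warn("Geweke test on fewer than 100 draws", UserWarning,
                      stacklevel=2)
    a = chain[: max(1, int(R * EARLY_FRAC))]
    b = chain[R - max(1, int(R * LATE_FRAC)):]
    va = long_run_variance(a)
    vb = long_run_variance(b)
    se2 = va / a.size + vb / b.size
    dmean = a.mean() - b.mean()
    if se2 == 0.0:
        if dmean == 0.0:
            return 0.0, 1.0
        warnings.warn("degenerate chain: zero variance but unequal segment "
                      "means", UserWarning, stacklevel=2)
        return np.inf if dmean > 0 else -np.inf, 0.0
    z = dmean / np.sqrt(se2)
    p = 2.0 * st.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class ConvergenceReport:
    gene_id: str
    accept_rate_regression: float
    accept_rate_dispersion: float
    geweke_z: dict = field(default_factory=dict)      # param -> z
    geweke_p: dict = field(default_factory=dict)      # param -> raw p
    geweke_p_adj: dict = field(default_factory=dict)  # param -> BH p (across genes)
    failed: bool = False
    failure_reasons: list = field(default_factory=list)


def screened_parameters(chains: PosteriorChains) -> dict[str, np.ndarray]:
    """Chains entering the Geweke screen: all beta elements, log alpha and
    (q=1) the log random-intercept variance, on the log scale for symmetry."""
    names = chains.column_names or [f"beta{j}" for j in range(chains.beta.shape[1])]
    params = {f"beta:{name}": chains.beta[:, j] for j, name in enumerate(names)}
    params["log_alpha"] = chains.log_alpha
    if chains.sigma2 is not None:
        params["log_sigma2"] = np.log(chains.sigma2)
    return params


def chain_diagnostics(chains: PosteriorChains) -> ConvergenceReport:
    """Acceptance rates and raw Geweke statistics for one gene (adjusted
    p-values are filled in later, across genes)."""
    nb = chains.n_burn
    rep = ConvergenceReport(
        gene_id=chains.gene_id,
        accept_rate_regression=acceptance_rate(chains.accept_beta[nb:]),
        accept_rate_dispersion=acceptance_rate(chains.accept_alpha[nb:]),
    )
    for name, chain in screened_parameters(chains).items():
        z, p = geweke_test(chain)
        rep.geweke_z[name] = z
        rep.geweke_p[name] = p
    if chains.failed:
        rep.failed = True
        rep.failure_reasons.append("sampler_abort")
    return rep


def flag_convergence(reports: list[ConvergenceReport],
                     min_accept: float = MIN_ACCEPTANCE,
                     geweke_alpha: float = GEWEKE_ALPHA) -> list[ConvergenceReport]:
    """Apply the composite failure rule across genes.

    Geweke p-values are BH-adjusted across genes separately for each
    parameter; a gene fails if any acceptance rate < ``min_accept`` or any
    adjusted Geweke p < ``geweke_alpha`` (or its sampler aborted).
    """
    if not reports:
        return reports
    param_names = sorted({k for r in reports for k in r.geweke_p})
    for name in param_names:
        idx = [i for i, r in enumerate(reports) if name in r.geweke_p]
        raw = np.array([reports[i].geweke_p[name] for i in idx])
        adj = bh_adjust(raw)
        for i, a in zip(idx, adj):
            reports[i].geweke_p_adj[name] = float(a)
    for r in reports:
        if r.accept_rate_regression < min_accept:
            r.failed = True
            r.failure_reasons.append("acceptance:regression")
        if r.accept_rate_dispersion < min_accept:
            r.failed = True
            r.failure_reasons.append("acceptance:dispersion")
        bad = [n for n, a in r.geweke_p_adj.items() if a < geweke_alpha]
        if bad:
            r.failed = True
            r.failure_reasons.extend(f"geweke:{n}" for n in bad)
    return reports


def reports_to_frame(reports: list[ConvergenceReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "gene_id": r.gene_id,
            "accept_regression": r.accept_rate_regression,
            "accept_dispersion": r.accept_rate_dispersion,
            "failed": r.failed,
            "failure_reasons": ";".join(r.failure_reasons),
        }
        for n, pval in r.geweke_p.items():
            row[f"geweke_p[{n}]"] = pval
        for n, pval in r.geweke_p_adj.items():
            row[f"geweke_p_adj[{n}]"] = pval
        rows.append(row)
    return pd.DataFrame(rows)
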