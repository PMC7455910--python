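"""Compiled per-gene MCMC kernel.

One iteration of the hybrid sampler is:

1. joint Metropolis-Hastings update of (beta, b) using a one-step weighted
   least squares (Gamerman-style) Gaussian proposal built at the current
   state, with the asymmetric-proposal correction;
2. random-walk Metropolis update of log(alpha), step size adapted toward a
   target acceptance rate during burn-in only;
3. exact Gibbs draw of the random-intercept variance sigma2_b from its
   inverse-gamma full conditional (shape U + I/2, scale V + sum(b^2)/2).

All randomness is pre-generated by the caller (standard normals, uniforms
and unit-scale gamma variates), which keeps chains bit-reproducible and
independent of threading.

The negative binomial is parametrized by mean mu and dispersion alpha with
Var(Y) = mu + alpha*mu^2 (size r = 1/alpha). Terms constant in all
Metropolis ratios (lgamma(y+1)) are dropped inside the kernel.
"""

import math

import numpy as np
from numba import njit

ETA_MAX = 50.0       # |linear predictor| cap; beyond this the move is rejected
LOG_ALPHA_MAX = 25.0


@njit(cache=True, nogil=True, inline="always")
def _chol_inplace(Q, L):
    """Lower Cholesky of Q into L; returns False if not positive definite."""
    n = Q.shape[0]
    for i in range(n):
        for j in range(i + 1):
            s = Q[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
        for j in range(i + 1, n):
            L[i, j] = 0.0
    return True


@njit(cache=True, nogil=True, inline="always")
def _solve_lower(L, b, out):
    n = L.shape[0]
    for i in range(n):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * out[k]
        out[i] = s / L[i, i]


@njit(cache=True, nogil=True, inline="always")
def _solve_upper_t(L, b, out):
    """Solve L^T out = b with L lower triangular."""
    n = L.shape[0]
    for i in range(n - 1, -1, -1):
        s = b[i]
        for k in range(i + 1, n):
            s -= L[k, i] * out[k]
        out[i] = s / L[i, i]


@njit(cache=True, nogil=True)
def _eta_mu(theta, X, subj, I, offs, eta, mu):
    """Linear predictor and mean; returns False if eta exceeds the cap."""
    S, p = X.shape
    ok = True
    for s in range(S):
        e = offs[s]
        for a in range(p):
            e += X[s, a] * theta[a]
        if I > 0:
            e += theta[p + subj[s]]
        eta[s] = e
        if e > ETA_MAX or e < -ETA_MAX:
            ok = False
        mu[s] = np.exp(min(max(e, -ETA_MAX), ETA_MAX))
    return ok


@njit(cache=True, nogil=True)
def _nb_const(y, r):
    """Sum of lgamma(y+r) - lgamma(r) over samples (mu-independent part)."""
    s = 0.0
    lgr = math.lgamma(r)
    for i in range(y.shape[0]):
        s += math.lgamma(y[i] + r) - lgr
    return s


@njit(cache=True, nogil=True)
def _nb_mu_part(y, eta, mu, r):
    """mu-dependent part of the NB log likelihood: sum over samples of
    r*log r - (y+r)*log(r+mu) + y*eta."""
    lr = np.log(r)
    s = 0.0
    for i in range(y.shape[0]):
        s += r * lr - (y[i] + r) * np.log(r + mu[i]) + y[i] * eta[i]
    return s


@njit(cache=True, nogil=True)
def _prior_quad(theta, M, Tinv, sigma2, p, I):
    """Log N(beta; M, T) + sum log N(b_i; 0, sigma2), dropping constants
    that cancel in the regression MH ratio (sigma2 fixed within it)."""
    qf = 0.0
    for a in range(p):
        for b2 in range(p):
            qf += (theta[a] - M[a]) * Tinv[a, b2] * (theta[b2] - M[b2])
    lp = -0.5 * qf
    if I > 0:
        for i in range(I):
            lp -= 0.5 * theta[p + i] * theta[p + i] / sigma2
    return lp


@njit(cache=True, nogil=True)
def _build_wls(theta, y, X, subj, I, offs, M, Tinv, sigma2, alpha,
               eta, mu, Q, L, rhs, mean, work):
    """One weighted-least-squares step from ``theta``.

    Fills ``mean`` (proposal mean) and ``L`` (lower Cholesky factor of the
    proposal *precision* Q = C'WC + P). Returns the log-sqrt-determinant
    of Q (sum of log diag L), or NaN if the system is not positive
    definite even after one diagonal jitter.
    """
    S, p = X.shape
    dim = p + I
    for a in range(dim):
        for b2 in range(dim):
            Q[a, b2] = 0.0
        rhs[a] = 0.0
    for s in range(S):
        m = mu[s]
        w = m / (1.0 + alpha * m)
        z = (eta[s] - offs[s]) + (y[s] - m) / m
        wz = w * z
        for a in range(p):
            xa = X[s, a]
            rhs[a] += xa * wz
            xw = xa * w
            for b2 in range(a, p):
                Q[a, b2] += xw * X[s, b2]
        if I > 0:
            j = p + subj[s]
            for a in range(p):
                Q[a, j] += X[s, a] * w
            Q[j, j] += w
            rhs[j] += wz
    # prior precision and prior-mean pull (random effects have prior mean 0)
    for a in range(p):
        acc = 0.0
        for b2 in range(p):
            acc += Tinv[a, b2] * M[b2]
            if b2 >= a:
                Q[a, b2] += Tinv[a, b2]
        rhs[a] += acc
    if I > 0:
        inv_s2 = 1.0 / sigma2
        for i in range(I):
            Q[p + i, p + i] += inv_s2
    for a in range(dim):
        for b2 in range(a + 1, dim):
            Q[b2, a] = Q[a, b2]
    if not _chol_inplace(Q, L):
        for a in range(dim):
            Q[a, a] += 1.0e-8
        if not _chol_inplace(Q, L):
            return np.nan
    # mean = Q^{-1} rhs
    _solve_lower(L, rhs, work)
    _solve_upper_t(L, work, mean)
    logsqrtdet = 0.0
    for a in range(dim):
        logsqrtdet += np.log(L[a, a])
    return logsqrtdet


@njit(cache=True, nogil=True)
def run_chain_kernel(y, X, subj, I, offs, M, Tinv, A, B, U, V,
                     n_iter, n_burn, xi, xi_d, u_reg, u_disp, gam,
                     step_sd_init, adapt_target, save_b, b_thin):
    """Run one gene's chain; see module docstring for the update cycle.

    Returns (beta_chain, log_alpha_chain, sigma2_chain, b_chain,
    accept_beta, accept_alpha, n_bad, step_sd_final). ``n_bad`` counts
    iterations whose regression proposal could not be built.
    """
    S, p = X.shape
    dim = p + I
    R = n_iter - n_burn

    theta = np.zeros(dim)
    if S > 0:  # S == 0 samples the prior; start at its center
        mean_y = 0.0
        mean_off = 0.0
        for s in range(S):
            mean_y += y[s]
            mean_off += offs[s]
        theta[0] = np.log(max(mean_y / S, 0.5)) - mean_off / S
    log_alpha = A
    alpha = np.exp(log_alpha)
    r = 1.0 / alpha
    sigma2 = 0.1

    eta = np.empty(S)
    mu = np.empty(S)
    eta_p = np.empty(S)
    mu_p = np.empty(S)
    Q = np.empty((dim, dim))
    L = np.empty((dim, dim))
    Lp = np.empty((dim, dim))
    rhs = np.empty(dim)
    mean_c = np.empty(dim)
    mean_p = np.empty(dim)
    work = np.empty(dim)
    theta_p = np.empty(dim)
    diff = np.empty(dim)

    _eta_mu(theta, X, subj, I, offs, eta, mu)
    cur_mu_part = _nb_mu_part(y, eta, mu, r)
    cur_const = _nb_const(y, r)

    beta_out = np.empty((R, p))
    la_out = np.empty(R)
    s2_out = np.empty(R)
    nb_rows = (R + b_thin - 1) // b_thin if save_b else 1
    b_out = np.zeros((nb_rows, I if I > 0 else 1))
    acc_b = np.zeros(n_iter, np.uint8)
    acc_a = np.zeros(n_iter, np.uint8)

    log_step = np.log(step_sd_init)
    n_bad = 0

    for t in range(n_iter):
        # --- (beta, b) joint MH with WLS proposal ---
        lsd_c = _build_wls(theta, y, X, subj, I, offs, M, Tinv, sigma2,
                           alpha, eta, mu, Q, L, rhs, mean_c, work)
        if np.isnan(lsd_c):
            n_bad += 1
        else:
            # draw theta* = mean_c + L^{-T} xi
            _solve_upper_t(L, xi[t], work)
            norm_xi = 0.0
            for a in range(dim):
                theta_p[a] = mean_c[a] + work[a]
                norm_xi += xi[t, a] * xi[t, a]
            logq_fwd = lsd_c - 0.5 * norm_xi
            ok = _eta_mu(theta_p, X, subj, I, offs, eta_p, mu_p)
            if not ok:
                pass  # reject: linear predictor out of range
            else:
                prop_mu_part = _nb_mu_part(y, eta_p, mu_p, r)
                lp_prop = prop_mu_part + _prior_quad(theta_p, M, Tinv, sigma2, p, I)
                lp_cur = cur_mu_part + _prior_quad(theta, M, Tinv, sigma2, p, I)
                lsd_p = _build_wls(theta_p, y, X, subj, I, offs, M, Tinv,
                                   sigma2, alpha, eta_p, mu_p, Q, Lp, rhs,
                                   mean_p, work)
                # _build_wls overwrote eta_p/mu_p? no: it only reads them
                if np.isnan(lsd_p):
                    n_bad += 1
                else:
                    for a in range(dim):
                        diff[a] = theta[a] - mean_p[a]
                    # v = Lp^T diff
                    nv = 0.0
                    for a in range(dim):
                        s_ = 0.0
                        for k in range(a, dim):
                            s_ += Lp[k, a] * diff[k]
                        nv += s_ * s_
                    logq_rev = lsd_p - 0.5 * nv
                    log_ratio = (lp_prop + logq_rev) - (lp_cur + logq_fwd)
                    if np.isfinite(log_ratio) and np.log(u_reg[t]) < log_ratio:
                        for a in range(dim):
                            theta[a] = theta_p[a]
                        for s in range(S):
                            eta[s] = eta_p[s]
                            mu[s] = mu_p[s]
                        cur_mu_part = prop_mu_part
                        acc_b[t] = 1

        # --- log(alpha) random walk ---
        step = np.exp(log_step)
        la_p = log_alpha + step * xi_d[t]
        if la_p > LOG_ALPHA_MAX or la_p < -LOG_ALPHA_MAX:
            pa = 0.0
        else:
            r_p = np.exp(-la_p)
            const_p = _nb_const(y, r_p)
            mu_part_p = _nb_mu_part(y, eta, mu, r_p)
            lr = (const_p + mu_part_p - cur_const - cur_mu_part
                  - 0.5 * (la_p - A) ** 2 / B
                  + 0.5 * (log_alpha - A) ** 2 / B)
            pa = np.exp(min(0.0, lr)) if np.isfinite(lr) else 0.0
            if np.log(u_disp[t]) < lr:
                log_alpha = la_p
                alpha = np.exp(log_alpha)
                r = r_p
                cur_const = const_p
                cur_mu_part = mu_part_p
                acc_a[t] = 1
        if t < n_burn:
            # Robbins-Monro on the log step size, frozen after burn-in
            log_step += (pa - adapt_target) / (t + 1.0) ** 0.6

        # --- sigma2 Gibbs (exact, always accepted) ---
        if I > 0:
            ssq = 0.0
            for i in range(I):
                ssq += theta[p + i] * theta[p + i]
            sigma2 = (V + 0.5 * ssq) / gam[t]
            if sigma2 < 1.0e-12:
                sigma2 = 1.0e-12

        if t >= n_burn:
            j = t - n_burn
            for a in range(p):
                beta_out[j, a] = theta[a]
            la_out[j] = log_alpha
            s2_out[j] = sigma2
            if save_b and I > 0 and j % b_thin == 0:
                for i in range(I):
                    b_out[j // b_thin, i] = theta[p + i]

    return beta_out, la_out, s2_out, b_out, acc_b, acc_a, n_bad, np.exp(log_step)
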