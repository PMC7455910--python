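# Methods

## Model

For gene *g*, subject *i* and observation *j*, counts are modeled as
negative binomial with a log link and a subject-level random intercept:

    Y_gij ~ NB(mu_gij, alpha_g),        Var(Y) = mu + alpha_g * mu^2
    log(mu_gij) = X_ij beta_g + b_gi + rho_ij
    b_gi ~ N(0, sigma2_gb)

`X_ij` is the fixed-effect row (intercept first), `rho_ij` a known
per-sample offset (natural log of the median-of-ratios size factor), and
`alpha_g` the gene's dispersion (`alpha -> 0` recovers the Poisson). The
random intercept induces compound-symmetric correlation among a subject's
samples; dropping it (`random="none"`) gives a plain NB GLM. Only a single
random intercept is exposed at the interface (q = 0 or 1); the internal
linear algebra is written against the stacked coefficient vector
(beta, b_1..b_I) and generalizes.

Priors per gene:

    beta_g      ~ MVN(M_g, T)
    log alpha_g ~ N(A_g, B)
    sigma2_gb   ~ InvGamma(U, V)

* `M_g`: log of the gene's mean raw count in the intercept slot, zeros
  elsewhere — deliberately uninformative about any group or time effect.
* `T = diag(7^2)`: vague coefficient prior (sd 7 on a log scale covers any
  plausible fold change).
* `U = V = 0.01`: diffuse variance prior. **Parametrization note:** the
  inverse gamma here is shape/scale with density proportional to
  `x^(-U-1) exp(-V/x)`; the Gibbs full conditional is
  `InvGamma(U + I/2, V + sum(b_i^2)/2)`.
* `(A_g, B)`: the information-sharing dispersion prior, below.

## Empirical dispersion prior

Per-gene dispersion cannot be estimated stably from a handful of samples,
so the prior borrows strength across genes. For every gene a naive
method-of-moments estimate is computed from counts scaled to the median
library size: `(v_g - m_g) / m_g^2` with the S−1 variance divisor. The log
of the positive estimates is regressed on mean log(CPM) with a LOESS fit
(local quadratic, tricube weights, span 0.75, no robustness iterations —
span is exposed in the config). `A_g` is the fitted trend at the gene's
mean log(CPM) — for every gene, including those whose own estimate was
nonpositive; evaluation outside the fitted range clamps to the nearest
endpoint, since LOESS does not extrapolate. `B = (k * tau)^2`, where `tau`
is the residual SD of the fit and `k` (default 2) inflates it because
method-of-moments estimates are upward biased — they ignore the variance
explained by the fixed and random effects. Smaller `k` is more
conservative. If the trend fits exactly (`tau = 0`), `B` is floored at
`(0.1 k)^2` to avoid a point-mass prior. At least 20 genes with positive
estimates are required; otherwise `A` and `B` must be supplied.

The LOESS curve is evaluated on a 201-point grid over the observed
mean-log(CPM) range and interpolated linearly; against R's
`loess(span=0.75, degree=2, surface="direct")` on an 80-point fixture the
predictions agree to ~1e-4, far below `tau`.

## Sampler

Each gene runs one chain of a hybrid Metropolis–Hastings/Gibbs sampler
(default 30,000 iterations, first 10% discarded):

1. **(beta, b) jointly** — a Gaussian proposal from one weighted least
   squares step at the current state (Gamerman's scheme): with combined
   design `C = [X | Z]`, weights `w = mu/(1 + alpha mu)` and working
   response `z = (eta - rho) + (y - mu)/mu`, the proposal is
   `N((C'WC + P)^{-1} (C'Wz + P m0), (C'WC + P)^{-1})` with `P` the
   block-diagonal prior precision. The proposal is asymmetric (it depends
   on the current state), so the reverse density is recomputed at the
   proposed state for the acceptance ratio. The WLS map's fixed point is
   the penalized-likelihood mode, so proposals track the conditional
   posterior closely; acceptance rates on well-behaved genes sit around
   0.5–0.8. One step per proposal, never iterated.
2. **log alpha** — Gaussian random walk. Initial step SD 0.5, adapted
   toward 0.40 acceptance by Robbins–Monro on the log step size during
   burn-in only, then frozen, which preserves detailed balance for all
   retained draws.
3. **sigma2_b** — exact inverse-gamma Gibbs draw (always accepted, and
   therefore excluded from the acceptance-rate diagnostic).

Numerical choices: initialization at `beta_0 = log(mean count) - mean
offset`, other coefficients 0, `b = 0`, `log alpha = A_g`, `sigma2 = 0.1`
(inside the prior bulk); linear predictors beyond |50| reject the move;
a non-positive-definite WLS system is jittered by 1e-8 on the diagonal
once and the iteration is rejected if it remains non-SPD; a gene aborts
(failure marker) if more than half its iterations cannot build a
proposal. All per-gene randomness is pre-generated from a
`SeedSequence((master_seed, crc32(gene_id)))` stream, so results are
bit-reproducible, independent of the worker count, and unchanged by
subsetting or reordering genes. The per-iteration update order is
(beta, b), then log alpha, then sigma2. beta/log alpha/sigma2 chains are
stored unthinned (the contour-probability resolution is 2/R); random
effects are stored every 10th draw and only on request.

The inner loop is compiled with numba; one gene at n=5/group costs about
5 µs per iteration on one core.

## Inference

A contrast `c` is summarized by the posterior median and 95% equal-tailed
interval of the draw-wise `c' beta`, plus the contour probability

    p_c = min(1, 2/R * #{draws with theta^(j) * median < 0}),

the Bayesian analogue of a two-sided p-value. Draws exactly at zero never
count (strict inequality); a chain perfectly symmetric about zero
therefore yields `p_c = 0` and triggers a degeneracy warning (median
numerically zero with balanced tails). `p_c = 0` is reported as 0, not
floored at 2/R; the resolution limit is documented and 0 participates in
the BH pool as 0. Across genes, each contrast's contour probabilities are
BH-adjusted separately (matching per-contrast error-rate evaluation);
convergence failures are excluded from the pool by default and carry NaN
adjusted values (overridable).

## Convergence screen

Two per-gene screens: (a) post burn-in acceptance rates of the regression
block and of log alpha; (b) a Geweke mean-equality z-test between the
first 20% and last 50% of each retained parameter chain (every beta
element, log alpha, and log sigma2_b — the log scale symmetrizes the
variance chain). Geweke p-values are BH-adjusted across genes per
parameter; a gene fails when any acceptance rate is below 0.10 or any
adjusted Geweke p is below 0.05.

The Geweke segment variances are long-run variances estimated with
Geyer's initial monotone sequence of autocovariances (FFT-based), not the
independent-sample variance. This matters: MCMC draws are autocorrelated,
and a naive two-sample t-test variance under-estimates the variance of a
segment mean by the integrated autocorrelation time, flagging the
majority of perfectly stationary chains. With the long-run variance the
test is calibrated (p-values uniform on iid chains by construction, and
on stationary MCMC chains near-uniform), and the composite rule flags
well under 1% of genes on data simulated from the model at n=10/group.

## Synthetic data generator

The benchmark design is a paired two-group study: `2n` subjects split
evenly into treatment and control, each with a baseline and a follow-up
sample. Fixed effects follow
`beta0 + beta1*I_trt + beta2*I_fup + beta3*I_trt*I_fup + b_i`, with
`beta1 = beta2 = 0` for all genes and `beta3` zero for 80% of genes and
±ES otherwise (10% up, 10% down), ES drawn per gene from a gamma with
mode ln 2 and SD 0.5 (shape ≈ 3.648, scale ≈ 0.2618). Three contrasts
carry truth labels: between-subject (beta1+beta3), within-subject
(beta2+beta3) and interaction (beta3).

Gene-level parameters come from parametric stand-ins chosen to resemble
deep human bulk RNA-seq with repeated measures, all replaceable in
`ParameterSource`:

* `ln(mean CPM) ~ N(ln 16, 1.5^2)` truncated to `[ln 1, ln 4000]`,
  mapped to an intercept through a nominal library size of 25 million;
* `ln alpha = -1.8 - 0.3 (ln CPM - ln 16) + N(0, 0.6^2)` — a decreasing
  mean–dispersion trend with scatter, which is exactly the structure the
  empirical prior exploits;
* `sigma2_gb ~ Gamma(shape 2, scale 0.25)` (mean 0.5, i.e. subject
  effects with SD ≈ 0.7 on the log scale).

Library sizes are equal in expectation (no per-sample scaling) by
default. What the generator does **not** emulate: gene–gene correlation,
outlier samples, batch effects, zero inflation beyond the NB, and
empirical (rather than parametric) parameter distributions. Passing
benchmarks on this generator therefore demonstrates correctness of the
model/sampler/inference chain under its own assumptions, not robustness
to real-data pathologies.

Evaluation follows the standard testing characteristics: type-1 error =
FP/#null at unadjusted thresholds {0.0001, 0.01, 0.05, 0.1}; FDR =
FP/#significant (defined as 0 when nothing is significant) and power =
TP/#DE at BH-adjusted thresholds {0.01, 0.05, 0.1}; per-dataset values
are averaged unweighted across datasets. Significance is `p <= t`. Genes
with missing p-values (excluded convergence failures) leave all
denominators and are counted separately. The low-expression filter keeps
genes with CPM > 1 (strict) in at least `m` samples, `m` the size of the
smallest experimental unit (computed on the raw, unfiltered matrix); CPM
uses raw column sums. In the paired benchmark `m = n` per group.

## Problem sizes used by the shipped checks

The statistical test suite uses 200 genes at n=10/group with default
chains (parameter recovery, coverage, convergence), 2,000 all-null and
2,000 mixed genes at n=5/group with 10,000-iteration chains (calibration
and FDR). `scripts/acceptance.py` recomputes the headline quantities at
4x2,000 genes (FDR, n=5), 2,000 null genes (type-1 error, n=5) and 500
genes at n=10 with default chains (convergence-failure percentage).
These sizes put 3 binomial Monte Carlo standard errors at roughly ±0.015
on a 0.05 rate, which is the slack the checks allow.

## Known limitations

* Single random intercept only; no random slopes or nested clustering.
* The contour probability's resolution is 2/R; genes with `p_c = 0` are
  indistinguishable below that resolution, and ties at 0 are ranked
  arbitrarily by BH within the same adjusted value.
* The Geweke screen tests mean stationarity only; a chain stuck in one
  mode of a multimodal posterior passes.
* The LOESS trend assumes dispersions vary smoothly with expression;
  gene sets with systematically atypical dispersion (e.g. immune loci)
  are shrunk toward the global trend.
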