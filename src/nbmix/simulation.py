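"""Paired two-group simulation with known truth, and the testing-
characteristics evaluator.

The generator emulates a paired design: subjects split evenly into
treatment and control groups, each contributing a baseline and a follow-up
sample. Per gene g,

    log mu = beta_g0 + beta_g1*I_trt + beta_g2*I_fup
             + beta_g3*I_trt*I_fup + b_i,    b_i ~ N(0, sigma2_gb)
    Y ~ NB(mu, alpha_g)

with beta_g1 = beta_g2 = 0 for all genes and beta_g3 zero for a fraction
of genes (default 80%) and +/-ES otherwise, ES drawn per gene from a gamma
distribution with mode ln 2 and SD 0.5. Gene-level parameters (beta_g0,
alpha_g, sigma2_gb) come from a configurable parametric source whose
defaults reproduce the qualitative features of deeply sequenced human
bulk RNA-seq with repeated measures: a wide mean-expression distribution
and a decreasing mean-dispersion trend (see docs/methods.md).

Three contrasts carry truth labels: "between" (beta1+beta3, groups at
follow-up), "within" (beta2+beta3, change over time in the treatment
group) and "interaction" (beta3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .inference import Contrast
from .io import CountMatrix, RunConfig, SampleMetadata
from .preprocess import filter_low_expression
from .workflow import fit_workflow

UNADJ_THRESHOLDS = (0.0001, 0.01, 0.05, 0.1)
ADJ_THRESHOLDS = (0.01, 0.05, 0.1)

#: contrast name -> coefficient vector on (intercept, trt, fup, trt:fup)
STANDARD_CONTRASTS = {
    "between": np.array([0.0, 1.0, 0.0, 1.0]),
    "within": np.array([0.0, 0.0, 1.0, 1.0]),
    "interaction": np.array([0.0, 0.0, 0.0, 1.0]),
}


def standard_contrasts() -> list[Contrast]:
    return [Contrast(name, c) for name, c in STANDARD_CONTRASTS.items()]


def es_gamma_params(mode: float, sd: float) -> tuple[float, float]:
    """Shape and scale of the gamma distribution with the given mode and SD.

    Solves (shape-1)*scale = mode and sqrt(shape)*scale = sd; with
    s = sqrt(shape) the defining equations reduce to
    sd*s^2 - mode*s - sd = 0, whose positive root gives the solution.
    """
    if mode <= 0 or sd <= 0:
        raise ValueError("mode and sd must be positive")
    s = (mode + np.sqrt(mode**2 + 4 * sd**2)) / (2 * sd)
    shape = s**2
    scale = sd / s
    return float(shape), float(scale)


@dataclass
class ParameterSource:
    """Distributions for per-gene (beta_g0, alpha_g, sigma2_gb).

    Mean expression: ln(mean CPM) ~ N(ln 16, 1.5^2) truncated to
    [ln 1, ln 4000], mapped to an intercept via a nominal library size of
    25 million reads. Dispersion: ln(alpha) decreases with expression,
    ln(alpha) = -1.8 - 0.3*(ln CPM - ln 16) + N(0, 0.6^2). Random-intercept
    variance: gamma(shape 2, scale 0.25) (mean 0.5).
    """

    log_cpm_mean: float = np.log(16.0)
    log_cpm_sd: float = 1.5
    log_cpm_range: tuple[float, float] = (np.log(1.0), np.log(4000.0))
    library_size: float = 25e6
    disp_intercept: float = -1.8
    disp_slope: float = -0.3
    disp_sd: float = 0.6
    sigma2_shape: float = 2.0
    sigma2_scale: float = 0.25

    def draw(self, G: int, rng: np.random.Generator):
        lo, hi = self.log_cpm_range
        log_cpm = np.empty(G)
        need = np.ones(G, dtype=bool)
        while need.any():  # truncation by rejection; acceptance is ~0.9
            draw = rng.normal(self.log_cpm_mean, self.log_cpm_sd, need.sum())
            log_cpm[need] = draw
            need &= (log_cpm < lo) | (log_cpm > hi)
        beta0 = log_cpm + np.log(self.library_size / 1e6)
        log_alpha = (self.disp_intercept
                     + self.disp_slope * (log_cpm - self.log_cpm_mean)
                     + rng.normal(0.0, self.disp_sd, G))
        sigma2 = rng.gamma(self.sigma2_shape, self.sigma2_scale, G)
        return beta0, np.exp(log_alpha), sigma2


@dataclass
class SimulationConfig:
    """Study conditions for the paired two-group benchmark."""

    n_per_group: int = 5
    G: int = 15_000
    prop_null: float = 0.80
    prop_up: float = 0.10
    prop_down: float = 0.10
    es_mode: float = float(np.log(2.0))
    es_sd: float = 0.5
    n_datasets: int = 10
    params: ParameterSource = field(default_factory=ParameterSource)
    all_null: bool = False

    def __post_init__(self) -> None:
        total = self.prop_null + self.prop_up + self.prop_down
        if abs(total - 1.0) > 1e-9:
            raise ValueError("null/up/down proportions must sum to 1")


@dataclass
class SimTruth:
    table: pd.DataFrame  # gene_id, beta0..beta3, alpha, sigma2, label per contrast


def read_truth(path) -> pd.DataFrame:
    """Read a truth table written by ``simulate``.

    The literal label string "null" is data here, not a missing value, so
    pandas' default NA parsing must be disabled.
    """
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def _labels(value: np.ndarray) -> np.ndarray:
    return np.where(value > 0, "up", np.where(value < 0, "down", "null"))


def simulate_dataset(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[CountMatrix, SampleMetadata, SimTruth]:
    """Simulate one paired two-group dataset with known truth."""
    n = config.n_per_group
    I = 2 * n
    S = 2 * I
    G = config.G

    subjects = [f"subj{i + 1:03d}" for i in range(I)]
    group = np.array(["control"] * n + ["treatment"] * n)
    sample_ids, subj_of_sample, grp_col, time_col = [], [], [], []
    for i in range(I):
        for tp in ("baseline", "followup"):
            sample_ids.append(f"{subjects[i]}_{tp}")
            subj_of_sample.append(subjects[i])
            grp_col.append(group[i])
            time_col.append(tp)
    is_trt = np.array([g == "treatment" for g in grp_col], dtype=float)
    is_fup = np.array([t == "followup" for t in time_col], dtype=float)

    beta0, alpha, sigma2 = config.params.draw(G, rng)
    beta3 = np.zeros(G)
    if not config.all_null:
        shape, scale = es_gamma_params(config.es_mode, config.es_sd)
        u = rng.random(G)
        up = u < config.prop_up
        down = (u >= config.prop_up) & (u < config.prop_up + config.prop_down)
        es = rng.gamma(shape, scale, G)
        beta3[up] = es[up]
        beta3[down] = -es[down]

    b = rng.normal(0.0, np.sqrt(sigma2)[:, None], (G, I))
    subj_idx = np.array([subjects.index(s) for s in subj_of_sample])
    log_mu = (beta0[:, None]
              + beta3[:, None] * (is_trt * is_fup)[None, :]
              + b[:, subj_idx])
    mu = np.exp(log_mu)
    r = 1.0 / alpha
    counts = rng.negative_binomial(r[:, None], r[:, None] / (r[:, None] + mu),
                                   (G, S))

    gene_ids = [f"gene{g + 1:05d}" for g in range(G)]
    cm = CountMatrix(gene_ids, sample_ids, counts)
    md = SampleMetadata(
        sample_ids=sample_ids,
        subject_id=subj_of_sample,
        covariates=pd.DataFrame({"group": grp_col, "time": time_col}),
    )
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "beta0": beta0,
        "beta1": 0.0,
        "beta2": 0.0,
        "beta3": beta3,
        "alpha": alpha,
        "sigma2": sigma2,
        "label_between": _labels(beta3),      # beta1 + beta3 = beta3
        "label_within": _labels(beta3),       # beta2 + beta3 = beta3
        "label_interaction": _labels(beta3),
    })
    return cm, md, SimTruth(truth)


def evaluate_testing_characteristics(
    results: pd.DataFrame,
    truth: SimTruth,
    unadj_thresholds=UNADJ_THRESHOLDS,
    adj_thresholds=ADJ_THRESHOLDS,
) -> pd.DataFrame:
    """Type-1 error, FDR and power per contrast.

    ``results`` is the tidy per-gene-x-contrast table with columns
    gene_id, contrast, contour_prob, adj_contour_prob. Genes with missing
    p-values (convergence failures excluded from BH) leave all
    denominators; their count is reported in the ``n_missing`` column.

    type-1 error = FP / #null genes at unadjusted thresholds;
    FDR = FP / #significant (0 when nothing is significant) and
    power = TP / #truly-differentially-expressed at adjusted thresholds.
    """
    truth_tab = truth.table.set_index("gene_id")
    rows = []
    for contrast, sub in results.groupby("contrast"):
        label_col = f"label_{contrast}"
        if label_col not in truth_tab.columns:
            raise ValueError(f"truth carries no labels for contrast {contrast!r}")
        sub = sub.set_index("gene_id")
        labels = truth_tab.loc[sub.index, label_col]
        is_null = (labels == "null").to_numpy()
        raw = sub["contour_prob"].to_numpy(dtype=float)
        adj = sub["adj_contour_prob"].to_numpy(dtype=float)
        ok_raw = np.isfinite(raw)
        ok_adj = np.isfinite(adj)
        for t in unadj_thresholds:
            sig = ok_raw & (raw <= t)
            n_null = int((is_null & ok_raw).sum())
            fp = int((sig & is_null).sum())
            rows.append({
                "contrast": contrast, "metric": "type1_error",
                "threshold": t, "value": fp / n_null if n_null else 0.0,
                "n_missing": int((~ok_raw).sum()),
            })
        for t in adj_thresholds:
            sig = ok_adj & (adj <= t)
            fp = int((sig & is_null).sum())
            tp = int((sig & ~is_null).sum())
            n_sig = int(sig.sum())
            n_de = int((~is_null & ok_adj).sum())
            rows.append({
                "contrast": contrast, "metric": "fdr",
                "threshold": t, "value": fp / n_sig if n_sig else 0.0,
                "n_missing": int((~ok_adj).sum()),
            })
            rows.append({
                "contrast": contrast, "metric": "power",
                "threshold": t, "value": tp / n_de if n_de else 0.0,
                "n_missing": int((~ok_adj).sum()),
            })
    return pd.DataFrame(rows)


def run_simulation_study(
    config: SimulationConfig,
    run_config: RunConfig | None = None,
    filter_min_samples: int | None = None,
    master_seed: int = 0,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Simulate, fit and evaluate ``config.n_datasets`` datasets.

    Returns the per-dataset metric tables and their unweighted average.
    Dataset d uses the seeded stream (master_seed, d) for generation and
    master_seed + d for the fits, so the whole study is reproducible.
    """
    run_config = run_config or RunConfig()
    if filter_min_samples is None:
        filter_min_samples = config.n_per_group
    per_dataset = []
    for d in range(config.n_datasets):
        rng = np.random.default_rng(np.random.SeedSequence((master_seed, d)))
        cm, md, truth = simulate_dataset(config, rng)
        fit_cfg = replace(run_config, master_seed=(master_seed + d) & 0x7FFFFFFF)
        fit = fit_workflow(
            cm, md, fixed="group * time", contrasts=standard_contrasts(),
            random="intercept", config=fit_cfg,
            filter_min_samples=filter_min_samples,
        )
        res = fit.results_frame
        metrics = evaluate_testing_characteristics(res, truth)
        metrics["dataset"] = d
        per_dataset.append(metrics)
    stacked = pd.concat(per_dataset, ignore_index=True)
    averaged = (stacked.groupby(["contrast", "metric", "threshold"],
                                as_index=False)
                .agg(value=("value", "mean"), n_missing=("n_missing", "sum")))
    return per_dataset, averaged
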