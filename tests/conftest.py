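import numpy as np
import pandas as pd
import pytest

from nbmix import (CountMatrix, ModelDesign, RunConfig, SampleMetadata,
                   SimulationConfig, fit_workflow, simulate_dataset,
                   standard_contrasts)


@pytest.fixture
def toy_counts() -> CountMatrix:
    return CountMatrix(
        gene_ids=["g1", "g2"],
        sample_ids=["s1", "s2", "s3"],
        counts=np.array([[10, 20, 30], [5, 0, 15]]),
    )


@pytest.fixture
def paired_metadata() -> SampleMetadata:
    """Two groups x two timepoints, two subjects per group."""
    rows = []
    for i, grp in enumerate(["control", "control", "treatment", "treatment"]):
        for tp in ["baseline", "followup"]:
            rows.append((f"subj{i}_{tp}", f"subj{i}", grp, tp))
    df = pd.DataFrame(rows, columns=["sample_id", "subject_id", "group", "time"])
    return SampleMetadata(
        sample_ids=list(df.sample_id),
        subject_id=list(df.subject_id),
        covariates=df[["group", "time"]],
    )


def make_design(X, subject_index=None, n_subjects=0, offsets=None,
                names=None) -> ModelDesign:
    X = np.asarray(X, dtype=float)
    return ModelDesign(
        X=X,
        column_names=names or [f"b{j}" for j in range(X.shape[1])],
        subject_index=subject_index,
        n_subjects=n_subjects,
        offsets=np.zeros(X.shape[0]) if offsets is None else offsets,
    )


@pytest.fixture(scope="session")
def sim_small():
    """Small paired two-group dataset with known truth (n=5/group, 40 genes)."""
    rng = np.random.default_rng(np.random.SeedSequence((2024, 0)))
    config = SimulationConfig(n_per_group=5, G=40, n_datasets=1)
    return simulate_dataset(config, rng)


@pytest.fixture(scope="session")
def fitted_small(sim_small):
    counts, metadata, truth = sim_small
    fit = fit_workflow(
        counts, metadata, fixed="group * time", contrasts=standard_contrasts(),
        config=RunConfig(n_iter=1500, master_seed=5), filter_min_samples=5,
    )
    return fit, truth


@pytest.fixture(scope="session")
def null_fit():
    """200 all-null genes at n=5/group, fit with a short chain; shared by the
    diagnostics and inference calibration checks."""
    rng = np.random.default_rng(np.random.SeedSequence((7, 0)))
    config = SimulationConfig(n_per_group=5, G=200, n_datasets=1, all_null=True)
    counts, metadata, truth = simulate_dataset(config, rng)
    fit = fit_workflow(
        counts, metadata, fixed="group * time", contrasts=standard_contrasts(),
        config=RunConfig(n_iter=4000, master_seed=7), filter_min_samples=5,
    )
    return fit, truth
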