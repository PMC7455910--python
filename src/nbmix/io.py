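"""Data containers and file I/O.

Counts are raw (un-normalized) nonnegative integers, genes in rows and
samples in columns. Metadata carries one row per sample with a subject
identifier (the clustering variable) plus arbitrary covariates. Designs
are built from a formula over the metadata columns, with an optional
random intercept per subject.
"""

from __future__ import annotations

import binascii
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene x sample matrix of raw sequencing counts.

    Attributes
    ----------
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    counts : ndarray of shape (G, S)
        Nonnegative integer counts.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D array")
        G, S = self.counts.shape
        if len(self.gene_ids) != G or len(self.sample_ids) != S:
            raise ValidationError(
                f"id lengths ({len(self.gene_ids)}, {len(self.sample_ids)}) "
                f"do not match counts shape {self.counts.shape}"
            )
        if len(set(self.gene_ids)) != G:
            raise ValidationError("duplicate gene_ids")
        if len(set(self.sample_ids)) != S:
            raise ValidationError("duplicate sample_ids")
        arr = self.counts
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(~np.isfinite(arr.astype(float))):
            raise ValidationError("counts contain missing/non-finite entries")
        if np.any(arr < 0):
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count for gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if np.any(arr != np.floor(arr)):
            g, s = np.argwhere(arr != np.floor(arr))[0]
            raise ValidationError(
                f"non-integer count for gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}; raw integer counts required"
            )
        self.counts = arr.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask, dtype=bool)
        ids = [g for g, m in zip(self.gene_ids, mask) if m]
        return CountMatrix(ids, list(self.sample_ids), self.counts[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations aligned to a CountMatrix's column order."""

    sample_ids: list[str]
    subject_id: list[str]
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids in metadata")
        if len(self.subject_id) != len(self.sample_ids):
            raise ValidationError("subject_id length mismatch")
        self.covariates = self.covariates.reset_index(drop=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.subject_id == other.subject_id
            and self.covariates.equals(other.covariates)
        )


@dataclass
class ModelDesign:
    """Fixed/random design for the NB mixed model.

    X is the S x p fixed-effect matrix (intercept first); Z, when present,
    is the implicit subject indicator encoded by ``subject_index`` (one
    random intercept per subject, q = 1). ``offsets`` enter the linear
    predictor additively (natural-log size factors).
    """

    X: np.ndarray
    column_names: list[str]
    subject_index: np.ndarray | None  # per-sample subject integer, or None (q=0)
    n_subjects: int
    offsets: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if not np.all(np.isfinite(self.offsets)):
            raise ValidationError("offsets must be finite")
        if self.X.shape[0] != self.offsets.shape[0]:
            raise ValidationError("offsets length must match rows of X")
        if self.X.shape[0] > 0 and np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValidationError(
                "design matrix is rank deficient; collinear columns: "
                + ", ".join(self.column_names)
            )
        if self.subject_index is not None:
            self.subject_index = np.asarray(self.subject_index, dtype=np.int64)
            if self.subject_index.shape[0] != self.X.shape[0]:
                raise ValidationError("subject_index length must match X")
            counts = np.bincount(self.subject_index, minlength=self.n_subjects)
            if np.any(counts == 0):
                raise ValidationError("every subject must have at least one sample")

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return 0 if self.subject_index is None else 1

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


@dataclass
class RunConfig:
    """MCMC run settings.

    Defaults follow standard practice for this sampler: 30,000 iterations
    with the first 10% discarded as burn-in.
    """

    n_iter: int = 30_000
    burn_in_fraction: float = 0.10
    master_seed: int = 0
    n_workers: int = 1
    prior_k: float = 2.0
    loess_span: float = 0.75
    step_sd_init: float = 0.5
    adapt_target: float = 0.40
    save_random_effects: bool = False

    def __post_init__(self) -> None:
        if self.n_iter <= 0:
            raise ValidationError("n_iter must be positive")
        if not 0.0 < self.burn_in_fraction < 1.0:
            raise ValidationError("burn_in_fraction must be in (0, 1)")
        if self.n_retained < 1_000:
            warnings.warn(
                f"only {self.n_retained} retained draws; inference resolution "
                "will be poor (>= 1,000 recommended)",
                UserWarning,
                stacklevel=2,
            )

    @property
    def n_burn(self) -> int:
        return int(round(self.n_iter * self.burn_in_fraction))

    @property
    def n_retained(self) -> int:
        return self.n_iter - self.n_burn


def gene_seed(master_seed: int, gene_id: str) -> np.random.SeedSequence:
    """Per-gene RNG stream keyed by the stable gene identifier.

    Hashing the id (not the row index) means subsetting or reordering genes
    never changes any gene's chain.
    """
    h = binascii.crc32(gene_id.encode("utf-8")) & 0x7FFFFFFF
    return np.random.SeedSequence((int(master_seed) & 0x7FFFFFFF, h))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a count matrix from TSV, CSV or MatrixMarket.

    TSV/CSV: first column holds gene ids, header row holds sample ids.
    MTX: ``path`` is the .mtx file; gene and sample ids are read from
    sibling files ``<stem>.genes.txt`` and ``<stem>.samples.txt`` (one id
    per line, rows/columns of the matrix respectively).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv"
        )
    if format == "mtx":
        import scipy.io as sio

        genes_file = path.with_suffix("").with_suffix(".genes.txt")
        samples_file = path.with_suffix("").with_suffix(".samples.txt")
        for companion in (genes_file, samples_file):
            if not companion.exists():
                raise FileNotFoundError(
                    f"MatrixMarket companion id file missing: {companion}"
                )
        mat = sio.mmread(str(path))
        counts = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        gene_ids = genes_file.read_text().split()
        sample_ids = samples_file.read_text().split()
        return CountMatrix(gene_ids, sample_ids, counts)

    sep = "\t" if format == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"failed to parse {path}: {exc}") from exc
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ValidationError(f"missing entry in row {row!r} of {path}")
    return CountMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], df.to_numpy()
    )


def write_counts(counts: CountMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv"
        )
    if format == "mtx":
        import scipy.io as sio
        import scipy.sparse as sp

        sio.mmwrite(str(path), sp.csr_matrix(counts.counts))
        path.with_suffix("").with_suffix(".genes.txt").write_text(
            "\n".join(counts.gene_ids) + "\n"
        )
        path.with_suffix("").with_suffix(".samples.txt").write_text(
            "\n".join(counts.sample_ids) + "\n"
        )
        return
    sep = "\t" if format == "tsv" else ","
    counts.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def read_metadata(
    path: str | Path,
    counts: CountMatrix,
    sample_col: str = "sample_id",
    subject_col: str = "subject_id",
) -> SampleMetadata:
    """Read a TSV metadata table and align it to the count-matrix columns.

    Rows for samples absent from the counts are dropped; a sample present
    in the counts but missing from the table is an error.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype={sample_col: str, subject_col: str})
    return align_metadata(df, counts, sample_col=sample_col, subject_col=subject_col)


def align_metadata(
    df: pd.DataFrame,
    counts: CountMatrix,
    sample_col: str = "sample_id",
    subject_col: str = "subject_id",
) -> SampleMetadata:
    for col in (sample_col, subject_col):
        if col not in df.columns:
            raise ValidationError(f"metadata is missing required column {col!r}")
    df = df.copy()
    df[sample_col] = df[sample_col].astype(str)
    if df[sample_col].duplicated().any():
        dup = df[sample_col][df[sample_col].duplicated()].iloc[0]
        raise ValidationError(f"sample {dup!r} appears more than once in metadata")
    missing = [s for s in counts.sample_ids if s not in set(df[sample_col])]
    if missing:
        raise ValidationError(
            "samples present in counts but missing from metadata: "
            + ", ".join(missing)
        )
    df = df.set_index(sample_col).loc[counts.sample_ids].reset_index()
    covars = df.drop(columns=[sample_col, subject_col])
    return SampleMetadata(
        sample_ids=list(df[sample_col]),
        subject_id=[str(x) for x in df[subject_col]],
        covariates=covars,
    )


def build_design(
    metadata: SampleMetadata,
    fixed_spec: str,
    random_spec: str = "intercept",
    offsets: np.ndarray | Sequence[float] | None = None,
) -> ModelDesign:
    """Build the fixed/random design from a formula over metadata columns.

    ``fixed_spec`` is a Wilkinson formula for the fixed effects, e.g.
    ``"group * time"`` (an intercept is always included first). Categorical
    covariates are reference-coded with levels in lexicographic order, the
    first level as reference. ``random_spec`` is ``"intercept"`` for one
    random intercept per subject or ``"none"`` for a plain NB GLM.
    """
    import patsy

    if random_spec not in ("intercept", "none"):
        raise ValidationError("random_spec must be 'intercept' or 'none'")
    frame = metadata.covariates.copy()
    # lexicographic level order => reference level is the lexicographically first
    for col in frame.columns:
        if frame[col].dtype == object or isinstance(
            frame[col].dtype, pd.CategoricalDtype
        ):
            frame[col] = pd.Categorical(
                frame[col].astype(str), categories=sorted(set(frame[col].astype(str)))
            )
    try:
        dm = patsy.dmatrix("1 + " + fixed_spec, frame, return_type="dataframe")
    except patsy.PatsyError as exc:
        raise ValidationError(f"bad fixed-effect specification: {exc}") from exc
    X = dm.to_numpy()
    names = list(dm.columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            "design matrix is rank deficient; check columns: " + ", ".join(names)
        )

    if random_spec == "intercept":
        subjects = sorted(set(metadata.subject_id))
        lut = {s: i for i, s in enumerate(subjects)}
        subject_index = np.array([lut[s] for s in metadata.subject_id])
        n_subjects = len(subjects)
    else:
        subject_index = None
        n_subjects = 0

    if offsets is None:
        offsets = np.zeros(X.shape[0])
    return ModelDesign(
        X=X,
        column_names=names,
        subject_index=subject_index,
        n_subjects=n_subjects,
        offsets=np.asarray(offsets, dtype=float),
    )


RESULT_COLUMNS = [
    "gene_id",
    "contrast",
    "estimate",
    "ci_lower",
    "ci_upper",
    "contour_prob",
    "adj_contour_prob",
    "converged",
]


def results_to_frame(results: list) -> pd.DataFrame:
    """Flatten GeneResult objects into a tidy one-row-per-gene-x-contrast table."""
    rows = []
    for res in results:
        for name, summ in res.contrasts.items():
            rows.append(
                {
                    "gene_id": res.gene_id,
                    "contrast": name,
                    "estimate": summ.median,
                    "ci_lower": summ.ci_lower,
                    "ci_upper": summ.ci_upper,
                    "contour_prob": summ.contour_prob,
                    "adj_contour_prob": summ.adj_contour_prob,
                    "converged": bool(res.converged),
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: list, path: str | Path) -> None:
    """Write per-gene, per-contrast posterior summaries as TSV.

    Columns: gene id, contrast name, posterior median, 95% equal-tailed
    credible interval, contour probability, BH-adjusted value (empty for
    genes excluded from the adjustment pool), convergence flag.
    """
    df = results_to_frame(results)
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.6g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")
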