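"""Library-size normalization and low-expression filtering.

Sequencing depth differs between samples, so raw counts are not directly
comparable. Size factors are estimated with the median-of-ratios method:
each sample's factor is the median, over genes expressed in every sample,
of the ratio of its count to that gene's geometric mean. The natural log
of the size factor enters the model as a per-sample offset. Genes with
consistently negligible expression (counts-per-million <= 1 in most
samples) are removed before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CountMatrix, SampleMetadata, ValidationError


@dataclass
class NormalizationResult:
    size_factors: np.ndarray  # S positive reals
    offsets: np.ndarray       # ln(size_factors)
    library_sizes: np.ndarray  # column sums


def median_of_ratios_size_factors(counts: CountMatrix) -> NormalizationResult:
    """Median-of-ratios size factors and their natural-log offsets.

    Only genes with strictly positive counts in every sample form the
    reference set (the geometric mean of a row containing a zero is
    degenerate).
    """
    arr = counts.counts.astype(float)
    all_positive = np.all(arr > 0, axis=1)
    if not np.any(all_positive):
        raise ValidationError(
            "no gene has positive counts in every sample; filter low-expression "
            "genes first or supply offsets explicitly"
        )
    ref = arr[all_positive]
    geomean = np.exp(np.mean(np.log(ref), axis=1))
    size_factors = np.median(ref / geomean[:, None], axis=0)
    return NormalizationResult(
        size_factors=size_factors,
        offsets=np.log(size_factors),
        library_sizes=counts.counts.sum(axis=0),
    )


def cpm(counts: CountMatrix) -> np.ndarray:
    """Counts per million, using raw column sums as library sizes."""
    lib = counts.counts.sum(axis=0).astype(float)
    if np.any(lib <= 0):
        s = int(np.argmax(lib <= 0))
        raise ValidationError(
            f"sample {counts.sample_ids[s]!r} has zero total counts"
        )
    return counts.counts / lib[None, :] * 1e6


def filter_low_expression(
    counts: CountMatrix, m: int
) -> tuple[CountMatrix, np.ndarray]:
    """Keep genes with CPM > 1 (strict) in at least ``m`` samples.

    ``m`` is normally the number of samples in the smallest experimental
    unit of interest. CPM is computed on the unfiltered matrix. Returns the
    filtered matrix and the boolean kept-gene mask.
    """
    if m > counts.n_samples:
        raise ValidationError(
            f"m={m} exceeds the number of samples ({counts.n_samples})"
        )
    if m <= 0:
        mask = np.ones(counts.n_genes, dtype=bool)
    else:
        mask = (cpm(counts) > 1.0).sum(axis=1) >= m
    return counts.subset_genes(mask), mask


def smallest_unit_size(
    metadata: SampleMetadata, unit_columns: list[str]
) -> int:
    """Sample count of the smallest cell in the cross-classification of
    the given covariates (empty cells ignored)."""
    if not unit_columns:
        return len(metadata.sample_ids)
    for col in unit_columns:
        if col not in metadata.covariates.columns:
            raise ValidationError(f"unknown metadata column {col!r}")
    cells = metadata.covariates.groupby(
        [metadata.covariates[c].astype(str) for c in unit_columns], observed=True
    ).size()
    return int(cells.min())
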