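"""Cohort preprocessing: normalization, abundance filter, log transform,
quality gating, and tissue/gender/age-bin partitioning.

The fixed pipeline order is normalize -> abundance filter -> log ->
quality gate -> partition; the first two operate on the linear RPKM
scale.  :func:`preprocess_cohort` runs the whole chain.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from geroscreen.matrix import AGE_BINS, ExpressionMatrix, validate_metadata

log = logging.getLogger(__name__)

LIBRARY_SIZE = 1_000_000.0


def normalize_library_size(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every sample to a total of one million reads.

    Gene proportions within a sample are unchanged; only the column
    totals are rescaled.
    """
    matrix.require_stage("linear")
    totals = matrix.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with nonpositive total counts: {list(zero.index[:5])}")
    scaled = matrix.values * (LIBRARY_SIZE / totals)
    return ExpressionMatrix(scaled, stage="linear")


def filter_low_abundance_global(
    matrix: ExpressionMatrix,
    threshold: float = 0.1,
    sample_fraction: float = 0.8,
) -> ExpressionMatrix:
    """Drop genes whose value is below ``threshold`` in at least
    ``sample_fraction`` of samples.

    The rule is strict ``<`` on the value and ``>=`` on the fraction of
    samples, applied over all samples of the loaded matrix (before any
    tissue partitioning).  Gene order is otherwise preserved.
    """
    matrix.require_stage("linear")
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise ValueError("cannot abundance-filter an empty matrix")
    below = (matrix.values.to_numpy() < threshold).mean(axis=1)
    keep = below < sample_fraction
    dropped = int((~keep).sum())
    if dropped:
        log.info("abundance filter removed %d/%d genes", dropped, matrix.n_genes)
    return ExpressionMatrix(matrix.values.loc[keep], stage="linear")


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Apply v -> log2(v + 1) and flip the stage flag to post-log."""
    matrix.require_stage("linear")
    vals = matrix.values.to_numpy()
    if vals.size and vals.min() < 0:
        raise ValueError("negative values cannot be log-transformed")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(vals + 1.0), index=matrix.genes, columns=matrix.samples),
        stage="log2",
    )


def filter_samples_by_quality(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    min_rin: float = 6.0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Retain samples with RIN >= ``min_rin`` (inclusive) that are
    flagged usable; subset matrix columns and metadata rows accordingly."""
    validate_metadata(metadata, matrix.samples)
    meta = metadata.loc[matrix.samples]
    keep = (meta["rin"] >= min_rin) & meta["usable"].astype(bool)
    kept = matrix.samples[keep.to_numpy()]
    log.info("quality gate retained %d/%d samples", len(kept), matrix.n_samples)
    return matrix.subset_samples(kept), meta.loc[kept]


def partition(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    exclude_cell_lines: bool = True,
) -> dict[tuple[str, str, str], ExpressionMatrix]:
    """Split samples into (tissue, gender, age_bin) groups.

    Cell-line-derived tissues (labels containing "Cells" or flagged via
    an ``is_cell_line`` metadata column) are excluded when
    ``exclude_cell_lines`` is set.  The partition is exhaustive and
    disjoint over the retained samples.
    """
    validate_metadata(metadata, matrix.samples)
    meta = metadata.loc[matrix.samples]
    if exclude_cell_lines and len(meta):
        cell_line = meta["tissue"].astype(str).str.contains("Cells", case=False)
        if "is_cell_line" in meta.columns:
            cell_line |= meta["is_cell_line"].astype(bool)
        meta = meta.loc[~cell_line]
    groups: dict[tuple[str, str, str], ExpressionMatrix] = {}
    for (tissue, gender, age_bin), sub in meta.groupby(
        ["tissue", "gender", "age_bin"], sort=True, observed=True
    ):
        if age_bin not in AGE_BINS:
            raise ValueError(f"unknown age_bin label {age_bin!r}")
        groups[(tissue, gender, age_bin)] = matrix.subset_samples(sub.index)
    return groups


def preprocess_cohort(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    abundance_threshold: float = 0.1,
    abundance_sample_fraction: float = 0.8,
    min_rin: float = 6.0,
    quality_gate_first: bool = False,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict[tuple[str, str, str], ExpressionMatrix]]:
    """Run the full preprocessing chain.

    The default order is normalize -> abundance filter -> log ->
    quality gate.  Because normalization is per-sample and the
    abundance filter is fraction-based, gating earlier changes the
    result; ``quality_gate_first=True`` applies the gate before
    normalization for comparison.  Returns the processed (post-log,
    quality-gated) matrix, the retained metadata, and the
    (tissue, gender, age_bin) partition.
    """
    m, meta = matrix, metadata
    if quality_gate_first:
        m, meta = filter_samples_by_quality(m, meta, min_rin=min_rin)
    m = normalize_library_size(m)
    m = filter_low_abundance_global(m, abundance_threshold, abundance_sample_fraction)
    m = log_transform(m)
    if not quality_gate_first:
        m, meta = filter_samples_by_quality(m, meta, min_rin=min_rin)
    else:
        meta = meta.loc[m.samples]
    return m, meta, partition(m, meta)
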