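"""Expression matrix container with an explicit processing-stage flag.

Expression data moves through two scales: linear RPKM-like abundances
("linear" stage, as read from a GCT file) and log2(x+1) values ("log2"
stage).  The abundance filter operates on the linear scale while
classification requires the log scale, so the stage is carried
explicitly and checked by every operation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: valid processing stages
STAGES = ("linear", "log2")

# canonical ordered decade age bins; "70-79" is accepted on input but
# never used as an "old" group downstream (too few donors in practice)
AGE_BINS = ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79")
OLD_BIN = "60-69"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus a stage flag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id.
    stage : str
        Either ``"linear"`` (RPKM-like, nonnegative) or ``"log2"``
        (log2(x+1) transformed).
    """

    values: pd.DataFrame
    stage: str = "linear"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.values.size and np.nanmin(self.values.to_numpy()) < 0:
            raise ValueError(f"negative expression values at stage {self.stage!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise ValueError(
                f"operation requires stage {stage!r} but matrix is at {self.stage!r}"
            )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Row subset preserving the matrix's own gene order."""
        keep = self.values.index[self.values.index.isin(pd.Index(genes))]
        return ExpressionMatrix(self.values.loc[keep], stage=self.stage)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        keep = self.values.columns[self.values.columns.isin(pd.Index(samples))]
        return ExpressionMatrix(self.values[keep], stage=self.stage)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), stage=self.stage)


def validate_metadata(metadata: pd.DataFrame, samples: pd.Index) -> None:
    """Check that every sample has exactly one metadata row.

    ``metadata`` is indexed by sample id with columns
    ``tissue, gender, age_bin, rin, usable``.
    """
    required = {"tissue", "gender", "age_bin", "rin", "usable"}
    missing_cols = required - set(metadata.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    if not metadata.index.is_unique:
        raise ValueError("metadata sample ids are not unique")
    missing = samples.difference(metadata.index)
    if len(missing):
        raise ValueError(f"samples missing metadata: {list(missing[:5])}")
    bad_bins = set(metadata["age_bin"]) - set(AGE_BINS)
    if bad_bins:
        raise ValueError(f"unknown age_bin labels: {sorted(bad_bins)}")
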