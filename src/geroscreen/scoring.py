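"""Drug-perturbation scoring against age classifiers.

Each model gets a prototype "middle-age" transcriptome (average of the
median young and median old profiles of its training contrast).
Linear-scale drug fold changes are applied to that prototype in RPKM
space, and the model returns the probability that the resulting
drug-induced transcriptome is "young".  Per drug, the best instance per
model is kept, and probabilities are converted to a geroprotective
index centered at 0 with maximal amplitude 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from geroscreen.classify import AgeClassifierModel, AgeComparisonDataset

log = logging.getLogger(__name__)

#: metadata columns of a perturbation table; the rest are gene columns
PERTURBATION_META_COLS = ("drug", "cell_line", "dose", "duration")


def perturbation_genes(perturbations: pd.DataFrame) -> pd.Index:
    return perturbations.columns[~perturbations.columns.isin(PERTURBATION_META_COLS)]


@dataclass
class MiddleAgeProfile:
    """Per-model prototype transcriptome on the log2 scale."""

    tissue: str
    gender: str
    young_bin: str
    values: pd.Series  # indexed by gene id


def middle_age_profile(
    dataset: AgeComparisonDataset, gene_list: list[str] | None = None
) -> MiddleAgeProfile:
    """(median over young samples + median over old samples) / 2,
    per gene, on the post-log scale."""
    genes = pd.Index(gene_list) if gene_list is not None else dataset.genes
    missing = genes.difference(dataset.genes)
    if len(missing):
        raise ValueError(f"genes missing from dataset: {list(missing[:5])}")
    med_young = dataset.young.loc[genes].median(axis=1)
    med_old = dataset.old.loc[genes].median(axis=1)
    return MiddleAgeProfile(
        tissue=dataset.tissue,
        gender=dataset.gender,
        young_bin=dataset.young_bin,
        values=(med_young + med_old) / 2.0,
    )


def collapse_probes(
    probe_folds: pd.DataFrame, probe_map: pd.Series | dict
) -> pd.DataFrame:
    """Collapse probe-level fold changes (instances x probes) to
    gene level by the per-gene median (midpoint convention for even
    counts).  Probes absent from the map, and genes with no probe, are
    dropped."""
    probe_map = pd.Series(probe_map)
    if probe_map.empty:
        raise ValueError("empty probe->gene map")
    keep = probe_folds.columns.intersection(probe_map.index)
    folds = probe_folds[keep]
    return folds.T.groupby(probe_map.loc[keep]).median().T


def apply_fold_changes(
    profile: MiddleAgeProfile,
    fold_changes: pd.Series | pd.DataFrame,
    drug: str = "?",
) -> pd.Series | pd.DataFrame:
    """Apply linear fold changes to a post-log profile.

    Per gene with log value v and fold f: x = 2^v - 1 (back to linear),
    x' = max(f * x, 0), v' = log2(x' + 1).  Genes missing from the fold
    table default to f = 1 (logged as a warning); nonpositive folds are
    rejected.
    """
    single = isinstance(fold_changes, pd.Series)
    F = fold_changes.to_frame().T if single else fold_changes
    genes = profile.values.index
    missing = genes.difference(F.columns)
    if len(missing):
        log.warning(
            "drug %s: %d profile gene(s) missing fold changes; defaulting to 1.0",
            drug, len(missing),
        )
        F = F.reindex(columns=genes, fill_value=1.0)
    else:
        F = F[genes]
    vals = F.to_numpy(dtype=float)
    if (vals <= 0).any():
        bad_i, bad_j = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"nonpositive fold change for drug {drug!r}, gene {genes[bad_j]!r}"
        )
    x = np.exp2(profile.values.to_numpy()) - 1.0
    x_new = np.maximum(vals * x, 0.0)
    v_new = np.log2(x_new + 1.0)
    out = pd.DataFrame(v_new, index=F.index, columns=genes)
    return out.iloc[0] if single else out


def classify_perturbations(
    models: list[AgeClassifierModel],
    profiles: dict[str, MiddleAgeProfile],
    perturbations: pd.DataFrame,
    max_missing_fraction: float = 0.5,
) -> pd.DataFrame:
    """Probability-young of every (instance, model) pair.

    ``profiles`` maps model name -> its own middle-age profile.  For
    each model, fold changes of all instances are applied to the
    model's profile at once, standardized with the model's stored
    center/scale constants, and scored.  An instance missing more than
    ``max_missing_fraction`` of a model's genes is flagged missing
    (NaN) and ignored downstream.
    """
    gene_cols = perturbation_genes(perturbations)
    out = pd.DataFrame(
        index=perturbations.index, columns=[m.name for m in models], dtype=float
    )
    for model in models:
        profile = profiles[model.name]
        model_genes = pd.Index(model.genes)
        covered = model_genes.isin(gene_cols).mean()
        if 1.0 - covered > max_missing_fraction:
            log.warning(
                "model %s: instances cover only %.0f%% of model genes; flagged missing",
                model.name, 100 * covered,
            )
            out[model.name] = np.nan
            continue
        folds = perturbations[gene_cols.intersection(model_genes)]
        induced = apply_fold_changes(profile, folds)
        out[model.name] = model.predict_proba_young(induced)
    return out


def consolidate_per_drug(
    instance_probs: pd.DataFrame, instance_drugs: pd.Series
) -> pd.DataFrame:
    """drugs x models matrix keeping, per cell, the maximum
    probability-young over the drug's instances (the most
    geroprotective prediction); missing cells are ignored, and a drug
    with all instances missing for a model keeps NaN there."""
    if not instance_probs.index.equals(instance_drugs.index):
        instance_drugs = instance_drugs.loc[instance_probs.index]
    return instance_probs.groupby(instance_drugs).max()


def geroprotective_index(
    drug_probs: pd.DataFrame, mode: str = "rescaled"
) -> pd.DataFrame:
    """Convert probability-young to the geroprotective index.

    ``plain``: index = p - 0.5.  ``rescaled`` (default): p - 0.5 is
    additionally rescaled per model column by a single positive factor
    so the column's maximum absolute index equals 0.5 (a column
    constant at p = 0.5 maps to all zeros).  Order within a column is
    preserved and the sign matches p vs 0.5 in both modes.
    """
    if mode not in ("rescaled", "plain"):
        raise ValueError(f"unknown index mode {mode!r}")
    centered = drug_probs - 0.5
    if mode == "plain":
        return centered
    amp = centered.abs().max(axis=0)
    factor = pd.Series(
        np.where(amp > 0, 0.5 / amp.to_numpy(dtype=float), 1.0), index=amp.index
    )
    return centered * factor
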