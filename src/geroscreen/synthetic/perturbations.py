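"""Synthetic drug-perturbation table with planted ground truth.

Fold changes are emitted directly on the linear scale, one row per
perturbation instance (drug x cell line x dose x duration).  A
rejuvenating drug's fold changes move the signature genes of a
middle-age profile toward the young median profile by
``reversal_strength`` of the half-gap; a pro-aging drug moves them
toward old; neutral drugs (and all non-signature genes) carry only
lognormal noise.  With reversal_strength = 1 and no noise, applying a
rejuvenating drug's folds to the reference middle-age profile lands
exactly on the young median profile — the screen's positive control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from geroscreen.synthetic.cohort import AgingSignature

CELL_LINES = ("MCF7", "PC3", "HL60")
DOSES = ("100 nM", "1 uM", "10 uM")
DURATIONS = ("6 h", "12 h")

REJUVENATING = "rejuvenating"
PROAGING = "proaging"
NEUTRAL = "neutral"


@dataclass
class PerturbationConfig:
    n_drugs: int = 200
    n_rejuvenating: int = 10
    n_proaging: int = 10
    instances_per_drug: int = 3
    reversal_strength: float = 1.0
    fold_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rejuvenating + self.n_proaging > self.n_drugs:
            raise ValueError("n_rejuvenating + n_proaging must not exceed n_drugs")
        if self.reversal_strength < 0:
            raise ValueError("reversal_strength must be >= 0")
        if self.instances_per_drug < 1:
            raise ValueError("instances_per_drug must be >= 1")


def _target_folds(signature: AgingSignature, strength: float, toward: str) -> np.ndarray:
    """Linear folds that move the reference middle-age profile a
    ``strength`` fraction of the way toward the young (or old) median.

    With v_m = (v_young + v_old)/2 the middle log2 value and x = 2^v - 1
    the linear value, the fold is f = x_target / x_middle, so that the
    multiplicative linear action x -> f*x recovers v_target exactly.
    """
    v_y = signature.young_log2.to_numpy()
    v_o = signature.old_log2.to_numpy()
    v_m = (v_y + v_o) / 2.0
    v_end = v_y if toward == "young" else v_o
    v_t = v_m + strength * (v_end - v_m)
    x_m = np.exp2(v_m) - 1.0
    x_t = np.exp2(v_t) - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(x_m > 0, x_t / np.maximum(x_m, 1e-300), 1.0)
    return np.where(f > 0, f, 1.0)


def generate_perturbations(
    config: PerturbationConfig,
    signature: AgingSignature,
    genes,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate (perturbation table, per-drug truth labels).

    ``genes`` is the full screened gene universe; ``signature.genes``
    must be a subset of it.  The table has one row per instance with
    metadata columns drug, cell_line, dose, duration followed by one
    linear fold-change column per gene.  Noise (lognormal, sd
    ``fold_noise_sd`` on the log2 scale) is drawn independently per
    instance for every non-target gene; target-gene folds are
    deterministic per drug.
    """
    genes = pd.Index(genes)
    if len(signature.genes) == 0:
        raise ValueError("cannot plant a reversal on an empty aging signature")
    if not signature.genes.isin(genes).all():
        raise ValueError("signature genes must be a subset of the gene universe")

    rng = np.random.default_rng(config.seed)
    drugs = [f"drug{i:04d}" for i in range(config.n_drugs)]
    roles = np.array([NEUTRAL] * config.n_drugs, dtype=object)
    special = rng.choice(
        config.n_drugs, size=config.n_rejuvenating + config.n_proaging, replace=False
    )
    roles[special[: config.n_rejuvenating]] = REJUVENATING
    roles[special[config.n_rejuvenating:]] = PROAGING
    labels = pd.Series(roles, index=pd.Index(drugs, name="drug"), name="label")

    sig_pos = genes.get_indexer(signature.genes)
    rejuv_f = _target_folds(signature, config.reversal_strength, "young")
    proage_f = _target_folds(signature, config.reversal_strength, "old")

    n_rows = config.n_drugs * config.instances_per_drug
    folds = np.exp2(rng.normal(0.0, config.fold_noise_sd, size=(n_rows, len(genes))))

    meta_rows = []
    for d_i, drug in enumerate(drugs):
        for inst in range(config.instances_per_drug):
            row = d_i * config.instances_per_drug + inst
            if roles[d_i] == REJUVENATING:
                folds[row, sig_pos] = rejuv_f
            elif roles[d_i] == PROAGING:
                folds[row, sig_pos] = proage_f
            meta_rows.append(
                {
                    "drug": drug,
                    "cell_line": CELL_LINES[inst % len(CELL_LINES)],
                    "dose": DOSES[inst % len(DOSES)],
                    "duration": DURATIONS[inst % len(DURATIONS)],
                }
            )
    table = pd.concat(
        [
            pd.DataFrame(meta_rows),
            pd.DataFrame(folds, columns=genes),
        ],
        axis=1,
    )
    return table, labels


def generate_known_set(
    labels: pd.Series,
    contamination: float = 0.0,
    n_true: int | None = None,
    seed: int = 0,
) -> set[str]:
    """Emulate a curated known-geroprotector database: a subset of the
    true rejuvenators plus decoys.

    ``n_true`` true rejuvenators (default: all) are included, plus
    round(contamination * n_true) neutral decoys.
    """
    if not 0 <= contamination <= 1:
        raise ValueError("contamination must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rejuv = labels.index[labels == REJUVENATING].to_numpy()
    neutral = labels.index[labels == NEUTRAL].to_numpy()
    if len(rejuv) == 0:
        return set()
    take = len(rejuv) if n_true is None else min(n_true, len(rejuv))
    chosen = rng.choice(rejuv, size=take, replace=False)
    n_decoys = min(int(round(contamination * take)), len(neutral))
    decoys = rng.choice(neutral, size=n_decoys, replace=False) if n_decoys else []
    return set(chosen) | set(decoys)
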