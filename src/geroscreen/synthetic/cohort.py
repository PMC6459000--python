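"""Synthetic age-stratified expression cohort.

The generator emits linear RPKM-like values (lognormal around a
per-gene baseline) so that the full preprocessing path
(normalize -> abundance filter -> log2) is exercised end to end.  A
chosen subset of "aging" genes carries a monotone log2-scale trend
across age bins: the expected log2 mean of an aging gene in bin i is
shifted by direction * effect_size * noise_sd * i relative to the
youngest bin, with half the aging genes trending up and half down.
Non-aging genes are age-independent.  A small fraction of samples is
given RIN < 6 or an unusable flag to exercise the quality gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from geroscreen.matrix import ExpressionMatrix


@dataclass
class CohortConfig:
    """Study-design knobs for the synthetic cohort.

    effect_size is the standardized per-decade mean shift of aging
    genes, in units of the within-bin SD (noise_sd, log2 scale).
    """

    n_genes: int = 1000
    n_aging_genes: int = 100
    tissues: tuple[str, ...] = ("Adipose", "Artery", "Lung", "Skin")
    genders: tuple[str, ...] = ("female",)
    age_bins: tuple[str, ...] = ("30-39", "40-49", "50-59", "60-69")
    samples_per_cell: int = 30
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_log2_range: tuple[float, float] = (3.0, 8.0)
    low_rin_fraction: float = 0.05
    unusable_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_cell < 1:
            raise ValueError("samples_per_cell must be >= 1")
        if not 0 <= self.n_aging_genes <= self.n_genes:
            raise ValueError("n_aging_genes must be in [0, n_genes]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.low_rin_fraction <= 1 or not 0 <= self.unusable_fraction <= 1:
            raise ValueError("quality-failure fractions must be in [0, 1]")


@dataclass
class CohortTruth:
    """Ground truth of the planted signal: which genes age, and in
    which direction (+1 up with age, -1 down)."""

    aging_genes: list[str]
    directions: pd.Series  # +1 / -1 per aging gene


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, CohortTruth]:
    """Generate (raw linear expression matrix, sample metadata, truth).

    Metadata columns: tissue, gender, age_bin, rin, usable; indexed by
    sample id.  Identical configs (same seed) give bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]
    gene_idx = pd.Index(genes)

    aging = rng.choice(config.n_genes, size=config.n_aging_genes, replace=False)
    aging = np.sort(aging)
    # half up, half down with age
    dirs = np.ones(config.n_aging_genes)
    dirs[rng.permutation(config.n_aging_genes)[: config.n_aging_genes // 2]] = -1.0

    lo, hi = config.baseline_log2_range
    baseline = rng.uniform(lo, hi, size=config.n_genes)
    trend = np.zeros(config.n_genes)
    trend[aging] = dirs * config.effect_size * config.noise_sd

    cells = [
        (t, g, b, i)
        for t in config.tissues
        for g in config.genders
        for b in config.age_bins
        for i in range(config.samples_per_cell)
    ]
    sample_ids = [f"S-{t[:4].upper()}-{g[0].upper()}-{b}-{i:03d}" for t, g, b, i in cells]
    bin_index = {b: i for i, b in enumerate(config.age_bins)}

    n_samples = len(cells)
    means = np.empty((config.n_genes, n_samples))
    for j, (t, g, b, i) in enumerate(cells):
        means[:, j] = baseline + trend * bin_index[b]
    log2_expr = means + rng.normal(0.0, config.noise_sd, size=means.shape)
    values = pd.DataFrame(np.exp2(log2_expr), index=gene_idx, columns=sample_ids)

    rin = rng.uniform(6.0, 10.0, size=n_samples)
    low = rng.random(n_samples) < config.low_rin_fraction
    rin[low] = rng.uniform(3.0, 5.9, size=low.sum())
    usable = rng.random(n_samples) >= config.unusable_fraction

    metadata = pd.DataFrame(
        {
            "tissue": [c[0] for c in cells],
            "gender": [c[1] for c in cells],
            "age_bin": [c[2] for c in cells],
            "rin": np.round(rin, 1),
            "usable": usable,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = CohortTruth(
        aging_genes=[genes[i] for i in aging],
        directions=pd.Series(dirs, index=[genes[i] for i in aging]),
    )
    return ExpressionMatrix(values, stage="linear"), metadata, truth


@dataclass
class AgingSignature:
    """Per-gene young and old median log2 profiles of a reference
    young-vs-old contrast; the perturbation generator plants fold
    changes against it."""

    young_log2: pd.Series
    old_log2: pd.Series

    def __post_init__(self) -> None:
        if not self.young_log2.index.equals(self.old_log2.index):
            raise ValueError("young and old profiles must share a gene index")

    @property
    def genes(self) -> pd.Index:
        return self.young_log2.index

    @property
    def delta(self) -> pd.Series:
        """old - young log2 difference (the aging trend)."""
        return self.old_log2 - self.young_log2


def compute_aging_signature(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    young_bin: str,
    old_bin: str,
    genes=None,
) -> AgingSignature:
    """Median log2 profiles of the pooled young-bin and old-bin samples
    (all tissues/genders), optionally restricted to ``genes``."""
    matrix.require_stage("log2")
    meta = metadata.loc[matrix.samples]
    young_samples = meta.index[meta["age_bin"] == young_bin]
    old_samples = meta.index[meta["age_bin"] == old_bin]
    if len(young_samples) == 0 or len(old_samples) == 0:
        raise ValueError(f"no samples in bin {young_bin!r} or {old_bin!r}")
    vals = matrix.values if genes is None else matrix.values.loc[
        matrix.genes[matrix.genes.isin(pd.Index(genes))]
    ]
    return AgingSignature(
        young_log2=vals[young_samples].median(axis=1),
        old_log2=vals[old_samples].median(axis=1),
    )
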