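"""End-to-end screen driver.

``execute_screen`` runs preprocess -> assemble -> train -> evaluate ->
select -> score -> rank fully in memory on a synthetic cohort and
returns a :class:`ScreenResult`; ``run_screen`` additionally persists
models, matrices, the ranking and a provenance manifest to a run
directory.  A single global seed is expanded into fixed per-stage
seeds so stages can be rerun in isolation and reruns with the same
config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from geroscreen.classify import (
    AgeClassifierModel,
    ModelQualityGate,
    assemble_comparison,
    evaluate_classifier,
    models_report,
    save_model,
    select_models,
    train_classifier,
)
from geroscreen.matrix import OLD_BIN
from geroscreen.preprocess import preprocess_cohort
from geroscreen.ranking import (
    candidate_list,
    count_supporting_models,
    enrichment_pvalues,
    known_set_overlap_test,
    mad_cutoff,
    rank_drugs,
)
from geroscreen.scoring import (
    classify_perturbations,
    consolidate_per_drug,
    geroprotective_index,
    middle_age_profile,
    perturbation_genes,
)
from geroscreen.synthetic import (
    CohortConfig,
    PerturbationConfig,
    WormExperimentConfig,
    compute_aging_signature,
    generate_cohort,
    generate_known_set,
    generate_perturbations,
)

log = logging.getLogger(__name__)

_STAGE_IDS = {"cohort": 1, "perturbations": 2, "known_set": 3, "worms": 4, "train": 5}


def stage_seed(global_seed: int, stage: str, item: int = 0) -> int:
    """Deterministic per-stage seed derived from the global seed,
    always below 2**31."""
    ss = np.random.SeedSequence(entropy=[int(global_seed), _STAGE_IDS[stage], item])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All stage parameters of the screen; the numeric defaults are
    the screen's canonical settings (10-sample minimum per side, 10%
    abundance drop, DE filter at p < 0.01, 70/30 split, 10-fold CV,
    500 trees, 0.75 quality gate, q <= 0.05 candidates)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    perturbations: PerturbationConfig = field(default_factory=PerturbationConfig)
    worms: WormExperimentConfig | None = None
    known_contamination: float = 0.0
    min_n: int = 10
    abundance_threshold: float = 0.1
    abundance_sample_fraction: float = 0.8
    min_rin: float = 6.0
    abundance_drop: float = 0.10
    de_alpha: float = 0.01
    train_fraction: float = 0.70
    cv_folds: int = 10
    cv_repeats: int = 2
    n_trees: int = 500
    cv_n_trees: int = 50
    gate_cutoff: float = 0.75
    index_mode: str = "rescaled"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.index_mode not in ("rescaled", "plain"):
            raise ValueError("index_mode must be 'rescaled' or 'plain'")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class ScreenResult:
    """Everything the screen computes, in memory."""

    config: PipelineConfig
    truth_labels: pd.Series
    report: pd.DataFrame
    passing_models: list[AgeClassifierModel]
    profiles: dict[str, pd.Series]
    instance_probs: pd.DataFrame | None
    index_matrix: pd.DataFrame | None
    cutoff: float | None
    ranking: pd.DataFrame | None
    candidates: list[str]
    overlap: object | None
    manifest: dict

    @property
    def status(self) -> str:
        return "ok" if self.passing_models else "no_models"


def execute_screen(config: PipelineConfig, known_set: set[str] | None = None) -> ScreenResult:
    """Run the synthetic-mode screen end to end in memory."""
    seed = config.seed
    cohort_cfg = dataclasses.replace(config.cohort, seed=stage_seed(seed, "cohort"))
    raw, metadata, truth = generate_cohort(cohort_cfg)
    processed, meta, parts = preprocess_cohort(
        raw,
        metadata,
        abundance_threshold=config.abundance_threshold,
        abundance_sample_fraction=config.abundance_sample_fraction,
        min_rin=config.min_rin,
    )
    manifest: dict = {
        "seed": seed,
        "n_genes_raw": raw.n_genes,
        "n_samples_raw": raw.n_samples,
        "n_genes_processed": processed.n_genes,
        "n_samples_processed": processed.n_samples,
    }

    young_bins = [b for b in cohort_cfg.age_bins if b != OLD_BIN]
    old_bin = OLD_BIN if OLD_BIN in cohort_cfg.age_bins else cohort_cfg.age_bins[-1]

    signature = compute_aging_signature(
        processed, meta, young_bin=cohort_cfg.age_bins[0], old_bin=old_bin,
        genes=[g for g in truth.aging_genes if g in processed.genes],
    )
    pert_cfg = dataclasses.replace(
        config.perturbations, seed=stage_seed(seed, "perturbations")
    )
    perturbations, labels = generate_perturbations(pert_cfg, signature, raw.genes)
    universe = perturbation_genes(perturbations)
    manifest["n_perturbation_instances"] = len(perturbations)
    manifest["n_drugs"] = int(labels.size)

    datasets, models = {}, []
    item = 0
    for tissue in cohort_cfg.tissues:
        for gender in cohort_cfg.genders:
            for young_bin in young_bins:
                ds = assemble_comparison(
                    parts, tissue, gender, young_bin, universe,
                    min_n=config.min_n,
                    abundance_drop=config.abundance_drop,
                    de_alpha=config.de_alpha,
                    old_bin=old_bin,
                )
                if ds is None:
                    continue
                model = train_classifier(
                    ds,
                    train_fraction=config.train_fraction,
                    cv_folds=config.cv_folds,
                    cv_repeats=config.cv_repeats,
                    n_trees=config.n_trees,
                    cv_n_trees=config.cv_n_trees,
                    seed=stage_seed(seed, "train", item),
                )
                evaluate_classifier(model)
                datasets[model.name] = ds
                models.append(model)
                item += 1

    gate = ModelQualityGate(config.gate_cutoff)
    report = models_report(models, gate)
    passing = select_models(models, gate)
    manifest["n_models_trained"] = len(models)
    manifest["n_models_passing"] = len(passing)

    if not passing:
        log.warning("no model passed the %.2f quality gate", config.gate_cutoff)
        return ScreenResult(
            config=config, truth_labels=labels, report=report, passing_models=[],
            profiles={}, instance_probs=None, index_matrix=None, cutoff=None,
            ranking=None, candidates=[], overlap=None, manifest=manifest,
        )

    profiles = {m.name: middle_age_profile(datasets[m.name], m.genes) for m in passing}
    inst_probs = classify_perturbations(passing, profiles, perturbations)
    drug_probs = consolidate_per_drug(inst_probs, perturbations["drug"])
    index = geroprotective_index(drug_probs, mode=config.index_mode)

    cutoff = mad_cutoff(index.to_numpy())
    counts = count_supporting_models(index, cutoff)
    total_predictions = int(index.notna().to_numpy().sum())
    total_above = int((index > cutoff).to_numpy().sum())
    stats_table = enrichment_pvalues(counts, total_predictions, total_above)
    ranking = rank_drugs(stats_table, alpha=config.alpha)
    candidates = candidate_list(ranking)
    manifest["mad_cutoff"] = cutoff
    manifest["n_candidates"] = len(candidates)

    if known_set is None and config.perturbations.n_rejuvenating > 0:
        known_set = generate_known_set(
            labels,
            contamination=config.known_contamination,
            seed=stage_seed(seed, "known_set"),
        )
    overlap = None
    if known_set:
        overlap = known_set_overlap_test(candidates, known_set, universe_size=len(labels))
        manifest["overlap_p"] = overlap.p_value

    inst_table = pd.concat(
        [perturbations[["drug", "cell_line", "dose", "duration"]], inst_probs], axis=1
    )
    return ScreenResult(
        config=config, truth_labels=labels, report=report, passing_models=passing,
        profiles={name: p.values for name, p in profiles.items()},
        instance_probs=inst_table, index_matrix=index, cutoff=cutoff,
        ranking=ranking, candidates=candidates, overlap=overlap, manifest=manifest,
    )


def run_screen(config: PipelineConfig, out_dir: str | Path, known_set: set[str] | None = None) -> ScreenResult:
    """Execute the screen and persist artifacts to ``out_dir``.

    Writes the model report, per-model bundles, the drug x model index
    matrix, the ranking CSV, the candidate list and a provenance
    manifest.  When no model passes the quality gate the run directory
    still receives the report and manifest (status "no_models").
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = execute_screen(config, known_set=known_set)
    result.report.to_csv(out / "models_report.csv", index=False)
    for m in result.passing_models:
        save_model(m, out / "models" / m.name.replace("|", "_"),
                   profile=result.profiles.get(m.name))
    if result.instance_probs is not None:
        result.instance_probs.to_csv(out / "instance_probabilities.csv", index=False)
    if result.index_matrix is not None:
        result.index_matrix.to_csv(out / "geroprotective_index.csv")
    if result.ranking is not None:
        result.ranking.to_csv(out / "ranking.csv")
        (out / "candidates.txt").write_text("\n".join(result.candidates) + "\n")
    if result.overlap is not None:
        (out / "overlap_test.json").write_text(json.dumps(result.overlap.as_dict(), indent=2))
    manifest = dict(result.manifest)
    manifest["status"] = result.status
    manifest["config"] = _config_to_jsonable(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def _config_to_jsonable(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    return convert(config)


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain (e.g. YAML-loaded) mapping."""
    raw = dict(raw)
    cohort = CohortConfig(**{
        **raw.pop("cohort", {}),
    })
    pert = PerturbationConfig(**raw.pop("perturbations", {}))
    worms_raw = raw.pop("worms", None)
    worms = WormExperimentConfig(**worms_raw) if worms_raw else None
    # tuples where dataclass defaults are tuples
    return PipelineConfig(cohort=cohort, perturbations=pert, worms=worms, **raw)
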