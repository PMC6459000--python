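"""Binary young-vs-old age classifiers per tissue/gender contrast.

For every tissue and gender, each young decade bin (20-29 ... 50-59) is
contrasted against the fixed old bin (60-69).  Feature reduction
(universe intersection, 10% abundance drop, per-gene equal-variance
t-test at p < 0.01) precedes training.  Classes are balanced by random
downsampling, a stratified 70/30 split is made, per-gene center/scale
constants are fitted on the training split, and a 500-tree random
forest is tuned over an mtry grid by repeated stratified 10-fold CV
maximizing ROC-AUC.  A model is retained only if CV ROC-AUC,
sensitivity, specificity, held-out ROC-AUC and held-out accuracy all
exceed 0.75.

Convention: "young" is the positive class throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from geroscreen.matrix import OLD_BIN, ExpressionMatrix

log = logging.getLogger(__name__)

YOUNG_LABEL = "young"
OLD_LABEL = "old"


@dataclass
class AgeComparisonDataset:
    """One young-vs-old contrast after all gene filters.

    ``young`` and ``old`` are genes x samples DataFrames on the log2
    scale, restricted to the filtered gene set.
    """

    tissue: str
    gender: str
    young_bin: str
    old_bin: str
    young: pd.DataFrame
    old: pd.DataFrame
    de_pvalues: pd.Series | None = None

    @property
    def genes(self) -> pd.Index:
        return self.young.index

    @property
    def name(self) -> str:
        return f"{self.tissue}|{self.gender}|{self.young_bin}"


@dataclass
class AgeClassifierModel:
    """A fitted age classifier plus its provenance, scaling constants
    and quality metrics.

    ``center``/``scale`` are per-gene constants estimated on the 70%
    training split only; every transcriptome scored by the model is
    standardized with them first.
    """

    tissue: str
    gender: str
    young_bin: str
    old_bin: str
    genes: list[str]
    center: np.ndarray
    scale: np.ndarray
    forest: RandomForestClassifier
    mtry: int
    cv_roc_auc: float
    cv_sensitivity: float
    cv_specificity: float
    seed: int
    test_roc_auc: float | None = None
    test_accuracy: float | None = None
    # held-out 30% split (samples x genes, raw log2 values) and labels
    holdout_X: pd.DataFrame | None = None
    holdout_y: np.ndarray | None = None

    @property
    def name(self) -> str:
        return f"{self.tissue}|{self.gender}|{self.young_bin}"

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center) / self.scale

    def predict_proba_young(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Probability of the "young" class for samples x genes input
        given on the raw log2 scale (standardization applied here)."""
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != list(self.genes):
                X = X[self.genes]
            X = X.to_numpy()
        Z = self.standardize(np.asarray(X, dtype=np.float64))
        idx = list(self.forest.classes_).index(YOUNG_LABEL)
        return self.forest.predict_proba(np.asarray(Z, dtype=np.float32))[:, idx]

    def metrics(self) -> dict[str, float | None]:
        return {
            "cv_roc_auc": self.cv_roc_auc,
            "cv_sensitivity": self.cv_sensitivity,
            "cv_specificity": self.cv_specificity,
            "test_roc_auc": self.test_roc_auc,
            "test_accuracy": self.test_accuracy,
        }


@dataclass
class ModelQualityGate:
    """All-five-metrics gate: CV ROC-AUC, CV sensitivity, CV
    specificity, test ROC-AUC and test accuracy must each exceed
    ``cutoff`` (strict)."""

    cutoff: float = 0.75

    def passes(self, model: AgeClassifierModel) -> bool:
        vals = model.metrics().values()
        if any(v is None for v in vals):
            raise ValueError(f"model {model.name} has incomplete metrics")
        return all(v > self.cutoff for v in vals)


def differential_filter(
    young: pd.DataFrame, old: pd.DataFrame, alpha: float
) -> tuple[pd.Index, pd.Series]:
    """Per-gene two-sided equal-variance (pooled) t-test; a gene
    survives iff p < alpha.  Zero-variance genes with equal means are
    assigned p = 1 and dropped.  Returns surviving gene ids and the
    full p-value series."""
    if young.shape[1] < 2 or old.shape[1] < 2:
        raise ValueError("differential filter needs >=2 samples per side")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(
            young.to_numpy(), old.to_numpy(), axis=1, equal_var=True
        )
    p = pd.Series(res.pvalue, index=young.index, name="p")
    p = p.fillna(1.0)  # no pooled variance, no mean difference -> no evidence
    return young.index[(p < alpha).to_numpy()], p


def assemble_comparison(
    partition_map: dict[tuple[str, str, str], ExpressionMatrix],
    tissue: str,
    gender: str,
    young_bin: str,
    universe,
    min_n: int = 10,
    abundance_drop: float = 0.10,
    de_alpha: float = 0.01,
    old_bin: str = OLD_BIN,
) -> AgeComparisonDataset | None:
    """Build one young-vs-old dataset, or return None (a skip, not an
    error) when either side has fewer than ``min_n`` samples.

    Gene filtering order: (1) intersect with the perturbation
    ``universe``; (2) drop the ``abundance_drop`` fraction of genes with
    the lowest mean expression over the combined comparison samples
    (floor of fraction x gene count, stable order for ties); (3) keep
    genes passing the differential filter at p < ``de_alpha`` with no
    multiplicity correction.
    """
    if young_bin == old_bin:
        raise ValueError("young_bin must differ from old_bin")
    young_m = partition_map.get((tissue, gender, young_bin))
    old_m = partition_map.get((tissue, gender, old_bin))
    if young_m is None or old_m is None:
        log.info("skip %s|%s|%s: bin absent from partition", tissue, gender, young_bin)
        return None
    if young_m.n_samples < min_n or old_m.n_samples < min_n:
        log.info(
            "skip %s|%s|%s: %d young / %d old samples (< %d)",
            tissue, gender, young_bin, young_m.n_samples, old_m.n_samples, min_n,
        )
        return None
    young_m.require_stage("log2")
    old_m.require_stage("log2")

    universe = pd.Index(universe)
    genes = young_m.genes[young_m.genes.isin(universe)]
    if len(genes) == 0:
        return None
    young = young_m.values.loc[genes]
    old = old_m.values.loc[genes]

    combined_mean = pd.concat([young, old], axis=1).mean(axis=1)
    n_drop = int(np.floor(abundance_drop * len(genes)))
    if n_drop > 0:
        order = np.argsort(combined_mean.to_numpy(), kind="stable")
        keep_mask = np.ones(len(genes), dtype=bool)
        keep_mask[order[:n_drop]] = False
        young, old = young.loc[keep_mask], old.loc[keep_mask]

    survivors, pvals = differential_filter(young, old, de_alpha)
    if len(survivors) == 0:
        log.info("skip %s|%s|%s: no genes pass DE filter", tissue, gender, young_bin)
        return None
    return AgeComparisonDataset(
        tissue=tissue,
        gender=gender,
        young_bin=young_bin,
        old_bin=old_bin,
        young=young.loc[survivors],
        old=old.loc[survivors],
        de_pvalues=pvals.loc[survivors],
    )


def default_mtry_grid(n_features: int) -> list[int]:
    """Grid around the classical sqrt(p) heuristic:
    {floor(sqrt(p))/2, floor(sqrt(p)), 2 floor(sqrt(p)), p/3},
    clipped to [1, p], deduplicated, ascending."""
    r = int(np.floor(np.sqrt(n_features)))
    cand = [r // 2, r, 2 * r, n_features // 3]
    return sorted({int(np.clip(c, 1, n_features)) for c in cand})


def _fold_metrics(y_true: np.ndarray, prob_young: np.ndarray) -> tuple[float, float, float]:
    """ROC-AUC, sensitivity and specificity (young positive, 0.5 cut)."""
    pos = y_true == YOUNG_LABEL
    auc = roc_auc_score(pos, prob_young)
    pred_pos = prob_young > 0.5
    sens = float(pred_pos[pos].mean()) if pos.any() else np.nan
    spec = float((~pred_pos[~pos]).mean()) if (~pos).any() else np.nan
    return float(auc), sens, spec


def train_classifier(
    dataset: AgeComparisonDataset,
    train_fraction: float = 0.70,
    cv_folds: int = 10,
    cv_repeats: int = 2,
    n_trees: int = 500,
    cv_n_trees: int = 50,
    mtry_grid: list[int] | None = None,
    seed: int = 0,
) -> AgeClassifierModel:
    """Balance, split, scale, tune and fit one age classifier.

    Steps: (1) the majority class is randomly downsampled to the
    minority size; (2) a stratified ``train_fraction`` split is made;
    (3) per-gene center/scale constants are estimated on the training
    split (sd with n-1 denominator; zero sd replaced by 1); (4) the
    forest is tuned over ``mtry_grid`` by repeated stratified k-fold CV
    maximizing mean ROC-AUC (ties broken toward the smallest mtry),
    with sensitivity/specificity at the 0.5 probability threshold
    averaged over folds; (5) the returned model is refit with
    ``n_trees`` trees on the full training split.  Tuning forests use
    ``cv_n_trees`` trees to keep the grid search tractable; ranking of
    mtry values by CV AUC is insensitive to this at these sample sizes.
    """
    rng = np.random.default_rng(seed)
    ny, no = dataset.young.shape[1], dataset.old.shape[1]
    if ny == 0 or no == 0:
        raise ValueError("both classes must be nonempty")
    n_min = min(ny, no)
    young_cols = rng.choice(ny, size=n_min, replace=False) if ny > n_min else np.arange(ny)
    old_cols = rng.choice(no, size=n_min, replace=False) if no > n_min else np.arange(no)
    young = dataset.young.iloc[:, np.sort(young_cols)]
    old = dataset.old.iloc[:, np.sort(old_cols)]

    X = pd.concat([young.T, old.T], axis=0)  # samples x genes
    y = np.array([YOUNG_LABEL] * n_min + [OLD_LABEL] * n_min)

    split_seed = int(rng.integers(0, 2**31 - 1))
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, stratify=y, random_state=split_seed
    )
    n_per_class_train = min((y_tr == YOUNG_LABEL).sum(), (y_tr == OLD_LABEL).sum())
    if n_per_class_train < cv_folds:
        raise ValueError(
            f"training split has {n_per_class_train} samples in the smaller class, "
            f"fewer than cv_folds={cv_folds}; lower cv_folds"
        )

    center = X_tr.mean(axis=0).to_numpy()
    scale = X_tr.std(axis=0, ddof=1).to_numpy()
    scale = np.where(scale > 0, scale, 1.0)
    Z_tr = np.asarray((X_tr.to_numpy() - center) / scale, dtype=np.float32)

    grid = mtry_grid if mtry_grid is not None else default_mtry_grid(X.shape[1])
    cv_seed = int(rng.integers(0, 2**31 - 1))
    rf_seed = int(rng.integers(0, 2**31 - 1))
    cv = RepeatedStratifiedKFold(
        n_splits=cv_folds, n_repeats=cv_repeats, random_state=cv_seed
    )
    splits = list(cv.split(Z_tr, y_tr))

    results: dict[int, tuple[float, float, float]] = {}
    for mtry in grid:
        aucs, senss, specs = [], [], []
        for i, (tr_idx, va_idx) in enumerate(splits):
            rf = RandomForestClassifier(
                n_estimators=cv_n_trees,
                max_features=mtry,
                random_state=rf_seed + i,
            )
            rf.fit(Z_tr[tr_idx], y_tr[tr_idx])
            idx = list(rf.classes_).index(YOUNG_LABEL)
            prob = rf.predict_proba(Z_tr[va_idx])[:, idx]
            a, s, sp = _fold_metrics(y_tr[va_idx], prob)
            aucs.append(a), senss.append(s), specs.append(sp)
        results[mtry] = (
            float(np.mean(aucs)),
            float(np.nanmean(senss)),
            float(np.nanmean(specs)),
        )

    # best mean AUC; smallest mtry wins ties (grid is ascending)
    best_mtry = max(grid, key=lambda m: (results[m][0], -m))
    cv_auc, cv_sens, cv_spec = results[best_mtry]

    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features=best_mtry, random_state=rf_seed
    )
    forest.fit(Z_tr, y_tr)

    model = AgeClassifierModel(
        tissue=dataset.tissue,
        gender=dataset.gender,
        young_bin=dataset.young_bin,
        old_bin=dataset.old_bin,
        genes=list(dataset.genes),
        center=center,
        scale=scale,
        forest=forest,
        mtry=best_mtry,
        cv_roc_auc=cv_auc,
        cv_sensitivity=cv_sens,
        cv_specificity=cv_spec,
        seed=seed,
        holdout_X=X_te,
        holdout_y=y_te,
    )
    return model


def evaluate_classifier(
    model: AgeClassifierModel,
    holdout_X: pd.DataFrame | None = None,
    holdout_y: np.ndarray | None = None,
) -> tuple[float, float]:
    """Score the model on its held-out 30% split (or an explicit one).

    Returns (ROC-AUC, accuracy at the 0.5 probability cut) and stores
    both on the model.
    """
    X = holdout_X if holdout_X is not None else model.holdout_X
    y = holdout_y if holdout_y is not None else model.holdout_y
    if X is None or y is None:
        raise ValueError("no held-out split available")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("held-out split contains a single class; ROC-AUC undefined")
    prob = model.predict_proba_young(X)
    pos = y == YOUNG_LABEL
    auc = float(roc_auc_score(pos, prob))
    acc = float(((prob > 0.5) == pos).mean())
    model.test_roc_auc, model.test_accuracy = auc, acc
    return auc, acc


def select_models(
    models: list[AgeClassifierModel], gate: ModelQualityGate | None = None
) -> list[AgeClassifierModel]:
    """Return exactly the models whose five gated metrics all exceed
    the cutoff (strict)."""
    gate = gate or ModelQualityGate()
    return [m for m in models if gate.passes(m)]


# ---------------------------------------------------------------------------
# persistence

def save_model(
    model: AgeClassifierModel, out_dir: str | Path, profile: pd.Series | None = None
) -> Path:
    """Persist a model bundle: manifest.json, scaling.csv,
    forest.joblib, and optionally the model's middle-age profile
    (profile.csv) so the bundle can score perturbations on its own."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if profile is not None:
        profile.rename("value").rename_axis("gene").to_csv(out / "profile.csv")
    manifest = {
        "format_version": 1,
        "tissue": model.tissue,
        "gender": model.gender,
        "young_bin": model.young_bin,
        "old_bin": model.old_bin,
        "mtry": model.mtry,
        "seed": model.seed,
        **model.metrics(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    pd.DataFrame(
        {"gene": model.genes, "center": model.center, "scale": model.scale}
    ).to_csv(out / "scaling.csv", index=False)
    joblib.dump(model.forest, out / "forest.joblib")
    return out


def load_model_profile(bundle_dir: str | Path) -> pd.Series | None:
    """The middle-age profile stored alongside a model bundle, if any."""
    path = Path(bundle_dir) / "profile.csv"
    if not path.exists():
        return None
    return pd.read_csv(path, index_col=0)["value"]


def load_model(bundle_dir: str | Path) -> AgeClassifierModel:
    bundle = Path(bundle_dir)
    manifest = json.loads((bundle / "manifest.json").read_text())
    scaling = pd.read_csv(bundle / "scaling.csv")
    forest = joblib.load(bundle / "forest.joblib")
    return AgeClassifierModel(
        tissue=manifest["tissue"],
        gender=manifest["gender"],
        young_bin=manifest["young_bin"],
        old_bin=manifest["old_bin"],
        genes=scaling["gene"].tolist(),
        center=scaling["center"].to_numpy(),
        scale=scaling["scale"].to_numpy(),
        forest=forest,
        mtry=manifest["mtry"],
        cv_roc_auc=manifest["cv_roc_auc"],
        cv_sensitivity=manifest["cv_sensitivity"],
        cv_specificity=manifest["cv_specificity"],
        seed=manifest["seed"],
        test_roc_auc=manifest.get("test_roc_auc"),
        test_accuracy=manifest.get("test_accuracy"),
    )


def models_report(models: list[AgeClassifierModel], gate: ModelQualityGate | None = None) -> pd.DataFrame:
    """Tabular model inventory: provenance, the five gated metrics and
    the pass/fail flag."""
    gate = gate or ModelQualityGate()
    rows = []
    for m in models:
        rows.append(
            {
                "tissue": m.tissue,
                "gender": m.gender,
                "young_bin": m.young_bin,
                "n_genes": len(m.genes),
                "mtry": m.mtry,
                **m.metrics(),
                "passes_gate": gate.passes(m),
            }
        )
    return pd.DataFrame(rows)
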