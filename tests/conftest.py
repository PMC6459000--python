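import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from geroscreen.classify import AgeComparisonDataset, evaluate_classifier, train_classifier
from geroscreen.matrix import ExpressionMatrix

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_separable_dataset(
    n_per_side: int = 30,
    n_genes: int = 50,
    n_informative: int = 5,
    shift_sd: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    tissue: str = "Lung",
) -> AgeComparisonDataset:
    """Young-vs-old toy contrast with a few genes shifted by
    ``shift_sd`` standard deviations between the groups."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    base = rng.uniform(4, 8, size=n_genes)
    young = base[:, None] + rng.normal(0, noise_sd, size=(n_genes, n_per_side))
    old = base[:, None] + rng.normal(0, noise_sd, size=(n_genes, n_per_side))
    old[:n_informative] += shift_sd * noise_sd
    return AgeComparisonDataset(
        tissue=tissue,
        gender="female",
        young_bin="30-39",
        old_bin="60-69",
        young=pd.DataFrame(young, index=genes, columns=[f"y{i}" for i in range(n_per_side)]),
        old=pd.DataFrame(old, index=genes, columns=[f"o{i}" for i in range(n_per_side)]),
    )


@pytest.fixture(scope="session")
def small_trained_model():
    """One quick, clearly separable classifier shared by scoring tests."""
    ds = make_separable_dataset(n_per_side=15, n_genes=20, n_informative=4, seed=3)
    model = train_classifier(ds, cv_folds=3, cv_repeats=1, cv_n_trees=25, n_trees=100, seed=11)
    evaluate_classifier(model)
    return ds, model


def toy_matrix(values, genes=None, samples=None, stage="linear") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), stage=stage)
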