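"""Synthetic cohort, perturbation and worm-experiment generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from geroscreen.scoring import MiddleAgeProfile, apply_fold_changes, perturbation_genes
from geroscreen.synthetic import (
    AgingSignature,
    CohortConfig,
    PerturbationConfig,
    WormExperimentConfig,
    generate_cohort,
    generate_known_set,
    generate_perturbations,
    generate_worm_experiment,
)
from geroscreen.synthetic.perturbations import NEUTRAL, PROAGING, REJUVENATING


class TestCohort:
    def test_deterministic_given_seed(self):
        cfg = CohortConfig(n_genes=50, n_aging_genes=5, tissues=("A",), samples_per_cell=3, seed=9)
        m1, meta1, t1 = generate_cohort(cfg)
        m2, meta2, t2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(meta1, meta2)
        assert t1.aging_genes == t2.aging_genes

    def test_zero_samples_per_cell_rejected(self):
        with pytest.raises(ValueError, match="samples_per_cell"):
            CohortConfig(samples_per_cell=0)

    def test_shapes_and_metadata(self):
        cfg = CohortConfig(
            n_genes=40, n_aging_genes=4, tissues=("A", "B"), genders=("male", "female"),
            age_bins=("30-39", "60-69"), samples_per_cell=5, seed=1,
        )
        m, meta, truth = generate_cohort(cfg)
        assert m.values.shape == (40, 2 * 2 * 2 * 5)
        assert (m.values.to_numpy() >= 0).all()
        assert set(meta.columns) == {"tissue", "gender", "age_bin", "rin", "usable"}
        assert len(truth.aging_genes) == 4
        ups = (truth.directions > 0).sum()
        assert ups == 2  # half up, half down

    def test_null_cohort_t_test_calibration(self):
        # with no planted effect, the youngest-vs-oldest t-test rejects
        # ~1% of genes at alpha=0.01
        cfg = CohortConfig(
            n_genes=2000, n_aging_genes=0, tissues=("A",), samples_per_cell=30,
            effect_size=0.0, seed=5,
        )
        m, meta, _ = generate_cohort(cfg)
        log2 = np.log2(m.values.to_numpy() + 1)
        youngest = meta["age_bin"] == cfg.age_bins[0]
        oldest = meta["age_bin"] == cfg.age_bins[-1]
        p = stats.ttest_ind(log2[:, youngest.to_numpy()], log2[:, oldest.to_numpy()], axis=1).pvalue
        frac = float((p < 0.01).mean())
        assert 0.003 < frac < 0.03

    def test_strong_signal_power(self):
        # planted aging genes are nearly all detectable between extreme bins
        cfg = CohortConfig(
            n_genes=500, n_aging_genes=50, tissues=("A",), samples_per_cell=30,
            effect_size=2.0, noise_sd=0.5, seed=2,
        )
        m, meta, truth = generate_cohort(cfg)
        log2 = np.log2(m.values + 1)
        youngest = meta.index[meta["age_bin"] == cfg.age_bins[0]]
        oldest = meta.index[meta["age_bin"] == cfg.age_bins[-1]]
        p = stats.ttest_ind(
            log2.loc[truth.aging_genes, youngest],
            log2.loc[truth.aging_genes, oldest],
            axis=1,
        ).pvalue
        assert (p < 0.01).mean() > 0.9

    def test_planted_shift_matches_bin_index(self):
        cfg = CohortConfig(
            n_genes=200, n_aging_genes=40, tissues=("A",), samples_per_cell=200,
            effect_size=1.0, noise_sd=0.5, low_rin_fraction=0.0, unusable_fraction=0.0,
            seed=3,
        )
        m, meta, truth = generate_cohort(cfg)
        log2 = np.log2(m.values + 1)
        up = truth.directions.index[truth.directions > 0]
        means = {
            b: log2.loc[up, meta.index[meta["age_bin"] == b]].mean(axis=1).mean()
            for b in cfg.age_bins
        }
        step = cfg.effect_size * cfg.noise_sd
        observed = means[cfg.age_bins[-1]] - means[cfg.age_bins[0]]
        expected = step * (len(cfg.age_bins) - 1)
        assert observed == pytest.approx(expected, abs=0.1)


def small_signature(n: int = 6) -> AgingSignature:
    genes = [f"GENE{i:05d}" for i in range(n)]
    young = pd.Series(np.linspace(4, 6, n), index=genes)
    old = young + pd.Series([1, -1] * (n // 2), index=genes, dtype=float)
    return AgingSignature(young_log2=young, old_log2=old)


class TestPerturbations:
    def test_row_count_is_drugs_times_instances(self):
        sig = small_signature()
        cfg = PerturbationConfig(n_drugs=200, n_rejuvenating=5, n_proaging=5,
                                 instances_per_drug=3, seed=0)
        table, labels = generate_perturbations(cfg, sig, sig.genes)
        assert len(table) == 600
        assert labels.value_counts()[REJUVENATING] == 5
        assert set(table["drug"]) == set(labels.index)

    def test_full_reversal_reaches_young_profile_exactly(self):
        sig = small_signature()
        cfg = PerturbationConfig(n_drugs=4, n_rejuvenating=2, n_proaging=1,
                                 instances_per_drug=1, reversal_strength=1.0,
                                 fold_noise_sd=0.0, seed=1)
        table, labels = generate_perturbations(cfg, sig, sig.genes)
        middle = MiddleAgeProfile(
            tissue="ref", gender="f", young_bin="30-39",
            values=(sig.young_log2 + sig.old_log2) / 2,
        )
        rejuv = labels.index[labels == REJUVENATING][0]
        row = table[table["drug"] == rejuv].iloc[0]
        folds = row[perturbation_genes(table)].astype(float)
        induced = apply_fold_changes(middle, folds)
        assert np.allclose(induced.to_numpy(), sig.young_log2.to_numpy(), atol=1e-9)
        proage = labels.index[labels == PROAGING][0]
        row = table[table["drug"] == proage].iloc[0]
        induced = apply_fold_changes(middle, row[perturbation_genes(table)].astype(float))
        assert np.allclose(induced.to_numpy(), sig.old_log2.to_numpy(), atol=1e-9)

    def test_zero_reversal_is_pure_noise(self):
        sig = small_signature()
        cfg = PerturbationConfig(n_drugs=6, n_rejuvenating=2, n_proaging=2,
                                 instances_per_drug=1, reversal_strength=0.0,
                                 fold_noise_sd=0.0, seed=1)
        table, labels = generate_perturbations(cfg, sig, sig.genes)
        folds = table[perturbation_genes(table)].to_numpy(dtype=float)
        assert np.allclose(folds, 1.0)

    def test_empty_signature_rejected(self):
        empty = AgingSignature(
            young_log2=pd.Series(dtype=float), old_log2=pd.Series(dtype=float)
        )
        with pytest.raises(ValueError, match="empty"):
            generate_perturbations(PerturbationConfig(seed=0), empty, pd.Index(["g1"]))

    def test_deterministic(self):
        sig = small_signature()
        cfg = PerturbationConfig(n_drugs=10, n_rejuvenating=2, n_proaging=2, seed=4)
        t1, l1 = generate_perturbations(cfg, sig, sig.genes)
        t2, l2 = generate_perturbations(cfg, sig, sig.genes)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_series_equal(l1, l2)


class TestKnownSet:
    @pytest.fixture
    def labels(self):
        roles = [REJUVENATING] * 5 + [PROAGING] * 3 + [NEUTRAL] * 12
        return pd.Series(roles, index=[f"drug{i:02d}" for i in range(20)])

    def test_no_contamination_subset_of_rejuvenators(self, labels):
        known = generate_known_set(labels, contamination=0.0, seed=0)
        rejuv = set(labels.index[labels == REJUVENATING])
        assert known == rejuv

    def test_full_contamination_counts(self, labels):
        known = generate_known_set(labels, contamination=1.0, seed=0)
        rejuv = set(labels.index[labels == REJUVENATING])
        assert len(known) == 10
        assert len(known - rejuv) == 5  # exactly 5 neutral decoys
        assert all(labels[d] == NEUTRAL for d in known - rejuv)

    def test_empty_truth_gives_empty_set(self):
        labels = pd.Series([NEUTRAL] * 4, index=list("abcd"))
        assert generate_known_set(labels, seed=0) == set()

    def test_contamination_out_of_range_rejected(self, labels):
        with pytest.raises(ValueError):
            generate_known_set(labels, contamination=1.5)


class TestWorms:
    def test_median_ratio_tracks_multiplier(self):
        cfg = WormExperimentConfig(
            n_worms_per_arm=500, arms={"control": 1.0, "treated": 1.25}, seed=0
        )
        surv, _ = generate_worm_experiment(cfg)
        med = surv.groupby("arm")["day"].median()
        assert med["treated"] / med["control"] == pytest.approx(1.25, abs=0.1)

    def test_no_censoring_by_default(self):
        cfg = WormExperimentConfig(n_worms_per_arm=60, censor_prob=0.0, seed=1)
        surv, _ = generate_worm_experiment(cfg)
        assert (surv["censored"] == 0).all()

    def test_censor_prob_produces_censored_records(self):
        cfg = WormExperimentConfig(n_worms_per_arm=100, censor_prob=0.3, seed=1)
        surv, _ = generate_worm_experiment(cfg)
        frac = surv["censored"].mean()
        assert 0.15 < frac < 0.45

    def test_positions_freeze_after_all_deaths(self):
        cfg = WormExperimentConfig(
            n_worms_per_arm=50, arms={"control": 1.0}, median_control_lifespan=5.0,
            frames_per_day=2, seed=2,
        )
        surv, pos = generate_worm_experiment(cfg)
        last_death = surv["day"].max()
        late = pos[pos["timepoint"] > last_death]
        if not late.empty:
            per_frame = late.groupby("timepoint").apply(
                lambda d: sorted(zip(d["plate"], d["x"], d["y"])), include_groups=False
            )
            first = per_frame.iloc[0]
            assert all(frame == first for frame in per_frame)

    def test_deterministic(self):
        cfg = WormExperimentConfig(n_worms_per_arm=60, seed=5)
        s1, p1 = generate_worm_experiment(cfg)
        s2, p2 = generate_worm_experiment(cfg)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(p1, p2)

    def test_invalid_multiplier_rejected(self):
        with pytest.raises(ValueError):
            WormExperimentConfig(arms={"control": 0.0})
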