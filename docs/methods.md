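# Methods

`geroscreen` implements a transcriptomics-based screen for
geroprotective compounds, together with the synthetic data needed to
exercise it and the survival/healthspan analytics used to validate
candidates in *C. elegans*. This note records the models, the
parameters that matter, the numerical choices, and the limits of what
the synthetic tests demonstrate.

## The screen

**Cohort preprocessing.** Expression matrices arrive as linear
RPKM-like values (GCT 1.2). The fixed processing order is: per-sample
normalization to a library size of 10^6; removal of genes whose value
is < 0.1 in ≥ 80% of all loaded samples (strict `<` on the value, `≥`
on the fraction, computed before any tissue partitioning); a
pseudocount of 1 and log2 transform; a quality gate retaining samples
with RIN ≥ 6 (inclusive) that are flagged usable; partitioning by
tissue, gender and decade age bin, with cell-line-derived tissues
excluded. The abundance filter precedes the log transform because it
is defined on the RPKM scale. The bin 70-79 is accepted on input but
never used as an "old" group.

**Age classifiers.** For each tissue and gender, every young decade
bin (20-29 … 50-59) is contrasted with the fixed old bin 60-69,
provided both sides have ≥ 10 samples. Features are reduced in three
steps: intersection with the perturbation gene universe, removal of
the 10% of genes with the lowest mean expression over the combined
comparison samples (floor of 0.10 × gene count; ties broken by stable
order), and a per-gene two-sided pooled-variance t-test keeping genes
with p < 0.01, uncorrected. Training balances the classes by seeded
downsampling of the majority class, makes a stratified 70/30 split,
estimates per-gene center/scale constants on the 70% split (sd with
n−1 denominator; zero sd replaced by 1), and tunes a 500-tree random
forest over the mtry grid {⌊√p⌋/2, ⌊√p⌋, 2⌊√p⌋, p/3} (clipped to
[1, p], deduplicated) by repeated stratified 10-fold cross-validation
maximizing mean ROC-AUC, with "young" as the positive class and ties
broken toward the smallest mtry. Sensitivity and specificity at the
0.5 probability threshold are averaged over CV folds. A model is
retained only if CV ROC-AUC, CV sensitivity, CV specificity, held-out
ROC-AUC and held-out accuracy all exceed 0.75 (strict).

*Tuning budget.* Cross-validation forests use a reduced tree count
(`cv_n_trees`, default 50) and 2 CV repeats; the final model is refit
with the full 500 trees on the whole training split. At these sample
sizes (tens of samples per class) forest fitting cost is dominated by
per-tree overhead, and the ranking of mtry values by mean CV AUC is
insensitive to the tuning-forest size; the reduced budget makes
repeated grid search tractable on a single core. The CV metrics that
feed the quality gate are measured on the tuning forests and are
therefore slightly noisier than 500-tree estimates — in practice a
conservative bias.

*Leakage caveat.* The differential-expression filter is computed on
the **full** comparison, before the train/test split, mirroring the
original recipe in which feature reduction is part of dataset
preparation. This means the held-out 30% participated in feature
selection, and both CV and test metrics are optimistically biased on
data with little true signal: on pure-noise cohorts the ~1% of genes
selected at p < 0.01 genuinely separate the realized samples in every
split, and roughly half of the trained models clear the 0.75 gate.
The screen's false-positive control therefore does *not* come from the
model gate but from the downstream enrichment ranking, which stays
correctly calibrated (empty candidate lists on null screens; see
below). Recomputing the DE filter inside the training split would
remove the optimism but would no longer be the method being
implemented; the center/scale constants and the mtry tuning, by
contrast, are strictly leakage-free (perturbing held-out values leaves
the tuned mtry unchanged, which the tests assert).

**Drug scoring.** Each model gets a "middle-age" prototype: per gene,
the average of the median young and median old log2 profiles of its
training contrast. Perturbations are linear-scale fold changes per
gene (probe-level tables are first collapsed to gene level by the
median, midpoint convention for even counts). A fold f acts
multiplicatively in linear space: x = 2^v − 1, x' = max(f·x, 0),
v' = log2(x' + 1); a fold of 1 is the identity to machine precision
and v = 0 is a fixed point. Genes missing from a fold table default
to 1 with a warning; nonpositive folds are rejected. The standardized
drug-induced transcriptome is scored by the model, giving a
probability-young per (instance, model); per drug and model the
maximum over instances is kept (the most geroprotective prediction).
Probabilities are converted to the geroprotective index by centering
at 0.5 and rescaling each model column by a single positive factor so
its maximum absolute value is 0.5 (`index_mode="rescaled"`, the
default, chosen for cross-model comparability; `"plain"` keeps
p − 0.5). Both modes preserve within-column order and the sign of
p − 0.5.

**Enrichment ranking.** The support cutoff is the mean absolute
deviation around the mean of all pooled index values; a model supports
a drug iff its index is strictly above the cutoff. Per drug, the
support count k over its M non-missing predictions is tested against
the pooled distribution with an upper-tail hypergeometric law
(population N = all non-missing drug × model predictions, successes
K = all above-cutoff predictions, draws M); a binomial variant is
available for comparison. p values are corrected across drugs by
Benjamini–Hochberg (configurable), and drugs are ranked by
(q asc, p asc, k desc, name asc) with candidates at q ≤ 0.05.
Candidate lists are validated against a known-geroprotector set by a
one-sided Fisher exact test on the candidate × known 2×2 table over
the screened universe, case-insensitive.

## Synthetic data

The cohort generator emits linear lognormal expression with per-gene
baselines uniform on log2 [3, 8] and within-bin SD `noise_sd`
(default 0.5 log2 units). A chosen subset of aging genes (default
100 of 1,000) shifts its log2 mean by `effect_size × noise_sd` per
decade step (default effect size 2), half up and half down; all other
genes are age-independent. 5% of samples get RIN < 6 and 2% an
unusable flag to exercise the gate. Default design: 4 tissues × 1
gender × 4 age bins × 30 samples — large enough for every contrast to
clear the 10-sample rule after gating, small enough to train a full
screen in under a minute per seed.

Note that library-size normalization couples genes: planted trends
shift sample totals (the up/down split cancels only to first order),
so on strong-signal cohorts many non-aging genes also become
differentially expressed. This is a faithful property of
normalize-then-test pipelines, not a bug, and the classifiers are
indifferent to it.

The perturbation generator plants, for rejuvenating drugs, fold
changes f = (2^{v_t} − 1)/(2^{v_m} − 1) per signature gene, where v_m
is the reference middle-age log2 value and v_t lies
`reversal_strength` of the way from v_m toward the young median (old
median for pro-aging drugs). With reversal_strength 1 and no noise, a
rejuvenating drug applied to the reference middle-age profile lands
exactly on the young median profile. Non-target genes (and all genes
of neutral drugs) get lognormal noise folds (SD 0.1 log2 units —
small enough that neutral drugs rarely look young, large enough that
indices have spread). 200 drugs with 10 rejuvenators, 10 pro-aging
and 3 instances each mirror the screened-universe structure at desk
scale.

The worm generator draws event times from a Weibull law
(shape 4, control median 20 d) scaled per arm; censoring is optional.
Worms random-walk on a 120×120 arena in plates of 30: at time t a
living worm jumps to a nearby pixel with probability
2^(−t / (halflife × multiplier)) and otherwise stays; dead worms
freeze but remain visible. The decaying move *probability* (rather
than a shrinking step) makes the adjacent-frame correlation
approximately linear in the moving fraction, so the normalized
activity curve crosses 0.5 near the configured half-life (default
4 d), and scaling the half-life by the arm's lifespan multiplier ties
healthspan to lifespan, which is what the activity analytics are meant
to detect. Real data differ in ways the generator ignores: worm
objects span many pixels, tracking loses and re-finds objects, plates
differ systematically, and expression cohorts have correlated genes
and batch effects — passing tests show the analytics are correct, not
that the biology is this clean.

## Worm analytics

Kaplan–Meier estimation and the unweighted log-rank test come from
lifelines; the median is the smallest t with S(t) ≤ 0.5 and is
reported as absent when the curve never reaches 0.5. Arms with fewer
than 50 tracked worms are rejected unless the gate is explicitly
waived. Median-lifespan change is 100 × (treated − control)/control.

The activity procedure builds one binary occupancy grid per plate and
timepoint, computes Pearson correlations of adjacent flattened grids
(zero-variance frames yield missing values; timepoints beyond the
population's death — by default the arm's last observed event — are
omitted), pools plates, averages duplicate times, smooths with a
GCV-tuned smoothing spline (`scipy.interpolate.make_smoothing_spline`;
fewer than 5 unique timepoints fall back to linear interpolation), and
affinely maps the smoothed curve so its minimum (most movement) is
activity 1 and its maximum is 0. Values before the activity peak are
clamped to 1, values after the end of movement to 0. A constant
correlation sequence has no affine map and degenerates to a step curve
at the death time, with a warning. The curve is invariant to a global
shift of all correlations; the mirror/normalize step is applied to the
smoothed curve (matching the procedure's order), with `smooth=False`
available for comparison.

## Reproducibility and problem sizes

Every generator and the trainer are pure functions of their seed; the
pipeline expands one global seed into fixed per-stage seeds
(`stage_seed`), so reruns are byte-identical and stages can be rerun
in isolation. The test suite runs the full screen at the default
conditions over 5 seeds (signal recovery) and 20 seeds (null
calibration); `scripts/acceptance.py` reports the same quantities from
2 strong-signal and 6 null screens plus one worm experiment at
500 worms/arm, sizes chosen so the whole script completes in a few
minutes on one core.

## Known limitations

- The model gate's metrics inherit the feature-selection optimism
  described above; they should be read as internal consistency checks,
  not generalization estimates.
- The hypergeometric population treats a drug's M predictions as
  draws from the pooled prediction distribution; predictions from the
  same drug share fold changes and are not independent, so the
  enrichment p is a ranking statistic more than a calibrated tail
  probability (its null calibration is nevertheless verified
  empirically).
- Synthetic cohorts have independent genes and no batch structure;
  the amplitude-to-fold-change conversion of real perturbation
  databases is out of scope (fold changes are consumed directly on
  the linear scale).
- The index rescaling ("rescaled" mode) makes indices comparable
  across models but dependent on each column's extremes; "plain" mode
  avoids this at the cost of comparability.
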