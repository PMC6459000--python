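# geroscreen

A tested, reusable implementation of a transcriptomics-based screen
for **geroprotectors** — compounds that push a transcriptome toward a
"young" state — together with the organismal validation analytics
(worm survival and population-activity curves) used to confirm
candidates in *C. elegans*.

## Who this is for

Computational biologists who want to (a) train binary young-vs-old
age classifiers from an age-stratified expression cohort, (b) score a
database of drug-perturbation fold changes by how strongly each drug
shifts a prototype "middle-age" transcriptome toward a young
classification, (c) rank drugs by cross-model enrichment, and (d)
analyze lifespan-machine output (survival tables and
`animal_position.csv` position logs). A synthetic-data module
generates cohorts, perturbation tables, known-geroprotector sets and
worm experiments with the statistical structure the analysis assumes,
so the entire pipeline runs and is tested without any data download.

## The method

1. **Preprocessing** — per-sample normalization to 10⁶ reads, removal
   of genes with RPKM < 0.1 in ≥ 80% of samples, log2(x+1),
   a RIN ≥ 6 + usable-flag quality gate, and partitioning by
   (tissue, gender, decade age bin).
2. **Age classifiers** — for each tissue/gender, each young bin
   (20-29 … 50-59) vs the fixed old bin 60-69 (both sides ≥ 10
   samples). Genes are intersected with the perturbation universe,
   pruned of the 10% least abundant, then of genes failing a
   per-gene pooled-variance t-test at p < 0.01. Classes are balanced
   by downsampling; a stratified 70/30 split is made; per-gene
   center/scale constants come from the 70% split; a 500-tree random
   forest is tuned over an mtry grid by repeated stratified 10-fold
   CV maximizing ROC-AUC. Models pass only if CV ROC-AUC, CV
   sensitivity, CV specificity, test ROC-AUC and test accuracy all
   exceed 0.75.
3. **Drug scoring** — per model, a middle-age prototype
   m_g = (median young_g + median old_g)/2; linear fold changes act as
   x → f·x in linear space and are re-logged; the model returns
   P(young); per drug and model the best instance is kept; indices are
   centered at 0 and rescaled per model to a maximal amplitude of 0.5
   (the *geroprotective index*).
4. **Ranking** — a drug is *supported* by a model when its index
   exceeds the mean absolute deviation of the pooled index
   distribution; support counts are tested with an upper-tail
   hypergeometric law against the pooled predictions and corrected by
   Benjamini–Hochberg; candidates are drugs with q ≤ 0.05, validated
   against a known-geroprotector set with a one-sided Fisher exact
   test.
5. **Worm analytics** — Kaplan–Meier curves and medians
   (S(t) ≤ 0.5 convention, ≥ 50 worms per arm), unweighted log-rank
   tests, median-lifespan percent change, and normalized population
   activity curves from Pearson correlations of adjacent binary
   worm-position frames (spline-smoothed, mirrored to [0, 1],
   clamped outside the active window).

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and known limitations (including the feature-selection
leakage caveat inherited from the original recipe).

## Worked example

```python
from geroscreen.pipeline import PipelineConfig, execute_screen

result = execute_screen(PipelineConfig(seed=1))
labels = result.truth_labels
print("passing models:", len(result.passing_models))
print("candidates:", len(result.candidates))
rejuv = set(labels[labels == "rejuvenating"].index)
print("planted rejuvenators recovered:",
      len(rejuv & set(result.candidates)), "/", len(rejuv))
```

prints

```
passing models: 12
candidates: 10
planted rejuvenators recovered: 10 / 10
```

i.e. on the default synthetic conditions (4 tissues × 4 age bins ×
30 samples, 1,000 genes with 100 aging genes; 200 drugs of which 10
are planted full-reversal rejuvenators) all 12 tissue/bin classifiers
pass the quality gate and the q ≤ 0.05 candidate list is exactly the
10 planted rejuvenators.

The same screen is available from a shell:

```bash
geroscreen run --out run1 --seed 1         # end-to-end
geroscreen simulate --out sim --seed 1     # write synthetic inputs
geroscreen worm --survival sim/survival.csv \
    --positions sim/animal_position.csv --out worm1
```

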