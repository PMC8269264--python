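# bariomics

Analysis pipeline for longitudinal gut-microbiome cohorts around bariatric
surgery: it asks whether the stool microbiome of obese patients *before any
treatment* carries enough signal to (a) separate patient groups, and (b)
predict how much body-mass index (BMI) a patient will lose months after
surgery — and how the community rearranges itself over the surgical course.

It is written for microbiome/biostatistics practitioners working with
16S rRNA feature tables (QIIME2-style exports) and per-sample clinical
metadata, and for methodologists who want every stage verifiable against
simulated ground truth.

## The model

Starting from a samples × features relative-abundance table with
Greengenes-style lineages, the pipeline applies

1. **Normalization** — features are averaged into genera, contaminant
   lineages (`Thermi`, `S24-7`, `Chloroplast`) removed, taxa present in
   fewer than 5 samples dropped, then `x → log10(x + 0.1)` and per-taxon
   whitening `z = (x − μ)/σ`.
2. **Decomposition** — PCA on the z-scored table over *all* samples (every
   obese time point plus the lean controls) gives one shared score space;
   the first 8 PCs are kept. PCs are screened against BMI, age, gender and
   A1C by Spearman correlation with Benjamini–Hochberg correction per
   covariate.
3. **Classification** — a linear SVM on the 8 PC scores separates lean (H)
   from obese and pre- (A, B) from post-surgery (C, D, E) samples; the ROC
   AUC is calibrated by scrambling class labels (add-one permutation
   p-value, 1000 scrambles).
4. **Outcome prediction** — for each subject, the enrollment (time-point A)
   score vector enters an L1-penalized regression of
   ΔBMI = BMI(6/12/18 months) − BMI(A), validated leave-one-out with the
   penalty chosen by nested inner LOO (one-SE rule). Reported: per-subject
   out-of-fold predictions, fold-averaged coefficients, the median-split
   ROC AUC with permutation p, and Spearman ρ(predicted, observed).
5. **Dynamics** — within-subject steps between consecutive sampled time
   points define y_i = x_i(t+1) − x_i(t); for every taxon *i* an OLS
   regression y_i ≈ Σ_j β_ji x_j(t) is fitted, and coefficients surviving
   Bonferroni at α = 0.05 over all taxa² tests become the directed signed
   interaction network (largest weakly connected component reported).

A synthetic-cohort generator (`bariomics.synthetic`) emulates the study
design — 83 lean / 66 obese subjects, five time points with attrition,
heavy-tailed abundances, latent subject factors driving the BMI outcome,
and linear log-scale dynamics with a known sparse interaction matrix — so
every stage is tested by parameter/structure recovery.

## Worked example

```python
import bariomics as bm

# simulate a cohort with known ground truth
table, meta, truth = bm.generate_cohort(bm.CohortSpec(seed=1))

ztable = bm.normalize_pipeline(table)            # collapse/filter/log/z-score
model  = bm.fit_pca(ztable, n_components=8)
scores = bm.project(ztable, model)
meta   = meta.loc[scores.sample_ids]

labels = bm.contrast_labels(meta, "lean_vs_obese")
clf = bm.GroupClassifier(scores, labels).fit(n_perm=1000, seed=1)
print(f"lean vs obese AUC {clf.auc:.3f}, permutation p {clf.p_perm:.4g}")

outcome = bm.OutcomeModel.from_scores(scores, meta, horizon="6m")
fit = outcome.fit(n_perm=1000, seed=1)
print(fit.summary())
```

prints:

```
lean vs obese AUC 1.000, permutation p 0.000999
BMI-change prediction, horizon 6m (delta = follow-up − baseline; negative = loss)
  subjects: 66
  median-split AUC: 0.943 (permutation p = 0.000999, 1000 scrambles)
  Spearman rho(predicted, observed): 0.866 (p = 5.811e-21)
  mean LOO coefficients:
       PC1: +0.0000
       PC2: -0.8598
       PC3: -0.9868
       PC4: +0.0000
       ...
```

Reading this: the microbiome separates lean from obese samples perfectly
out of fold (AUC 1.0; no scramble of the labels ever did as well, so p is
at its floor 1/1001). Presurgery PC scores predict the 6-month BMI change
of held-out subjects well above chance (median-split AUC 0.94, ρ = 0.87),
and the LASSO kept exactly the two PCs (`fit.support == ['PC2', 'PC3']`)
that track the generator's two outcome-linked latent factors — the
structure the cohort was built with.

The same flow is available from the shell:

```bash
bariomics simulate --seed 17 --out-dir sim/
bariomics normalize --table sim/feature_table.tsv --taxonomy sim/taxonomy.tsv --out z.tsv
bariomics decompose --ztable z.tsv --meta sim/metadata.tsv --out-scores scores.tsv
bariomics classify --scores scores.tsv --meta sim/metadata.tsv \
    --contrast lean_vs_obese --nperm 1000 --seed 17 --out clf.tsv
bariomics predict --scores scores.tsv --meta sim/metadata.tsv --horizon 6m --out pred.tsv
```

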