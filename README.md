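# methdex

Gene-level promoter-vs-body methylation scoring (**SIMPO**), a
**methylation-derived depression index (mDI)** built from it, and a downstream
**breast-cancer risk model** that combines the index with blood cell
proportions — as a tested, reusable pipeline exercised on synthetic
Illumina-450K-style cohorts.

## Who this is for

Epigenetics researchers working with probe-level DNA methylation beta values
(probes × samples, values in [0, 1]) who want a per-gene summary that contrasts
promoter methylation against gene-body methylation, a case/control risk index
derived from those summaries by resampling-based feature selection, and a way
to validate a frozen index on new cohorts — without touching probe-level
machinery downstream.

## The statistics at the core

**SIMPO score** — for one gene in one sample, with x the beta values of its m
promoter probes (TSS1500/TSS200) and y the beta values of its n other-region
probes (5'UTR, 1stExon, gene body, 3'UTR), the score is the pooled two-sample
t statistic

```
score = (x̄ − ȳ) / (S_w · √(1/m + 1/n)),   S_w² = [(m−1)S₁² + (n−1)S₂²] / (m+n−2)
```

**Gene selection** — 90% of samples are drawn (stratified, without replacement)
300 times; per draw, each gene's SIMPO values are compared between cases and
controls with a pooled t-test and the 50 smallest-p genes score one
*occurrence*. Genes are ranked by occurrence count.

**mDI** — the top-K ranked genes are split by the sign of their mean
case-control t into a positive and a negative set; a sample's index is a
Welch-style contrast of its SIMPO values over the two sets,

```
mDI = 1 + (x̄ − ȳ) / √(S_x²/n + S_y²/m)
```

K is fixed by sweeping 10–500 and keeping the K whose index has the highest
point-biserial (Pearson) correlation with the case label. The frozen gene sets
and K transfer verbatim to validation cohorts.

**Cancer risk model** — per follow-up year, cumulative cases vs never-diagnosed
controls are modelled by bidirectional stepwise logistic regression (deviance
tests, entry p < 0.05, removal p > 0.10) over seven z-scored predictors — mDI,
monocyte/granulocyte/lymphocyte proportions, CD4/CD8, NLR, MLR — and their 21
pairwise interactions, plus a random-forest comparator and top-vs-bottom
quartile odds ratios of the mDI.

## Worked example

```python
import methdex as mx

cfg = mx.SimulationConfig(rng_seed=1)          # 1,000 genes, 50 causal, 150/150
beta, ann, pheno, truth = mx.generate_methylation_cohort(cfg)
model = mx.DepressionIndexModel.from_cohort(beta, ann, pheno)
res = model.fit(n_iter=100, seed=7)
print(res.summary())

val = mx.SimulationConfig(rng_seed=2)          # independent cohort, same law
beta2, ann2, pheno2, _ = mx.generate_methylation_cohort(val)
simpo2 = mx.simpo_matrix(beta2, mx.build_gene_region_index(ann2, beta2))
report = res.evaluate(res.score(simpo2), pheno2)
print(f"validation AUC = {report.auc:.3f}, r = {report.pearson_r:.3f}")
```

prints

```
Methylation-derived depression index (mDI)
==============================================
chosen K:                 44
  positive genes:         23
  negative genes:         21
training point-biserial r: 0.9739 (p = 7.59e-194)
training AUC:             1.0000
case-control t:           73.996 (p = 7.59e-194)
OR (median split):        90601.000 [1785.965, 4596137.147]
OR (Q4 vs Q1):            22801.000 [446.572, 1164169.350]
samples:                  150 cases / 150 controls
provenance:               seed=7, n_iter=100, fraction=0.9, top_n=50, k_min=10, k_max=500
validation AUC = 1.000, r = 0.973
```

The simulated promoter shift (d = 1.0 on the logit scale) is deliberately
strong, so the index separates the classes essentially perfectly: the sweep
settles at K = 44 (close to the 50 genes that actually carry signal), the sign
partition matches the simulated shift directions, and — the part that matters —
the *frozen* index keeps its full discrimination on an independent cohort.
`res.plot_k_curve()` shows the correlation-vs-K curve the sweep maximised.

The same objects drive the command line:

```
methdex simulate --config sim.yaml --outdir cohort/
methdex simpo    --beta cohort/beta.tsv --annotation cohort/annotation.tsv --out simpo.tsv
methdex select   --simpo simpo.tsv --pheno cohort/phenotype.csv --seed 17 --out sel.tsv
methdex mdi      --simpo simpo.tsv --selection sel.tsv --pheno cohort/phenotype.csv --out model.json
methdex score    --model model.json --simpo simpo.tsv --out scores.csv
methdex evaluate --scores scores.csv --pheno cohort/phenotype.csv --out report.json
methdex predict-cancer --scores scores.csv --pheno prospective.csv --out cancer.json
```

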