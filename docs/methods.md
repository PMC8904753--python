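# Methods

This note documents the statistical procedures `methdex` implements, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the package's known limitations.

## SIMPO: a per-gene promoter-vs-body contrast

Each gene's probes are partitioned by the Illumina manifest region labels:
*promoter* = {TSS1500, TSS200}, *other* = {5'UTR, 1stExon, Body, 3'UTR}. A
probe annotated to both a promoter and a non-promoter group of the same gene
contributes to **both** sides; manifests genuinely multi-label probes and
dropping them would silently shrink the side counts. Region membership comes
from the labels only — no genome coordinates or strand handling.

For one gene in one sample the score is the pooled two-sample t statistic of
promoter vs other beta values, with unbiased (count−1) variances and the
pooled variance S_w² = [(m−1)S₁² + (n−1)S₂²]/(m+n−2), i.e. the textbook form
implied by the t(m+n−2) reference distribution. Consequences:

* **min_probes = 2 per side** (default): both variance terms are undefined for
  singleton sides; genes failing this are excluded when the region index is
  built.
* **Missing beta values are dropped per (gene, sample, side)**, not imputed —
  the simplest defensible policy; per-sample side counts are re-derived from
  the non-missing values.
* **Zero pooled variance ⇒ invalid cell (NaN)**, not ±∞: a constant-
  methylation gene carries no contrast, and infinities would poison every
  downstream statistic. "Zero" is tested against a numerical floor of 1e-24
  because a constant side can leave float noise of order 1e-33 in the
  two-pass variance.
* Genes invalid in more than 5% of samples (default) are dropped with a
  warning before any selection sees them.

No p-value is attached to SIMPO scores; the score is used as a quantitative
trait.

## Resampling gene selection

Each of `n_iter` (default 300) iterations draws `fraction` (default 0.9) of
the samples **without replacement, stratified by case/control label** —
stratification prevents degenerate class imbalance in small cohorts. Per
iteration every gene gets a pooled two-sample t (cases − controls) over its
valid SIMPO cells; genes with fewer than two valid cells in a class get the
sentinel (t = 0, p = 1). The `top_n` (default 50) genes by ascending p score
one occurrence; ties break by larger |t|, then gene symbol, so the whole
procedure is bit-reproducible from its seed.

`mean_t` averages each gene's t over **all** iterations, not only those where
the gene entered the top list: every iteration computes genome-wide t-scores,
and conditioning on top-list membership would bias |mean_t| upward. The final
ranking sorts by occurrence count, then |mean_t|, then symbol.

## The mDI and the K sweep

The top-K ranked genes are split by the sign of `mean_t` (exactly 0 goes to
the positive set). A sample's index is 1 plus the Welch-style contrast of its
SIMPO values over the positive vs negative set — the Welch denominator
(S_x²/n + S_y²/m) is used here deliberately, in contrast to the pooled form
inside SIMPO, and the "1 +" offset makes mDI = 1 mean "no contrast". Samples
with fewer than two valid genes on either side are flagged, never silently
scored.

K is swept inclusively in steps of 1 (default 10–500, clamped to the ranked
list) and the K with the **highest signed point-biserial correlation** between
the index and the 0/1 label is kept; ties go to the smallest K (parsimony).
Signed, not absolute, correlation is correct because the sign partition
already orients the index with cases high. The sweep is computed from
rank-ordered cumulative sums (counts, sums, sums of squares per sign), which
makes the full curve O(genes × samples) and is cross-checked in the tests
against explicit per-K scoring at 1e-8.

Two properties of this selection rule are worth knowing:

* **Training correlation is optimistically biased.** The resampling step
  already looked at the labels, so even on signal-free cohorts the training
  r at the chosen K is large (≈0.5–0.65 at 300 samples). This is why
  validation uses the **frozen** gene sets and K — nothing is re-selected on
  new data — and why the null-calibration tests judge the index on held-out
  cohorts and against a label-permutation null of the whole
  selection-plus-sweep pipeline (Monte-Carlo permutation p-value with 39
  permutations).
* **The chosen K overshoots the causal-gene count.** Past the causal prefix,
  noise genes ranked high by the resampling still carry label-correlated
  noise in-sample, so the training-r curve creeps upward before it declines
  and the maximiser lands ~1.5–2× above the number of genes that truly carry
  signal. The full curve is exposed (`DepressionIndexResults.curve`,
  `plot_k_curve`) so a plateau heuristic can be applied manually when a
  parsimonious K matters.

## Evaluation statistics

Pearson r with a 0/1 label (point-biserial) is reported with the two-sided p
from t with n−2 df, which is algebraically identical to the pooled two-sample
t-test p — the tests assert agreement to 1e-9 as an internal cross-check. AUC
uses the Mann-Whitney formulation with ties counting 1/2. Because a published
odds ratio rarely states its dichotomisation, three ORs are computed: a median
split (ties at the median go low), top-vs-bottom quartile (quartile cuts at
the empirical 25th/75th percentiles, boundary ties to the lower bin), and a
per-SD logistic OR that needs no cut. CIs are Woolf (log-normal) with the
Haldane-Anscombe 0.5 correction on zero cells (flagged in the report). An
optional bootstrap AUC CI (seeded, 2,000 resamples by default in the CLI) is
provided instead of a DeLong interval.

## Cancer risk model

Per follow-up year y ≥ 3 (years with fewer than 10 cumulative cases are
skipped), cases are participants diagnosed by year y and controls are
participants cancer-free through the final follow-up. Predictors — mDI, mono,
gran, lympho, CD4/CD8, NLR (gran/lympho), MLR (mono/lympho) — are z-scored
with the (n−1) SD **on each year's modelling subset**; interaction columns are
products of the z-scored parents, not re-standardised.

Stepwise selection is bidirectional over the 7 main effects and all 21
pairwise interactions, driven by deviance (likelihood-ratio) chi-square tests
with entry p < 0.05 and removal p > 0.10 — the documented defaults of the
classical stepwise-GLM routines. Adding an interaction pulls in missing
parents in the same step (the entry test then has one df per added column),
and a parent is never removed while one of its interactions remains, so a weak
main effect can legitimately sit in the final table with a large p purely to
support an interaction. Ties on p break by term name; candidate order cannot
change the result. The reported table carries Wald statistics; deviance tests
only drive selection. Age can be forced into the model via `forced=`; default
off. If any working fit shows |coefficient| > 15 on the z scale (separation),
the fit is flagged and redone with a ridge penalty of λ = 1e-6 via penalised
IRLS (no penalty on the intercept).

**Familywise behaviour under the null.** With 28 candidates tested at
p_enter = 0.05, the probability that at least one spurious term enters a
signal-free cohort is large — about 0.5 as measured here (the single-test
bound 1 − 0.95²⁸ ≈ 0.76 is diluted by the multi-df entry tests that hierarchy
imposes on interactions). The per-candidate entry test is calibrated (type-I
≈ 0.05, verified by simulation), but the *procedure* is not a familywise-
controlled test and the final model on weak data should be read accordingly.

McFadden pseudo-R² (1 − ll/ll_null) quantifies fit; the contribution of the
mDI is assessed by removing it and every interaction containing it and
reporting the pseudo-R² drop with the likelihood-ratio p of the removed block.
The random-forest comparator (500 trees, seeded) uses the 7 main effects only,
with stratified 5-fold cross-validated AUC and permutation importances (20
shuffles, scored by AUC).

## Synthetic cohorts

The methylation generator emulates exactly the structure the analysis assumes:
per gene, 2–8 promoter and 2–8 other probes (uniform), probe-level mean
methylation on the logit scale around a hypomethylated promoter baseline (−1.0)
and a more-methylated body baseline (+0.5) with probe-mean spread 0.5; a
sample's beta is the inverse logit of the probe mean plus N(0, 0.5) noise,
clipped to (0.001, 0.999) to keep logits finite; 1% of entries go missing at
random. *Causal* genes (default 50 of 1,000, directions alternating up/down so
both sides of the sign partition are exercised) shift their **promoter probes
only** by ±d (default d = 1.0, logit scale) in case samples — shifting both
sides equally would, by construction, produce no SIMPO signal, and that is
itself a test. The array design (probe counts and means) is drawn from a
separate fixed design seed so cohorts that differ only in the sampling seed
share a manifest and a frozen index transfers meaningfully; cohort sizes
default to 150 cases / 150 controls.

The cancer generator draws (mono, gran, lympho) from a Dirichlet(8, 60, 30)
(granulocyte-dominated blood), a log-normal CD4/CD8 ratio (median 1.8,
log-SD 0.35), and a binary outcome from
logit p = −0.59 + 0.6037·z(mDI) + 0.5579·z(mDI)·z(CD4/CD8)
— an intercept matching a ~36% final cumulative incidence over 11 follow-up
years, with diagnosed samples given a uniform diagnosis year in 1..11.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: type I/II probe chemistry and normalisation artifacts,
batch effects, detection-p failures, spatial correlation between neighbouring
probes, cell-composition effects on methylation itself (cell proportions are
independent covariates here), age/sex effects on methylation, and informative
censoring in the prospective cohort. Tests on these cohorts establish that the
*procedures* are implemented correctly and behave as designed under their own
assumptions, not that the index has any particular power on real cohorts.

## Numerical and testing choices

* Variance floor 1e-24 (see above); mDI denominators use its square root.
* All resampling, sweeping and model fitting is bit-reproducible from the
  seeds recorded in each result's provenance; the CLI pipeline is tested to be
  bit-identical across runs.
* Deterministic tie-breaks everywhere: p, then |t|, then gene symbol inside
  iterations; occurrence, then |mean_t|, then symbol for the final ranking;
  smallest K on sweep ties; term name in stepwise scans.
* Test problem sizes: formula oracles run 1,000 random inputs against
  independent scipy recomputations at 1e-10; signal recovery uses the default
  generator conditions with 100 resampling iterations; null calibration runs
  50 replicates of 300-gene cohorts (train 150/150, held-out 300/300, 39
  permutations each); stepwise behaviour uses 100 replicates at n = 650 and
  1,000 single-candidate replicates for type-I calibration.

## Known limitations

* The stepwise procedure's familywise false-entry rate under a global null is
  ~50% with the full 28-candidate set (see above); it is a selection
  heuristic, not a test.
* The K chosen by training-correlation maximisation overshoots the number of
  truly informative genes; use the exposed curve if parsimony matters.
* Odds ratios depend on the dichotomisation; all three reported modes answer
  slightly different questions.
* Cell proportions are consumed as given covariates; estimating them from
  methylation is out of scope.
* No survival modelling: the prospective cohort is analysed as per-year binary
  cohorts, which discards time-to-event information.
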