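# Methods

This note documents the statistical model behind `dpbm`, the choices made
where the procedure admits more than one reasonable reading, the synthetic
data the tests rely on, and the package's known limitations.

## Problem setting

A cohort of tumour samples carries (i) a log-scale expression matrix
(genes × samples, assumed pre-normalised and complete) and (ii)
right-censored follow-up for one organ-specific metastasis event — a
sample is an *event* when the organ of interest (bone, in the motivating
application) is the **first** metastatic site, and censored otherwise
(no metastasis, or first metastasis elsewhere). The goal is a
binary high/low risk stratifier whose risk groups differ in
metastasis-free survival, built from pathway-coherent gene sets. Because
censoring makes a case/control dichotomy lossy, all per-gene screening
uses Cox proportional-hazards regression on the full follow-up rather
than a t-test on thresholded labels.

## Pipeline stages

### 1. Bootstrap Cox stability selection (`gene_selection`)

Defaults: `n_runs = 400`, `subsample_fraction = 0.75` (without
replacement), `per_run_alpha = 0.05`, `stability_threshold = 0.80`.
Per run one subsample is drawn and shared by every gene; each gene gets a
univariate Cox fit on it. A gene's *stability* is the fraction of runs
with Wald p < 0.05; genes with stability **strictly** above 0.80 are
candidates. Mean coefficient and mean p are taken over **all** runs,
including non-significant ones. Interpretation choices:

* "randomly selected 3/4 of the samples" is read as subsampling without
  replacement (`replace=True` switches to a classical bootstrap);
* a run in which a gene's fit fails to converge (monotone likelihood,
  iteration cap) counts as non-significant for that gene in that run —
  conservative, and it keeps the run count identical across genes;
* a subsample with zero events carries no partial-likelihood information
  and is redrawn (the redraw count is reported).

### 2. Hypergeometric enrichment (`enrichment`)

A pathway with `N` measured genes is dysregulated when the **upper** tail
P(X ≥ x) of Hypergeometric(M, K, N) falls below `alpha = 0.05`, where `x`
is its overlap with the `K` candidates and `M` the universe size. The
upper tail (not the CDF) is the only direction consistent with calling
overlaps of 5–12 genes significant. The tail is accumulated in log space
(log-gamma binomial coefficients, log-sum-exp), exact to ~1e-13 relative
error against integer-arithmetic enumeration for all M ≤ 60.

Open choices, resolved as:

* **Universe `M`** defaults to the measured genes that appear in at least
  one pathway (both candidate status and membership are defined only
  there); `universe="measured"` uses all measured genes instead.
* Raw p-values, no multiple-testing correction, matching the procedure's
  published form; a Benjamini–Hochberg flag exists for users.
* `min_size = 5` measured genes per pathway, to avoid one-gene
  "pathways"; size filtering is otherwise unspecified.

### 3. Per-pathway sub-models and the ensemble (`dpbm_model`)

A sub-model's score is the unweighted signed sum of its dysregulated
genes' expression, positive-coefficient genes adding and
negative-coefficient genes subtracting (grade-index style; the signed-sum
form is reconstructed from the grade-index precedent and the stated roles
of the positive/negative genes). Deliberately **unweighted**: coefficient
magnitudes are noisy under bootstrap averaging, signs are stable.

Threshold selection is 10-fold cross-validation. Per fold, on the k−1
training folds: `n` = number of event-free patients there, candidate
threshold = n-th smallest training-fold score (order statistics on the
sorted multiset, duplicates counted, no interpolation). The held-out fold
is labelled by that threshold and its log-rank p recorded; the candidate
with the smallest **held-out** p wins, ties breaking toward the smaller
threshold. Held-out evaluation was chosen over whole-training-set
evaluation to avoid optimistic bias; a fold whose predicted groups are
degenerate records p = 1. Votes are strict (`score > threshold`), and the
final label is high-risk iff strictly more than half the sub-models vote
high — an even split is low-risk. Genes absent from the expression matrix
are dropped from a sub-model at build time, never imputed; a pathway left
with no signed genes is dropped with a warning.

### 4. Evaluation (`evaluation`)

Risk groups are summarised by the Mantel–Cox log-rank test
(hypergeometric variance per distinct event time, χ² with 1 df), the
hazard ratio exp(β) of an indicator Cox fit with Wald 95% CI, and
Kaplan–Meier curves. Because predicted groups are usually imbalanced,
`balanced_resample_eval` re-draws `m = min(n_high, n_low)` samples
without replacement from each group per repeat (default 1000 repeats) and
reports arithmetic means of per-repeat hazard ratios and log-rank
p-values (a geometric-mean HR accessor exists; repeats with monotone
likelihood are excluded from the HR mean with a warning).

### 5. Network topology (`network_topology`)

Degree and exact Brandes betweenness (normalized 2/((n−1)(n−2)), computed
per component with global normalization) of the dysregulated genes are
compared against (a) the remaining candidates and (b) all remaining
network genes, with the Mann–Whitney–Wilcoxon test (two-sided by default;
a one-sided "greater" mode serves directional claims). Genes absent from
the network are excluded and counted. The Mann–Whitney p is invariant to
the monotone normalization, so the normalization choice cannot change any
conclusion.

## Statistical primitives (`survival_stats`)

* **Univariate Cox**: Newton–Raphson with step-halving on the partial
  likelihood; Efron tie correction by default (better than Breslow with
  the tied follow-up times of discretised clinical data; `ties="breslow"`
  available). Convergence at |Δβ| < 1e-8, cap 50 iterations. p-values are
  two-sided Wald. Zero-variance covariates return the non-informative fit
  (β = 0, p = 1) flagged rather than raising; |β| > 15 is treated as
  monotone-likelihood divergence and flagged non-converged. A vectorised
  multi-gene fitter shares one risk-set layout across thousands of genes
  (the bootstrap selector's workhorse) and is tested to agree with the
  scalar path and with an independent grid-search maximiser to 2e-4.
* **Mann–Whitney**: exact tie-aware permutation distribution by dynamic
  programming when both samples have ≤ 12 observations; tie-corrected
  normal approximation with continuity correction otherwise.

## Synthetic data (`synthetic_data`)

The generator emulates the merged multi-study breast-cancer cohort shape
the method targets: defaults `n_samples = 569`, `n_genes = 2000`,
`n_signal_genes = 20`, `censoring_rate = 0.703` (≈30% observed events),
50 pathways of 15–40 genes with 3 planted enriched pathways. Expression
is independent standard normal per gene; event times follow a
proportional-hazards model with cumulative hazard
`baseline_hazard · exp(Σ effect·x) · t^shape` (shape 1 = exponential, the
simplest Cox-consistent choice; a Weibull shape is exposed for robustness
checks); censoring is independent exponential with its rate calibrated so
the **expected** censored fraction equals `censoring_rate` given the
realised hazards (closed form for shape 1, numerical integration
otherwise). Non-planted pathways are drawn uniformly from the whole gene
universe so that the enrichment test's null behaviour is measurable; an
equicorrelation parameter can tie signal genes to a shared latent factor.
Passing an existing truth record to `simulate_cohort` draws an
independent cohort from the *same* population — the correct way to build
a matched test set.

What the generator does **not** emulate: platform/batch effects, the
heavy-tailed marginal distributions of real array data, gene–gene
correlation beyond the optional single-factor block, and informative
censoring. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted structure, not real-data
performance.

### A note on marginal attenuation

With many independent signal genes, each univariate Cox fit sees the
others as unobserved frailty: 20 genes at |β| = 0.8 leave ~12 units of
unexplained log-hazard variance, which attenuates each gene's *marginal*
coefficient to roughly 0.25–0.35 even though the conditional effect is
0.8. This is expected behaviour of proportional-hazards marginalisation
(non-collapsibility), not an estimation error — with a single planted
gene the estimator recovers β to within sampling error, which the test
suite verifies. It also means stability selection at the 0.80 threshold
recovers only the stronger-margin part of a dense signal; real
signatures' published coefficients (0.1–0.5) are consistent with such
attenuated marginal effects.

## Study sizes used by tests and the acceptance script

Test-time simulations are sized to make each property measurable with
comfortable statistical margins at desk scale: the selection-recovery
study uses 300 samples × 2000 genes with the full 400-run default; the
enrichment-calibration study uses 50 pathway collections; the end-to-end
separation study uses 50 replicates of a 400-sample, 300-gene cohort with
three planted pathways and 100 bootstrap runs; log-rank calibration uses
2000 null cohorts of 100 samples. The acceptance script repeats the same
studies (20–30 replicates where a mean is reported).

## Determinism

Every stochastic routine takes a seed; the pipeline fans one master seed
out to per-stage seeds via `numpy.random.SeedSequence` spawn keys, so a
run is a pure function of (inputs, config, seed) and each stage is
individually reproducible. Two runs with the same config and seed produce
byte-identical numeric outputs.

## Known limitations

* Univariate screening only — no multivariate or penalised selection, no
  FDR control across genes (stability filtering plays that role).
* The cohort split is unstratified by default (per-study or per-event
  stratification is a flag-level extension).
* No multivariate Cox, time-varying covariates, stratified log-rank,
  competing-risks handling, or probability calibration of the vote.
* Exact gene-identifier matching; no identifier-mapping service.
* No comparison classifiers (SVM, shrunken centroids) and no external
  annotation services; those analyses are out of scope.
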