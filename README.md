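# dpbm — dysregulated-pathway ensemble prediction of bone-metastasis risk

`dpbm` implements a pathway-level ensemble survival classifier for
predicting the risk of organ-specific metastasis (the motivating case is
bone metastasis in breast cancer) from a gene-expression matrix and
right-censored metastasis-free follow-up. It is written for computational
biologists who have an expression cohort with clinical follow-up, a pathway
collection (GMT, e.g. an MSigDB KEGG subset) and optionally a
protein–protein interaction network, and who want a risk stratifier whose
features are interpretable pathway gene sets rather than an opaque
signature.

## The method

1. **Candidate genes by bootstrap Cox stability selection.** For each of
   400 runs, subsample 3/4 of the training cohort without replacement and
   fit a univariate Cox proportional-hazards model per gene
   (Newton–Raphson on the partial likelihood, Efron tie handling). A gene
   is a *candidate* when its Wald p-value is below 0.05 in strictly more
   than 80% of runs; its coefficient and p-value are averaged over all
   runs.
2. **Dysregulated pathways by hypergeometric enrichment.** With `x` the
   overlap between a pathway and the candidates, `K` candidates, `N`
   measured pathway genes and `M` universe genes, a pathway is
   *dysregulated* when the upper tail P(X ≥ x), X ~ Hypergeometric(M, K, N),
   is below 0.05. The candidates inside it are its *dysregulated genes*.
3. **One sub-model per dysregulated pathway.** Its risk score is the
   unweighted signed sum (grade-index style)
   `RiskScore = Σ_{i: β̄_i>0} x_i − Σ_{j: β̄_j<0} x_j`,
   and its cut-off is picked by 10-fold cross-validation: per fold the
   candidate threshold is the n-th smallest training-fold score (n = number
   of event-free training-fold patients), and the fold with the best
   held-out log-rank p supplies the final threshold.
4. **Majority-vote ensemble.** A patient is high-risk iff strictly more
   than half of the sub-models vote high-risk. Risk groups are evaluated
   with the log-rank test, the two-group hazard ratio with 95% CI,
   Kaplan–Meier curves, and a balanced-resampling robustness check;
   dysregulated genes can additionally be compared with other genes on PPI
   degree and betweenness centrality (Mann–Whitney–Wilcoxon).

The survival primitives (univariate Cox, Kaplan–Meier, log-rank, exact
small-sample Mann–Whitney) are implemented in-package and cross-checked
against independent oracles in the test suite. The package also ships the
published eight-pathway bone-metastasis signature (35 unique genes with
signed Cox coefficients) as a reference table, `dpbm.datasets`.

## Worked example

`DPBMClassifier` follows the scikit-learn estimator API (`X` is samples ×
genes; `y` carries censored survival). On a synthetic cohort with three
planted pathways:

```python
from dpbm import DPBMClassifier, SimulationDesign, evaluate_groups
from dpbm.synthetic_data import simulate_cohort, simulate_pathways

design = SimulationDesign(
    n_samples=400, n_genes=300, n_signal_genes=8, effect_size=1.0,
    censoring_rate=0.65, n_pathways=20, pathway_size_range=(10, 20),
    n_enriched_pathways=3, enrichment_overlap=6, seed=7,
)
expr, surv, truth = simulate_cohort(design)
pathways, truth = simulate_pathways(design, truth)

clf = DPBMClassifier(pathways=pathways, n_runs=100, random_state=0)
clf.fit(expr.T, surv)
print("candidate genes:", len(clf.candidate_genes_))
print("dysregulated pathways:", [r.pathway_name for r in clf.enrichment_])

expr_test, surv_test, _ = simulate_cohort(design.with_seed(99), truth=truth)
labels = clf.predict(expr_test.T)
ev = evaluate_groups(labels == "high", surv_test)
print(f"high/low: {ev.n_high}/{ev.n_low}")
print(f"hazard ratio: {ev.hr.hr:.2f} (95% CI {ev.hr.ci_low:.2f}-{ev.hr.ci_high:.2f})")
print(f"log-rank p: {ev.logrank.p_value:.2e}")
```

prints

```
candidate genes: 10
dysregulated pathways: ['pathway_00', 'pathway_01', 'pathway_02', 'pathway_03']
high/low: 102/298
hazard ratio: 10.00 (95% CI 6.98-14.34)
log-rank p: 1.52e-51
```

The selector found 10 candidates (8 planted signal genes plus 2 chance
hits), the enrichment step recovered all three planted pathways (plus one
pathway that happens to overlap the candidates), and on an *independent*
cohort drawn from the same population the ensemble's high-risk group has
ten times the bone-metastasis hazard of the low-risk group.

The same pipeline is scriptable from the shell:

```bash
dpbm simulate --seed 5 --out sim/
dpbm run-all --config config.json        # split→select→enrich→train→predict→evaluate→topology
dpbm select --expression expr.tsv --clinical clinical.tsv \
     --runs 400 --fraction 0.75 --alpha 0.05 --stability 0.8 --seed 1 --out selection.tsv
```

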