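# nkdeconv

Natural-killer (NK) cells infiltrate solid tumors in distinct activation
states — resting, IL-2-expanded, and PDGF-DD-activated — and the balance of
these phenotypes carries prognostic information in bulk tumor RNA-seq.
`nkdeconv` implements the full computational chain needed to quantify such
phenotypes from bulk transcriptomes and to ask, *before* touching patient
data, whether the chain can detect survival-linked abundance changes at all:

1. **Reference modelling.** For every gene *g* and cell type *c*, replicate
   counts are modelled as negative binomial, `y ~ NB(mu_gc, phi)` with
   `Var = mu + phi mu^2`, offset by library size (CPM scale). An
   empirical-Bayes normal approximation on `log mu_gc` (prior mean = the
   gene's global log-CPM, prior sd = 2) yields equal-tailed 95% credible
   intervals that stay finite even for a single replicate or an all-zero gene.
2. **Hierarchical marker selection.** Cell types sit in a three-level
   taxonomy (24 leaves; epithelial / endothelial / fibroblast / immune at
   level 1, immune lineages at level 2, fine phenotypes — including the
   three NK states — at level 3). For every ordered pair (A, B) of siblings
   at each level, genes are ranked by credible-interval separation
   `lower95(A) − upper95(B)`; the top 5 / 10 / 20 positively-separated genes
   per pair (levels 1 / 2 / 3) are retained and their union forms the
   **signature matrix** (marker genes × 24 cell types, CPM scale).
3. **Deconvolution.** CIBERSORT-style linear nu-SVR (nu grid
   {0.25, 0.5, 0.75}, joint z-scoring, negativity truncation, sum-to-one
   renormalization) plus a non-negative least-squares oracle backend.
4. **Survival benchmark.** Simulated tissue mixtures — proportion-weighted
   sums of reference profiles, with the focal type's logit-share tied
   linearly to progression-free survival — are censored (time halved, event
   cleared for half the samples), deconvolved, and fed to one multiple Cox
   regression on logit proportions (Efron ties). Significance calls for the
   tracked IL-2-NK phenotype against ground truth yield per-condition ROC
   curves and AUCs over a grid of 81 conditions (replicates 250–1,000,
   slope −1..1, unknown "foreign" cell fraction 0–0.8) with 63 runs each.
5. **Clinical-style statistics.** Kaplan–Meier median splits, Mantel–Cox
   log-rank tests, Benjamini–Hochberg adjustment, two-variable (L/L…H/H and
   HH-vs-rest) strata, and rank-based grade comparisons.

All inputs are generated by the package's own synthetic-data module, whose
statistical structure (hierarchy-structured NB counts, right-skewed Weibull
survival times, an out-of-taxonomy foreign cell type) matches what the
analysis assumes, so every stage is testable offline; real expression and
clinical TSVs can be substituted at any stage.

## Worked example

```python
from nkdeconv import (
    gen_taxonomy, gen_reference_compendium, gen_survival_pool,
    fit_hierarchy_posteriors, select_markers, build_signature_matrix,
    SimulationCondition, run_benchmark,
)

tax = gen_taxonomy()                                   # 24-leaf hierarchy
comp = gen_reference_compendium(tax, seed=11)          # 1000 genes x 240 profiles
post = fit_hierarchy_posteriors(comp, tax)             # NB posteriors, all units
sig = build_signature_matrix(post, select_markers(post, tax), tax)
print(len(sig.genes), "x", len(sig.cell_types))        # -> 485 x 24

pool = gen_survival_pool(2000, seed=12)
res = run_benchmark(
    [SimulationCondition(n_replicates=1000, slope=1.0, foreign_prop=0.0)],
    comp, sig, pool, runs_per_condition=63, seed=20260919,
)
print(round(res[0].auc, 2))                            # -> 1.0
```

The signature has 485 marker genes because every ordered sibling pair at
levels 1/2/3 contributes exactly 5/10/20 cleanly separated genes and the
union de-duplicates them. The AUC of 1.0 says that with 1,000 mixtures, a
strong proportion–survival slope, and no unknown cell contamination, every
run in which the IL-2-NK phenotype truly changed received a smaller Cox
p-value than every run in which it did not. At slope 0 the same pipeline's
AUC sits near 0.5 (no false signal), and its type-I error at alpha = 0.05
is calibrated (see `tests/test_acceptance.py`).

The numbered scripts under `analysis/` run the same stages as a narrative —
reference generation, posterior fitting, signature assembly, a reduced
benchmark grid, and a median-split Kaplan–Meier analysis of a simulated
cohort — writing their summary tables under `results/`.

A `nkdeconv` command-line interface exposes the stages individually
(`simulate-reference`, `fit-model`, `select-markers`, `build-signature`,
`deconvolve`, `survival`, `benchmark`, `run-all`) for use on user-supplied
TSVs; see `nkdeconv --help`.

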