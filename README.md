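# oncodecon

Integrative analysis of driver lesions, gene expression, blood counts and
survival in cancer cohorts — built around the kind of data collected for
myelodysplastic syndromes (MDS) and AML: a log-scale expression matrix, a
binary matrix of recurrent point mutations and cytogenetic alterations,
diagnostic blood and bone-marrow counts with missing values, demographics
and right-censored (leukaemia-free) survival.

The package answers three questions:

1. **How do driver lesions reshape the transcriptome?**
   Each gene *k* is modelled additively,

       Y_ik = β_0k + Σ_j X_ij β_jk + ε_ik,   Var(ε_.k) = σ_k²,

   where `X` holds a disease indicator, one 0/1 column per recurrent
   lesion, sex and age. Residual variances are shrunk towards a shared
   scaled-inverse-χ²(d₀, s₀²) prior estimated across genes by closed-form
   moment matching on log variances, giving moderated t statistics per
   coefficient and a moderated F over the genomic block, with
   Benjamini-Hochberg FDR control, per-gene genomic R², per-lesion target
   gene sets, and a permutation scheme that verifies calibration.
   Co-mutation structure (Haldane-corrected odds ratios) is contrasted
   with the Jaccard overlap of target sets.

2. **How much of each blood count do lesions and expression explain?**
   Each clinical variable is mapped by a range-dependent transform
   (identity / log / logit), then LASSO-regressed on lesions, the leading
   expression principal components and demographics. The penalty maximises
   the fivefold cross-validated generalized R²,
   `R² = 1 − exp(−(2/n)(ℓ_model − ℓ_null))`, and the explained variance is
   attributed to covariate groups by signed covariance components.

3. **Which data class predicts outcome?** A Cox proportional-hazards model
   with a single shared ridge precision τ on all coefficients (chosen by
   inner cross-validated partial likelihood) is scored per data class by
   fivefold cross-validated Harrell's C. The variance of the fitted
   log-hazard r is decomposed exactly into generalized group components
   s_g = Σ_h Cov[r_.g, r_.h] with Σ_g s_g = Var(r). Genotype-predicted
   expression (PC scores regressed on the lesion matrix) is available as
   its own predictor class.

Because the raw study cohorts are external, the package ships a
synthetic-cohort generator (`oncodecon.simulate`) that reproduces the
statistical structure of such data — lesion co-occurrence/exclusivity,
sparse additive expression effects with inverse-χ² gene noise, latent
expression factors, link-transformed phenotypes with missingness, and
exponential survival with independent censoring — together with the full
generative truth, so every stage is testable end to end.

## Worked example

```python
from oncodecon.simulate import SimulationConfig, simulate_cohort
from oncodecon.deconvolution import build_design_matrix, GeneLesionDeconvolution

cfg = SimulationConfig(seed=42)          # 150 MDS + 17 normals, 2000 genes, 16 lesions
bundle, truth = simulate_cohort(cfg)
design = build_design_matrix(bundle, min_recurrence=5)
model = GeneLesionDeconvolution(fdr=0.05).fit(design, bundle.expression.values)

print("estimated prior: d0=%.2f  s0^2=%.3f" % (model.d0_, model.s0_sq_))
print("genes with q_F < 0.05:", int((model.q_f_ < 0.05).sum()))
sets = model.target_sets()
for lesion in ["SF3B1", "TP53", "del_5q"]:
    print(f"{lesion}: {len(sets[lesion])} target genes")
print("max genomic R^2: %.3f" % model.r2_["r2_genomic"].max())
```

prints

```
estimated prior: d0=4.41  s0^2=0.303
genes with q_F < 0.05: 190
SF3B1: 29 target genes
TP53: 27 target genes
del_5q: 23 target genes
max genomic R^2: 0.751
```

The estimated prior is close to the generative values (d₀=4, s₀²=0.25);
190 of 2000 genes are significantly associated with at least one driver
(moderated F, FDR < 0.05); each lesion's recovered target set is the
detectable subset of its 50 planted targets; and the best-explained gene
has three quarters of its expression variance attributable to genotype.

## Command line

```sh
oncodecon simulate   --seed 1 --out cohort/          # write cohort TSVs + truth
oncodecon run-all    --seed 1 --out run/             # all stages + report.md
oncodecon deconvolute --cohort cohort/ --out run/    # single stages...
oncodecon phenotypes  --cohort cohort/ --out run/ --pcs 20
oncodecon survive     --cohort cohort/ --out run/
oncodecon compare     --cohort cohort/ --out run/ \
    --classes genetic,expression,predicted-expression
oncodecon report      --run-dir run/
```

All outputs are deterministic TSV/JSON under the run directory, with a
`manifest.json` recording config and seed; re-running with the same seed
reproduces byte-identical files.

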