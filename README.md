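# glfd — guided latent factor discovery for gene expression

`glfd` finds **hidden per-sample factors that act together with observed
clinical factors to regulate a gene module**. In a study that pairs a gene
expression matrix *G* (p genes × n samples) with clinical factor scores
*B* (n × m) — treatment response, disease subtype, a measured outcome —
standard analyses keep only genes with a first-order relation to *B*. But
a biological response is usually coordinated: unobserved regulators (latent
factors *F*, n × r) can act in combination with the clinical factors on the
same module of genes,

```
G_module = L [B  F]ᵀ + E
```

with loading matrix *L* and residual noise *E*. `glfd` recovers such latent
factors while guaranteeing they are orthogonal to the clinical factors, so
they describe structure *beyond* the first-order response.

Intended users: computational biologists analysing bulk or single-cell
expression studies with clinical covariates, and methodologists studying
latent factor models for modular gene regulation.

## Method

Three steps, all driven by projection lengths of unit-length gene vectors
(for a standardized gene *g* and orthonormal basis *V*, `l = ‖Vᵀg‖`; under
independence `F = (l²/k)·(n−k−1)/(1−l²) ~ F(k, n−k−1)`):

1. **Guided residualization.** Standardize each gene row (mean 0, length 1)
   and whiten *B* into an orthonormal basis *B\**. Each gene's residual
   `r_i = g_i − B*(B*ᵀg_i)` is weighted by a steep sigmoid
   `w_i = 1 − 1/(1+exp(φ(l_i−δ)))` of its clinical projection length, with
   δ the exact F-test threshold at level α. Genes not significantly
   associated with the clinic are effectively removed from the search.
2. **Modular subspace search.** The weighted residual matrix, scaled by its
   longest row, is decomposed by an EM-style iteration: rows are re-weighted
   by their projection onto the current factor estimate, and factors are
   re-estimated as leading right singular vectors of the re-weighted matrix.
   Module dimensionality k is chosen either exhaustively over k = 1..K or by
   step-forward search; modules are extracted iteratively and projected out.
   Module membership is decided **leave-one-out**: a gene counts only if its
   projection length survives re-estimating the factors without that gene's
   own contribution.
3. **Overlap-based selection.** Back on the original expression matrix, the
   genes associated with *B\** and with each candidate factor set (F-test →
   Benjamini–Hochberg FDR at λ) are intersected and scored by a conservative
   hypergeometric tail probability with FDR-deflated counts
   (`m' = ⌈m(1−λ)⌉`, `r' = ⌊r(1−λ)²⌋`). Factor sets with significant
   overlap are retested factor by factor; only individually significant
   factors are retained.

A built-in simulator reproduces the benchmark design used throughout: 2000
genes × 100 samples, one 200-gene module driven by the clinical factor plus
0–3 latent factors, four background modules of 2–4 independent factors,
1000 pure-noise genes, standard-normal factor scores, Gaussian noise at
S/N 0.5 / 1 / 2.

## Worked example

```python
import glfd

# simulate one benchmark dataset: one latent factor co-regulating
# module 1 with the clinical factor, S/N = 2
cfg = glfd.SimulationConfig(snr=2.0, n_coreg_latent=1, seed=3)
expr, clinical, truth = glfd.simulate_dataset(cfg)

expr_std = glfd.standardize_genes(expr)
clin = glfd.whiten_clinical(clinical, sample_ids=expr.sample_ids)
result = glfd.fit_glfd(expr_std, clin)

for rf in result.retained:
    print(rf.label, f"overlap p = {rf.overlap.p_value:.3g}")
r2 = glfd.recovery_r2(truth.coreg_latent_scores[:, 0], result.retained_factors)
print(f"recovery R^2 = {r2:.3f}")
```

Output:

```
M1.F1 overlap p = 1.01e-73
recovery R^2 = 0.985
```

One latent factor is retained (first factor of the first extracted module);
its associated genes overlap the clinically associated genes far beyond
chance (p ≈ 10⁻⁷³), and a regression of the true planted factor on the
identified factor gives R² = 0.985 — the masked factor is recovered almost
exactly. On a null dataset (`n_coreg_latent=0`) the retained list is empty.

The same pipeline runs from the shell:

```bash
glfd simulate --outdir sim --seed 3 --snr 2.0
glfd run --expression sim/expression.tsv --clinical sim/clinical.tsv --outdir out
glfd evaluate-fpr --n-reps 100 --snr 1.0 --search-mode exhaustive
```

`glfd run` writes the retained factor scores, a module summary, per-gene
association tables, the overlap-test report and a machine-readable run
summary, all tab-delimited/YAML.

## Limitations

- Latent factors are orthogonal to the clinical factors by construction,
  so they do not help predict the clinical outcome; they are for
  interpretation and hypothesis generation.
- Factors are reported unrotated; post-hoc rotation (oblique, PCA) is left
  to the user.
- Comparator methods (partial least squares, supervised principal
  components) are not included.

See `docs/methods.md` for the model, parameter semantics, numerical
choices and known limitations.
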