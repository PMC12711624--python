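# omicsfactor

Multi-view latent factor analysis for cancer prognosis.

Tumour cohorts are increasingly profiled on several molecular layers at
once — somatic mutations, miRNA, mRNA, protein and phospho-site abundances.
`omicsfactor` is a pipeline for finding the **shared latent factors** that
drive covariation across those layers and turning one of them into a
portable prognostic score: it fits a multi-view factor model, projects new
cohorts onto the trained loadings, derives varimax-rotated gene signatures,
tests loading enrichment against gene sets, associates factors with
clinical variables, stratifies survival, and scores single cells for the
derived signature. It ships a synthetic-data generator with planted ground
truth, so every stage is testable end to end.

## The model

Each omics layer *m* is a samples × features matrix `Y_m` (z-scored;
mutations centred). The model decomposes all layers jointly as

```
Y_m ≈ Z W_mᵀ ,        m = 1 … M
```

with shared factor scores `Z` (samples × K), view-specific loadings `W_m`
and per-view residual variance τ_m, fitted by monotone MAP coordinate
ascent with ARD shrinkage that switches off unused factor–view pairs.
Missing entries — including whole missing layers for a patient — are simply
left out of the estimation. Downstream:

- **Projection**: a new cohort is scored by least squares,
  `Z_new = Y_new · pinv(Wᵀ)`;
- **Signature**: varimax-rotated loadings, genes with |weight| above a
  threshold (on the unit-max scale) and protein–mRNA correlation above a
  cut;
- **Enrichment**: competitive gene-permutation test of |loading| per gene
  set, BH-adjusted;
- **Survival**: Kaplan–Meier, log-rank, and Cox proportional hazards on
  score-stratified groups;
- **Single cell**: module score against expression-bin-matched control
  genes, summarised per cell type and tissue.

See `docs/methods.md` for the full model description and every numerical
convention.

## Worked example

The `demo` stage runs the whole chain on one synthetic cohort (200 samples,
four layers, five planted factors, one of them prognostic with log-hazard
−0.7) and reports how well each stage recovered the planted structure:

```sh
omicsfactor demo --seed 7 --out results/demo
```

or in Python:

```python
from omicsfactor.pipeline import run_demo
report = run_demo({"seed": 7}, "results/demo")
```

which prints (abridged):

```json
{
  "factor_recovery_mean_abs_corr": 0.9814,
  "variance_explained": {"mutation": 0.0742, "mrna": 0.6977, "protein": 0.6630, "phospho": 0.6663},
  "planted_signal_fraction": {"mutation": 0.0894, "mrna": 0.6939, "protein": 0.6577, "phospho": 0.6650},
  "projection_abs_corr_with_truth": 0.9945,
  "signature_n_genes": 31,
  "signature_precision": 0.9677,
  "signature_recall": 1.0,
  "enrichment_planted_p": 0.000999,
  "logrank_chi2": 32.41,
  "cox_hr_per_score_unit": 2.27,
  "sc_top_scoring_type": "myofibroblast",
  "sc_tumour_normal_positive_ratio": 5.13
}
```

Reading this: the five planted factor score vectors are recovered at mean
|r| ≈ 0.98 after one-to-one matching; per-layer variance explained matches
the planted signal fractions to ~0.02; a held-out 150-sample cohort
projected onto the frozen loadings reproduces its true prognostic scores at
|r| ≈ 0.99; the 30 planted signature genes are recovered at precision 0.97 /
recall 1.0 with thresholds (0.5, 0.5); the planted gene set hits the
permutation floor p = 1/1001; the median-split log-rank test strongly
separates survival and the Cox hazard ratio per score unit (2.27, i.e.
|log HR| ≈ 0.82) agrees with the planted effect (0.7) up to sampling noise —
the fitted factor's canonical sign is flipped relative to the planted one,
which is why the HR is above 1; and in synthetic single cells the planted
cell type scores highest, with ~5× more signature-positive myofibroblasts
in tumour than in normal tissue, matching the planted frequency design.

Individual stages (`simulate`, `preprocess`, `fit`, `project`, `signature`,
`enrich`, `associate`, `survive`, `score-sc`) run from a YAML config and
write versioned artifacts plus JSON manifests; `omicsfactor --help` lists
them.

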