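# Methods

## The model

`omicsfactor` analyses a cohort measured on several omics layers — somatic
mutation (binary), miRNA, mRNA, protein and phospho-site abundances — that
share a sample universe. The central object is a multi-view linear latent
factor model

    Y_m ≈ Z W_m',   m = 1 … M

with a shared samples × K score matrix `Z`, view-specific loading matrices
`W_m` (features × K) and per-view residual variance `τ_m`. Continuous views
are z-scored per feature before fitting; the mutation view is centred only
and modelled with the same Gaussian likelihood — a deliberate simplification
relative to a full non-Gaussian variational treatment, justified because the
binary layer is weak (planted signal ≈ 8% of its variance under the default
conditions, and only variance-explained summaries are consumed downstream).

Estimation is MAP coordinate ascent with exact updates:

- `Z` rows: ridge regression against all observed features of all views;
- `W_m` rows: ridge regression against `Z` over the samples observed for
  that feature;
- `τ_m`: mean squared residual over observed entries;
- ARD precisions `α_km` (one per factor-view pair): `α = D_m / Σ_d w_dk²`,
  clipped to a wide box. The ARD prior is scaled by the view weight so the
  shrinkage-to-likelihood ratio is identical in every view.

Missing entries — including whole missing views for a sample — are simply
excluded from every sufficient statistic; no imputation enters the fit
(zero-imputation is used once, for the SVD initialisation only). Each update
exactly minimises the penalized objective, so the objective is monotone
non-increasing per sweep (asserted in tests). Views are weighted by
1/√(feature count) so the largest layer cannot dominate the shared scores.
With `ard=False` all priors are dropped and the procedure reduces to
alternating least squares, whose fixed point on a single complete view spans
the top-K principal subspace (tested against an SVD oracle).

After fitting, the gauge is fixed deterministically: scores scaled to unit
sample SD (scale absorbed into loadings), sign set so each factor's
largest-|loading| entry is positive, columns ordered by descending total
variance explained.

### Key parameters

| parameter | default | rationale |
|---|---|---|
| `K` | 15 | conventional over-complete choice for ~5 active factors; ARD prunes surplus factors to exactly zero |
| `tol` | 1e-8 (relative objective change) | at 1e-6 the coordinate ascent stops while correlated factors are still disentangling: matched recovery on the default synthetic cohort is ~0.94 at 1e-6 vs ~0.98 at 1e-8 |
| `max_iter` | 2000 | the default cohort typically converges in 300–1000 sweeps; the cap bounds runtime (~10 s at 200 × 2900) |
| `ard` | on | needed whenever K exceeds the true factor count; a factor is considered inactive in a view when its R² < 1e-4 |

Variance explained per factor and view is
`R²[k,m] = 1 − SS(Y_m − z_k w_mk') / SS(Y_m)` over observed entries; the
per-view total uses the full reconstruction and the grand total is the
feature-count-weighted mean of per-view totals (the weighting is a
documented convention — no universally agreed "total" exists across
unequal-sized views).

## Cohort projection

A validation cohort is scored on frozen loadings by least squares:
`Z = Y pinv(W')`, the Moore–Penrose solution of `Y ≈ Z W'` (for one factor
this is `Y w / w'w`). `W` is non-square, so the pseudo-inverse is the only
coherent reading of "matrix inversion of the model weights". Singular values
below `rcond·σ_max` (default 1e-10) are truncated and the smallest retained
singular value is reported so users can detect ill-conditioned projections.
The new cohort is z-scored with its own means/SDs; features are matched by
exact id (optional case-fold/version-suffix normalisation, off by default).
Projecting all factors jointly and reading off the column of interest
removes cross-talk from correlated loadings and is what the demo pipeline
does; single-factor projection is available and agrees closely when
loadings are near-orthogonal.

## Varimax signatures

Loadings of a chosen view are varimax-rotated (SVD form of the classic
iteration; Kaiser row-normalisation off by default since nothing requires
it). Because rotation permutes and sign-flips columns arbitrarily, rotated
columns are re-matched to the input factors (Hungarian assignment on |R|)
so factor indices keep their meaning. The target factor's weights are then
oriented so the top feature loads **negatively** — ECM-programme factors
conventionally carry their top features with negative sign, and an
absolute-weight threshold on an unoriented column would be irreproducible —
and scaled to unit maximum |weight|, the scale on which thresholds such as
0.5 / 0.74 are meaningful. The signature is the genes with |rotated weight|
above the threshold, optionally filtered by protein–mRNA Pearson
correlation > 0.5 across common samples (cross-layer coherence). A stricter
weight threshold with no correlation filter gives the refined "focused"
variant.

## Loading enrichment

Gene-set enrichment of a factor's loadings is competitive and
permutation-based: the statistic is a pooled-variance two-sample t contrast
of |loading| between in-set and out-of-set genes, the null permutes gene
labels preserving set size, and `p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm)`
so p is never 0 and the floor is 1/(n_perm+1). |loading| is used because the
factor is single-signed after orientation. BH adjustment runs once across
all tested sets. An exhaustive mode enumerates every same-size subset for
tiny universes (used by the exactness tests). The t-contrast variant is this
package's documented choice among the family of competitive set statistics.

## Clinical association and survival

Factor–clinical associations use Pearson correlation with the two-sided
t-test on n−2 df; ordinal variables are integer-encoded (stage I–IV → 1–4;
MSS < MSI-L < MSI-H → 0–2; binary sex/metastasis → 0/1 — fixed conventions,
documented for reproducibility), multi-level categoricals go through
Kruskal–Wallis instead, and one BH pass covers the whole factor × variable
matrix. Pairwise-complete deletion handles missing clinical values, with the
pair count reported.

Survival uses lifelines: product-limit Kaplan–Meier curves, the two-group
log-rank test, and Cox proportional hazards with Efron tie handling
(lifelines' and the reference implementation's default; Breslow is not
exposed because the alternative backend reports no standard errors).
Separation / monotone-likelihood situations are flagged on the returned fit
rather than raised — small validation cohorts produce them routinely — and a
logged, explicit utility drops zero-event strata before multivariable fits.
An optional ridge penalty is available as a separation rescue, off by
default. Test oracles are independent of lifelines: hand O/E/V tabulation
for the log-rank statistic, a direct score-test identity on tie-free data,
and a 1e-4-step grid maximisation of the Efron partial likelihood.

## Single-cell module scoring

The module score of a cell is mean(signature expression) − mean(control
expression), with controls drawn per signature gene from its
dataset-average-expression bin (24 equal-frequency bins, 100 controls per
gene, the reference implementation's defaults; ties in average expression
broken by gene id; drawing is with replacement when a bin is small, and
signature genes are excluded from control pools). Bin matching cancels
depth/abundance effects, so a random gene set scores ≈ 0 and a constant
matrix scores exactly 0. Tissue-level positivity is reported as
(positive cells of the designated type) / (all cells of the tissue), with a
bootstrap 95% CI on the tumour/normal ratio — matching how "signature-
positive myofibroblast" abundance is compared between tissues. The
positivity threshold is a parameter (default 0): no principled universal
cut-point exists.

## The synthetic-data generator

The generator is the test surface: every downstream stage is validated
against its planted truth. It draws `Z` (n × K, standardised columns),
view-specific Gaussian loadings with 30% sparsity, a factor × view activity
mask, and emits continuous views `ZW' + N(0, σ²)` plus a binary view
`Bernoulli(logistic(ZW'))`. Defaults (chosen once, as the study
conditions): n = 200; views 300 (binary) / 1000 / 800 / 800 echoing the
mutation / mRNA / protein / phospho size asymmetry at desk scale; K = 5;
σ = 1; binary loading scale 0.4, which keeps the logistic link near-linear
and the mutation layer weak (~8% signal) relative to the continuous layers
(~65–70%).

Factor strengths default to the geometric sequence 1.6·0.8^k. This is
load-bearing: with equal strengths and dense Gaussian loadings the model is
identified only up to rotation and no method could match fitted to planted
factors one-to-one; distinct strengths create the eigengap that makes
factors identifiable, just as real latent factors are separated by variance
explained.

Clinical structure: factor 1 (the prognostic factor) sets an exponential
survival time with log-hazard `hazard_coef · z` (default −0.7), independent
uniform administrative censoring calibrated by bisection to the requested
censoring rate (0.3), and a 4-level ordinal stage via fixed quantile
thresholds on `−z + noise` (low score ↔ advanced stage). Factor 0 drives a
3-level MSI-like covariate the same way. 30 signature genes shared between
the protein and mRNA views load only on the prognostic factor (negative
sign, protein magnitude 3.0, mRNA 1.5; all other loadings zeroed for those
genes) so that cross-layer correlation filtering has planted positives.
10% of samples lack each view, in disjoint blocks so nobody loses every
view. A validation cohort is generated by reusing a training cohort's
loadings (`loadings_from=`) with fresh samples — without shared loadings,
cross-cohort projection would be meaningless.

Single-cell counts are Gamma–Poisson (negative binomial, dispersion 2) with
log-normal gene means; the designated cell type multiplies signature-gene
means by `fold_change` and is 5× more frequent in tumour than normal tissue.

### What the generator does not emulate

Linear Gaussian views with homogeneous noise; no batch effects, no
heavy-tailed abundances, no realistic mutation co-occurrence or signatures,
no miRNA-specific biology, no doublets/ambient RNA in the single-cell
counts, exponential (constant-hazard) survival. Passing tests therefore
demonstrate correctness of the algorithms under the model's own
assumptions, not robustness to real-data pathologies.

## Numerical choices and degenerate inputs

Zero-variance features are dropped (not imputed) at z-scoring — their
z-score is undefined. SDs use ddof=1 over observed entries; top-k ties are
broken lexicographically by feature id. Threshold ties in score
stratification go to the "low" group. ARD precisions are clipped to
[1e-6, 1e8]; residual variances floored at 1e-12. The model container is
HDF5 written without timestamps, so identical models produce byte-identical
files. All stochastic components take explicit seeds and are bit-reproducible.

## Problem sizes used by tests and the acceptance script

The default cohort (200 × ~2900 features, K_fit = 8) fits in ~10 s on one
CPU. Operating-characteristic simulations (Cox CI coverage, log-rank power,
enrichment calibration) use 200 replicates at the sizes stated in their
tests (n = 500 and n = 300 cohorts with two small views; 200 random gene
sets at 199 permutations); these sizes give Monte-Carlo error comfortably
below the asserted margins. The acceptance script runs the full chain once
at the default conditions plus a 150-sample held-out cohort and 2000
synthetic cells.

## Known limitations

The Gaussian treatment of the centred mutation view underestimates that
view's variance explained slightly (logistic nonlinearity); multivariable
Cox with many factors on small cohorts can legitimately fail to converge
(flagged, mirroring real-cohort behaviour); varimax column re-matching can
in principle be ambiguous when the rotation mixes factors heavily —
reported correlations and conditioning numbers are the guard rails.
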