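# Methods

This note documents the models, algorithmic choices, and limitations of
`enterosig`. It is written for users who want to know exactly what the
package computes and why, in the package's own terms.

## The factorization model

The observed matrix `V` (samples × features, non-negative, TSS-scaled
to per-sample proportions) is approximated as `V ≈ W·H` with `W ≥ 0`
(samples × k loadings) and `H ≥ 0` (k × features profiles). We minimize
the generalized Kullback–Leibler divergence

    D(V‖WH) = Σᵢⱼ [ Vᵢⱼ log(Vᵢⱼ/(WH)ᵢⱼ) − Vᵢⱼ + (WH)ᵢⱼ ],

the Poisson-likelihood objective appropriate for count-derived
proportions, using the classical multiplicative updates

    H ← H ⊙ (Wᵀ(V⊘WH)) ⊘ (Wᵀ1),   W ← W ⊙ ((V⊘WH)Hᵀ) ⊘ (1Hᵀ),

which never increase the objective. Implementation details:

- **Initialization.** Seeded uniform(0,1) entries scaled by
  `sqrt(mean(V)/k)`, so the initial reconstruction matches the data
  scale. Every run takes an explicit integer seed; no global RNG state
  is read anywhere in the package.
- **Convergence.** The objective is evaluated once per 10-iteration
  window; iteration stops when the relative decrease over a window
  falls below `tol` (default 1e-6) or at `max_iter` (default 2000).
  Rank-scan runs use a 1000-iteration budget: they estimate consensus
  stability rather than deliver the final model, and the consensus/fit
  metrics plateau well before full convergence. The final model is
  refitted with the full budget and 30 starts.
- **Scale identifiability.** After fitting, each row of `H` is scaled
  to sum to 1 and `W` absorbs the scale; `W·H` is unchanged to within
  rounding, and loadings become comparable across samples.
- **Numerics.** Denominators and the reconstruction are floored at
  1e-12 before division/log. A numba-compiled inner loop is used when
  available, with an arithmetically identical numpy fallback.

## Rank selection

For each candidate rank (default 2–8, 10 runs each) we compute, from
the best run and the argmax-connectivity consensus matrix `C`
(fraction of runs in which two samples share the same dominant
factor):

- cophenetic correlation between `1−C` and the cophenetic distances of
  its average-linkage dendrogram;
- mean silhouette width of the consensus clustering (average-linkage
  cut at k) under distance `1−C`;
- residual sum of squares Σ(V−WH)² and explained variance
  1 − rss/ΣV²;
- dispersion, mean of 4(C−½)².

A metric *accepts* a rank whose value is within a relative tolerance
(default 0.10 for MAG analyses, 0.05 for KO analyses) of the metric's
optimum — maximum for all metrics except rss, which is minimized. When
a metric's optimum is non-positive (possible for silhouette), the
relative band is ill-defined and the comparison falls back to absolute
distance ≤ tolerance·|optimum|. The most-accepted rank is chosen;
ties break toward the larger rank, trading parsimony for ecological
resolution (merging distinct subcommunities into composites loses more
information than splitting one). Missing metric values make that
metric abstain at that rank, and abstentions are reported.

## Stability validation

The reference solution is the full-data fit. Each of 100 iterations
draws an 80% subsample of samples **without replacement, stratified by
(line, timepoint)** so no design cell empties, refits with 5 inner
starts (a cost/stability compromise, exposed as a parameter), extracts
each factor's top-30 features with the same ranking rule used for
signature reporting, and matches factors to the reference by
Hungarian-optimal total Jaccard similarity. Refits reuse the reference
seed block, so subsampling is the only source of variation being
measured — with the full sample, the refit reproduces the reference
exactly. Feature persistence pools all (signature, top-feature) pairs
and reports the fraction recovered in ≥ 80% of iterations. Unequal
factor counts pair the surplus with the empty set at Jaccard 0.

## Signature characterization

For feature j and signature s, specificity(s,j) = H[s,j]/Σₛ'H[s',j]
and enrichment(s,j) = k·specificity(s,j) ∈ [0,k]; a feature exclusive
to one of 8 signatures scores enrichment 8.000, specificity 1.0.
Within a signature, features are ranked by the z-score of their
loading when the coefficient of variation of (nonzero) enrichment is
below 0.5 — enrichment then carries little contrast — and by
fold-enrichment otherwise; the mode used is recorded. Note that
fold-enrichment saturates at k for fully exclusive features, so
rankings inside a large exclusive block are tie-dominated; the
recorded rank mode and the loading column let users re-rank when this
matters. Dominant-signature assignment (argmax of each W row, ties to
the lowest index and flagged) is used only for descriptive composition
tables; all inference uses continuous loadings. Loading diversity is
Shannon H′ = −Σ pᵢ ln pᵢ (natural log, 0·ln 0 = 0) on row-normalized
loadings, with evenness H′/ln(k) so both use the same base.

## Loading normalization

NMF loadings are compositional, so before modeling:

1. **TMM scale factors.** The reference sample is the one whose
   upper-quartile proportion is closest to the cohort mean. Per
   sample, the factor is 2^(weighted trimmed mean of M-values), with
   log-ratios trimmed 30% total on M and 5% total on A and
   inverse-variance weights — the conventional trims. Factors are
   rescaled to geometric mean 1; a sample sharing no co-positive
   signatures with the reference gets factor 1 with a warning.
2. **CLR.** Scaled loadings are log-transformed and row-centered:
   x → ln x − mean(ln x), so each row sums to zero exactly. Zeros are
   replaced by half the smallest positive scaled value (multiplicative
   replacement), leaving strictly positive rows untouched. Loadings
   below 1e-12 of the matrix maximum are treated as zeros first —
   multiplicative updates leave denormal residues that would otherwise
   produce absurd log-ratios.

Whether to add an offset everywhere instead of replacing zeros only is
exposed through the recorded pseudocount; the replace-zeros form was
chosen because it keeps the transform exact on positive data.

## Mixed models and inference

Two models per signature, both with a random intercept per animal
(`u ~ N(0, σ²ₐ)`, residual `N(0, σ²ₑ)`), fitted by REML with the error
variance profiled out (one-dimensional bounded search over
log(σ²ₐ/σ²ₑ)):

- dynamics: `CLR loading ~ timepoint * line`;
- host association: `phenotype ~ loading * timepoint * line` with the
  loading as a continuous covariate and the full two- and three-way
  interaction structure retained, as a pre-specified plan.

Fixed factors use sum-to-zero coding, so the F test of each term's
coefficient block is the type-III partial test. Denominator degrees of
freedom follow Satterthwaite: for a contrast ℓ,
ν = 2(ℓ'Cℓ)²/(g'Ag) with C the fixed-effect covariance, g the
gradient of ℓ'Cℓ in the variance components, and A their asymptotic
covariance from the inverse REML information; multi-df terms combine
one-df ν's through the spectral decomposition of the contrast
covariance. On the balanced 25-animal × 3-timepoint design these dfs
reduce to the classical 23 (between-animal) and 46 (within-animal)
values, and the variance components agree with an independent REML
implementation to ~6 digits (tested). Aliased design columns are
dropped by pivoted QR and reported; σ²ₐ estimates below 1e-6·σ²ₑ set a
singularity flag; non-converged fits are excluded from downstream
tables.

Estimated marginal means are computed on the line × timepoint grid
with balanced factor weights (covariates at their mean); the contrast
family is line difference at each timepoint plus all within-line
temporal differences, FDR-adjusted within the family
(Benjamini–Hochberg), with the conventional significance annotations
(*** < 0.001, ** < 0.01, * < 0.05, · < 0.10). Cohen's *d* between
lines is (mean difference)/(pooled SD) with a 95% CI from inverting
the noncentral-*t* distribution; it is computed on the same normalized
(CLR) scale as the models.

## Cross-layer integration

- Spearman rank correlations between all taxonomic and functional
  signature score vectors over shared samples, with per-pair p-values
  retained for annotation; constant vectors yield missing entries.
- Centroid trend test: the statistic is Δ = d(last) − d(first), where
  d(t) is the Euclidean distance between the two lines' mean W rows at
  timepoint t. The null permutes **line labels at the animal level**
  (samples within an animal are dependent, so the animal is the
  exchangeable unit); p = (1 + #{|Δ_null| ≥ |Δ_obs|})/(1 + n_perm),
  reported for the observed direction (divergence/convergence). The
  magnitude comparison keeps the p-value uniform under the null even
  though the direction is read off the data; permutations that empty a
  design cell are redrawn and counted. W rows enter on their raw
  (TSS-derived) scale; a CLR-space variant is a caller choice.
- PERMANOVA per timepoint on Euclidean distances among W rows:
  R² = SS_between/SS_total from the distance decomposition (equal to
  the ordinary ANOVA between-group fraction for Euclidean distances),
  pseudo-F p by label permutation with the +1 correction.

## The synthetic cohort

The generator emulates the target study design: 13 + 12 animals in two
lines, timepoints d4/d8/d14, one sample dropped at random (75 → 74).
Loadings are symmetric Dirichlet(α = 0.3 by default — spiky mixed
membership with one dominant subcommunity per sample, typical of gut
communities); design effects are added on the simplex and rows
renormalized, keeping loadings interpretable as mixed membership.
Profiles H are exponential variates with an expected 80% zero fraction
by default (distinct, overlapping signatures over 300 features).
Counts are multinomial draws at depth 1e5 per sample, optionally
Dirichlet-multinomial overdispersed (concentration p/φ) — the standard
extra-variance model for metagenomic counts. A KO layer is derived
through a guild-structured MAG→KO map (guild members share a KO block)
to emulate functional redundancy. Phenotypes are linear in true
loadings plus design offsets and Gaussian noise.

What the generator does **not** emulate: taxonomic correlation
structure beyond the planted factors, depth variation between samples,
zero-inflation beyond what multinomial sampling of sparse profiles
produces, phylogenetic signal, or measurement error in phenotypes
beyond i.i.d. noise. Passing tests therefore demonstrate correctness
of the algorithms and calibration of the inference under the stated
generative model, not robustness to every feature of real metagenomic
data.

## Problem sizes and numerical choices

Validation runs use cohorts of 74 samples × 300 features with 4
planted subcommunities, the rank grid 2–8 at 10 runs per rank, 100
stability iterations, 500-replicate null calibrations for the mixed
models, and 200 simulated datasets × 999 permutations for permutation
validity — sizes at which every check completes quickly on a single
CPU while keeping Monte Carlo error well inside the asserted margins.
Permutation counts for reported analyses default to 9999. All
tolerance constants (1e-12 flooring, 1e-9 simplex checks, 1e-6 REML
convergence) are stated at their definition sites.

## Known limitations

- KL-divergence NMF is non-convex; multi-run consensus mitigates but
  does not eliminate local-optimum sensitivity. Rank selection
  tie-breaks toward larger ranks and can prefer k_true + 1 when the
  extra factor is a stable split.
- Satterthwaite dfs are an approximation; with 25 animals the
  three-way-interaction phenotype model is near the edge of what the
  design supports, and higher-order terms should be read cautiously.
- Only a random-intercept covariance structure is implemented (no
  Kenward–Roger, no serial correlation); subsampling is
  without-replacement only (no bootstrap mode).
- The KO functional-category keyword heuristic is out of scope;
  category labels can be joined from a user-provided mapping table.
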