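# enterosig

Enterosignature analysis of longitudinal microbiome cohorts.

Gut microbial communities are mixtures of co-occurring subcommunities
rather than discrete types. **Enterosignatures (ES)** capture this by
decomposing a non-negative samples × features abundance matrix `V`
(features being metagenome-assembled genomes, MAGs, or KEGG Orthology
groups, KOs) with non-negative matrix factorization:

```
V ≈ W · H      W: samples × k  (per-sample signature loadings)
               H: k × features (per-signature feature profiles)
```

`enterosig` implements the full analysis path for a repeated-measures
cohort design (two treatment groups/genetic lines, three timepoints,
one random intercept per animal):

1. **Preparation** — prevalence/abundance feature filtering, total-sum
   scaling (TSS), MAG→KO aggregation.
2. **Factorization** — Brunet-style NMF minimizing the generalized
   Kullback–Leibler divergence `D(V‖WH)` with multiplicative updates,
   repeated from many seeded starts.
3. **Rank selection** — consensus voting across five quality metrics
   (cophenetic correlation, silhouette width, residual sum of squares,
   dispersion, explained variance): each metric accepts ranks within a
   relative tolerance of its optimum; the most-accepted rank wins,
   ties going to the larger rank.
4. **Stability** — refitting on 80% subsamples (100 iterations) and
   matching each factor's top-30 features to the reference solution by
   Hungarian-optimal Jaccard similarity, plus feature persistence.
5. **Characterization** — per-feature enrichment (fold over the mean
   loading across signatures) and specificity (fraction of a feature's
   loading on one signature, so enrichment = k × specificity), ranked
   top features, dominant-signature composition summaries, Shannon
   diversity/evenness of loadings.
6. **Association** — TMM scale factors + centered log-ratio transform
   of loadings, then linear mixed models
   `loading ~ timepoint * line + (1|animal)` and
   `phenotype ~ loading * timepoint * line + (1|animal)` with type-III
   F tests (Satterthwaite degrees of freedom), Benjamini–Hochberg FDR,
   estimated marginal means with pairwise contrasts, and Cohen's *d*
   with noncentral-*t* confidence intervals.
7. **Integration** — Spearman correlation between taxonomic and
   functional signature scores, between-line centroid-distance trend
   tests with animal-level permutations, per-timepoint PERMANOVA.

A first-class synthetic-cohort generator plants known ground truth
(mixed-membership loadings, sparse signature profiles, design effects,
phenotype couplings) so every stage can be validated against truth.

## Worked example

```bash
# 1. simulate a cohort: 25 animals x 3 timepoints (one sample dropped),
#    4 planted subcommunities over 300 features, depth 1e5
enterosig simulate --k 4 --n-features 300 --depth 100000 --seed 12345 --out demo/

# 2. pick the rank by metric consensus
enterosig select-rank --abundance demo/mag_abundance.tsv --grid 2:8 \
    --runs 10 --tolerance 0.10 --seed 12345
```

The second command prints (abridged):

```json
{
  "acceptable_sets": {"cophenetic": [2, 3, 4, 5, 6, 7, 8],
                      "silhouette": [3, 4], "dispersion": [4],
                      "evar": [4, 5, 6, 7, 8], "rss": [4, 5, 6, 7, 8]},
  "votes": {"2": 1, "3": 2, "4": 5, "5": 3, "6": 3, "7": 3, "8": 3},
  "chosen_k": 4,
  "tolerance": 0.1
}
```

All five metrics accept rank 4 — the planted number of subcommunities —
so `chosen_k = 4` with 5 of 5 votes. The full pipeline (`enterosig run-all --config
config.yaml`) then factorizes at the chosen rank with 30 runs, writes
`W`/`H` matrices, stability and signature tables, mixed-model ANOVA
tables with FDR-adjusted p-values, and cross-layer trend tests, plus a
manifest with content hashes so a rerun can be verified bit-for-bit.

From Python the same stages are plain functions:

```python
from enterosig import (tss_normalize, multi_run, select_rank,
                       tmm_clr, fit_es_model)
from enterosig.nmf import scan_ranks
from enterosig.synthetic import simulate_cohort

cohort = simulate_cohort(seed=12345)
V = tss_normalize(cohort.mag_matrix)
metrics = scan_ranks(V, range(2, 9), n_runs=10, base_seed=12345)
k = select_rank(metrics, tolerance=0.10).chosen_k      # -> 4
model, consensus = multi_run(V, k, n_runs=30, base_seed=12345)
norm = tmm_clr(model.W)
result = fit_es_model(norm.clr[:, 0], cohort.metadata)  # ES1 dynamics
print(result.anova)
```

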