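"""Subsampling stability of the factorization.

Reproducibility of each signature is scored by refitting the NMF on
random 80% subsamples of the cohort and comparing the top-N feature
sets of each refitted factor to the reference (full-data) solution via
Jaccard similarity with optimal one-to-one factor matching (Hungarian
algorithm).  Feature persistence summarizes, over the pooled reference
top features, how many are recovered in at least a threshold fraction
of iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .matrices import AbundanceMatrix
from .nmf import multi_run
from .signatures import top_feature_sets


def jaccard(a: set, b: set) -> float:
    """|a & b| / |a | b|; 1.0 when both sets are empty."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def match_signatures(
    ref_top: list[set], sub_top: list[set]
) -> tuple[list[tuple[int, int | None]], np.ndarray]:
    """Optimal one-to-one matching of subsample factors to reference.

    Maximizes the total Jaccard similarity over assignments (Hungarian
    algorithm).  When counts differ, unmatched reference factors pair
    with the empty set at Jaccard 0.  Returns (pairs, per-reference
    Jaccard), where pairs[i] = (ref_index, sub_index or None).
    """
    if not ref_top or not sub_top:
        raise ValueError("both factor lists must be non-empty")
    nr, ns = len(ref_top), len(sub_top)
    S = np.zeros((nr, ns))
    for i, a in enumerate(ref_top):
        for j, b in enumerate(sub_top):
            S[i, j] = jaccard(a, b)
    ri, sj = linear_sum_assignment(-S)
    assigned = dict(zip(ri.tolist(), sj.tolist()))
    pairs: list[tuple[int, int | None]] = []
    scores = np.zeros(nr)
    for i in range(nr):
        j = assigned.get(i)
        pairs.append((i, j))
        scores[i] = S[i, j] if j is not None else 0.0
    return pairs, scores


@dataclass
class StabilityReport:
    per_signature_jaccard: np.ndarray  # mean over iterations, per reference factor
    mean_jaccard: float
    persistence: float
    per_iteration: pd.DataFrame  # iteration x reference factor Jaccard
    n_iter: int
    n_skipped: int
    subsample_fraction: float
    top_n: int
    persistence_threshold: float

    def to_dict(self) -> dict:
        return {
            "per_signature_jaccard": self.per_signature_jaccard.tolist(),
            "mean_jaccard": self.mean_jaccard,
            "persistence": self.persistence,
            "n_iter": self.n_iter,
            "n_skipped": self.n_skipped,
            "subsample_fraction": self.subsample_fraction,
            "top_n": self.top_n,
            "persistence_threshold": self.persistence_threshold,
        }


def _stratified_subsample(
    metadata: pd.DataFrame | None, n: int, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Row indices of a without-replacement subsample.

    When metadata with (line, timepoint) is given, sampling is
    stratified by cell so no design cell empties; otherwise simple
    random sampling.
    """
    if metadata is None:
        m = max(1, int(round(fraction * n)))
        return np.sort(rng.choice(n, size=m, replace=False))
    idx = []
    groups = metadata.reset_index(drop=True).groupby(
        ["line", "timepoint"], observed=True
    )
    for _, grp in groups:
        rows = grp.index.to_numpy()
        m = max(1, int(round(fraction * len(rows))))
        idx.append(rng.choice(rows, size=m, replace=False))
    return np.sort(np.concatenate(idx))


def subsample_stability(
    V,
    k: int,
    n_iter: int = 100,
    fraction: float = 0.8,
    top_n: int = 30,
    seed: int = 0,
    metadata: pd.DataFrame | None = None,
    n_inner_runs: int = 5,
    persistence_threshold: float = 0.8,
    max_iter: int = 2000,
    tol: float = 1e-6,
    reference: np.ndarray | None = None,
) -> StabilityReport:
    """Score signature reproducibility over random subsamples.

    The reference is the full-data best-of-``n_inner_runs`` fit at rank
    ``k`` (or a supplied H matrix).  Each iteration subsamples the rows
    at ``fraction`` (stratified by design cell when metadata is given),
    refits, extracts top-``top_n`` feature sets per factor, and matches
    them to the reference.  Iterations whose refit fails are skipped;
    more than 20% skipped is an error.
    """
    Va = V.values if isinstance(V, AbundanceMatrix) else np.asarray(V, float)
    feature_ids = (
        V.feature_ids if isinstance(V, AbundanceMatrix)
        else [f"f{j}" for j in range(Va.shape[1])]
    )
    n = Va.shape[0]
    if fraction * n < k + 1:
        raise ValueError("subsample too small for the requested rank")

    if reference is None:
        ref_model, _ = multi_run(
            Va, k, n_runs=n_inner_runs, base_seed=seed, max_iter=max_iter, tol=tol
        )
        ref_H = ref_model.H
    else:
        ref_H = np.asarray(reference, float)
    ref_top = top_feature_sets(ref_H, feature_ids, top_n=top_n)

    rng = np.random.default_rng(seed)
    rows = []
    recovery = {
        (s, f): 0 for s, top in enumerate(ref_top) for f in top
    }
    n_skipped = 0
    for it in range(n_iter):
        idx = _stratified_subsample(metadata, n, fraction, rng)
        try:
            # refits reuse the reference seed block so subsampling is the
            # only source of variation being measured
            sub_model, _ = multi_run(
                Va[idx], k, n_runs=n_inner_runs, base_seed=seed,
                max_iter=max_iter, tol=tol,
            )
        except (RuntimeError, ValueError):
            n_skipped += 1
            continue
        sub_top = top_feature_sets(sub_model.H, feature_ids, top_n=top_n)
        pairs, scores = match_signatures(ref_top, sub_top)
        rows.append(scores)
        for (i, j) in pairs:
            if j is None:
                continue
            for f in ref_top[i] & sub_top[j]:
                recovery[(i, f)] += 1
    if n_skipped > 0.2 * n_iter:
        raise RuntimeError(
            f"{n_skipped}/{n_iter} stability refits failed to converge"
        )
    per_iter = pd.DataFrame(
        rows, columns=[f"ES{s + 1}" for s in range(len(ref_top))]
    )
    done = len(rows)
    per_sig = per_iter.mean(axis=0).to_numpy()
    persistence = float(
        np.mean([cnt >= persistence_threshold * done for cnt in recovery.values()])
    )
    return StabilityReport(
        per_signature_jaccard=per_sig,
        mean_jaccard=float(per_sig.mean()),
        persistence=persistence,
        per_iteration=per_iter,
        n_iter=done,
        n_skipped=n_skipped,
        subsample_fraction=fraction,
        top_n=top_n,
        persistence_threshold=persistence_threshold,
    )
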