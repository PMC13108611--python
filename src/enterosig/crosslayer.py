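"""Integration of taxonomic and functional decompositions.

Three complementary views link the two latent spaces fitted on the same
samples: (1) a Spearman rank-correlation matrix between every
taxonomic and functional signature score vector; (2) a directional
permutation test on between-line centroid distances in loading space,
asking whether the two genetic lines diverge (or converge) from the
first to the last timepoint; and (3) per-timepoint PERMANOVA
quantifying how much loading-space variance the line labels explain.

Because samples within an animal are dependent (repeated measures),
the permutation unit for the trend test and PERMANOVA is the animal:
all of an animal's samples carry its permuted line label together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def spearman_matrix(
    W_tax: np.ndarray, W_fun: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations between all taxonomic and
    functional signature score vectors over the shared samples.

    Returns (rho, p) DataFrames of shape (k_tax, k_fun).  Pairs
    involving a constant vector are reported as NaN.
    """
    W_tax = np.asarray(W_tax, float)
    W_fun = np.asarray(W_fun, float)
    if W_tax.shape[0] != W_fun.shape[0]:
        raise ValueError("score matrices must share samples in the same order")
    if W_tax.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    kt, kf = W_tax.shape[1], W_fun.shape[1]
    rho = np.full((kt, kf), np.nan)
    pval = np.full((kt, kf), np.nan)
    for i in range(kt):
        if np.ptp(W_tax[:, i]) == 0:
            continue
        for j in range(kf):
            if np.ptp(W_fun[:, j]) == 0:
                continue
            r, p = stats.spearmanr(W_tax[:, i], W_fun[:, j])
            rho[i, j], pval[i, j] = r, p
    t_ids = [f"T-ES{i + 1}" for i in range(kt)]
    f_ids = [f"F-ES{j + 1}" for j in range(kf)]
    return (
        pd.DataFrame(rho, index=t_ids, columns=f_ids),
        pd.DataFrame(pval, index=t_ids, columns=f_ids),
    )


@dataclass
class TrendTestResult:
    centroid_distance: dict[str, float]  # timepoint -> between-line distance
    delta: float  # distance(last) - distance(first)
    perm_p: float  # one-sided in the observed direction
    direction: str  # "divergence" or "convergence"
    n_perm: int


def _between_line_distance(
    W: np.ndarray, is_first_line: np.ndarray
) -> float:
    c1 = W[is_first_line].mean(axis=0)
    c2 = W[~is_first_line].mean(axis=0)
    return float(np.linalg.norm(c1 - c2))


def centroid_trend_test(
    W: np.ndarray,
    metadata: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
    timepoints: tuple[str, str] | None = None,
) -> TrendTestResult:
    """Directional permutation test of between-line centroid distance.

    The observed statistic is delta = d(last timepoint) - d(first
    timepoint), where d is the Euclidean distance between the two
    lines' centroid loading vectors.  The null is built by permuting
    line labels at the animal level; the p-value compares magnitudes,
    p = (1 + #{|null delta| >= |observed delta|}) / (1 + n_perm),
    reported for the observed direction (divergence when delta >= 0,
    convergence otherwise).  The magnitude comparison keeps the
    p-value uniform under exchangeability even though the direction
    itself is read off the data.
    """
    W = np.asarray(W, float)
    md = metadata.reset_index(drop=True)
    tps = [t for t in ("d4", "d8", "d14") if t in set(md["timepoint"])]
    if not tps:
        tps = list(pd.unique(md["timepoint"]))
    first_tp, last_tp = (timepoints if timepoints else (tps[0], tps[-1]))

    lines = sorted(md["line"].unique())
    if len(lines) != 2:
        raise ValueError("trend test requires exactly two lines")
    animal_idx = pd.factorize(md["animal_id"])[0]
    animal_order = pd.factorize(md["animal_id"])[1]
    # line flag per animal, aligned with factorization order
    line_of_animal = (
        md.groupby("animal_id")["line"].first().reindex(animal_order).to_numpy()
    )
    n_line1 = int((line_of_animal == lines[0]).sum())

    masks = {tp: (md["timepoint"] == tp).to_numpy() for tp in tps}
    for tp in (first_tp, last_tp):
        sub_lines = md.loc[masks[tp], "line"].unique()
        if len(sub_lines) < 2:
            raise ValueError(f"both lines must be present at timepoint {tp}")

    def delta_for(flags: np.ndarray) -> float:
        """flags: per-animal boolean, True = first line."""
        sample_flag = flags[animal_idx]
        ds = {}
        for tp in (first_tp, last_tp):
            m = masks[tp]
            f = sample_flag[m]
            if f.sum() == 0 or (~f).sum() == 0:
                return np.nan
            ds[tp] = _between_line_distance(W[m], f)
        return ds[last_tp] - ds[first_tp]

    obs_flags = line_of_animal == lines[0]
    distances = {}
    for tp in tps:
        m = masks[tp]
        f = obs_flags[animal_idx][m]
        distances[tp] = _between_line_distance(W[m], f)
    observed = distances[last_tp] - distances[first_tp]
    direction = "divergence" if observed >= 0 else "convergence"

    rng = np.random.default_rng(seed)
    n_animals = len(line_of_animal)
    hits = 0
    done = 0
    redraws = 0
    while done < n_perm:
        perm = np.zeros(n_animals, dtype=bool)
        perm[rng.choice(n_animals, size=n_line1, replace=False)] = True
        d = delta_for(perm)
        if np.isnan(d):  # a (line, timepoint) cell emptied; redraw
            redraws += 1
            if redraws > 100 * n_perm:
                raise RuntimeError("could not draw valid permutations")
            continue
        done += 1
        if abs(d) >= abs(observed):
            hits += 1
    perm_p = (1 + hits) / (1 + n_perm)
    return TrendTestResult(
        centroid_distance=distances,
        delta=float(observed),
        perm_p=float(perm_p),
        direction=direction,
        n_perm=n_perm,
    )


@dataclass
class PermanovaResult:
    r2: float
    pseudo_f: float
    p: float
    n_perm: int


def permanova(
    W: np.ndarray,
    labels,
    n_perm: int = 9999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances among loading rows.

    R^2 = SS_between / SS_total from the distance decomposition
    (equivalently the ordinary ANOVA between-group fraction for
    Euclidean distances); the p-value permutes group labels with the
    +1 correction.
    """
    W = np.asarray(W, float)
    labels = np.asarray(labels)
    groups, codes = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("each group needs at least 2 samples")
    n = W.shape[0]
    a = len(groups)

    # squared Euclidean distances via Gram expansion
    sq = (W**2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * W @ W.T
    np.clip(D2, 0.0, None, out=D2)
    ss_total = D2[np.triu_indices(n, k=1)].sum() / n

    def ss_within(cds: np.ndarray) -> float:
        ssw = 0.0
        for g in range(a):
            idx = np.where(cds == g)[0]
            sub = D2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
        return ssw

    ssw_obs = ss_within(codes)
    ssb_obs = ss_total - ssw_obs
    r2 = ssb_obs / ss_total if ss_total > 0 else 0.0
    f_obs = (ssb_obs / (a - 1)) / (ssw_obs / (n - a)) if ssw_obs > 0 else np.inf

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        ssw = ss_within(perm)
        ssb = ss_total - ssw
        f = (ssb / (a - 1)) / (ssw / (n - a)) if ssw > 0 else np.inf
        if f >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(r2=float(r2), pseudo_f=float(f_obs), p=float(p), n_perm=n_perm)
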