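"""Signature characterization: enrichment, specificity, ranked top
features, dominant-signature assignment, and loading diversity.

For a coefficient matrix H (signatures x features), specificity of a
feature for a signature is the fraction of that feature's total loading
carried by the signature, and enrichment is the loading relative to the
mean across signatures — hence enrichment = k x specificity, bounded by
the number of signatures k.  A feature exclusive to one of 8 signatures
therefore scores enrichment 8.000 and specificity 1.0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def enrichment_specificity(H: np.ndarray, feature_ids=None) -> pd.DataFrame:
    """Per-(signature, feature) loading, enrichment, and specificity.

    Features whose total loading across signatures is zero get
    enrichment and specificity 0 and are flagged in the ``zero_total``
    column.
    """
    H = np.asarray(H, dtype=float)
    if (H < 0).any():
        raise ValueError("H must be non-negative")
    k, p = H.shape
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(p)]
    totals = H.sum(axis=0)
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    spec = H / safe[None, :]
    spec[:, zero] = 0.0
    enr = k * spec
    rows = []
    for s in range(k):
        for j in range(p):
            rows.append(
                {
                    "signature": s + 1,
                    "feature_id": feature_ids[j],
                    "loading": H[s, j],
                    "enrichment": enr[s, j],
                    "specificity": spec[s, j],
                    "zero_total": bool(zero[j]),
                }
            )
    return pd.DataFrame(rows)


def rank_features(
    table: pd.DataFrame, cv_threshold: float = 0.5, top_n: int = 30
) -> pd.DataFrame:
    """Rank features within each signature and keep the top ``top_n``.

    The ranking statistic adapts to how variable enrichment is within
    the signature: when the coefficient of variation of (nonzero)
    enrichment values is below ``cv_threshold``, enrichment carries
    little contrast and features are ranked by the z-score of their
    loading instead; otherwise they are ranked by fold-enrichment.
    The mode used is recorded per signature in ``rank_mode``.
    """
    out = []
    for sig, grp in table.groupby("signature"):
        enr = grp["enrichment"].to_numpy()
        nz = enr[enr > 0]
        if nz.size == 0 or nz.mean() == 0:
            cv = 0.0
        else:
            cv = nz.std(ddof=0) / nz.mean()
        if cv < cv_threshold:
            mode = "zscore"
            x = grp["loading"].to_numpy()
            sd = x.std(ddof=0)
            stat = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        else:
            mode = "fold_enrichment"
            stat = enr
        g = grp.assign(rank_stat=stat, rank_mode=mode)
        g = g.sort_values(
            ["rank_stat", "feature_id"], ascending=[False, True]
        ).reset_index(drop=True)
        if len(g) < top_n:
            warnings.warn(
                f"signature {sig} has only {len(g)} features (< top_n={top_n})",
                stacklevel=2,
            )
        g = g.head(top_n)
        g["rank"] = np.arange(1, len(g) + 1)
        out.append(g)
    return pd.concat(out, ignore_index=True)


def top_feature_sets(
    H: np.ndarray, feature_ids=None, cv_threshold: float = 0.5, top_n: int = 30
) -> list[set[str]]:
    """Top-N feature identity sets per signature (ranking rule above)."""
    ranked = rank_features(
        enrichment_specificity(H, feature_ids), cv_threshold=cv_threshold, top_n=top_n
    )
    return [
        set(ranked.loc[ranked["signature"] == s, "feature_id"])
        for s in sorted(ranked["signature"].unique())
    ]


def dominant_es(W: np.ndarray) -> pd.DataFrame:
    """Dominant signature per sample: argmax of the loading row.

    Ties go to the lowest factor index and are flagged.  Labels are
    1-based.  Used only for descriptive composition summaries; all
    inference uses the continuous loadings.
    """
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("W must be non-negative")
    if (W.sum(axis=1) == 0).any():
        raise ValueError("W has all-zero rows; dominant signature undefined")
    labels = np.argmax(W, axis=1)
    row_max = W.max(axis=1)
    ties = (W == row_max[:, None]).sum(axis=1) > 1
    return pd.DataFrame({"dominant_es": labels + 1, "tie": ties})


def composition_by_group(
    labels: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Percentage of samples per dominant signature within each
    (line, timepoint) cell; each cell's percentages sum to 100."""
    if len(labels) != len(metadata):
        raise ValueError("labels must cover all samples")
    df = metadata[["line", "timepoint"]].reset_index(drop=True).copy()
    df["dominant_es"] = labels["dominant_es"].to_numpy()
    counts = (
        df.groupby(["line", "timepoint", "dominant_es"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    cell_totals = counts.groupby(["line", "timepoint"], observed=True)["n"].transform("sum")
    counts["percent"] = 100.0 * counts["n"] / cell_totals
    return counts


def loading_diversity(W: np.ndarray) -> pd.DataFrame:
    """Shannon diversity H' (nats) and evenness of each sample's loadings.

    p_i is the row-normalized loading; H' = -sum p_i ln p_i with
    0 ln 0 = 0; evenness = H' / ln(k).
    """
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("W must be non-negative")
    totals = W.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero loading rows have undefined diversity")
    P = W / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    h = -terms.sum(axis=1)
    k = W.shape[1]
    return pd.DataFrame({"H_prime": h, "evenness": h / np.log(k)})
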