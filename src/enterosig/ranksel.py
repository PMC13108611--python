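"""Consensus tolerance-based selection of the factorization rank.

Each quality metric votes for the candidate ranks whose value lies
within a relative tolerance of that metric's optimum (maximum for
cophenetic correlation, silhouette, dispersion and explained variance;
minimum for residual sum of squares).  The rank accepted by the most
metrics wins; ties are broken toward the larger rank to preserve
ecological resolution, since merging distinct subcommunities into
composite factors loses more information than splitting one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metric -> True if larger is better
METRIC_ORIENTATION = {
    "cophenetic": True,
    "silhouette": True,
    "dispersion": True,
    "evar": True,
    "rss": False,
}


@dataclass
class RankSelectionResult:
    candidate_ranks: list[int]
    acceptable_sets: dict[str, set[int]]
    votes: dict[int, int]
    chosen_k: int
    tolerance: float
    abstentions: dict[str, list[int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "candidate_ranks": self.candidate_ranks,
            "acceptable_sets": {m: sorted(s) for m, s in self.acceptable_sets.items()},
            "votes": {str(r): v for r, v in self.votes.items()},
            "chosen_k": self.chosen_k,
            "tolerance": self.tolerance,
            "abstentions": self.abstentions,
        }


def _acceptable(values: pd.Series, maximize: bool, tolerance: float) -> set[int]:
    """Ranks within relative tolerance of the metric's optimum.

    With a non-positive optimum a relative band is ill-defined, so the
    comparison falls back to absolute distance <= tolerance * |optimum|.
    """
    vals = values.dropna()
    if vals.empty:
        return set()
    opt = vals.max() if maximize else vals.min()
    if opt > 0:
        cut = (1 - tolerance) * opt if maximize else (1 + tolerance) * opt
        ok = vals >= cut if maximize else vals <= cut
    else:
        ok = (vals - opt).abs() <= tolerance * abs(opt)
    return set(vals.index[ok].astype(int))


def select_rank(
    metrics: pd.DataFrame,
    tolerance: float = 0.10,
    prefer_higher: bool = True,
) -> RankSelectionResult:
    """Choose the rank accepted by the most quality metrics.

    ``metrics`` is a table indexed by candidate rank with columns
    cophenetic, silhouette, rss, dispersion, evar (missing values make
    the metric abstain at that rank).  ``tolerance`` is the relative
    acceptance band (e.g. 0.10 for taxonomic, 0.05 for functional
    analyses).
    """
    if len(metrics) < 2:
        raise ValueError("need at least two candidate ranks")
    if not (0 < tolerance < 1):
        raise ValueError("tolerance must be in (0, 1)")
    ranks = [int(r) for r in metrics.index]
    if ranks != sorted(ranks):
        raise ValueError("candidate ranks must be strictly increasing")

    acceptable: dict[str, set[int]] = {}
    abstentions: dict[str, list[int]] = {}
    for metric, maximize in METRIC_ORIENTATION.items():
        if metric not in metrics.columns:
            continue
        col = metrics[metric]
        missing = [int(r) for r in col.index[col.isna()]]
        if missing:
            abstentions[metric] = missing
        acceptable[metric] = _acceptable(col, maximize, tolerance)

    votes = {r: sum(r in s for s in acceptable.values()) for r in ranks}
    best_votes = max(votes.values())
    tied = [r for r, v in votes.items() if v == best_votes]
    chosen = max(tied) if prefer_higher else min(tied)
    return RankSelectionResult(
        candidate_ranks=ranks,
        acceptable_sets=acceptable,
        votes=votes,
        chosen_k=chosen,
        tolerance=tolerance,
        abstentions=abstentions,
    )
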