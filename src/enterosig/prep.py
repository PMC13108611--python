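"""Feature filtering, total-sum scaling, and sparsity diagnostics.

Features are retained when they are prevalent (non-zero in at least a
fraction of samples) OR abundant (mean above a quantile of all feature
means); the disjunction keeps rare-but-dominant taxa that a prevalence
rule alone would discard.  Total-sum scaling (TSS) converts each sample
to within-sample proportions, the standard preprocessing for NMF on
microbiome data because it removes library-size effects while keeping
the matrix non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrices import AbundanceMatrix


@dataclass
class FilterReport:
    n_features_before: int
    n_features_after: int
    sparsity_before: float
    sparsity_after: float
    prevalence_min: float
    abundance_quantile: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_features(
    m: AbundanceMatrix,
    prevalence_min: float = 0.20,
    abundance_quantile: float = 0.75,
    return_report: bool = False,
):
    """Keep features present in >= ``prevalence_min`` of samples or with a
    mean abundance strictly above the ``abundance_quantile`` quantile of all
    per-feature means.

    "Present" means strictly greater than zero.  The quantile is computed
    over the per-feature means of the *input* matrix with linear
    interpolation.  Column order is preserved; values are untouched.
    """
    if not (0 < prevalence_min <= 1):
        raise ValueError("prevalence_min must be in (0, 1]")
    if not (0 < abundance_quantile < 1):
        raise ValueError("abundance_quantile must be in (0, 1)")
    if m.n_samples == 0 or m.n_features == 0:
        raise ValueError("cannot filter an empty matrix")

    prevalence = (m.values > 0).mean(axis=0)
    means = m.values.mean(axis=0)
    threshold = np.quantile(means, abundance_quantile)
    keep = (prevalence >= prevalence_min) | (means > threshold)
    if not keep.any():
        raise ValueError(
            "filtering removed every feature "
            f"(prevalence_min={prevalence_min}, abundance_quantile={abundance_quantile}); "
            f"max prevalence {prevalence.max():.3f}, quantile threshold {threshold:.4g}"
        )
    out = m.subset_features(np.where(keep)[0])
    if return_report:
        report = FilterReport(
            n_features_before=m.n_features,
            n_features_after=out.n_features,
            sparsity_before=sparsity(m),
            sparsity_after=sparsity(out),
            prevalence_min=prevalence_min,
            abundance_quantile=abundance_quantile,
        )
        return out, report
    return out


def tss_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Total-sum scaling: divide each sample row by its total.

    All-zero rows are left all-zero and reported with a warning rather
    than raising, so sample count is never changed silently.
    """
    totals = m.values.sum(axis=1)
    zero_rows = totals == 0
    if zero_rows.any():
        ids = [m.sample_ids[i] for i in np.where(zero_rows)[0]]
        warnings.warn(f"all-zero samples left unnormalized: {ids}", stacklevel=2)
    safe = np.where(zero_rows, 1.0, totals)
    return AbundanceMatrix(
        values=m.values / safe[:, None],
        sample_ids=list(m.sample_ids),
        feature_ids=list(m.feature_ids),
        kind=m.kind,
    )


def sparsity(m: AbundanceMatrix) -> float:
    """Fraction of exactly-zero entries."""
    if m.values.size == 0:
        raise ValueError("sparsity of an empty matrix is undefined")
    return float((m.values == 0).mean())
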