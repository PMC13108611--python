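"""Loading normalization and longitudinal association statistics.

NMF loadings are compositional (per-sample contributions that sum to a
constant scale), so before modeling they are normalized in two steps:
trimmed-mean-of-M-values (TMM) scale factors absorb sample-level
composition bias, and a centered log-ratio (CLR) transform maps each
sample's loadings to an unconstrained space whose rows sum to zero.

Two mixed models are fitted per signature, both with a random intercept
per animal:

  loading  ~ timepoint * line                      (signature dynamics)
  phenotype ~ loading * timepoint * line           (host associations)

Inference uses type-III F tests with Satterthwaite denominator degrees
of freedom, Benjamini-Hochberg FDR within each test family, estimated
marginal means with pairwise contrasts, and Cohen's d between genetic
lines with noncentral-t 95% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .mixedlm import LMMFit, anova_table, fit_lmm

LINE_LEVELS = ("TOL", "SEN")
TIME_LEVELS = ("d4", "d8", "d14")


# ---------------------------------------------------------------- TMM / CLR


@dataclass
class NormalizedLoadings:
    clr: np.ndarray  # samples x signatures, rows sum to 0
    tmm_factors: np.ndarray
    pseudocount: float
    reference_sample: int


def _tmm_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> float:
    """One TMM scale factor: weighted mean of doubly trimmed log-ratios.

    M-values (log2 ratios) are trimmed by ``logratio_trim`` total and
    A-values (mean log2 abundance) by ``abs_trim`` total, with inverse
    approximate-variance weights, following the conventional TMM
    recipe.
    """
    n_o, n_r = obs.sum(), ref.sum()
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        warnings.warn("sample shares no co-positive entries with the reference; "
                      "TMM factor set to 1", stacklevel=3)
        return 1.0
    o, r = obs[mask] / n_o, ref[mask] / n_r
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    w = 1.0 / ((1 - obs[mask] / n_o) / obs[mask] + (1 - ref[mask] / n_r) / ref[mask])
    m = M.size
    lo_m, hi_m = np.floor(m * logratio_trim / 2), np.ceil(m * (1 - logratio_trim / 2))
    lo_a, hi_a = np.floor(m * abs_trim / 2), np.ceil(m * (1 - abs_trim / 2))
    rank_m = stats.rankdata(M, method="ordinal")
    rank_a = stats.rankdata(A, method="ordinal")
    keep = (rank_m > lo_m) & (rank_m <= hi_m) & (rank_a > lo_a) & (rank_a <= hi_a)
    if keep.sum() == 0:
        keep = np.ones(m, dtype=bool)
    f = float(np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    return float(2.0**f)


def tmm_clr(
    W: np.ndarray,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> NormalizedLoadings:
    """TMM-scale then CLR-transform a loading matrix.

    The reference sample is the one whose upper-quartile loading
    (relative to its total) is closest to the mean upper quartile.
    Scale factors are normalized to geometric mean 1.  A pseudocount of
    half the smallest positive scaled value replaces zeros before the
    log transform; CLR rows sum to zero exactly.
    """
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("loadings must be non-negative")
    # multiplicative NMF updates can leave denormal residues; anything
    # below machine precision relative to the matrix scale is a zero
    tiny = 1e-12 * W.max()
    W = np.where(W > tiny, W, 0.0)
    totals = W.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("loading rows must have positive sums")
    q75 = np.array([np.quantile(row / tot, 0.75) for row, tot in zip(W, totals)])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array(
        [
            _tmm_factor(W[i], W[ref_idx], logratio_trim, abs_trim)
            if i != ref_idx else 1.0
            for i in range(W.shape[0])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    scaled = W / (totals * factors)[:, None]
    positive = scaled[scaled > 0]
    pc = 0.5 * positive.min() if positive.size else 1e-9
    # multiplicative zero replacement: only zeros receive the pseudocount,
    # so CLR is exact on strictly positive rows
    filled = np.where(scaled > 0, scaled, pc)
    logx = np.log(filled)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return NormalizedLoadings(
        clr=clr, tmm_factors=factors, pseudocount=float(pc),
        reference_sample=ref_idx,
    )


# ------------------------------------------------------------------ designs


def _sum_code(values: pd.Series, levels: tuple[str, ...]) -> np.ndarray:
    """Sum-to-zero (deviation) coding: L levels -> L-1 columns."""
    out = np.zeros((len(values), len(levels) - 1))
    arr = values.to_numpy()
    for c, lev in enumerate(levels[:-1]):
        out[arr == lev, c] = 1.0
    out[arr == levels[-1], :] = -1.0
    return out


class _Design:
    """Fixed-effect design with sum coding and named term blocks.

    Building the matrix by explicit column products keeps the mapping
    from terms to columns (needed for type-III tests) and lets the
    same machinery emit prediction rows for estimated marginal means.
    """

    def __init__(self, metadata: pd.DataFrame, es: np.ndarray | None = None):
        self.time_levels = tuple(
            t for t in TIME_LEVELS if t in set(metadata["timepoint"])
        ) or tuple(pd.unique(metadata["timepoint"]))
        self.line_levels = tuple(
            l for l in LINE_LEVELS if l in set(metadata["line"])
        ) or tuple(pd.unique(metadata["line"]))
        self.has_es = es is not None
        self.es_mean = float(np.mean(es)) if self.has_es else 0.0
        self.X, self.names, self.term_slices = self._build(metadata, es)

    def _blocks(self, tp: np.ndarray, ln: np.ndarray, es_col: np.ndarray | None):
        blocks: dict[str, np.ndarray] = {"Intercept": np.ones((len(tp), 1))}
        T = np.zeros((len(tp), len(self.time_levels) - 1))
        arr = np.asarray(tp)
        for c, lev in enumerate(self.time_levels[:-1]):
            T[arr == lev, c] = 1.0
        T[arr == self.time_levels[-1], :] = -1.0
        G = np.zeros((len(ln), len(self.line_levels) - 1))
        arr = np.asarray(ln)
        for c, lev in enumerate(self.line_levels[:-1]):
            G[arr == lev, c] = 1.0
        G[arr == self.line_levels[-1], :] = -1.0
        blocks["timepoint"] = T
        blocks["line"] = G
        blocks["timepoint:line"] = np.einsum("ni,nj->nij", T, G).reshape(len(tp), -1)
        if es_col is not None:
            E = es_col[:, None]
            blocks["loading"] = E
            blocks["loading:timepoint"] = E * T
            blocks["loading:line"] = E * G
            blocks["loading:timepoint:line"] = E * blocks["timepoint:line"]
        return blocks

    _TERM_ORDER = (
        "Intercept", "loading", "timepoint", "line", "loading:timepoint",
        "loading:line", "timepoint:line", "loading:timepoint:line",
    )

    def _build(self, metadata: pd.DataFrame, es: np.ndarray | None):
        blocks = self._blocks(
            metadata["timepoint"].to_numpy(),
            metadata["line"].to_numpy(),
            np.asarray(es, float) if es is not None else None,
        )
        cols, names, slices = [], [], {}
        j = 0
        for term in self._TERM_ORDER:
            if term not in blocks:
                continue
            B = blocks[term]
            cols.append(B)
            slices[term] = np.arange(j, j + B.shape[1])
            names += [f"{term}[{c}]" for c in range(B.shape[1])]
            j += B.shape[1]
        return np.hstack(cols), names, slices

    def prediction_row(self, line: str, timepoint: str, es: float | None = None):
        md = pd.DataFrame({"timepoint": [timepoint], "line": [line]})
        es_col = np.array([es if es is not None else self.es_mean]) if self.has_es else None
        blocks = self._blocks(
            md["timepoint"].to_numpy(), md["line"].to_numpy(), es_col
        )
        row = [blocks[t][0] for t in self._TERM_ORDER if t in blocks]
        return np.concatenate(row)


# --------------------------------------------------------------- model fits


@dataclass
class AssociationResult:
    """Inference bundle for one response.

    ``anova`` holds type-III F tests (with BH-adjusted p across the
    model's effects); ``emmeans`` the line x timepoint marginal means;
    ``contrasts`` the pairwise comparisons (BH-adjusted within this
    model's contrast family); ``effect_sizes`` Cohen's d between lines
    per timepoint with 95% CI.
    """

    response: str
    anova: pd.DataFrame
    emmeans: pd.DataFrame
    contrasts: pd.DataFrame
    effect_sizes: pd.DataFrame
    converged: bool
    singular: bool
    fit: LMMFit = field(repr=False, default=None)


def significance_code(p: float) -> str:
    """Conventional annotation: *** <0.001, ** <0.01, * <0.05, . <0.10."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "."
    return ""


def fdr_adjust(p, family=None) -> np.ndarray:
    """Benjamini-Hochberg step-up, independently within each family."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if family is None:
        family = np.zeros(p.size)
    family = np.asarray(family)
    out = np.empty_like(p)
    for fam in pd.unique(family):
        idx = np.where(family == fam)[0]
        if idx.size == 0:
            raise ValueError("empty p-value family")
        finite = np.isfinite(p[idx])
        out[idx] = np.nan
        if finite.any():
            out[idx[finite]] = multipletests(p[idx[finite]], method="fdr_bh")[1]
    return out


def cohens_d(x, y, ci: float = 0.95) -> tuple[float, float, float]:
    """Standardized mean difference with a noncentral-t confidence interval.

    d = (mean_x - mean_y) / s_pooled, where s_pooled uses the
    (n_x + n_y - 2)-df pooled variance.  The CI inverts the noncentral-t
    distribution of the associated two-sample t statistic.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 values")
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("zero pooled standard deviation")
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    scale = np.sqrt(1.0 / nx + 1.0 / ny)
    t_obs = d / scale
    alpha = 1.0 - ci

    def _cdf(nc: float) -> float:
        v = stats.nct.cdf(t_obs, df, nc)
        if np.isnan(v):  # extreme noncentrality underflows; use the limit
            return 0.0 if nc > t_obs else 1.0
        return float(v)

    def _solve(target: float) -> float:
        # cdf is decreasing in nc; expand a bracket around t_obs
        f = lambda nc: _cdf(nc) - target
        lo, hi, step = t_obs, t_obs, 1.0
        while f(lo) < 0:
            lo -= step
            step *= 2
        step = 1.0
        while f(hi) > 0:
            hi += step
            step *= 2
        return optimize.brentq(f, lo, hi, xtol=1e-8)

    nc_lo = _solve(1.0 - alpha / 2.0)
    nc_hi = _solve(alpha / 2.0)
    return float(d), float(nc_lo * scale), float(nc_hi * scale)


def _emmeans_and_contrasts(fit: LMMFit, design: _Design) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marginal means on the line x timepoint grid and the pairwise
    contrast family: line difference per timepoint, then temporal
    differences within each line."""
    grid_rows, grid_meta = [], []
    for ln in design.line_levels:
        for tp in design.time_levels:
            grid_rows.append(design.prediction_row(ln, tp))
            grid_meta.append((ln, tp))
    emm = []
    for (ln, tp), row in zip(grid_meta, grid_rows):
        est, se, df, p = fit.contrast_t(row)
        emm.append({"line": ln, "timepoint": tp, "emmean": est, "SE": se, "df": df})
    emm = pd.DataFrame(emm)

    rowmap = {m: r for m, r in zip(grid_meta, grid_rows)}
    contrasts = []
    if len(design.line_levels) == 2:
        l1, l2 = design.line_levels
        for tp in design.time_levels:
            ell = rowmap[(l1, tp)] - rowmap[(l2, tp)]
            est, se, df, p = fit.contrast_t(ell)
            contrasts.append(
                {"contrast": f"{l1}-{l2} @ {tp}", "estimate": est, "SE": se,
                 "df": df, "p": p}
            )
    for ln in design.line_levels:
        tps = design.time_levels
        for i in range(len(tps)):
            for j in range(i + 1, len(tps)):
                ell = rowmap[(ln, tps[i])] - rowmap[(ln, tps[j])]
                est, se, df, p = fit.contrast_t(ell)
                contrasts.append(
                    {"contrast": f"{tps[i]}-{tps[j]} @ {ln}", "estimate": est,
                     "SE": se, "df": df, "p": p}
                )
    contrasts = pd.DataFrame(contrasts)
    if len(contrasts):
        contrasts["p_adj"] = fdr_adjust(contrasts["p"].to_numpy())
        contrasts["sig"] = [significance_code(q) for q in contrasts["p_adj"]]
    return emm, contrasts


def marginal_means_contrasts(fit: LMMFit, design: _Design) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Public wrapper: estimated marginal means and pairwise contrasts."""
    return _emmeans_and_contrasts(fit, design)


def _line_effect_sizes(
    y: np.ndarray, metadata: pd.DataFrame, design: _Design
) -> pd.DataFrame:
    rows = []
    if len(design.line_levels) != 2:
        return pd.DataFrame(rows)
    l1, l2 = design.line_levels
    for tp in design.time_levels:
        a = y[(metadata["line"] == l1) & (metadata["timepoint"] == tp)]
        b = y[(metadata["line"] == l2) & (metadata["timepoint"] == tp)]
        if len(a) < 2 or len(b) < 2:
            continue
        try:
            d, lo, hi = cohens_d(a, b)
        except ValueError:
            continue
        rows.append(
            {"timepoint": tp, "comparison": f"{l1}-{l2}", "d": d,
             "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)


def fit_es_model(
    y: np.ndarray, metadata: pd.DataFrame, response: str = "loading"
) -> AssociationResult:
    """Signature-dynamics model: loading ~ timepoint * line + (1 | animal).

    ``y`` is a normalized (TMM + CLR) loading vector aligned with
    ``metadata`` rows.
    """
    y = np.asarray(y, dtype=float)
    _check_metadata(metadata, y)
    design = _Design(metadata)
    fit = fit_lmm(
        y, design.X, metadata["animal_id"].to_numpy(),
        column_names=design.names, term_slices=design.term_slices,
    )
    return _bundle(fit, design, y, metadata, response)


def fit_phenotype_model(
    P: np.ndarray, es_load: np.ndarray, metadata: pd.DataFrame,
    response: str = "phenotype",
) -> AssociationResult:
    """Host-association model:
    phenotype ~ loading * timepoint * line + (1 | animal),
    with the signature loading as a continuous covariate and the full
    two- and three-way interaction structure retained."""
    P = np.asarray(P, dtype=float)
    es_load = np.asarray(es_load, dtype=float)
    _check_metadata(metadata, P)
    if len(es_load) != len(P):
        raise ValueError("es_load and P must align")
    design = _Design(metadata, es=es_load)
    fit = fit_lmm(
        P, design.X, metadata["animal_id"].to_numpy(),
        column_names=design.names, term_slices=design.term_slices,
    )
    return _bundle(fit, design, P, metadata, response)


def _check_metadata(metadata: pd.DataFrame, y: np.ndarray) -> None:
    for col in ("animal_id", "line", "timepoint"):
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    if len(metadata) != len(y):
        raise ValueError("response and metadata must align")
    if metadata["line"].nunique() < 2 or metadata["timepoint"].nunique() < 2:
        raise ValueError("each design factor needs at least 2 observed levels")


def _bundle(
    fit: LMMFit, design: _Design, y: np.ndarray, metadata: pd.DataFrame,
    response: str,
) -> AssociationResult:
    table = anova_table(fit)
    if len(table):
        table["p_adj"] = fdr_adjust(table["p"].to_numpy())
        table["sig"] = [significance_code(q) for q in table["p_adj"]]
        table.insert(0, "response", response)
    if fit.converged:
        emm, contrasts = _emmeans_and_contrasts(fit, design)
    else:
        emm, contrasts = pd.DataFrame(), pd.DataFrame()
    eff = _line_effect_sizes(y, metadata, design)
    return AssociationResult(
        response=response,
        anova=table,
        emmeans=emm,
        contrasts=contrasts,
        effect_sizes=eff,
        converged=fit.converged,
        singular=fit.singular,
        fit=fit,
    )
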