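"""KL-divergence (Brunet) NMF with multi-run consensus and quality metrics.

The factorization V ~ W.H (V: samples x features, W: samples x k
loadings, H: k x features coefficients) is fitted by the classical
multiplicative updates for the generalized Kullback-Leibler divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ],

which are monotone non-increasing in the objective.  Because NMF is
non-convex, rank assessment relies on repeated runs from random starts:
the consensus matrix records how often two samples share the same
dominant factor across runs, and five quality metrics (cophenetic
correlation, silhouette width, residual sum of squares, dispersion,
explained variance) summarize fit and stability per candidate rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .matrices import AbundanceMatrix

_EPS = 1e-12

try:  # optional JIT fast path; the numpy fallback is arithmetically identical
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco


@njit(cache=False)
def _mu_kl_core(V, W, H, max_iter, tol, window, eps):
    """Multiplicative KL updates; objective checked once per window."""
    n, p = V.shape
    k = W.shape[1]
    vlogv = 0.0
    for i in range(n):
        for j in range(p):
            v = V[i, j]
            if v > 0.0:
                vlogv += v * np.log(v) - v
    trace = np.empty(max_iter // window + 1)
    nt = 0
    prev = np.inf
    converged = False
    n_iter = 0
    WH = np.empty((n, p))
    R = np.empty((n, p))
    for it in range(max_iter):
        np.dot(W, H, WH)
        for i in range(n):
            for j in range(p):
                s = WH[i, j]
                if s < eps:
                    s = eps
                R[i, j] = V[i, j] / s
        numH = np.dot(W.T, R)
        for t in range(k):
            ws = 0.0
            for i in range(n):
                ws += W[i, t]
            if ws < eps:
                ws = eps
            for j in range(p):
                H[t, j] *= numH[t, j] / ws
        np.dot(W, H, WH)
        for i in range(n):
            for j in range(p):
                s = WH[i, j]
                if s < eps:
                    s = eps
                R[i, j] = V[i, j] / s
        numW = np.dot(R, H.T)
        for t in range(k):
            hs = 0.0
            for j in range(p):
                hs += H[t, j]
            if hs < eps:
                hs = eps
            for i in range(n):
                W[i, t] *= numW[i, t] / hs
        n_iter = it + 1
        if n_iter % window == 0 or n_iter == max_iter:
            np.dot(W, H, WH)
            obj = vlogv
            for i in range(n):
                for j in range(p):
                    s = WH[i, j]
                    if s < eps:
                        s = eps
                    obj += s
                    if V[i, j] > 0.0:
                        obj -= V[i, j] * np.log(s)
            trace[nt] = obj
            nt += 1
            denom = abs(prev) if np.isfinite(prev) and prev != 0.0 else 1.0
            if np.isfinite(prev) and (prev - obj) / denom < tol:
                converged = True
                break
            prev = obj
    return W, H, trace[:nt], converged, n_iter


@dataclass
class NMFModel:
    """One fitted factorization.

    ``objective_trace`` holds the KL objective evaluated at the end of
    each convergence window (every ``window`` iterations); it is
    non-increasing by the multiplicative-update guarantee.  After
    fitting, H rows are scaled to sum to 1 and W absorbs the scale, so
    loadings are comparable across samples while W @ H is unchanged.
    """

    W: np.ndarray
    H: np.ndarray
    k: int
    objective_trace: np.ndarray
    converged: bool
    seed: int
    n_runs: int = 1
    best_run_index: int = 0

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class ConsensusMatrix:
    """Sample x sample co-assignment frequencies over NMF runs."""

    C: np.ndarray
    n_runs: int

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if not np.allclose(C, C.T):
            raise ValueError("consensus matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("consensus diagonal must be 1")
        if C.min() < -1e-12 or C.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")
        self.C = np.clip(C, 0.0, 1.0)


def _as_array(V) -> np.ndarray:
    if isinstance(V, AbundanceMatrix):
        return V.values
    return np.asarray(V, dtype=float)


def _mu_kl_numpy(V, W, H, max_iter, tol, window):
    """Pure-numpy mirror of the jitted update loop."""
    nz = V > 0
    v_nz = V[nz]
    vlogv = float(np.sum(v_nz * np.log(v_nz)) - V.sum())
    WH = np.empty_like(V)
    trace = []
    converged = False
    prev = np.inf
    for it in range(max_iter):
        np.matmul(W, H, out=WH)
        np.maximum(WH, _EPS, out=WH)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        np.matmul(W, H, out=WH)
        np.maximum(WH, _EPS, out=WH)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        n_iter = it + 1
        if n_iter % window == 0 or n_iter == max_iter:
            np.matmul(W, H, out=WH)
            np.maximum(WH, _EPS, out=WH)
            obj = vlogv + WH.sum() - float(np.sum(v_nz * np.log(WH[nz])))
            trace.append(obj)
            denom = abs(prev) if np.isfinite(prev) and prev != 0 else 1.0
            if np.isfinite(prev) and (prev - obj) / denom < tol:
                converged = True
                break
            prev = obj
    return W, H, np.asarray(trace), converged


def nmf_brunet(
    V,
    k: int,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
    window: int = 10,
) -> NMFModel:
    """Fit one KL-divergence NMF by multiplicative updates.

    W and H are initialized from seeded uniform(0, 1) variates scaled to
    the mean of V.  Iteration stops when the relative objective change
    over a ``window``-iteration span drops below ``tol``, or at
    ``max_iter``.
    """
    V = _as_array(V)
    n, p = V.shape
    if not np.all(np.isfinite(V)):
        raise ValueError("V contains non-finite values")
    if (V < 0).any():
        raise ValueError("V must be non-negative")
    if not (1 <= k < min(n, p)):
        raise ValueError(f"rank {k} out of range for a {n}x{p} matrix")
    row_sums = V.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("V has all-zero rows; drop or flag them before fitting")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k)
    W = scale * rng.uniform(_EPS, 1.0, size=(n, k))
    H = scale * rng.uniform(_EPS, 1.0, size=(k, p))

    if _HAVE_NUMBA:
        W, H, trace, converged, _ = _mu_kl_core(
            np.ascontiguousarray(V), W, H, max_iter, tol, window, _EPS
        )
    else:  # pragma: no cover - exercised only without numba
        W, H, trace, converged = _mu_kl_numpy(V, W, H, max_iter, tol, window)

    # fix factor scale: H rows sum to 1, W absorbs the scale
    h_scale = H.sum(axis=1)
    ok = h_scale > 0
    H[ok] /= h_scale[ok, None]
    W[:, ok] *= h_scale[ok][None, :]

    return NMFModel(
        W=W, H=H, k=k, objective_trace=trace, converged=converged, seed=seed,
    )


def _connectivity(W: np.ndarray) -> np.ndarray:
    labels = np.argmax(W, axis=1)
    return (labels[:, None] == labels[None, :]).astype(float)


def multi_run(
    V,
    k: int,
    n_runs: int = 10,
    base_seed: int = 12345,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[NMFModel, ConsensusMatrix]:
    """Repeat the factorization from ``n_runs`` seeded starts.

    Returns the run with the lowest final KL objective together with
    the consensus matrix (fraction of runs in which each sample pair
    shares its dominant factor).  Runs that fail numerically are
    excluded with a warning; all runs failing is an error.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    Va = _as_array(V)
    models: list[NMFModel] = []
    C = np.zeros((Va.shape[0], Va.shape[0]))
    used = 0
    for r in range(n_runs):
        try:
            m = nmf_brunet(Va, k, max_iter=max_iter, tol=tol, seed=base_seed + r)
        except (ValueError, FloatingPointError):
            raise
        if not np.isfinite(m.final_objective):
            warnings.warn(f"run {r} (seed {base_seed + r}) diverged; excluded",
                          stacklevel=2)
            continue
        models.append(m)
        C += _connectivity(m.W)
        used += 1
    if not models:
        raise RuntimeError("all NMF runs failed")
    C /= used
    np.fill_diagonal(C, 1.0)
    best_idx = int(np.argmin([m.final_objective for m in models]))
    best = models[best_idx]
    best.n_runs = used
    best.best_run_index = best_idx
    return best, ConsensusMatrix(C=C, n_runs=used)


def _cophenetic_correlation(C: np.ndarray) -> float:
    d = squareform(1.0 - C, checks=False)
    if d.size == 0:
        return float("nan")
    Z = average(d)
    coph = cophenet(Z)
    if np.std(d) == 0 or np.std(coph) == 0:
        # degenerate: all pairwise consensus identical
        return 1.0 if np.allclose(d, coph) else 0.0
    return float(np.corrcoef(d, coph)[0, 1])


def consensus_clusters(C: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage hierarchical clustering of 1 - C cut at k clusters."""
    Z = average(squareform(1.0 - C, checks=False))
    return fcluster(Z, t=k, criterion="maxclust")


def quality_metrics(V, model: NMFModel, consensus: ConsensusMatrix) -> dict:
    """The five per-rank quality metrics.

    cophenetic: Pearson correlation between 1 - C distances and the
    cophenetic distances of their average-linkage dendrogram.
    silhouette: mean silhouette width of the consensus clustering at k
    clusters under distance 1 - C (NaN with a warning if the clustering
    is degenerate).  rss: sum((V - WH)^2).  dispersion: mean of
    4 (C - 1/2)^2.  evar: 1 - rss / sum(V^2).
    """
    Va = _as_array(V)
    C = consensus.C
    WH = model.reconstruct()
    rss = float(np.sum((Va - WH) ** 2))
    evar = 1.0 - rss / float(np.sum(Va**2))
    dispersion = float(np.mean(4.0 * (C - 0.5) ** 2))
    coph = _cophenetic_correlation(C)
    labels = consensus_clusters(C, model.k)
    n_occupied = len(np.unique(labels))
    if n_occupied < 2 or n_occupied >= len(labels):
        warnings.warn(
            f"degenerate consensus clustering ({n_occupied} clusters); "
            "silhouette reported as missing", stacklevel=2,
        )
        sil = float("nan")
    else:
        sil = float(silhouette_score(1.0 - C, labels, metric="precomputed"))
    return {
        "rank": model.k,
        "cophenetic": coph,
        "silhouette": sil,
        "rss": rss,
        "dispersion": dispersion,
        "evar": evar,
    }


def scan_ranks(
    V,
    ranks=range(2, 9),
    n_runs: int = 10,
    base_seed: int = 12345,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Fit every candidate rank and tabulate the five quality metrics.

    Each rank gets its own seed block (``base_seed + 1000 * rank``) so
    runs never share a stream across ranks.  Scan runs estimate
    stability rather than deliver the final model, so their iteration
    budget defaults to half the final-fit budget; the consensus and
    fit metrics plateau well before full convergence.
    """
    rows = []
    for k in ranks:
        best, cons = multi_run(
            V, k, n_runs=n_runs, base_seed=base_seed + 1000 * k,
            max_iter=max_iter, tol=tol,
        )
        rows.append(quality_metrics(V, best, cons))
    table = pd.DataFrame(rows).set_index("rank")
    if not table.index.is_monotonic_increasing:
        table = table.sort_index()
    return table
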