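"""Random-intercept linear mixed model with Satterthwaite inference.

The model is y = X beta + Z u + e, with one random intercept per
animal, u ~ N(0, sigma_a^2 I) and e ~ N(0, sigma_e^2 I).  Variance
components are estimated by REML with the error variance profiled out,
leaving a one-dimensional search over the ratio lambda =
sigma_a^2 / sigma_e^2.  Fixed effects are the GLS solution at the
estimated covariance; type-III F tests use sum-to-zero factor coding so
each term's coefficient block tests its partial hypothesis; and
denominator degrees of freedom follow Satterthwaite's approximation:
for a contrast l, nu = 2 (l' C l)^2 / (g' A g), where C is the
fixed-effect covariance, g the gradient of l' C l with respect to the
variance components, and A their asymptotic (inverse REML information)
covariance.  Multi-degree-of-freedom terms combine one-df contrasts
through the spectral decomposition of the contrast covariance, as in
standard mixed-model ANOVA practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_SINGULAR_TOL = 1e-6


@dataclass
class LMMFit:
    """Fitted random-intercept model and the pieces inference needs."""

    beta: np.ndarray
    cov_beta: np.ndarray  # C = (X' V^-1 X)^-1
    sigma_a2: float
    sigma_e2: float
    theta_cov: np.ndarray  # asymptotic cov of (sigma_a2, sigma_e2)
    XtVinv: np.ndarray  # X' V^-1  (for Satterthwaite gradients)
    ZZt: np.ndarray
    n: int
    p: int
    column_names: list[str]
    term_slices: dict[str, np.ndarray]  # term -> column indices
    converged: bool
    singular: bool
    reml: float
    dropped_columns: list[str] = field(default_factory=list)

    # -- Satterthwaite machinery -------------------------------------

    def _grad_var(self, ell: np.ndarray) -> np.ndarray:
        """Gradient of l' C l w.r.t. (sigma_a2, sigma_e2)."""
        # dC/dtheta_i = C X'V^-1 (dV/dtheta_i) V^-1 X C
        a = self.XtVinv.T @ (self.cov_beta @ ell)  # V^-1 X C l  (n,)
        g_a = float(a @ self.ZZt @ a)
        g_e = float(a @ a)
        return np.array([g_a, g_e])

    def contrast_t(self, ell: np.ndarray) -> tuple[float, float, float, float]:
        """Estimate, SE, Satterthwaite df, and two-sided p for l' beta."""
        ell = np.asarray(ell, dtype=float)
        est = float(ell @ self.beta)
        var = float(ell @ self.cov_beta @ ell)
        se = np.sqrt(var)
        g = self._grad_var(ell)
        denom = float(g @ self.theta_cov @ g)
        df = 2.0 * var**2 / denom if denom > 0 else float(self.n - self.p)
        df = min(max(df, 1.0), float(self.n - 1))
        t = est / se if se > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(t), df)
        return est, se, df, p

    def ftest(self, L: np.ndarray) -> tuple[float, int, float, float]:
        """Type-III style F test of L beta = 0 with Satterthwaite df.

        Returns (F, df_num, df_den, p).
        """
        L = np.atleast_2d(np.asarray(L, dtype=float))
        q = np.linalg.matrix_rank(L)
        M = L @ self.cov_beta @ L.T
        Minv = np.linalg.pinv(M)
        Lb = L @ self.beta
        F = float(Lb @ Minv @ Lb) / q
        # combine 1-df Satterthwaite dfs through the eigenstructure of M
        vals, vecs = np.linalg.eigh(M)
        keep = vals > vals.max() * 1e-10 if vals.max() > 0 else vals > 0
        nus = []
        for lam, u in zip(vals[keep], vecs[:, keep].T):
            ell = L.T @ u
            var = float(ell @ self.cov_beta @ ell)  # == lam
            g = self._grad_var(ell)
            denom = float(g @ self.theta_cov @ g)
            nu = 2.0 * var**2 / denom if denom > 0 else float(self.n - self.p)
            nus.append(min(max(nu, 1.0 + 1e-8), float(self.n - 1)))
        nus = np.array(nus)
        big = nus > 2.0
        if big.all():
            E = float(np.sum(nus / (nus - 2.0)))
            df_den = 2.0 * E / (E - q) if E > q else float(self.n - self.p)
        else:
            df_den = float(np.mean(nus))
        p = stats.f.sf(F, q, df_den)
        return F, int(q), df_den, float(p)


def _drop_aliased(X: np.ndarray, names: list[str]):
    """Remove linearly dependent columns via pivoted QR."""
    from scipy.linalg import qr as _qr

    n, p = X.shape
    _, R, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    dropped = [names[j] for j in range(p) if j not in set(keep.tolist())]
    return X[:, keep], [names[j] for j in keep], keep, dropped


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    column_names: list[str] | None = None,
    term_slices: dict[str, np.ndarray] | None = None,
) -> LMMFit:
    """REML fit of the random-intercept model.

    ``groups`` assigns each observation to an animal; ``term_slices``
    maps fixed-effect term names to their column indices in X (used by
    the ANOVA table builder).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p0 = X.shape
    if column_names is None:
        column_names = [f"x{j}" for j in range(p0)]
    X, column_names, keep, dropped = _drop_aliased(X, list(column_names))
    if term_slices is not None:
        pos = {int(j): i for i, j in enumerate(keep)}
        term_slices = {
            t: np.array([pos[int(j)] for j in idx if int(j) in pos], dtype=int)
            for t, idx in term_slices.items()
        }
        term_slices = {t: idx for t, idx in term_slices.items() if idx.size}
    p = X.shape[1]

    codes = pd.factorize(np.asarray(groups))[0]
    Z = np.zeros((n, codes.max() + 1))
    Z[np.arange(n), codes] = 1.0
    ZZt = Z @ Z.T

    In = np.eye(n)

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        G = In + lam * ZZt
        cho = np.linalg.cholesky(G)
        logdetG = 2.0 * np.log(np.diag(cho)).sum()
        Gi_y = np.linalg.solve(G, y)
        Gi_X = np.linalg.solve(G, X)
        XtGiX = X.T @ Gi_X
        sign, logdetXGX = np.linalg.slogdet(XtGiX)
        beta = np.linalg.solve(XtGiX, X.T @ Gi_y)
        r = y - X @ beta
        quad = float(r @ np.linalg.solve(G, r))
        s2 = max(quad / (n - p), 1e-12)  # guard exact-fit responses
        return (n - p) * np.log(s2) + logdetG + logdetXGX

    res = optimize.minimize_scalar(
        neg2_reml, bounds=(-20.0, 15.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    converged = bool(res.success)

    G = In + lam * ZZt
    Gi_X = np.linalg.solve(G, X)
    XtGiX = X.T @ Gi_X
    beta = np.linalg.solve(XtGiX, X.T @ np.linalg.solve(G, y))
    r = y - X @ beta
    sigma_e2 = max(float(r @ np.linalg.solve(G, r)) / (n - p), 1e-12)
    sigma_a2 = lam * sigma_e2
    singular = sigma_a2 < _SINGULAR_TOL * sigma_e2

    V = sigma_e2 * G
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    C = np.linalg.inv(XtVinv @ X)

    # REML information for (sigma_a2, sigma_e2): I_ij = tr(P Vi P Vj)/2
    P = Vinv - Vinv @ X @ C @ XtVinv
    PZ = P @ ZZt
    info = 0.5 * np.array(
        [
            [np.trace(PZ @ PZ), np.trace(PZ @ P)],
            [np.trace(PZ @ P), np.trace(P @ P)],
        ]
    )
    try:
        theta_cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        theta_cov = np.linalg.pinv(info)

    return LMMFit(
        beta=beta,
        cov_beta=C,
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        theta_cov=theta_cov,
        XtVinv=XtVinv,
        ZZt=ZZt,
        n=n,
        p=p,
        column_names=column_names,
        term_slices=term_slices or {},
        converged=converged,
        singular=singular,
        reml=float(res.fun),
        dropped_columns=dropped,
    )


def anova_table(fit: LMMFit) -> pd.DataFrame:
    """Type-III F tests (Satterthwaite df) for every non-intercept term."""
    rows = []
    for term, idx in fit.term_slices.items():
        if term in ("Intercept", "1"):
            continue
        L = np.zeros((len(idx), fit.p))
        for r, j in enumerate(idx):
            L[r, j] = 1.0
        F, df1, df2, pval = fit.ftest(L)
        rows.append(
            {"effect": term, "F": F, "df_num": df1, "df_den": df2, "p": pval}
        )
    return pd.DataFrame(rows)
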