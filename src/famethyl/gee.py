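"""Generalized estimating equations for Gaussian clustered outcomes.

Identity link, working variance A_i = phi * I, and an independence or
exchangeable working correlation.  Coefficients solve

    sum_i X_i' A_i^{-1/2} R_i^{-1} A_i^{-1/2} (y_i - X_i beta) = 0

by iterating a weighted least-squares update of beta with moment updates of
the dispersion phi and the common correlation alpha (the standard
Liang-Zeger choices).  Three coefficient covariances are produced: the
model-based inverse bread, the robust sandwich, and the Mancl-DeRouen
bias-corrected sandwich in which each cluster's residual outer product is
inflated by the inverse of (I - H_i), H_i being the cluster leverage.

Clusters are grouped by size internally so the per-iteration work is a few
einsums per distinct cluster size; the exchangeable inverse
R^{-1} = [I - alpha/(1+(n-1)alpha) J] / (1-alpha) is used in closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class LeverageError(np.linalg.LinAlgError):
    """(I - H_i) singular: a cluster saturates the fit."""


@dataclass
class _SizeGroup:
    size: int
    cluster_index: np.ndarray  # positions in the original cluster order
    Y: np.ndarray  # (m, n)
    X: np.ndarray  # (m, n, p)


@dataclass
class ClusteredDesign:
    """Per-cluster outcome vectors and design matrices.

    Build with :meth:`from_long` from stacked arrays plus cluster labels.
    Cluster sizes may vary; all clusters share the same ``p`` columns.
    """

    ys: list[np.ndarray]
    Xs: list[np.ndarray]
    _groups: list[_SizeGroup] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.ys:
            raise ValueError("design needs at least one cluster")
        p = self.Xs[0].shape[1]
        for y, X in zip(self.ys, self.Xs):
            if X.shape != (y.shape[0], p):
                raise ValueError("inconsistent cluster shapes")
            if y.shape[0] < 1:
                raise ValueError("empty cluster")
        if self.n_obs < p:
            raise ValueError("fewer observations than coefficients")
        by_size: dict[int, list[int]] = {}
        for i, y in enumerate(self.ys):
            by_size.setdefault(y.shape[0], []).append(i)
        self._groups = [
            _SizeGroup(
                size=n,
                cluster_index=np.asarray(idx),
                Y=np.stack([self.ys[i] for i in idx]),
                X=np.stack([self.Xs[i] for i in idx]),
            )
            for n, idx in sorted(by_size.items())
        ]

    @classmethod
    def from_long(cls, y, X, groups) -> "ClusteredDesign":
        """Split stacked (y, X) by cluster label (order of first appearance)."""
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        groups = np.asarray(groups)
        seen: dict = {}
        for g in groups:
            if g not in seen:
                seen[g] = len(seen)
        ys, Xs = [], []
        for g in seen:
            mask = groups == g
            ys.append(y[mask])
            Xs.append(X[mask])
        return cls(ys=ys, Xs=Xs)

    @property
    def n_clusters(self) -> int:
        return len(self.ys)

    @property
    def n_obs(self) -> int:
        return sum(y.shape[0] for y in self.ys)

    @property
    def p(self) -> int:
        return self.Xs[0].shape[1]

    @property
    def max_size(self) -> int:
        return max(y.shape[0] for y in self.ys)

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        return np.concatenate(self.ys), np.vstack(self.Xs)


@dataclass
class MarginalFit:
    beta: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray
    cov_bc: np.ndarray
    alpha: float
    phi: float
    structure: str
    n_iter: int
    converged: bool

    @property
    def cov_beta(self) -> np.ndarray:
        """Default covariance for Wald tests: the robust sandwich."""
        return self.cov_robust


def _exch_coefs(alpha: float, n: int) -> tuple[float, float]:
    """R^{-1} = c1 * I - c2 * J for the exchangeable structure."""
    c1 = 1.0 / (1.0 - alpha)
    c2 = alpha / ((1.0 - alpha) * (1.0 + (n - 1) * alpha))
    return c1, c2


def _gls_solve(design: ClusteredDesign, alpha: float) -> np.ndarray:
    p = design.p
    A = np.zeros((p, p))
    b = np.zeros(p)
    for grp in design._groups:
        c1, c2 = _exch_coefs(alpha, grp.size)
        S = grp.X.sum(axis=1)  # (m, p)
        sy = grp.Y.sum(axis=1)  # (m,)
        A += c1 * np.einsum("mnp,mnq->pq", grp.X, grp.X) - c2 * S.T @ S
        b += c1 * np.einsum("mnp,mn->p", grp.X, grp.Y) - c2 * S.T @ sy
    return np.linalg.solve(A, b)


def _moments(design: ClusteredDesign, beta: np.ndarray) -> tuple[float, float]:
    """Moment estimates (phi, alpha) from residuals at beta."""
    p = design.p
    M = design.n_obs
    ss = 0.0
    cross = 0.0
    npairs = 0.0
    for grp in design._groups:
        E = grp.Y - np.einsum("mnp,p->mn", grp.X, beta)
        ss += float((E**2).sum())
        tot = E.sum(axis=1)
        cross += float(((tot**2 - (E**2).sum(axis=1)) / 2.0).sum())
        npairs += grp.cluster_index.shape[0] * grp.size * (grp.size - 1) / 2.0
    phi = ss / (M - p)
    denom = npairs - p
    alpha = cross / phi / denom if denom > 0 else 0.0
    return phi, alpha


def _clip_alpha(alpha: float, max_size: int) -> float:
    lo = -1.0 / (max_size - 1) + 1e-6 if max_size > 1 else -0.999
    hi = 0.999
    if alpha < lo or alpha > hi:
        clipped = min(max(alpha, lo), hi)
        logger.warning(
            "alpha=%.4f outside positive-definite range, clipped to %.4f",
            alpha,
            clipped,
        )
        return clipped
    return alpha


def fit_gee(
    design: ClusteredDesign,
    structure: str = "exchangeable",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> MarginalFit:
    """Fit the marginal linear model by GEE.

    ``structure`` is ``"independence"`` (alpha fixed at 0, so beta equals
    ordinary least squares) or ``"exchangeable"``.  Non-convergence is
    flagged on the returned fit, never raised.
    """
    if structure not in ("independence", "exchangeable"):
        raise ValueError(f"unknown working structure {structure!r}")
    y_all, X_all = design.stacked()
    beta = np.linalg.lstsq(X_all, y_all, rcond=None)[0]
    alpha = 0.0
    phi, _ = _moments(design, beta)
    converged = structure == "independence"
    n_iter = 0
    if structure == "exchangeable":
        for n_iter in range(1, max_iter + 1):
            phi, alpha = _moments(design, beta)
            alpha = _clip_alpha(alpha, design.max_size)
            beta_new = _gls_solve(design, alpha)
            delta = float(np.max(np.abs(beta_new - beta)))
            beta = beta_new
            if delta < tol:
                converged = True
                break
        else:
            logger.warning("GEE did not converge in %d iterations", max_iter)
        phi, alpha_raw = _moments(design, beta)
        alpha = _clip_alpha(alpha_raw, design.max_size)
    fit = MarginalFit(
        beta=beta,
        cov_model=np.empty(0),
        cov_robust=np.empty(0),
        cov_bc=np.empty(0),
        alpha=alpha,
        phi=phi,
        structure=structure,
        n_iter=n_iter,
        converged=converged,
    )
    fit.cov_model = _bread_inv(fit, design)
    fit.cov_robust = robust_cov(fit, design)
    fit.cov_bc = mancl_derouen_cov(fit, design)
    return fit


def _bread(fit: MarginalFit, design: ClusteredDesign) -> np.ndarray:
    """B = sum_i X_i' V_i^{-1} X_i with V_i = phi * R_i."""
    p = design.p
    B = np.zeros((p, p))
    for grp in design._groups:
        c1, c2 = _exch_coefs(fit.alpha, grp.size)
        S = grp.X.sum(axis=1)
        B += c1 * np.einsum("mnp,mnq->pq", grp.X, grp.X) - c2 * S.T @ S
    return B / fit.phi


def _bread_inv(fit: MarginalFit, design: ClusteredDesign) -> np.ndarray:
    return np.linalg.inv(_bread(fit, design))


def _cluster_scores(fit, grp, E) -> np.ndarray:
    """u_i = X_i' V_i^{-1} e_i for every cluster in a size group, (m, p)."""
    c1, c2 = _exch_coefs(fit.alpha, grp.size)
    tot = E.sum(axis=1)
    U = c1 * np.einsum("mnp,mn->mp", grp.X, E) - c2 * grp.X.sum(axis=1) * tot[:, None]
    return U / fit.phi


def robust_cov(fit: MarginalFit, design: ClusteredDesign) -> np.ndarray:
    """Liang-Zeger sandwich B^{-1} M B^{-1}, M = sum_i u_i u_i'."""
    Binv = _bread_inv(fit, design)
    p = design.p
    M = np.zeros((p, p))
    for grp in design._groups:
        E = grp.Y - np.einsum("mnp,p->mn", grp.X, fit.beta)
        U = _cluster_scores(fit, grp, E)
        M += U.T @ U
    return Binv @ M @ Binv


def mancl_derouen_cov(fit: MarginalFit, design: ClusteredDesign) -> np.ndarray:
    """Bias-corrected sandwich with residuals inflated by (I - H_i)^{-1}.

    H_i = X_i B^{-1} X_i' V_i^{-1} is the cluster leverage; the correction
    removes the downward small-sample bias of the plain sandwich and reduces
    to it when every H_i vanishes.
    """
    Binv = _bread_inv(fit, design)
    p = design.p
    M = np.zeros((p, p))
    for grp in design._groups:
        n = grp.size
        c1, c2 = _exch_coefs(fit.alpha, n)
        E = grp.Y - np.einsum("mnp,p->mn", grp.X, fit.beta)
        T = np.einsum("mnp,pq,mkq->mnk", grp.X, Binv, grp.X)
        # H = T @ Vinv, Vinv = (c1 I - c2 J)/phi; T @ J has constant columns
        H = (c1 * T - c2 * T.sum(axis=2, keepdims=True)) / fit.phi
        ImH = np.eye(n)[None, :, :] - H
        try:
            Eadj = np.linalg.solve(ImH, E[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError as exc:
            raise LeverageError(
                "(I - H_i) singular: a cluster saturates the fit"
            ) from exc
        U = _cluster_scores(fit, grp, Eadj)
        M += U.T @ U
    return Binv @ M @ Binv
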