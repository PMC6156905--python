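"""Quadratic inference functions for Gaussian clustered outcomes.

The inverse exchangeable working correlation is expanded over two basis
matrices, M1 = I and M2 with zeros on the diagonal and ones elsewhere, which
turns the GEE score into m = 2 sets of unbiased extended scores

    g_i(beta) = [ X_i' A_i^{-1/2} M1 A_i^{-1/2} (y_i - X_i beta) ;
                  X_i' A_i^{-1/2} M2 A_i^{-1/2} (y_i - X_i beta) ].

beta minimizes the quadratic inference function
Q_N(beta) = N * gbar' C_N^{-1} gbar with C_N = mean of g_i g_i', by the
two-step GMM scheme: freeze C_N at the current beta, take the exact Newton
step (the scores are linear in beta), and iterate to the fixed point.
Singleton clusters contribute a structurally zero M2 block and are kept with
zero padding so dimensions never change.

Covariances: plain GMM N^{-1} (J' C^{-1} J)^{-1}, and a Mancl-DeRouen-type
bias-corrected version in which C_N is rebuilt from cluster residuals
premultiplied by (I - H_i)^{-1} (independence-working cluster hat matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gee import ClusteredDesign, LeverageError

logger = logging.getLogger(__name__)

RIDGE_EPS = 1e-10


@dataclass
class QifFit:
    beta: np.ndarray
    cov_plain: np.ndarray
    cov_bc: np.ndarray
    q_stat: float
    phi: float
    n_iter: int
    converged: bool

    @property
    def cov_beta(self) -> np.ndarray:
        return self.cov_plain


def basis_matrices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exchangeable basis (M1, M2) for cluster size n; M2 is 0 for n = 1."""
    m1 = np.eye(n)
    m2 = np.ones((n, n)) - m1
    return m1, m2


def _phi_independence(design: ClusteredDesign) -> float:
    y, X = design.stacked()
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    return float(resid @ resid) / (design.n_obs - design.p)


def _components(design: ClusteredDesign, phi: float):
    """Per-cluster a_i (2p,) and B_i (2p, p) with g_i = a_i - B_i beta."""
    N, p = design.n_clusters, design.p
    A = np.zeros((N, 2 * p))
    B = np.zeros((N, 2 * p, p))
    for grp in design._groups:
        S = grp.X.sum(axis=1)  # (m, p)
        sy = grp.Y.sum(axis=1)  # (m,)
        Xty = np.einsum("mnp,mn->mp", grp.X, grp.Y)
        XtX = np.einsum("mnp,mnq->mpq", grp.X, grp.X)
        idx = grp.cluster_index
        A[idx, :p] = Xty / phi
        A[idx, p:] = (S * sy[:, None] - Xty) / phi
        B[idx, :p, :] = XtX / phi
        B[idx, p:, :] = (np.einsum("mp,mq->mpq", S, S) - XtX) / phi
    return A, B


def extended_scores(beta, design: ClusteredDesign, phi: float = 1.0):
    """Mean extended score gbar and the list of per-cluster scores g_i."""
    beta = np.asarray(beta, dtype=float)
    A, B = _components(design, phi)
    G = A - np.einsum("ikp,p->ik", B, beta)
    return G.mean(axis=0), [G[i] for i in range(design.n_clusters)]


def _regularized_inverse_factor(C: np.ndarray):
    """Cholesky of C, ridging toward eps*tr(C)/dim*I if needed."""
    from scipy.linalg import cho_factor

    dim = C.shape[0]
    try:
        return cho_factor(C)
    except np.linalg.LinAlgError:
        pass
    ridge = RIDGE_EPS * np.trace(C) / dim
    logger.warning("C_N numerically singular; adding ridge %.3e", ridge)
    return cho_factor(C + ridge * np.eye(dim))


def fit_qif(
    design: ClusteredDesign,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> QifFit:
    """Fit by two-step GMM over the exchangeable basis expansion.

    The working marginal variance is A_i = phi * I with phi taken from a
    GEE-independence prefit (the objective and estimate are invariant to
    this scale; it only keeps the extended scores well conditioned).
    """
    from scipy.linalg import cho_solve

    N, p = design.n_clusters, design.p
    phi = _phi_independence(design)
    A, B = _components(design, phi)
    abar = A.mean(axis=0)
    Bbar = B.mean(axis=0)  # (2p, p); J = -Bbar
    y_all, X_all = design.stacked()
    beta = np.linalg.lstsq(X_all, y_all, rcond=None)[0]
    q_prev = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        G = A - np.einsum("ikp,p->ik", B, beta)
        C = G.T @ G / N
        cf = _regularized_inverse_factor(C)
        W_B = cho_solve(cf, Bbar)  # C^{-1} Bbar
        W_a = cho_solve(cf, abar)
        beta_new = np.linalg.solve(Bbar.T @ W_B, Bbar.T @ W_a)
        gbar = abar - Bbar @ beta_new
        q = float(N * gbar @ cho_solve(cf, gbar))
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < tol and abs(q - q_prev) < tol * (1.0 + abs(q)):
            converged = True
            q_prev = q
            break
        q_prev = q
    else:
        logger.warning("QIF did not converge in %d iterations", max_iter)
    G = A - np.einsum("ikp,p->ik", B, beta)
    C = G.T @ G / N
    cf = _regularized_inverse_factor(C)
    from scipy.linalg import cho_solve as _cs

    JWJ = Bbar.T @ _cs(cf, Bbar)
    cov_plain = np.linalg.inv(JWJ) / N
    fit = QifFit(
        beta=beta,
        cov_plain=cov_plain,
        cov_bc=np.empty(0),
        q_stat=max(q_prev, 0.0),
        phi=phi,
        n_iter=n_iter,
        converged=converged,
    )
    fit.cov_bc = qif_bc_cov(fit, design)
    return fit


def qif_bc_cov(fit: QifFit, design: ClusteredDesign) -> np.ndarray:
    """Bias-corrected GMM covariance for small numbers of clusters.

    Two finite-sample downward biases of the plain covariance are removed:

    * residual shrinkage -- C_N is rebuilt from scores computed on
      (I - H_i)^{-1} e_i, the Mancl-DeRouen leverage adjustment, with
      H_i = X_i (sum_j X_j' X_j)^{-1} X_i' the cluster hat matrix under the
      independence working model;
    * weighting-matrix estimation -- C_N is a q x q covariance (q = 2p)
      estimated from N cluster scores, and the inverse of such an estimate
      is biased upward by the usual Wishart factor, so the plug-in
      N^{-1} (J' C^{-1} J)^{-1} underestimates the variance by about
      (N - q - 1)/N; the result is rescaled by N / (N - q - 1).

    Both adjustments vanish as N grows, so the corrected covariance reduces
    to the plain one in the many-cluster, zero-leverage limit.
    """
    from scipy.linalg import cho_solve

    N, p = design.n_clusters, design.p
    phi = fit.phi
    _, X_all = design.stacked()
    XtX_inv = np.linalg.inv(X_all.T @ X_all)
    Gbc = np.zeros((N, 2 * p))
    Bbar = _components(design, phi)[1].mean(axis=0)
    for grp in design._groups:
        n = grp.size
        E = grp.Y - np.einsum("mnp,p->mn", grp.X, fit.beta)
        H = np.einsum("mnp,pq,mkq->mnk", grp.X, XtX_inv, grp.X)
        ImH = np.eye(n)[None, :, :] - H
        try:
            Eadj = np.linalg.solve(ImH, E[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError as exc:
            raise LeverageError(
                "(I - H_i) singular: a cluster saturates the fit"
            ) from exc
        S = grp.X.sum(axis=1)
        tot = Eadj.sum(axis=1)
        XtE = np.einsum("mnp,mn->mp", grp.X, Eadj)
        idx = grp.cluster_index
        Gbc[idx, :p] = XtE / phi
        Gbc[idx, p:] = (S * tot[:, None] - XtE) / phi
    Cbc = Gbc.T @ Gbc / N
    cf = _regularized_inverse_factor(Cbc)
    q = 2 * p
    wishart = N / (N - q - 1) if N > q + 1 else 1.0
    return wishart * np.linalg.inv(Bbar.T @ cho_solve(cf, Bbar)) / N
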