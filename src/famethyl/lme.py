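"""Linear mixed model with a kinship-structured genetic random effect.

Model: y = X beta + g + e with g ~ N(0, sigma_g^2 * 2*Phi) and
e ~ N(0, sigma_e^2 * I).  The relationship matrix 2*Phi is eigendecomposed
once; rotating (y, X) by the eigenvectors diagonalizes the covariance, after
which beta and sigma_e^2 are profiled out of the (restricted) likelihood and
the single variance ratio delta = sigma_g^2 / sigma_e^2 is optimized by
bounded one-dimensional search.  This is the standard spectral trick used by
fast mixed-model association software; it makes each fit O(n p^2) after a
one-off decomposition that can be shared across fits on the same cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .pedigree import KinshipMatrix

_LOG2PI = math.log(2.0 * math.pi)

DELTA_BRACKET = (1e-8, 1e4)


class KinshipPSDError(ValueError):
    """Relationship matrix has an eigenvalue materially below zero."""


@dataclass
class RelationshipSpectrum:
    """Eigendecomposition of a relationship matrix 2*Phi = U diag(lam) U^T."""

    values: np.ndarray
    vectors: np.ndarray


@dataclass
class LmeFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_g: float
    sigma2_e: float
    loglik: float
    method: str
    converged: bool
    delta: float


@dataclass(frozen=True)
class WaldTest:
    estimate: float
    se: float
    z: float
    p: float


def _as_relationship(K) -> np.ndarray:
    if isinstance(K, KinshipMatrix):
        return K.relationship()
    return np.asarray(K, dtype=float)


def relationship_spectrum(K, floor: float = -1e-8) -> RelationshipSpectrum:
    """Eigendecompose 2*Phi, flooring tiny negative eigenvalues at zero."""
    rel = _as_relationship(K)
    lam, u = np.linalg.eigh(rel)
    if lam.min() < floor * max(1.0, lam.max()):
        raise KinshipPSDError(
            f"relationship matrix not PSD (min eigenvalue {lam.min():.3e})"
        )
    return RelationshipSpectrum(values=np.clip(lam, 0.0, None), vectors=u)


def _profile(delta, lam, yt, Xt, method):
    """Profiled negative log-likelihood pieces at a given variance ratio."""
    n, p = Xt.shape
    d = delta * lam + 1.0
    w = 1.0 / d
    Xw = Xt * w[:, None]
    A = Xw.T @ Xt
    b = Xw.T @ yt
    beta = np.linalg.solve(A, b)
    r = yt - Xt @ beta
    rss = float(w @ r**2)
    logdet_d = float(np.log(d).sum())
    if method == "REML":
        sigma2 = rss / (n - p)
        sign, logdet_a = np.linalg.slogdet(A)
        ll = -0.5 * (
            (n - p) * (math.log(sigma2) + 1.0 + _LOG2PI) + logdet_d + logdet_a
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * (math.log(sigma2) + 1.0 + _LOG2PI) + logdet_d)
    return ll, beta, sigma2, A


def lmm_loglik(y, X, K, sigma2_g: float, sigma2_e: float, method: str = "REML") -> float:
    """(Restricted) log-likelihood at fixed variance components, via rotation.

    Exposed so the rotated computation can be checked against a dense
    multivariate-normal evaluation.
    """
    spec = relationship_spectrum(K)
    yt = spec.vectors.T @ np.asarray(y, dtype=float)
    Xt = spec.vectors.T @ np.asarray(X, dtype=float)
    n, p = Xt.shape
    d = sigma2_g * spec.values + sigma2_e
    w = 1.0 / d
    Xw = Xt * w[:, None]
    A = Xw.T @ Xt
    beta = np.linalg.solve(A, Xw.T @ yt)
    r = yt - Xt @ beta
    quad = float(w @ r**2)
    logdet = float(np.log(d).sum())
    if method == "REML":
        sign, logdet_a = np.linalg.slogdet(A)
        return -0.5 * (quad + logdet + logdet_a + (n - p) * _LOG2PI)
    return -0.5 * (quad + logdet + n * _LOG2PI)


def fit_lme_kinship(
    y,
    X,
    K,
    method: str = "REML",
    spectrum: RelationshipSpectrum | None = None,
) -> LmeFit:
    """Fit the kinship mixed model by profiled 1-D optimization of delta.

    ``K`` may be a :class:`KinshipMatrix` (its relationship matrix 2*Phi is
    used) or a raw relationship matrix; pass ``spectrum`` to reuse a
    precomputed eigendecomposition across many fits on the same cohort.
    """
    if method not in ("REML", "ML"):
        raise ValueError("method must be REML or ML")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    spec = spectrum if spectrum is not None else relationship_spectrum(K)
    lam = spec.values
    yt = spec.vectors.T @ y
    Xt = spec.vectors.T @ X

    def neg_ll_log(t: float) -> float:
        return -_profile(math.exp(t), lam, yt, Xt, method)[0]

    lo, hi = math.log(DELTA_BRACKET[0]), math.log(DELTA_BRACKET[1])
    # coarse grid to localize the optimum, then Brent refinement
    grid = np.linspace(lo, hi, 61)
    vals = np.array([neg_ll_log(t) for t in grid])
    k = int(np.argmin(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        neg_ll_log, bounds=(a, b), method="bounded", options={"xatol": 1e-10}
    )
    cand = [(res.fun, math.exp(res.x)), (vals[0], DELTA_BRACKET[0])]
    fun, delta = min(cand, key=lambda t: t[0])
    ll, beta, sigma2_e, A = _profile(delta, lam, yt, Xt, method)
    sigma2_g = delta * sigma2_e
    cov_beta = sigma2_e * np.linalg.inv(A)
    return LmeFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        loglik=ll,
        method=method,
        converged=bool(res.success),
        delta=delta,
    )


def wald_fixed_effect(fit, index: int) -> WaldTest:
    """Two-sided Wald test of one fixed-effect coefficient (normal reference).

    Works for any fit object exposing ``beta`` and a coefficient covariance
    (``cov_beta`` here; the marginal-model engines provide their own wrappers).
    """
    beta = np.asarray(fit.beta)
    if not (0 <= index < beta.shape[0]):
        raise IndexError(f"coefficient index {index} out of range")
    se = math.sqrt(fit.cov_beta[index, index])
    z = beta[index] / se if se > 0 else math.inf * np.sign(beta[index])
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if beta[index] == 0.0:
        p = 1.0
    return WaldTest(estimate=float(beta[index]), se=se, z=float(z), p=p)
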