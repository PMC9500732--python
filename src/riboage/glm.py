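"""Vectorized negative-binomial log-link GLM fitted by IRLS.

Fits the same small design to many genes at once.  The NB2 parameterization
is used throughout: ``Var(y) = mu + alpha * mu**2`` with per-gene dispersion
``alpha``.  The working weights are ``w = mu / (1 + alpha * mu)`` and the
Wald covariance is ``(X' W X)^{-1}``, evaluated at convergence (relative
deviance change below ``tol``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NBGlmFit", "fit_nb_glm", "nb_deviance"]

_ETA_CLIP = 30.0


@dataclass
class NBGlmFit:
    """Batch fit result: arrays indexed (gene, parameter)."""

    beta: np.ndarray        # (G, P) coefficients, natural log scale
    se: np.ndarray          # (G, P) Wald standard errors
    deviance: np.ndarray    # (G,)
    converged: np.ndarray   # (G,) bool
    n_iter: np.ndarray      # (G,) iterations used
    mu: np.ndarray          # (G, S) fitted means


def nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 deviance per gene (rows); alpha broadcast per gene."""
    y = np.asarray(y, float)
    mu = np.maximum(mu, 1e-12)
    a = np.asarray(alpha, float).reshape(-1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    term2 = (y + 1.0 / a) * np.log((1.0 + a * y) / (1.0 + a * mu))
    return 2.0 * (term1 - term2).sum(axis=1)


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> NBGlmFit:
    """Fit ``log mu = offset + X beta`` per gene with NB2 errors.

    Parameters
    ----------
    y : (G, S) counts.
    X : (S, P) design matrix shared across genes.
    offset : (S,) or (G, S) known log offsets (e.g. log size factors).
    alpha : scalar or (G,) NB dispersion(s).
    """
    y = np.asarray(y, float)
    G, S = y.shape
    X = np.asarray(X, float)
    P = X.shape[1]
    offset = np.broadcast_to(np.asarray(offset, float), (G, S))
    a = np.broadcast_to(np.asarray(alpha, float), (G,)).reshape(-1, 1)

    # init from a log-linear least-squares fit
    z0 = np.log(y + 0.5) - offset
    beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T  # (G, P)
    eta = np.clip(offset + beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    dev = nb_deviance(y, mu, a)
    converged = np.zeros(G, dtype=bool)
    n_iter = np.zeros(G, dtype=np.int64)
    XtWX = None

    active = np.arange(G)
    for it in range(max_iter):
        if active.size == 0:
            break
        w = mu[active] / (1.0 + a[active] * mu[active])  # (g, S)
        z = (eta[active] - offset[active]) + (y[active] - mu[active]) / mu[active]
        XtWX_a = np.einsum("sp,gs,sq->gpq", X, w, X)
        XtWz = np.einsum("sp,gs,gs->gp", X, w, z)
        # ridge jitter guards rank deficiency from degenerate weights
        XtWX_a = XtWX_a + 1e-10 * np.eye(P)
        beta_new = np.linalg.solve(XtWX_a, XtWz[..., None])[..., 0]
        beta[active] = beta_new
        eta[active] = np.clip(offset[active] + beta_new @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu[active] = np.exp(eta[active])
        dev_new = nb_deviance(y[active], mu[active], a[active])
        rel = np.abs(dev_new - dev[active]) / (np.abs(dev_new) + 0.1)
        dev[active] = dev_new
        n_iter[active] = it + 1
        done = rel < tol
        converged[active[done]] = True
        active = active[~done]

    # Wald covariance at the final fit, for all genes
    w = mu / (1.0 + a * mu)
    XtWX = np.einsum("sp,gs,sq->gpq", X, w, X) + 1e-10 * np.eye(P)
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return NBGlmFit(beta, se, dev, converged, n_iter, mu)
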