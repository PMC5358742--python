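"""Spectral REML for two-variance-component mixed models.

Shared numerical core for the association scan and RR-BLUP: the model
y = X b + g + e with Var(g) = Vg * G and Var(e) = Ve * I is profiled on
the ratio delta = Ve / Vg after one eigendecomposition of G, so each
likelihood evaluation is O(n).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

_LOG_DELTA_BOUNDS = (-12.0, 12.0)


def eigen_g(G: np.ndarray):
    """Eigendecomposition of a PSD covariance structure matrix."""
    G = np.asarray(G, dtype=float)
    s, U = np.linalg.eigh((G + G.T) / 2.0)
    if s.min() < -1e-6 * max(s.max(), 1.0):
        raise ValueError("covariance structure matrix is not PSD")
    return np.clip(s, 0.0, None), U


def _profile(delta: float, s, ys, Xs):
    w = 1.0 / (s + delta)
    XtW = Xs.T * w
    A = XtW @ Xs
    beta = np.linalg.solve(A, XtW @ ys)
    r = ys - Xs @ beta
    rss_w = float(np.sum(w * r * r))
    return beta, A, rss_w


def reml_loglik(delta: float, s, ys, Xs) -> float:
    """Restricted log-likelihood at ratio delta (constants dropped)."""
    n, q = Xs.shape
    _, A, rss_w = _profile(delta, s, ys, Xs)
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    return -0.5 * (
        (n - q) * np.log(rss_w) + np.sum(np.log(s + delta)) + logdet_A
    )


def fit_variance_components(y, X, G=None, eig=None):
    """REML estimates (Vg, Ve, beta) for y = X b + g + e, Var(g) = Vg G.

    ``eig`` may carry a precomputed ``(s, U)`` pair from :func:`eigen_g`
    to amortise the decomposition across refits.  Returns a dict with
    Vg, Ve, delta, beta, the eigenpair and the rotated data.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("X and y must have matching rows")
    s, U = eig if eig is not None else eigen_g(G)
    ys = U.T @ y
    Xs = U.T @ X
    lo, hi = _LOG_DELTA_BOUNDS
    grid = np.linspace(lo, hi, 97)
    vals = np.array([reml_loglik(np.exp(g), s, ys, Xs) for g in grid])
    k = int(np.argmax(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda t: -reml_loglik(np.exp(t), s, ys, Xs),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-6},
    )
    delta = float(np.exp(res.x))
    beta, _, rss_w = _profile(delta, s, ys, Xs)
    n, q = Xs.shape
    vg = rss_w / (n - q)
    return {
        "Vg": float(vg),
        "Ve": float(vg * delta),
        "delta": delta,
        "beta": beta,
        "eig": (s, U),
        "rotated": (ys, Xs),
    }
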