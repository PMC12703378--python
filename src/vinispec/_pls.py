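"""NIPALS partial least squares core.

Single-response PLS1 shared by the regression models and the wavelength
selectors (UVE stability, CARS reweighting).  For a single y the NIPALS
weight vector is obtained directly from the X'y covariance, so no inner
power iteration is needed; components are extracted by successive deflation
of the centered predictor matrix.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = ["PLSModel", "nipals_pls", "pls_predict", "pls_rmsecv", "cv_fold_assignment"]


class PLSModel(NamedTuple):
    x_mean: np.ndarray      # (p,)
    y_mean: float
    weights: np.ndarray     # W, (p, a)
    x_loadings: np.ndarray  # P, (p, a)
    y_loadings: np.ndarray  # q, (a,)
    scores: np.ndarray      # T, (n, a) training scores
    coef: np.ndarray        # (p,) regression vector on the original X scale
    intercept: float
    n_components: int


def nipals_pls(X: np.ndarray, y: np.ndarray, n_components: int,
               tol: float = 1e-13) -> PLSModel:
    """Fit PLS1 by NIPALS on column-centered ``X`` and centered ``y``.

    ``n_components`` is capped at ``min(n-1, p)`` and extraction stops early
    when the residual covariance vanishes (exactly collinear or exhausted
    data), so the returned model may hold fewer components than requested.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"y has {y.size} entries for {n} spectra")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    a_max = min(n_components, n - 1, p)

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    # scale used only to make the stopping tolerance unit-free
    x_norm = np.linalg.norm(Xc) or 1.0
    y_norm = np.linalg.norm(yc) or 1.0

    Ws, Ps, qs, Ts = [], [], [], []
    for _ in range(a_max):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= tol * x_norm * y_norm:
            break
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= (tol * x_norm) ** 2:
            break
        p_load = (Xc.T @ t) / tt
        q_load = float(yc @ t) / tt
        Xc -= np.outer(t, p_load)
        yc = yc - q_load * t
        Ws.append(w)
        Ps.append(p_load)
        qs.append(q_load)
        Ts.append(t)

    a = len(Ws)
    if a == 0:
        # degenerate: y uncorrelated with X (or constant) -> mean predictor
        coef = np.zeros(p)
        return PLSModel(x_mean, y_mean, np.zeros((p, 0)), np.zeros((p, 0)),
                        np.zeros(0), np.zeros((n, 0)), coef, y_mean, 0)
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    q = np.asarray(qs)
    T = np.column_stack(Ts)
    # B = W (P'W)^-1 q ; P'W is unit upper triangular in exact arithmetic
    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(x_mean, y_mean, W, P, q, T, coef, intercept, a)


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X @ model.coef + model.intercept


def cv_fold_assignment(n: int, folds: int) -> np.ndarray:
    """Deterministic interleaved fold labels (sample i -> fold i mod folds)."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if folds > n:
        raise ValueError(f"{folds} folds for {n} samples")
    return np.arange(n) % folds


def pls_rmsecv(X: np.ndarray, y: np.ndarray, n_components: int,
               folds: int = 5) -> float:
    """K-fold cross-validated RMSE of a PLS1 model (deterministic folds)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    assign = cv_fold_assignment(n, folds)
    resid = np.empty(n)
    for k in range(folds):
        test = assign == k
        model = nipals_pls(X[~test], y[~test], n_components)
        resid[test] = pls_predict(model, X[test]) - y[test]
    return float(np.sqrt(np.mean(resid ** 2)))
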