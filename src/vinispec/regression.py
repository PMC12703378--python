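"""Calibration models: PLSR (NIPALS), epsilon-SVR with RBF kernel, and ELM.

Every fit function returns a :class:`FittedModel` whose fitted constants
(centering/scaling, latent variables, support vectors, random hidden
weights) are derived exclusively from calibration rows.  A FittedModel can
optionally carry a frozen preprocessing chain and a wavelength subset, in
which case :func:`predict` expects new spectra on the *full* wavelength
grid and replays preprocessing -> column subset -> standardization ->
model without any refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.svm import SVR

from ._pls import PLSModel, cv_fold_assignment, nipals_pls, pls_predict
from .preprocessing import PreprocessChain
from .spectra_io import SpectraSet

__all__ = ["FittedModel", "plsr_fit", "svm_fit", "elm_fit", "predict"]


@dataclass
class FittedModel:
    """A fitted calibration model plus the frozen pipeline it belongs to."""

    kind: str                                   # "plsr" | "svm" | "elm"
    inner: Any                                  # PLSModel | SVR | dict (ELM) | float (constant)
    hyperparameters: dict = field(default_factory=dict)
    x_mean: np.ndarray | None = None            # standardization (svm/elm)
    x_scale: np.ndarray | None = None
    chain: PreprocessChain | None = None        # frozen preprocessing
    selected_indices: np.ndarray | None = None  # wavelength subset
    wavelengths: np.ndarray | None = None       # full grid the chain expects
    training_predictions: np.ndarray | None = None
    n_features: int = 0

    def with_pipeline(self, chain: PreprocessChain | None,
                      selected_indices: np.ndarray | None,
                      wavelengths: np.ndarray) -> "FittedModel":
        """Attach the frozen preprocessing chain and wavelength subset."""
        self.chain = chain
        self.selected_indices = (None if selected_indices is None
                                 else np.asarray(selected_indices, dtype=int))
        self.wavelengths = np.asarray(wavelengths, dtype=float)
        return self


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return mean, scale


# ---------------------------------------------------------------------------
# PLSR


def plsr_fit(X: np.ndarray, y: np.ndarray, max_lv: int = 20,
             cv_folds: int = 5) -> FittedModel:
    """NIPALS PLSR with the number of latent variables chosen by K-fold
    cross-validated RMSE over 1..max_lv.  Deterministic (contiguous
    interleaved folds, no shuffling); predictors are column-centered only,
    per common chemometric practice."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance")
    if not 1 <= max_lv <= min(n - 1, p):
        raise ValueError(f"max_lv={max_lv} outside [1, min(n-1, p)={min(n - 1, p)}]")

    assign = cv_fold_assignment(n, cv_folds)
    press = np.zeros(max_lv)
    for k in range(cv_folds):
        test = assign == k
        # one NIPALS sweep per fold gives all component counts at once:
        # refit at max_lv and read nested sub-models off the stored factors
        model = nipals_pls(X[~test], y[~test], max_lv)
        resid = _nested_residuals(model, X[test], y[test], max_lv)
        press += (resid ** 2).sum(axis=1)
    rmsecv = np.sqrt(press / n)
    n_lv = int(np.argmin(rmsecv)) + 1

    final = nipals_pls(X, y, n_lv)
    preds = pls_predict(final, X)
    return FittedModel(
        kind="plsr", inner=final,
        hyperparameters={"n_lv": final.n_components, "max_lv": max_lv,
                         "cv_folds": cv_folds,
                         "rmsecv_by_lv": rmsecv.tolist()},
        training_predictions=preds, n_features=p,
    )


def _nested_residuals(model: PLSModel, X_test: np.ndarray, y_test: np.ndarray,
                      max_lv: int) -> np.ndarray:
    """Residuals of every nested sub-model with 1..max_lv components.

    Uses the identity B_a = W_a (P_a' W_a)^{-1} q_a on the leading a
    factors of the fitted decomposition.
    """
    a_fit = model.n_components
    out = np.empty((max_lv, y_test.size))
    for a in range(1, max_lv + 1):
        a_use = min(a, a_fit)
        if a_use == 0:
            pred = np.full(y_test.size, model.y_mean)
        else:
            W = model.weights[:, :a_use]
            P = model.x_loadings[:, :a_use]
            q = model.y_loadings[:a_use]
            coef = W @ np.linalg.solve(P.T @ W, q)
            pred = (X_test - model.x_mean) @ coef + model.y_mean
        out[a - 1] = pred - y_test
    return out


# ---------------------------------------------------------------------------
# SVR


def _default_grid() -> np.ndarray:
    return 2.0 ** np.arange(-8, 9)


def svm_fit(X: np.ndarray, y: np.ndarray,
            c_grid: np.ndarray | None = None,
            g_grid: np.ndarray | None = None,
            epsilon: float | None = None,
            cv_folds: int = 5) -> FittedModel:
    """Epsilon-SVR with RBF kernel; (c, g) chosen by exhaustive grid search
    scored by K-fold RMSECV, then refit on the full calibration set.

    Predictors are standardized with calibration statistics.  Default grids
    are 2^-8..2^8 (17 log-spaced points each) and epsilon defaults to
    ``0.01 * sd(y)``.  A constant y yields a constant predictor with a
    warning.  Ties in the grid search go to the first candidate in
    (c, g)-iteration order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    c_grid = _default_grid() if c_grid is None else np.asarray(c_grid, float)
    g_grid = _default_grid() if g_grid is None else np.asarray(g_grid, float)
    if c_grid.size == 0 or g_grid.size == 0:
        raise ValueError("hyperparameter grids must be nonempty")

    if np.ptp(y) == 0:
        warnings.warn("constant y: returning constant predictor",
                      RuntimeWarning, stacklevel=2)
        return FittedModel(kind="svm", inner=float(y[0]),
                           hyperparameters={"constant": True},
                           training_predictions=np.full(n, y[0]), n_features=p)

    if epsilon is None:
        epsilon = 0.01 * float(np.std(y, ddof=1))
    mean, scale = _standardize_fit(X)
    Xs = (X - mean) / scale

    assign = cv_fold_assignment(n, cv_folds)
    best = (np.inf, None, None)
    for c in c_grid:
        for g in g_grid:
            resid = np.empty(n)
            for k in range(cv_folds):
                test = assign == k
                svr = SVR(kernel="rbf", C=float(c), gamma=float(g),
                          epsilon=float(epsilon))
                svr.fit(Xs[~test], y[~test])
                resid[test] = svr.predict(Xs[test]) - y[test]
            rmse = float(np.sqrt(np.mean(resid ** 2)))
            if rmse < best[0]:
                best = (rmse, float(c), float(g))
    rmsecv, c_best, g_best = best
    svr = SVR(kernel="rbf", C=c_best, gamma=g_best, epsilon=float(epsilon))
    svr.fit(Xs, y)
    return FittedModel(
        kind="svm", inner=svr,
        hyperparameters={"c": c_best, "g": g_best, "epsilon": float(epsilon),
                         "cv_folds": cv_folds, "rmsecv": rmsecv},
        x_mean=mean, x_scale=scale,
        training_predictions=svr.predict(Xs), n_features=p,
    )


# ---------------------------------------------------------------------------
# ELM


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def elm_fit(X: np.ndarray, y: np.ndarray, n_hidden: int = 50, seed: int = 0,
            activation: str = "sigmoid") -> FittedModel:
    """Extreme learning machine: random input weights, analytic output layer.

    Input-to-hidden weights W and biases b are drawn uniform [-1, 1] from
    the seeded generator; hidden activations H = act(X_std W + b); output
    weights are the minimum-norm least-squares solution
    ``beta = pinv(H) y``.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    act = {"sigmoid": _sigmoid, "identity": lambda z: z}.get(activation)
    if act is None:
        raise ValueError(f"unknown activation {activation!r}")

    mean, scale = _standardize_fit(X)
    Xs = (X - mean) / scale
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(p, n_hidden))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    H = act(Xs @ W + b)
    beta = np.linalg.pinv(H) @ y
    inner = {"W": W, "b": b, "beta": beta, "activation": activation}
    return FittedModel(
        kind="elm", inner=inner,
        hyperparameters={"n_hidden": n_hidden, "seed": seed,
                         "activation": activation},
        x_mean=mean, x_scale=scale,
        training_predictions=H @ beta, n_features=p,
    )


# ---------------------------------------------------------------------------
# prediction


def predict(m: FittedModel, X_new: np.ndarray) -> np.ndarray:
    """Apply a fitted model to new spectra: frozen preprocessing ->
    wavelength subset -> standardization -> model.  No refitting.

    When the model carries a preprocessing chain, ``X_new`` must be on the
    full wavelength grid the chain was fitted with; otherwise it must
    already match the feature count seen at fit time.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if m.chain is not None or m.selected_indices is not None:
        if m.wavelengths is None:
            raise ValueError("model carries a pipeline but no wavelength grid")
        if X_new.shape[1] != m.wavelengths.size:
            raise ValueError(f"grid mismatch: got {X_new.shape[1]} wavelengths, "
                             f"pipeline expects {m.wavelengths.size}")
        if m.chain is not None:
            ids = [f"q{i}" for i in range(X_new.shape[0])]
            X_new = m.chain.apply(
                SpectraSet(m.wavelengths, X_new, ids)).reflectance
        if m.selected_indices is not None:
            X_new = X_new[:, m.selected_indices]
    if X_new.shape[1] != m.n_features:
        raise ValueError(f"feature mismatch: got {X_new.shape[1]}, "
                         f"model fitted on {m.n_features}")

    if m.kind == "plsr":
        return pls_predict(m.inner, X_new)
    if m.kind == "svm":
        if isinstance(m.inner, float):  # constant-y degenerate model
            return np.full(X_new.shape[0], m.inner)
        return m.inner.predict((X_new - m.x_mean) / m.x_scale)
    if m.kind == "elm":
        inner = m.inner
        act = _sigmoid if inner["activation"] == "sigmoid" else (lambda z: z)
        H = act(((X_new - m.x_mean) / m.x_scale) @ inner["W"] + inner["b"])
        return H @ inner["beta"]
    raise ValueError(f"unknown model kind {m.kind!r}")
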