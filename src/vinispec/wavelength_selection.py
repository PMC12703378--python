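"""Characteristic-wavelength selection: SPA, UVE-PLS and CARS.

All three selectors operate on *calibration* spectra only (rows that will
later be predicted must never be shown to a selector) and return a
:class:`SelectionResult` with sorted wavelength-grid indices plus the
method's diagnostic traces.

SPA (successive projections algorithm)
    Forward selection that grows, from every candidate starting column, a
    chain in which each new column maximises the norm of its projection
    onto the orthogonal complement of the span of the columns already
    chosen — minimising collinearity.  The final (start, size) pair is the
    one whose multiple linear regression scores best on an internal
    validation split.

UVE (uninformative variable elimination)
    Appends an artificial noise matrix of the same width as X, runs
    leave-one-out PLS, and computes for every column the stability
    t = mean(b) / sd(b) of its regression coefficient across folds.  Real
    variables whose |t| does not exceed the largest noise |t| (times a
    threshold factor) are eliminated as uninformative.

CARS (competitive adaptive reweighted sampling)
    Monte-Carlo PLS runs on random sample subsets; after each run the
    variable set is shrunk by an exponentially decreasing enforced
    schedule and then resampled in proportion to |coefficient| (adaptive
    reweighted sampling).  The run with minimal cross-validated RMSE
    defines the selected subset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._pls import nipals_pls, pls_rmsecv
from .splitting import gradient_split

__all__ = [
    "SelectionResult",
    "spa_chain",
    "spa_select",
    "uve_select",
    "cars_reduction_schedule",
    "cars_select",
]


@dataclass
class SelectionResult:
    """Selected wavelength indices plus method diagnostics."""

    method: str
    selected_indices: np.ndarray
    selected_nm: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)
    best_run: int | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_indices, dtype=int).ravel()
        if idx.size and (np.unique(idx).size != idx.size):
            raise ValueError("selected indices must be unique")
        self.selected_indices = np.sort(idx)
        if self.selected_nm is not None:
            self.selected_nm = np.asarray(self.selected_nm, dtype=float)

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)

    def to_json(self, path: str | Path) -> None:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.integer, np.floating)):
                return v.item()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v
        payload = {
            "method": self.method,
            "selected_indices": self.selected_indices.tolist(),
            "selected_nm": None if self.selected_nm is None else self.selected_nm.tolist(),
            "best_run": self.best_run,
            "diagnostics": _clean(self.diagnostics),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# SPA


def spa_chain(X: np.ndarray, start: int, max_vars: int) -> np.ndarray:
    """Projection chain from one starting column (reference implementation).

    At each step the remaining column with the largest norm after
    projection onto the orthogonal complement of the span of the selected
    columns is appended.  Stops early if every remaining projected norm is
    numerically zero.
    """
    X = np.asarray(X, dtype=float)
    chains = _spa_chains_batch(X, np.asarray([start]), max_vars)
    chain = chains[0]
    return chain[chain >= 0]


def _spa_chains_batch(X: np.ndarray, starts: np.ndarray, max_vars: int,
                      batch: int = 24) -> np.ndarray:
    """Chains for many starting columns; -1 marks early-terminated steps."""
    n, p = X.shape
    sq0 = np.einsum("np,np->p", X, X)
    tol = 1e-12 * (sq0.max() or 1.0)
    chains = np.full((starts.size, max_vars), -1, dtype=int)
    for lo in range(0, starts.size, batch):
        bs = starts[lo:lo + batch]
        m = bs.size
        B = np.broadcast_to(X, (m, n, p)).copy()
        dead = np.zeros((m, p), dtype=bool)     # selected or numerically gone
        alive = np.ones(m, dtype=bool)          # chains still growing
        last = bs.copy()
        chains[lo:lo + m, 0] = bs
        dead[np.arange(m), bs] = True
        for step in range(1, max_vars):
            q = B[np.arange(m), :, last]                       # (m, n)
            qn = np.linalg.norm(q, axis=1)
            alive &= qn > np.sqrt(tol)
            if not alive.any():
                break
            q = q / np.where(qn > 0, qn, 1.0)[:, None]
            proj = np.einsum("mn,mnp->mp", q, B)
            B -= q[:, :, None] * proj[:, None, :]
            sq = np.einsum("mnp,mnp->mp", B, B)
            sq[dead] = -1.0
            sq[sq <= tol] = -1.0
            nxt = np.argmax(sq, axis=1)
            ok = alive & (sq[np.arange(m), nxt] > 0)
            chains[lo + np.flatnonzero(ok), step] = nxt[ok]
            dead[np.arange(m), nxt] = True
            alive = ok
            last = nxt
    return chains


def spa_select(X: np.ndarray, y: np.ndarray, max_vars: int = 30,
               wavelengths: np.ndarray | None = None,
               internal_ratio: tuple[int, int] = (3, 1)) -> SelectionResult:
    """SPA selection with internal-validation sizing of the subset.

    Chains are built on an internal calibration subset (rank split of the
    calibration rows by y); every chain prefix of size 1..max_vars is
    scored by the RMSE of a multiple linear regression on the held-out
    internal validation rows, and the best (start, size) wins.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if np.ptp(y) == 0:
        raise ValueError("y is constant; SPA validation RMSE undefined")
    if max_vars > min(n - 1, p):
        raise ValueError(f"max_vars={max_vars} exceeds min(n-1, p)="
                         f"{min(n - 1, p)}")

    ids = [str(i) for i in range(n)]
    split = gradient_split(ids, y, ratio=internal_ratio)
    cal_rows = np.asarray([int(s) for s in split.calibration_ids])
    val_rows = np.asarray([int(s) for s in split.prediction_ids])
    Xc, yc = X[cal_rows], y[cal_rows]
    Xv, yv = X[val_rows], y[val_rows]
    max_vars_eff = min(max_vars, Xc.shape[0] - 1)

    sq0 = np.einsum("np,np->p", Xc, Xc)
    starts = np.flatnonzero(sq0 > 0)
    chains = _spa_chains_batch(Xc, starts, max_vars_eff)

    ones_c = np.ones((Xc.shape[0], 1))
    ones_v = np.ones((Xv.shape[0], 1))
    best = (np.inf, -1, 0)  # rmse, start_row, size
    rmse_by_size = np.full(max_vars_eff, np.inf)
    for s_row in range(starts.size):
        chain = chains[s_row]
        chain = chain[chain >= 0]
        if chain.size == 0:
            continue
        A = np.hstack([ones_c, Xc[:, chain]])
        Av = np.hstack([ones_v, Xv[:, chain]])
        Q, R = np.linalg.qr(A)
        qty = Q.T @ yc
        diag = np.abs(np.diag(R))
        dtol = 1e-10 * (diag.max() or 1.0)
        for k in range(1, chain.size + 1):
            if np.any(diag[:k + 1] < dtol):
                break  # rank-deficient from here on
            beta = np.linalg.solve(R[:k + 1, :k + 1], qty[:k + 1])
            rmse = float(np.sqrt(np.mean((Av[:, :k + 1] @ beta - yv) ** 2)))
            if rmse < rmse_by_size[k - 1]:
                rmse_by_size[k - 1] = rmse
            if rmse < best[0]:
                best = (rmse, s_row, k)
    if best[1] < 0:
        raise RuntimeError("SPA found no valid chain prefix")
    rmse_best, s_row, size = best
    chain = chains[s_row]
    selected = chain[chain >= 0][:size]
    return SelectionResult(
        method="spa",
        selected_indices=selected,
        selected_nm=None if wavelengths is None else np.sort(
            np.asarray(wavelengths, float)[np.sort(selected)]),
        diagnostics={
            "rmse_by_size": rmse_by_size,
            "best_start": int(starts[s_row]),
            "best_size": int(size),
            "best_rmse": rmse_best,
        },
    )


# ---------------------------------------------------------------------------
# UVE


def uve_select(X: np.ndarray, y: np.ndarray, n_lv: int = 10,
               noise_scale: float | None = None,
               threshold_factor: float = 0.99,
               seed: int = 0,
               wavelengths: np.ndarray | None = None,
               min_keep: int = 2) -> SelectionResult:
    """Uninformative variable elimination by PLS-coefficient stability.

    A uniform-[0, noise_scale] noise matrix with the same column count as
    X is appended (by convention a tiny amplitude, default
    ``1e-10 * max|X|``, so it cannot perturb the fit); leave-one-out PLS
    with ``n_lv`` components yields per-fold coefficient vectors, and each
    column's stability is ``t = mean(b) / sd(b)``.  Real variables are
    retained when ``|t|`` exceeds ``threshold_factor`` times the largest
    noise-column ``|t|``.

    The extremal noise cutoff grows with the number of noise columns and
    can eliminate *every* real variable when the analyte signal is weak;
    in that degenerate case the ``min_keep`` top-|t| real variables are
    retained with a warning so a (deliberately minimal) model can still be
    built.  Pass ``min_keep=0`` to observe the unmodified elimination
    rule.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 5:
        raise ValueError(f"UVE needs at least 5 samples, got {n}")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if noise_scale is None:
        noise_scale = 1e-10 * (np.abs(X).max() or 1.0)
    rng = np.random.default_rng(seed)
    Z = np.hstack([X, rng.uniform(0.0, noise_scale, size=(n, p))])

    a = min(n_lv, n - 2)
    coefs = np.empty((n, 2 * p))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        coefs[i] = nipals_pls(Z[mask], y[mask], a).coef
        mask[i] = True

    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1)
    zero_sd = sd == 0
    if zero_sd.any():
        warnings.warn(f"UVE: {int(zero_sd.sum())} columns with zero coefficient "
                      "spread across folds; stability set to +/-inf",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_sd, np.sign(mean) * np.inf, mean / sd)
        t = np.where(zero_sd & (mean == 0), np.inf, t)

    abs_t = np.abs(t)
    threshold = threshold_factor * abs_t[p:].max()
    selected = np.flatnonzero(abs_t[:p] > threshold)
    if selected.size < min_keep:
        warnings.warn(
            f"UVE eliminated all but {selected.size} variables; retaining the "
            f"{min_keep} most stable instead", RuntimeWarning, stacklevel=2)
        selected = np.sort(np.argsort(-abs_t[:p], kind="stable")[:min_keep])
    return SelectionResult(
        method="uve",
        selected_indices=selected,
        selected_nm=None if wavelengths is None else
        np.asarray(wavelengths, float)[selected],
        diagnostics={
            "stability_t": t[:p],
            "noise_t": t[p:],
            "threshold": float(threshold),
            "n_lv": a,
        },
    )


# ---------------------------------------------------------------------------
# CARS


def cars_reduction_schedule(p: int, n_runs: int) -> np.ndarray:
    """Enforced retained-variable ratio r_i = a*exp(-k*i) for i = 1..n_runs.

    The constants are fixed by the endpoints r_1 = 1 (all p variables) and
    r_{n_runs} = 2/p (two variables): ``k = ln(p/2)/(n_runs - 1)`` and
    ``a = exp(k)``.
    """
    if p < 3:
        raise ValueError("need at least 3 variables")
    if n_runs < 2:
        raise ValueError("need at least 2 sampling runs")
    k = np.log(p / 2.0) / (n_runs - 1)
    a = np.exp(k)
    i = np.arange(1, n_runs + 1)
    return a * np.exp(-k * i)


def cars_select(X: np.ndarray, y: np.ndarray, n_lv: int = 10,
                n_runs: int = 100, cv_folds: int = 5,
                sample_fraction: float = 0.8, seed: int = 0,
                wavelengths: np.ndarray | None = None) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Each run fits PLS on a random ``sample_fraction`` subset of the
    calibration rows using the currently retained variables, converts
    |coefficients| to weights, applies the enforced exponential reduction
    (:func:`cars_reduction_schedule`), resamples the survivors by weight
    (adaptive reweighted sampling), and records the K-fold RMSECV of a PLS
    model on the surviving set.  The run with minimal RMSECV defines the
    selection.  The retained count is clamped at 2 and is non-increasing
    across runs by construction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p0 = X.shape
    schedule = cars_reduction_schedule(p0, n_runs)  # validates p0, n_runs
    rng = np.random.default_rng(seed)

    retained = np.arange(p0)
    rmsecv_trace = np.empty(n_runs)
    count_trace = np.empty(n_runs, dtype=int)
    subsets: list[np.ndarray] = []
    coef_path = np.zeros((n_runs, p0))

    n_sub = max(2, int(round(sample_fraction * n)))
    for i in range(n_runs):
        rows = rng.choice(n, size=n_sub, replace=False)
        a_fit = min(n_lv, retained.size, n_sub - 1)
        model = nipals_pls(X[np.ix_(rows, retained)], y[rows], max(1, a_fit))
        absb = np.abs(model.coef)
        coef_path[i, retained] = model.coef

        keep = int(round(schedule[i] * p0))
        keep = max(2, min(keep, retained.size))
        order = np.argsort(-absb, kind="stable")[:keep]
        forced = retained[order]
        w = absb[order]
        probs = w / w.sum() if w.sum() > 0 else np.full(keep, 1.0 / keep)
        draws = rng.choice(keep, size=keep, replace=True, p=probs)
        survivors = np.unique(forced[draws])
        if survivors.size < 2:
            survivors = np.sort(forced[:2])
        retained = np.sort(survivors)

        count_trace[i] = retained.size
        subsets.append(retained.copy())
        a_cv = min(n_lv, retained.size)
        rmsecv_trace[i] = pls_rmsecv(X[:, retained], y, max(1, a_cv), cv_folds)

    best_run = int(np.argmin(rmsecv_trace))
    selected = subsets[best_run]
    return SelectionResult(
        method="cars",
        selected_indices=selected,
        selected_nm=None if wavelengths is None else
        np.asarray(wavelengths, float)[selected],
        best_run=best_run,
        diagnostics={
            "rmsecv": rmsecv_trace,
            "n_retained": count_trace,
            "coef_path": coef_path,
            "schedule": schedule,
        },
    )
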