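"""Model evaluation metrics and the preprocessing x selector x model grid.

Metrics follow standard chemometric usage: Rc/Rp are Pearson correlations
between measured and predicted values on the calibration / prediction
set, RMSEC/RMSEP are root mean square errors with an n denominator, and
RPD is the prediction-set reference standard deviation (n-1 denominator)
divided by RMSEP.  R-squared columns are emitted alongside R to avoid
the usual correlation-vs-determination ambiguity.

:func:`run_grid` reproduces the two standard report layouts of a
calibration study: a pretreatment comparison (each preprocessing chain x
full-spectrum PLSR) and a selector/model comparison (one chain x
{SPA, UVE, CARS} x {PLSR, SVM, ELM}), per reference parameter, with the
best cell per parameter flagged by maximal RPD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import regression
from .preprocessing import PreprocessChain
from .spectra_io import SpectraSet, ReferenceTable
from .splitting import gradient_split
from .synthetic_data import SyntheticDataset
from .wavelength_selection import cars_select, spa_select, uve_select

__all__ = [
    "compute_metrics",
    "rpd_from_sd",
    "compute_rpd",
    "GridConfig",
    "EvaluationReport",
    "run_grid",
]


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and RMSE (n denominator) of predictions."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError(f"length mismatch: {y_true.size} vs {y_pred.size}")
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(y_true) == 0:
        raise ValueError("correlation undefined for constant measured values")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if np.ptp(y_pred) == 0:
        r = 0.0  # constant predictor carries no correlation
    else:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return r, rmse


def rpd_from_sd(sd: float, rmsep: float) -> float:
    """RPD = prediction-set reference standard deviation / RMSEP."""
    if rmsep == 0:
        warnings.warn("RMSEP is zero; RPD reported as +inf", RuntimeWarning,
                      stacklevel=2)
        return float("inf")
    if rmsep < 0:
        raise ValueError("RMSEP must be >= 0")
    return float(sd / rmsep)


def compute_rpd(y_true_prediction_set: np.ndarray, rmsep: float) -> float:
    """RPD from the prediction-set reference values (sd with n-1 denominator)."""
    y = np.asarray(y_true_prediction_set, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 prediction-set values")
    return rpd_from_sd(float(np.std(y, ddof=1)), rmsep)


# ---------------------------------------------------------------------------
# grid configuration


@dataclass
class GridConfig:
    """Configuration of one evaluation grid run.

    ``selectors`` may contain ``"full"`` (no selection), ``"spa"``,
    ``"uve"`` and ``"cars"``; ``models`` any of ``"plsr"``, ``"svm"``,
    ``"elm"``.  One split is performed per target parameter (each ordered
    by its own reference values); set ``per_parameter_split=False`` to
    split once on the first parameter and reuse it.
    """

    parameters: tuple[str, ...] = ("SSC", "TA", "pH")
    chains: tuple[str, ...] = ("raw", "fd", "sg", "fd+sg", "msc", "snv")
    selectors: tuple[str, ...] = ("full",)
    models: tuple[str, ...] = ("plsr",)
    split_ratio: tuple[int, int] = (3, 1)
    per_parameter_split: bool = True
    seed: int = 0
    # preprocessing
    sg_window: int = 11
    sg_polyorder: int = 2
    # selectors
    spa_max_vars: int = 30
    uve_n_lv: int = 10
    uve_threshold_factor: float = 0.99
    cars_n_lv: int = 10
    cars_n_runs: int = 100
    cars_cv_folds: int = 5
    cars_sample_fraction: float = 0.8
    # models
    plsr_max_lv: int = 20
    cv_folds: int = 5
    svm_c_grid: tuple[float, ...] | None = None
    svm_g_grid: tuple[float, ...] | None = None
    elm_n_hidden: int = 50


@dataclass
class EvaluationReport:
    """Tidy table of grid results, one row per evaluated cell."""

    table: pd.DataFrame
    config: GridConfig | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.table)

    def best_rows(self) -> pd.DataFrame:
        """The maximal-RPD cell per parameter."""
        return self.table[self.table["best"]]

    def cell(self, parameter: str, preprocess: str, selector: str,
             model: str) -> pd.Series:
        t = self.table
        hit = t[(t.parameter == parameter) & (t.preprocess == preprocess)
                & (t.selector == selector) & (t.model == model)]
        if len(hit) != 1:
            raise KeyError(f"no unique cell ({parameter}, {preprocess}, "
                           f"{selector}, {model})")
        return hit.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        self.table.to_json(path, orient="records", indent=1)


def _cell_seed(base_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([base_seed, *key])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _select(selector: str, X: np.ndarray, y: np.ndarray,
            wavelengths: np.ndarray, config: GridConfig, seed: int):
    if selector == "full":
        return None
    if selector == "spa":
        return spa_select(X, y, max_vars=min(config.spa_max_vars,
                                             X.shape[0] - 1, X.shape[1]),
                          wavelengths=wavelengths)
    if selector == "uve":
        return uve_select(X, y, n_lv=config.uve_n_lv,
                          threshold_factor=config.uve_threshold_factor,
                          seed=seed, wavelengths=wavelengths)
    if selector == "cars":
        return cars_select(X, y, n_lv=config.cars_n_lv,
                           n_runs=config.cars_n_runs,
                           cv_folds=config.cars_cv_folds,
                           sample_fraction=config.cars_sample_fraction,
                           seed=seed, wavelengths=wavelengths)
    raise KeyError(f"unknown selector {selector!r}")


def _fit(model_name: str, X: np.ndarray, y: np.ndarray,
         config: GridConfig, seed: int) -> regression.FittedModel:
    if model_name == "plsr":
        max_lv = min(config.plsr_max_lv, X.shape[0] - 1, X.shape[1])
        return regression.plsr_fit(X, y, max_lv=max_lv, cv_folds=config.cv_folds)
    if model_name == "svm":
        c = None if config.svm_c_grid is None else np.asarray(config.svm_c_grid)
        g = None if config.svm_g_grid is None else np.asarray(config.svm_g_grid)
        return regression.svm_fit(X, y, c_grid=c, g_grid=g,
                                  cv_folds=config.cv_folds)
    if model_name == "elm":
        return regression.elm_fit(X, y, n_hidden=config.elm_n_hidden, seed=seed)
    raise KeyError(f"unknown model {model_name!r}")


def _hyper_summary(m: regression.FittedModel) -> str:
    h = m.hyperparameters
    if m.kind == "plsr":
        return f"n_lv={h['n_lv']}"
    if m.kind == "svm":
        if h.get("constant"):
            return "constant"
        return f"c={h['c']:g},g={h['g']:g}"
    if m.kind == "elm":
        return f"n_hidden={h['n_hidden']}"
    return ""


def run_grid(dataset: SyntheticDataset | tuple[SpectraSet, ReferenceTable],
             config: GridConfig) -> EvaluationReport:
    """Evaluate every (parameter, preprocess, selector, model) cell.

    For each parameter the samples are split by the gradient concentration
    method; each preprocessing chain is fitted on calibration rows only;
    selectors see only preprocessed calibration spectra; models are fitted
    on the selected calibration columns and evaluated with Rc/RMSEC on the
    calibration rows and Rp/RMSEP/RPD on the prediction rows.  Fully
    reproducible given ``config.seed``.
    """
    if isinstance(dataset, SyntheticDataset):
        spectra, references = dataset.spectra, dataset.references
    else:
        spectra, references = dataset
    if spectra.sample_ids != references.sample_ids:
        raise ValueError("spectra and references must share sample ids")

    rows: list[dict] = []
    shared_split = None
    for pi, parameter in enumerate(config.parameters):
        y_all = references.values(parameter)
        if config.per_parameter_split or shared_split is None:
            split = gradient_split(spectra.sample_ids, y_all,
                                   ratio=config.split_ratio,
                                   target_parameter=parameter)
            if not config.per_parameter_split:
                shared_split = split
        else:
            split = shared_split
        cal = spectra.take_samples(split.calibration_ids)
        pred = spectra.take_samples(split.prediction_ids)
        y_cal = references.values(parameter, split.calibration_ids)
        y_pred_true = references.values(parameter, split.prediction_ids)

        for ci, chain_name in enumerate(config.chains):
            chain = PreprocessChain.from_name(chain_name,
                                              sg_window=config.sg_window,
                                              sg_polyorder=config.sg_polyorder)
            try:
                X_cal_full = chain.fit_apply(cal).reflectance
                X_pred_full = chain.apply(pred).reflectance
            except Exception as exc:
                raise RuntimeError(f"[{parameter}/{chain_name}] preprocessing "
                                   f"failed: {exc}") from exc

            for si, selector in enumerate(config.selectors):
                sel_seed = _cell_seed(config.seed, pi, ci, si)
                try:
                    sel = _select(selector, X_cal_full, y_cal,
                                  cal.wavelengths, config, sel_seed)
                except Exception as exc:
                    raise RuntimeError(f"[{parameter}/{chain_name}/{selector}] "
                                       f"selection failed: {exc}") from exc
                if sel is None:
                    idx = np.arange(X_cal_full.shape[1])
                    n_selected = int(idx.size)
                else:
                    idx = sel.selected_indices
                    n_selected = sel.n_selected
                    if n_selected == 0:
                        raise RuntimeError(f"[{parameter}/{chain_name}/{selector}] "
                                           "selected no wavelengths")
                X_cal = X_cal_full[:, idx]
                X_pred = X_pred_full[:, idx]

                for mi, model_name in enumerate(config.models):
                    fit_seed = _cell_seed(config.seed, pi, ci, si, mi)
                    try:
                        model = _fit(model_name, X_cal, y_cal, config, fit_seed)
                    except Exception as exc:
                        raise RuntimeError(
                            f"[{parameter}/{chain_name}/{selector}/{model_name}] "
                            f"fit failed: {exc}") from exc
                    model.with_pipeline(chain, idx, spectra.wavelengths)
                    yc_hat = model.training_predictions
                    yp_hat = regression.predict(model, pred.reflectance)
                    rc, rmsec = compute_metrics(y_cal, yc_hat)
                    rp, rmsep = compute_metrics(y_pred_true, yp_hat)
                    rpd = compute_rpd(y_pred_true, rmsep)
                    rows.append({
                        "parameter": parameter,
                        "preprocess": chain_name,
                        "selector": selector,
                        "model": model_name,
                        "n_selected": n_selected,
                        "hyperparameters": _hyper_summary(model),
                        "Rc": rc, "RMSEC": rmsec, "R2c": rc ** 2,
                        "Rp": rp, "RMSEP": rmsep, "R2p": rp ** 2,
                        "RPD": rpd,
                        "n_calibration": split.n_calibration,
                        "n_prediction": split.n_prediction,
                    })

    table = pd.DataFrame(rows)
    table["best"] = False
    for parameter in config.parameters:
        mask = table.parameter == parameter
        if mask.any():
            table.loc[table.loc[mask, "RPD"].idxmax(), "best"] = True
    return EvaluationReport(table, config)
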