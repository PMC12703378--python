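"""Spectral pretreatments: first derivative, Savitzky-Golay smoothing,
SNV, MSC, and composable chains thereof.

All transforms map a :class:`~vinispec.spectra_io.SpectraSet` to a new
SpectraSet on the same wavelength grid.  MSC is the only stateful
transform: its reference spectrum is the column mean of the *calibration*
spectra and is frozen once fitted, so prediction spectra are corrected
against the calibration reference and no information leaks backwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import SpectraSet

__all__ = [
    "first_derivative",
    "savitzky_golay",
    "snv",
    "msc_reference",
    "msc_fit_apply",
    "PreprocessChain",
    "CHAIN_NAMES",
]


def first_derivative(s: SpectraSet, scale_by_grid: bool = True) -> SpectraSet:
    """Grid-aware first derivative dR/dlambda.

    Central differences ``(R[i+1] - R[i-1]) / (lam[i+1] - lam[i-1])`` at
    interior points, one-sided differences at the endpoints; handles
    non-uniform grids.  With ``scale_by_grid=False`` the divisor is the
    index distance instead of nm, giving plain differences.
    """
    if s.n_wavelengths < 3:
        raise ValueError("first derivative needs at least 3 wavelengths")
    r = s.reflectance
    lam = s.wavelengths if scale_by_grid else np.arange(s.n_wavelengths, dtype=float)
    d = np.empty_like(r)
    d[:, 1:-1] = (r[:, 2:] - r[:, :-2]) / (lam[2:] - lam[:-2])
    d[:, 0] = (r[:, 1] - r[:, 0]) / (lam[1] - lam[0])
    d[:, -1] = (r[:, -1] - r[:, -2]) / (lam[-1] - lam[-2])
    return s.with_reflectance(d)


def savitzky_golay(s: SpectraSet, window: int = 11, polyorder: int = 2) -> SpectraSet:
    """Savitzky-Golay least-squares polynomial smoothing along wavelengths.

    Endpoints are handled by fitting the edge polynomial on the truncated
    one-sided window and evaluating it at the edge points.
    """
    if window % 2 == 0:
        raise ValueError(f"SG window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(f"SG window ({window}) must exceed polyorder ({polyorder})")
    if window > s.n_wavelengths:
        raise ValueError(f"SG window ({window}) exceeds {s.n_wavelengths} wavelengths")
    sm = savgol_filter(s.reflectance, window_length=window, polyorder=polyorder,
                       axis=1, mode="interp")
    return s.with_reflectance(sm)


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: per spectrum ``(x - mean(x)) / sd(x)``,
    sample standard deviation (n-1 denominator).  Removes per-spectrum
    multiplicative gain and additive offset."""
    means = s.reflectance.mean(axis=1, keepdims=True)
    sds = s.reflectance.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sds.ravel() == 0)
    if bad.size:
        raise ValueError(f"SNV undefined for zero-variance spectrum "
                         f"{s.sample_ids[bad[0]]!r}")
    return s.with_reflectance((s.reflectance - means) / sds)


def msc_reference(calib: SpectraSet) -> np.ndarray:
    """MSC reference spectrum: column-wise mean of the calibration set."""
    if calib.n_samples == 0:
        raise ValueError("MSC needs a nonempty calibration set")
    ref = calib.reflectance.mean(axis=0)
    if np.ptp(ref) == 0:
        raise ValueError("MSC reference spectrum is constant (degenerate regressor)")
    return ref


def msc_fit_apply(calib: SpectraSet, apply_to: SpectraSet | None = None,
                  reference: np.ndarray | None = None,
                  slope_tol: float = 1e-10) -> SpectraSet:
    """Multiplicative scatter correction against the calibration mean.

    Each spectrum ``x`` is regressed on the reference by ordinary least
    squares, ``x ~ b0 + b1 * ref``; the corrected spectrum is
    ``(x - b0) / b1``.  A slope smaller than ``slope_tol`` in magnitude is
    an error naming the offending sample.
    """
    ref = msc_reference(calib) if reference is None else np.asarray(reference, float)
    if np.ptp(ref) == 0:
        raise ValueError("MSC reference spectrum is constant (degenerate regressor)")
    target = calib if apply_to is None else apply_to
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    x = target.reflectance
    b1 = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.flatnonzero(np.abs(b1) < slope_tol)
    if bad.size:
        raise ValueError(f"MSC slope ~ 0 for spectrum {target.sample_ids[bad[0]]!r}")
    b0 = x.mean(axis=1) - b1 * ref.mean()
    corrected = (x - b0[:, None]) / b1[:, None]
    return target.with_reflectance(corrected)


# ---------------------------------------------------------------------------
# chains

TransformSpec = tuple[str, dict]

# the evaluated pretreatment set: raw spectra, first derivative, SG
# smoothing, their combination, and the two scatter corrections
CHAIN_NAMES = ("raw", "fd", "sg", "fd+sg", "msc", "snv")


@dataclass
class PreprocessChain:
    """Ordered, left-to-right list of pretreatment steps.

    Construct from explicit ``(name, params)`` steps or via
    :meth:`from_name` for the standard single-treatment chains.  ``fit``
    freezes any stateful step (MSC's reference spectrum) on the
    calibration set; ``apply`` then transforms any SpectraSet with the
    frozen state.
    """

    steps: list[TransformSpec] = field(default_factory=list)
    name: str = ""
    _msc_reference: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_name(cls, name: str, sg_window: int = 11, sg_polyorder: int = 2) -> "PreprocessChain":
        name = name.lower()
        sg = {"window": sg_window, "polyorder": sg_polyorder}
        table: dict[str, list[TransformSpec]] = {
            "raw": [],
            "fd": [("fd", {})],
            "sg": [("sg", dict(sg))],
            "fd+sg": [("fd", {}), ("sg", dict(sg))],
            "msc": [("msc", {})],
            "snv": [("snv", {})],
        }
        if name not in table:
            raise KeyError(f"unknown chain {name!r}; expected one of {CHAIN_NAMES}")
        return cls(steps=table[name], name=name)

    @property
    def is_fitted(self) -> bool:
        needs_fit = any(n == "msc" for n, _ in self.steps)
        return (not needs_fit) or self._msc_reference is not None

    def fit(self, calib: SpectraSet) -> "PreprocessChain":
        """Freeze stateful steps on the calibration spectra."""
        current = calib
        for step_name, params in self.steps:
            if step_name == "msc":
                self._msc_reference = msc_reference(current)
                current = msc_fit_apply(current, reference=self._msc_reference,
                                        **params)
            else:
                current = self._apply_stateless(step_name, params, current)
        return self

    def apply(self, s: SpectraSet) -> SpectraSet:
        if not self.is_fitted:
            raise RuntimeError("chain contains MSC and must be fitted first")
        current = s
        for step_name, params in self.steps:
            if step_name == "msc":
                current = msc_fit_apply(current, reference=self._msc_reference,
                                        **params)
            else:
                current = self._apply_stateless(step_name, params, current)
        return current

    def fit_apply(self, calib: SpectraSet) -> SpectraSet:
        self.fit(calib)
        return self.apply(calib)

    @staticmethod
    def _apply_stateless(step_name: str, params: dict, s: SpectraSet) -> SpectraSet:
        fns: dict[str, Callable[..., SpectraSet]] = {
            "fd": first_derivative,
            "sg": savitzky_golay,
            "snv": snv,
        }
        if step_name not in fns:
            raise KeyError(f"unknown preprocessing step {step_name!r}")
        return fns[step_name](s, **params)
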