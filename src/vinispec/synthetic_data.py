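"""Synthetic Vis-NIR grape spectra with planted analyte bands.

Emulates a storage-trial dataset of table-grape berries: per-sample
reference chemistry (SSC %, TA g/L, pH) drawn from truncated normal
distributions with a monotone storage-time trend, and reflectance spectra
built from a fixed background shape (peaks near 530-630, 720 and 810 nm,
valleys near 670 and 970 nm) plus analyte-linked Gaussian bands,
a polynomial baseline, per-sample multiplicative gain / additive offset
scatter and white noise.

The analyte bands are *planted*: their grid indices are recorded as ground
truth so wavelength selectors can be validated against known informative
regions.  The pH band is deliberately weak and broad, making pH the
hardest parameter to calibrate, as is typical for juice pH in the NIR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .spectra_io import ReferenceTable, SpectraSet

__all__ = [
    "BandSpec",
    "ReferenceRange",
    "SimulationConfig",
    "SyntheticDataset",
    "generate_references",
    "generate_spectra",
    "generate_dataset",
]


@dataclass(frozen=True)
class BandSpec:
    """One analyte-linked Gaussian band: amplitude = coefficient x value."""

    center_nm: float
    width_nm: float
    parameter: str       # "SSC" | "TA" | "pH"
    coefficient: float   # reflectance units per parameter unit


@dataclass(frozen=True)
class ReferenceRange:
    """Target distribution for one reference parameter (truncated normal)."""

    minimum: float
    maximum: float
    mean: float
    sd: float


# Reference distributions for a seedless white table-grape storage trial:
# SSC 9.23-22.73 % (mean 17.35, sd 2.30), TA 3.87-9.79 g/L (5.92, 1.46),
# pH 3.06-4.59 (3.82, 0.20).
DEFAULT_REFERENCE_RANGES: dict[str, ReferenceRange] = {
    "SSC": ReferenceRange(9.23, 22.73, 17.35, 2.30),
    "TA": ReferenceRange(3.87, 9.79, 5.92, 1.46),
    "pH": ReferenceRange(3.06, 4.59, 3.82, 0.20),
}

# SSC: carbohydrate/O-H band at 970 nm plus a secondary band at 840 nm.
# TA: bands at 890 and 1040 nm.  pH: single weak, broad band at 1010 nm
# with a low coefficient so the pH signal sits near the noise floor.
DEFAULT_BAND_SPECS: tuple[BandSpec, ...] = (
    BandSpec(970.0, 12.0, "SSC", -0.0040),
    BandSpec(840.0, 10.0, "SSC", +0.0030),
    BandSpec(890.0, 10.0, "TA", -0.0080),
    BandSpec(1040.0, 12.0, "TA", +0.0060),
    BandSpec(1010.0, 35.0, "pH", +0.0040),
)

# storage trial: 15 days at cold storage (2.7 C), refrigeration (10.0 C)
# and room temperature (20.6 C), sampled every third day
DEFAULT_STORAGE_DESIGN: tuple[tuple[float, tuple[int, ...]], ...] = (
    (2.7, (0, 3, 6, 9, 12, 15)),
    (10.0, (0, 3, 6, 9, 12, 15)),
    (20.6, (0, 3, 6, 9, 12, 15)),
)

# direction of the storage drift per parameter: sugars concentrate, acids
# are respired away (pH rises as TA falls)
TREND_DIRECTION = {"SSC": +1.0, "TA": -1.0, "pH": +1.0}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the 145-sample trial."""

    n_samples: int = 145
    wavelength_start_nm: float = 400.0
    wavelength_end_nm: float = 1100.0
    wavelength_step_nm: float = 0.5
    band_specs: tuple[BandSpec, ...] = DEFAULT_BAND_SPECS
    scatter_gain_range: tuple[float, float] = (0.9, 1.1)
    scatter_offset_sd: float = 0.01
    baseline_poly_coeffs: tuple[float, ...] = (0.0, 0.02)  # in normalized grid coordinate
    noise_sd: float = 0.003
    reference_ranges: dict[str, ReferenceRange] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_RANGES))
    storage_design: tuple[tuple[float, tuple[int, ...]], ...] = DEFAULT_STORAGE_DESIGN
    storage_trend_fraction: float = 0.10  # drift over the full trial at the warmest temperature
    replicate_noise_sd: float | None = None  # defaults to noise_sd
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 8:
            raise ValueError("n_samples must be >= 8")
        if self.wavelength_step_nm <= 0 or self.wavelength_start_nm >= self.wavelength_end_nm:
            raise ValueError("wavelength grid must be strictly increasing")
        if self.noise_sd < 0 or self.scatter_offset_sd < 0:
            raise ValueError("noise_sd and scatter_offset_sd must be >= 0")
        lo, hi = self.scatter_gain_range
        if not (0 < lo <= hi):
            raise ValueError("scatter_gain_range must satisfy 0 < low <= high")
        wl = self.wavelength_grid()
        for b in self.band_specs:
            if not (wl[0] <= b.center_nm <= wl[-1]):
                raise ValueError(f"band center {b.center_nm} nm outside grid "
                                 f"[{wl[0]}, {wl[-1]}] nm")
            if b.parameter not in self.reference_ranges:
                raise ValueError(f"band linked to unknown parameter {b.parameter!r}")
        for name, r in self.reference_ranges.items():
            if r.minimum >= r.maximum:
                raise ValueError(f"{name}: reference minimum must be < maximum")
            if r.sd <= 0:
                raise ValueError(f"{name}: reference sd must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.wavelength_end_nm - self.wavelength_start_nm)
                      / self.wavelength_step_nm)) + 1
        return self.wavelength_start_nm + self.wavelength_step_nm * np.arange(n)


@dataclass
class SyntheticDataset:
    """Spectra + references + the planted informative wavelength indices."""

    spectra: SpectraSet
    references: ReferenceTable
    ground_truth: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.spectra.sample_ids != self.references.sample_ids:
            raise ValueError("spectra and references must share sample ids one-to-one")
        p = self.spectra.n_wavelengths
        for param, idx in self.ground_truth.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= p):
                raise ValueError(f"ground truth indices for {param} outside grid")
            self.ground_truth[param] = idx


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _background(wl: np.ndarray) -> np.ndarray:
    """Fixed berry-reflectance shape: yellow-green skin peak around
    530-630 nm, peaks at 720 and 810 nm, chlorophyll valley at 670 nm and
    a water/carbohydrate valley at 970 nm."""
    return (0.35
            + 0.20 * _gauss(wl, 580.0, 45.0)
            + 0.10 * _gauss(wl, 720.0, 18.0)
            + 0.08 * _gauss(wl, 810.0, 25.0)
            - 0.12 * _gauss(wl, 670.0, 15.0)
            - 0.10 * _gauss(wl, 970.0, 28.0))


def _sample_design(config: SimulationConfig) -> pd.DataFrame:
    """Assign samples round-robin to (temperature, day) cells of the trial."""
    cells = [(temp, day) for temp, days in config.storage_design for day in days]
    ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    temp = [cells[i % len(cells)][0] for i in range(config.n_samples)]
    day = [cells[i % len(cells)][1] for i in range(config.n_samples)]
    return pd.DataFrame({"storage_day": day, "temperature": temp},
                        index=pd.Index(ids, name="sample_id"))


def generate_references(config: SimulationConfig) -> ReferenceTable:
    """Draw per-sample SSC, TA and pH values.

    Each parameter is a truncated normal with the configured (mean, sd) on
    (min, max), plus a monotone storage trend: the drift grows linearly with
    storage day and with temperature (zero at the coldest condition,
    ``storage_trend_fraction`` of the mean at the warmest condition on the
    final day).  SSC and pH drift upward, TA downward.  Values are clipped
    back into (min, max) after the trend.  Deterministic given the seed.
    """
    design = _sample_design(config)
    day = design["storage_day"].to_numpy(float)
    temp = design["temperature"].to_numpy(float)
    temps = [t for t, _ in config.storage_design]
    t_lo, t_hi = min(temps), max(temps)
    t_scale = (temp - t_lo) / (t_hi - t_lo) if t_hi > t_lo else np.zeros_like(temp)
    d_max = max((max(days) for _, days in config.storage_design), default=1) or 1

    cols: dict[str, np.ndarray] = {}
    for k, (name, r) in enumerate(config.reference_ranges.items()):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11, k]))
        a = (r.minimum - r.mean) / r.sd
        b = (r.maximum - r.mean) / r.sd
        base = truncnorm.rvs(a, b, loc=r.mean, scale=r.sd,
                             size=config.n_samples, random_state=rng)
        direction = TREND_DIRECTION.get(name, 0.0)
        trend = (direction * config.storage_trend_fraction * r.mean
                 * (day / d_max) * t_scale)
        cols[name] = np.clip(base + trend, r.minimum, r.maximum)

    table = pd.DataFrame(cols, index=design.index)
    table["day"] = design["storage_day"]
    table["temperature"] = design["temperature"]
    return ReferenceTable(table)


def clean_spectrum(values: dict[str, float], config: SimulationConfig) -> np.ndarray:
    """Noise-free, scatter-free spectrum for one sample: background +
    baseline + sum of coefficient x parameter_value x Gaussian bands."""
    wl = config.wavelength_grid()
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    spec = _background(wl) + np.polynomial.polynomial.polyval(
        u, np.asarray(config.baseline_poly_coeffs, dtype=float))
    for band in config.band_specs:
        spec = spec + band.coefficient * values[band.parameter] * _gauss(
            wl, band.center_nm, band.width_nm)
    return spec


def generate_spectra(references: ReferenceTable,
                     config: SimulationConfig) -> SyntheticDataset:
    """Turn reference values into reflectance spectra with instrument scatter.

    Each spectrum is ``gain * clean + offset + noise`` where gain is uniform
    in ``scatter_gain_range``, the offset is Gaussian with
    ``scatter_offset_sd`` and the noise is white with ``noise_sd`` (or
    ``replicate_noise_sd`` when replicates are generated).  Reflectance is
    clipped into (0, 1].  Per-sample RNG substreams make the output
    independent of sample order and deterministic given the seed.
    """
    if len(references) == 0:
        raise ValueError("reference table is empty")
    wl = config.wavelength_grid()
    noise_sd = config.noise_sd if config.replicate_noise_sd is None \
        else config.replicate_noise_sd

    ids: list[str] = []
    groups: list[str] = []
    rows = []
    meta_src = []
    for i, sid in enumerate(references.sample_ids):
        values = {name: float(references.table.loc[sid, name])
                  for name in config.reference_ranges}
        clean = clean_spectrum(values, config)
        for rep in range(config.n_replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 23, i, rep]))
            gain = rng.uniform(*config.scatter_gain_range)
            offset = rng.normal(0.0, config.scatter_offset_sd) \
                if config.scatter_offset_sd > 0 else 0.0
            noise = rng.normal(0.0, noise_sd, size=wl.size) \
                if noise_sd > 0 else 0.0
            rows.append(np.clip(gain * clean + offset + noise, 1e-6, 1.0))
            ids.append(sid if config.n_replicates == 1 else f"{sid}_r{rep + 1}")
            groups.append(sid)
            meta_src.append(sid)

    meta = references.table.loc[meta_src, ["day", "temperature"]].copy() \
        if {"day", "temperature"} <= set(references.table.columns) else \
        pd.DataFrame(index=meta_src)
    meta = meta.rename(columns={"day": "storage_day"})
    meta["replicate_group"] = groups
    meta.index = pd.Index(ids, name="sample_id")
    spectra = SpectraSet(wl, np.vstack(rows), ids, meta)

    ground_truth: dict[str, np.ndarray] = {}
    for name in config.reference_ranges:
        hits: set[int] = set()
        for band in config.band_specs:
            if band.parameter == name:
                in_band = np.abs(wl - band.center_nm) <= band.width_nm
                hits.update(np.flatnonzero(in_band).tolist())
        ground_truth[name] = np.asarray(sorted(hits), dtype=int)

    refs = references
    if config.n_replicates > 1:
        # one reference row per spectrum row so ids stay one-to-one
        expanded = references.table.loc[meta_src].copy()
        expanded.index = pd.Index(ids, name="sample_id")
        refs = ReferenceTable(expanded)
    return SyntheticDataset(spectra, refs, ground_truth)


def generate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Convenience: references + spectra in one call."""
    config = config or SimulationConfig()
    return generate_spectra(generate_references(config), config)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def write_ground_truth(dataset: SyntheticDataset, path: str | Path) -> None:
    import json
    payload = {k: np.asarray(v).tolist() for k, v in dataset.ground_truth.items()}
    Path(path).write_text(json.dumps(payload, indent=1))
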