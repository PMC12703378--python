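"""Containers and CSV I/O for wide-format reflectance spectra and reference tables.

A :class:`SpectraSet` holds a strictly increasing wavelength grid (nm), a
``samples x wavelengths`` reflectance matrix and per-sample metadata.  A
:class:`ReferenceTable` holds the wet-lab reference values (SSC in %, TA in
g/L tartaric-acid equivalents, pH) keyed by the same sample identifiers.

The exchange format is plain CSV: spectra are written wide (first column
``sample_id``, remaining column headers are wavelengths in nm); reference
tables are long, with columns ``sample_id, SSC, TA, pH`` plus optional
``day`` and ``temperature``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "ReferenceTable",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_reference_csv",
    "write_reference_csv",
    "truncate_range",
    "average_replicates",
]

REFERENCE_PARAMETERS = ("SSC", "TA", "pH")


@dataclass
class SpectraSet:
    """Reflectance spectra on a common wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing vector of wavelengths in nm, length ``p``.
    reflectance
        Matrix of shape ``(n_samples, p)``.  Dimensionless reflectance,
        normally in ``(0, 1]`` but arbitrary positive units are accepted.
    sample_ids
        Unique sample labels, length ``n_samples``.
    metadata
        Optional per-sample table (index = ``sample_ids``) carrying e.g.
        ``storage_day``, ``temperature``, ``replicate_group``.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_ids: list[str]
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.reflectance.shape != (len(self.sample_ids), self.wavelengths.size):
            raise ValueError(
                f"reflectance shape {self.reflectance.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if self.metadata is not None:
            self.metadata = self.metadata.copy()
            self.metadata.index = pd.Index(self.sample_ids, name="sample_id")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def with_reflectance(self, reflectance: np.ndarray) -> "SpectraSet":
        """Return a copy sharing grid/ids/metadata with new reflectance values."""
        return replace(self, reflectance=np.asarray(reflectance, dtype=float))

    def take_samples(self, ids: list[str]) -> "SpectraSet":
        """Row subset in the order given by ``ids``."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        idx = [pos[s] for s in ids]
        meta = self.metadata.iloc[idx] if self.metadata is not None else None
        return SpectraSet(self.wavelengths, self.reflectance[idx], list(ids), meta)


@dataclass
class ReferenceTable:
    """Per-sample reference chemistry: SSC (%), TA (g/L) and pH."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
        for col in REFERENCE_PARAMETERS:
            if col not in df.columns:
                raise ValueError(f"reference table missing column {col!r}")
        if df.index.has_duplicates:
            raise ValueError("reference table sample ids must be unique")
        if not np.all(df["SSC"].to_numpy(float) > 0):
            raise ValueError("SSC values must be positive")
        if not np.all(df["TA"].to_numpy(float) > 0):
            raise ValueError("TA values must be positive")
        ph = df["pH"].to_numpy(float)
        if not np.all((ph > 0) & (ph < 14)):
            raise ValueError("pH values must lie in (0, 14)")
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def values(self, parameter: str, ids: list[str] | None = None) -> np.ndarray:
        """Reference values for one parameter, optionally reordered by ``ids``."""
        if parameter not in REFERENCE_PARAMETERS:
            raise KeyError(f"unknown parameter {parameter!r}; expected one of {REFERENCE_PARAMETERS}")
        series = self.table[parameter]
        if ids is not None:
            series = series.loc[ids]
        return series.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# CSV I/O


def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read a wide-format spectra CSV (first column sample id, headers = nm).

    Malformed numeric cells, ragged rows, duplicate ids and a non-monotone
    wavelength header are all hard errors.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    try:
        wavelengths = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"spectra header is not numeric wavelengths: {exc}") from exc
    if wavelengths.size >= 2 and not np.all(np.diff(wavelengths) > 0):
        raise ValueError("wavelength header must be strictly increasing")
    if df.isna().any().any():
        raise ValueError("spectra file contains missing cells (ragged rows?)")
    try:
        refl = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"malformed numeric cell in spectra file: {exc}") from exc
    return SpectraSet(wavelengths, refl, [str(i) for i in df.index])


def write_spectra_csv(s: SpectraSet, path: str | Path) -> None:
    df = pd.DataFrame(s.reflectance, index=pd.Index(s.sample_ids, name="sample_id"),
                      columns=[format(w, "g") for w in s.wavelengths])
    df.to_csv(path)


def read_reference_csv(path: str | Path) -> ReferenceTable:
    return ReferenceTable(pd.read_csv(path))


def write_reference_csv(r: ReferenceTable, path: str | Path) -> None:
    r.table.to_csv(path)


# ---------------------------------------------------------------------------
# Operations


def truncate_range(s: SpectraSet, low_nm: float, high_nm: float) -> SpectraSet:
    """Keep exactly the columns with ``low_nm <= wavelength <= high_nm``.

    The interval is closed at both ends; sample rows are untouched.  Raises
    when the requested window contains no grid point.
    """
    if not low_nm < high_nm:
        raise ValueError(f"need low_nm < high_nm, got {low_nm} >= {high_nm}")
    keep = (s.wavelengths >= low_nm) & (s.wavelengths <= high_nm)
    if not keep.any():
        raise ValueError(
            f"no wavelengths in [{low_nm}, {high_nm}] nm "
            f"(grid spans {s.wavelengths[0]}-{s.wavelengths[-1]} nm)"
        )
    return SpectraSet(s.wavelengths[keep], s.reflectance[:, keep], list(s.sample_ids),
                      s.metadata)


def average_replicates(s: SpectraSet, group_key: str = "replicate_group") -> SpectraSet:
    """Arithmetic mean of replicate scans, one output row per replicate group.

    Groups are defined by the metadata column ``group_key``; output order is
    first-appearance order of the group labels and the group label becomes
    the new sample id.
    """
    if s.metadata is None or group_key not in s.metadata.columns:
        raise ValueError(f"every sample needs a {group_key!r} metadata label")
    labels = s.metadata[group_key]
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])[:5]
        raise ValueError(f"missing {group_key!r} labels for samples {missing}")
    labels = labels.astype(str).to_numpy()
    order: list[str] = []
    seen: set[str] = set()
    for lab in labels:
        if lab not in seen:
            seen.add(lab)
            order.append(lab)
    rows = np.empty((len(order), s.n_wavelengths))
    meta_rows = []
    for i, lab in enumerate(order):
        mask = labels == lab
        rows[i] = s.reflectance[mask].mean(axis=0)
        meta_rows.append(s.metadata.iloc[int(mask.nonzero()[0][0])])
    meta = pd.DataFrame(meta_rows)
    meta = meta.drop(columns=[group_key])
    return SpectraSet(s.wavelengths, rows, order, meta if len(meta.columns) else None)
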