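"""Spectral data containers and tabular I/O.

Absorbance spectra are the universal currency between pipeline stages:
a :class:`SpectralDataset` bundles a strictly increasing wavelength grid
(nm), an ``n_samples x n_wavelengths`` absorbance matrix, sample
identifiers, and (optionally) per-sample reference values such as soluble
solids content in %.

Raw instrument output arrives as intensity triplets (sample / white
reference / dark reference); :func:`compute_absorbance` converts a triplet
to absorbance via ``A = log10((white - dark) / (raw - dark))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawScan",
    "SpectralDataset",
    "compute_absorbance",
    "trim_wavelengths",
    "read_spectra_table",
    "write_spectra_table",
    "read_raw_table",
]

#: Column names reserved by the canonical spectral-table dialect.
RESERVED_COLUMNS = ("sample_id", "y")


class SpectraFormatError(ValueError):
    """Raised when a spectral table violates the canonical dialect."""


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def _check_increasing(wavelengths: np.ndarray) -> None:
    if wavelengths.size >= 2 and not np.all(np.diff(wavelengths) > 0):
        raise ValueError("wavelengths must be strictly increasing with no duplicates")


@dataclass(frozen=True)
class RawScan:
    """One acquisition: sample, white-reference and dark-reference intensities.

    Parameters
    ----------
    wavelengths : array-like
        Strictly increasing wavelength grid in nm.
    raw, white, dark : array-like
        Intensity counts on the same grid. ``white - dark`` must be
        positive everywhere (the reference must carry signal).
    mode : str
        Acquisition geometry: ``"DR"`` (diffuse reflection), ``"DT"``
        (diffuse transmission) or ``"FT"`` (full transmission).
    integration_time_ms : float
        Detector integration time; metadata only — it cancels in the
        white-reference ratio.
    """

    wavelengths: np.ndarray
    raw: np.ndarray
    white: np.ndarray
    dark: np.ndarray
    mode: str = "DR"
    integration_time_ms: float = 1.0

    def __post_init__(self):
        wl = _as_1d(self.wavelengths, "wavelengths")
        raw = _as_1d(self.raw, "raw")
        white = _as_1d(self.white, "white")
        dark = _as_1d(self.dark, "dark")
        n = wl.size
        if not (raw.size == white.size == dark.size == n):
            raise ValueError(
                "wavelengths, raw, white and dark must share length; got "
                f"{n}, {raw.size}, {white.size}, {dark.size}"
            )
        _check_increasing(wl)
        if self.mode not in ("DR", "DT", "FT"):
            raise ValueError(f"mode must be one of DR/DT/FT, got {self.mode!r}")
        if self.integration_time_ms <= 0:
            raise ValueError("integration_time_ms must be positive")
        if np.any(white - dark <= 0):
            bad = int(np.argmax(white - dark <= 0))
            raise ValueError(
                f"white - dark must be positive everywhere; first violation at "
                f"index {bad} ({wl[bad]:g} nm)"
            )
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "raw", raw)
        object.__setattr__(self, "white", white)
        object.__setattr__(self, "dark", dark)


def compute_absorbance(scan: RawScan, max_invalid_fraction: float = 0.01) -> np.ndarray:
    """Absorbance ``A = log10((white - dark) / (raw - dark))`` per element.

    Elements where ``raw - dark <= 0`` (saturated dark or dead pixels) are
    flagged as NaN. If more than ``max_invalid_fraction`` of elements are
    invalid the whole scan is rejected.
    """
    signal = scan.raw - scan.dark
    reference = scan.white - scan.dark
    valid = signal > 0
    n_invalid = int(np.count_nonzero(~valid))
    if n_invalid > max_invalid_fraction * signal.size:
        raise ValueError(
            f"scan rejected: {n_invalid}/{signal.size} elements have "
            f"raw - dark <= 0 (limit {max_invalid_fraction:.1%})"
        )
    out = np.full(signal.shape, np.nan)
    out[valid] = np.log10(reference[valid] / signal[valid])
    return out


@dataclass
class SpectralDataset:
    """Wavelength grid + absorbance matrix + optional reference values."""

    wavelengths: np.ndarray
    X: np.ndarray
    sample_ids: list = field(default_factory=list)
    y: np.ndarray | None = None

    def __post_init__(self):
        self.wavelengths = _as_1d(self.wavelengths, "wavelengths")
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError(f"X must be a 2-D matrix, got shape {self.X.shape}")
        if self.X.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"X has {self.X.shape[1]} columns but there are "
                f"{self.wavelengths.size} wavelengths"
            )
        _check_increasing(self.wavelengths)
        if not np.all(np.isfinite(self.X)):
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(f"non-finite absorbance at row {i}, column {j}")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.X.shape[0])]
        if len(self.sample_ids) != self.X.shape[0]:
            raise ValueError("sample_ids length must match number of rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.y is not None:
            self.y = _as_1d(self.y, "y")
            if self.y.size != self.X.shape[0]:
                raise ValueError("y length must match number of samples")
            if not np.all(np.isfinite(self.y)):
                raise ValueError("y contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    def with_X(self, X: np.ndarray) -> "SpectralDataset":
        """Copy with a replacement absorbance matrix on the same grid."""
        return SpectralDataset(self.wavelengths.copy(), np.asarray(X, dtype=float),
                               list(self.sample_ids),
                               None if self.y is None else self.y.copy())

    def take_rows(self, idx: Sequence[int]) -> "SpectralDataset":
        idx = np.asarray(idx, dtype=int)
        return SpectralDataset(
            self.wavelengths.copy(),
            self.X[idx],
            [self.sample_ids[i] for i in idx],
            None if self.y is None else self.y[idx],
        )

    def take_columns(self, idx: Sequence[int]) -> "SpectralDataset":
        idx = np.asarray(idx, dtype=int)
        return SpectralDataset(
            self.wavelengths[idx], self.X[:, idx], list(self.sample_ids),
            None if self.y is None else self.y.copy(),
        )


def trim_wavelengths(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Retain the columns with ``lo <= wavelength <= hi`` (closed interval)."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    mask = (ds.wavelengths >= lo) & (ds.wavelengths <= hi)
    if not mask.any():
        raise ValueError(
            f"requested window [{lo}, {hi}] nm selects no wavelengths from grid "
            f"[{ds.wavelengths[0]:g}, {ds.wavelengths[-1]:g}] nm"
        )
    return ds.take_columns(np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# Canonical spectral-table dialect: CSV, header row = wavelengths in nm,
# reserved columns `sample_id` and (optional) `y`, one row per sample.
# ---------------------------------------------------------------------------

def write_spectra_table(ds: SpectralDataset, path) -> None:
    """Write a dataset as CSV; round-trips losslessly through float repr."""
    cols: dict = {"sample_id": ds.sample_ids}
    if ds.y is not None:
        cols["y"] = ds.y
    for j, wl in enumerate(ds.wavelengths):
        cols[repr(float(wl))] = ds.X[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_spectra_table(path) -> SpectralDataset:
    """Read a canonical spectral table; errors name the offending row/column."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise SpectraFormatError(f"{path}: missing reserved column 'sample_id'")
    sample_ids = df["sample_id"].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        dupes = {s for s in sample_ids if sample_ids.count(s) > 1}
        raise SpectraFormatError(f"{path}: duplicate sample ids {sorted(dupes)}")
    y = None
    if "y" in df.columns:
        y = pd.to_numeric(df["y"], errors="coerce").to_numpy()
        if np.any(~np.isfinite(y)):
            row = int(np.argmax(~np.isfinite(y)))
            raise SpectraFormatError(f"{path}: non-numeric y at row {row}")
    wl_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric wavelength header: {exc}") from None
    X = df[wl_cols].apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.any(~np.isfinite(X)):
        i, j = np.argwhere(~np.isfinite(X))[0]
        raise SpectraFormatError(
            f"{path}: missing or non-numeric value at row {i}, "
            f"column {wl_cols[j]!r}"
        )
    return SpectralDataset(wavelengths, X, sample_ids, y)


def read_raw_table(path, mode: str = "DR", integration_time_ms: float = 1.0):
    """Read intensity triplets from one CSV with `_raw`/`_white`/`_dark` suffixes.

    The header carries wavelength values suffixed by channel, e.g.
    ``650.0_raw``; rows are samples. Returns a list of :class:`RawScan`
    sharing the session's single white/dark reference pair if the reference
    columns repeat identical values, or per-row references otherwise.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    suffixes = ("_raw", "_white", "_dark")
    wl = sorted({float(c[: -len(s)]) for c in df.columns for s in suffixes if c.endswith(s)})
    wavelengths = np.array(wl)
    scans = []
    for _, row in df.iterrows():
        parts = {}
        for s in suffixes:
            parts[s] = np.array([float(row[f"{w:g}{s}"]) for w in wl])
        scans.append(RawScan(wavelengths, parts["_raw"], parts["_white"],
                             parts["_dark"], mode=mode,
                             integration_time_ms=integration_time_ms))
    return scans
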