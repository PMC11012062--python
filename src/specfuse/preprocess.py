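"""Scatter-correction and normalization pre-processors.

Fruit spectra mix chemical absorption with physical light-scattering
artefacts. In the mixture picture each measured spectrum is

    x_i = p_i * sum_j c_ij * s_j + b_i * 1 + noise

where ``p_i`` is a sample-specific multiplicative factor (optical-path
change) and ``b_i`` an additive baseline. The correctors here attack those
two effects:

* MSC / SNV / min-max are the standard full corrections.
* LRC (linear regression correction) removes only the additive ``b_i``:
  each spectrum is regressed on a reference mean spectrum and the fitted
  intercept subtracted. The slope is deliberately *not* divided out.
* The spectra-to-spectra ratio (S/S) removes the multiplicative ``p_i``:
  after LRC, each spectrum is divided by its own value at a reference
  wavelength. If the constituent sensed at that wavelength is (nearly)
  constant across samples, the ratio cancels ``p_i`` exactly. The
  reference wavelength is found by global search: every candidate is
  scored by the Monte-Carlo cross-validated RMSECV of a PLSR model built
  on the corrected spectra, and the argmin wins.

All fit-time statistics (reference mean, reference wavelength) come from
the calibration set only and are frozen into the returned model, so
prediction-set processing never leaks information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .crossval import MCCVConfig, mccv_splits
from .io import SpectralDataset
from .regressors import rmsecv_by_lv

__all__ = [
    "snv",
    "minmax_norm",
    "msc",
    "lrc",
    "LRCResult",
    "SSCorrectionModel",
    "ss_fit",
    "ss_apply",
    "apply_preprocessing",
    "PREPROCESSORS",
]


def snv(ds: SpectralDataset) -> SpectralDataset:
    """Standard normal variate: each spectrum to mean 0, SD 1."""
    mu = ds.X.mean(axis=1, keepdims=True)
    sd = ds.X.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(f"constant spectrum, SNV undefined: sample "
                         f"{ds.sample_ids[flat[0]]!r}")
    return ds.with_X((ds.X - mu) / sd)


def minmax_norm(ds: SpectralDataset) -> SpectralDataset:
    """Row-wise min-max normalization of each spectrum to [0, 1]."""
    lo = ds.X.min(axis=1, keepdims=True)
    hi = ds.X.max(axis=1, keepdims=True)
    flat = np.flatnonzero((hi - lo).ravel() == 0)
    if flat.size:
        raise ValueError(f"constant spectrum, min-max undefined: sample "
                         f"{ds.sample_ids[flat[0]]!r}")
    return ds.with_X((ds.X - lo) / (hi - lo))


def _row_regression(X: np.ndarray, ref: np.ndarray):
    """Per-row simple least squares of each spectrum on ``ref``.

    Returns (slopes, intercepts) of x = a*ref + b + e.
    """
    ref = np.asarray(ref, dtype=float).ravel()
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise ValueError("reference spectrum is constant; regression degenerate")
    slopes = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    intercepts = X.mean(axis=1) - slopes * ref.mean()
    return slopes, intercepts


def msc(ds: SpectralDataset, reference=None, slope_tol: float = 1e-8) -> SpectralDataset:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference (x = a*ref + b + e) and
    replaced by (x - b) / a. ``reference=None`` uses the dataset mean — for
    prediction-set data pass the *calibration* mean explicitly.
    """
    ref = ds.X.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.size != ds.n_wavelengths:
        raise ValueError("reference length does not match wavelength grid")
    slopes, intercepts = _row_regression(ds.X, ref)
    tiny = np.flatnonzero(np.abs(slopes) < slope_tol)
    if tiny.size:
        raise ValueError(
            f"MSC slope below tolerance for sample {ds.sample_ids[tiny[0]]!r}; "
            "spectrum uncorrectable")
    return ds.with_X((ds.X - intercepts[:, None]) / slopes[:, None])


@dataclass
class LRCResult:
    """Additive-effect elimination: spectra minus fitted intercepts."""

    corrected: SpectralDataset
    intercepts: np.ndarray
    slopes: np.ndarray
    reference_mean: np.ndarray


def lrc(ds: SpectralDataset, reference_mean=None) -> LRCResult:
    """Linear regression correction: subtract only the fitted intercept.

    Removes the additive baseline while preserving the multiplicative
    structure (the slope is not divided out), so a subsequent ratio step
    can cancel the multiplicative factor cleanly.
    """
    ref = ds.X.mean(axis=0) if reference_mean is None else np.asarray(reference_mean, float)
    if ref.size != ds.n_wavelengths:
        raise ValueError("reference_mean length does not match wavelength grid")
    slopes, intercepts = _row_regression(ds.X, ref)
    return LRCResult(
        corrected=ds.with_X(ds.X - intercepts[:, None]),
        intercepts=intercepts,
        slopes=slopes,
        reference_mean=ref.copy(),
    )


@dataclass
class SSCorrectionModel:
    """Fitted spectra-to-spectra corrector.

    ``reference_wavelength_index`` is the column whose (LRC-corrected)
    value divides each spectrum; after application that column is exactly
    1 for every sample. ``rmsecv_trace`` holds the search criterion per
    candidate (NaN for excluded candidates).
    """

    reference_wavelength_index: int
    reference_wavelength_nm: float
    reference_mean: np.ndarray
    rmsecv_trace: np.ndarray
    excluded_candidates: np.ndarray
    mccv_config: MCCVConfig
    max_lvs: int = 15

    def to_json(self, path) -> None:
        payload = {
            "reference_wavelength_index": int(self.reference_wavelength_index),
            "reference_wavelength_nm": float(self.reference_wavelength_nm),
            "reference_mean": self.reference_mean.tolist(),
            "rmsecv_trace": [None if not np.isfinite(v) else float(v)
                             for v in self.rmsecv_trace],
            "excluded_candidates": self.excluded_candidates.tolist(),
            "mccv_config": {
                "validation_fraction": self.mccv_config.validation_fraction,
                "n_repeats": self.mccv_config.n_repeats,
                "seed": self.mccv_config.seed,
            },
            "max_lvs": self.max_lvs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SSCorrectionModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            reference_wavelength_index=d["reference_wavelength_index"],
            reference_wavelength_nm=d["reference_wavelength_nm"],
            reference_mean=np.asarray(d["reference_mean"], dtype=float),
            rmsecv_trace=np.array([np.nan if v is None else v for v in d["rmsecv_trace"]]),
            excluded_candidates=np.asarray(d["excluded_candidates"], dtype=int),
            mccv_config=MCCVConfig(**d["mccv_config"]),
            max_lvs=d.get("max_lvs", 15),
        )


def ss_fit(ds_cal: SpectralDataset, mccv: MCCVConfig | None = None,
           max_lvs: int = 15, epsilon: float = 1e-6) -> SSCorrectionModel:
    """Global search for the spectra-to-spectra reference wavelength.

    The calibration set is LRC-corrected first (additive before
    multiplicative elimination). Each non-excluded candidate wavelength in
    turn divides every corrected spectrum by its own value there; the
    resulting matrix is scored by the MCCV RMSECV of PLSR (minimum over
    1..max_lvs latent variables), and the candidate minimizing the
    criterion becomes the reference wavelength. Candidates where any
    sample's corrected value falls below ``epsilon`` in magnitude are
    excluded as division-unstable.
    """
    if ds_cal.y is None:
        raise ValueError("calibration reference values (y) required for ss_fit")
    mccv = mccv or MCCVConfig()
    res = lrc(ds_cal)
    Xc = res.corrected.X
    y = ds_cal.y
    n, p = Xc.shape
    unstable = np.abs(Xc).min(axis=0) < epsilon
    excluded = np.flatnonzero(unstable)
    if excluded.size == p:
        raise ValueError("every candidate wavelength has a near-zero divisor; "
                         "spectra-to-spectra search impossible")
    trace = np.full(p, np.nan)
    splits = list(mccv_splits(n, mccv))
    for lam in range(p):
        if unstable[lam]:
            continue
        Z = Xc / Xc[:, lam][:, None]
        trace[lam] = float(np.nanmin(rmsecv_by_lv(Z, y, splits, max_lvs)))
    lam_star = int(np.nanargmin(trace))
    return SSCorrectionModel(
        reference_wavelength_index=lam_star,
        reference_wavelength_nm=float(ds_cal.wavelengths[lam_star]),
        reference_mean=res.reference_mean,
        rmsecv_trace=trace,
        excluded_candidates=excluded,
        mccv_config=mccv,
        max_lvs=max_lvs,
    )


def ss_apply(ds: SpectralDataset, model: SSCorrectionModel,
             epsilon: float = 1e-6) -> SpectralDataset:
    """Apply a fitted spectra-to-spectra correction to any dataset.

    LRC against the stored calibration mean, then row-wise division by the
    sample's own value at the reference wavelength. Deterministic; raises
    if any divisor magnitude falls below ``epsilon``.
    """
    if ds.n_wavelengths != model.reference_mean.size:
        raise ValueError("dataset wavelength grid does not match the fitted model")
    res = lrc(ds, reference_mean=model.reference_mean)
    div = res.corrected.X[:, model.reference_wavelength_index]
    bad = np.flatnonzero(np.abs(div) < epsilon)
    if bad.size:
        raise ValueError(
            f"near-zero divisor at reference wavelength for sample "
            f"{ds.sample_ids[bad[0]]!r}")
    out = res.corrected.X / div[:, None]
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite values after spectra-to-spectra ratio")
    return ds.with_X(out)


def apply_preprocessing(name: str, ds_cal: SpectralDataset,
                        ds_other: SpectralDataset | None = None,
                        mccv: MCCVConfig | None = None, max_lvs: int = 15):
    """Fit a named pre-processor on calibration data and apply to both sets.

    ``name`` is one of ``raw``, ``msc``, ``snv``, ``nm``, ``ss``. Returns
    ``(cal_corrected, other_corrected_or_None, fitted_state_or_None)``.
    """
    if name == "raw":
        return ds_cal, ds_other, None
    if name == "snv":
        return snv(ds_cal), None if ds_other is None else snv(ds_other), None
    if name == "nm":
        return (minmax_norm(ds_cal),
                None if ds_other is None else minmax_norm(ds_other), None)
    if name == "msc":
        ref = ds_cal.X.mean(axis=0)
        return (msc(ds_cal, reference=ref),
                None if ds_other is None else msc(ds_other, reference=ref), ref)
    if name == "ss":
        model = ss_fit(ds_cal, mccv=mccv, max_lvs=max_lvs)
        return (ss_apply(ds_cal, model),
                None if ds_other is None else ss_apply(ds_other, model), model)
    raise ValueError(f"unknown preprocessing {name!r}; "
                     "expected raw/msc/snv/nm/ss")


PREPROCESSORS = ("raw", "msc", "snv", "nm", "ss")
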