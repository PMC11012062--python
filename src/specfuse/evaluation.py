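"""Splitting, performance metrics and comparison reports.

The figures of merit are the chemometric standards: Pearson correlation on
the calibration set (Rc) and prediction set (Rp), root mean square errors
RMSEC / RMSEP, and the residual predictive deviation

    RPD = SD(prediction-set reference values) / RMSEP

with SD computed with the n-1 denominator. RPD > 2 indicates a model fit
for quantitative use, 1.4-2 an ordinary model, < 1.4 a poor one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SpectralDataset

__all__ = [
    "SplitSpec",
    "split_dataset",
    "EvaluationReport",
    "evaluate",
    "rpd_class",
    "compare_report",
]


@dataclass(frozen=True)
class SplitSpec:
    """Random calibration/prediction split at ratio cal:pred (default 3:1).

    ``rounding`` controls how the prediction-set count ``n /
    (1 + cal/pred)`` is discretized: ``"nearest"`` (default) or ``"up"``.
    For n = 105 at 3:1 these give 26 and 27 held-out samples respectively.
    """

    ratio: tuple = (3, 1)
    seed: int = 0
    rounding: str = "nearest"
    method: str = "random"

    def __post_init__(self):
        cal, pred = self.ratio
        if cal <= 0 or pred <= 0:
            raise ValueError("ratio parts must be positive")
        if self.rounding not in ("nearest", "up"):
            raise ValueError("rounding must be 'nearest' or 'up'")
        if self.method != "random":
            raise ValueError("only random splitting is supported")

    def n_prediction(self, n: int) -> int:
        frac = self.ratio[1] / (self.ratio[0] + self.ratio[1])
        raw = n * frac
        n_pred = int(np.ceil(raw)) if self.rounding == "up" else int(round(raw))
        return int(np.clip(n_pred, 1, n - 1))


def split_dataset(ds: SpectralDataset, spec: SplitSpec | None = None):
    """Disjoint, exhaustive random partition into (calibration, prediction)."""
    spec = spec or SplitSpec()
    n = ds.n_samples
    if n < 8:
        raise ValueError(f"need at least 8 samples to split, got {n}")
    n_pred = spec.n_prediction(n)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    pred_idx = np.sort(perm[:n_pred])
    cal_idx = np.sort(perm[n_pred:])
    return ds.take_rows(cal_idx), ds.take_rows(pred_idx)


@dataclass
class EvaluationReport:
    """Standard five-metric report for one fitted model."""

    model: str
    r_cal: float
    rmsec: float
    r_pred: float
    rmsep: float
    rpd: float
    n_cal: int
    n_pred: int
    factor: str = ""
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "factor": self.factor,
            "Rc": self.r_cal,
            "RMSEC": self.rmsec,
            "Rp": self.r_pred,
            "RMSEP": self.rmsep,
            "RPD": self.rpd,
            "n_cal": self.n_cal,
            "n_pred": self.n_pred,
        }
        d.update(self.extra)
        return d

    def summary(self, digits: int = 3) -> str:
        rpd = "inf" if np.isinf(self.rpd) else f"{self.rpd:.{digits}f}"
        return (f"{self.model}: Rc={self.r_cal:.{digits}f} "
                f"RMSEC={self.rmsec:.{digits}f} Rp={self.r_pred:.{digits}f} "
                f"RMSEP={self.rmsep:.{digits}f} RPD={rpd}")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0:
        raise ValueError("zero-variance truth vector; correlation undefined")
    if np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _rmse(truth: np.ndarray, fit: np.ndarray) -> float:
    e = np.asarray(fit, float) - np.asarray(truth, float)
    return float(np.sqrt(np.mean(e**2)))


def evaluate(y_cal_true, y_cal_fit, y_pred_true, y_pred_fit,
             model: str = "", factor: str = "") -> EvaluationReport:
    """Compute Rc/RMSEC on calibration and Rp/RMSEP/RPD on prediction data.

    RPD uses the prediction set's reference SD with the n-1 denominator.
    Perfect predictions (RMSEP = 0) report RPD = +inf.
    """
    y_cal_true = np.asarray(y_cal_true, float).ravel()
    y_cal_fit = np.asarray(y_cal_fit, float).ravel()
    y_pred_true = np.asarray(y_pred_true, float).ravel()
    y_pred_fit = np.asarray(y_pred_fit, float).ravel()
    if y_cal_true.size != y_cal_fit.size or y_pred_true.size != y_pred_fit.size:
        raise ValueError("truth/fit length mismatch")
    if y_pred_true.size < 3:
        raise ValueError("need at least 3 prediction samples")
    rmsec = _rmse(y_cal_true, y_cal_fit)
    rmsep = _rmse(y_pred_true, y_pred_fit)
    sd_pred = float(np.std(y_pred_true, ddof=1))
    rpd = np.inf if rmsep == 0 else sd_pred / rmsep
    return EvaluationReport(
        model=model,
        r_cal=_pearson(y_cal_true, y_cal_fit),
        rmsec=rmsec,
        r_pred=_pearson(y_pred_true, y_pred_fit),
        rmsep=rmsep,
        rpd=rpd,
        n_cal=int(y_cal_true.size),
        n_pred=int(y_pred_true.size),
        factor=factor,
    )


def rpd_class(rpd: float) -> str:
    """Interpret an RPD value: > 2 good, 1.4-2 ordinary, < 1.4 poor.

    The boundary values 1.4 and 2.0 are assigned to ``ordinary``.
    """
    if rpd < 0:
        raise ValueError("RPD cannot be negative")
    if rpd > 2.0:
        return "good"
    if rpd >= 1.4:
        return "ordinary"
    return "poor"


def compare_report(reports: list) -> pd.DataFrame:
    """Rank reports by RPD descending, ties broken by RMSEP ascending."""
    if not reports:
        raise ValueError("no reports to compare")
    df = pd.DataFrame([r.to_dict() for r in reports])
    cols = ["model", "factor", "Rc", "RMSEC", "Rp", "RMSEP", "RPD"]
    df = df[cols + [c for c in df.columns if c not in cols]]
    return df.sort_values(["RPD", "RMSEP"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
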