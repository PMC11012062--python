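"""Model/Results interface over the full calibration stack.

:class:`SSCCalibration` is constructed from a :class:`SpectralDataset`
(spectra + reference values) and a recipe — pre-processing, optional
wavelength selection, base regressor or fusion topology, and a split
specification. ``fit()`` executes split -> preprocess (fit on calibration,
apply to both) -> select (calibration only) -> train -> (optionally) fuse
-> evaluate, and returns a :class:`CalibrationResults` carrying the five
standard metrics, the fitted components, and ``summary()`` /
``predict()`` / ``plot_predictions()``.

Example
-------
>>> from specfuse import scenario, simulate, SSCCalibration
>>> ds, _ = simulate(scenario("both", seed=7))
>>> res = SSCCalibration(ds, preprocess="ss", selector="cars", seed=7).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .crossval import MCCVConfig, derive_seed
from .evaluation import EvaluationReport, SplitSpec, evaluate, rpd_class, split_dataset
from .fusion import COMBINERS, build_cncmf, build_mcmf
from .io import SpectralDataset
from .preprocess import PREPROCESSORS, apply_preprocessing, ss_apply, msc, minmax_norm, snv
from .regressors import PSOConfig, fit_lssvr, fit_plsr, fit_pso_elm, tune_lssvr
from .selection import SELECTORS, SelectionConfig

__all__ = ["SSCCalibration", "CalibrationResults"]

REGRESSORS = ("plsr", "lssvr", "pso-elm")
FUSIONS = ("mcmf", "cncmf")


class SSCCalibration:
    """Spectral calibration model for a scalar quality attribute.

    Parameters
    ----------
    dataset : SpectralDataset
        Spectra with reference values (``y`` required).
    preprocess : str
        One of ``raw``, ``msc``, ``snv``, ``nm``, ``ss``.
    selector : str or None
        ``cars``, ``boss`` or ``ivissa``; None keeps the full spectrum.
    regressor : str
        Base learner for single-model recipes: ``plsr``, ``lssvr`` or
        ``pso-elm``.
    fusion : str or None
        ``mcmf`` (members from all three selectors) or ``cncmf`` (CARS
        subset vs complement); overrides ``selector``/``regressor``.
    combiner : str
        Fusion combiner: ``sa``, ``bg``, ``mlr``, ``lssvr``, ``pso-elm``.
    split : SplitSpec
        Calibration/prediction partition recipe (default 3:1 random).
    seed : int
        Global seed; every stochastic stage derives its own stream from it.
    """

    def __init__(self, dataset: SpectralDataset, preprocess: str = "ss",
                 selector: str | None = None, regressor: str = "plsr",
                 fusion: str | None = None, combiner: str = "sa",
                 split: SplitSpec | None = None, max_lvs: int = 15,
                 mccv: MCCVConfig | None = None,
                 selection_config: SelectionConfig | None = None,
                 hidden_nodes: int = 30, pso: PSOConfig | None = None,
                 seed: int = 0):
        if dataset.y is None:
            raise ValueError("dataset must carry reference values (y)")
        if preprocess not in PREPROCESSORS:
            raise ValueError(f"unknown preprocess {preprocess!r}")
        if selector is not None and selector not in SELECTORS:
            raise ValueError(f"unknown selector {selector!r}")
        if regressor not in REGRESSORS:
            raise ValueError(f"unknown regressor {regressor!r}")
        if fusion is not None and fusion not in FUSIONS:
            raise ValueError(f"unknown fusion {fusion!r}")
        if combiner not in COMBINERS:
            raise ValueError(f"unknown combiner {combiner!r}")
        self.dataset = dataset
        self.preprocess = preprocess
        self.selector = selector
        self.regressor = regressor
        self.fusion = fusion
        self.combiner = combiner
        self.split = split or SplitSpec(seed=derive_seed(seed, "split"))
        self.max_lvs = max_lvs
        self.mccv = mccv
        self.selection_config = selection_config
        self.hidden_nodes = hidden_nodes
        self.pso = pso
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, y: str = "y",
                       sample_id: str = "sample_id", **kwargs) -> "SSCCalibration":
        """Build from a wide DataFrame (wavelength-named numeric columns)."""
        wl_cols = [c for c in df.columns if c not in (y, sample_id)]
        wavelengths = np.array([float(c) for c in wl_cols])
        ids = (df[sample_id].astype(str).tolist() if sample_id in df.columns
               else [f"s{i}" for i in range(len(df))])
        ds = SpectralDataset(wavelengths, df[wl_cols].to_numpy(float), ids,
                             df[y].to_numpy(float) if y in df.columns else None)
        return cls(ds, **kwargs)

    # -- fitting ------------------------------------------------------------

    def _label(self) -> str:
        bits = [self.preprocess.upper() if self.preprocess != "ss" else "S/S"]
        if self.fusion:
            bits += [self.fusion.upper(), self.combiner.upper()]
        else:
            if self.selector:
                bits.append(self.selector.upper())
            bits.append(self.regressor.upper())
        return "-".join(bits)

    def _fit_single(self, Xc, yc, seed: int):
        if self.regressor == "plsr":
            mccv = self.mccv or MCCVConfig(seed=derive_seed(seed, "plsr-lv"))
            model = fit_plsr(Xc, yc, max_lvs=self.max_lvs, mccv=mccv)
            return model, f"LVs: {model.n_lvs}"
        if self.regressor == "lssvr":
            gamma, sigma2 = tune_lssvr(Xc, yc, cv_folds=min(10, Xc.shape[0]),
                                       seed=derive_seed(seed, "lssvr"))
            model = fit_lssvr(Xc, yc, gamma, sigma2)
            return model, f"gamma: {gamma:.4g}, sigma2: {sigma2:.4g}"
        pso = self.pso or PSOConfig(seed=derive_seed(seed, "pso"))
        model = fit_pso_elm(Xc, yc, hidden_nodes=self.hidden_nodes, pso=pso)
        return model, f"Hidden nodes: {self.hidden_nodes}"

    def fit(self) -> "CalibrationResults":
        self._single_model = None
        self._single_cols = None
        ds_cal, ds_pred = split_dataset(self.dataset, self.split)
        mccv_ss = MCCVConfig(seed=derive_seed(self.seed, "ss-search"))
        cal, pred, prep_state = apply_preprocessing(
            self.preprocess, ds_cal, ds_pred, mccv=mccv_ss, max_lvs=self.max_lvs)
        sel_cfg = self.selection_config or SelectionConfig(
            seed=derive_seed(self.seed, "selection"))
        selection_results: dict = {}
        fusion_model = None
        selection = None
        if self.fusion == "mcmf":
            for key, fn in (("CARS", SELECTORS["cars"]),
                            ("BOSS", SELECTORS["boss"]),
                            ("iVISSA", SELECTORS["ivissa"])):
                selection_results[key] = fn(cal.X, cal.y, sel_cfg)
            fusion_model, y_pred_fit = build_mcmf(
                cal, pred, selection_results, combiner=self.combiner,
                seed=derive_seed(self.seed, "fusion"), max_lvs=self.max_lvs)
            y_cal_fit = fusion_model.predict(cal.X)
            factor = fusion_model.factor_string()
        elif self.fusion == "cncmf":
            selection_results["CARS"] = SELECTORS["cars"](cal.X, cal.y, sel_cfg)
            fusion_model, y_pred_fit = build_cncmf(
                cal, pred, selection_results["CARS"], combiner=self.combiner,
                seed=derive_seed(self.seed, "fusion"), max_lvs=self.max_lvs)
            y_cal_fit = fusion_model.predict(cal.X)
            factor = fusion_model.factor_string()
        else:
            cols = np.arange(cal.n_wavelengths)
            if self.selector:
                selection = SELECTORS[self.selector](cal.X, cal.y, sel_cfg)
                cols = selection.selected
            model, factor = self._fit_single(cal.X[:, cols], cal.y,
                                             derive_seed(self.seed, "train"))
            y_cal_fit = model.predict(cal.X[:, cols])
            y_pred_fit = model.predict(pred.X[:, cols])
            fusion_model = None
            self._single_model, self._single_cols = model, cols
        report = evaluate(cal.y, y_cal_fit, pred.y, y_pred_fit,
                          model=self._label(), factor=factor)
        return CalibrationResults(
            model=self, report=report, ds_cal=cal, ds_pred=pred,
            y_cal_fit=np.asarray(y_cal_fit), y_pred_fit=np.asarray(y_pred_fit),
            preprocess_state=prep_state, selection=selection,
            selection_results=selection_results or None,
            fusion_model=fusion_model,
            regressor_model=getattr(self, "_single_model", None),
            regressor_columns=getattr(self, "_single_cols", None),
        )


class CalibrationResults:
    """Fitted calibration: metrics, components, prediction and plotting."""

    def __init__(self, model, report: EvaluationReport, ds_cal, ds_pred,
                 y_cal_fit, y_pred_fit, preprocess_state=None, selection=None,
                 selection_results=None, fusion_model=None,
                 regressor_model=None, regressor_columns=None):
        self.model = model
        self.report = report
        self.ds_cal = ds_cal
        self.ds_pred = ds_pred
        self.y_cal_fit = y_cal_fit
        self.y_pred_fit = y_pred_fit
        self.preprocess_state = preprocess_state
        self.selection = selection
        self.selection_results = selection_results
        self.fusion_model = fusion_model
        self.regressor_model = regressor_model
        self.regressor_columns = regressor_columns

    # -- metric shortcuts ---------------------------------------------------
    @property
    def rc(self) -> float:
        return self.report.r_cal

    @property
    def rmsec(self) -> float:
        return self.report.rmsec

    @property
    def rp(self) -> float:
        return self.report.r_pred

    @property
    def rmsep(self) -> float:
        return self.report.rmsep

    @property
    def rpd(self) -> float:
        return self.report.rpd

    def _preprocess_new(self, ds: SpectralDataset) -> SpectralDataset:
        name = self.model.preprocess
        if name == "raw":
            return ds
        if name == "snv":
            return snv(ds)
        if name == "nm":
            return minmax_norm(ds)
        if name == "msc":
            return msc(ds, reference=self.preprocess_state)
        return ss_apply(ds, self.preprocess_state)

    def predict(self, ds: SpectralDataset | np.ndarray) -> np.ndarray:
        """Predict reference values for new spectra on the fitted grid.

        Accepts a dataset (preprocessed with the calibration-fitted state)
        or an already-preprocessed matrix.
        """
        if isinstance(ds, SpectralDataset):
            X = self._preprocess_new(ds).X
        else:
            X = np.atleast_2d(np.asarray(ds, float))
        if self.fusion_model is not None:
            return self.fusion_model.predict(X)
        return self.regressor_model.predict(X[:, self.regressor_columns])

    def summary(self, digits: int = 3) -> str:
        r = self.report
        rpd = "inf" if np.isinf(r.rpd) else f"{r.rpd:.{digits}f}"
        lines = [
            "Spectral calibration results",
            "=" * 58,
            f"Model:            {r.model}",
            f"Factor:           {r.factor}",
            f"Samples:          {r.n_cal} calibration / {r.n_pred} prediction",
            f"Rc   (calib r):   {r.r_cal:.{digits}f}",
            f"RMSEC (%):        {r.rmsec:.{digits}f}",
            f"Rp   (pred r):    {r.r_pred:.{digits}f}",
            f"RMSEP (%):        {r.rmsep:.{digits}f}",
            f"RPD:              {rpd}  ({rpd_class(r.rpd)})",
        ]
        if self.selection is not None:
            lines.append(f"Wavelengths kept: {self.selection.selected.size} "
                         f"({self.selection.algorithm})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = self.report.to_dict()
        if self.selection is not None:
            d["selected_wavelengths"] = self.selection.selected.tolist()
        if self.fusion_model is not None:
            d["fusion"] = self.fusion_model.to_dict()
        return d

    def plot_predictions(self, ax=None):
        """Measured-vs-predicted scatter for both sample sets."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(self.ds_cal.y, self.y_cal_fit, s=18, alpha=0.7,
                   label=f"calibration (Rc={self.rc:.3f})")
        ax.scatter(self.ds_pred.y, self.y_pred_fit, s=22, marker="^",
                   alpha=0.8, label=f"prediction (Rp={self.rp:.3f})")
        lo = min(self.ds_cal.y.min(), self.ds_pred.y.min())
        hi = max(self.ds_cal.y.max(), self.ds_pred.y.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel("measured")
        ax.set_ylabel("predicted")
        ax.set_title(self.report.model)
        ax.legend(frameon=False)
        return ax
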