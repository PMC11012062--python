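"""Member-model fusion: MCMF and CNCMF topologies with five combiners.

A *member* is a PLSR model restricted to one wavelength subset. Two
topologies are supported:

* MCMF — multiple characteristic-wavelength member fusion: members
  f1/f2/f3 are built on the CARS/BOSS/iVISSA selections of the same
  preprocessed calibration set.
* CNCMF — characteristic / non-characteristic fusion: f4 is built on the
  CARS selection, f5 on its complement, so the two subsets are disjoint
  and jointly cover the full grid.

Member predictions are combined by one of:

* SA   — simple averaging, (f1 + ... + fm) / m;
* BG   — Bates-Granger inverse-variance weights w_k = (1/v_k) / sum(1/v_j),
         with member variances estimated from seeded k-fold cross-validated
         calibration residuals;
* MLR  — ordinary least squares stacking with intercept;
* LSSVR / PSO-ELM — nonlinear stacking over the m-dimensional member
  prediction vector, reusing the base regressors (hidden nodes 15 for the
  ELM stacker).

Combiners are fitted on in-sample calibration member predictions by
default; an out-of-fold option is available for leakage-averse use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crossval import MCCVConfig, derive_seed, kfold_indices
from .io import SpectralDataset
from .regressors import (PLSRModel, PSOConfig, fit_lssvr, fit_plsr,
                         fit_pso_elm, simpls_paths, tune_lssvr)
from .selection import SelectionResult

__all__ = [
    "MemberSpec",
    "FusionModel",
    "fuse_sa",
    "fuse_bg",
    "fit_stack_mlr",
    "build_mcmf",
    "build_cncmf",
    "COMBINERS",
]

COMBINERS = ("sa", "bg", "mlr", "lssvr", "pso-elm")

FUSION_HIDDEN_NODES = 15  # ELM stacker width over member predictions


@dataclass
class MemberSpec:
    """One fusion member: a wavelength subset plus its fitted PLSR."""

    label: str
    wavelength_subset: np.ndarray
    regressor: PLSRModel
    provenance: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.regressor.predict(np.atleast_2d(X)[:, self.wavelength_subset])


def fuse_sa(member_preds: np.ndarray) -> np.ndarray:
    """Simple averaging across members (row-wise mean)."""
    P = np.atleast_2d(np.asarray(member_preds, float))
    if P.shape[1] < 2:
        raise ValueError("simple averaging needs at least 2 members")
    return P.mean(axis=1)


def fuse_bg(member_preds: np.ndarray, member_variances) -> tuple[np.ndarray, np.ndarray]:
    """Bates-Granger inverse-variance weighting.

    Returns ``(fused_prediction, weights)`` with
    ``w_k = (1/v_k) / sum_j (1/v_j)``; weights are nonnegative, sum to 1,
    and are invariant to rescaling all variances.
    """
    P = np.atleast_2d(np.asarray(member_preds, float))
    v = np.asarray(member_variances, float).ravel()
    if v.size != P.shape[1]:
        raise ValueError("one variance per member required")
    if np.any(v <= 0):
        raise ValueError("member variances must be positive")
    inv = 1.0 / v
    w = inv / inv.sum()
    return P @ w, w


def fit_stack_mlr(member_preds_train, y_train,
                  cond_limit: float = 1e10) -> tuple[np.ndarray, float]:
    """OLS of y on member predictions with intercept.

    Returns ``(coefficients, intercept)``. By the least-squares property
    the fused training RMSE is bounded by every single member's. Raises on
    near-collinear members (condition number above ``cond_limit``) with a
    hint to remove a member.
    """
    P = np.atleast_2d(np.asarray(member_preds_train, float))
    y = np.asarray(y_train, float).ravel()
    design = np.column_stack([P, np.ones(P.shape[0])])
    cond = np.linalg.cond(design)
    if cond > cond_limit:
        raise ValueError(
            f"member predictions are collinear (cond {cond:.2e}); "
            "consider removing a member before MLR stacking")
    sol, *_ = np.linalg.lstsq(design, y, rcond=None)
    return sol[:-1], float(sol[-1])


@dataclass
class FusionModel:
    """Fitted fusion: member registry + combiner parameters."""

    members: list
    combiner: str
    combiner_params: dict = field(default_factory=dict)
    topology: str = "MCMF"

    def __post_init__(self):
        labels = [m.label for m in self.members]
        if len(set(labels)) != len(labels):
            raise ValueError("member labels must be unique")
        if self.combiner not in COMBINERS:
            raise ValueError(f"unknown combiner {self.combiner!r}")
        if self.topology == "MCMF":
            if len(self.members) < 2:
                raise ValueError("MCMF requires at least 2 members")
        elif self.topology == "CNCMF":
            if len(self.members) != 2:
                raise ValueError("CNCMF requires exactly 2 members")
            a = set(self.members[0].wavelength_subset.tolist())
            b = set(self.members[1].wavelength_subset.tolist())
            if a & b:
                raise ValueError("CNCMF member subsets must be disjoint")
        else:
            raise ValueError(f"unknown topology {self.topology!r}")

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.predict(X) for m in self.members])

    def combine(self, member_preds: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(np.asarray(member_preds, float))
        if P.shape[1] != len(self.members):
            raise ValueError(
                f"expected {len(self.members)} member columns, got {P.shape[1]}")
        if self.combiner == "sa":
            return fuse_sa(P) if P.shape[1] >= 2 else P[:, 0]
        if self.combiner == "bg":
            return P @ self.combiner_params["weights"]
        if self.combiner == "mlr":
            return P @ self.combiner_params["coef"] + self.combiner_params["intercept"]
        return self.combiner_params["stacker"].predict(P)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.combine(self.member_predictions(X))

    def factor_string(self, digits: int = 3) -> str:
        """Printed-style description, e.g. '0.553 f4 + 0.447 f5'."""
        labels = [m.label for m in self.members]
        if self.combiner == "sa":
            return f"({' + '.join(labels)})/{len(labels)}"
        if self.combiner == "bg":
            w = self.combiner_params["weights"]
            return " + ".join(f"{wi:.{digits}f} {lab}" for wi, lab in zip(w, labels))
        if self.combiner == "mlr":
            coef = self.combiner_params["coef"]
            c0 = self.combiner_params["intercept"]
            parts = []
            for i, (ci, lab) in enumerate(zip(coef, labels)):
                lead = ("-" if ci < 0 else "") if i == 0 else ("- " if ci < 0 else "+ ")
                parts.append(f"{lead}{abs(ci):.{digits}f} {lab}")
            parts.append(f"{'-' if c0 < 0 else '+'} {abs(c0):.{digits}f}")
            return " ".join(parts)
        if self.combiner == "lssvr":
            s = self.combiner_params["stacker"]
            return f"gamma: {s.gamma:.3f}, sigma2: {s.sigma2:.3f}"
        return f"Hidden nodes: {self.combiner_params['stacker'].hidden_nodes}"

    def to_dict(self) -> dict:
        d = {
            "topology": self.topology,
            "combiner": self.combiner,
            "factor": self.factor_string(),
            "members": [
                {"label": m.label,
                 "provenance": m.provenance,
                 "wavelength_subset": m.wavelength_subset.tolist(),
                 "n_lvs": int(m.regressor.n_lvs)}
                for m in self.members
            ],
        }
        if self.combiner == "bg":
            d["weights"] = self.combiner_params["weights"].tolist()
        if self.combiner == "mlr":
            d["coef"] = self.combiner_params["coef"].tolist()
            d["intercept"] = self.combiner_params["intercept"]
        return d


def _member_cv_predictions(X, y, members, cv_folds: int, seed: int):
    """Out-of-fold member predictions on the calibration set.

    Each member's PLSR is refit per fold at its chosen LV count; used both
    for BG variance estimation and the optional out-of-fold combiner fit.
    """
    n = X.shape[0]
    P = np.zeros((n, len(members)))
    for train, val in kfold_indices(n, cv_folds, seed=seed):
        for k, m in enumerate(members):
            sub = m.wavelength_subset
            B, xm, ym, n_eff = simpls_paths(X[np.ix_(train, sub)], y[train],
                                            max(m.regressor.n_lvs, 1))
            lv = min(m.regressor.n_lvs, max(n_eff, 1))
            P[val, k] = (X[np.ix_(val, sub)] - xm) @ B[:, lv - 1] + ym
    return P


def _fit_combiner(P_cal, y_cal, combiner: str, seed: int,
                  member_variances=None) -> dict:
    if combiner == "sa":
        return {}
    if combiner == "bg":
        if member_variances is None:
            raise ValueError("BG combiner needs member variances")
        _, w = fuse_bg(P_cal, member_variances)
        return {"weights": w}
    if combiner == "mlr":
        coef, intercept = fit_stack_mlr(P_cal, y_cal)
        return {"coef": coef, "intercept": intercept}
    if combiner == "lssvr":
        gamma, sigma2 = tune_lssvr(P_cal, y_cal,
                                   cv_folds=min(10, P_cal.shape[0]),
                                   seed=derive_seed(seed, "stack-lssvr"))
        return {"stacker": fit_lssvr(P_cal, y_cal, gamma, sigma2)}
    if combiner == "pso-elm":
        stacker = fit_pso_elm(
            P_cal, y_cal, hidden_nodes=FUSION_HIDDEN_NODES,
            pso=PSOConfig(seed=derive_seed(seed, "stack-pso")))
        return {"stacker": stacker}
    raise ValueError(f"unknown combiner {combiner!r}")


def _build(ds_cal: SpectralDataset, ds_pred, member_defs, combiner: str,
           topology: str, seed: int, max_lvs: int, mccv: MCCVConfig | None,
           combiner_out_of_fold: bool, cv_folds: int = 5):
    if ds_cal.y is None:
        raise ValueError("calibration reference values (y) required")
    y = ds_cal.y
    members = []
    # one shared MCCV stream for LV selection: identical subsets then yield
    # identical member models
    member_mccv = mccv or MCCVConfig(seed=derive_seed(seed, "member-lv"))
    for label, subset, provenance in member_defs:
        subset = np.unique(np.asarray(subset, dtype=int))
        if subset.size == 0:
            raise ValueError(f"member {label}: empty wavelength subset")
        if subset.min() < 0 or subset.max() >= ds_cal.n_wavelengths:
            raise ValueError(f"member {label}: subset outside the grid")
        model = fit_plsr(ds_cal.X[:, subset], y, max_lvs=max_lvs,
                         mccv=member_mccv)
        members.append(MemberSpec(label, subset, model, provenance))
    P_cal = np.column_stack([m.predict(ds_cal.X) for m in members])
    variances = None
    if combiner == "bg":
        P_oof = _member_cv_predictions(ds_cal.X, y, members, cv_folds,
                                       derive_seed(seed, "bg-folds"))
        variances = ((P_oof - y[:, None]) ** 2).mean(axis=0)
    P_fit = P_cal
    if combiner_out_of_fold and combiner in ("mlr", "lssvr", "pso-elm"):
        P_fit = _member_cv_predictions(ds_cal.X, y, members, cv_folds,
                                       derive_seed(seed, "oof-folds"))
    params = _fit_combiner(P_fit, y, combiner, seed, member_variances=variances)
    if variances is not None:
        params["member_variances"] = variances
    fm = FusionModel(members=members, combiner=combiner,
                     combiner_params=params, topology=topology)
    preds = None if ds_pred is None else fm.predict(ds_pred.X)
    return fm, preds


def build_mcmf(ds_cal: SpectralDataset, ds_pred, selector_results: dict,
               combiner: str = "sa", seed: int = 0, max_lvs: int = 15,
               mccv: MCCVConfig | None = None,
               combiner_out_of_fold: bool = False):
    """MCMF: members f1/f2/f3 from the CARS/BOSS/iVISSA selections.

    ``selector_results`` maps the provenance names ``"CARS"``, ``"BOSS"``,
    ``"iVISSA"`` to :class:`SelectionResult` (or raw index arrays). Returns
    ``(FusionModel, prediction_set_predictions)``.
    """
    member_defs = []
    for label, key in (("f1", "CARS"), ("f2", "BOSS"), ("f3", "iVISSA")):
        if key not in selector_results:
            raise ValueError(f"missing selector result for {key}")
        res = selector_results[key]
        subset = res.selected if isinstance(res, SelectionResult) else np.asarray(res)
        member_defs.append((label, subset, key))
    return _build(ds_cal, ds_pred, member_defs, combiner, "MCMF", seed,
                  max_lvs, mccv, combiner_out_of_fold)


def build_cncmf(ds_cal: SpectralDataset, ds_pred, cars_result,
                combiner: str = "sa", seed: int = 0, max_lvs: int = 15,
                mccv: MCCVConfig | None = None,
                combiner_out_of_fold: bool = False):
    """CNCMF: f4 on the CARS subset, f5 on its complement.

    The two subsets are disjoint and jointly cover the full grid. Raises
    if the CARS subset is empty or covers everything (empty complement).
    """
    subset = (cars_result.selected if isinstance(cars_result, SelectionResult)
              else np.unique(np.asarray(cars_result, dtype=int)))
    p = ds_cal.n_wavelengths
    if subset.size == 0:
        raise ValueError("CARS subset is empty")
    if subset.size >= p:
        raise ValueError("CARS subset covers the whole grid; complement empty")
    complement = np.setdiff1d(np.arange(p), subset)
    member_defs = [("f4", subset, "CARS"),
                   ("f5", complement, "non-CARS-complement")]
    return _build(ds_cal, ds_pred, member_defs, combiner, "CNCMF", seed,
                  max_lvs, mccv, combiner_out_of_fold)
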