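"""Characteristic-wavelength screening: CARS, BOSS and iVISSA.

All three selectors wrap the same primitive — score a candidate wavelength
subset by the seeded k-fold RMSECV of a PLSR model (latent-variable count
chosen by inner minimum RMSECV, capped at the subset rank) — and differ in
how they propose subsets:

* CARS (competitive adaptive reweighted sampling): Monte-Carlo loop; each
  iteration fits PLSR on a random row subsample, weights variables by
  |regression coefficient|, keeps a fraction given by an exponentially
  decreasing schedule calibrated from all variables down to 2, then
  resamples survivors proportionally to weight.
* BOSS (bootstrapping soft shrinkage): weighted bootstrap sampling of
  variables generates sub-models; variable weights are updated from their
  frequency in the best fraction of sub-models (soft shrinkage — weights
  shrink, variables are never hard-eliminated) until one variable remains.
* iVISSA (interval variable iterative space shrinkage approach): a global
  phase updates per-variable inclusion probabilities by weighted
  binary-matrix sampling, then a local phase grows contiguous wavelength
  intervals around the surviving variables while the criterion improves.

Every selector is deterministic given ``SelectionConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .crossval import derive_seed, kfold_indices
from .regressors import rmsecv_by_lv, simpls_paths

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "cars_select",
    "boss_select",
    "ivissa_select",
    "selector_folds",
    "SELECTORS",
]

#: Monte-Carlo run counts used when ``SelectionConfig.n_runs`` is None.
DEFAULT_N_RUNS = {"CARS": 100, "BOSS": 1000, "iVISSA": 500}


@dataclass(frozen=True)
class SelectionConfig:
    """Shared selector settings: 15 max LVs, 5-fold CV, seeded runs."""

    max_lvs: int = 15
    cv_folds: int = 5
    n_runs: int | None = None
    seed: int = 0
    cars_row_fraction: float = 0.8
    best_fraction: float = 0.1
    max_outer: int = 50

    def __post_init__(self):
        if self.max_lvs < 1 or self.cv_folds < 2:
            raise ValueError("max_lvs >= 1 and cv_folds >= 2 required")
        if self.n_runs is not None and self.n_runs < 1:
            raise ValueError("n_runs must be positive")
        if not 0 < self.cars_row_fraction <= 1:
            raise ValueError("cars_row_fraction must be in (0, 1]")
        if not 0 < self.best_fraction <= 1:
            raise ValueError("best_fraction must be in (0, 1]")

    def runs_for(self, algorithm: str) -> int:
        return self.n_runs if self.n_runs is not None else DEFAULT_N_RUNS[algorithm]


@dataclass
class SelectionResult:
    """Selected wavelength indices plus search diagnostics."""

    selected: np.ndarray
    rmsecv_best: float
    trace: list = field(default_factory=list)  # (subset_size, rmsecv) per step
    frequencies_or_weights: np.ndarray | None = None
    algorithm: str = ""
    n_lvs_best: int = 1

    def __post_init__(self):
        self.selected = np.unique(np.asarray(self.selected, dtype=int))
        if self.selected.size == 0:
            raise ValueError("empty wavelength selection")

    def to_json(self, path, wavelengths=None) -> None:
        payload = {
            "algorithm": self.algorithm,
            "selected": self.selected.tolist(),
            "selected_nm": (None if wavelengths is None
                            else np.asarray(wavelengths)[self.selected].tolist()),
            "rmsecv_best": float(self.rmsecv_best),
            "n_lvs_best": int(self.n_lvs_best),
            "trace": [[int(a), float(b)] for a, b in self.trace],
            "frequencies_or_weights": (
                None if self.frequencies_or_weights is None
                else np.asarray(self.frequencies_or_weights, dtype=float).tolist()),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def selector_folds(n: int, cfg: SelectionConfig):
    """The fixed seeded fold partition shared by all scoring in one run."""
    return list(kfold_indices(n, cfg.cv_folds, seed=derive_seed(cfg.seed, "folds")))


class _SubsetScorer:
    """RMSECV scoring of wavelength subsets with memoization."""

    def __init__(self, X, y, folds, max_lvs):
        self.X = X
        self.y = y
        self.folds = folds
        self.max_lvs = max_lvs
        self._cache: dict = {}

    def __call__(self, subset) -> tuple[float, int]:
        subset = np.asarray(subset, dtype=int)
        key = subset.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        rms = rmsecv_by_lv(self.X[:, subset], self.y, self.folds, self.max_lvs)
        lv = int(np.argmin(rms)) + 1
        out = (float(rms[lv - 1]), lv)
        self._cache[key] = out
        return out


def _better(rms, subset, best):
    """Tie-break: lower RMSECV, then smaller subset, then lowest start."""
    if best is None:
        return True
    b_rms, b_sub, _ = best
    if rms != b_rms:
        return rms < b_rms
    if subset.size != b_sub.size:
        return subset.size < b_sub.size
    return tuple(subset) < tuple(b_sub)


def _validate(X, y, cfg):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < cfg.cv_folds:
        raise ValueError("fewer samples than CV folds")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 wavelengths to select from")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X, y


def cars_select(X_cal, y_cal, cfg: SelectionConfig | None = None) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    The retention schedule ``r(i) = a * exp(-k * i)`` is calibrated so that
    ``r(1) = 1`` (all variables) and ``r(N) = 2/p`` (two variables), which
    makes the retained-count sequence non-increasing down to ~2.
    """
    cfg = cfg or SelectionConfig()
    X, y = _validate(X_cal, y_cal, cfg)
    n, p = X.shape
    N = cfg.runs_for("CARS")
    rng = np.random.default_rng(derive_seed(cfg.seed, "cars"))
    folds = selector_folds(n, cfg)
    score = _SubsetScorer(X, y, folds, cfg.max_lvs)
    # EDF schedule constants: r(1)=1, r(N)=2/p
    if p <= 2:
        raise ValueError("CARS needs more than 2 starting variables")
    a = (p / 2.0) ** (1.0 / (N - 1)) if N > 1 else 1.0
    k = np.log(p / 2.0) / (N - 1) if N > 1 else 0.0
    n_rows = max(cfg.cv_folds, int(round(cfg.cars_row_fraction * n)))
    current = np.arange(p)
    freq = np.zeros(p)
    trace = []
    best = None
    for i in range(1, N + 1):
        rows = rng.choice(n, size=min(n_rows, n), replace=False)
        sub_lvs = min(cfg.max_lvs, current.size)
        inner = list(kfold_indices(rows.size, cfg.cv_folds,
                                   seed=derive_seed(cfg.seed, f"cars-inner-{i}")))
        rms_inner = rmsecv_by_lv(X[np.ix_(rows, current)], y[rows], inner, sub_lvs)
        lv = int(np.argmin(rms_inner)) + 1
        B, *_ = simpls_paths(X[np.ix_(rows, current)], y[rows], lv)
        weights = np.abs(B[:, lv - 1])
        # exponentially decreasing retention, then adaptive reweighted sampling
        keep_n = int(np.clip(round(a * np.exp(-k * i) * p), 2, current.size))
        order = np.argsort(-weights, kind="stable")
        kept = order[:keep_n]
        w_kept = weights[kept]
        if w_kept.sum() <= 0:
            survivors = kept[:2]
        else:
            draws = rng.choice(kept, size=keep_n, replace=True,
                               p=w_kept / w_kept.sum())
            survivors = np.unique(draws)
            if survivors.size < 2:
                survivors = np.unique(np.concatenate([survivors, kept[:2]]))[:2]
        current = np.sort(current[survivors])
        freq[current] += 1
        rms, lv_full = score(current)
        trace.append((current.size, rms))
        if _better(rms, current, best):
            best = (rms, current.copy(), lv_full)
    rms, subset, lv = best
    return SelectionResult(selected=subset, rmsecv_best=rms, trace=trace,
                           frequencies_or_weights=freq, algorithm="CARS",
                           n_lvs_best=lv)


def boss_select(X_cal, y_cal, cfg: SelectionConfig | None = None) -> SelectionResult:
    """Bootstrapping soft shrinkage.

    Each outer round draws ``n_runs`` variable sub-models by weighted
    bootstrap sampling (p draws with replacement, probabilities
    proportional to the current weights), keeps the best
    ``best_fraction`` by RMSECV, and updates every variable's weight to
    the sum of its normalized absolute PLSR regression coefficients over
    those winners. Informative variables accumulate weight, so the
    bootstrap concentrates and the unique-variable count shrinks
    *softly* — nothing is eliminated outright until its weight decays to
    zero. If a round fails to shrink the surviving set, the lowest-weight
    variable is dropped so the count strictly decreases and the loop
    terminates at one variable.
    """
    cfg = cfg or SelectionConfig()
    X, y = _validate(X_cal, y_cal, cfg)
    n, p = X.shape
    K = cfg.runs_for("BOSS")
    rng = np.random.default_rng(derive_seed(cfg.seed, "boss"))
    folds = selector_folds(n, cfg)
    score = _SubsetScorer(X, y, folds, cfg.max_lvs)
    weights = np.ones(p)
    active = np.arange(p)
    trace = []
    best = None
    outer = 0
    while active.size > 1 and outer < cfg.max_outer:
        outer += 1
        prob = weights[active] / weights[active].sum()
        scored = []
        for _ in range(K):
            draw = rng.choice(active, size=active.size, replace=True, p=prob)
            sub = np.unique(draw)
            rms, lv = score(sub)
            scored.append((rms, sub, lv))
            if _better(rms, sub, best):
                best = (rms, sub.copy(), lv)
        scored.sort(key=lambda t: t[0])
        n_best = max(1, int(round(cfg.best_fraction * K)))
        new_weights = np.zeros(p)
        for rms, sub, lv in scored[:n_best]:
            B, *_ = simpls_paths(X[:, sub], y, lv)
            coef = np.abs(B[:, lv - 1])
            total = coef.sum()
            if total > 0:
                new_weights[sub] += coef / total
        new_active = np.flatnonzero(new_weights > 0)
        if new_active.size == 0:
            break
        if new_active.size >= active.size:
            # shrinkage stalled: drop the lowest-weight variables
            order = np.argsort(new_weights[new_active], kind="stable")
            new_active = np.sort(new_active[order[-(active.size - 1):]])
            mask = np.zeros(p, dtype=bool)
            mask[new_active] = True
            new_weights[~mask] = 0.0
        weights = new_weights
        active = new_active
        trace.append((active.size, scored[0][0]))
    rms, subset, lv = best
    return SelectionResult(selected=subset, rmsecv_best=rms, trace=trace,
                           frequencies_or_weights=weights, algorithm="BOSS",
                           n_lvs_best=lv)


def _intervals_from(indices: np.ndarray):
    """Split a sorted index set into maximal contiguous runs [lo, hi]."""
    runs = []
    start = prev = int(indices[0])
    for v in indices[1:]:
        v = int(v)
        if v == prev + 1:
            prev = v
        else:
            runs.append([start, prev])
            start = prev = v
    runs.append([start, prev])
    return runs


def ivissa_select(X_cal, y_cal, cfg: SelectionConfig | None = None,
                  improve_tol: float = 1e-8) -> SelectionResult:
    """Interval variable iterative space shrinkage approach.

    Global phase: per-variable inclusion probabilities start at 0.5 and are
    replaced each round by the variable's frequency in the best fraction
    of ``n_runs`` random binary sub-models; rounds stop when the
    probabilities saturate to {0, 1} or ``max_outer`` is hit. Local phase:
    the surviving variables seed contiguous intervals that are grown one
    wavelength per side while the pooled RMSECV improves by more than
    ``improve_tol``. The selection is the union of the final intervals.
    """
    cfg = cfg or SelectionConfig()
    X, y = _validate(X_cal, y_cal, cfg)
    n, p = X.shape
    K = cfg.runs_for("iVISSA")
    rng = np.random.default_rng(derive_seed(cfg.seed, "ivissa"))
    folds = selector_folds(n, cfg)
    score = _SubsetScorer(X, y, folds, cfg.max_lvs)
    prob = np.full(p, 0.5)
    best = None
    for _ in range(cfg.max_outer):
        counts = np.zeros(p)
        scored = []
        for _ in range(K):
            mask = rng.random(p) < prob
            if mask.sum() < 2:
                mask[np.argsort(-prob, kind="stable")[:2]] = True
            sub = np.flatnonzero(mask)
            rms, lv = score(sub)
            scored.append((rms, sub, lv))
            if _better(rms, sub, best):
                best = (rms, sub.copy(), lv)
        scored.sort(key=lambda t: t[0])
        n_best = max(1, int(round(cfg.best_fraction * K)))
        for rms, sub, _ in scored[:n_best]:
            counts[sub] += 1
        prob = counts / n_best
        if np.all((prob == 0) | (prob == 1)):
            break
    # local phase: grow contiguous intervals around the saturated/best set
    seeds = np.flatnonzero(prob == 1)
    if seeds.size == 0:
        seeds = best[1]
    intervals = _intervals_from(np.unique(seeds))

    def union(ivals):
        cols = sorted({j for lo, hi in ivals for j in range(lo, hi + 1)})
        return np.asarray(cols, dtype=int)

    cur_rms, cur_lv = score(union(intervals))
    # trace records the monotone interval-growth path; its minimum is the
    # final (returned) union by construction
    trace = [(union(intervals).size, cur_rms)]
    improved = True
    while improved:
        improved = False
        for idx in range(len(intervals)):
            for side, delta in (("lo", -1), ("hi", +1)):
                lo, hi = intervals[idx]
                nlo, nhi = (lo + delta, hi) if side == "lo" else (lo, hi + delta)
                if nlo < 0 or nhi > p - 1:
                    continue
                cand = [iv if i != idx else [nlo, nhi]
                        for i, iv in enumerate(intervals)]
                rms, lv = score(union(cand))
                if rms < cur_rms - improve_tol:
                    intervals = cand
                    cur_rms, cur_lv = rms, lv
                    trace.append((union(intervals).size, cur_rms))
                    improved = True
    selected = union(intervals)
    return SelectionResult(selected=selected, rmsecv_best=cur_rms, trace=trace,
                           frequencies_or_weights=prob, algorithm="iVISSA",
                           n_lvs_best=cur_lv)


SELECTORS = {"cars": cars_select, "boss": boss_select, "ivissa": ivissa_select}
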