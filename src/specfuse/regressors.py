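"""Base learners: PLSR, LS-SVR, ELM and PSO-ELM.

PLSR is implemented as SIMPLS with mean-centering only (scatter-corrected
absorbance shares units across wavelengths, so autoscaling would only
amplify noise bands). The implementation returns the regression-vector
*path* for every latent-variable count in a single pass, which is what
makes RMSECV loops over thousands of candidate wavelength subsets
affordable.

LS-SVR solves the least-squares SVM dual system with an RBF kernel
``K(x, z) = exp(-||x - z||^2 / sigma2)`` (LS-SVM toolbox convention, not
the 1/(2 sigma^2) variant). The extreme learning machine draws a random
sigmoid hidden layer and solves the output weights by least squares;
PSO-ELM searches hidden weights/biases by particle swarm with a
cross-validated fitness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .crossval import MCCVConfig, derive_seed, kfold_indices, mccv_splits

__all__ = [
    "simpls_paths",
    "rmsecv_by_lv",
    "PLSRModel",
    "fit_plsr",
    "predict_plsr",
    "LSSVRModel",
    "fit_lssvr",
    "tune_lssvr",
    "ELMModel",
    "fit_elm",
    "PSOConfig",
    "fit_pso_elm",
]


# ---------------------------------------------------------------------------
# PLSR (SIMPLS)
# ---------------------------------------------------------------------------

def simpls_paths(X: np.ndarray, y: np.ndarray, max_lvs: int):
    """SIMPLS regression-vector paths for 1..max_lvs latent variables.

    Returns ``(B, x_mean, y_mean, n_effective)`` where column ``a-1`` of
    ``B`` is the regression vector using ``a`` latent variables. Extraction
    stops early when the score norm collapses (rank exhausted); remaining
    columns repeat the last valid vector. Zero-variance columns (e.g. the
    all-ones reference column left by the spectra-to-spectra ratio) receive
    exactly zero coefficient: they vanish under centering.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if max_lvs < 1:
        raise ValueError("max_lvs must be >= 1")
    A = min(max_lvs, max(n - 1, 1), p)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    X0 = X - x_mean
    y0 = y - y_mean
    B = np.zeros((p, max_lvs))
    R = np.zeros((p, A))
    V = np.zeros((p, A))
    Q = np.zeros(A)
    s = X0.T @ y0
    nt0 = None
    n_eff = 0
    for a in range(A):
        r = s.copy()
        t = X0 @ r
        nt = float(np.linalg.norm(t))
        if nt0 is None:
            nt0 = nt
        if nt <= 1e-12 * max(nt0, 1e-300):
            break
        t /= nt
        r /= nt
        pload = X0.T @ t
        q = float(y0 @ t)
        v = pload.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pload)
        nv = float(np.linalg.norm(v))
        if nv <= 1e-12:
            break
        v /= nv
        s = s - v * (v @ s)
        R[:, a] = r
        V[:, a] = v
        Q[a] = q
        n_eff = a + 1
        B[:, a] = R[:, : a + 1] @ Q[: a + 1]
    if n_eff == 0:
        return B, x_mean, y_mean, 0
    for a in range(n_eff, max_lvs):
        B[:, a] = B[:, n_eff - 1]
    return B, x_mean, y_mean, n_eff


def rmsecv_by_lv(X, y, splits, max_lvs: int) -> np.ndarray:
    """Pooled cross-validated RMSE for each latent-variable count.

    ``splits`` is an iterable of ``(train_idx, val_idx)`` pairs; errors are
    pooled over all held-out predictions before taking the root mean
    square.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    sse = np.zeros(max_lvs)
    n_val = 0
    for train, val in splits:
        B, xm, ym, _ = simpls_paths(X[train], y[train], max_lvs)
        pred = (X[val] - xm) @ B + ym
        err = pred - y[val, None]
        sse += (err**2).sum(axis=0)
        n_val += val.size
    if n_val == 0:
        raise ValueError("no validation samples produced by the splits")
    return np.sqrt(sse / n_val)


@dataclass
class PLSRModel:
    """Fitted PLSR model (centering + regression vector at chosen LVs)."""

    n_lvs: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray
    rmsecv_by_lv: np.ndarray | None = None
    max_lvs: int = 15

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.coef.size:
            raise ValueError(
                f"model expects {self.coef.size} wavelengths, got {X_new.shape[1]}"
            )
        return (X_new - self.x_mean) @ self.coef + self.y_mean

    def to_dict(self) -> dict:
        return {
            "n_lvs": int(self.n_lvs),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "coef": self.coef.tolist(),
            "rmsecv_by_lv": None if self.rmsecv_by_lv is None else self.rmsecv_by_lv.tolist(),
            "max_lvs": int(self.max_lvs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSRModel":
        return cls(
            n_lvs=d["n_lvs"],
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            coef=np.asarray(d["coef"], dtype=float),
            rmsecv_by_lv=None if d.get("rmsecv_by_lv") is None else np.asarray(d["rmsecv_by_lv"]),
            max_lvs=d.get("max_lvs", 15),
        )


def fit_plsr(X, y, max_lvs: int = 15, mccv: MCCVConfig | None = None,
             sample_ids=None, n_lvs: int | None = None) -> PLSRModel:
    """Fit PLSR; latent-variable count by minimum Monte-Carlo-CV RMSECV.

    ``sample_ids`` (if given) anchors the MCCV split assignment to sample
    identity rather than row position, so permuting rows leaves the fit
    unchanged. Passing ``n_lvs`` skips the search.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to fit PLSR")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; nothing to regress")
    if max_lvs < 1:
        raise ValueError("max_lvs must be >= 1")
    rmse_path = None
    if n_lvs is None:
        mccv = mccv or MCCVConfig()
        splits = mccv_splits(X.shape[0], mccv, order=sample_ids)
        rmse_path = rmsecv_by_lv(X, y, splits, max_lvs)
        n_lvs = int(np.argmin(rmse_path)) + 1
    B, xm, ym, n_eff = simpls_paths(X, y, max_lvs=max(n_lvs, 1))
    n_lvs = min(n_lvs, max(n_eff, 1))
    return PLSRModel(n_lvs=n_lvs, x_mean=xm, y_mean=ym,
                     coef=B[:, n_lvs - 1], rmsecv_by_lv=rmse_path,
                     max_lvs=max_lvs)


def predict_plsr(model: PLSRModel, X_new) -> np.ndarray:
    return model.predict(X_new)


# ---------------------------------------------------------------------------
# LS-SVR
# ---------------------------------------------------------------------------

def _rbf_kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    d2 = cdist(np.atleast_2d(A), np.atleast_2d(B), metric="sqeuclidean")
    return np.exp(-d2 / sigma2)


@dataclass
class LSSVRModel:
    """Least-squares SVR dual solution with RBF kernel."""

    gamma: float
    sigma2: float
    alphas: np.ndarray
    bias: float
    support: np.ndarray

    def predict(self, X_new) -> np.ndarray:
        K = _rbf_kernel(X_new, self.support, self.sigma2)
        return K @ self.alphas + self.bias


def fit_lssvr(X, y, gamma: float, sigma2: float) -> LSSVRModel:
    """Solve the LS-SVM dual linear system.

    The system is ``[[0, 1^T], [1, K + I/gamma]] [b; alpha] = [0; y]``;
    the solution must satisfy it to 1e-6 relative residual or the fit is
    rejected as ill-conditioned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if gamma <= 0 or sigma2 <= 0:
        raise ValueError("gamma and sigma2 must be positive")
    n = X.shape[0]
    K = _rbf_kernel(X, X, sigma2)
    M = np.zeros((n + 1, n + 1))
    M[0, 1:] = 1.0
    M[1:, 0] = 1.0
    M[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"LS-SVR dual system is singular (cond ~ {np.linalg.cond(M):.2e}): {exc}"
        ) from None
    resid = float(np.linalg.norm(M @ sol - rhs))
    if resid > 1e-6 * max(float(np.linalg.norm(y)), 1e-12):
        raise np.linalg.LinAlgError(
            f"LS-SVR dual solve failed: relative residual {resid:.2e}, "
            f"condition number {np.linalg.cond(M):.2e}"
        )
    return LSSVRModel(gamma=gamma, sigma2=sigma2, alphas=sol[1:],
                      bias=float(sol[0]), support=X.copy())


#: log10 search box for (gamma, sigma2); covers the magnitudes fitted on
#: real fruit spectra (gamma up to ~1e6, sigma2 up to ~1e6).
LSSVR_LOG_BOUNDS = ((-2.0, 8.0), (-2.0, 7.0))


def tune_lssvr(X, y, cv_folds: int = 10, seed: int = 0,
               n_chains: int = 4, n_steps: int = 30) -> tuple[float, float]:
    """Two-stage (gamma, sigma2) search: annealing then local grid.

    Stage 1 runs seeded multi-start simulated annealing in log10 space over
    ``LSSVR_LOG_BOUNDS``, scoring each candidate by k-fold CV RMSE. Stage 2
    refines the stage-1 optimum on a local log-grid. The returned pair
    attains the minimum CV RMSE over every point evaluated.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < cv_folds:
        raise ValueError(f"need at least cv_folds={cv_folds} samples, got {n}")
    if np.allclose(X, X[0]):
        raise ValueError("all rows of X are identical; LS-SVR tuning is degenerate")
    folds = list(kfold_indices(n, cv_folds, seed=derive_seed(seed, "lssvr-folds")))
    cache: dict = {}

    def score(lg_gamma: float, lg_sigma2: float) -> float:
        key = (round(lg_gamma, 6), round(lg_sigma2, 6))
        if key in cache:
            return cache[key]
        g, s2 = 10.0**lg_gamma, 10.0**lg_sigma2
        sse, cnt = 0.0, 0
        for train, val in folds:
            try:
                m = fit_lssvr(X[train], y[train], g, s2)
            except np.linalg.LinAlgError:
                cache[key] = np.inf
                return np.inf
            e = m.predict(X[val]) - y[val]
            sse += float(e @ e)
            cnt += val.size
        out = np.sqrt(sse / cnt)
        cache[key] = out
        return out

    rng = np.random.default_rng(derive_seed(seed, "lssvr-anneal"))
    (glo, ghi), (slo, shi) = LSSVR_LOG_BOUNDS
    best = None
    for _ in range(n_chains):
        pos = np.array([rng.uniform(glo, ghi), rng.uniform(slo, shi)])
        cur = score(*pos)
        if best is None or cur < best[0]:
            best = (cur, pos.copy())
        temp = 1.0
        for step in range(n_steps):
            scale = np.array([(ghi - glo), (shi - slo)]) * 0.15 * temp
            cand = pos + rng.normal(size=2) * scale
            cand[0] = np.clip(cand[0], glo, ghi)
            cand[1] = np.clip(cand[1], slo, shi)
            val = score(*cand)
            if val < cur or rng.random() < np.exp(-(val - cur) / max(temp, 1e-12)):
                pos, cur = cand, val
            if cur < best[0]:
                best = (cur, pos.copy())
            temp *= 0.9
    # stage 2: local log-grid refinement
    center = best[1]
    offsets = np.array([-0.5, -0.25, 0.0, 0.25, 0.5])
    for dg in offsets:
        for ds in offsets:
            cand = np.array([np.clip(center[0] + dg, glo, ghi),
                             np.clip(center[1] + ds, slo, shi)])
            val = score(*cand)
            if val < best[0]:
                best = (val, cand)
    lg_g, lg_s2 = best[1]
    return 10.0**lg_g, 10.0**lg_s2


# ---------------------------------------------------------------------------
# ELM / PSO-ELM
# ---------------------------------------------------------------------------

def _scale_to_unit(X, x_min, x_max):
    span = x_max - x_min
    span = np.where(span > 0, span, 1.0)
    return 2.0 * (X - x_min) / span - 1.0


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class ELMModel:
    """Extreme learning machine: random sigmoid hidden layer + LS output."""

    hidden_nodes: int
    input_weights: np.ndarray  # (n_features, hidden_nodes)
    hidden_biases: np.ndarray  # (hidden_nodes,)
    output_weights: np.ndarray  # (hidden_nodes,)
    x_min: np.ndarray
    x_max: np.ndarray
    pso_history: np.ndarray | None = None

    def hidden(self, X) -> np.ndarray:
        Xs = _scale_to_unit(np.atleast_2d(np.asarray(X, dtype=float)),
                            self.x_min, self.x_max)
        return _sigmoid(Xs @ self.input_weights + self.hidden_biases)

    def predict(self, X_new) -> np.ndarray:
        return self.hidden(X_new) @ self.output_weights


def _solve_output(H, y):
    beta, *_ = np.linalg.lstsq(H, y, rcond=None)
    return beta


def fit_elm(X, y, hidden_nodes: int = 30, seed: int = 0) -> ELMModel:
    """Random hidden layer from seeded uniform(-1, 1); LS output weights.

    Inputs are min-max scaled to [-1, 1] (train statistics) before the
    hidden layer so the sigmoid operates in its responsive range.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if hidden_nodes < 1:
        raise ValueError("hidden_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    d = X.shape[1]
    W = rng.uniform(-1, 1, size=(d, hidden_nodes))
    b = rng.uniform(-1, 1, size=hidden_nodes)
    x_min, x_max = X.min(axis=0), X.max(axis=0)
    model = ELMModel(hidden_nodes, W, b, np.zeros(hidden_nodes), x_min, x_max)
    model.output_weights = _solve_output(model.hidden(X), y)
    return model


@dataclass(frozen=True)
class PSOConfig:
    """Particle-swarm constants: swarm 30, 100 iterations, inertia
    linearly 0.9 -> 0.4, c1 = c2 = 2.0, positions clamped to [-1, 1]."""

    swarm_size: int = 30
    n_iterations: int = 100
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    bounds: tuple = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.swarm_size < 2 or self.n_iterations < 1:
            raise ValueError("swarm_size >= 2 and n_iterations >= 1 required")
        if not np.isfinite(self.bounds).all():
            raise ValueError("bounds must be finite")


def fit_pso_elm(X, y, hidden_nodes: int = 30, pso: PSOConfig | None = None,
                cv_folds: int = 5) -> ELMModel:
    """ELM with hidden weights/biases optimized by particle swarm.

    Particles encode the flattened (input_weights, hidden_biases); fitness
    is seeded k-fold CV RMSE with output weights re-solved per fold. One
    particle is initialized at the seed-matched plain ELM so the swarm can
    only improve on it. The returned model is rebuilt from the global best
    with output weights refit on all rows; ``pso_history`` records the
    non-increasing global-best fitness.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    pso = pso or PSOConfig()
    n, d = X.shape
    x_min, x_max = X.min(axis=0), X.max(axis=0)
    Xs = _scale_to_unit(X, x_min, x_max)
    folds = list(kfold_indices(n, min(cv_folds, n), seed=derive_seed(pso.seed, "pso-folds")))
    dim = d * hidden_nodes + hidden_nodes
    lo, hi = pso.bounds

    def unpack(theta):
        W = theta[: d * hidden_nodes].reshape(d, hidden_nodes)
        b = theta[d * hidden_nodes:]
        return W, b

    def fitness(theta) -> float:
        W, b = unpack(theta)
        H = _sigmoid(Xs @ W + b)
        sse, cnt = 0.0, 0
        for train, val in folds:
            beta = _solve_output(H[train], y[train])
            e = H[val] @ beta - y[val]
            sse += float(e @ e)
            cnt += val.size
        return np.sqrt(sse / cnt)

    rng = np.random.default_rng(pso.seed)
    # particle 0 reproduces the plain seed-matched ELM draw
    elm_rng = np.random.default_rng(pso.seed)
    theta0 = np.concatenate([
        elm_rng.uniform(-1, 1, size=(d, hidden_nodes)).ravel(),
        elm_rng.uniform(-1, 1, size=hidden_nodes),
    ])
    positions = rng.uniform(lo, hi, size=(pso.swarm_size, dim))
    positions[0] = np.clip(theta0, lo, hi)
    velocities = np.zeros_like(positions)
    pbest = positions.copy()
    pbest_fit = np.array([fitness(p) for p in positions])
    g = int(np.argmin(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    history = [gbest_fit]
    for it in range(pso.n_iterations):
        w = pso.inertia_start + (pso.inertia_end - pso.inertia_start) * (
            it / max(pso.n_iterations - 1, 1))
        r1 = rng.random(size=(pso.swarm_size, dim))
        r2 = rng.random(size=(pso.swarm_size, dim))
        velocities = (w * velocities
                      + pso.c1 * r1 * (pbest - positions)
                      + pso.c2 * r2 * (gbest - positions))
        positions = np.clip(positions + velocities, lo, hi)
        for i in range(pso.swarm_size):
            f = fitness(positions[i])
            if f < pbest_fit[i]:
                pbest_fit[i] = f
                pbest[i] = positions[i].copy()
                if f < gbest_fit:
                    gbest_fit = f
                    gbest = positions[i].copy()
        history.append(gbest_fit)
    W, b = unpack(gbest)
    model = ELMModel(hidden_nodes, W, b, np.zeros(hidden_nodes), x_min, x_max,
                     pso_history=np.asarray(history))
    model.output_weights = _solve_output(model.hidden(X), y)
    return model
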