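"""Synthetic mixture spectra with known scatter effects.

Real fruit spectra obey, to good approximation, the mixture law

    X_i = p_i * sum_j c_ij * s_j + b_i * 1 + noise

with per-sample multiplicative factor ``p_i`` (optical-path change),
additive baseline ``b_i``, smooth nonnegative component spectra ``s_j``
and concentrations ``c_ij``. This module generates such data with the
ground truth retained, so every pipeline stage (additive elimination,
multiplicative ratio, wavelength selection, regression, fusion) can be
tested for parameter recovery without access to real spectra.

One component (the *constant component*) has the same concentration in
every sample and a spectral peak placed in a reserved window where it
contributes >90% of the absorbance — exactly the situation in which
dividing by the spectrum's value at such a wavelength cancels ``p_i``.

A second family of generators plants known informative variables (single
wavelengths or contiguous blocks) in otherwise uninformative spectra, for
testing the wavelength selectors against a known support.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import SpectralDataset

__all__ = [
    "MixtureModelParams",
    "PlantedParams",
    "make_component_spectra",
    "simulate_dataset",
    "simulate_planted",
    "simulate",
    "scenario",
    "SCENARIOS",
]


def _default_grid() -> np.ndarray:
    return np.arange(600.0, 901.0)  # 600-900 nm, 1 nm step


@dataclass(frozen=True)
class MixtureModelParams:
    """Generative parameters of the mixture model.

    Defaults are the benchmark conditions used throughout the test suite:
    105 samples, 3 components on a 600-900 nm grid, multiplicative factors
    U(0.7, 1.3), baselines N(0, 0.05^2), measurement noise SD 1e-3, and
    reference values (the target component's concentration) mapped onto a
    9-17 span to echo the range of fruit soluble-solids contents.
    """

    n_samples: int = 105
    wavelengths: np.ndarray = field(default_factory=_default_grid)
    n_components: int = 3
    p_range: tuple = (0.7, 1.3)
    b_sd: float = 0.05
    noise_sd: float = 1e-3
    constant_component: int = 0
    target_component: int = 1
    concentration_range: tuple = (0.5, 1.5)
    constant_concentration: float = 1.0
    y_range: tuple = (9.0, 17.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_components < 2:
            raise ValueError("need at least 2 components")
        if not (0 <= self.constant_component < self.n_components):
            raise ValueError("constant_component out of range")
        if not (0 <= self.target_component < self.n_components):
            raise ValueError("target_component out of range")
        if self.target_component == self.constant_component:
            raise ValueError("target component cannot be the constant component")
        if self.p_range[0] > self.p_range[1] or self.p_range[0] <= 0:
            raise ValueError("invalid multiplicative-factor range")
        if self.b_sd < 0 or self.noise_sd < 0:
            raise ValueError("spread parameters must be nonnegative")


def _cosine(a, b) -> float:
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def make_component_spectra(n_components: int, wavelengths, seed: int = 0,
                           reserved_component: int = 0,
                           max_attempts: int = 100) -> list:
    """Smooth nonnegative component spectra: sums of 1-3 Gaussians.

    ``reserved_component`` gets a single peak in the low-wavelength fifth
    of the window while all other peaks sit above the 30% point, which
    guarantees a dominance region for it. Components are resampled until
    every pair has cosine similarity below 0.95; failure after
    ``max_attempts`` raises.
    """
    if n_components < 2:
        raise ValueError("need at least 2 components")
    wl = np.asarray(wavelengths, dtype=float)
    lo, hi = wl[0], wl[-1]
    width = hi - lo
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        spectra = []
        for j in range(n_components):
            s = np.zeros_like(wl)
            if j == reserved_component:
                centers = [rng.uniform(lo + 0.05 * width, lo + 0.15 * width)]
            else:
                n_peaks = rng.integers(1, 4)
                centers = rng.uniform(lo + 0.30 * width, hi, size=n_peaks)
            for c in centers:
                sigma = rng.uniform(0.03, 0.08) * width
                amp = rng.uniform(0.5, 1.0)
                s += amp * np.exp(-0.5 * ((wl - c) / sigma) ** 2)
            spectra.append(s)
        ok = all(_cosine(spectra[i], spectra[j]) < 0.95
                 for i in range(n_components) for j in range(i + 1, n_components))
        if ok:
            return spectra
    raise RuntimeError(
        f"could not draw {n_components} sufficiently dissimilar component "
        f"spectra in {max_attempts} attempts")


def simulate_dataset(params: MixtureModelParams):
    """Generate spectra from the mixture law; returns (dataset, truth).

    ``truth`` carries the exact generative quantities: component spectra,
    concentration matrix, multiplicative factors, baselines, the noise-free
    mixture, and the indices of the constant component's dominance region
    (wavelengths where it contributes >90% of the noise-free absorbance).
    """
    rng = np.random.default_rng(params.seed)
    wl = np.asarray(params.wavelengths, dtype=float)
    J = params.n_components
    spectra = make_component_spectra(J, wl, seed=params.seed,
                                     reserved_component=params.constant_component)
    S = np.vstack(spectra)  # J x n_wavelengths
    n = params.n_samples
    C = rng.uniform(*params.concentration_range, size=(n, J))
    C[:, params.constant_component] = params.constant_concentration
    p = rng.uniform(*params.p_range, size=n)
    b = rng.normal(0.0, params.b_sd, size=n) if params.b_sd > 0 else np.zeros(n)
    mixture = C @ S
    X = p[:, None] * mixture + b[:, None]
    if params.noise_sd > 0:
        X = X + rng.normal(0.0, params.noise_sd, size=X.shape)
    c_lo, c_hi = params.concentration_range
    y = (params.y_range[0]
         + (C[:, params.target_component] - c_lo) / (c_hi - c_lo)
         * (params.y_range[1] - params.y_range[0]))
    contrib = params.constant_concentration * S[params.constant_component]
    frac = contrib[None, :] / np.clip(mixture, 1e-12, None)
    dominance = np.flatnonzero(frac.min(axis=0) > 0.9)
    ds = SpectralDataset(wl, X, [f"sim{i}" for i in range(n)], y)
    truth = {
        "component_spectra": S,
        "concentrations": C,
        "p": p,
        "b": b,
        "noise_sd": params.noise_sd,
        "noise_free": p[:, None] * mixture + b[:, None],
        "dominance_region": dominance,
        "params": params,
    }
    return ds, truth


@dataclass(frozen=True)
class PlantedParams:
    """Planted-support regression data for selector recovery tests.

    ``block_width = 1`` plants isolated informative wavelengths (default
    five of them among 200 variables, n = 80, noise SD 0.1);
    ``block_width > 1`` plants contiguous informative intervals whose
    within-block variables share a latent signal.
    """

    n_samples: int = 80
    n_variables: int = 200
    planted_starts: tuple = (20, 60, 100, 140, 180)
    block_width: int = 1
    coefs: tuple = ()
    noise_sd: float = 0.1
    within_block_noise: float = 0.3
    seed: int = 0

    @property
    def planted_indices(self) -> np.ndarray:
        idx = [s + k for s in self.planted_starts for k in range(self.block_width)]
        return np.asarray(sorted(idx), dtype=int)


def simulate_planted(params: PlantedParams):
    """Generate planted-support data; returns (dataset, truth).

    Background variables are i.i.d. standard normal. For isolated planted
    wavelengths, y is a linear function of those columns plus noise. For
    blocks, each block shares one latent factor observed in every block
    column with ``within_block_noise``, and y sums the latents.
    """
    rng = np.random.default_rng(params.seed)
    n, pvar = params.n_samples, params.n_variables
    X = rng.standard_normal((n, pvar))
    planted = params.planted_indices
    if planted.max() >= pvar:
        raise ValueError("planted indices exceed variable count")
    if params.block_width == 1:
        coefs = (np.asarray(params.coefs, float) if params.coefs
                 else np.ones(planted.size))
        y = X[:, planted] @ coefs
    else:
        y = np.zeros(n)
        for start in params.planted_starts:
            u = rng.standard_normal(n)
            for k in range(params.block_width):
                X[:, start + k] = u + params.within_block_noise * rng.standard_normal(n)
            y = y + u
    y = y + params.noise_sd * rng.standard_normal(n)
    wl = np.arange(600.0, 600.0 + pvar)
    ds = SpectralDataset(wl, X, [f"pl{i}" for i in range(n)], y)
    return ds, {"planted": planted, "params": params}


SCENARIOS = ("clean", "additive_only", "multiplicative_only", "both",
             "planted_wavelengths")


def scenario(name: str, seed: int = 0, **overrides):
    """Frozen, seeded parameter presets used by the test suite.

    ``clean``: no scatter effects, no noise. ``additive_only``: baselines
    only (noise 1e-4, small enough for intercept-recovery checks).
    ``multiplicative_only``: path factors only. ``both``: the full
    benchmark conditions. ``planted_wavelengths``: the selector-recovery
    dataset with five isolated informative variables.
    """
    if name == "clean":
        params = MixtureModelParams(p_range=(1.0, 1.0), b_sd=0.0, noise_sd=0.0,
                                    seed=seed)
    elif name == "additive_only":
        params = MixtureModelParams(p_range=(1.0, 1.0), b_sd=0.05,
                                    noise_sd=1e-4, seed=seed)
    elif name == "multiplicative_only":
        params = MixtureModelParams(p_range=(0.7, 1.3), b_sd=0.0,
                                    noise_sd=1e-3, seed=seed)
    elif name == "both":
        params = MixtureModelParams(seed=seed)
    elif name == "planted_wavelengths":
        params = PlantedParams(seed=seed)
    else:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    return replace(params, **overrides) if overrides else params


def simulate(params):
    """Dispatch on parameter type: mixture spectra or planted support."""
    if isinstance(params, MixtureModelParams):
        return simulate_dataset(params)
    if isinstance(params, PlantedParams):
        return simulate_planted(params)
    raise TypeError(f"unsupported parameter object {type(params).__name__}")
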