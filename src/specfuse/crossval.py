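"""Cross-validation configuration and seeded split helpers.

Two resampling schemes recur throughout the stack:

* Monte-Carlo cross-validation (MCCV): repeated random calibration/
  validation splits, used to pick PLSR latent-variable counts and to score
  candidate reference wavelengths in the spectra-to-spectra search.
* seeded k-fold, used inside the wavelength selectors and for the
  inverse-variance (Bates-Granger) member variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MCCVConfig", "mccv_splits", "kfold_indices", "derive_seed"]


def derive_seed(base: int, label: str) -> int:
    """Stable stage-scoped seed below 2**31 derived from a global seed."""
    import hashlib

    h = hashlib.blake2s(f"{base}:{label}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2**31)


@dataclass(frozen=True)
class MCCVConfig:
    """Monte-Carlo cross-validation: repeated random hold-out splits.

    ``validation_fraction`` of the samples is held out in each of
    ``n_repeats`` seeded draws (default 30% held out, 50 repeats).
    """

    validation_fraction: float = 0.3
    n_repeats: int = 50
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def mccv_splits(n: int, cfg: MCCVConfig, order=None):
    """Yield (train_idx, val_idx) pairs for ``n`` samples.

    ``order`` optionally maps positions to a canonical ordering (e.g. the
    rank of sample ids) so that splits are invariant to row permutation.
    """
    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    if n_val >= n:
        raise ValueError(f"validation fraction leaves no training rows (n={n})")
    canon = np.arange(n) if order is None else np.argsort(np.asarray(order))
    for _ in range(cfg.n_repeats):
        perm = rng.permutation(n)
        val = canon[perm[:n_val]]
        train = canon[perm[n_val:]]
        yield train, val


def kfold_indices(n: int, k: int, seed: int):
    """Seeded shuffled k-fold partition; yields (train_idx, val_idx)."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    for i in range(k):
        val = folds[i]
        train = np.concatenate([folds[j] for j in range(k) if j != i])
        yield train, val
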