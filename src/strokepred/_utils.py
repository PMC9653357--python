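"""Shared helpers: seed derivation, standardization, small validators."""

from __future__ import annotations

import numpy as np

# Child seeds are derived from the master seed by fixed documented offsets so
# that every sub-generator is a pure function of (parameters, master seed).
SEED_OFFSETS = {
    "basis": 11,
    "mixing_weights": 23,
    "disconnection_noise": 37,
    "outcome_weights": 53,
    "latent_noise": 71,
    "battery_noise": 89,
    "voxel": 101,
    "split": 131,
    "shuffle": 151,
}

_SEED_MOD = 2**31 - 1


def child_seed(master_seed: int, stream: str) -> int:
    """Derive a deterministic child seed for a named sub-generator."""
    if stream not in SEED_OFFSETS:
        raise KeyError(f"unknown seed stream {stream!r}")
    return (int(master_seed) + SEED_OFFSETS[stream]) % _SEED_MOD


class Standardizer:
    """Column z-scoring with stored training statistics.

    Constant columns get unit scale so transforming never divides by zero;
    their z-scores are identically zero.
    """

    def __init__(self, mean: np.ndarray, scale: np.ndarray):
        self.mean = np.asarray(mean, dtype=float)
        self.scale = np.asarray(scale, dtype=float)

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean, scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(np.asarray(d["mean"]), np.asarray(d["scale"]))


def as_2d_float(X, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {X.shape}")
    if X.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite entries")
    return X
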