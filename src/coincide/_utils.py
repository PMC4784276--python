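"""Shared numerical helpers: seeded RNG streams and correlation kernels."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed", "standardize_columns", "pearson_columns"]


def _key_entropy(key) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    return int(key) & 0xFFFFFFFF


def derive_seed(seed, *keys) -> int:
    """Deterministic child seed (< 2**31) from a root seed and string/int keys."""
    ss = np.random.SeedSequence([_key_entropy(seed), *(_key_entropy(k) for k in keys)])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def derive_rng(seed, *keys) -> np.random.Generator:
    """Independent Generator stream keyed by (seed, *keys).

    Dataset IDs and stage names act as keys so that every dataset/stage gets a
    reproducible stream regardless of iteration order.
    """
    if seed is None:
        return np.random.default_rng()
    ss = np.random.SeedSequence([_key_entropy(seed), *(_key_entropy(k) for k in keys)])
    return np.random.default_rng(ss)


def standardize_columns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale columns so that Z_a.T @ Z_b is the Pearson matrix.

    Returns (Z, constant_mask); constant columns are zeroed and flagged so the
    caller can treat their correlations as undefined (-inf in assignments).
    """
    mat = np.asarray(mat, dtype=float)
    mu = mat.mean(axis=0, keepdims=True)
    centered = mat - mu
    norm = np.sqrt((centered**2).sum(axis=0, keepdims=True))
    constant = norm[0] <= 1e-12 * max(1.0, float(np.abs(mat).max(initial=0.0)))
    safe = np.where(norm > 0, norm, 1.0)
    z = centered / safe
    z[:, constant] = 0.0
    return z, constant


def pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every column of `a` and every column of `b`.

    Both matrices share the observation axis (rows, e.g. genes). Constant
    columns yield -inf correlations (never nearest under argmax).
    """
    za, ca = standardize_columns(a)
    zb, cb = standardize_columns(b)
    corr = za.T @ zb
    if ca.any():
        corr[ca, :] = -np.inf
    if cb.any():
        corr[:, cb] = -np.inf
    return corr
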