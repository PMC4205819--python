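"""Small shared helpers: edge vectorization, RNG plumbing, validation."""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_rng",
    "check_finite_2d",
    "triu_pairs",
    "upper_vec",
    "vec_to_sym",
]


def as_rng(seed) -> np.random.Generator:
    """Return a Generator; passes existing Generators through unchanged."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def check_finite_2d(arr, name: str, n_cols: int | None = None) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got shape {a.shape}")
    if n_cols is not None and a.shape[1] != n_cols:
        raise ValueError(f"{name} must have {n_cols} columns, got {a.shape[1]}")
    if not np.all(np.isfinite(a)):
        bad = np.argwhere(~np.isfinite(a))[0]
        raise ValueError(f"{name} contains a non-finite value at row {bad[0]}, column {bad[1]}")
    return a


def triu_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle (the edge order used everywhere)."""
    return np.triu_indices(n, k=1)


def upper_vec(mat: np.ndarray) -> np.ndarray:
    """Strict-upper-triangle entries of a square matrix as a 1-D edge vector."""
    mat = np.asarray(mat)
    i, j = triu_pairs(mat.shape[-1])
    return mat[..., i, j]


def vec_to_sym(vec: np.ndarray, n: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`upper_vec`: symmetric matrix with constant diagonal."""
    vec = np.asarray(vec, dtype=float)
    out = np.full((n, n), diag, dtype=float)
    i, j = triu_pairs(n)
    if vec.shape[-1] != i.size:
        raise ValueError(f"edge vector length {vec.shape[-1]} does not match n={n}")
    out[i, j] = vec
    out[j, i] = vec
    return out
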