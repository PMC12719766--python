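"""Shared numeric helpers: RNG fan-out, RDM vectorization, PSD repair."""

from __future__ import annotations

import numpy as np


def child_rng(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic per-stage generator derived from a top-level seed.

    Every random operation in the package draws from a stream identified by a
    small tuple of integer keys, so a single seed fans out reproducibly to all
    stages irrespective of execution order.
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, keys))))


def lower_tri(mat: np.ndarray) -> np.ndarray:
    """Vectorize a square matrix: lower triangle excluding the diagonal, row-major.

    This is the package-wide RDM vectorization convention; correlations between
    RDMs are computed on these vectors.
    """
    mat = np.asarray(mat)
    i, j = np.tril_indices(mat.shape[0], k=-1)
    return mat[i, j]


def squareform_from_lower(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`lower_tri` producing a symmetric zero-diagonal matrix."""
    out = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    out[i, j] = vec
    out[j, i] = vec
    return out


def nearest_psd_correlation(s: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix with unit diagonal.

    Eigenvalue clipping followed by diagonal renormalization; adequate for
    repairing similarity matrices (1 - RDM) that are mildly indefinite.
    """
    s = 0.5 * (s + s.T)
    w, v = np.linalg.eigh(s)
    w = np.clip(w, eps, None)
    s = (v * w) @ v.T
    d = np.sqrt(np.diag(s))
    s = s / np.outer(d, d)
    np.fill_diagonal(s, 1.0)
    return 0.5 * (s + s.T)


def patterns_from_similarity(
    s: np.ndarray, dims: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Draw row patterns whose pairwise Pearson correlations equal ``s`` exactly.

    Rows of the returned (n_items, dims) matrix are zero-mean and unit-norm, so
    their sample Pearson correlation matrix reproduces ``s`` up to PSD repair.
    Returns ``(patterns, repaired)`` where ``repaired`` flags that the input
    similarity was not PSD and was projected first.

    Requires ``dims >= n_items + 1`` (one dimension is lost to mean removal).
    """
    s = np.asarray(s, dtype=float)
    n = s.shape[0]
    if dims < n + 1:
        raise ValueError(f"need dims >= n_items + 1, got dims={dims}, n_items={n}")
    repaired = False
    w = np.linalg.eigvalsh(0.5 * (s + s.T))
    if w.min() < -1e-10:
        s = nearest_psd_correlation(s)
        repaired = True
    else:
        s = nearest_psd_correlation(s)  # also normalizes diagonal / symmetry
    # Orthonormal zero-mean basis rows.
    basis = rng.standard_normal((n, dims))
    basis -= basis.mean(axis=1, keepdims=True)
    # Gram-Schmidt with re-centering (centering is idempotent w.r.t. the span
    # because the centered rows stay centered under linear combinations).
    q, _ = np.linalg.qr(basis.T)
    q = q[:, :n].T
    q -= q.mean(axis=1, keepdims=True)
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    # Re-orthonormalize after the centering touch-up.
    qq, _ = np.linalg.qr(q.T)
    q = qq[:, :n].T
    q -= q.mean(axis=1, keepdims=True)
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    l = np.linalg.cholesky(s + 1e-12 * np.eye(n))
    return l @ q, repaired
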