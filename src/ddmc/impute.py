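"""Low-rank matrix completion for initialization and baseline imputation.

Two variants of the same iterative-SVD scheme:

* ``soft_impute`` — soft-thresholds the singular values each sweep
  (nuclear-norm-regularized completion), used to complete the abundance
  matrix before k-means initialization of the mixture model.
* ``pca_complete`` — hard truncation to a fixed rank, the "matrix completion
  by PCA" baseline.
"""

from __future__ import annotations

import numpy as np


def _initial_fill(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fill unobserved cells with the row mean (column mean / 0 as fallbacks)."""
    filled = X.copy()
    row_mean = np.divide(
        (X * mask).sum(axis=1),
        mask.sum(axis=1),
        out=np.zeros(X.shape[0]),
        where=mask.sum(axis=1) > 0,
    )
    obs_total = mask.sum()
    grand = (X * mask).sum() / obs_total if obs_total else 0.0
    row_mean = np.where(mask.sum(axis=1) > 0, row_mean, grand)
    filled[~mask] = np.broadcast_to(row_mean[:, None], X.shape)[~mask]
    return filled


def _iterative_svd(X, mask, rank, shrink_frac, max_iter, tol):
    mask = np.asarray(mask, dtype=bool)
    X = np.asarray(X, dtype=float)
    if mask.all():
        return X.copy()
    Z = _initial_fill(X, mask)
    prev = None
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        if shrink_frac > 0:
            s = np.maximum(s - shrink_frac * s[0], 0.0)
        if rank is not None:
            s[rank:] = 0.0
        low = (U * s) @ Vt
        Z = np.where(mask, X, low)
        delta = np.abs(Z[~mask] - prev).max() if prev is not None else np.inf
        prev = Z[~mask].copy()
        if delta < tol:
            break
    return Z


def soft_impute(
    X: np.ndarray,
    mask: np.ndarray,
    rank: int = 5,
    shrink_frac: float = 0.05,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> np.ndarray:
    """Complete X by iterative soft-thresholded SVD; observed cells untouched.

    ``shrink_frac`` scales the soft threshold relative to the current leading
    singular value; ``rank`` caps the number of components retained.
    """
    return _iterative_svd(X, mask, rank, shrink_frac, max_iter, tol)


def pca_complete(
    X: np.ndarray,
    mask: np.ndarray,
    rank: int = 5,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> np.ndarray:
    """Complete X by iterative rank-``rank`` truncated SVD (PCA completion)."""
    return _iterative_svd(X, mask, rank, 0.0, max_iter, tol)
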