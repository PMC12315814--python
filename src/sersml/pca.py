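"""Principal component analysis for exploratory scores/loadings and optional
dimensionality reduction ahead of the SVM.

Centering only (no unit-variance scaling), the standard convention for
intensity matrices.  The sign of each loading vector is fixed so that its
largest-magnitude element is positive, making results reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DomainError, InputError


@dataclass
class PCAModel:
    mean: np.ndarray                      # (n_points,)
    loadings: np.ndarray                  # (n_points, k), orthonormal columns
    explained_variance_ratio: np.ndarray  # (k,), non-increasing
    k: int

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        """Project rows onto the principal axes: (X - mean) @ loadings."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[-1] != self.mean.size:
            raise InputError(
                f"matrix has {matrix.shape[-1]} columns, model expects {self.mean.size}"
            )
        return (matrix - self.mean) @ self.loadings

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, float) @ self.loadings.T + self.mean


def fit_pca(matrix: np.ndarray, k: int = 2) -> PCAModel:
    """Fit a rank-``k`` PCA by SVD of the column-centred matrix.

    The returned model minimises reconstruction error over all rank-k linear
    models; ``explained_variance_ratio`` is each component's share of the
    total column variance.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise InputError("matrix must be 2-D")
    if not np.all(np.isfinite(x)):
        raise InputError("matrix must be finite")
    n, p = x.shape
    if not (1 <= k <= min(n - 1, p)):
        raise ConfigurationError(
            f"k={k} must satisfy 1 <= k <= min(n_samples - 1, n_points) = {min(n - 1, p)}"
        )
    mean = x.mean(axis=0)
    xc = x - mean
    total_var = xc.var(axis=0, ddof=1).sum()
    if total_var <= 0:
        raise DomainError("matrix has zero variance; PCA undefined")
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    loadings = vt[:k].T.copy()
    # deterministic sign: largest-|loading| element of each component positive
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    explained = (s[:k] ** 2) / (n - 1) / total_var
    return PCAModel(mean=mean, loadings=loadings,
                    explained_variance_ratio=explained, k=k)
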