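"""Point-distribution shape model: alignment + PCA over landmark coordinates.

Training point sets are aligned by translating each to a common center of
gravity (a full-Procrustes variant removing rotation and scale is available
behind a flag), flattened to vectors (x0, y0, x1, y1, ...) and decomposed by
PCA.  The model is the linear family

    x = x_mean + Q_x c

where the columns of Q_x are the orthonormal eigenvectors of the sample
covariance ordered by decreasing eigenvalue, and the mode scores c are
obtained by orthogonal projection.  Modes are retained up to a cumulative
explained-variance threshold (default 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import PointSet

__all__ = ["PCAModel", "ShapeModel", "align_translation", "align_procrustes",
           "fit_pca", "fit_shape_pca", "shape_from_params", "params_from_shape"]


# ---------------------------------------------------------------------------
# Generic exact PCA (shared by shape, texture and appearance models)


@dataclass
class PCAModel:
    """Mean + orthonormal modes + eigenvalues of a sample of vectors."""

    mean: np.ndarray          # (d,)
    modes: np.ndarray         # (d, k) orthonormal columns
    eigenvalues: np.ndarray   # (k,) non-increasing, >= 0
    variance_threshold: float
    total_variance: float     # trace of the sample covariance

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def project(self, x: np.ndarray) -> np.ndarray:
        return self.modes.T @ (np.asarray(x, dtype=float) - self.mean)

    def synthesize(self, params: np.ndarray) -> np.ndarray:
        params = np.asarray(params, dtype=float)
        if params.size > self.n_modes:
            raise ValueError(
                f"{params.size} params but only {self.n_modes} retained modes")
        full = np.zeros(self.n_modes)
        full[:params.size] = params
        return self.mean + self.modes @ full

    def explained_variance_curve(self) -> np.ndarray:
        """Cumulative explained-variance fractions of the retained modes."""
        if self.total_variance == 0:
            return np.ones_like(self.eigenvalues)
        return np.cumsum(self.eigenvalues) / self.total_variance


def fit_pca(vectors: np.ndarray, variance_threshold: float = 0.95) -> PCAModel:
    """Exact PCA by eigendecomposition in the smaller of (samples, features).

    Deterministic: no randomized solvers, and each eigenvector's sign is fixed
    so its largest-magnitude component is positive.  Retains the smallest
    number of modes whose cumulative variance fraction reaches the threshold
    (zero-variance data retains no modes).
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("need at least 2 sample vectors")
    if not (0 < variance_threshold <= 1):
        raise ValueError("variance_threshold must be in (0, 1]")
    n, d = vectors.shape
    mean = vectors.mean(axis=0)
    centered = vectors - mean
    if n <= d:
        # Gram trick: eigenvectors of X X^T / (n-1), mapped back to feature space
        gram = centered @ centered.T / (n - 1)
        lam, u = np.linalg.eigh(gram)
        order = np.argsort(lam)[::-1]
        lam = np.maximum(lam[order], 0.0)
        u = u[:, order]
        nonzero = lam > max(lam[0], 1.0) * 1e-12 if lam.size else lam > 0
        lam = lam[nonzero]
        u = u[:, nonzero]
        modes = centered.T @ u
        norms = np.linalg.norm(modes, axis=0)
        modes = modes / np.where(norms == 0, 1.0, norms)
    else:
        cov = centered.T @ centered / (n - 1)
        lam, modes = np.linalg.eigh(cov)
        order = np.argsort(lam)[::-1]
        lam = np.maximum(lam[order], 0.0)
        modes = modes[:, order]
        nonzero = lam > max(lam[0] if lam.size else 0.0, 1.0) * 1e-12
        lam = lam[nonzero]
        modes = modes[:, nonzero]
    total = float(centered.var(axis=0, ddof=1).sum())
    if lam.size == 0 or total == 0:
        return PCAModel(mean, np.zeros((d, 0)), np.zeros(0),
                        variance_threshold, total)
    cum = np.cumsum(lam) / total
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, lam.size)
    lam = lam[:k]
    modes = modes[:, :k]
    # sign convention: largest-magnitude component of each mode is positive
    for j in range(k):
        i = int(np.argmax(np.abs(modes[:, j])))
        if modes[i, j] < 0:
            modes[:, j] = -modes[:, j]
    return PCAModel(mean, modes, lam, variance_threshold, total)


# ---------------------------------------------------------------------------
# Shape-specific wrappers


@dataclass
class ShapeModel:
    """PCA point-distribution model over aligned landmark configurations."""

    mean_shape: np.ndarray     # (2n,) flattened (x0, y0, x1, y1, ...)
    modes: np.ndarray          # (2n, k)
    eigenvalues: np.ndarray    # (k,)
    n_points: int
    variance_threshold: float
    scheme_id: str
    total_variance: float

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def mean_pointset(self) -> PointSet:
        return PointSet(self.mean_shape.reshape(-1, 2), self.scheme_id)


def align_translation(pointsets: list[PointSet]) -> list[PointSet]:
    """Translate every set so its center of gravity sits at the origin."""
    if not pointsets:
        raise ValueError("empty training set")
    out = []
    for ps in pointsets:
        if ps.n == 0:
            raise ValueError("empty point set")
        out.append(PointSet(ps.coords - ps.centroid(), ps.scheme_id))
    return out


def align_procrustes(pointsets: list[PointSet],
                     n_iter: int = 3) -> list[PointSet]:
    """Full Procrustes alignment (translation + rotation + scale removal).

    Optional variant; iteratively aligns every set to the evolving mean shape,
    with the mean normalized to unit centroid size.
    """
    centered = align_translation(pointsets)
    ref = centered[0].coords
    ref = ref / np.linalg.norm(ref)
    for _ in range(n_iter):
        aligned = []
        for ps in centered:
            a = ps.coords / np.linalg.norm(ps.coords)
            # optimal 2D rotation by SVD of the cross-covariance
            h = a.T @ ref
            u, _, vt = np.linalg.svd(h)
            d = np.sign(np.linalg.det(u @ vt))
            rot = u @ np.diag([1.0, d]) @ vt
            aligned.append(a @ rot)
        ref = np.mean(aligned, axis=0)
        ref = ref / np.linalg.norm(ref)
    return [PointSet(a, ps.scheme_id) for a, ps in zip(aligned, pointsets)]


def fit_shape_pca(aligned: list[PointSet],
                  variance_threshold: float = 0.95) -> ShapeModel:
    """PCA over aligned landmark vectors with threshold mode retention."""
    if len(aligned) < 2:
        raise ValueError("need at least 2 training shapes")
    scheme_id = aligned[0].scheme_id
    n_points = aligned[0].n
    vectors = np.stack([ps.coords.ravel() for ps in aligned])
    pca = fit_pca(vectors, variance_threshold)
    return ShapeModel(pca.mean, pca.modes, pca.eigenvalues, n_points,
                      variance_threshold, scheme_id, pca.total_variance)


def shape_from_params(model: ShapeModel, params: np.ndarray) -> PointSet:
    """Linear synthesis x = x_mean + Q_x c; trailing params default to 0."""
    params = np.atleast_1d(np.asarray(params, dtype=float))
    if params.size > model.n_modes:
        raise ValueError(
            f"{params.size} params but only {model.n_modes} retained modes")
    full = np.zeros(model.n_modes)
    full[:params.size] = params
    x = model.mean_shape + model.modes @ full
    return PointSet(x.reshape(-1, 2), model.scheme_id)


def params_from_shape(model: ShapeModel, aligned: PointSet,
                      centroid_tol: float = 1e-6) -> np.ndarray:
    """Orthogonal projection c = Q_x^T (x - x_mean) of an aligned shape.

    Refuses unaligned input: the centroid must sit at the origin (within
    ``centroid_tol`` relative to the shape scale).
    """
    centroid = aligned.centroid()
    scale = max(float(np.abs(aligned.coords).max()), 1.0)
    offset = float(np.linalg.norm(centroid))
    if offset > centroid_tol * scale:
        raise ValueError(
            f"point set is not centered: centroid offset {centroid} "
            f"(norm {offset:.3g}); align with align_translation first")
    return model.modes.T @ (aligned.coords.ravel() - model.mean_shape)
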