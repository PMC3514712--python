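"""Generalized Procrustes Analysis and shape-space geometry.

Superimposition removes position (centering), scale (unit centroid size) and
orientation (least-squares rotation, reflections excluded) from each landmark
configuration, leaving shape.  The iterated consensus is the standard GPA
fixed point; aligned shapes are then orthogonally projected onto the linear
tangent space at the consensus so ordinary multivariate statistics apply.

Conventions fixed here and relied on downstream:

* full Procrustes fitting — every configuration scaled to unit centroid size;
* rotations are proper (det = +1): left/right landmark homology forbids
  reflections;
* tangent projection is the orthogonal projection onto the affine hyperplane
  through the consensus, perpendicular to it;
* Procrustes distance between two shapes from one superimposition is the
  Euclidean norm of the flattened coordinate difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProcrustesResult",
    "centroid_size",
    "optimal_rotation",
    "gpa",
    "procrustes_distance",
    "interlandmark_distance",
    "mean_shape",
]

#: default convergence tolerance on consensus change (root-sum-square)
GPA_TOL = 1e-10
#: default iteration cap; far more than plausible data ever need
GPA_MAX_ITER = 100


@dataclass
class ProcrustesResult:
    """Output of :func:`gpa`.

    Attributes
    ----------
    aligned : (n, k, d) ndarray
        Tangent-space shape coordinates (projected at the consensus).
    consensus : (k, d) ndarray
        Mean shape; centroid at the origin, centroid size 1.
    centroid_sizes : (n,) ndarray
        Pre-superimposition centroid sizes (mm).
    log_centroid_sizes : (n,) ndarray
        Natural log of centroid sizes.
    iterations : int
    converged : bool
    specimen_ids : list of str or None
    landmark_names : tuple of str or None
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    log_centroid_sizes: np.ndarray
    iterations: int
    converged: bool
    specimen_ids: list | None = None
    landmark_names: tuple | None = None

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    @property
    def d(self) -> int:
        return self.aligned.shape[2]


def _coords(config) -> np.ndarray:
    """Accept a LandmarkConfiguration or a bare (k, d) array."""
    coords = getattr(config, "coords", config)
    return np.asarray(coords, dtype=float)


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid."""
    x = _coords(config)
    if x.shape[0] < 2:
        raise ValueError("centroid size needs at least 2 landmarks")
    dev = x - x.mean(axis=0)
    cs = float(np.sqrt((dev**2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


def _canonical_svd(M: np.ndarray):
    """SVD with a deterministic sign convention on the singular vectors.

    The largest-magnitude element of each left singular vector is made
    positive (the paired right vector flips with it, leaving the product
    unchanged), so degenerate spectra still give reproducible factors.
    """
    U, s, Vt = np.linalg.svd(M)
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            if j < Vt.shape[0]:
                Vt[j, :] = -Vt[j, :]
    return U, s, Vt


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R (det = +1) minimising ||B - A @ R||_F.

    A and B must be centered.  Solved by SVD of the cross-product matrix
    (Kabsch); if the unconstrained optimum is a reflection, the singular
    direction with the smallest singular value is flipped.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    M = A.T @ B
    U, s, Vt = _canonical_svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U = U.copy()
        U[:, -1] = -U[:, -1]
        R = U @ Vt
    return R


def _batch_rotations(Z: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Proper rotations aligning each Z[i] to the consensus, batched."""
    M = np.einsum("nkd,ke->nde", Z, consensus)
    U, s, Vt = np.linalg.svd(M)
    det = np.linalg.det(U @ Vt)
    flip = det < 0
    if np.any(flip):
        U = U.copy()
        U[flip, :, -1] = -U[flip, :, -1]
    return U @ Vt


def gpa(dataset, tol: float = GPA_TOL, max_iter: int = GPA_MAX_ITER) -> ProcrustesResult:
    """Generalized Procrustes superimposition of a landmark dataset.

    Accepts a :class:`~funnelmorph.landmark_io.LandmarkDataset` or an
    (n, k, d) array.  Iterates rotate-to-consensus / re-estimate-consensus
    until the consensus moves less than ``tol`` (root-sum-square), then
    projects all aligned shapes orthogonally onto the tangent space at the
    consensus.
    """
    ids = None
    names = None
    if hasattr(dataset, "coords_array"):
        X = dataset.coords_array()
        ids = dataset.specimen_ids
        names = dataset.landmark_names
    else:
        X = np.asarray(dataset, dtype=float)
    if X.ndim != 3:
        raise ValueError(f"expected (n, k, d) coordinates, got shape {X.shape}")
    n = X.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 specimens")

    Xc = X - X.mean(axis=1, keepdims=True)
    cs = np.sqrt((Xc**2).sum(axis=(1, 2)))
    if np.any(cs == 0):
        bad = np.nonzero(cs == 0)[0].tolist()
        raise ValueError(f"degenerate configurations (zero centroid size): {bad}")
    Z = Xc / cs[:, None, None]

    consensus = Z[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        R = _batch_rotations(Z, consensus)
        Z = np.einsum("nkd,nde->nke", Z, R)
        new = Z.mean(axis=0)
        new -= new.mean(axis=0)
        new /= np.sqrt((new**2).sum())
        delta = np.sqrt(((new - consensus) ** 2).sum())
        consensus = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations", RuntimeWarning
        )

    # orthogonal projection onto the tangent hyperplane at the consensus
    c = consensus.ravel()
    Zf = Z.reshape(n, -1)
    proj = Zf + (1.0 - Zf @ c)[:, None] * c
    aligned = proj.reshape(n, *consensus.shape)

    return ProcrustesResult(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=cs,
        log_centroid_sizes=np.log(cs),
        iterations=iterations,
        converged=converged,
        specimen_ids=ids,
        landmark_names=names,
    )


def procrustes_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """Euclidean norm of the flattened difference between two shapes.

    Both shapes must come from the same superimposition (tangent-space
    approximation to Procrustes distance).
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError(f"shape mismatch: {s1.shape} vs {s2.shape}")
    return float(np.linalg.norm((s1 - s2).ravel()))


def interlandmark_distance(config, a: str, b: str) -> float:
    """Euclidean distance between two named landmarks in raw coordinates."""
    names = getattr(config, "landmark_names", None)
    if names is None:
        raise ValueError("configuration has no landmark names")
    coords = _coords(config)
    try:
        ia, ib = names.index(a), names.index(b)
    except ValueError:
        raise KeyError(
            f"unknown landmark among {a!r}, {b!r}; available: {list(names)}"
        ) from None
    return float(np.linalg.norm(coords[ia] - coords[ib]))


def mean_shape(shapes) -> np.ndarray:
    """Coordinate-wise arithmetic mean of a stack of aligned shapes."""
    arr = np.asarray(shapes, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.size == 0:
        raise ValueError("mean of an empty set of shapes")
    return arr.mean(axis=0)
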