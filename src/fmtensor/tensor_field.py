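"""Sliding-window variance–covariance tensor fields over descriptor sets.

Each window of side ``W`` (default 90 µm) centred on a point of a regular
stride grid (default 20 µm) pools the descriptors whose midpoint falls in
the window.  Every descriptor contributes its two extreme points
``±vector/2`` to a point cloud whose mean is exactly zero by construction;
the window tensor is the population covariance of that cloud,

    CM = (1 / 2N) * sum over the 2N endpoints of p p^T  (µm²),

a symmetric positive semi-definite 3×3 matrix whose eigenvectors/values
give the locally prevailing orientation and its spread.  Windows with fewer
than ``min_count`` descriptors are flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .descriptors import DescriptorSet

__all__ = [
    "TensorField",
    "EigenField",
    "VectorMap",
    "compute_tensor_field",
    "eigendecompose",
    "principal_vector_field",
]


@dataclass
class TensorField:
    """Per-window covariance matrices on a regular grid of window centres."""

    origin: np.ndarray  # (3,) µm, first window centre
    stride: np.ndarray  # (3,) µm
    window: float  # µm, cubic window side
    matrices: np.ndarray  # (nx, ny, nz, 3, 3) µm²
    counts: np.ndarray  # (nx, ny, nz) descriptors per window
    min_count: int = 2
    kind: str = "vascular"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.stride = np.broadcast_to(np.asarray(self.stride, dtype=float), (3,)).copy()
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.matrices.shape[-2:] != (3, 3) or self.matrices.ndim != 5:
            raise ValueError("matrices must be (nx, ny, nz, 3, 3)")
        if self.counts.shape != self.matrices.shape[:3]:
            raise ValueError("counts must match the centre grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.matrices.shape[:3]

    @property
    def valid(self) -> np.ndarray:
        ok = self.counts >= self.min_count
        finite = np.isfinite(self.matrices).all(axis=(-2, -1))
        return ok & finite

    def centers(self) -> np.ndarray:
        """Physical µm coordinates of all window centres, shape (nx, ny, nz, 3)."""
        axes = [self.origin[k] + np.arange(self.shape[k]) * self.stride[k] for k in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)


@dataclass
class EigenField:
    """Sorted eigen-system of a :class:`TensorField`.

    ``eigenvalues[..., i]`` are descending (λ1 ≥ λ2 ≥ λ3, µm²) and
    ``eigenvectors[..., :, i]`` is the unit eigenvector v_{i+1}.  Signs are
    normalized so each eigenvector's largest-magnitude component is
    nonnegative (eigenvectors are axial; the sign carries no meaning).
    """

    origin: np.ndarray
    stride: np.ndarray
    window: float
    eigenvalues: np.ndarray  # (nx, ny, nz, 3)
    eigenvectors: np.ndarray  # (nx, ny, nz, 3, 3), columns are v1, v2, v3
    valid: np.ndarray  # (nx, ny, nz) bool
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.stride = np.broadcast_to(np.asarray(self.stride, dtype=float), (3,)).copy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.eigenvalues.shape[:3]

    def centers(self) -> np.ndarray:
        axes = [self.origin[k] + np.arange(self.shape[k]) * self.stride[k] for k in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)


@dataclass
class VectorMap:
    """A per-centre 3-vector map aligned with an :class:`EigenField` grid."""

    origin: np.ndarray
    stride: np.ndarray
    vectors: np.ndarray  # (nx, ny, nz, 3); zero where invalid
    valid: np.ndarray


def compute_tensor_field(
    descriptors: DescriptorSet,
    window: float = 90.0,
    stride: float = 20.0,
    min_count: int = 2,
    sample_normalization: bool = False,
    origin=None,
    shape=None,
) -> TensorField:
    """Pool descriptors into sliding windows and form per-window covariances.

    Window membership is by midpoint only (half-open on the high side:
    ``c - W/2 <= m < c + W/2`` per axis), so a segment spanning a window
    boundary belongs to exactly one window and is never double counted.
    The centre grid spans the descriptor bounding box from its minimum
    corner with the given stride unless ``origin``/``shape`` pin it
    explicitly.  ``sample_normalization`` divides by ``2N - 1`` instead of
    the population ``2N``.
    """
    stride3 = np.broadcast_to(np.asarray(stride, dtype=float), (3,)).astype(float)
    if window <= 0 or (stride3 <= 0).any():
        raise ValueError("window and stride must be positive")
    if window < stride3.max():
        raise ValueError("window must be >= stride")
    lo, hi = descriptors.bounding_box
    if origin is None:
        origin = lo
    origin = np.asarray(origin, dtype=float)
    if shape is None:
        # ceil guarantees the last centre's window still covers the bbox max,
        # so every midpoint belongs to exactly one window (never zero)
        shape = tuple(int(np.ceil((hi[k] - origin[k]) / stride3[k])) + 1 for k in range(3))
    shape = tuple(int(s) for s in shape)

    matrices = np.zeros(shape + (3, 3))
    counts = np.zeros(shape, dtype=np.int64)
    if len(descriptors) > 0:
        centers = TensorField(origin, stride3, window, matrices, counts).centers()
        flat_centers = centers.reshape(-1, 3)
        tree = cKDTree(descriptors.midpoints)
        half = window / 2.0
        hits = tree.query_ball_point(flat_centers, r=half * (1 + 1e-9), p=np.inf)
        V = descriptors.vectors
        M = descriptors.midpoints
        mats = matrices.reshape(-1, 3, 3)
        cnts = counts.reshape(-1)
        for ci, idx in enumerate(hits):
            if not idx:
                continue
            c = flat_centers[ci]
            m = M[idx]
            keep = ((m >= c - half) & (m < c + half)).all(axis=1)
            sel = np.asarray(idx)[keep]
            n = sel.size
            if n == 0:
                continue
            v = V[sel]
            s = v.T @ v  # = sum over endpoints of 2 * (v/2)(v/2)^T * 2
            denom = 2.0 * (2 * n - 1) if sample_normalization else 4.0 * n
            mats[ci] = s / denom
            cnts[ci] = n
    return TensorField(
        origin=origin,
        stride=stride3,
        window=float(window),
        matrices=matrices,
        counts=counts,
        min_count=min_count,
        kind=descriptors.kind,
    )


def eigendecompose(field: TensorField) -> EigenField:
    """Sorted, sign-normalized eigen-system of every valid window tensor.

    Eigenvalues in ``[-1e-9, 0)`` (numerical round-off of a PSD matrix) are
    clamped to zero; NaN matrices are marked invalid.
    """
    valid = field.valid.copy()
    vals = np.zeros(field.shape + (3,))
    vecs = np.broadcast_to(np.eye(3), field.shape + (3, 3)).copy()
    if valid.any():
        M = field.matrices[valid]
        asym = np.abs(M - np.swapaxes(M, -1, -2)).max() if M.size else 0.0
        if asym > 1e-9:
            raise ValueError(f"tensor matrices are not symmetric (max dev {asym:.2e})")
        w, v = np.linalg.eigh(M)
        w = w[:, ::-1]
        v = v[:, :, ::-1]
        w[(w < 0) & (w >= -1e-9)] = 0.0
        # axial sign convention: largest-|.| component nonnegative
        comp = np.argmax(np.abs(v), axis=1)  # (m, 3) index of extreme component per column
        picked = np.take_along_axis(v, comp[:, None, :], axis=1)[:, 0, :]
        sign = np.where(picked < 0, -1.0, 1.0)
        v = v * sign[:, None, :]
        vals[valid] = w
        vecs[valid] = v
    return EigenField(
        origin=field.origin,
        stride=field.stride,
        window=field.window,
        eigenvalues=vals,
        eigenvectors=vecs,
        valid=valid,
        counts=field.counts.copy(),
    )


def principal_vector_field(
    eigen: EigenField, index: int = 1, scale_by_sqrt_eigenvalue: bool = False
) -> VectorMap:
    """Per-centre eigenvector ``v_index`` (unit, or scaled by √λ on request).

    Invalid centres get the zero vector.
    """
    if index not in (1, 2, 3):
        raise ValueError("eigenvector index must be 1, 2 or 3")
    v = eigen.eigenvectors[..., :, index - 1].copy()
    if scale_by_sqrt_eigenvalue:
        v = v * np.sqrt(np.clip(eigen.eigenvalues[..., index - 1], 0, None))[..., None]
    v[~eigen.valid] = 0.0
    return VectorMap(eigen.origin, eigen.stride, v, eigen.valid.copy())
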