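"""Synthetic specimens with known ground truth.

Two specimen classes are emulated at desk scale: tubular branching
vasculature whose local direction follows a prescribed helix-angle law
across a cylindrical wall, and populations of solid ellipsoidal cells with
a prescribed axial orientation distribution.  Both can be rasterized to
masks / label volumes so that every downstream stage (skeletonization,
descriptor extraction, tensor fields, tractography) can be validated
against analytic truth.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .descriptors import DescriptorSet
from .grids import BinaryMask, LabelVolume

__all__ = [
    "UniformCloudSpec",
    "IsotropicCloudSpec",
    "HelicalShellSpec",
    "CellPopulationSpec",
    "GroundTruth",
    "make_segment_cloud",
    "rasterize_tubes",
    "make_cell_volume",
]


# ---------------------------------------------------------------------------
# specs


@dataclass
class UniformCloudSpec:
    """Segments of one common direction, midpoints uniform in a box."""

    n: int = 1000
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    segment_length: float = 15.0  # µm
    bounds: tuple = ((0.0, 0.0, 0.0), (200.0, 200.0, 200.0))  # µm
    jitter_deg: float = 0.0


@dataclass
class IsotropicCloudSpec:
    """Segments with uniformly random orientations, midpoints uniform in a box."""

    n: int = 10_000
    segment_length: float = 15.0
    bounds: tuple = ((0.0, 0.0, 0.0), (200.0, 200.0, 200.0))


@dataclass
class HelicalShellSpec:
    """A cylindrical wall whose fibre direction follows a helix-angle law.

    The transmural depth ``d`` runs from 0 at the outer (epicardial) surface
    to 1 at the inner (endocardial) surface.  The default law is linear from
    ``+alpha_epi`` at d=0 to ``-alpha_endo`` at d=1; ``ha_law`` (degrees as a
    function of d) overrides it.  Segment midpoints are uniform in the shell
    volume and each segment vector is ``segment_length`` times the local
    fibre direction, tilted by a random jitter angle (std ``jitter_deg``).
    """

    inner_radius: float = 120.0  # µm
    outer_radius: float = 380.0  # µm
    height: float = 300.0  # µm
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)  # long-axis direction
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    alpha_epi: float = 60.0  # degrees at d=0
    alpha_endo: float = 60.0  # degrees (sign applied internally) at d=1
    ha_law: Optional[Callable[[np.ndarray], np.ndarray]] = None
    segment_length: float = 15.0  # µm
    density: float = 1.0e-4  # segments per µm^3
    jitter_deg: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("need 0 < inner_radius < outer_radius")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.height <= 0:
            raise ValueError("height must be positive")

    def helix_angle(self, d: np.ndarray) -> np.ndarray:
        """Helix angle in degrees at transmural depth ``d`` in [0, 1]."""
        d = np.asarray(d, dtype=float)
        if self.ha_law is not None:
            ha = np.asarray(self.ha_law(d), dtype=float)
        else:
            ha = self.alpha_epi + d * (-self.alpha_endo - self.alpha_epi)
        if not np.isfinite(ha).all():
            raise ValueError("helix-angle law must be finite on [0, 1]")
        return ha


@dataclass
class CellPopulationSpec:
    """Solid ellipsoidal cells with Watson-distributed principal axes.

    ``semi_axes = (a, b, c)`` with ``a >= b >= c > 0`` in µm.  The principal
    axis of each cell is drawn from an axial Watson distribution about
    ``mean_orientation`` with concentration ``kappa`` (0 = isotropic,
    ``np.inf`` = all axes exactly at the mean).  Cells are placed by
    rejection sampling so that bounding spheres never overlap, which keeps
    per-cell moment ground truth exact.
    """

    n_cells: int = 50
    semi_axes: tuple[float, float, float] = (10.0, 4.0, 4.0)
    mean_orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    concentration: float = 300.0
    bounds: tuple = ((0.0, 0.0, 0.0), (150.0, 150.0, 90.0))  # µm
    max_attempts: int = 100_000

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not a >= b >= c > 0:
            raise ValueError("semi-axes must satisfy a >= b >= c > 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class GroundTruth:
    """Per-object truth matched 1:1 to the generated descriptors/cells."""

    directions: Optional[np.ndarray] = None  # (n, 3) unit, pre-jitter
    depths: Optional[np.ndarray] = None  # (n,) transmural depth d
    helix_angles_deg: Optional[np.ndarray] = None  # (n,)
    cell_centers: Optional[np.ndarray] = None  # (n, 3) µm
    cell_axes: Optional[np.ndarray] = None  # (n, 3, 3), columns = principal axes
    cell_semi_axes: Optional[np.ndarray] = None  # (n, 3) µm


# ---------------------------------------------------------------------------
# helpers


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _orthonormal_triad(axis) -> np.ndarray:
    """Rotation matrix whose third column is ``axis`` (deterministic)."""
    w = _unit(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(helper, w))
    v = np.cross(w, u)
    return np.column_stack([u, v, w])


def _jitter_directions(dirs: np.ndarray, jitter_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Tilt each unit vector by an angle ~ |N(0, jitter)| about a random azimuth."""
    if jitter_deg == 0:
        return dirs.copy()
    n = dirs.shape[0]
    tilt = np.abs(rng.normal(0.0, np.deg2rad(jitter_deg), n))
    phi = rng.uniform(0.0, 2 * np.pi, n)
    out = np.empty_like(dirs)
    for i in range(n):
        R = _orthonormal_triad(dirs[i])
        e1, e2, w = R[:, 0], R[:, 1], R[:, 2]
        out[i] = (
            np.cos(tilt[i]) * w
            + np.sin(tilt[i]) * (np.cos(phi[i]) * e1 + np.sin(phi[i]) * e2)
        )
    return out


def sample_watson_axes(
    mean: Sequence[float], kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` axial unit vectors from a bipolar Watson distribution.

    Density on the sphere is proportional to ``exp(kappa * (mu . x)^2)``.
    Sampling of ``t = mu . x``: substitute ``w = 1 - |t|``; the density is
    dominated by ``Exp(kappa)`` with acceptance probability
    ``exp(-kappa * w * (1 - w)) <= 1`` (about 50% for large kappa).
    ``kappa = inf`` returns the mean axis for every sample.
    """
    mu = _unit(mean)
    R = _orthonormal_triad(mu)
    if np.isinf(kappa):
        return np.tile(mu, (n, 1))
    if kappa < 1e-12:
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    ts = np.empty(0)
    while ts.size < n:
        m = 2 * (n - ts.size) + 16
        if kappa <= 5.0:
            # plain rejection against the uniform envelope
            t = rng.uniform(-1.0, 1.0, m)
            acc = rng.uniform(size=m) < np.exp(kappa * (t * t - 1.0))
            ts = np.concatenate([ts, t[acc]])
        else:
            w = rng.exponential(1.0 / kappa, m)
            keep = w <= 1.0
            w = w[keep]
            acc = rng.uniform(size=w.size) < np.exp(-kappa * w * (1.0 - w))
            t = 1.0 - w[acc]
            ts = np.concatenate([ts, t])
    t = ts[:n]
    sign = rng.choice([-1.0, 1.0], n)  # axial: both poles equivalent
    t = t * sign
    phi = rng.uniform(0.0, 2 * np.pi, n)
    s = np.sqrt(np.clip(1.0 - t * t, 0.0, None))
    local = np.column_stack([s * np.cos(phi), s * np.sin(phi), t])
    return local @ R.T


# ---------------------------------------------------------------------------
# segment clouds


def make_segment_cloud(kind: str, spec, seed: int = 0) -> tuple[DescriptorSet, GroundTruth]:
    """Generate a midpoint-anchored segment cloud with ground truth.

    ``kind`` selects the geometry: ``"uniform"`` (one common direction),
    ``"isotropic"`` (uniform random orientations) or ``"helical_shell"``
    (cylindrical wall with a transmural helix-angle law).  Vectors are
    ``segment_length`` times the (jittered) local direction with a random
    axial sign flip; ground truth stores the pre-jitter directions.
    """
    rng = np.random.default_rng(seed)
    if kind == "uniform":
        return _uniform_cloud(spec, rng)
    if kind == "isotropic":
        return _isotropic_cloud(spec, rng)
    if kind == "helical_shell":
        return _helical_cloud(spec, rng)
    raise ValueError(f"unknown segment-cloud kind: {kind!r}")


def _finish_cloud(mids, dirs, length, jitter_deg, rng, extra=None):
    jittered = _jitter_directions(dirs, jitter_deg, rng)
    signs = rng.choice([-1.0, 1.0], len(mids))
    vectors = jittered * signs[:, None] * length
    dset = DescriptorSet(mids, vectors, kind="vascular")
    truth = GroundTruth(directions=dirs, **(extra or {}))
    return dset, truth


def _uniform_cloud(spec: UniformCloudSpec, rng) -> tuple[DescriptorSet, GroundTruth]:
    if spec.n <= 0:
        raise ValueError("empty geometry: n must be positive")
    lo, hi = (np.asarray(b, dtype=float) for b in spec.bounds)
    mids = rng.uniform(lo, hi, (spec.n, 3))
    dirs = np.tile(_unit(spec.direction), (spec.n, 1))
    return _finish_cloud(mids, dirs, spec.segment_length, spec.jitter_deg, rng)


def _isotropic_cloud(spec: IsotropicCloudSpec, rng) -> tuple[DescriptorSet, GroundTruth]:
    if spec.n <= 0:
        raise ValueError("empty geometry: n must be positive")
    lo, hi = (np.asarray(b, dtype=float) for b in spec.bounds)
    mids = rng.uniform(lo, hi, (spec.n, 3))
    v = rng.normal(size=(spec.n, 3))
    dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
    return _finish_cloud(mids, dirs, spec.segment_length, 0.0, rng)


def _helical_cloud(spec: HelicalShellSpec, rng) -> tuple[DescriptorSet, GroundTruth]:
    volume = np.pi * (spec.outer_radius**2 - spec.inner_radius**2) * spec.height
    n = int(round(spec.density * volume))
    if n <= 0:
        raise ValueError("empty geometry: density * volume rounds to zero segments")
    # uniform in the annular shell: r^2 uniform, theta and z uniform
    r = np.sqrt(rng.uniform(spec.inner_radius**2, spec.outer_radius**2, n))
    theta = rng.uniform(0.0, 2 * np.pi, n)
    z = rng.uniform(-spec.height / 2.0, spec.height / 2.0, n)
    d = (spec.outer_radius - r) / (spec.outer_radius - spec.inner_radius)
    ha = np.deg2rad(spec.helix_angle(d))
    # local wall frame in shell coordinates (long axis = +z)
    r_hat = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
    l_hat = np.tile([0.0, 0.0, 1.0], (n, 1))
    c_hat = np.cross(l_hat, r_hat)
    dirs_local = np.cos(ha)[:, None] * c_hat + np.sin(ha)[:, None] * l_hat
    mids_local = r[:, None] * r_hat + z[:, None] * l_hat
    R = _orthonormal_triad(spec.axis)  # maps shell frame -> lab frame
    mids = mids_local @ R.T + np.asarray(spec.center, dtype=float)
    dirs = dirs_local @ R.T
    return _finish_cloud(
        mids,
        dirs,
        spec.segment_length,
        spec.jitter_deg,
        rng,
        extra={"depths": d, "helix_angles_deg": np.rad2deg(ha)},
    )


# ---------------------------------------------------------------------------
# rasterization


def rasterize_tubes(
    segments,
    radius: float,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> BinaryMask:
    """Rasterize tubes of the given radius (µm) around centreline segments.

    ``segments`` is an ``(n, 2, 3)`` array of µm endpoints, a
    :class:`~fmtensor.descriptors.DescriptorSet` (midpoint ± vector/2), or a
    skeleton graph (one segment per edge chord).  A voxel is foreground when
    its centre lies within ``radius`` of any centreline.
    """
    spacing = np.asarray(spacing, dtype=float)
    if radius < spacing.min():
        raise ValueError(
            f"radius {radius} µm is below the finest voxel pitch {spacing.min()} µm; "
            "tubes this thin cannot be resolved on the grid"
        )
    segs = _as_segments(segments)
    origin = np.asarray(origin, dtype=float)
    data = np.zeros(shape, dtype=np.uint8)
    for p0, p1 in segs:
        lo = np.minimum(p0, p1) - radius
        hi = np.maximum(p0, p1) + radius
        i0 = np.maximum(np.floor((lo - origin) / spacing).astype(int), 0)
        i1 = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 1, shape)
        if (i0 >= i1).any():
            continue
        ax = [origin[k] + np.arange(i0[k], i1[k]) * spacing[k] for k in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        seg = p1 - p0
        L2 = seg @ seg
        rel = pts - p0
        if L2 == 0:
            dist2 = np.einsum("...k,...k->...", rel, rel)
        else:
            t = np.clip(np.einsum("...k,k->...", rel, seg) / L2, 0.0, 1.0)
            closest = t[..., None] * seg
            diff = rel - closest
            dist2 = np.einsum("...k,...k->...", diff, diff)
        inside = dist2 <= radius * radius
        data[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]] |= inside.astype(np.uint8)
    return BinaryMask(data, tuple(spacing), tuple(origin))


def _as_segments(segments) -> np.ndarray:
    if isinstance(segments, DescriptorSet):
        if len(segments) == 0:
            return np.zeros((0, 2, 3))
        half = segments.vectors / 2.0
        return np.stack([segments.midpoints - half, segments.midpoints + half], axis=1)
    if hasattr(segments, "edges") and hasattr(segments, "nodes"):
        segs = []
        for u, v in sorted(segments.edges()):
            segs.append(
                [segments.nodes[u]["position"], segments.nodes[v]["position"]]
            )
        return np.asarray(segs, dtype=float).reshape(-1, 2, 3)
    segs = np.asarray(segments, dtype=float)
    if segs.size == 0:
        return np.zeros((0, 2, 3))
    if segs.ndim != 3 or segs.shape[1:] != (2, 3):
        raise ValueError("segments must be an (n, 2, 3) array of µm endpoints")
    return segs


# ---------------------------------------------------------------------------
# cell volumes


def make_cell_volume(
    spec: CellPopulationSpec,
    seed: int = 0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[LabelVolume, GroundTruth]:
    """Voxelize a non-overlapping population of oriented ellipsoidal cells.

    Label ``i`` (1-based) occupies the i-th ellipsoid.  Returns the label
    volume and the per-cell ground truth (centre, principal-axis triad,
    semi-axes).  Raises if ``n_cells`` cannot be placed within
    ``max_attempts`` rejection-sampling draws.
    """
    rng = np.random.default_rng(seed)
    lo, hi = (np.asarray(b, dtype=float) for b in spec.bounds)
    a = spec.semi_axes[0]
    if ((hi - lo) < 2 * a).any():
        raise ValueError("cells do not fit in the volume bounds")
    axes = sample_watson_axes(spec.mean_orientation, spec.concentration, spec.n_cells, rng)
    centers = np.empty((spec.n_cells, 3))
    placed = 0
    attempts = 0
    while placed < spec.n_cells:
        if attempts >= spec.max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_cells} cells after {attempts} attempts"
            )
        attempts += 1
        c = rng.uniform(lo + a, hi - a)
        if placed and (np.linalg.norm(centers[:placed] - c, axis=1) < 2 * a).any():
            continue  # bounding spheres overlap -> reject, keeps moments exact
        centers[placed] = c
        placed += 1

    spacing = np.asarray(spacing, dtype=float)
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int))
    data = np.zeros(shape, dtype=np.int32)
    triads = np.empty((spec.n_cells, 3, 3))
    semi = np.asarray(spec.semi_axes, dtype=float)
    for i in range(spec.n_cells):
        R = _orthonormal_triad(axes[i])
        # principal axis is the triad's third column; reorder to (a, b, c)
        triads[i] = np.column_stack([R[:, 2], R[:, 0], R[:, 1]])
        _rasterize_ellipsoid(data, i + 1, centers[i], triads[i], semi, spacing, lo)
    vol = LabelVolume(data, tuple(spacing), tuple(lo))
    truth = GroundTruth(
        cell_centers=centers,
        cell_axes=triads,
        cell_semi_axes=np.tile(semi, (spec.n_cells, 1)),
        directions=triads[:, :, 0],
    )
    return vol, truth


def _rasterize_ellipsoid(data, label, center, triad, semi, spacing, origin) -> None:
    lo = center - semi[0]
    hi = center + semi[0]
    i0 = np.maximum(np.floor((lo - origin) / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 1, data.shape)
    ax = [origin[k] + np.arange(i0[k], i1[k]) * spacing[k] for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    rel = np.stack([X, Y, Z], axis=-1) - center
    local = np.einsum("...k,kj->...j", rel, triad)  # coordinates in the cell frame
    q = ((local / semi) ** 2).sum(axis=-1)
    data[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]][q <= 1.0] = label
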