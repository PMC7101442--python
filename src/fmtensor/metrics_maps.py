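"""Eigenvalue-derived scalar/colour maps and the cardiac wall-frame analysis.

Scalar metrics follow the standard diffusion-tensor conventions:

* fractional anisotropy
  ``FA = sqrt(3/2) * sqrt(sum (λi - λmean)^2) / sqrt(sum λi^2)`` in [0, 1];
* Westin shape coefficients in the sum-normalized convention
  ``cl = (λ1 - λ2)/Σλ``, ``cp = 2(λ2 - λ3)/Σλ``, ``cs = 3 λ3/Σλ``,
  which partition 1 (a λ1-normalized variant is available by flag);
* directionally encoded colour (DEC): RGB = |eigenvector XYZ components|
  (X red, Y green, Z blue).

The wall frame is an idealized cylinder built from a user-supplied long
axis: radial (outward), longitudinal and circumferential unit vectors plus
a transmural depth d running from 0 at the epicardial (outer) surface to 1
at the endocardial (inner) surface.  The helix angle is the signed angle
between the principal eigenvector's projection on the wall-tangent plane
and the circumferential direction, in (-90°, 90°] with axial identification
(v and -v give the same angle); the transverse angle is the elevation out
of that plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tensor_field import EigenField

__all__ = [
    "ScalarMap",
    "RGBMap",
    "WallFrame",
    "TransmuralProfile",
    "fractional_anisotropy",
    "westin_coefficients",
    "dec_map",
    "build_wall_frame",
    "helix_transverse_angles",
    "transmural_profile",
]


@dataclass
class ScalarMap:
    """Per-centre scalar values on the eigenfield grid; NaN where invalid."""

    origin: np.ndarray
    stride: np.ndarray
    values: np.ndarray  # (nx, ny, nz)

    @property
    def shape(self):
        return self.values.shape


@dataclass
class RGBMap:
    """Per-centre RGB triples in [0, 1]^3 on the eigenfield grid."""

    origin: np.ndarray
    stride: np.ndarray
    values: np.ndarray  # (nx, ny, nz, 3)

    @property
    def shape(self):
        return self.values.shape[:3]


@dataclass
class WallFrame:
    """Orthonormal wall triad and transmural depth per grid centre.

    ``c_hat`` circumferential, ``l_hat`` longitudinal, ``r_hat`` outward
    radial, each (nx, ny, nz, 3); ``depth`` in [0, 1] from epicardium (0)
    to endocardium (1).  The generating cylinder (axis point/direction and
    the epi/endo radii) is retained for window-support checks.
    """

    origin: np.ndarray
    stride: np.ndarray
    c_hat: np.ndarray
    l_hat: np.ndarray
    r_hat: np.ndarray
    depth: np.ndarray
    valid: np.ndarray
    axis_point: np.ndarray | None = None
    axis_direction: np.ndarray | None = None
    epi_radius: float | None = None
    endo_radius: float | None = None


@dataclass
class TransmuralProfile:
    """Helix angle aggregated in transmural-depth bins, plus a linear fit.

    ``span_deg`` is HA(d=0) - HA(d=1) extrapolated from a robust
    (Theil–Sen) linear fit of HA against depth.
    """

    bin_centers: np.ndarray
    mean_ha_deg: np.ndarray  # circular (axial) mean per bin; NaN when empty
    median_ha_deg: np.ndarray
    counts: np.ndarray
    span_deg: float
    slope_deg: float
    intercept_deg: float


# ---------------------------------------------------------------------------
# scalar metrics


def fractional_anisotropy(eigen: EigenField) -> ScalarMap:
    """FA of every valid centre; NaN for invalid centres and zero tensors."""
    lam = eigen.eigenvalues
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, np.nan)
    fa[~eigen.valid] = np.nan
    return ScalarMap(eigen.origin, eigen.stride, np.clip(fa, 0.0, 1.0))


def westin_coefficients(
    eigen: EigenField, variant: str = "sum"
) -> tuple[ScalarMap, ScalarMap, ScalarMap]:
    """Westin linear / planar / spherical shape coefficients.

    ``variant="sum"`` normalizes by Σλ so cl + cp + cs = 1 at every valid
    centre; ``variant="lambda1"`` uses the λ1-normalized convention
    cl = (λ1-λ2)/λ1, cp = (λ2-λ3)/λ1, cs = λ3/λ1.
    """
    lam = eigen.eigenvalues
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    if variant == "sum":
        den = lam.sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cl = (l1 - l2) / den
            cp = 2.0 * (l2 - l3) / den
            cs = 3.0 * l3 / den
    elif variant == "lambda1":
        den = l1
        with np.errstate(invalid="ignore", divide="ignore"):
            cl = (l1 - l2) / den
            cp = (l2 - l3) / den
            cs = l3 / den
    else:
        raise ValueError(f"unknown Westin variant {variant!r}")
    bad = ~(eigen.valid & (den > 0))
    out = []
    for arr in (cl, cp, cs):
        arr = np.where(bad, np.nan, arr)
        out.append(ScalarMap(eigen.origin, eigen.stride, arr))
    return tuple(out)  # type: ignore[return-value]


def dec_map(
    eigen: EigenField, index: int = 1, weight: str = "none"
) -> RGBMap:
    """Directionally encoded colour map of eigenvector ``v_index``.

    RGB channels are the absolute X, Y, Z components of the eigenvector;
    ``weight="fa"`` multiplies all channels by FA, ``weight="count"`` by the
    window count normalized to its maximum.  Invalid centres are black.
    """
    if index not in (1, 2, 3):
        raise ValueError("eigenvector index must be 1, 2 or 3")
    rgb = np.abs(eigen.eigenvectors[..., :, index - 1])
    if weight == "fa":
        fa = fractional_anisotropy(eigen).values
        rgb = rgb * np.nan_to_num(fa)[..., None]
    elif weight == "count":
        if eigen.counts is None:
            raise ValueError("count weighting requires an eigenfield with counts")
        cmax = eigen.counts[eigen.valid].max() if eigen.valid.any() else 1
        rgb = rgb * (eigen.counts / max(int(cmax), 1))[..., None]
    elif weight != "none":
        raise ValueError(f"unknown weight {weight!r}")
    rgb = np.clip(rgb, 0.0, 1.0)
    rgb[~eigen.valid] = 0.0
    return RGBMap(eigen.origin, eigen.stride, rgb)


# ---------------------------------------------------------------------------
# wall frame and angles


def build_wall_frame(
    grid,
    axis_point,
    axis_direction,
    epi_radius: float,
    endo_radius: float,
) -> WallFrame:
    """Idealized cylindrical wall frame on the centre grid of ``grid``.

    ``grid`` is any object with ``origin``, ``stride`` and ``centers()``
    (an :class:`EigenField` or :class:`~fmtensor.tensor_field.TensorField`).
    ``epi_radius > endo_radius``; depth d = (epi_r - r)/(epi_r - endo_r)
    clipped to [0, 1].  Centres on the long axis have no radial direction
    and are marked invalid.
    """
    if not epi_radius > endo_radius > 0:
        raise ValueError("need epi_radius > endo_radius > 0")
    p0 = np.asarray(axis_point, dtype=float)
    l_hat = np.asarray(axis_direction, dtype=float)
    l_hat = l_hat / np.linalg.norm(l_hat)
    centers = grid.centers()
    rel = centers - p0
    axial = np.einsum("...k,k->...", rel, l_hat)
    radial = rel - axial[..., None] * l_hat
    r = np.linalg.norm(radial, axis=-1)
    valid = r > 1e-9
    with np.errstate(invalid="ignore", divide="ignore"):
        r_hat = radial / r[..., None]
    r_hat[~valid] = 0.0
    l_field = np.broadcast_to(l_hat, r_hat.shape).copy()
    c_hat = np.cross(l_field, r_hat)
    depth = np.clip((epi_radius - r) / (epi_radius - endo_radius), 0.0, 1.0)
    return WallFrame(
        origin=np.asarray(grid.origin, dtype=float),
        stride=np.asarray(grid.stride, dtype=float),
        c_hat=c_hat,
        l_hat=l_field,
        r_hat=r_hat,
        depth=depth,
        valid=valid,
        axis_point=p0,
        axis_direction=l_hat,
        epi_radius=float(epi_radius),
        endo_radius=float(endo_radius),
    )


def helix_transverse_angles(
    eigen: EigenField, frame: WallFrame
) -> tuple[ScalarMap, ScalarMap]:
    """Helix and transverse angle (degrees) of v1 in the local wall frame.

    The eigenvector sign is first normalized axially so the circumferential
    component is nonnegative (longitudinal if the former vanishes); then
    HA = atan2(longitudinal, circumferential) in (-90°, 90°] and
    TA = atan2(radial, in-plane magnitude).  A v1 parallel to the radial
    direction has no defined helix angle (NaN) and TA = ±90°.
    """
    v1 = eigen.eigenvectors[..., :, 0]
    c = np.einsum("...k,...k->...", v1, frame.c_hat)
    l = np.einsum("...k,...k->...", v1, frame.l_hat)
    r = np.einsum("...k,...k->...", v1, frame.r_hat)
    flip = (c < 0) | ((c == 0) & (l < 0))
    sign = np.where(flip, -1.0, 1.0)
    c, l, r = c * sign, l * sign, r * sign
    planar = np.hypot(c, l)
    with np.errstate(invalid="ignore"):
        ha = np.degrees(np.arctan2(l, c))
        ta = np.degrees(np.arctan2(r, planar))
    ha = np.where(planar > 1e-12, ha, np.nan)
    bad = ~(eigen.valid & frame.valid)
    ha[bad] = np.nan
    ta = np.where(bad, np.nan, ta)
    return (
        ScalarMap(eigen.origin, eigen.stride, ha),
        ScalarMap(eigen.origin, eigen.stride, ta),
    )


def _axial_circular_mean_deg(deg: np.ndarray) -> float:
    """Mean of axial angles in (-90, 90] via the double-angle embedding."""
    two = np.deg2rad(2.0 * deg)
    s, c = np.sin(two).mean(), np.cos(two).mean()
    return float(np.rad2deg(np.arctan2(s, c)) / 2.0)


def transmural_profile(
    ha: ScalarMap,
    frame: WallFrame,
    n_bins: int = 10,
    window: float | None = None,
) -> TransmuralProfile:
    """Bin helix angles by transmural depth and fit the transmural course.

    When ``window`` (the tensor-field window side, µm) is given, centres
    whose sampling cube is not fully supported by the wall annulus are
    excluded: a window protruding past the epi/endo surface samples depth
    one-sidedly and would bias the edge bins.  The support test bounds the
    cube's radial extent exactly at the corners (max) and conservatively
    towards the axis (min).

    The span is HA(0) - HA(1) from a Theil–Sen fit over all retained
    centres, robust to the residual dispersion of the per-window estimates.
    """
    vals = ha.values
    good = np.isfinite(vals) & frame.valid
    if window is not None and frame.axis_point is not None:
        supported = good & _window_inside_wall(frame, window)
        # a wall thinner than the window has no fully supported centre;
        # fall back to all valid centres rather than an empty profile
        if supported.any():
            good = supported
    d = frame.depth[good]
    a = vals[good]
    if a.size == 0:
        raise ValueError("no valid helix-angle values to profile")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    mean = np.full(n_bins, np.nan)
    median = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        counts[b] = int(sel.sum())
        if counts[b]:
            mean[b] = _axial_circular_mean_deg(a[sel])
            median[b] = float(np.median(a[sel]))
    # Theil–Sen is O(n^2) in pairs; an evenly spaced depth-ordered subsample
    # keeps the fit robust while bounding memory on dense fields
    if d.size > 2000:
        order = np.argsort(d, kind="stable")
        pick = order[np.linspace(0, d.size - 1, 2000).astype(int)]
        d_fit, a_fit = d[pick], a[pick]
    else:
        d_fit, a_fit = d, a
    if np.unique(d_fit).size > 1:
        slope, intercept, _, _ = stats.theilslopes(a_fit, d_fit)
    else:
        slope, intercept = 0.0, float(np.mean(a_fit))
    return TransmuralProfile(
        bin_centers=centers,
        mean_ha_deg=mean,
        median_ha_deg=median,
        counts=counts,
        span_deg=float(-slope),
        slope_deg=float(slope),
        intercept_deg=float(intercept),
    )


def _window_inside_wall(frame: WallFrame, window: float) -> np.ndarray:
    """Centres whose W-cube lies radially inside [endo_radius, epi_radius]."""
    h = window / 2.0
    # in-plane projections of the grid axes scaled by the half-window
    l_hat = frame.axis_direction
    P = np.eye(3) - np.outer(l_hat, l_hat)
    grid_axes = np.eye(3)
    proj = (P @ grid_axes.T).T * h  # rows: in-plane offset vectors
    # reconstruct centre coordinates and their in-plane radial vectors
    shape = frame.depth.shape
    axes = [frame.origin[k] + np.arange(shape[k]) * frame.stride[k] for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([X, Y, Z], axis=-1)
    rel = centers - frame.axis_point
    axial = np.einsum("...k,k->...", rel, l_hat)
    q = rel - axial[..., None] * l_hat
    qn = np.linalg.norm(q, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        q_hat = q / qn[..., None]
    q_hat = np.nan_to_num(q_hat)
    # max radius: attained at a cube corner (radius is convex)
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
    )
    offsets = corners @ proj  # (8, 3)
    r_max = np.zeros(shape)
    for off in offsets:
        r_max = np.maximum(r_max, np.linalg.norm(q + off, axis=-1))
    # conservative min radius: retreat along -q_hat by the maximal support
    support = np.abs(np.einsum("...k,jk->...j", q_hat, proj)).sum(axis=-1)
    r_min = np.clip(qn - support, 0.0, None)
    return (r_max <= frame.epi_radius) & (r_min >= frame.endo_radius)
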