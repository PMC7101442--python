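"""Deterministic streamline tracking through eigenvector fields.

Integration is a 2nd-order Runge-Kutta (midpoint) scheme: the direction at
the current point (sign-aligned with the previous heading, because
eigenvectors are axial) advances a half step, the direction there gives the
full step.  A propagation angle greater than ``max_angle`` (default 35°)
between consecutive headings is the single termination criterion besides
leaving the field or entering an invalid window; no anisotropy threshold is
applied.  Tracking is bidirectional from every seed by default and the two
half-tracks are concatenated at the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor_field import EigenField

__all__ = ["Streamline", "StreamlineSet", "track", "subsample", "filter_by_length"]

TERMINATION_REASONS = ("angle", "boundary", "invalid_voxel", "max_length")


@dataclass
class Streamline:
    """An ordered µm polyline with its seed and termination metadata."""

    points: np.ndarray  # (m, 3) µm
    seed: np.ndarray  # (3,) µm
    eigen_index: int
    reasons: tuple[str, ...]  # termination reason per tracked direction

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.seed = np.asarray(self.seed, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValueError("a streamline needs at least 2 points")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class StreamlineSet:
    """Streamlines plus the tracking parameters that produced them."""

    streamlines: list[Streamline]
    parameters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


class _DirectionField:
    """Axial direction lookup on an eigenfield grid (nearest or trilinear)."""

    def __init__(self, eigen: EigenField, index: int, interpolation: str):
        self.vectors = np.ascontiguousarray(eigen.eigenvectors[..., :, index - 1])
        self.valid = eigen.valid
        self.origin = eigen.origin
        self.stride = eigen.stride
        self.shape = np.asarray(eigen.shape)
        if interpolation not in ("nearest", "trilinear"):
            raise ValueError(f"unknown interpolation {interpolation!r}")
        self.interpolation = interpolation

    def __call__(self, x, ref):
        """Unit direction at x sign-aligned with ref, or (None, reason)."""
        f = (x - self.origin) / self.stride
        if self.interpolation == "nearest":
            idx = np.rint(f).astype(int)
            if (idx < 0).any() or (idx >= self.shape).any():
                return None, "boundary"
            i, j, k = idx
            if not self.valid[i, j, k]:
                return None, "invalid_voxel"
            v = self.vectors[i, j, k]
        else:
            base = np.floor(f).astype(int)
            frac = f - base
            acc = np.zeros(3)
            wsum = 0.0
            any_inside = False
            for di in (0, 1):
                for dj in (0, 1):
                    for dk in (0, 1):
                        i, j, k = base[0] + di, base[1] + dj, base[2] + dk
                        if not (0 <= i < self.shape[0] and 0 <= j < self.shape[1] and 0 <= k < self.shape[2]):
                            continue
                        any_inside = True
                        if not self.valid[i, j, k]:
                            continue
                        w = (
                            (frac[0] if di else 1 - frac[0])
                            * (frac[1] if dj else 1 - frac[1])
                            * (frac[2] if dk else 1 - frac[2])
                        )
                        if w <= 0:
                            continue
                        c = self.vectors[i, j, k]
                        if ref is not None and np.dot(c, ref) < 0:
                            c = -c  # axial sign correction before averaging
                        elif ref is None and wsum > 0 and np.dot(c, acc) < 0:
                            c = -c
                        acc = acc + w * c
                        wsum += w
            if not any_inside:
                return None, "boundary"
            if wsum <= 0:
                return None, "invalid_voxel"
            norm = np.linalg.norm(acc)
            if norm == 0:
                return None, "invalid_voxel"
            v = acc / norm
        if ref is not None and np.dot(v, ref) < 0:
            v = -v
        return v, None


def track(
    eigen: EigenField,
    index: int = 1,
    step: float = 10.0,
    max_angle: float = 35.0,
    seeds="all",
    max_points: int = 10_000,
    bidirectional: bool = True,
    interpolation: str = "nearest",
    seed_stride: int = 1,
) -> StreamlineSet:
    """Deterministic RK2 streamline tracking along eigenvector ``index``.

    ``seeds="all"`` seeds every valid window centre (``seed_stride``
    decimates the seed grid for speed); otherwise pass an ``(n, 3)`` µm
    array.  ``max_points`` caps the points per tracked direction.  Seeds in
    invalid or out-of-field regions are skipped.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if index not in (1, 2, 3):
        raise ValueError("eigenvector index must be 1, 2 or 3")
    if not eigen.valid.any():
        raise ValueError("eigenfield has no valid centre")
    direction = _DirectionField(eigen, index, interpolation)
    if isinstance(seeds, str) and seeds == "all":
        centers = eigen.centers()
        sl = (slice(None, None, seed_stride),) * 3
        seed_pts = centers[sl][eigen.valid[sl]]
        seeds_spec = f"all_voxels(stride={seed_stride})"
    else:
        seed_pts = np.atleast_2d(np.asarray(seeds, dtype=float))
        seeds_spec = f"list({len(seed_pts)})"

    cos_limit = np.cos(np.deg2rad(max_angle))
    lines: list[Streamline] = []
    for s in seed_pts:
        v0, _ = direction(s, None)
        if v0 is None:
            continue
        # canonical axial sign at the seed: tracks are invariant under a
        # global sign flip of the eigenvector field
        j = int(np.argmax(np.abs(v0)))
        if v0[j] < 0:
            v0 = -v0
        fwd_pts, fwd_reason = _half_track(s, v0, direction, step, cos_limit, max_points)
        if bidirectional:
            bwd_pts, bwd_reason = _half_track(s, -v0, direction, step, cos_limit, max_points)
            pts = bwd_pts[::-1] + fwd_pts[1:]
            reasons = (fwd_reason, bwd_reason)
        else:
            pts = fwd_pts
            reasons = (fwd_reason,)
        if len(pts) < 2:
            continue
        lines.append(Streamline(np.asarray(pts), s, index, reasons))
    return StreamlineSet(
        lines,
        parameters={
            "eigen_index": index,
            "step_um": float(step),
            "max_angle_deg": float(max_angle),
            "seeds": seeds_spec,
            "max_points": int(max_points),
            "bidirectional": bool(bidirectional),
            "interpolation": interpolation,
        },
    )


def _half_track(x0, v0, direction, step, cos_limit, max_points):
    pts = [np.asarray(x0, dtype=float)]
    x = pts[0]
    prev = v0
    reason = "max_length"
    while len(pts) < max_points:
        va, r = direction(x, prev)
        if va is None:
            reason = r
            break
        xm = x + (step / 2.0) * va
        vb, r = direction(xm, va)
        if vb is None:
            reason = r
            break
        if np.dot(prev, vb) < cos_limit:
            reason = "angle"
            break
        xn = x + step * vb
        probe, r = direction(xn, vb)
        if probe is None:
            reason = r
            break
        pts.append(xn)
        x = xn
        prev = vb
    return pts, reason


def subsample(tracks: StreamlineSet, fraction: float, seed: int = 0) -> StreamlineSet:
    """Uniform random subset of ``round(fraction * n)`` tracks, order kept.

    The display convention for dense tractograms keeps ~15% of tracks.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(tracks)
    if n == 0:
        return StreamlineSet([], dict(tracks.parameters))
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=k, replace=False))
    params = dict(tracks.parameters)
    params.update({"subsample_fraction": float(fraction), "subsample_seed": int(seed)})
    return StreamlineSet([tracks.streamlines[i] for i in keep], params)


def filter_by_length(tracks: StreamlineSet, min_length: float) -> StreamlineSet:
    """Keep tracks whose polyline length is at least ``min_length`` µm."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    kept = [s for s in tracks if s.length >= min_length]
    params = dict(tracks.parameters)
    params["min_length_um"] = float(min_length)
    return StreamlineSet(kept, params)
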