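"""Oriented feature descriptors extracted from skeleton graphs or label volumes.

A descriptor is an axial (sign-ambiguous) vector anchored at a midpoint:
for the microvasculature it is the straight chord between two adjacent
skeleton-graph nodes; for cell populations it is the principal axis of the
best-fitting ellipsoid of each labelled cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import LabelVolume

__all__ = ["DescriptorSet", "segments_from_graph", "cell_axes_from_labels"]

log = logging.getLogger(__name__)


@dataclass
class DescriptorSet:
    """A set of midpoint-anchored axial feature vectors (µm).

    Attributes
    ----------
    midpoints : (n, 3) float array, µm XYZ.
    vectors : (n, 3) float array, µm XYZ; sign is not meaningful.
    source_ids : length-n list of strings naming the originating structure.
    kind : ``"vascular"`` or ``"cellular"``.
    n_degenerate : structures counted but excluded because their orientation
        was direction-degenerate (e.g. near-spherical cells).
    """

    midpoints: np.ndarray
    vectors: np.ndarray
    source_ids: list[str] = field(default_factory=list)
    kind: str = "vascular"
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        self.midpoints = np.atleast_2d(np.asarray(self.midpoints, dtype=float))
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if len(self) == 0:
            self.midpoints = self.midpoints.reshape(0, 3)
            self.vectors = self.vectors.reshape(0, 3)
        if self.midpoints.shape != self.vectors.shape or self.midpoints.shape[1:] != (3,):
            raise ValueError("midpoints and vectors must both be (n, 3)")
        if not (np.isfinite(self.midpoints).all() and np.isfinite(self.vectors).all()):
            raise ValueError("descriptors must be finite")
        if len(self) and (np.linalg.norm(self.vectors, axis=1) == 0).any():
            raise ValueError("descriptor vectors must have positive norm")
        if not self.source_ids:
            self.source_ids = [str(i) for i in range(len(self))]

    def __len__(self) -> int:
        return self.midpoints.shape[0]

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) µm bounds of the midpoints."""
        if len(self) == 0:
            z = np.zeros(3)
            return z, z
        return self.midpoints.min(axis=0), self.midpoints.max(axis=0)

    # -- serialization ----------------------------------------------------

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "midpoint_x": self.midpoints[:, 0],
                "midpoint_y": self.midpoints[:, 1],
                "midpoint_z": self.midpoints[:, 2],
                "vec_x": self.vectors[:, 0],
                "vec_y": self.vectors[:, 1],
                "vec_z": self.vectors[:, 2],
                "source_id": self.source_ids,
                "kind": self.kind,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DescriptorSet":
        df = pd.read_csv(path)
        kind = str(df["kind"].iloc[0]) if len(df) else "vascular"
        return cls(
            midpoints=df[["midpoint_x", "midpoint_y", "midpoint_z"]].to_numpy(float),
            vectors=df[["vec_x", "vec_y", "vec_z"]].to_numpy(float),
            source_ids=[str(s) for s in df["source_id"]],
            kind=kind,
        )


def segments_from_graph(graph) -> DescriptorSet:
    """One descriptor per graph edge: the chord between the two node positions.

    The vector is ``pos2 - pos1`` and the midpoint the average of the node
    positions.  Zero-length chords (coincident nodes, e.g. a self-loop on a
    closed skeleton cycle) are dropped with a logged count.
    """
    mids, vecs, ids = [], [], []
    dropped = 0
    for u, v, key in sorted(graph.edges(keys=True)):
        p1 = np.asarray(graph.nodes[u]["position"], dtype=float)
        p2 = np.asarray(graph.nodes[v]["position"], dtype=float)
        chord = p2 - p1
        if np.linalg.norm(chord) == 0:
            dropped += 1
            continue
        mids.append(0.5 * (p1 + p2))
        vecs.append(chord)
        ids.append(f"{u}-{v}-{key}")
    if dropped:
        log.info("segments_from_graph: dropped %d zero-length chords", dropped)
    if not mids:
        return DescriptorSet(np.zeros((0, 3)), np.zeros((0, 3)), kind="vascular")
    return DescriptorSet(np.array(mids), np.array(vecs), ids, kind="vascular")


def cell_axes_from_labels(
    labels: LabelVolume,
    min_voxels: int = 20,
    degenerate_tol: float = 0.05,
) -> DescriptorSet:
    """Principal ellipsoid axes of every labelled cell.

    For each label the 3x3 second central moment matrix of its voxel
    physical coordinates is diagonalized.  The descriptor vector is the
    principal eigenvector scaled by ``2 * sqrt(5 * lambda_1)``: for a solid
    ellipsoid the coordinate variance along a semi-axis ``a`` is ``a^2 / 5``,
    so the scaling makes the descriptor magnitude the cell's long diameter.
    The midpoint is the centroid.

    Labels smaller than ``min_voxels`` are skipped.  Cells whose two leading
    eigenvalues are within ``degenerate_tol`` relative spread —
    ``(l1 - l2)/l1 < tol`` — have no meaningful axis direction (spheres);
    they are excluded from the set but tallied in ``n_degenerate``.
    """
    labs = labels.labels()
    if labs.size == 0:
        raise ValueError("label volume contains no labels")
    spacing = np.asarray(labels.spacing)
    origin = np.asarray(labels.origin)
    objects = ndimage.find_objects(labels.data)
    mids, vecs, ids = [], [], []
    n_degenerate = 0
    for lab in labs:
        sl = objects[int(lab) - 1]
        if sl is None:
            continue
        sub = labels.data[sl] == lab
        n = int(sub.sum())
        if n < min_voxels:
            continue
        idx = np.argwhere(sub) + np.array([s.start for s in sl])
        coords = origin + idx * spacing
        centroid = coords.mean(axis=0)
        x = coords - centroid
        mom = (x.T @ x) / n
        vals, v = np.linalg.eigh(mom)
        vals, v = vals[::-1], v[:, ::-1]
        if vals[0] <= 0:
            n_degenerate += 1
            continue
        if (vals[0] - vals[1]) / vals[0] < degenerate_tol:
            n_degenerate += 1
            continue
        mids.append(centroid)
        vecs.append(v[:, 0] * 2.0 * np.sqrt(5.0 * vals[0]))
        ids.append(str(int(lab)))
    if not mids:
        return DescriptorSet(
            np.zeros((0, 3)), np.zeros((0, 3)), kind="cellular", n_degenerate=n_degenerate
        )
    return DescriptorSet(
        np.array(mids), np.array(vecs), ids, kind="cellular", n_degenerate=n_degenerate
    )
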