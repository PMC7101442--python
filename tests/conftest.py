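"""Shared fixtures: analytic eigenfields and rasterized tube phantoms."""

from __future__ import annotations

import numpy as np
import pytest

import fmtensor as fm
from fmtensor.tensor_field import EigenField


def make_eigen_field(origin, stride, shape, direction_fn, valid=None) -> EigenField:
    """Analytic rank-1 eigenfield with v1 = direction_fn(centres)."""
    origin = np.asarray(origin, dtype=float)
    stride = np.broadcast_to(np.asarray(stride, dtype=float), (3,))
    axes = [origin[k] + np.arange(shape[k]) * stride[k] for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([X, Y, Z], axis=-1)
    v1 = np.asarray(direction_fn(centers), dtype=float)
    n = np.linalg.norm(v1, axis=-1, keepdims=True)
    v1 = np.where(n > 0, v1 / np.where(n == 0, 1, n), [1.0, 0.0, 0.0])
    vals = np.zeros(shape + (3,))
    vals[..., 0] = 1.0
    helper = np.where(np.abs(v1[..., [0]]) < 0.9, [1.0, 0, 0], [0, 1.0, 0])
    v2 = np.cross(v1, helper)
    v2 = v2 / np.linalg.norm(v2, axis=-1, keepdims=True)
    vecs = np.zeros(shape + (3, 3))
    vecs[..., :, 0] = v1
    vecs[..., :, 1] = v2
    vecs[..., :, 2] = np.cross(v1, v2)
    if valid is None:
        valid = np.ones(shape, dtype=bool)
    return EigenField(origin, stride.copy(), 90.0, vals, vecs, valid)


def straight_tube_phantom():
    """A single straight tube: truth (2 endpoints, 0 junctions, 1 edge of 80 µm)."""
    segs = np.array([[[10, 8, 8], [90, 8, 8]]], dtype=float)
    mask = fm.rasterize_tubes(segs, 3.0, (100, 16, 16), (1, 1, 1))
    return mask, {"endpoints": 2, "junctions": 0, "edges": 1, "lengths": [80.0]}


def y_tube_phantom():
    """Three 50 µm arms meeting at 120°: truth (3 endpoints, 1 junction, 3 edges)."""
    c = np.array([60.0, 60.0, 8.0])
    arms = [c + 50 * np.array([np.cos(a), np.sin(a), 0]) for a in np.deg2rad([90, 210, 330])]
    segs = np.array([[c, a] for a in arms])
    mask = fm.rasterize_tubes(segs, 3.0, (120, 120, 16), (1, 1, 1))
    return mask, {"endpoints": 3, "junctions": 1, "edges": 3, "lengths": [50.0] * 3}


def h_tube_phantom():
    """Two 100 µm verticals bridged by a 40 µm crossbar (4 ep, 2 jn, 5 edges)."""
    lv, rv = 20.0, 60.0
    segs = np.array(
        [
            [[lv, 10, 8], [lv, 60, 8]],
            [[lv, 60, 8], [lv, 110, 8]],
            [[rv, 10, 8], [rv, 60, 8]],
            [[rv, 60, 8], [rv, 110, 8]],
            [[lv, 60, 8], [rv, 60, 8]],
        ],
        dtype=float,
    )
    mask = fm.rasterize_tubes(segs, 3.0, (80, 120, 16), (1, 1, 1))
    return mask, {
        "endpoints": 4,
        "junctions": 2,
        "edges": 5,
        "lengths": [40.0, 50.0, 50.0, 50.0, 50.0],
    }


def graph_census(G):
    """(endpoint count, junction count, edge count, sorted edge lengths)."""
    eps = sum(1 for _, d in G.nodes(data=True) if d["cls"] == "endpoint")
    jns = sum(1 for _, d in G.nodes(data=True) if d["cls"] == "junction")
    lens = sorted(d["length_um"] for _, _, d in G.edges(data=True))
    return eps, jns, G.number_of_edges(), np.asarray(lens)


@pytest.fixture(scope="session")
def helical_recovery():
    """Full helical-shell phantom run: descriptors -> tensors -> HA profile.

    Shared across tests because the phantom is the package's largest fixture.
    """
    spec = fm.HelicalShellSpec()  # ±60° linear law, 5° jitter
    dset, truth = fm.make_segment_cloud("helical_shell", spec, seed=11)
    field = fm.compute_tensor_field(dset, window=90.0, stride=20.0, min_count=2)
    eigen = fm.eigendecompose(field)
    frame = fm.build_wall_frame(
        eigen, (0, 0, 0), spec.axis, spec.outer_radius, spec.inner_radius
    )
    ha, ta = fm.helix_transverse_angles(eigen, frame)
    profile = fm.transmural_profile(ha, frame, n_bins=10, window=field.window)
    return {
        "spec": spec,
        "descriptors": dset,
        "truth": truth,
        "field": field,
        "eigen": eigen,
        "frame": frame,
        "ha": ha,
        "ta": ta,
        "profile": profile,
    }


@pytest.fixture(scope="session")
def cell_recovery():
    """Cell-population phantom and recovered per-cell axis descriptors."""
    spec = fm.CellPopulationSpec()  # 50 cells, semi-axes (10, 4, 4) µm, kappa=300
    volume, truth = fm.make_cell_volume(spec, seed=7)
    dset = fm.cell_axes_from_labels(volume)
    return {"spec": spec, "volume": volume, "truth": truth, "descriptors": dset}
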