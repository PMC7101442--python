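"""Readers and writers for every on-disk format the pipeline touches.

Formats: multi-page TIFF stacks (masks, labels, scalar volumes), NRRD
(tensor fields, six upper-triangular components plus the window count),
TrackVis ``.trk`` (streamlines, via nibabel), GraphML/CSV (skeleton
graphs), PNG plus a text sidecar (2D map exports) and legacy ASCII VTK
polydata (tensor glyphs).

Geometry conventions: TIFF pages are Z slices with (Y, X) page axes and are
transposed to the package's (X, Y, Z) array order on read.  The ``.trk``
affine is identity orientation with the TrackVis corner-origin voxel-mm
convention; points are stored in physical µm interpreted as mm.  Every
writer/reader pair is a lossless round trip at the precision of its format.
"""

from __future__ import annotations

import os
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile
from PIL import Image

import nibabel as nib
from nibabel.streamlines import Tractogram
from nibabel.streamlines.trk import TrkFile

from .grids import BinaryMask, LabelVolume, VoxelGrid
from .metrics_maps import RGBMap, ScalarMap, dec_map
from .tensor_field import EigenField, TensorField
from .tractography import Streamline, StreamlineSet

__all__ = [
    "read_volume",
    "write_volume",
    "write_tensor_field",
    "read_tensor_field",
    "write_streamlines",
    "read_streamlines",
    "write_graph",
    "read_graph",
    "export_map",
    "export_glyphs",
]


# ---------------------------------------------------------------------------
# TIFF volumes


def read_volume(path, spacing, origin=(0.0, 0.0, 0.0)) -> VoxelGrid:
    """Read a (multi-page) 3D TIFF into a :class:`VoxelGrid`.

    ``spacing`` (µm per axis, XYZ) is supplied by the caller and overrides
    any file metadata; intensities are passed through unmodified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = tifffile.imread(str(path))
    arr = np.squeeze(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected 3D TIFF content, got shape {arr.shape}")
    data = arr.transpose(2, 1, 0)  # (z, y, x) pages -> (x, y, z)
    return VoxelGrid(data, spacing, origin)


def write_volume(grid: VoxelGrid, path) -> Path:
    """Write a grid as a multi-page TIFF (pages = Z slices)."""
    path = Path(path)
    tifffile.imwrite(str(path), np.ascontiguousarray(grid.data.transpose(2, 1, 0)))
    return path


def as_binary(grid: VoxelGrid) -> BinaryMask:
    return BinaryMask(grid.data != 0, grid.spacing, grid.origin)


def as_labels(grid: VoxelGrid) -> LabelVolume:
    return LabelVolume(grid.data.astype(np.int32), grid.spacing, grid.origin)


# ---------------------------------------------------------------------------
# NRRD tensor fields

_NRRD_COMPONENTS = "xx xy xz yy yz zz count"


def write_tensor_field(field: TensorField, path) -> Path:
    """Write a tensor field as 4D NRRD (first axis: 6 components + count).

    Component order is upper-triangular row-major (xx, xy, xz, yy, yz, zz)
    in µm², followed by the per-window descriptor count N.  Grid spacing is
    the window stride; the window size and descriptor kind are key/value
    header fields.  Raw little-endian doubles, fastest axis first.
    """
    M = field.matrices
    asym = np.abs(M - np.swapaxes(M, -1, -2)).max() if M.size else 0.0
    if asym > 1e-12:
        raise ValueError(f"tensor matrices must be symmetric (max asymmetry {asym:.2e})")
    comp = np.stack(
        [
            M[..., 0, 0], M[..., 0, 1], M[..., 0, 2],
            M[..., 1, 1], M[..., 1, 2], M[..., 2, 2],
            field.counts.astype(float),
        ],
        axis=0,
    )
    sizes = " ".join(str(s) for s in comp.shape)
    sx, sy, sz = field.stride
    ox, oy, oz = field.origin
    header = [
        "NRRD0004",
        "# fmtensor orientation tensor field",
        "type: double",
        "dimension: 4",
        f"sizes: {sizes}",
        "encoding: raw",
        "endian: little",
        "kinds: none domain domain domain",
        "space dimension: 3",
        f"space origin: ({ox:.17g},{oy:.17g},{oz:.17g})",
        f"space directions: none ({sx:.17g},0,0) (0,{sy:.17g},0) (0,0,{sz:.17g})",
        f"window_um:={field.window:.17g}",
        f"min_count:={field.min_count}",
        f"descriptor_kind:={field.kind}",
        f"component_order:={_NRRD_COMPONENTS}",
        "",
    ]
    path = Path(path)
    with open(path, "wb") as f:
        f.write("\n".join(header).encode("ascii"))
        f.write(b"\n")
        f.write(np.asarray(comp, dtype="<f8").tobytes(order="F"))
    return path


def read_tensor_field(path) -> TensorField:
    """Read a tensor field written by :func:`write_tensor_field`."""
    path = Path(path)
    with open(path, "rb") as f:
        raw = f.read()
    head, _, body = raw.partition(b"\n\n")
    fields: dict[str, str] = {}
    for line in head.decode("ascii").splitlines()[1:]:
        if line.startswith("#") or not line.strip():
            continue
        if ":=" in line:
            k, _, v = line.partition(":=")
        else:
            k, _, v = line.partition(":")
        fields[k.strip()] = v.strip()
    sizes = tuple(int(s) for s in fields["sizes"].split())
    if len(sizes) != 4 or sizes[0] != 7:
        raise ValueError(f"not an fmtensor tensor NRRD: sizes {sizes}")
    comp = np.frombuffer(body, dtype="<f8").reshape(sizes, order="F")
    origin = _parse_tuple(fields["space origin"])
    dirs = fields["space directions"].split(") (")
    stride = np.array(
        [
            _parse_tuple(dirs[0].split("(", 1)[1])[0],
            _parse_tuple(dirs[1])[1],
            _parse_tuple(dirs[2].rstrip(")"))[2],
        ]
    )
    shape = sizes[1:]
    M = np.empty(shape + (3, 3))
    xx, xy, xz, yy, yz, zz = (comp[i] for i in range(6))
    M[..., 0, 0], M[..., 0, 1], M[..., 0, 2] = xx, xy, xz
    M[..., 1, 0], M[..., 1, 1], M[..., 1, 2] = xy, yy, yz
    M[..., 2, 0], M[..., 2, 1], M[..., 2, 2] = xz, yz, zz
    return TensorField(
        origin=np.asarray(origin),
        stride=stride,
        window=float(fields["window_um"]),
        matrices=M,
        counts=np.rint(comp[6]).astype(np.int64),
        min_count=int(fields.get("min_count", 2)),
        kind=fields.get("descriptor_kind", "vascular"),
    )


def _parse_tuple(s: str) -> np.ndarray:
    return np.array([float(x) for x in s.strip().strip("()").split(",")])


# ---------------------------------------------------------------------------
# TrackVis streamlines


def _reference_affine(reference: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(reference.spacing)
    aff[:3, 3] = reference.origin
    return aff


def write_streamlines(tracks: StreamlineSet, path, reference: VoxelGrid) -> Path:
    """Write streamlines as TrackVis ``.trk`` v2 (µm treated as mm).

    The header carries the reference grid's dimensions and voxel size with
    an identity-orientation voxel-to-physical affine; nibabel converts the
    physical-space points into TrackVis' corner-origin voxel-mm convention.
    All points must lie inside the reference grid's physical bounds.
    """
    lo, hi = reference.bounds
    pts_list = []
    for s in tracks:
        pts = np.asarray(s.points, dtype=float)
        if not np.isfinite(pts).all():
            raise ValueError("streamline contains NaN/inf points")
        if (pts < lo).any() or (pts > hi).any():
            raise ValueError("streamline point outside the reference volume bounds")
        pts_list.append(pts)
    affine = _reference_affine(reference)
    header = {
        "voxel_to_rasmm": affine.astype(np.float32),
        "voxel_sizes": np.asarray(reference.spacing, dtype=np.float32),
        "dimensions": np.asarray(reference.shape, dtype=np.int16),
        "voxel_order": b"RAS",
    }
    tractogram = Tractogram(pts_list, affine_to_rasmm=np.eye(4))
    TrkFile(tractogram, header).save(str(path))
    return Path(path)


def read_streamlines(path) -> list[np.ndarray]:
    """Load ``.trk`` streamlines back as a list of (m, 3) µm arrays."""
    trk = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=float) for s in trk.tractogram.streamlines]


# ---------------------------------------------------------------------------
# skeleton graphs


def write_graph(graph: nx.MultiGraph, path, dialect: str = "graphml") -> Path:
    """Serialize a skeleton graph (GraphML, or a nodes/edges CSV pair).

    Node attributes: x, y, z (µm) and class; edge attributes: length_um and
    n_slab_voxels.  The in-memory per-edge voxel path is not serialized.
    For ``dialect="csv"`` two files ``<stem>_nodes.csv``/``<stem>_edges.csv``
    are written next to ``path``.
    """
    path = Path(path)
    if dialect == "graphml":
        H = nx.MultiGraph()
        for n, data in graph.nodes(data=True):
            x, y, z = data["position"]
            H.add_node(n, x=float(x), y=float(y), z=float(z), cls=str(data["cls"]))
        for u, v, k, data in graph.edges(keys=True, data=True):
            H.add_edge(
                u, v, key=k,
                length_um=float(data["length_um"]),
                n_slab_voxels=int(data["n_slab_voxels"]),
            )
        nx.write_graphml(H, str(path))
        return path
    if dialect == "csv":
        nodes = pd.DataFrame(
            [
                {
                    "id": n,
                    "x": d["position"][0],
                    "y": d["position"][1],
                    "z": d["position"][2],
                    "cls": d["cls"],
                }
                for n, d in graph.nodes(data=True)
            ]
        )
        edges = pd.DataFrame(
            [
                {
                    "source": u,
                    "target": v,
                    "key": k,
                    "length_um": d["length_um"],
                    "n_slab_voxels": d["n_slab_voxels"],
                }
                for u, v, k, d in graph.edges(keys=True, data=True)
            ]
        )
        nodes.to_csv(path.with_name(path.stem + "_nodes.csv"), index=False)
        edges.to_csv(path.with_name(path.stem + "_edges.csv"), index=False)
        return path
    raise ValueError(f"unknown graph dialect {dialect!r}")


def read_graph(path, dialect: str = "graphml") -> nx.MultiGraph:
    """Read a graph written by :func:`write_graph` back into memory."""
    path = Path(path)
    G = nx.MultiGraph()
    if dialect == "graphml":
        H = nx.read_graphml(str(path), force_multigraph=True)
        for n, d in H.nodes(data=True):
            G.add_node(
                int(n) if str(n).lstrip("-").isdigit() else n,
                position=(float(d["x"]), float(d["y"]), float(d["z"])),
                cls=str(d["cls"]),
            )
        for u, v, k, d in H.edges(keys=True, data=True):
            uu = int(u) if str(u).lstrip("-").isdigit() else u
            vv = int(v) if str(v).lstrip("-").isdigit() else v
            G.add_edge(
                uu, vv,
                length_um=float(d["length_um"]),
                n_slab_voxels=int(d["n_slab_voxels"]),
            )
        return G
    if dialect == "csv":
        nodes = pd.read_csv(path.with_name(path.stem + "_nodes.csv"))
        edges = pd.read_csv(path.with_name(path.stem + "_edges.csv"))
        for _, r in nodes.iterrows():
            G.add_node(int(r["id"]), position=(r["x"], r["y"], r["z"]), cls=str(r["cls"]))
        for _, r in edges.iterrows():
            G.add_edge(
                int(r["source"]), int(r["target"]),
                length_um=float(r["length_um"]),
                n_slab_voxels=int(r["n_slab_voxels"]),
            )
        return G
    raise ValueError(f"unknown graph dialect {dialect!r}")


# ---------------------------------------------------------------------------
# 2D map exports


def export_map(m, path, slice_index: int | None = None, axis: int = 2) -> Path:
    """Export a 2D slice of a scalar or RGB map as PNG.

    Scalar maps become 16-bit grayscale, min–max scaled with the scale
    recorded in a ``<path>.txt`` sidecar; RGB maps become 8-bit colour.
    ``slice_index`` selects the slice along ``axis`` (default Z); it is
    required for 3D maps with more than one slice on that axis.
    """
    path = Path(path)
    values = m.values
    is_rgb = isinstance(m, RGBMap) or (values.ndim == 4 and values.shape[-1] == 3)
    nslices = values.shape[axis]
    if slice_index is None:
        if nslices != 1:
            raise ValueError("slice_index required for 3D maps")
        slice_index = 0
    sl = [slice(None)] * 3
    sl[axis] = slice_index
    plane = values[tuple(sl)]
    # image rows = second remaining axis, columns = first (x horizontal for axis=2)
    if is_rgb:
        img = np.clip(np.nan_to_num(plane), 0.0, 1.0)
        arr = np.round(img.transpose(1, 0, 2) * 255).astype(np.uint8)
        Image.fromarray(arr, mode="RGB").save(path)
        return path
    finite = np.isfinite(plane)
    if not finite.any():
        raise ValueError("all-NaN slice cannot be exported")
    vmin = float(plane[finite].min())
    vmax = float(plane[finite].max())
    scaled = np.zeros_like(plane, dtype=float)
    if vmax > vmin:
        scaled[finite] = (plane[finite] - vmin) / (vmax - vmin)
    arr = np.round(scaled.T * 65535).astype(np.uint16)
    Image.fromarray(arr).save(path)
    with open(str(path) + ".txt", "w") as f:
        f.write(f"min {vmin:.17g}\nmax {vmax:.17g}\n")
    return path


# ---------------------------------------------------------------------------
# VTK glyphs


def _unit_sphere(n_lat: int = 8, n_lon: int = 16):
    """Vertices and quad/tri faces of a UV sphere of radius 1."""
    verts = [(0.0, 0.0, 1.0)]
    for i in range(1, n_lat):
        th = np.pi * i / n_lat
        for j in range(n_lon):
            ph = 2 * np.pi * j / n_lon
            verts.append(
                (np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th))
            )
    verts.append((0.0, 0.0, -1.0))
    faces = []
    ring = lambda i, j: 1 + (i - 1) * n_lon + (j % n_lon)
    for j in range(n_lon):  # top cap
        faces.append((0, ring(1, j), ring(1, j + 1)))
    for i in range(1, n_lat - 1):
        for j in range(n_lon):
            faces.append((ring(i, j), ring(i + 1, j), ring(i + 1, j + 1), ring(i, j + 1)))
    last = len(verts) - 1
    for j in range(n_lon):  # bottom cap
        faces.append((last, ring(n_lat - 1, j + 1), ring(n_lat - 1, j)))
    return np.asarray(verts), faces


def export_glyphs(eigen: EigenField, path, scale: float = 10.0) -> Path:
    """Write tensor-ellipsoid glyphs as legacy ASCII VTK polydata.

    Each valid window becomes an ellipsoid with radii ``scale * sqrt(λi)``
    along the eigenvectors v_i, coloured by the DEC of v1.  ``scale`` is µm
    per unit √λ.  A field with no valid windows yields empty polydata.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    sphere, faces = _unit_sphere()
    centers = eigen.centers()[eigen.valid]
    vals = eigen.eigenvalues[eigen.valid]
    vecs = eigen.eigenvectors[eigen.valid]
    rgb = np.abs(vecs[..., :, 0])
    nv = sphere.shape[0]
    points, polys, colors = [], [], []
    for g in range(centers.shape[0]):
        radii = scale * np.sqrt(np.clip(vals[g], 0.0, None))
        T = vecs[g] @ np.diag(radii)  # columns scaled by ellipsoid radii
        pts = centers[g] + sphere @ T.T
        base = g * nv
        points.append(pts)
        polys.extend(tuple(base + idx for idx in f) for f in faces)
        colors.append(np.tile(rgb[g], (nv, 1)))
    path = Path(path)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("fmtensor tensor-ellipsoid glyphs\n")
        f.write("ASCII\nDATASET POLYDATA\n")
        all_pts = np.concatenate(points) if points else np.zeros((0, 3))
        f.write(f"POINTS {len(all_pts)} float\n")
        for p in all_pts:
            f.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        total = sum(len(f_) + 1 for f_ in polys)
        f.write(f"POLYGONS {len(polys)} {total}\n")
        for face in polys:
            f.write(" ".join([str(len(face))] + [str(i) for i in face]) + "\n")
        f.write(f"POINT_DATA {len(all_pts)}\n")
        f.write("COLOR_SCALARS rgb 3\n")
        all_cols = np.concatenate(colors) if colors else np.zeros((0, 3))
        for c in all_cols:
            f.write(f"{c[0]:.4f} {c[1]:.4f} {c[2]:.4f}\n")
    return path
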