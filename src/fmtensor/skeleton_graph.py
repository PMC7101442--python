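"""Binary mask -> unit-width skeleton -> node/branch graph.

Thinning uses Lee-style 3D medial-axis erosion (scikit-image).  Skeleton
voxels are classified by their number of 26-neighbours among skeleton
voxels: endpoints (<2), slabs (=2) and junctions (>2).  Mutually adjacent
endpoint/junction voxels are merged into one graph node at their centroid;
edges are traced through slab-voxel chains and measure length along the
voxel path in physical µm (anisotropic spacing honoured).
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import morphology

from .grids import STRUCT_26, BinaryMask, VoxelGrid

__all__ = [
    "binarize_baseline",
    "skeletonize",
    "classify_voxels",
    "build_graph",
    "prune_graph",
    "dice",
    "CLASS_BACKGROUND",
    "CLASS_ENDPOINT",
    "CLASS_SLAB",
    "CLASS_JUNCTION",
]

CLASS_BACKGROUND = 0
CLASS_ENDPOINT = 1
CLASS_SLAB = 2
CLASS_JUNCTION = 3

_OFFSETS_26 = np.array(
    [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)], dtype=int
)


def binarize_baseline(
    volume: VoxelGrid, threshold: float, min_object_voxels: int = 0
) -> BinaryMask:
    """Threshold an intensity volume and drop small 26-connected components.

    A deliberately simple baseline segmenter: the tensor-imaging pipeline is
    independent of how masks are produced, so any externally segmented mask
    can be substituted for its output.
    """
    mask = volume.data >= threshold
    if min_object_voxels > 0 and mask.any():
        lab, n = ndimage.label(mask, structure=STRUCT_26)
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_object_voxels
        keep[0] = False
        mask = keep[lab]
    return BinaryMask(mask.astype(np.uint8), volume.spacing, volume.origin)


def skeletonize(mask: BinaryMask) -> BinaryMask:
    """Thin a mask to its unit-width medial axis (Lee-style 3D thinning)."""
    if mask.n_foreground == 0:
        return BinaryMask(np.zeros_like(mask.data), mask.spacing, mask.origin)
    skel = morphology.skeletonize(mask.data.astype(bool), method="lee")
    return BinaryMask(skel.astype(np.uint8), mask.spacing, mask.origin)


def classify_voxels(skeleton: BinaryMask) -> np.ndarray:
    """Per-voxel class map: 0 background, 1 endpoint, 2 slab, 3 junction.

    A skeleton voxel with fewer than 2 of its 26 neighbours on the skeleton
    is an endpoint (isolated voxels included), exactly 2 a slab, more than 2
    a junction.
    """
    skel = skeleton.data.astype(np.uint8)
    kernel = np.ones((3, 3, 3), dtype=np.uint8)
    kernel[1, 1, 1] = 0
    counts = ndimage.convolve(skel, kernel, mode="constant", cval=0)
    classes = np.zeros_like(skel, dtype=np.uint8)
    fg = skel == 1
    classes[fg & (counts < 2)] = CLASS_ENDPOINT
    classes[fg & (counts == 2)] = CLASS_SLAB
    classes[fg & (counts > 2)] = CLASS_JUNCTION
    return classes


def build_graph(skeleton: BinaryMask) -> nx.MultiGraph:
    """Convert a classified skeleton into a node/branch multigraph.

    Nodes carry ``position`` (µm XYZ tuple) and ``cls`` in
    {"endpoint", "junction"}; edges carry ``length_um`` (summed µm steps
    along the voxel path), ``n_slab_voxels`` and ``path`` (ordered µm
    coordinates of the traversed voxels, terminal node voxels included).
    Isolated voxels become endpoint nodes with no edges; a closed slab
    cycle gets one inserted junction node with a self-edge so that every
    slab voxel belongs to exactly one edge path.
    """
    spacing = np.asarray(skeleton.spacing)
    origin = np.asarray(skeleton.origin)
    classes = classify_voxels(skeleton)
    node_mask = (classes == CLASS_ENDPOINT) | (classes == CLASS_JUNCTION)
    node_lab, n_clusters = ndimage.label(node_mask, structure=STRUCT_26)

    G = nx.MultiGraph(spacing=tuple(skeleton.spacing), origin=tuple(skeleton.origin))
    if n_clusters:
        # centroid (µm) and class of every node cluster
        idx = np.argwhere(node_mask)
        labs = node_lab[tuple(idx.T)]
        for cid in range(1, n_clusters + 1):
            vox = idx[labs == cid]
            centroid = origin + vox.mean(axis=0) * spacing
            is_junction = (classes[tuple(vox.T)] == CLASS_JUNCTION).any()
            G.add_node(
                int(cid),
                position=tuple(float(c) for c in centroid),
                cls="junction" if is_junction else "endpoint",
            )

    slab_mask = classes == CLASS_SLAB
    slab_lab, n_chains = ndimage.label(slab_mask, structure=STRUCT_26)
    if n_chains == 0:
        return G

    shape = np.asarray(skeleton.shape)
    comp_voxels: dict[int, list[tuple[int, int, int]]] = {}
    for v in map(tuple, np.argwhere(slab_mask)):
        comp_voxels.setdefault(int(slab_lab[v]), []).append(v)

    next_node = n_clusters + 1
    for cid in range(1, n_chains + 1):
        voxels = sorted(comp_voxels[cid])
        chain = _order_chain(voxels, slab_lab, cid, shape)
        if chain is None:  # closed cycle of slabs: insert one node
            chain = _order_cycle(voxels, slab_lab, cid, shape)
            pos = origin + np.asarray(chain[0]) * spacing
            G.add_node(next_node, position=tuple(map(float, pos)), cls="junction")
            path_vox = [chain[0]] + chain[1:] + [chain[0]]
            _add_edge(G, next_node, next_node, path_vox, 0, spacing, origin, len(chain))
            next_node += 1
            continue
        attach0 = _attached_node_voxel(chain[0], chain[1] if len(chain) > 1 else None,
                                       node_lab, shape)
        attach1 = _attached_node_voxel(chain[-1], chain[-2] if len(chain) > 1 else None,
                                       node_lab, shape, exclude=attach0 if len(chain) == 1 else None)
        path_vox = [attach0] + chain + [attach1]
        n0 = int(node_lab[attach0])
        n1 = int(node_lab[attach1])
        _add_edge(G, n0, n1, path_vox, 0, spacing, origin, len(chain))
    return G


def _add_edge(G, n0, n1, path_vox, key_hint, spacing, origin, n_slab) -> None:
    path = origin + np.asarray(path_vox, dtype=float) * spacing
    steps = np.diff(path, axis=0)
    length = float(np.linalg.norm(steps, axis=1).sum())
    G.add_edge(n0, n1, length_um=length, n_slab_voxels=int(n_slab), path=path)


def _neighbors(v, shape):
    nb = np.asarray(v) + _OFFSETS_26
    ok = ((nb >= 0) & (nb < shape)).all(axis=1)
    return nb[ok]


def _order_chain(voxels, slab_lab, cid, shape):
    """Order a slab component into a path; None if it is a closed cycle."""
    vset = set(voxels)
    adj = {}
    for v in voxels:
        nbs = [tuple(n) for n in _neighbors(v, shape) if tuple(n) in vset]
        adj[v] = nbs
    ends = sorted(v for v, nbs in adj.items() if len(nbs) < 2)
    if not ends:
        return None
    start = ends[0]
    chain = [start]
    prev = None
    cur = start
    while True:
        nxt = [n for n in adj[cur] if n != prev]
        if not nxt:
            break
        prev, cur = cur, nxt[0]
        chain.append(cur)
    return chain


def _order_cycle(voxels, slab_lab, cid, shape):
    vset = set(voxels)
    start = min(voxels)
    chain = [start]
    prev = None
    cur = start
    while True:
        nbs = [tuple(n) for n in _neighbors(cur, shape) if tuple(n) in vset and tuple(n) != prev]
        nxt = next((n for n in sorted(nbs) if n != start), None)
        if nxt is None:
            break
        prev, cur = cur, nxt
        chain.append(cur)
    return chain


def _attached_node_voxel(end, inward, node_lab, shape, exclude=None):
    """The node voxel a chain end attaches to (deterministic choice)."""
    cands = sorted(
        tuple(n) for n in _neighbors(end, shape) if node_lab[tuple(n)] > 0
    )
    if exclude is not None:
        cands = [c for c in cands if c != exclude] or cands
    if not cands:
        raise RuntimeError("slab chain end without an adjacent node voxel")
    return cands[0]


def prune_graph(G: nx.MultiGraph, min_length_um: float) -> nx.MultiGraph:
    """Remove terminal branches shorter than ``min_length_um`` (off by default).

    Only edges with at least one endpoint-class node of degree 1 are
    candidates; orphaned nodes are dropped.
    """
    H = G.copy()
    to_remove = []
    for u, v, k, data in H.edges(keys=True, data=True):
        if data["length_um"] >= min_length_um:
            continue
        for n in (u, v):
            if H.nodes[n]["cls"] == "endpoint" and H.degree(n) == 1:
                to_remove.append((u, v, k))
                break
    H.remove_edges_from(to_remove)
    H.remove_nodes_from([n for n in list(H.nodes) if H.degree(n) == 0 and G.degree(n) > 0])
    return H


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)``; 1.0 when both masks are empty."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = a.n_foreground, b.n_foreground
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)
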