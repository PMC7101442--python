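"""One-command orchestration: phantom -> mask -> skeleton -> graph ->
descriptors -> tensor -> metrics -> tracks.

A :class:`PipelineConfig` carries every stage parameter and is serialized
verbatim into each output directory together with a run log (parameters,
timings, descriptor/track counts), so that a run is reproducible from its
config and seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import volumes_io
from .descriptors import segments_from_graph
from .grids import BinaryMask, VoxelGrid
from .metrics_maps import (
    build_wall_frame,
    dec_map,
    fractional_anisotropy,
    helix_transverse_angles,
    transmural_profile,
    westin_coefficients,
)
from .phantoms import HelicalShellSpec, make_segment_cloud, rasterize_tubes
from .skeleton_graph import binarize_baseline, build_graph, prune_graph, skeletonize
from .tensor_field import compute_tensor_field, eigendecompose
from .tractography import subsample, track

__all__ = ["PipelineConfig", "validate", "run"]

STAGES = ("phantom", "binarize", "skeletonize", "graph", "descriptors",
          "tensor", "metrics", "track")


@dataclass
class PipelineConfig:
    """All stage parameters of the end-to-end pipeline (units: µm, degrees)."""

    seed: int = 0
    stages: tuple = STAGES
    input_path: str | None = None  # TIFF mask/intensity input when phantom is off
    spacing: tuple = (2.0, 2.0, 2.0)

    # phantom stage: a desk-scale helical shell rasterized to a mask
    phantom_inner_radius: float = 50.0
    phantom_outer_radius: float = 110.0
    phantom_height: float = 100.0
    phantom_alpha_epi: float = 60.0
    phantom_alpha_endo: float = 60.0
    phantom_density: float = 2.0e-4
    phantom_segment_length: float = 15.0
    phantom_jitter_deg: float = 5.0
    phantom_tube_radius: float = 4.0

    # baseline binarization (intensity inputs only)
    binarize_threshold: float = 0.5
    binarize_min_object_voxels: int = 0

    prune_below_um: float = 0.0  # optional spur pruning, off by default

    # tensor stage (mesoscale defaults: 90 µm window, 20 µm stride)
    tensor_window: float = 90.0
    tensor_stride: float = 20.0
    tensor_min_count: int = 2

    # wall frame for the helix-angle analysis (defaults follow the phantom)
    wall_axis_point: tuple | None = None
    wall_axis_direction: tuple = (0.0, 0.0, 1.0)
    wall_epi_radius: float | None = None
    wall_endo_radius: float | None = None
    profile_bins: int = 10

    # tractography
    track_eigen_index: int = 1
    track_step: float = 10.0
    track_max_angle: float = 35.0
    track_max_points: int = 2000
    track_subsample_fraction: float = 0.15

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(_plain(dataclasses.asdict(self)), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        kwargs = {}
        for f_ in dataclasses.fields(cls):
            if f_.name in raw:
                v = raw[f_.name]
                kwargs[f_.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def validate(config: PipelineConfig) -> list[str]:
    """List out-of-range or inconsistent parameters without running."""
    v: list[str] = []
    if any(s <= 0 for s in config.spacing):
        v.append("spacing must be strictly positive")
    if config.tensor_stride <= 0 or config.tensor_window <= 0:
        v.append("tensor window and stride must be positive")
    elif config.tensor_stride > config.tensor_window:
        v.append(
            f"tensor stride ({config.tensor_stride}) exceeds window ({config.tensor_window})"
        )
    if config.tensor_min_count < 1:
        v.append("tensor min_count must be >= 1")
    if not 0 < config.track_subsample_fraction <= 1:
        v.append(f"subsample fraction {config.track_subsample_fraction} outside (0, 1]")
    if config.track_step <= 0:
        v.append("tracking step must be positive")
    if not 0 < config.track_max_angle <= 180:
        v.append("tracking max angle must be in (0, 180] degrees")
    if config.track_eigen_index not in (1, 2, 3):
        v.append("eigen index must be 1, 2 or 3")
    if "phantom" in config.stages:
        if not 0 < config.phantom_inner_radius < config.phantom_outer_radius:
            v.append("phantom radii must satisfy 0 < inner < outer")
        if config.phantom_density <= 0:
            v.append("phantom density must be positive")
    elif config.input_path is None:
        v.append("input_path required when the phantom stage is disabled")
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        v.append(f"unknown stages: {sorted(unknown)}")
    return v


def run(config: PipelineConfig, outdir) -> Path:
    """Execute the enabled stages in order, writing every artifact.

    Artifacts (standard formats): ``mask.tif``, ``skel.tif``,
    ``graph.graphml``, ``descriptors.csv``, ``tensor.nrrd``, ``fa.tif``,
    ``dec.png``, ``profile.csv``, ``tracks.trk``, plus ``config.yaml`` and
    ``run_log.json``.  A stage failure aborts with the failing stage named;
    partial outputs are kept.
    """
    problems = validate(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    log: dict = {"stages": {}, "counts": {}}
    state: dict = {}

    def _stage(name, fn):
        if name not in config.stages:
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as e:  # noqa: BLE001 - annotate failing stage
            _write_log(outdir, log)
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
        log["stages"][name] = round(time.perf_counter() - t0, 3)

    def do_phantom():
        spec = HelicalShellSpec(
            inner_radius=config.phantom_inner_radius,
            outer_radius=config.phantom_outer_radius,
            height=config.phantom_height,
            alpha_epi=config.phantom_alpha_epi,
            alpha_endo=config.phantom_alpha_endo,
            density=config.phantom_density,
            segment_length=config.phantom_segment_length,
            jitter_deg=config.phantom_jitter_deg,
        )
        dset, _truth = make_segment_cloud("helical_shell", spec, seed=config.seed)
        margin = config.phantom_tube_radius + 2 * max(config.spacing)
        lo = np.array([-spec.outer_radius - margin] * 2 + [-spec.height / 2 - margin])
        extent = np.array(
            [2 * (spec.outer_radius + margin)] * 2 + [spec.height + 2 * margin]
        )
        shape = tuple(np.ceil(extent / np.asarray(config.spacing)).astype(int))
        mask = rasterize_tubes(
            dset, config.phantom_tube_radius, shape, config.spacing, tuple(lo)
        )
        state["mask"] = mask
        log["counts"]["phantom_segments"] = len(dset)
        volumes_io.write_volume(mask, outdir / "mask.tif")

    def do_binarize():
        if "mask" in state:  # phantom output is already binary
            return
        if config.input_path is None or not Path(config.input_path).exists():
            raise FileNotFoundError(f"input volume not found: {config.input_path}")
        vol = volumes_io.read_volume(config.input_path, config.spacing)
        mask = binarize_baseline(
            vol, config.binarize_threshold, config.binarize_min_object_voxels
        )
        state["mask"] = mask
        volumes_io.write_volume(mask, outdir / "mask.tif")

    def do_skeletonize():
        state["skel"] = skeletonize(state["mask"])
        volumes_io.write_volume(state["skel"], outdir / "skel.tif")

    def do_graph():
        G = build_graph(state["skel"])
        if config.prune_below_um > 0:
            G = prune_graph(G, config.prune_below_um)
        state["graph"] = G
        log["counts"]["graph_nodes"] = G.number_of_nodes()
        log["counts"]["graph_edges"] = G.number_of_edges()
        volumes_io.write_graph(G, outdir / "graph.graphml")

    def do_descriptors():
        dset = segments_from_graph(state["graph"])
        state["descriptors"] = dset
        log["counts"]["descriptors"] = len(dset)
        dset.to_csv(outdir / "descriptors.csv")

    def do_tensor():
        field = compute_tensor_field(
            state["descriptors"],
            window=config.tensor_window,
            stride=config.tensor_stride,
            min_count=config.tensor_min_count,
        )
        state["tensor"] = field
        state["eigen"] = eigendecompose(field)
        log["counts"]["valid_windows"] = int(field.valid.sum())
        volumes_io.write_tensor_field(field, outdir / "tensor.nrrd")

    def do_metrics():
        eigen = state["eigen"]
        fa = fractional_anisotropy(eigen)
        grid = VoxelGrid(
            fa.values.astype(np.float32), tuple(eigen.stride), tuple(eigen.origin)
        )
        volumes_io.write_volume(grid, outdir / "fa.tif")
        cl, cp, cs = westin_coefficients(eigen)
        volumes_io.export_map(
            dec_map(eigen, 1), outdir / "dec.png", slice_index=eigen.shape[2] // 2
        )
        # wall frame defaults follow the phantom geometry
        axis_point = config.wall_axis_point or (0.0, 0.0, 0.0)
        epi = config.wall_epi_radius or config.phantom_outer_radius
        endo = config.wall_endo_radius or config.phantom_inner_radius
        frame = build_wall_frame(
            eigen, axis_point, config.wall_axis_direction, epi, endo
        )
        ha, _ta = helix_transverse_angles(eigen, frame)
        prof = transmural_profile(
            ha, frame, n_bins=config.profile_bins, window=eigen.window
        )
        pd.DataFrame(
            {
                "depth": prof.bin_centers,
                "mean_HA": prof.mean_ha_deg,
                "median_HA": prof.median_ha_deg,
                "count": prof.counts,
            }
        ).to_csv(outdir / "profile.csv", index=False)
        log["counts"]["transmural_span_deg"] = round(prof.span_deg, 3)
        state["frame"] = frame

    def do_track():
        eigen = state["eigen"]
        tracks = track(
            eigen,
            index=config.track_eigen_index,
            step=config.track_step,
            max_angle=config.track_max_angle,
            max_points=config.track_max_points,
        )
        shown = subsample(tracks, config.track_subsample_fraction, seed=config.seed)
        log["counts"]["tracks"] = len(tracks)
        log["counts"]["tracks_displayed"] = len(shown)
        ref = VoxelGrid(
            np.zeros(eigen.shape, dtype=np.uint8),
            tuple(eigen.stride),
            tuple(eigen.origin),
        )
        volumes_io.write_streamlines(shown, outdir / "tracks.trk", ref)

    _stage("phantom", do_phantom)
    _stage("binarize", do_binarize)
    _stage("skeletonize", do_skeletonize)
    _stage("graph", do_graph)
    _stage("descriptors", do_descriptors)
    _stage("tensor", do_tensor)
    _stage("metrics", do_metrics)
    _stage("track", do_track)
    _write_log(outdir, log)
    return outdir


def _write_log(outdir: Path, log: dict) -> None:
    from . import __version__

    log["version"] = __version__
    with open(outdir / "run_log.json", "w") as f:
        json.dump(_plain(log), f, indent=2, sort_keys=True)
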