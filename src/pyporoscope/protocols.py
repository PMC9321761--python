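"""The three analysis protocols as reproducible, logged pipelines.

* pore analysis: median -> Otsu -> erosion/dilation opening -> Basic +
  Blob + Skeleton analysis of the pore phase;
* multiphase separation: k-means -> phase mask -> chamfer distance ->
  negate -> H-minima -> watershed -> connected components -> blob table;
* bone morphometry: (optional Otsu) -> plate-model trabecular indices.

Configuration + input fully determine the output: there is no unseeded
randomness on any path, so re-running a protocol with the same config
yields a byte-identical report.  When an output directory is given, every
intermediate volume is written with a stage-indexed name and all stage
parameters are echoed to a run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .basic import basic_analysis
from .blobs import blob_metrics, export_blob_table
from .morphology import (
    DistanceVolume,
    StructuringElement,
    chamfer_distance,
    dilate,
    erode,
    h_minima,
    label_components,
    watershed,
)
from .morphometry import MorphometryResult, bone_morphometry
from .segmentation import extract_phase_mask, kmeans_segment, median_filter_3d, otsu_threshold
from .skeleton import (
    connectivity_density,
    export_skeleton_graph,
    lkc_skeletonize,
    prune_skeleton,
    skeleton_graph,
)
from .volumes import BinaryVolume, GrayVolume, LabelVolume, crop_voi, write_volume

__all__ = [
    "ProtocolConfig",
    "parse_config_file",
    "run_pore_protocol",
    "run_multiphase_protocol",
    "run_morphometry_protocol",
]

log = logging.getLogger("pyporoscope")


@dataclass
class ProtocolConfig:
    """Stage parameters shared by the three protocols.

    Defaults follow the reference protocol parameter set: median width 3,
    erosion/dilation width 3, pruning length 5 voxels, H-minima depth 4,
    object connectivity 26.
    """

    voi_origin: tuple[int, int, int] | None = None
    voi_shape: tuple[int, int, int] | None = None
    median_width: int = 3
    polarity: str = "above"  # Otsu object side
    se_shape: str = "cube"
    se_width: int = 3
    closing: bool = False  # dilation-first instead of the default opening
    prune_length: float = 5.0
    k: int = 4  # k-means classes (multiphase)
    phase_classes: tuple[int, ...] = ()  # empty -> brightest class
    h: float = 4.0  # H-minima depth
    connectivity: int = 26
    mil_directions: int = 512
    mil_spacing: float = 2.0
    min_voxels: int = 1
    seed: int = 0

    def as_dict(self) -> dict:
        d = asdict(self)
        d["phase_classes"] = list(self.phase_classes)
        return d


_CONFIG_TYPES = {
    "voi_origin": lambda s: tuple(int(v) for v in s.split(",")),
    "voi_shape": lambda s: tuple(int(v) for v in s.split(",")),
    "median_width": int,
    "polarity": str,
    "se_shape": str,
    "se_width": int,
    "closing": lambda s: s.lower() in ("1", "true", "yes"),
    "prune_length": float,
    "k": int,
    "phase_classes": lambda s: tuple(int(v) for v in s.split(",") if v != ""),
    "h": float,
    "connectivity": int,
    "mil_directions": int,
    "mil_spacing": float,
    "min_voxels": int,
    "seed": int,
}


def parse_config_file(path) -> ProtocolConfig:
    """Flat ``key = value`` config dialect; '#' starts a comment."""
    cfg = ProtocolConfig()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        if key not in _CONFIG_TYPES:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        setattr(cfg, key, _CONFIG_TYPES[key](val))
    return cfg


class _Run:
    """Stage logger + numbered intermediate writer."""

    def __init__(self, outdir, name: str):
        self.outdir = Path(outdir) if outdir is not None else None
        self.stage = 0
        self._fh = None
        if self.outdir is not None:
            self.outdir.mkdir(parents=True, exist_ok=True)
            self._fh = open(self.outdir / f"{name}.log", "w")

    def info(self, msg: str) -> None:
        log.info(msg)
        if self._fh is not None:
            self._fh.write(msg + "\n")
            self._fh.flush()

    def save(self, vol, tag: str) -> None:
        self.stage += 1
        if self.outdir is not None:
            write_volume(vol, self.outdir / f"{self.stage:02d}_{tag}.tif")
        self.info(f"stage {self.stage}: {tag}")

    def report(self, report: dict, name: str) -> None:
        if self.outdir is not None:
            with open(self.outdir / name, "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
                fh.write("\n")

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()


def _maybe_crop(vol, cfg: ProtocolConfig):
    if cfg.voi_origin is not None and cfg.voi_shape is not None:
        return crop_voi(vol, cfg.voi_origin, cfg.voi_shape)
    return vol


def _skeleton_report(mask: BinaryVolume, cfg: ProtocolConfig, run: _Run) -> dict:
    skel = lkc_skeletonize(mask)
    run.save(skel, "skeleton")
    pruned = prune_skeleton(skel, cfg.prune_length)
    run.save(pruned, f"skeleton_pruned_{cfg.prune_length:g}")
    graph = skeleton_graph(pruned)
    if run.outdir is not None:
        export_skeleton_graph(
            graph, run.outdir / "skeleton_graph.csv", run.outdir / "skeleton_graph.graphml"
        )
    voi_mm3 = mask.data.size * mask.voxel_volume_mm3
    by_type: dict[str, int] = {}
    for b in graph.branches:
        by_type[b.type] = by_type.get(b.type, 0) + 1
    return {
        "n_skeleton_voxels": int(np.count_nonzero(pruned.data)),
        "n_nodes": len(graph.nodes),
        "n_ends": len(graph.ends),
        "n_branches": len(graph.branches),
        "branches_by_type": by_type,
        "total_branch_length_mm": float(sum(b.length_mm for b in graph.branches)),
        "connectivity_density_per_mm3": connectivity_density(graph, voi_mm3),
    }


def run_pore_protocol(
    gray: GrayVolume, cfg: ProtocolConfig | None = None, outdir=None
) -> dict:
    """Pore analysis pipeline; returns the consolidated report dict.

    The report carries the Basic Analysis block (VV, SV, MV, chi_v, I, EA),
    a blob-table summary (full table written to the output directory, and
    embedded as records), and the skeleton block with connectivity density.
    """
    cfg = cfg or ProtocolConfig()
    run = _Run(outdir, "pore")
    try:
        run.info(f"pore protocol, parameters: {json.dumps(cfg.as_dict(), sort_keys=True)}")
        vol = _maybe_crop(gray, cfg)
        filt = median_filter_3d(vol, cfg.median_width)
        run.save(filt, f"median_{cfg.median_width}")
        seg = otsu_threshold(filt, polarity=cfg.polarity)
        mask = extract_phase_mask(seg, [1])
        run.info(f"otsu threshold: {seg.threshold:g} (polarity {cfg.polarity})")
        run.save(mask, "otsu_mask")
        se = StructuringElement(cfg.se_shape, cfg.se_width)
        first, second = (dilate, erode) if cfg.closing else (erode, dilate)
        mask = second(first(mask, se), se)
        run.save(mask, "closing" if cfg.closing else "opening")

        basic = basic_analysis(
            mask,
            n_directions=cfg.mil_directions,
            line_spacing=cfg.mil_spacing,
            seed=cfg.seed,
        )
        labels = label_components(mask, cfg.connectivity)
        run.save(labels, "components")
        table = blob_metrics(labels, min_voxels=cfg.min_voxels)
        if run.outdir is not None:
            export_blob_table(table, run.outdir / "blobs.csv")
        skel_block = _skeleton_report(mask, cfg, run)

        report = {
            "protocol": "pore",
            "parameters": cfg.as_dict(),
            "input": {"shape": list(vol.shape), "voxel_size_um": vol.voxel_size},
            "otsu_threshold": seg.threshold,
            "basic": {
                "VV": basic.VV,
                "SV_per_mm": basic.SV,
                "MV_per_mm2": basic.MV,
                "chi_v_per_mm3": basic.chi_v,
                "I": basic.I,
                "EA": basic.EA,
            },
            "blobs": {
                "n_blobs": int(len(table)),
                "records": json.loads(table.to_json(orient="records")),
            },
            "skeleton": skel_block,
        }
        run.report(report, "pore_report.json")
        return report
    finally:
        run.close()


def run_multiphase_protocol(
    gray: GrayVolume, cfg: ProtocolConfig | None = None, outdir=None
) -> tuple[LabelVolume, pd.DataFrame, dict]:
    """Grain-separation pipeline: k-means, phase mask, chamfer distance,
    negation, H-minima, watershed, connected-component blob table."""
    cfg = cfg or ProtocolConfig()
    if cfg.k < 2:
        raise ValueError("multiphase protocol needs k >= 2")
    run = _Run(outdir, "multiphase")
    try:
        run.info(
            f"multiphase protocol, parameters: {json.dumps(cfg.as_dict(), sort_keys=True)}"
        )
        vol = _maybe_crop(gray, cfg)
        seg = kmeans_segment(vol, k=cfg.k, seed=cfg.seed)
        run.save(seg.labels, f"kmeans_{cfg.k}")
        run.info(f"k-means centroids: {np.round(seg.centroids, 3).tolist()}")
        classes = cfg.phase_classes or (seg.n_classes - 1,)
        mask = extract_phase_mask(seg, classes)
        run.save(mask, "phase_mask")
        dist = chamfer_distance(mask)
        run.save(BinaryVolume(dist.data > 0, mask.voxel_size), "distance_support")
        relief = DistanceVolume(-dist.data, dist.voxel_size)
        relief = h_minima(relief, cfg.h, connectivity=cfg.connectivity)
        labels = watershed(relief, mask, connectivity=cfg.connectivity)
        run.save(labels, f"watershed_h{cfg.h:g}")
        table = blob_metrics(labels, min_voxels=cfg.min_voxels)
        if run.outdir is not None:
            export_blob_table(table, run.outdir / "blobs.csv")
        report = {
            "protocol": "multiphase",
            "parameters": cfg.as_dict(),
            "input": {"shape": list(vol.shape), "voxel_size_um": vol.voxel_size},
            "kmeans_centroids": seg.centroids.tolist(),
            "phase_classes": list(classes),
            "class_voxel_counts": np.bincount(
                seg.labels.data.ravel(), minlength=seg.n_classes
            ).tolist(),
            "n_objects": int(labels.n_labels),
            "blobs": {
                "n_blobs": int(len(table)),
                "records": json.loads(table.to_json(orient="records")),
            },
        }
        run.report(report, "multiphase_report.json")
        return labels, table, report
    finally:
        run.close()


def run_morphometry_protocol(
    vol: GrayVolume | BinaryVolume, cfg: ProtocolConfig | None = None, outdir=None
) -> tuple[MorphometryResult, dict]:
    """Bone morphometry pipeline; gray input is Otsu-segmented first."""
    cfg = cfg or ProtocolConfig()
    run = _Run(outdir, "morphometry")
    try:
        run.info(
            f"morphometry protocol, parameters: {json.dumps(cfg.as_dict(), sort_keys=True)}"
        )
        vol = _maybe_crop(vol, cfg)
        if isinstance(vol, GrayVolume):
            seg = otsu_threshold(vol, polarity=cfg.polarity)
            run.info(f"otsu threshold: {seg.threshold:g} (polarity {cfg.polarity})")
            mask = extract_phase_mask(seg, [1])
            run.save(mask, "otsu_mask")
        else:
            mask = vol
        result = bone_morphometry(mask)
        report = {
            "protocol": "morphometry",
            "parameters": cfg.as_dict(),
            "input": {"shape": list(mask.shape), "voxel_size_um": mask.voxel_size},
            "indices": result.as_dict(),
        }
        run.report(report, "morphometry_report.json")
        return result, report
    finally:
        run.close()
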