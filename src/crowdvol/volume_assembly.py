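"""Mapping per-subject consensus back into the original volume.

Tiling with overlap means the same structure is seen (and aggregated) in
several subjects; assembly converts subject-local results to global
coordinates, merges duplicate detections across tiles, and fuses per-tile
agreement rasters into a volume-level consensus mask.  Overlap fusion takes
the mean agreement of all covering tiles and thresholds at 0.5, keeping the
"half or more" semantics across tiles.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from PIL import Image

from .consensus_contours import ConsensusSegmentation
from .consensus_points import ObjectDetection, dbscan
from .subject_builder import TileSpec, TilingSchema
from .volume_io import ImageVolume, to_uint8

__all__ = [
    "VolumeConsensus",
    "mark_to_global",
    "dedupe_detections",
    "fuse_masks",
    "export_mask_volume",
    "export_training_pairs",
]


@dataclass
class VolumeConsensus:
    """Volume-level consensus: mask, per-voxel tile coverage, mean agreement."""

    mask: np.ndarray        # bool (z, y, x)
    coverage: np.ndarray    # int (z, y, x): number of covering tiles
    agreement: np.ndarray   # float (z, y, x): mean agreement over covering tiles


def mark_to_global(
    local_xy: tuple[float, float],
    spec: TileSpec,
    schema: TilingSchema,
    metadata: dict,
    frame_index: int | None = None,
) -> tuple[tuple[float, float, float], bool]:
    """Subject-local mark -> global (x, y, z); flags marks landing in padding.

    (x, y) = tile origin + local − padding;
    z = subject z + (frame_index − annotation_frame_index) · z_stride.
    Returns (position, inside_original).  Marks in the padding band are
    flagged so assembly can exclude them.
    """
    u, v = local_xy
    x = spec.x0 + u - schema.pad_x
    y = spec.y0 + v - schema.pad_y
    anno_idx = int(metadata.get("annotation_frame_index", 0))
    z_stride = int(metadata.get("z_stride", 1))
    fi = anno_idx if frame_index is None else int(frame_index)
    z = float(metadata["z"]) + (fi - anno_idx) * z_stride
    inside = 0 <= x < schema.original_width and 0 <= y < schema.original_height
    return (float(x), float(y), float(z)), inside


def dedupe_detections(
    detections: Sequence[ObjectDetection],
    merge_radius: float,
    anisotropy: float = 1.0,
) -> list[ObjectDetection]:
    """Merge duplicate detections of one object found in overlapping tiles.

    Detections within ``merge_radius`` of each other (anisotropy-scaled z,
    min_samples = 1 so nothing is discarded) collapse to one object with a
    support-weighted mean centroid, summed support, and the label winning
    the support-weighted vote.  Invariant to tile processing order.
    """
    detections = list(detections)
    if not detections:
        return []
    order = np.argsort([d.object_id for d in detections], kind="stable")
    detections = [detections[i] for i in order]
    pts = np.array(
        [(d.centroid[0], d.centroid[1], anisotropy * d.centroid[2]) for d in detections]
    )
    labels = dbscan(pts, eps=merge_radius, min_samples=1)
    merged: list[ObjectDetection] = []
    for cluster in sorted(set(labels)):
        group = [d for d, lab in zip(detections, labels) if lab == cluster]
        weights = np.array([d.support for d in group], dtype=np.float64)
        centroids = np.array([d.centroid for d in group])
        centroid = tuple(float(v) for v in (centroids * weights[:, None]).sum(0) / weights.sum())
        label_weight: dict[str, float] = {}
        for d in group:
            if d.label is not None:
                label_weight[d.label] = label_weight.get(d.label, 0.0) + d.support
        label = None
        agreement = None
        if label_weight:
            top = max(label_weight.values())
            label = sorted(k for k, v in label_weight.items() if v == top)[0]
            agreement = top / sum(label_weight.values())
        members = [m for d in group for m in d.members]
        merged.append(
            ObjectDetection(
                object_id=f"vol{len(merged):04d}",
                centroid=centroid,
                support=int(sum(d.support for d in group)),
                members=members,
                label=label,
                label_agreement=agreement,
            )
        )
    return merged


def fuse_masks(
    segmentations: Sequence[tuple[ConsensusSegmentation, dict]],
    schema: TilingSchema,
    depth: int,
) -> VolumeConsensus:
    """Fuse per-subject consensus rasters into the original volume frame.

    Each item pairs a subject's ConsensusSegmentation with its metadata
    (needs x, y anchor in original coordinates — negative inside the padding
    band — and z).  Per voxel the agreement fractions of all covering tiles
    are averaged; the final mask keeps voxels with mean agreement >= 0.5.
    Tile pixels in the padding band are discarded; a subject mapping outside
    the volume beyond its padding is an error.
    """
    H, W = schema.original_height, schema.original_width
    agreement_sum = np.zeros((depth, H, W), dtype=np.float64)
    coverage = np.zeros((depth, H, W), dtype=np.int32)
    for seg, meta in segmentations:
        th, tw = seg.agreement.shape
        x_off, y_off, z = int(meta["x"]), int(meta["y"]), int(meta["z"])
        if not 0 <= z < depth:
            raise ValueError(f"subject at z={z} outside volume depth {depth}")
        if x_off + tw < 0 or x_off > W or y_off + th < 0 or y_off > H:
            raise ValueError(
                f"subject anchored at ({x_off}, {y_off}) maps entirely outside the volume"
            )
        sx_lo, sx_hi = max(x_off, 0), min(x_off + tw, W)
        sy_lo, sy_hi = max(y_off, 0), min(y_off + th, H)
        agreement_sum[z, sy_lo:sy_hi, sx_lo:sx_hi] += seg.agreement[
            sy_lo - y_off : sy_hi - y_off, sx_lo - x_off : sx_hi - x_off
        ]
        coverage[z, sy_lo:sy_hi, sx_lo:sx_hi] += 1
    with np.errstate(invalid="ignore"):
        mean_agreement = np.where(coverage > 0, agreement_sum / np.maximum(coverage, 1), 0.0)
    mask = (mean_agreement >= 0.5) & (coverage >= 1)
    return VolumeConsensus(mask=mask, coverage=coverage, agreement=mean_agreement)


def export_mask_volume(vc: VolumeConsensus, path: str | Path) -> None:
    """Write the consensus mask as a multi-page TIFF aligned to the source volume."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, vc.mask.astype(np.uint8) * 255, photometric="minisblack")


def export_training_pairs(volume: ImageVolume, vc: VolumeConsensus, out_dir: str | Path) -> Path:
    """Write per-slice image/mask PNG pairs plus a CSV index, for model training.

    Returns the index path; the index has one row per slice.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    if vc.mask.shape != volume.voxels.shape:
        raise ValueError("mask volume does not match image volume dimensions")
    index = out_dir / "training_index.csv"
    with open(index, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["z", "image", "mask"])
        for z in range(volume.depth):
            img_name = f"images/slice_{z:04d}.png"
            mask_name = f"masks/slice_{z:04d}.png"
            Image.fromarray(to_uint8(volume.voxels[z]), mode="L").save(out_dir / img_name)
            Image.fromarray(vc.mask[z].astype(np.uint8) * 255, mode="L").save(out_dir / mask_name)
            w.writerow([z, img_name, mask_name])
    return index
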