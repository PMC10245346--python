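"""Synthetic phantoms and simulated volunteers.

Real projects collect classifications from thousands of volunteers; this
module stands in for them so every pipeline stage can be exercised without
any download.  A phantom is a noisy volume containing bright ellipsoidal
objects with known per-slice boundary polygons, centroids and class labels.
The volunteer model reproduces the error modes seen in practice: contour
vertices jittered radially, centre marks jittered in-plane on the annotated
slice, occasional missed objects, spurious marks away from any object,
wrong answers to label questions, and outright spam annotations placed
elsewhere in the frame.

Determinism: every draw comes from a substream keyed by
(seed, volunteer index, subject key), so adding volunteers or subjects
never perturbs the annotations already generated — simulated datasets are
stable regression fixtures.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon, box

from .consensus_contours import (
    ClosedLoop,
    ClosureReject,
    close_polyline,
    cria_consensus,
    default_gap_tolerance,
    mask_iou,
    rasterize_interior,
    remove_outlier_annotations,
)
from .consensus_points import MarkRecord, aggregate_points
from .export_parser import Answer, Classification, FreehandLine, PointMark
from .subject_builder import TilingSchema, plan_tiles, volume_to_tile
from .volume_io import ImageVolume
from . import volume_assembly

__all__ = [
    "PhantomObject",
    "Phantom",
    "VolunteerModel",
    "make_phantom",
    "simulate_contour",
    "simulate_marks",
    "simulate_answers",
    "write_export",
    "contour_recovery_experiment",
    "point_recovery_experiment",
    "end_to_end_experiment",
]


@dataclass
class PhantomObject:
    object_id: str
    centroid: tuple[float, float, float]  # (x, y, z)
    radius: float
    label: str
    boundaries: dict  # z -> (n, 2) closed polygon vertices


@dataclass
class Phantom:
    volume: ImageVolume
    objects: list[PhantomObject]
    seed: int


@dataclass(frozen=True)
class VolunteerModel:
    """Behavioural parameters of a simulated contributor pool.

    Defaults: five volunteers, 1 px jitter on contours and points, no spam,
    no missed objects, 80% answer accuracy.  Spam annotations, when enabled,
    are emitted closed half the time (``spam_closed_fraction``) so both the
    closure-rejection path and the IoU outlier-removal path get exercised.
    """

    n_volunteers: int = 5
    contour_jitter_sigma: float = 1.0
    point_jitter_sigma: float = 1.0
    spam_rate: float = 0.0
    miss_rate: float = 0.0
    answer_accuracy: float = 0.8
    spam_closed_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spam_rate", "miss_rate", "answer_accuracy", "spam_closed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.contour_jitter_sigma < 0 or self.point_jitter_sigma < 0:
            raise ValueError("jitter sigmas must be >= 0")


def _subject_key(subject: str | int) -> int:
    if isinstance(subject, int):
        return subject & 0x7FFFFFFF
    return zlib.crc32(subject.encode("utf-8")) & 0x7FFFFFFF


def _rng(model: VolunteerModel, volunteer_index: int, subject: str | int, tag: str) -> np.random.Generator:
    """One independent substream per (seed, volunteer, subject, purpose)."""
    return np.random.default_rng(
        [model.seed & 0x7FFFFFFF, int(volunteer_index), _subject_key(subject), zlib.crc32(tag.encode()) & 0x7FFFFFFF]
    )


def _circle_polygon(cx: float, cy: float, r: float, n_vertices: int = 32) -> np.ndarray:
    theta = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
    pts = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    return np.vstack([pts, pts[:1]])


def make_phantom(
    depth: int,
    height: int,
    width: int,
    n_objects: int,
    radius_range: tuple[float, float] = (4.0, 8.0),
    noise_sigma: float = 0.05,
    seed: int = 0,
    min_separation: float = 4.0,
    labels: Sequence[str] = ("alpha", "beta"),
) -> Phantom:
    """Render a noisy volume with bright, non-overlapping ellipsoidal objects.

    Objects are packed by rejection sampling with a margin of radius + 2
    from every face (they never touch the boundary); centre-to-centre
    distance exceeds the radius sum plus ``min_separation``.  Ground-truth
    boundary polygons are stored for every slice an object intersects.
    Infeasible packings fail after bounded retries.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x9A17])
    r_lo, r_hi = radius_range
    centres: list[tuple[float, float, float]] = []
    radii: list[float] = []
    attempts = 0
    while len(centres) < n_objects:
        attempts += 1
        if attempts > 2000 * max(n_objects, 1):
            raise RuntimeError(
                f"could not pack {n_objects} objects of radius {radius_range} into "
                f"({depth}, {height}, {width}) after {attempts} attempts"
            )
        r = float(rng.uniform(r_lo, r_hi))
        margin = r + 2.0
        if 2 * margin >= min(depth, height, width):
            raise ValueError("volume too small for requested radii")
        cx = float(rng.uniform(margin, width - margin))
        cy = float(rng.uniform(margin, height - margin))
        cz = float(rng.uniform(margin, depth - margin))
        ok = all(
            math.dist((cx, cy, cz), c) > r + rr + min_separation
            for c, rr in zip(centres, radii)
        )
        if ok:
            centres.append((cx, cy, cz))
            radii.append(r)

    zz, yy, xx = np.meshgrid(
        np.arange(depth) + 0.5, np.arange(height) + 0.5, np.arange(width) + 0.5, indexing="ij"
    )
    vol = rng.normal(0.25, noise_sigma, size=(depth, height, width))
    objects: list[PhantomObject] = []
    for k, ((cx, cy, cz), r) in enumerate(zip(centres, radii)):
        d2 = ((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2) / (r * r)
        vol += 0.6 * np.exp(-(d2**2))
        boundaries = {}
        for z in range(depth):
            dz = (z + 0.5) - cz
            if abs(dz) >= r:
                continue
            r_z = math.sqrt(r * r - dz * dz)
            if r_z < 1.5:
                continue
            boundaries[z] = _circle_polygon(cx, cy, r_z)
        objects.append(
            PhantomObject(
                object_id=f"truth{k:03d}",
                centroid=(cx, cy, cz),
                radius=r,
                label=str(rng.choice(list(labels))),
                boundaries=boundaries,
            )
        )
    vol = ndimage.gaussian_filter(vol, sigma=0.5)
    return Phantom(volume=ImageVolume(np.clip(vol, 0, 1) * 255.0), objects=objects, seed=seed)


def truth_mask_volume(phantom: Phantom) -> np.ndarray:
    """Rasterized ground-truth mask volume from the per-slice boundary polygons."""
    depth, height, width = phantom.volume.voxels.shape
    mask = np.zeros((depth, height, width), dtype=bool)
    for obj in phantom.objects:
        for z, poly in obj.boundaries.items():
            mask[z] |= rasterize_interior(ClosedLoop(poly), width, height)
    return mask


def _spam_stroke(
    rng: np.random.Generator,
    avoid_bbox: tuple[float, float, float, float],
    frame_w: float,
    frame_h: float,
    closed: bool,
) -> np.ndarray:
    """A scribble placed in the frame corner farthest from the avoided bbox."""
    x_lo, y_lo, x_hi, y_hi = avoid_bbox
    cx, cy = (x_lo + x_hi) / 2, (y_lo + y_hi) / 2
    corner_x = 0.0 if cx > frame_w / 2 else frame_w
    corner_y = 0.0 if cy > frame_h / 2 else frame_h
    span = min(frame_w, frame_h) * 0.12
    base_x = corner_x + (span if corner_x == 0 else -span)
    base_y = corner_y + (span if corner_y == 0 else -span)
    if closed:
        r = max(2.0, span / 2)
        poly = _circle_polygon(base_x, base_y, r, n_vertices=10)
        return poly + rng.normal(0, 0.5, size=poly.shape)
    n = 6
    steps = rng.normal(0, span / 3, size=(n, 2))
    return np.array([base_x, base_y]) + np.cumsum(steps, axis=0)


def simulate_contour(
    truth_polygon: np.ndarray,
    model: VolunteerModel,
    volunteer_index: int,
    subject: str | int = 0,
    frame_shape: tuple[int, int] | None = None,
) -> FreehandLine:
    """One volunteer's freehand outline of a truth boundary (or spam).

    With probability ``spam_rate`` the stroke is a scribble placed away from
    the truth polygon's bounding box (closed with probability
    ``spam_closed_fraction``, otherwise an open polyline that will fail
    closure).  Otherwise the truth boundary is re-drawn with per-vertex
    radial Gaussian noise, and with probability 0.5 a small endpoint gap is
    left — as real freehand strokes do — to exercise loop closure.
    """
    rng = _rng(model, volunteer_index, subject, "contour")
    v = np.asarray(truth_polygon, dtype=np.float64)
    x_lo, y_lo = v.min(axis=0)
    x_hi, y_hi = v.max(axis=0)
    if frame_shape is None:
        frame_h = frame_w = float(max(x_hi, y_hi) * 1.5 + 10)
    else:
        frame_h, frame_w = float(frame_shape[0]), float(frame_shape[1])
    if rng.random() < model.spam_rate:
        closed = rng.random() < model.spam_closed_fraction
        pts = _spam_stroke(rng, (x_lo, y_lo, x_hi, y_hi), frame_w, frame_h, closed)
        return FreehandLine("T0", tuple((float(x), float(y)) for x, y in pts))
    centre = v[:-1].mean(axis=0)
    radial = v[:-1] - centre
    norms = np.maximum(np.linalg.norm(radial, axis=1), 1e-9)
    noise = rng.normal(0.0, model.contour_jitter_sigma, size=len(radial))
    jittered = v[:-1] + (radial / norms[:, None]) * noise[:, None]
    if rng.random() < 0.5:
        pts = jittered  # open: endpoint gap of one edge length, within closure tolerance
    else:
        pts = np.vstack([jittered, jittered[:1]])
    return FreehandLine("T0", tuple((float(x), float(y)) for x, y in pts))


def simulate_marks(
    objects: Sequence[PhantomObject],
    model: VolunteerModel,
    volunteer_index: int,
    bounds: tuple[int, int, int],
    subject: str | int = 0,
) -> list[tuple[float, float, float]]:
    """One volunteer's centre marks in volume coordinates, plus spurious marks.

    Each object is skipped with probability ``miss_rate``, otherwise marked
    with in-plane Gaussian jitter on the slice containing its centre: marks
    are drawn on a 2D canvas and the export format carries z only as an
    integer frame index, so z takes the voxel-centre value floor(cz) + 0.5
    rather than a continuous jitter.  Spurious marks are Poisson-distributed
    with mean ``spam_rate · n_objects``, placed uniformly but away from
    every true object.
    """
    rng = _rng(model, volunteer_index, subject, "marks")
    depth, height, width = bounds
    marks: list[tuple[float, float, float]] = []
    for obj in objects:
        if rng.random() < model.miss_rate:
            continue
        jitter = rng.normal(0.0, model.point_jitter_sigma, size=2)
        marks.append(
            (
                float(obj.centroid[0] + jitter[0]),
                float(obj.centroid[1] + jitter[1]),
                math.floor(obj.centroid[2]) + 0.5,
            )
        )
    n_spurious = int(rng.poisson(model.spam_rate * len(objects)))
    max_r = max((o.radius for o in objects), default=0.0)
    for _ in range(n_spurious):
        for _attempt in range(200):
            p = (
                float(rng.uniform(0, width)),
                float(rng.uniform(0, height)),
                float(rng.uniform(0, depth)),
            )
            if all(math.dist(p, o.centroid) > 2.5 * max_r + 5.0 for o in objects):
                marks.append(p)
                break
    return marks


def simulate_answers(
    true_label: str,
    labels: Sequence[str],
    model: VolunteerModel,
    volunteer_index: int,
    subject: str | int = 0,
) -> Answer:
    """True label with probability ``answer_accuracy``, else uniform over wrong labels."""
    rng = _rng(model, volunteer_index, subject, "answer")
    wrong = [l for l in labels if l != true_label]
    if not wrong or rng.random() < model.answer_accuracy:
        return Answer("T1", true_label)
    return Answer("T1", str(wrong[rng.integers(len(wrong))]))


# ---------------------------------------------------------------------------
# Export writing (the parser's dialect)

def _annotation_payload(ann) -> dict:
    if isinstance(ann, Answer):
        return {"task": ann.task_id, "value": ann.choice}
    if isinstance(ann, PointMark):
        return {"task": ann.task_id, "value": {"x": ann.x, "y": ann.y, "frame": ann.frame_index}}
    if isinstance(ann, FreehandLine):
        return {
            "task": ann.task_id,
            "value": {
                "points": [{"x": x, "y": y} for x, y in ann.vertices],
                "frame": ann.frame_index,
            },
        }
    # EllipseMark
    return {
        "task": ann.task_id,
        "value": {
            "x": ann.x,
            "y": ann.y,
            "rx": ann.rx,
            "ry": ann.ry,
            "angle": ann.angle,
            "frame": ann.frame_index,
        },
    }


def write_export(classifications: Sequence[Classification], path: str | Path) -> None:
    """Write classifications as a CSV export in the parser's dialect.

    ``parse_classifications(write_export(x)) == x``: contributor ids are
    already pseudonymous, so ingest keeps them stable.
    """
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = []
    for c in classifications:
        records.append(
            {
                "classification_id": c.classification_id,
                "user_name": c.contributor_id,
                "workflow_id": c.workflow_id,
                "workflow_version": c.workflow_version,
                "created_at": c.created_at,
                "annotations": json.dumps([_annotation_payload(a) for a in c.annotations]),
                "subject_data": "{}",
                "subject_ids": c.subject_id,
            }
        )
    columns = [
        "classification_id",
        "user_name",
        "workflow_id",
        "workflow_version",
        "created_at",
        "annotations",
        "subject_data",
        "subject_ids",
    ]
    pd.DataFrame.from_records(records, columns=columns).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Recovery experiments (shared by the test suite, the CLI and the
# acceptance script)

def _volunteer_masks(
    truth_polygon: np.ndarray,
    model: VolunteerModel,
    frame: int,
    subject: str | int,
    spam_indices: Sequence[int] = (),
) -> list[np.ndarray]:
    """Closable volunteer strokes for one truth boundary, rasterized per contributor."""
    tol = default_gap_tolerance(frame, frame)
    masks = []
    for v in range(model.n_volunteers):
        m = replace(model, spam_rate=1.0) if v in spam_indices else model
        line = simulate_contour(truth_polygon, m, v, subject, frame_shape=(frame, frame))
        loop = close_polyline(np.asarray(line.vertices), tol, contributor_id=f"vol{v}")
        if isinstance(loop, ClosureReject):
            continue
        masks.append(rasterize_interior(loop, frame, frame))
    return masks


def contour_recovery_experiment(
    seed: int,
    n_volunteers: int = 5,
    jitter_sigma: float = 1.0,
    spam_indices: Sequence[int] = (),
    outlier_removal: bool = False,
    frame: int = 64,
    radius: float = 18.0,
) -> dict:
    """Consensus-vs-truth IoU for one simulated contour-drawing subject."""
    truth = _circle_polygon(frame / 2, frame / 2, radius, n_vertices=40)
    truth_mask = rasterize_interior(ClosedLoop(truth), frame, frame)
    model = VolunteerModel(
        n_volunteers=n_volunteers, contour_jitter_sigma=jitter_sigma, seed=seed
    )
    masks = _volunteer_masks(truth, model, frame, subject="contour-recovery", spam_indices=spam_indices)
    if outlier_removal and len(masks) >= 2:
        consensus, _ = remove_outlier_annotations(masks)
    else:
        consensus = cria_consensus(masks)
    return {
        "iou": mask_iou(consensus.mask, truth_mask),
        "n_annotations": consensus.n_annotations,
        "n_excluded": len(consensus.excluded),
    }


def _match_detections(truth_objects, detections, match_radius: float = 3.0) -> dict:
    errors = []
    matched = set()
    for obj in truth_objects:
        dists = [
            (math.dist(obj.centroid, d.centroid), i) for i, d in enumerate(detections)
        ]
        if not dists:
            errors.append(math.inf)
            continue
        dist, i = min(dists)
        if dist <= match_radius:
            matched.add(i)
            errors.append(dist)
        else:
            errors.append(math.inf)
    n_recovered = sum(1 for e in errors if math.isfinite(e))
    return {
        "n_true": len(truth_objects),
        "n_detected": len(detections),
        "n_recovered": n_recovered,
        "n_spurious": len(detections) - len(matched),
        "max_centroid_error": max((e for e in errors if math.isfinite(e)), default=math.nan),
    }


def point_recovery_experiment(
    seed: int,
    n_volunteers: int = 10,
    jitter_sigma: float = 1.0,
    spurious_rate: float = 0.2,
    n_objects: int = 4,
    shape: tuple[int, int, int] = (28, 96, 96),
    eps: float = 5.0,
    min_samples: int | None = None,
) -> dict:
    """Object recovery from clustered point marks on one phantom."""
    phantom = make_phantom(
        *shape, n_objects=n_objects, radius_range=(4.0, 6.0), seed=seed, min_separation=22.0
    )
    model = VolunteerModel(
        n_volunteers=n_volunteers,
        point_jitter_sigma=jitter_sigma,
        spam_rate=spurious_rate,
        seed=seed,
    )
    if min_samples is None:
        min_samples = math.ceil(n_volunteers / 2)
    marks: list[MarkRecord] = []
    for v in range(model.n_volunteers):
        for x, y, z in simulate_marks(phantom.objects, model, v, shape, subject="point-recovery"):
            marks.append(MarkRecord(f"vol{v}", "s0", (x, y, z)))
    detections = aggregate_points(marks, eps=eps, min_samples=min_samples)
    return _match_detections(phantom.objects, detections)


def _clipped_truth_loops(obj_poly: np.ndarray, spec, schema: TilingSchema):
    """Intersect a truth polygon (original coords) with a tile's original footprint."""
    x_lo = spec.x0 - schema.pad_x
    y_lo = spec.y0 - schema.pad_y
    tile_box = box(
        max(x_lo, 0),
        max(y_lo, 0),
        min(x_lo + spec.tile_width, schema.original_width),
        min(y_lo + spec.tile_height, schema.original_height),
    )
    poly = Polygon(obj_poly[:-1])
    if not poly.is_valid:
        poly = poly.buffer(0)
    inter = poly.intersection(tile_box)
    pieces = []
    geoms = getattr(inter, "geoms", [inter])
    for g in geoms:
        if g.is_empty or g.area < 2.0 or g.geom_type != "Polygon":
            continue
        coords = np.asarray(g.exterior.coords)
        pieces.append(coords)
    return pieces


def end_to_end_experiment(
    seed: int,
    n_objects: int = 2,
    shape: tuple[int, int, int] = (26, 56, 56),
    tile: int = 32,
    model: VolunteerModel | None = None,
    eps: float = 5.0,
) -> dict:
    """Phantom -> overlapping tile subjects -> simulated volunteers -> aggregation -> assembly.

    Volunteers outline each object's slice boundary clipped to each tile's
    footprint and mark object centres on the centroid slice of each covering
    tile; contour consensus rasters are fused back into the volume frame and
    per-tile detections merged across the overlap.  Returns volume-mask IoU
    and detection recovery statistics against the phantom ground truth.
    """
    depth, height, width = shape
    if model is None:
        model = VolunteerModel(seed=seed)
    else:
        model = replace(model, seed=seed)
    phantom = make_phantom(
        depth, height, width, n_objects=n_objects, radius_range=(6.5, 8.0),
        seed=seed, min_separation=12.0,
    )
    schema = plan_tiles(width, height, tile, tile, overlap_fraction=0.5)
    truth_vol = truth_mask_volume(phantom)
    tol = default_gap_tolerance(tile, tile)

    segmentations = []
    all_detections = []
    min_samples = math.ceil(model.n_volunteers / 2)
    annotated_z = sorted({z for obj in phantom.objects for z in obj.boundaries})
    for z in range(depth):
        for spec in schema.tiles:
            subject_id = f"s_z{z:04d}_{spec.tile_id}"
            meta = {
                "x": spec.x0 - schema.pad_x,
                "y": spec.y0 - schema.pad_y,
                "z": z,
                "annotation_frame_index": 0,
                "z_stride": 1,
            }
            # contour task: each volunteer outlines every clipped truth piece
            masks = []
            if z in annotated_z:
                pieces = [
                    piece
                    for obj in phantom.objects
                    if z in obj.boundaries
                    for piece in _clipped_truth_loops(obj.boundaries[z], spec, schema)
                ]
            else:
                pieces = []
            for v in range(model.n_volunteers):
                contributor_mask = np.zeros((tile, tile), dtype=bool)
                for p_idx, piece in enumerate(pieces):
                    local = np.array(
                        [volume_to_tile(spec, schema, x, y) for x, y in piece]
                    )
                    line = simulate_contour(
                        local, model, v, subject=f"{subject_id}#{p_idx}", frame_shape=(tile, tile)
                    )
                    loop = close_polyline(np.asarray(line.vertices), tol)
                    if isinstance(loop, ClosureReject):
                        continue
                    contributor_mask |= rasterize_interior(loop, tile, tile)
                masks.append(contributor_mask)
            segmentations.append((cria_consensus(masks), meta))

            # point task: mark each object whose centroid slice is this z and
            # whose centre lies inside the tile's original footprint
            tile_marks: list[MarkRecord] = []
            for obj in phantom.objects:
                cx, cy, cz = obj.centroid
                if int(cz) != z:  # the voxel slice containing the centroid
                    continue
                gx_lo, gy_lo = spec.x0 - schema.pad_x, spec.y0 - schema.pad_y
                if not (gx_lo + 2 <= cx < gx_lo + tile - 2 and gy_lo + 2 <= cy < gy_lo + tile - 2):
                    continue
                for v in range(model.n_volunteers):
                    rng = _rng(model, v, f"{subject_id}:{obj.object_id}", "marks")
                    if rng.random() < model.miss_rate:
                        continue
                    jit = rng.normal(0.0, model.point_jitter_sigma, size=2)
                    u, vv = volume_to_tile(spec, schema, cx + jit[0], cy + jit[1])
                    (gpos, inside) = volume_assembly.mark_to_global((u, vv), spec, schema, meta)
                    if inside:
                        # z at the voxel centre of the annotated slice
                        tile_marks.append(
                            MarkRecord(f"vol{v}", subject_id, (gpos[0], gpos[1], gpos[2] + 0.5))
                        )
            if tile_marks:
                all_detections.extend(
                    aggregate_points(tile_marks, eps=eps, min_samples=min_samples)
                )

    vc = volume_assembly.fuse_masks(segmentations, schema, depth)
    merged = volume_assembly.dedupe_detections(all_detections, merge_radius=eps)
    stats = _match_detections(phantom.objects, merged)
    stats["mask_iou"] = mask_iou(vc.mask, truth_vol)
    return stats


# ---------------------------------------------------------------------------
# Self-contained simulated datasets (the CLI `simulate` presets)

def _timestamps(n: int) -> list[str]:
    base = pd.Timestamp("2024-01-01T00:00:00Z")
    return [(base + pd.Timedelta(seconds=i)).isoformat() for i in range(n)]


def _contributor(v: int) -> str:
    from .export_parser import pseudonymize

    return pseudonymize(f"volunteer-{v}")


def write_preset(preset: str, seed: int, out_dir: str | Path, n_volunteers: int = 5) -> Path:
    """Write a self-contained simulated dataset directory for one preset.

    Presets: ``questions`` (answer votes + truth labels), ``points``
    (phantom + centre marks), ``contours`` (phantom + freehand outlines),
    ``end2end`` (phantom + overlapping tile subjects with both tasks, plus
    the tiling parameters needed for reassembly).  Every preset writes
    ``export.csv`` in the parser's dialect and ground-truth files.
    """
    import json

    from .subject_builder import Subject, write_manifest
    from .volume_io import write_volume
    import tifffile
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = VolunteerModel(n_volunteers=n_volunteers, spam_rate=0.2, seed=seed)
    classifications: list[Classification] = []
    cid = 0

    def add_row(contributor_v: int, subject_id: str, annotations: list) -> None:
        nonlocal cid
        classifications.append(
            Classification(
                classification_id=f"c{cid:06d}",
                contributor_id=_contributor(contributor_v),
                subject_id=subject_id,
                workflow_id="wf1",
                workflow_version="2.10",
                created_at="",  # filled below so timestamps increase
                annotations=annotations,
            )
        )
        cid += 1

    if preset == "questions":
        labels = ("alpha", "beta", "gamma")
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x51])
        truth = {f"q{k:03d}": str(rng.choice(labels)) for k in range(8)}
        for subject_id, true_label in truth.items():
            for v in range(n_volunteers):
                add_row(v, subject_id, [simulate_answers(true_label, labels, model, v, subject_id)])
        pd.DataFrame(
            [{"subject_id": s, "true_label": t} for s, t in truth.items()]
        ).to_csv(out / "truth_labels.csv", index=False)
    elif preset in ("points", "contours"):
        if preset == "points":
            shape = (28, 96, 96)
            phantom = make_phantom(*shape, n_objects=4, radius_range=(4.0, 6.0),
                                   seed=seed, min_separation=22.0)
        else:
            shape = (36, 80, 80)
            phantom = make_phantom(*shape, n_objects=1, radius_range=(10.0, 13.0),
                                   seed=seed, min_separation=10.0)
        depth, height, width = shape
        write_volume(phantom.volume, out / "volume.tif")
        annotated_z = sorted({z for o in phantom.objects for z in o.boundaries})
        subjects = [
            Subject(
                subject_id=f"s_z{z:04d}",
                frames=[phantom.volume.voxels[z]],
                metadata={"x": 0, "y": 0, "z": z, "tile_id": "",
                          "annotation_frame_index": 0, "z_stride": 1},
            )
            for z in annotated_z
        ]
        write_manifest(subjects, out / "manifest.csv", out / "frames")
        if preset == "points":
            for v in range(n_volunteers):
                by_z: dict[int, list] = {}
                for x, y, z in simulate_marks(phantom.objects, model, v, shape, "points-preset"):
                    zi = min(max(int(round(z)), annotated_z[0]), annotated_z[-1])
                    zi = min(annotated_z, key=lambda a: abs(a - zi))
                    by_z.setdefault(zi, []).append(PointMark("T0", x, y, 0))
                for zi, anns in sorted(by_z.items()):
                    add_row(v, f"s_z{zi:04d}", anns)
        else:
            for z in annotated_z:
                for v in range(n_volunteers):
                    lines = [
                        simulate_contour(obj.boundaries[z], model, v,
                                         subject=f"s_z{z:04d}", frame_shape=(height, width))
                        for obj in phantom.objects
                        if z in obj.boundaries
                    ]
                    if lines:
                        add_row(v, f"s_z{z:04d}", lines)
            tifffile.imwrite(out / "truth_mask.tif",
                             truth_mask_volume(phantom).astype(np.uint8) * 255, photometric="minisblack")
        pd.DataFrame(
            [
                {"object_id": o.object_id, "x": o.centroid[0], "y": o.centroid[1],
                 "z": o.centroid[2], "radius": o.radius, "label": o.label}
                for o in phantom.objects
            ]
        ).to_csv(out / "truth_objects.csv", index=False)
    elif preset == "end2end":
        depth, height, width = 26, 56, 56
        tile = 32
        phantom = make_phantom(depth, height, width, n_objects=2,
                               radius_range=(6.5, 8.0), seed=seed, min_separation=12.0)
        schema = plan_tiles(width, height, tile, tile, overlap_fraction=0.5)
        write_volume(phantom.volume, out / "volume.tif")
        tifffile.imwrite(out / "truth_mask.tif",
                         truth_mask_volume(phantom).astype(np.uint8) * 255, photometric="minisblack")
        annotated_z = sorted({z for o in phantom.objects for z in o.boundaries})
        tol = default_gap_tolerance(tile, tile)
        subjects = []
        for z in annotated_z:
            for spec in schema.tiles:
                subject_id = f"s_z{z:04d}_{spec.tile_id}"
                frame = np.zeros((tile, tile))
                x_lo, y_lo = spec.x0 - schema.pad_x, spec.y0 - schema.pad_y
                sx_lo, sx_hi = max(x_lo, 0), min(x_lo + tile, width)
                sy_lo, sy_hi = max(y_lo, 0), min(y_lo + tile, height)
                frame[sy_lo - y_lo:sy_hi - y_lo, sx_lo - x_lo:sx_hi - x_lo] = (
                    phantom.volume.voxels[z, sy_lo:sy_hi, sx_lo:sx_hi]
                )
                subjects.append(
                    Subject(subject_id=subject_id, frames=[frame],
                            metadata={"x": x_lo, "y": y_lo, "z": z, "tile_id": spec.tile_id,
                                      "annotation_frame_index": 0, "z_stride": 1})
                )
                for v in range(n_volunteers):
                    anns: list = []
                    pieces = [
                        piece
                        for obj in phantom.objects
                        if z in obj.boundaries
                        for piece in _clipped_truth_loops(obj.boundaries[z], spec, schema)
                    ]
                    for p_idx, piece in enumerate(pieces):
                        local = np.array([volume_to_tile(spec, schema, x, y) for x, y in piece])
                        anns.append(
                            simulate_contour(local, model, v,
                                             subject=f"{subject_id}#{p_idx}",
                                             frame_shape=(tile, tile))
                        )
                    for obj in phantom.objects:
                        cx, cy, cz = obj.centroid
                        if int(cz) != z:
                            continue
                        if not (x_lo + 2 <= cx < x_lo + tile - 2 and y_lo + 2 <= cy < y_lo + tile - 2):
                            continue
                        rng = _rng(model, v, f"{subject_id}:{obj.object_id}", "marks")
                        jit = rng.normal(0.0, model.point_jitter_sigma, size=2)
                        u, vv = volume_to_tile(spec, schema, cx + jit[0], cy + jit[1])
                        anns.append(PointMark("T1", float(u), float(vv), 0))
                    if anns:
                        add_row(v, subject_id, anns)
        write_manifest(subjects, out / "manifest.csv", out / "frames")
        pd.DataFrame(
            [
                {"object_id": o.object_id, "x": o.centroid[0], "y": o.centroid[1],
                 "z": o.centroid[2], "radius": o.radius, "label": o.label}
                for o in phantom.objects
            ]
        ).to_csv(out / "truth_objects.csv", index=False)
        (out / "tiling.yaml").write_text(
            yaml.safe_dump(
                {
                    "original_width": width, "original_height": height, "depth": depth,
                    "tile_width": tile, "tile_height": tile, "overlap_fraction": 0.5,
                    "pad_x": schema.pad_x, "pad_y": schema.pad_y,
                    "stride_x": schema.stride_x, "stride_y": schema.stride_y,
                }
            )
        )
    else:
        raise ValueError(f"unknown preset {preset!r}")

    for i, ts in enumerate(_timestamps(len(classifications))):
        classifications[i].created_at = ts
    write_export(classifications, out / "export.csv")
    return out
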