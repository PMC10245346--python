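"""Cutting volumes into classification subjects and writing manifests.

Large volumes cannot be shown to a volunteer whole: the field of view is
reduced by tiling each slice into overlapping padded tiles (so that a
feature on the edge or corner of one tile sits centrally in a neighbour),
and 3D context is provided by "flipbooks" — short stacks of consecutive
slices annotated on the central plane.

Every subject carries an (x, y, z) anchor in original-volume coordinates in
its metadata and in the manifest, which is what makes the aggregated
results mappable back into the volume.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd
from PIL import Image

from .volume_io import ImageVolume, to_uint8

__all__ = [
    "TileSpec",
    "TilingSchema",
    "Subject",
    "Manifest",
    "ValidationReport",
    "plan_tiles",
    "crop_tile",
    "tile_to_volume",
    "volume_to_tile",
    "build_flipbook",
    "build_tile_subject",
    "sample_z",
    "encode_frame_png",
    "validate_subject",
    "write_manifest",
    "read_manifest",
    "MANIFEST_FIXED_COLUMNS",
]

WARN_LIMIT_BYTES = 600 * 1024   # recommended upload ceiling
MAX_LIMIT_BYTES = 1024 * 1024   # hard platform ceiling

MANIFEST_FIXED_COLUMNS = ("subject_id", "x", "y", "z", "tile_id", "annotation_frame_index", "z_stride")


@dataclass(frozen=True)
class TileSpec:
    """One tile: origin (x0, y0) in the *padded* frame plus its size."""

    tile_id: str
    x0: int
    y0: int
    tile_width: int
    tile_height: int


@dataclass
class TilingSchema:
    """The geometric plan mapping padded-frame tiles back to the original image."""

    original_width: int
    original_height: int
    pad_x: int
    pad_y: int
    stride_x: int
    stride_y: int
    tiles: list[TileSpec]

    @property
    def padded_width(self) -> int:
        return self.original_width + 2 * self.pad_x

    @property
    def padded_height(self) -> int:
        return self.original_height + 2 * self.pad_y

    def tile(self, tile_id: str) -> TileSpec:
        for t in self.tiles:
            if t.tile_id == tile_id:
                return t
        raise KeyError(f"no tile {tile_id!r} in schema")

    def pixel_multiplicity(self) -> np.ndarray:
        """Per-original-pixel count of tiles containing it.

        The operator can use the minimum of this map to lower the retirement
        limit proportionally to the duplicate coverage; the tool reports, it
        does not decide.
        """
        counts = np.zeros((self.original_height, self.original_width), dtype=np.int32)
        for t in self.tiles:
            x_lo = max(t.x0 - self.pad_x, 0)
            x_hi = min(t.x0 + t.tile_width - self.pad_x, self.original_width)
            y_lo = max(t.y0 - self.pad_y, 0)
            y_hi = min(t.y0 + t.tile_height - self.pad_y, self.original_height)
            if x_hi > x_lo and y_hi > y_lo:
                counts[y_lo:y_hi, x_lo:x_hi] += 1
        return counts


@dataclass
class Subject:
    """One unit of classification work: 1..n frames plus provenance metadata."""

    subject_id: str
    frames: list[np.ndarray]
    metadata: dict

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("subject needs at least one frame")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValueError("all frames must share dimensions")
        for key in ("x", "y", "z"):
            if key not in self.metadata:
                raise ValueError(f"subject metadata must contain {key!r}")


@dataclass
class Manifest:
    """Parsed manifest: one row per subject, with mandatory (x, y, z) anchors."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        for col in ("subject_id", "x", "y", "z"):
            if col not in df.columns:
                raise ValueError(f"manifest lacks mandatory column {col!r}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValueError(f"duplicate subject_id in manifest: {dup!r}")
        for col in ("x", "y", "z"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna() | (vals != np.floor(vals))]
            if len(bad):
                raise ValueError(f"manifest row {bad[0]}: column {col!r} is not integral")
            df[col] = vals.astype(int)

    def row_for(self, subject_id: str) -> pd.Series:
        hit = self.rows[self.rows["subject_id"] == subject_id]
        if hit.empty:
            raise KeyError(f"subject {subject_id!r} not in manifest")
        return hit.iloc[0]


@dataclass(frozen=True)
class ValidationReport:
    subject_id: str
    encoded_size_bytes: int
    status: str  # ok | warn | error
    message: str


def plan_tiles(
    original_width: int,
    original_height: int,
    tile_width: int,
    tile_height: int,
    overlap_fraction: float = 0.5,
) -> TilingSchema:
    """Plan an overlapping tiling of a padded frame.

    stride = tile · (1 − overlap_fraction); padding per side = tile − stride,
    so at the default 50% overlap the original image is padded by half a tile
    on every side and any edge or corner feature of one tile lies in the
    central region of an adjacent tile.  Tile origins advance by the stride;
    the final origin is clamped so the last tile flushes the padded edge
    (coverage may duplicate, it never truncates).
    """
    if tile_width < 2 or tile_height < 2:
        raise ValueError("tile dimensions must be >= 2")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")

    def axis_plan(orig: int, tile: int) -> tuple[int, int, list[int]]:
        stride_f = tile * (1.0 - overlap_fraction)
        if abs(stride_f - round(stride_f)) > 1e-9:
            raise ValueError(
                f"overlap_fraction {overlap_fraction} gives non-integral stride for tile {tile}"
            )
        stride = int(round(stride_f))
        pad = tile - stride
        padded = orig + 2 * pad
        origins = list(range(0, padded - tile + 1, stride))
        if origins[-1] != padded - tile:
            origins.append(padded - tile)  # clamp: flush the padded edge
        return stride, pad, origins

    stride_x, pad_x, xs = axis_plan(original_width, tile_width)
    stride_y, pad_y, ys = axis_plan(original_height, tile_height)
    tiles = [
        TileSpec(f"x{ix:02d}_y{iy:02d}", x0, y0, tile_width, tile_height)
        for iy, y0 in enumerate(ys)
        for ix, x0 in enumerate(xs)
    ]
    return TilingSchema(original_width, original_height, pad_x, pad_y, stride_x, stride_y, tiles)


def tile_to_volume(spec: TileSpec, schema: TilingSchema, u: float, v: float) -> tuple[float, float]:
    """Tile-local (u, v) -> original-image (x, y). Inverse of volume_to_tile."""
    return spec.x0 + u - schema.pad_x, spec.y0 + v - schema.pad_y


def volume_to_tile(spec: TileSpec, schema: TilingSchema, x: float, y: float) -> tuple[float, float]:
    """Original-image (x, y) -> tile-local (u, v). Inverse of tile_to_volume."""
    return x - spec.x0 + schema.pad_x, y - spec.y0 + schema.pad_y


def crop_tile(
    volume: ImageVolume,
    z: int,
    spec: TileSpec,
    schema: TilingSchema,
    pad_value: float = 0.0,
) -> np.ndarray:
    """Cut one tile from slice ``z``; positions outside the original image get ``pad_value``."""
    if not 0 <= z < volume.depth:
        raise IndexError(f"z={z} out of range [0, {volume.depth})")
    out = np.full((spec.tile_height, spec.tile_width), float(pad_value))
    x_lo = spec.x0 - schema.pad_x
    y_lo = spec.y0 - schema.pad_y
    sx_lo, sx_hi = max(x_lo, 0), min(x_lo + spec.tile_width, volume.width)
    sy_lo, sy_hi = max(y_lo, 0), min(y_lo + spec.tile_height, volume.height)
    if sx_hi > sx_lo and sy_hi > sy_lo:
        out[sy_lo - y_lo : sy_hi - y_lo, sx_lo - x_lo : sx_hi - x_lo] = volume.voxels[
            z, sy_lo:sy_hi, sx_lo:sx_hi
        ]
    return out


def build_tile_subject(
    volume: ImageVolume,
    z: int,
    spec: TileSpec,
    schema: TilingSchema,
    pad_value: float = 0.0,
    z_stride: int = 1,
) -> Subject:
    """Single-frame subject for one tile of one slice; anchor = original coords of the tile's (0,0) pixel."""
    frame = crop_tile(volume, z, spec, schema, pad_value)
    x_anchor, y_anchor = tile_to_volume(spec, schema, 0, 0)
    return Subject(
        subject_id=f"s_z{z:04d}_{spec.tile_id}",
        frames=[frame],
        metadata={
            "x": int(x_anchor),
            "y": int(y_anchor),
            "z": int(z),
            "tile_id": spec.tile_id,
            "annotation_frame_index": 0,
            "z_stride": int(z_stride),
        },
    )


def build_flipbook(
    volume: ImageVolume,
    x0: int,
    y0: int,
    tile_width: int,
    tile_height: int,
    z_center: int,
    context_half_width: int = 2,
    tile_id: str = "",
    z_stride: int = 1,
) -> Subject:
    """Build a flipbook subject: 2h+1 consecutive slices, annotated on the middle one.

    The default ``context_half_width=2`` gives a five-image stack with two
    slices of context above and below the annotation plane.  Centers too near
    the stack boundary are refused rather than clamped: annotation quality is
    known to degrade at the ends of a stack, so short stacks should be an
    explicit operator decision.
    """
    h = int(context_half_width)
    if h < 0:
        raise ValueError("context_half_width must be >= 0")
    if not h <= z_center <= volume.depth - 1 - h:
        raise ValueError(
            f"z_center={z_center} too near the stack boundary for half-width {h} "
            f"(depth {volume.depth}); refusing rather than clamping"
        )
    if not (0 <= x0 and x0 + tile_width <= volume.width and 0 <= y0 and y0 + tile_height <= volume.height):
        raise ValueError("flipbook window extends outside the volume")
    frames = [
        np.array(volume.voxels[z, y0 : y0 + tile_height, x0 : x0 + tile_width])
        for z in range(z_center - h, z_center + h + 1)
    ]
    return Subject(
        subject_id=f"fb_z{z_center:04d}_x{x0}_y{y0}",
        frames=frames,
        metadata={
            "x": int(x0),
            "y": int(y0),
            "z": int(z_center),
            "tile_id": tile_id,
            "annotation_frame_index": h,
            "z_stride": int(z_stride),
        },
    )


def sample_z(depth: int, z_stride: int, context_half_width: int) -> list[int]:
    """Annotation-plane z centers: h, h+stride, ... <= depth−1−h.

    Striding the volume in z trades volunteer effort against coverage; it
    distorts z scale, so the stride is recorded in the manifest and undone
    downstream.  Too-shallow stacks give an empty sequence with a warning.
    """
    if z_stride < 1:
        raise ValueError("z_stride must be >= 1")
    h = int(context_half_width)
    if depth < 2 * h + 1:
        warnings.warn(f"depth {depth} too shallow for context half-width {h}; no subjects")
        return []
    return list(range(h, depth - h, z_stride))


def encode_frame_png(frame: np.ndarray) -> bytes:
    """Encode one frame as lossless 8-bit PNG (the default upload format)."""
    buf = io.BytesIO()
    Image.fromarray(to_uint8(frame), mode="L").save(buf, format="PNG")
    return buf.getvalue()


def encoded_subject_size(subject: Subject) -> int:
    """Total encoded byte size of a subject's frames as uploaded (PNG)."""
    return sum(len(encode_frame_png(f)) for f in subject.frames)


def validate_subject(
    encoded_bytes_length: int,
    subject_id: str = "",
    warn_limit_bytes: int = WARN_LIMIT_BYTES,
    max_limit_bytes: int = MAX_LIMIT_BYTES,
) -> ValidationReport:
    """Check an encoded subject against the platform size limits.

    Upload sizes are recommended below 600 KB and hard-capped at 1 MB; the
    report carries ok/warn/error accordingly rather than raising.
    """
    n = int(encoded_bytes_length)
    if n < 0:
        raise ValueError("size must be >= 0")
    if n >= max_limit_bytes:
        return ValidationReport(subject_id, n, "error", f"{n} B exceeds hard maximum {max_limit_bytes} B")
    if n >= warn_limit_bytes:
        return ValidationReport(subject_id, n, "warn", f"{n} B exceeds recommended {warn_limit_bytes} B")
    return ValidationReport(subject_id, n, "ok", "within recommended size")


def write_manifest(
    subjects: Sequence[Subject],
    path: str | Path,
    frames_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Write subject frames (PNG) and the manifest CSV linking them to (x, y, z).

    Frame files are written before the manifest row that references them, so
    every referenced file exists at write time.  Returns the manifest frame.
    """
    path = Path(path)
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate subject_id: {dup!r}")
    frames_dir = Path(frames_dir) if frames_dir is not None else path.parent / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    path.parent.mkdir(parents=True, exist_ok=True)

    n_frames = max(len(s.frames) for s in subjects) if subjects else 0
    records = []
    for s in subjects:
        rec: dict = {"subject_id": s.subject_id}
        for k in range(n_frames):
            if k < len(s.frames):
                fname = f"{s.subject_id}_f{k}.png"
                (frames_dir / fname).write_bytes(encode_frame_png(s.frames[k]))
                rec[f"frame_{k}"] = fname
            else:
                rec[f"frame_{k}"] = ""
        for key, val in s.metadata.items():
            rec[key] = val
        records.append(rec)
    columns = ["subject_id"] + [f"frame_{k}" for k in range(n_frames)] + [
        c for c in MANIFEST_FIXED_COLUMNS if c != "subject_id"
    ]
    df = pd.DataFrame.from_records(records)
    extra = [c for c in df.columns if c not in columns]
    df = df.reindex(columns=columns + extra)
    df.to_csv(path, index=False)
    return df


def read_manifest(path: str | Path) -> Manifest:
    """Read and validate a manifest CSV (unique ids, integral x/y/z present)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such manifest: {path}")
    df = pd.read_csv(path)
    return Manifest(df)
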