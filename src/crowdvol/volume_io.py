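"""Reading, writing and pre-processing of 3D grayscale volumes.

Volumes are held as ``(z, y, x)``-indexed float arrays (``ImageVolume``),
with *y* increasing downward as in raster image files.  Two on-disk layouts
are supported: a single multi-page TIFF, or a directory of per-slice PNG or
single-page TIFF files named ``<stem>_<zero-padded z>.<ext>``.

Intensities are kept as floats internally so that chained pre-processing
(contrast stretching, binning) does not accumulate quantization error;
8-bit export quantizes once, by round-half-up.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "ImageVolume",
    "read_volume",
    "write_volume",
    "stretch_contrast",
    "bin_volume",
    "to_uint8",
]

Layout = Literal["multipage", "slice_directory"]

_SLICE_RE = re.compile(r"^(?P<stem>.*)_(?P<z>\d+)\.(?P<ext>png|tif|tiff)$", re.IGNORECASE)


@dataclass
class ImageVolume:
    """A 3D grayscale grid indexed ``(z, y, x)``."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x), got shape {arr.shape}")
        if min(arr.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {arr.shape}")
        self.voxels = arr

    @property
    def depth(self) -> int:
        return self.voxels.shape[0]

    @property
    def height(self) -> int:
        return self.voxels.shape[1]

    @property
    def width(self) -> int:
        return self.voxels.shape[2]

    @property
    def intensity_range(self) -> tuple[float, float]:
        return float(self.voxels.min()), float(self.voxels.max())

    def slice(self, z: int) -> np.ndarray:
        if not 0 <= z < self.depth:
            raise IndexError(f"z={z} out of range [0, {self.depth})")
        return self.voxels[z]


def to_uint8(image: np.ndarray) -> np.ndarray:
    """Quantize a float image to 8 bits by round-half-up, clipping to [0, 255]."""
    return np.clip(np.floor(np.asarray(image, dtype=np.float64) + 0.5), 0, 255).astype(np.uint8)


def _read_slice(path: Path) -> np.ndarray:
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path).convert("F"))
    except Exception as exc:  # pragma: no cover - message path
        raise OSError(f"unreadable image file: {path.name}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError(f"slice {path.name} is not a single-channel 2D image (shape {arr.shape})")
    return np.asarray(arr, dtype=np.float64)


def read_volume(path: str | Path, layout: Layout = "multipage") -> ImageVolume:
    """Read a volume from a multi-page TIFF or a directory of slice files.

    Slice files must carry a zero-padded numeric suffix (``stem_0003.png``)
    that fixes the z-order.  All slices must share the same (height, width);
    a mismatch is reported with the offending file name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")
    if layout == "multipage":
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3:
            raise ValueError(f"{path.name}: expected grayscale pages, got shape {arr.shape}")
        return ImageVolume(np.asarray(arr, dtype=np.float64))
    if layout == "slice_directory":
        if not path.is_dir():
            raise NotADirectoryError(f"slice_directory layout requires a directory: {path}")
        entries = []
        for f in sorted(path.iterdir()):
            m = _SLICE_RE.match(f.name)
            if m:
                entries.append((int(m.group("z")), f))
        if not entries:
            raise FileNotFoundError(f"no slice files matching <stem>_<z>.<ext> in {path}")
        entries.sort(key=lambda t: t[0])
        slices = []
        shape = None
        for _, f in entries:
            s = _read_slice(f)
            if shape is None:
                shape = s.shape
            elif s.shape != shape:
                raise ValueError(
                    f"inconsistent slice dimensions: {f.name} has {s.shape}, expected {shape}"
                )
            slices.append(s)
        return ImageVolume(np.stack(slices))
    raise ValueError(f"unknown layout: {layout!r}")


def write_volume(
    volume: ImageVolume,
    path: str | Path,
    layout: Layout = "multipage",
    *,
    stem: str = "slice",
    ext: str = "png",
) -> None:
    """Write a volume; ``read_volume(write_volume(v))`` round-trips voxel-for-voxel.

    Multi-page TIFF stores float32 pages losslessly for integer-valued data
    in the 8-bit range; slice directories are written as 8-bit PNG (or
    float32 single-page TIFF when ``ext='tif'``).
    """
    if str(path) == "":
        raise ValueError("empty path")
    path = Path(path)
    if layout == "multipage":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, volume.voxels.astype(np.float32), photometric="minisblack")
        return
    if layout == "slice_directory":
        path.mkdir(parents=True, exist_ok=True)
        ndigits = max(4, len(str(volume.depth - 1)))
        for z in range(volume.depth):
            fname = path / f"{stem}_{z:0{ndigits}d}.{ext}"
            if ext.lower() in ("tif", "tiff"):
                tifffile.imwrite(fname, volume.voxels[z].astype(np.float32))
            else:
                Image.fromarray(to_uint8(volume.voxels[z]), mode="L").save(fname)
        return
    raise ValueError(f"unknown layout: {layout!r}")


def stretch_contrast(
    volume: ImageVolume,
    low_percentile: float = 0.0,
    high_percentile: float = 1.0,
    out_range: tuple[float, float] = (0.0, 255.0),
) -> ImageVolume:
    """Linearly rescale so the given input percentiles map to ``out_range`` ends.

    Percentiles are fractions in [0, 1].  Values outside the percentile
    window are clipped.  A constant volume maps to the range minimum (no
    division blow-up).
    """
    if not 0.0 <= low_percentile < high_percentile <= 1.0:
        raise ValueError(
            f"need 0 <= low < high <= 1, got low={low_percentile}, high={high_percentile}"
        )
    lo_v, hi_v = np.quantile(volume.voxels, [low_percentile, high_percentile])
    lo_out, hi_out = out_range
    if hi_v <= lo_v:  # constant (or degenerate) input
        return ImageVolume(np.full_like(volume.voxels, lo_out))
    scaled = (volume.voxels - lo_v) / (hi_v - lo_v) * (hi_out - lo_out) + lo_out
    return ImageVolume(np.clip(scaled, min(lo_out, hi_out), max(lo_out, hi_out)))


def bin_volume(volume: ImageVolume, factor: int | Sequence[int]) -> ImageVolume:
    """Downsample by block averaging; noise-reduction preprocessing.

    ``factor`` is one integer per axis (z, y, x), or a single integer applied
    to all three.  Output dims are ``ceil(dim/factor)``; trailing partial
    blocks are averaged over their actual size so the field of view is
    preserved.
    """
    if np.isscalar(factor):
        factors = (int(factor),) * 3
    else:
        factors = tuple(int(f) for f in factor)
    if len(factors) != 3 or any(f < 1 for f in factors):
        raise ValueError(f"factor must be positive per axis, got {factors}")
    arr = volume.voxels
    for axis, f in enumerate(factors):
        if f == 1:
            continue
        n = arr.shape[axis]
        n_out = math.ceil(n / f)
        # sum within blocks, then divide by actual block sizes
        idx = np.arange(n) // f
        sums = np.add.reduceat(arr, np.arange(0, n, f), axis=axis)
        counts = np.bincount(idx, minlength=n_out).astype(np.float64)
        shape = [1] * 3
        shape[axis] = n_out
        arr = sums / counts.reshape(shape)
    return ImageVolume(arr)
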