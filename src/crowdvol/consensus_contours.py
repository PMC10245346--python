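"""CRIA — contour regression by interior averages.

Consensus segmentation from many volunteers' freehand outlines of the same
structure: each stroke is closed into a loop, the loop interior is
rasterized, interiors are stacked into a per-pixel count (the "height
map"), and the consensus keeps every pixel covered by half or more of the
volunteers.  Per-pixel agreement (height / N) is carried alongside the
binary mask, and annotations that disagree grossly with the provisional
consensus (low intersection-over-union) can be excluded as outliers before
the final pass.

Conventions that matter:

* Pixel (i, j) — column i, row j — is inside a loop iff its centre
  (i + 0.5, j + 0.5) is inside the polygon under the even-odd rule, which
  handles self-intersecting volunteer strokes deterministically and
  independently of stroke orientation.
* "Half or more" is inclusive (2·height ≥ N): with N = 2 the consensus is
  the union of both interiors.
* One contributor's multiple loops on a frame are OR-ed before counting,
  so N counts contributors, not strokes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ClosedLoop",
    "ClosureReject",
    "ConsensusSegmentation",
    "close_polyline",
    "rasterize_interior",
    "rasterize_loops",
    "height_map",
    "cria_consensus",
    "remove_outlier_annotations",
    "extract_consensus_contours",
    "compare_to_expert",
    "mask_iou",
]


@dataclass
class ClosedLoop:
    """Closed polygon: first vertex equals the last; >= 3 distinct vertices."""

    vertices: np.ndarray  # (n, 2) float, columns (x, y), closed
    contributor_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 4:
            raise ValueError("closed loop needs >= 4 stored vertices (first = last)")
        if not np.allclose(v[0], v[-1]):
            raise ValueError("loop is not closed (first vertex != last)")
        if not np.isfinite(v).all():
            raise ValueError("loop has non-finite coordinates")
        if len(np.unique(np.round(v[:-1], 9), axis=0)) < 3:
            raise ValueError("loop has fewer than 3 distinct vertices")
        self.vertices = v


@dataclass(frozen=True)
class ClosureReject:
    """A stroke that could not be closed; kept as a value, never guessed at."""

    reason: str
    contributor_id: str = ""


@dataclass
class ConsensusSegmentation:
    mask: np.ndarray        # bool raster
    agreement: np.ndarray   # float raster, height / N
    n_annotations: int
    excluded: tuple[str, ...] = ()
    all_excluded: bool = False


def close_polyline(
    vertices: Sequence[Sequence[float]] | np.ndarray,
    gap_tolerance: float,
    contributor_id: str = "",
) -> ClosedLoop | ClosureReject:
    """Close a freehand stroke into a loop, or reject it with a reason.

    Coincident endpoints pass through unchanged; an endpoint gap at most
    ``gap_tolerance`` pixels is closed by appending the first vertex; a
    larger gap, or a stroke with fewer than 3 distinct vertices, is rejected.
    """
    v = np.asarray(vertices, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 2:
        return ClosureReject("stroke needs at least 2 (x, y) vertices", contributor_id)
    if not np.isfinite(v).all():
        return ClosureReject("stroke has non-finite coordinates", contributor_id)
    gap = float(np.hypot(*(v[0] - v[-1])))
    if gap > gap_tolerance:
        return ClosureReject(
            f"endpoint gap {gap:.2f} px exceeds tolerance {gap_tolerance:.2f} px",
            contributor_id,
        )
    if gap > 0:
        v = np.vstack([v, v[0]])
    if len(np.unique(np.round(v[:-1], 9), axis=0)) < 3:
        return ClosureReject("stroke has fewer than 3 distinct vertices", contributor_id)
    try:
        return ClosedLoop(v, contributor_id)
    except ValueError as exc:
        return ClosureReject(str(exc), contributor_id)


def default_gap_tolerance(width: int, height: int) -> float:
    """Default closure tolerance: 5% of the frame diagonal."""
    return 0.05 * math.hypot(width, height)


def rasterize_interior(loop: ClosedLoop, width: int, height: int) -> np.ndarray:
    """Even-odd rasterization of a loop interior onto a (height, width) raster.

    Pixel (i, j) is set iff its centre (i + 0.5, j + 0.5) lies inside the
    polygon under the even-odd rule (ray cast toward +x, counting edge
    crossings).  Pixel centres at half-integer coordinates never coincide
    with the integer-valued horizontal scanlines of traced contours, so the
    rule is exact for loops produced by :func:`extract_consensus_contours`.
    """
    mask = np.zeros((height, width), dtype=bool)
    v = loop.vertices
    x1, y1 = v[:-1, 0], v[:-1, 1]
    x2, y2 = v[1:, 0], v[1:, 1]
    centres_x = np.arange(width) + 0.5
    for j in range(height):
        yc = j + 0.5
        # edges straddling the scanline (half-open in y so shared vertices count once)
        straddle = ((y1 <= yc) & (y2 > yc)) | ((y2 <= yc) & (y1 > yc))
        if not straddle.any():
            continue
        t = (yc - y1[straddle]) / (y2[straddle] - y1[straddle])
        xs = np.sort(x1[straddle] + t * (x2[straddle] - x1[straddle]))
        # inside iff an odd number of crossings lie strictly right of the centre
        n_right = len(xs) - np.searchsorted(xs, centres_x, side="right")
        mask[j] = (n_right % 2) == 1
    return mask


def rasterize_loops(loops: Sequence[ClosedLoop], width: int, height: int) -> np.ndarray:
    """XOR of loop interiors: the even-odd interior of a multi-loop boundary.

    Used to re-rasterize traced consensus contours; XOR makes holes come out
    as holes.
    """
    mask = np.zeros((height, width), dtype=bool)
    for loop in loops:
        mask ^= rasterize_interior(loop, width, height)
    return mask


def height_map(masks: Sequence[np.ndarray]) -> tuple[np.ndarray, int]:
    """Overlay per-contributor interior masks into a per-pixel count."""
    masks = list(masks)
    if not masks:
        raise ValueError("height_map needs at least one mask")
    shape = masks[0].shape
    for k, m in enumerate(masks):
        if m.shape != shape:
            raise ValueError(f"mask {k} has shape {m.shape}, expected {shape}")
    heights = np.zeros(shape, dtype=np.int64)
    for m in masks:
        heights += m.astype(bool)
    return heights, len(masks)


def cria_consensus(masks: Sequence[np.ndarray]) -> ConsensusSegmentation:
    """Consensus = pixels where half or more of the contributors agree.

    Inclusive threshold (2·height ≥ N); the consensus may comprise several
    disjoint regions.  The agreement raster height/N is retained for
    downstream fusion and inspection of low-consensus areas.
    """
    heights, n = height_map(masks)
    return ConsensusSegmentation(
        mask=(2 * heights) >= n,
        agreement=heights / n,
        n_annotations=n,
    )


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks; empty vs empty is 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def remove_outlier_annotations(
    masks: Sequence[np.ndarray],
    iou_cutoff: float = 0.3,
    contributor_ids: Sequence[str] | None = None,
    expert_mask: np.ndarray | None = None,
) -> tuple[ConsensusSegmentation, list[np.ndarray]]:
    """Two-pass consensus with exclusion of grossly discordant annotations.

    A provisional consensus over all masks (or the expert mask, if supplied)
    is the reference; masks with IoU below ``iou_cutoff`` against it are
    excluded and the consensus recomputed once on the survivors.  If the
    cutoff would exclude everyone, all masks are kept and the result flagged.
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if len(masks) < 2:
        raise ValueError("outlier removal needs at least 2 annotations")
    ids = list(contributor_ids) if contributor_ids is not None else [str(k) for k in range(len(masks))]
    if len(ids) != len(masks):
        raise ValueError("contributor_ids length must match masks")
    reference = (
        np.asarray(expert_mask, dtype=bool) if expert_mask is not None else cria_consensus(masks).mask
    )
    keep = [mask_iou(m, reference) >= iou_cutoff for m in masks]
    if not any(keep):
        result = cria_consensus(masks)
        result.all_excluded = True
        return result, masks
    kept = [m for m, k in zip(masks, keep) if k]
    result = cria_consensus(kept)
    result.excluded = tuple(i for i, k in zip(ids, keep) if not k)
    return result, kept


def _boundary_edges(mask: np.ndarray):
    """Directed unit edges (at integer pixel corners) separating in from out."""
    padded = np.pad(mask.astype(bool), 1)
    inside = padded[1:-1, 1:-1]
    edges = {}  # start corner -> list of end corners

    def add(a, b):
        edges.setdefault(a, []).append(b)

    ys, xs = np.nonzero(inside)
    for j, i in zip(ys.tolist(), xs.tolist()):
        if not padded[j, i + 1]:        # neighbour above (j-1) outside
            add((i, j), (i + 1, j))
        if not padded[j + 1, i + 2]:    # right neighbour outside
            add((i + 1, j), (i + 1, j + 1))
        if not padded[j + 2, i + 1]:    # below outside
            add((i + 1, j + 1), (i, j + 1))
        if not padded[j + 1, i]:        # left outside
            add((i, j + 1), (i, j))
    return edges


def extract_consensus_contours(mask: np.ndarray) -> list[ClosedLoop]:
    """Trace the boundary loops of a binary mask at pixel-corner resolution.

    Loops follow the exact pixel-square outlines (including hole boundaries),
    so XOR re-rasterization via :func:`rasterize_loops` reproduces the mask
    bit-for-bit.  Diagonally-touching pixels share a corner; the tracer keeps
    one consistent continuation there, which leaves the even-odd interior —
    and hence the round-trip — unchanged.
    """
    edges = _boundary_edges(np.asarray(mask, dtype=bool))
    for v in edges.values():
        v.sort()
    loops: list[ClosedLoop] = []
    while edges:
        start = min(edges)
        path = [start]
        cur = start
        while True:
            nxt = edges[cur].pop(0)
            if not edges[cur]:
                del edges[cur]
            path.append(nxt)
            cur = nxt
            if cur == start:
                break
        loops.append(ClosedLoop(np.array(path, dtype=np.float64)))
    return loops


def compare_to_expert(consensus_mask: np.ndarray, expert_mask: np.ndarray) -> dict:
    """Overlap statistics against an expert annotation: IoU, Dice, pixel agreement."""
    a = np.asarray(consensus_mask, dtype=bool)
    b = np.asarray(expert_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    inter = np.logical_and(a, b).sum()
    total = a.sum() + b.sum()
    dice = 1.0 if total == 0 else float(2 * inter / total)
    return {
        "iou": mask_iou(a, b),
        "dice": dice,
        "pixel_agreement": float((a == b).mean()),
    }
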