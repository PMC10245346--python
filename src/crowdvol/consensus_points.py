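"""Consensus object detection from many volunteers' point and ellipse marks.

Individual centre marks from different volunteers rarely coincide, so
aggregation clusters marks in 3D space, discards sparse outliers (which
tend to be unique errors by individual contributors) and averages the
member locations of each cluster into one detected object.  An optional
follow-up pass attaches a majority-voted class label per object.

DBSCAN is implemented directly from its density-reachability definition so
the behaviour is fully specified (and independently testable against a
brute-force oracle): a core point has at least ``min_samples`` neighbours
within ``eps`` (inclusive, counting itself); clusters are the connected
components of core points under eps-adjacency plus any border points
attached to a core neighbour; everything else is noise (label −1).
"""

from __future__ import annotations

import csv
from collections import Counter, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .consensus_questions import majority_vote

__all__ = [
    "MarkRecord",
    "ObjectDetection",
    "dbscan",
    "aggregate_points",
    "vote_object_labels",
    "export_objects",
    "read_objects",
]


@dataclass(frozen=True)
class MarkRecord:
    """One volunteer mark in original-volume coordinates."""

    contributor_id: str
    subject_id: str
    position: tuple[float, float, float]  # (x, y, z)
    source: str = "point"  # point | ellipse
    semi_axes: tuple[float, float] | None = None


@dataclass
class ObjectDetection:
    object_id: str
    centroid: tuple[float, float, float]
    support: int
    members: list
    label: str | None = None
    label_agreement: float | None = None


def dbscan(points: Sequence[Sequence[float]], eps: float, min_samples: int) -> np.ndarray:
    """Density-based clustering; returns one integer label per point, noise = −1."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    labels = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return labels
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    adjacency = d2 <= eps * eps  # inclusive; diagonal counts the point itself
    is_core = adjacency.sum(axis=1) >= min_samples

    cluster = 0
    for seed in range(n):
        if not is_core[seed] or labels[seed] != -1:
            continue
        # expand the connected component of core points reachable from seed
        labels[seed] = cluster
        queue = deque([seed])
        while queue:
            p = queue.popleft()
            for q in np.flatnonzero(adjacency[p]):
                if labels[q] == -1:
                    labels[q] = cluster  # border points attach to the first core reached
                    if is_core[q]:
                        queue.append(q)
        cluster += 1
    return labels


def aggregate_points(
    marks: Sequence[MarkRecord],
    eps: float,
    min_samples: int,
    anisotropy: float = 1.0,
) -> list[ObjectDetection]:
    """Cluster marks in 3D and average each cluster into one object detection.

    Distances use ``sqrt(dx² + dy² + (anisotropy·dz)²)``: ``anisotropy``
    defaults to 1 and should be set to the z-stride recorded in the manifest
    to undo the z scale distortion of strided sampling.  Noise points are
    discarded as outliers.  Support counts *distinct contributors*, so one
    volunteer double-marking an object cannot inflate it.
    """
    marks = list(marks)
    if not marks:
        return []
    scaled = np.array(
        [(m.position[0], m.position[1], anisotropy * m.position[2]) for m in marks]
    )
    labels = dbscan(scaled, eps=eps, min_samples=min_samples)
    detections: list[ObjectDetection] = []
    for cluster in sorted(set(labels) - {-1}):
        members = [m for m, lab in zip(marks, labels) if lab == cluster]
        pos = np.array([m.position for m in members], dtype=np.float64)
        centroid = tuple(float(v) for v in pos.mean(axis=0))
        support = len({m.contributor_id for m in members})
        detections.append(
            ObjectDetection(
                object_id=f"obj{len(detections):04d}",
                centroid=centroid,
                support=support,
                members=members,
            )
        )
    return detections


def vote_object_labels(
    detections: Sequence[ObjectDetection],
    label_votes: Sequence[tuple[str, str]],
    drop_rejected: bool = False,
    rejection_choice: str = "not an object",
) -> tuple[list[ObjectDetection], list[tuple[str, str]]]:
    """Attach majority-voted labels; the second-workflow cleaning pass.

    ``label_votes`` are (object_id, choice) pairs.  Objects whose winning
    choice is the designated rejection choice are dropped when
    ``drop_rejected`` is set.  Votes for unknown object ids are returned for
    reporting.  Objects without votes keep label=None.
    """
    known = {d.object_id for d in detections}
    votes_by_object: dict[str, list[str]] = {}
    unknown: list[tuple[str, str]] = []
    for object_id, choice in label_votes:
        if object_id in known:
            votes_by_object.setdefault(object_id, []).append(choice)
        else:
            unknown.append((object_id, choice))
    out: list[ObjectDetection] = []
    for d in detections:
        votes = votes_by_object.get(d.object_id)
        if votes:
            consensus = majority_vote(votes)
            d.label = consensus.winning_choice
            d.label_agreement = consensus.agreement_fraction
            if drop_rejected and d.label == rejection_choice:
                continue
        out.append(d)
    return out, unknown


def export_objects(detections: Sequence[ObjectDetection], path: str | Path) -> None:
    """Write detections as a simple CSV of 3D coordinates plus classification.

    The format (object_id, x, y, z, support, label, label_agreement) is
    importable by volumetric viewers that accept point+class tables.
    Unlabeled objects get empty cells, not the string "None".
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["object_id", "x", "y", "z", "support", "label", "label_agreement"])
        for d in detections:
            w.writerow(
                [
                    d.object_id,
                    d.centroid[0],
                    d.centroid[1],
                    d.centroid[2],
                    d.support,
                    d.label if d.label is not None else "",
                    d.label_agreement if d.label_agreement is not None else "",
                ]
            )


def read_objects(path: str | Path) -> list[ObjectDetection]:
    """Read an objects CSV written by :func:`export_objects`."""
    df = pd.read_csv(path, dtype={"object_id": str, "label": str})
    out = []
    for _, row in df.iterrows():
        label = row.get("label")
        label = None if pd.isna(label) else str(label)
        agreement = row.get("label_agreement")
        agreement = None if pd.isna(agreement) else float(agreement)
        out.append(
            ObjectDetection(
                object_id=str(row["object_id"]),
                centroid=(float(row["x"]), float(row["y"]), float(row["z"])),
                support=int(row["support"]),
                members=[],
                label=label,
                label_agreement=agreement,
            )
        )
    return out
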