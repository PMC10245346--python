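"""Parsing classification exports into typed records.

The export dialect is a CSV with one row per volunteer response, carrying
columns ``classification_id, user_name, workflow_id, workflow_version,
created_at, annotations, subject_data, subject_ids`` where ``annotations``
is a JSON array of ``{task, value}`` entries.  Drawing-task values are
objects (or lists of objects) with coordinate fields; question-task values
are bare strings.

Contributor identity is pseudonymized on ingest with a stable salted hash —
raw usernames are never stored downstream.  Malformed rows are collected in
a reject report, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "PointMark",
    "EllipseMark",
    "FreehandLine",
    "Answer",
    "Classification",
    "RejectedRow",
    "parse_classifications",
    "filter_workflow",
    "link_subjects",
    "deduplicate_contributor",
    "pseudonymize",
    "MANDATORY_COLUMNS",
]

MANDATORY_COLUMNS = (
    "classification_id",
    "user_name",
    "workflow_id",
    "workflow_version",
    "created_at",
    "annotations",
    "subject_data",
    "subject_ids",
)

_PSEUDONYM_RE = re.compile(r"^h:[0-9a-f]{12}$")
_SALT = b"crowdvol-pseudonym-v1|"


@dataclass(frozen=True)
class PointMark:
    task_id: str
    x: float
    y: float
    frame_index: int = 0


@dataclass(frozen=True)
class EllipseMark:
    task_id: str
    x: float
    y: float
    rx: float
    ry: float
    angle: float
    frame_index: int = 0


@dataclass(frozen=True)
class FreehandLine:
    task_id: str
    vertices: tuple[tuple[float, float], ...]
    frame_index: int = 0


@dataclass(frozen=True)
class Answer:
    task_id: str
    choice: str


Annotation = PointMark | EllipseMark | FreehandLine | Answer


@dataclass
class Classification:
    """One contributor's full response to one subject."""

    classification_id: str
    contributor_id: str
    subject_id: str
    workflow_id: str
    workflow_version: str
    created_at: str
    annotations: list


@dataclass(frozen=True)
class RejectedRow:
    row_index: int
    classification_id: str
    reason: str


def pseudonymize(name: str) -> str:
    """Stable salted hash of a contributor name; idempotent on its own output."""
    if _PSEUDONYM_RE.match(name):
        return name
    digest = hashlib.sha1(_SALT + name.encode("utf-8")).hexdigest()
    return f"h:{digest[:12]}"


def _finite(*vals: float) -> bool:
    return all(isinstance(v, (int, float)) and math.isfinite(v) for v in vals)


def _parse_mark(task: str, value) -> Annotation:
    if isinstance(value, str):
        return Answer(task, value)
    if not isinstance(value, dict):
        raise ValueError(f"task {task}: unsupported value type {type(value).__name__}")
    frame = int(value.get("frame", 0))
    if "points" in value:
        pts = tuple((float(p["x"]), float(p["y"])) for p in value["points"])
        if len(pts) < 2:
            raise ValueError(f"task {task}: freehand line needs >= 2 vertices")
        if not all(_finite(x, y) for x, y in pts):
            raise ValueError(f"task {task}: non-finite freehand coordinate")
        return FreehandLine(task, pts, frame)
    if "rx" in value or "ry" in value:
        x, y = float(value["x"]), float(value["y"])
        rx, ry = float(value["rx"]), float(value["ry"])
        angle = float(value.get("angle", 0.0))
        if not _finite(x, y, rx, ry, angle):
            raise ValueError(f"task {task}: non-finite ellipse field")
        if rx <= 0 or ry <= 0:
            raise ValueError(f"task {task}: ellipse semi-axes must be positive")
        return EllipseMark(task, x, y, rx, ry, angle, frame)
    if "x" in value and "y" in value:
        x, y = float(value["x"]), float(value["y"])
        if not _finite(x, y):
            raise ValueError(f"task {task}: non-finite point coordinate")
        return PointMark(task, x, y, frame)
    raise ValueError(f"task {task}: unrecognised drawing payload keys {sorted(value)}")


def _row_annotations(raw: str) -> list:
    payload = json.loads(raw)
    if not isinstance(payload, list):
        raise ValueError("annotations JSON is not an array")
    out: list = []
    for entry in payload:
        task = str(entry["task"])
        value = entry["value"]
        if isinstance(value, list):
            for v in value:
                out.append(_parse_mark(task, v))
        else:
            out.append(_parse_mark(task, value))
    if not out:
        raise ValueError("row has no annotations")
    return out


def parse_classifications(
    path: str | Path,
) -> tuple[list[Classification], list[RejectedRow]]:
    """Parse a classification export CSV into typed records plus a reject report.

    A missing mandatory column is a hard error; a malformed row (bad JSON,
    invariant violation) is rejected with a reason.  ``#parsed + #rejected``
    always equals the row count.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"export lacks mandatory column(s): {missing}")
    parsed: list[Classification] = []
    rejected: list[RejectedRow] = []
    for idx, row in df.iterrows():
        cid = row["classification_id"]
        try:
            annotations = _row_annotations(row["annotations"])
            json.loads(row["subject_data"] or "{}")
            name = row["user_name"].strip()
            if name:
                contributor = pseudonymize(name)
            elif row.get("session", "").strip():
                contributor = pseudonymize(f"session:{row['session'].strip()}")
            else:
                # anonymous row without session: its own pseudo-contributor,
                # so anonymous votes are never collapsed together
                contributor = pseudonymize(f"anon-row:{idx}")
            parsed.append(
                Classification(
                    classification_id=cid,
                    contributor_id=contributor,
                    subject_id=row["subject_ids"],
                    workflow_id=row["workflow_id"],
                    workflow_version=row["workflow_version"],
                    created_at=row["created_at"],
                    annotations=annotations,
                )
            )
        except Exception as exc:
            rejected.append(RejectedRow(int(idx), cid, str(exc)))
    return parsed, rejected


def _version_key(version: str) -> tuple[int, ...]:
    parts = version.strip().split(".")
    if not parts or not all(p.isdigit() for p in parts):
        raise ValueError(f"unparsable workflow version: {version!r}")
    return tuple(int(p) for p in parts)


def filter_workflow(
    classifications: Sequence[Classification],
    workflow_id: str,
    min_version: str | None = None,
) -> tuple[list[Classification], list[RejectedRow]]:
    """Keep rows for one workflow at or above a version, comparing versions numerically.

    Dotted components are compared as integers (10.1 > 2.3); rows with
    unparsable versions are rejected with a reason.  Order is stable.
    """
    min_key = _version_key(min_version) if min_version is not None else None
    kept: list[Classification] = []
    rejected: list[RejectedRow] = []
    for i, c in enumerate(classifications):
        if c.workflow_id != workflow_id:
            continue
        if min_key is not None:
            try:
                key = _version_key(c.workflow_version)
            except ValueError as exc:
                rejected.append(RejectedRow(i, c.classification_id, str(exc)))
                continue
            if key < min_key:
                continue
        kept.append(c)
    return kept, rejected


def link_subjects(classifications: Sequence[Classification], manifest) -> tuple[list, list]:
    """Inner-join classifications to manifest rows on subject_id.

    Returns (linked, unlinked): linked is a list of (Classification, manifest
    row); classifications whose subject is absent from the manifest are
    returned separately, not dropped.
    """
    df = manifest.rows
    if df["subject_id"].duplicated().any():
        raise ValueError("manifest has duplicate subject rows")
    by_id = {row["subject_id"]: row for _, row in df.iterrows()}
    linked, unlinked = [], []
    for c in classifications:
        row = by_id.get(c.subject_id)
        if row is None:
            unlinked.append(c)
        else:
            linked.append((c, row))
    return linked, unlinked


def deduplicate_contributor(
    classifications: Sequence[Classification],
) -> tuple[list[Classification], list[Classification]]:
    """Keep one vote per (contributor, subject, workflow): the earliest.

    Ties on created_at are broken by lowest classification_id.  Later
    duplicates are returned for reporting.
    """
    best: dict[tuple[str, str, str], Classification] = {}
    for c in classifications:
        key = (c.contributor_id, c.subject_id, c.workflow_id)
        cur = best.get(key)
        if cur is None or (pd.Timestamp(c.created_at), c.classification_id) < (
            pd.Timestamp(cur.created_at),
            cur.classification_id,
        ):
            best[key] = c
    kept_set = {id(c) for c in best.values()}
    kept = [c for c in classifications if id(c) in kept_set]
    duplicates = [c for c in classifications if id(c) not in kept_set]
    return kept, duplicates
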