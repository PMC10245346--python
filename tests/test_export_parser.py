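import json

import pandas as pd
import pytest

from crowdvol.export_parser import (
    Answer,
    Classification,
    FreehandLine,
    PointMark,
    deduplicate_contributor,
    filter_workflow,
    link_subjects,
    parse_classifications,
    pseudonymize,
)
from crowdvol.subject_builder import Manifest

COLUMNS = [
    "classification_id",
    "user_name",
    "workflow_id",
    "workflow_version",
    "created_at",
    "annotations",
    "subject_data",
    "subject_ids",
]


def _write(tmp_path, rows, name="export.csv"):
    path = tmp_path / name
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)
    return path


def _row(cid="c1", user="alice", subject="s1", annotations=None, version="2.3", created="2024-01-01T00:00:00Z"):
    return {
        "classification_id": cid,
        "user_name": user,
        "workflow_id": "wf1",
        "workflow_version": version,
        "created_at": created,
        "annotations": json.dumps(
            annotations
            if annotations is not None
            else [{"task": "T0", "value": {"x": 1.5, "y": 2.5, "frame": 0}}]
        ),
        "subject_data": "{}",
        "subject_ids": subject,
    }


class TestParse:
    def test_point_and_question_rows(self, tmp_path):
        path = _write(
            tmp_path,
            [
                _row("c1"),
                _row("c2", annotations=[{"task": "T1", "value": "yes"}]),
            ],
        )
        parsed, rejected = parse_classifications(path)
        assert len(parsed) == 2 and not rejected
        assert parsed[0].annotations == [PointMark("T0", 1.5, 2.5, 0)]
        assert parsed[1].annotations == [Answer("T1", "yes")]
        # usernames are pseudonymized on ingest, never stored raw
        assert parsed[0].contributor_id != "alice"
        assert parsed[0].contributor_id == pseudonymize("alice")

    def test_all_annotation_variants(self, tmp_path):
        path = _write(
            tmp_path,
            [
                _row(
                    "c1",
                    annotations=[
                        {"task": "T0", "value": {"x": 1, "y": 2, "frame": 1}},
                        {"task": "T0", "value": {"x": 3, "y": 4, "rx": 2, "ry": 1, "angle": 30, "frame": 0}},
                        {"task": "T2", "value": {"points": [{"x": 0, "y": 0}, {"x": 1, "y": 1}], "frame": 2}},
                        {"task": "T1", "value": "empty"},
                    ],
                )
            ],
        )
        parsed, rejected = parse_classifications(path)
        assert not rejected
        kinds = [type(a).__name__ for a in parsed[0].annotations]
        assert kinds == ["PointMark", "EllipseMark", "FreehandLine", "Answer"]

    def test_header_only_file(self, tmp_path):
        path = _write(tmp_path, [])
        parsed, rejected = parse_classifications(path)
        assert parsed == [] and rejected == []

    def test_truncated_json_rejected_not_dropped(self, tmp_path):
        row = _row("c1")
        row["annotations"] = row["annotations"][:-5]
        path = _write(tmp_path, [row, _row("c2")])
        parsed, rejected = parse_classifications(path)
        assert len(parsed) == 1 and len(rejected) == 1
        assert rejected[0].classification_id == "c1"

    def test_parse_is_lossless_modulo_rejects(self, tmp_path):
        rows = [_row(f"c{i}") for i in range(5)]
        rows[2]["annotations"] = "not json"
        rows[4]["annotations"] = json.dumps([{"task": "T0", "value": {"x": 1, "y": 2, "rx": -1, "ry": 1, "frame": 0}}])
        parsed, rejected = parse_classifications(_write(tmp_path, rows))
        assert len(parsed) + len(rejected) == 5

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        df = pd.DataFrame([_row("c1")]).drop(columns=["workflow_version"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="workflow_version"):
            parse_classifications(path)

    def test_anonymous_rows_are_distinct_contributors(self, tmp_path):
        parsed, _ = parse_classifications(
            _write(tmp_path, [_row("c1", user=""), _row("c2", user="")])
        )
        assert parsed[0].contributor_id != parsed[1].contributor_id


class TestFilterWorkflow:
    def _cls(self, version):
        return Classification(f"c-{version}", "h:aaaaaaaaaaaa", "s1", "wf1", version,
                              "2024-01-01T00:00:00Z", [Answer("T1", "x")])

    def test_numeric_not_lexicographic(self):
        kept, _ = filter_workflow([self._cls(v) for v in ("1.1", "2.3", "10.1")], "wf1", "2.0")
        assert [c.workflow_version for c in kept] == ["2.3", "10.1"]

    def test_no_min_version_is_identity(self):
        cls = [self._cls("1.1"), self._cls("2.3")]
        kept, _ = filter_workflow(cls, "wf1")
        assert kept == cls

    def test_wrong_workflow_empty(self):
        kept, _ = filter_workflow([self._cls("1.1")], "other")
        assert kept == []

    def test_unparsable_version_rejected_with_reason(self):
        kept, rejected = filter_workflow([self._cls("beta")], "wf1", "1.0")
        assert kept == [] and len(rejected) == 1 and "beta" in rejected[0].reason


class TestLinkAndDedup:
    def _manifest(self, ids):
        return Manifest(pd.DataFrame({"subject_id": ids, "x": 0, "y": 0, "z": 0}))

    def _cls(self, cid, subject, contributor="h:aaaaaaaaaaaa", created="2024-01-01T00:00:00Z"):
        return Classification(cid, contributor, subject, "wf1", "1.0", created, [Answer("T1", "x")])

    def test_inner_join_reports_unlinked(self):
        cls = [self._cls("c1", "s1"), self._cls("c2", "s2"), self._cls("c3", "s9")]
        linked, unlinked = link_subjects(cls, self._manifest(["s1", "s2"]))
        assert len(linked) == 2 and [c.classification_id for c in unlinked] == ["c3"]

    def test_empty_manifest_all_unlinked(self):
        linked, unlinked = link_subjects([self._cls("c1", "s1")], self._manifest([]))
        assert linked == [] and len(unlinked) == 1

    def test_duplicate_manifest_rows_hard_error(self):
        m = Manifest(pd.DataFrame({"subject_id": ["s1"], "x": 0, "y": 0, "z": 0}))
        m.rows = pd.concat([m.rows, m.rows])  # bypass constructor to simulate corruption
        with pytest.raises(ValueError):
            link_subjects([self._cls("c1", "s1")], m)

    def test_dedup_keeps_earliest(self):
        a = self._cls("c1", "s1", created="2024-01-01T00:00:05Z")
        b = self._cls("c2", "s1", created="2024-01-01T00:00:01Z")
        kept, dups = deduplicate_contributor([a, b])
        assert kept == [b] and dups == [a]

    def test_dedup_tie_break_lowest_id(self):
        a = self._cls("c2", "s1")
        b = self._cls("c1", "s1")
        kept, _ = deduplicate_contributor([a, b])
        assert kept == [b]

    def test_all_distinct_identity(self):
        cls = [self._cls("c1", "s1"), self._cls("c2", "s2", contributor="h:bbbbbbbbbbbb")]
        kept, dups = deduplicate_contributor(cls)
        assert kept == cls and dups == []


def test_round_trip_with_simulator_export(tmp_path):
    """parse(write(x)) == x for every annotation variant."""
    from crowdvol.export_parser import EllipseMark
    from crowdvol.simulate import write_export

    original = [
        Classification(
            "c000001",
            pseudonymize("vol-a"),
            "s1",
            "wf1",
            "2.10",
            "2024-01-01T00:00:00+00:00",
            [
                PointMark("T0", 3.25, 4.5, 1),
                EllipseMark("T0", 1.0, 2.0, 3.0, 4.0, 15.0, 0),
                FreehandLine("T2", ((0.0, 0.0), (1.5, 0.25), (1.0, 2.0)), 2),
                Answer("T1", "alpha"),
            ],
        ),
        Classification(
            "c000002",
            pseudonymize("vol-b"),
            "s2",
            "wf1",
            "2.10",
            "2024-01-01T00:00:01+00:00",
            [Answer("T1", "beta")],
        ),
    ]
    write_export(original, tmp_path / "export.csv")
    parsed, rejected = parse_classifications(tmp_path / "export.csv")
    assert rejected == []
    assert parsed == original
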