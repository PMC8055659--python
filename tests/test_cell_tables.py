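"""Cell-table reading, validation, writing, and coordinate-based merging."""

import numpy as np
import pandas as pd
import pytest

import mifspat as m
from mifspat.cell_tables import frames_by_key

from conftest import make_frame

TOY_CSV = """sample_id,roi_id,timepoint,cell_id,x_um,y_um,CD3,CD8
S1,R1,week1,c1,10.0,20.0,1,0
S1,R1,week1,c2,30.0,40.0,1,1
S1,R1,week1,c3,50.5,60.5,0,0
"""

SYNONYM_CSV = """Sample Name,ROI,week,Cell ID,Cell X Position,Cell Y Position,CD3,CD8
S1,R1,week1,c1,10.0,20.0,pos,neg
S1,R1,week1,c2,30.0,40.0,+,TRUE
S1,R1,week1,c3,50.5,60.5,neg,FALSE
"""


class TestReadCellTable:
    def test_toy_csv_parses_to_one_frame(self, tmp_path):
        p = tmp_path / "toy.csv"
        p.write_text(TOY_CSV)
        frames = m.read_cell_table(p)
        assert len(frames) == 1
        f = frames[0]
        assert f.key() == ("S1", "R1", "week1")
        assert f.n_cells == 3
        assert f.marker_names == ["CD3", "CD8"]
        assert f.cells["CD3"].tolist() == [True, True, False]
        assert f.cells["CD8"].tolist() == [False, True, False]

    def test_header_synonyms_give_identical_result(self, tmp_path):
        p1, p2 = tmp_path / "canon.csv", tmp_path / "vendor.csv"
        p1.write_text(TOY_CSV)
        p2.write_text(SYNONYM_CSV)
        f1, f2 = m.read_cell_table(p1)[0], m.read_cell_table(p2)[0]
        pd.testing.assert_frame_equal(f1.cells, f2.cells)

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,roi_id,cell_id,x_um,y_um,CD3\nS1,R1,c1,1,1,1\n")
        with pytest.raises(m.CellTableFormatError, match="timepoint"):
            m.read_cell_table(p)

    def test_non_numeric_coordinate_rejected_with_line_number(self, tmp_path, caplog):
        p = tmp_path / "bad.csv"
        p.write_text(TOY_CSV.replace("30.0", "oops"))
        with caplog.at_level("WARNING"):
            frames = m.read_cell_table(p)
        assert frames[0].n_cells == 2  # row conserved minus the rejected one
        assert any(":3:" in r.message for r in caplog.records)

    def test_strict_mode_raises_on_bad_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(TOY_CSV.replace("30.0", "oops"))
        with pytest.raises(m.CellTableFormatError, match="non-numeric"):
            m.read_cell_table(p, strict=True)

    def test_duplicate_cell_id_fails_validation(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(TOY_CSV.replace("c2", "c1"))
        with pytest.raises(m.ValidationError, match="duplicate cell_id"):
            m.read_cell_table(p)

    def test_generated_file_conserves_marker_counts(self, tmp_path, small_cohort):
        frames, truth = small_cohort
        f = frames[0]
        path = tmp_path / "gen.csv"
        m.write_cell_table([f], path)
        (back,) = m.read_cell_table(path)
        for marker in f.marker_names:
            assert back.cells[marker].sum() == f.cells[marker].sum()
        # per-class bookkeeping recorded at generation time
        assert back.cells["CK"].sum() >= truth["samples"]["S01"]["rois"]["R1"][
            "n_by_class_week1"
        ]["malignant"]


class TestWriteRoundTrip:
    def test_empty_frame_list_writes_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        m.write_cell_table([], p)
        assert p.read_text().strip() == "sample_id,roi_id,timepoint,cell_id,x_um,y_um"

    def test_two_cells_two_rows(self, tmp_path):
        f = make_frame(
            [("a", 1.0, 2.0, {"CD3": True}), ("b", 3.0, 4.0, {})], ["CD3"]
        )
        p = tmp_path / "two.csv"
        m.write_cell_table([f], p)
        assert len(p.read_text().strip().splitlines()) == 3

    def test_random_cohort_round_trips_exactly(self, tmp_path, small_cohort):
        frames, _ = small_cohort
        p = tmp_path / "cohort.csv"
        m.write_cell_table(frames, p)
        back = m.read_cell_table(p)
        orig = frames_by_key(frames)
        assert set(frames_by_key(back)) == set(orig)
        for f in back:
            o = orig[f.key()]
            pd.testing.assert_frame_equal(
                f.cells.sort_values("cell_id").reset_index(drop=True),
                o.cells.sort_values("cell_id").reset_index(drop=True),
            )


def _split_by_marker(frames, markers):
    return [
        [
            m.ROIFrame(
                f.sample_id, f.roi_id, f.timepoint, f.width, f.height,
                f.cells[["cell_id", "x_um", "y_um", marker]].copy(),
            )
            for f in frames
        ]
        for marker in markers
    ]


class TestMergeMarkerTables:
    def _two_tables(self):
        t1 = [make_frame([("a1", 1.0, 2.0, {"CD3": True}),
                          ("a2", 5.0, 6.0, {"CD3": False})], ["CD3"])]
        t2 = [make_frame([("b1", 1.0, 2.0, {"CD8": True}),
                          ("b2", 5.0, 6.0, {"CD8": True})], ["CD8"])]
        return t1, t2

    def test_identical_coordinates_merge_both_markers(self):
        merged, report = m.merge_marker_tables(self._two_tables())
        (f,) = merged
        assert f.marker_names == ["CD3", "CD8"]
        assert f.n_cells == 2
        assert report["CD3"] == {"n_rows": 2, "n_matched": 2, "n_dropped": 0}

    def test_offset_cell_is_dropped_and_reported(self):
        t1, t2 = self._two_tables()
        t2[0].cells.loc[1, "x_um"] = 10.0  # 5 um off -> no match
        merged, report = m.merge_marker_tables([t1, t2])
        assert merged[0].n_cells == 1
        assert report["CD3"]["n_dropped"] == 1
        assert report["CD8"]["n_dropped"] == 1

    def test_split_then_merge_recovers_consolidated_table(self):
        rng = np.random.default_rng(42)
        n = 200
        cells = [
            (f"c{i}", round(rng.uniform(0, 931), 1), round(rng.uniform(0, 698), 1),
             {"CK": bool(rng.random() < 0.5), "CD3": bool(rng.random() < 0.3),
              "CD68": bool(rng.random() < 0.1)})
            for i in range(n)
        ]
        consolidated = make_frame(cells, ["CD3", "CD68", "CK"])
        if consolidated.cells[["x_um", "y_um"]].duplicated().any():
            pytest.skip("coordinate collision in random fixture")
        tables = _split_by_marker([consolidated], ["CK", "CD3", "CD68"])
        merged, report = m.merge_marker_tables(tables)
        (f,) = merged
        assert f.n_cells == n
        got = f.cells.sort_values(["x_um", "y_um"]).reset_index(drop=True)
        want = consolidated.cells.sort_values(["x_um", "y_um"]).reset_index(drop=True)
        for marker in ["CD3", "CD68", "CK"]:
            assert got[marker].tolist() == want[marker].tolist()

    def test_merge_is_order_independent(self):
        t1, t2 = self._two_tables()
        a, _ = m.merge_marker_tables([t1, t2])
        b, _ = m.merge_marker_tables([t2, t1])
        pd.testing.assert_frame_equal(a[0].cells, b[0].cells)

    def test_conservation_matched_plus_dropped(self):
        t1, t2 = self._two_tables()
        t2[0].cells.loc[1, "x_um"] = 10.0
        _, report = m.merge_marker_tables([t1, t2])
        for lab in report:
            assert report[lab]["n_matched"] + report[lab]["n_dropped"] == report[lab]["n_rows"]

    def test_collision_within_tolerance_is_ambiguity_error(self):
        t1 = [make_frame([("a1", 1.04, 2.0, {"CD3": True}),
                          ("a2", 1.01, 2.0, {"CD3": False})], ["CD3"])]
        t2 = [make_frame([("b1", 1.0, 2.0, {"CD8": True})], ["CD8"])]
        with pytest.raises(m.MergeAmbiguityError):
            m.merge_marker_tables([t1, t2])

    def test_disjoint_keys_error(self):
        t1, t2 = self._two_tables()
        t2[0].roi_id = "R99"
        with pytest.raises(m.MergeError, match="no .* keys"):
            m.merge_marker_tables([t1, t2])


class TestValidation:
    def test_out_of_bounds_coordinate(self):
        f = make_frame([("a", 5000.0, 2.0, {})], ["CD3"])
        with pytest.raises(m.ValidationError, match="outside"):
            m.validate_frame(f)

    def test_missing_required_marker(self):
        f = make_frame([("a", 1.0, 2.0, {})], ["CD3"])
        with pytest.raises(m.ValidationError, match="CD8"):
            m.validate_frame(f, required_markers=["CD3", "CD8"])
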