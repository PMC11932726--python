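import numpy as np
import pandas as pd
import pytest

import tribune as tb
from tribune.data_model import ValidationError


def write_csv(path, text):
    path.write_text(text)
    return path


class TestExpressionTableIO:
    def test_basic_parse(self, tmp_path):
        p = write_csv(tmp_path / "cells.csv",
                      "cell_id,CD3,CD20\nc1,0.1,0.9\nc2,0.5,0.2\nc3,0.7,0.3\n")
        X = tb.read_expression_table(p, id_column="cell_id")
        assert X.n_cells == 3
        assert X.marker_names == ["CD3", "CD20"]
        assert X.cell_ids == ["c1", "c2", "c3"]
        np.testing.assert_allclose(X.values[:, 0], [0.1, 0.5, 0.7])

    def test_empty_numeric_cell_cites_row(self, tmp_path):
        p = write_csv(tmp_path / "cells.csv", "cell_id,CD3\nc1,0.1\nc2,\nc3,0.3\n")
        with pytest.raises(ValidationError, match="row 1"):
            tb.read_expression_table(p, id_column="cell_id")

    def test_non_numeric_cell_names_column(self, tmp_path):
        p = write_csv(tmp_path / "cells.csv", "cell_id,CD3\nc1,abc\n")
        with pytest.raises(ValidationError, match="CD3"):
            tb.read_expression_table(p, id_column="cell_id")

    def test_coordinate_columns_routed(self, tmp_path):
        p = write_csv(tmp_path / "cells.csv",
                      "cell_id,CD3,x,y\nc1,0.1,10,20\nc2,0.5,30,40\n")
        X = tb.read_expression_table(p, id_column="cell_id", x_column="x", y_column="y")
        assert X.marker_names == ["CD3"]
        np.testing.assert_allclose(X.coords, [[10, 20], [30, 40]])

    def test_unnamed_columns_dropped_with_warning(self, tmp_path, caplog):
        p = write_csv(tmp_path / "cells.csv",
                      "cell_id,CD3,junk\nc1,0.1,zzz\n")
        with caplog.at_level("WARNING", logger="tribune"):
            X = tb.read_expression_table(p, marker_columns=["CD3"], id_column="cell_id")
        assert X.marker_names == ["CD3"]
        assert "junk" in caplog.text

    def test_duplicate_marker_rejected(self, tmp_path):
        p = write_csv(tmp_path / "cells.csv", "CD3,CD3\n1,2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            tb.read_expression_table(p)

    def test_missing_values_rejected(self):
        with pytest.raises(ValidationError, match="non-finite"):
            tb.ExpressionMatrix(["a", "b"], ["M"], np.array([[1.0], [np.nan]]))

    def test_expression_roundtrip_exact(self, tmp_path, rng):
        X = tb.ExpressionMatrix(
            cell_ids=[f"c{i}" for i in range(20)],
            marker_names=["A", "B", "C"],
            values=rng.uniform(size=(20, 3)),
            coords=rng.uniform(size=(20, 2)),
        )
        p = tmp_path / "x.csv"
        tb.write_expression_table(X, p)
        X2 = tb.read_expression_table(p, id_column="cell_id",
                                      x_column="x", y_column="y")
        assert X2.cell_ids == X.cell_ids
        assert X2.marker_names == X.marker_names
        # values compared exactly as written, at full printed precision
        np.testing.assert_array_equal(X2.values, X.values)
        np.testing.assert_array_equal(X2.coords, X.coords)


class TestLogicValidation:
    def test_entry_outside_alphabet(self):
        with pytest.raises(ValidationError, match="not in"):
            tb.LogicTable("L", tb.ROOT_PARENT, ["A"], ["m1", "m2"],
                          np.array([[1, 2]]))

    def test_no_positive_marker(self):
        with pytest.raises(ValidationError, match="no positive"):
            tb.LogicTable("L", tb.ROOT_PARENT, ["Stroma"], ["m1", "m2"],
                          np.array([[0, -1]]))

    def test_orphan_parent_label(self, tiny_logic):
        child = tb.LogicTable("sub", "Ghost", ["X"], ["CD3"], np.array([[1]]))
        with pytest.raises(ValidationError, match="Ghost"):
            tb.LogicHierarchy([tiny_logic, child])

    def test_reserved_labels_rejected(self):
        for bad in ("other", "undefined", ""):
            with pytest.raises(ValidationError, match="reserved"):
                tb.LogicTable("L", tb.ROOT_PARENT, [bad], ["m"], np.array([[1]]))

    def test_parent_at_earlier_level_accepted(self, tiny_logic):
        child = tb.LogicTable("sub", "Immune", ["Tcell", "Bcell"], ["CD3", "CD45"],
                              np.array([[1, 0], [-1, 1]]))
        h = tb.LogicHierarchy([tiny_logic, child])
        assert h.level_names == ["global", "sub"]

    def test_missing_logic_marker_is_hard_error(self, tiny_logic, rng):
        X = tb.ExpressionMatrix(["a"], ["PanCK"], rng.uniform(size=(1, 1)))
        with pytest.raises(ValidationError, match="CD45"):
            X.marker_values(tiny_logic.markers)


class TestLogicHierarchyIO:
    def _write_dir(self, d):
        d.mkdir()
        (d / "1_global__root.csv").write_text(
            "cell_type,PanCK,CD45,CD3\nTumor,1,-1,0\nImmune,-1,1,1\n")
        (d / "2_sub__Immune.csv").write_text(
            "cell_type,CD3,CD45\nTcell,1,0\nBcell,-1,1\n")
        return d

    def test_read_directory(self, tmp_path):
        h = tb.read_logic_hierarchy(self._write_dir(tmp_path / "logic"))
        assert h.level_names == ["global", "sub"]
        assert h.levels[0].parent_label == tb.ROOT_PARENT
        assert h.levels[1].parent_label == "Immune"
        np.testing.assert_array_equal(h.levels[0].entries, [[1, -1, 0], [-1, 1, 1]])

    def test_workbook_matches_directory(self, tmp_path):
        from openpyxl import Workbook

        d = self._write_dir(tmp_path / "logic")
        wb = Workbook()
        ws = wb.active
        ws.title = "global"
        ws.append(["parent=root"])
        ws.append(["cell_type", "PanCK", "CD45", "CD3"])
        ws.append(["Tumor", 1, -1, 0])
        ws.append(["Immune", -1, 1, 1])
        ws2 = wb.create_sheet("sub")
        ws2.append(["parent=Immune"])
        ws2.append(["cell_type", "CD3", "CD45"])
        ws2.append(["Tcell", 1, 0])
        ws2.append(["Bcell", -1, 1])
        xlsx = tmp_path / "logic.xlsx"
        wb.save(xlsx)

        h_dir = tb.read_logic_hierarchy(d)
        h_wb = tb.read_logic_hierarchy(xlsx)
        assert h_wb.level_names == h_dir.level_names
        for a, b in zip(h_wb.levels, h_dir.levels):
            assert a.cell_types == b.cell_types
            assert a.markers == b.markers
            assert a.parent_label == b.parent_label
            np.testing.assert_array_equal(a.entries, b.entries)

    def test_roundtrip_write_read(self, tmp_path):
        h = tb.read_logic_hierarchy(self._write_dir(tmp_path / "logic"))
        tb.write_logic_hierarchy(h, tmp_path / "out")
        h2 = tb.read_logic_hierarchy(tmp_path / "out")
        for a, b in zip(h.levels, h2.levels):
            np.testing.assert_array_equal(a.entries, b.entries)

    def test_bad_filename_rejected(self, tmp_path):
        d = tmp_path / "logic"
        d.mkdir()
        (d / "global.csv").write_text("cell_type,m\nA,1\n")
        with pytest.raises(ValidationError, match="does not match"):
            tb.read_logic_hierarchy(d)


class TestLabelIO:
    def _result(self):
        return tb.LabelResult(
            cell_ids=["c1", "c2"],
            level_names=["global"],
            labels=np.array([["Tumor"], ["other"]], dtype=object),
            best_scores=np.array([[0.9], [0.01]]),
            score_gaps=np.array([[0.5], [0.004]]),
        )

    def test_written_shape(self, tmp_path):
        p = tmp_path / "labels.csv"
        tb.write_labels(self._result(), p)
        df = pd.read_csv(p)
        assert list(df.columns) == ["cell_id", "global", "final_label",
                                    "best_score", "score_gap"]
        assert len(df) == 2

    def test_roundtrip_labels_exact(self, tmp_path):
        p = tmp_path / "labels.csv"
        res = self._result()
        tb.write_labels(res, p)
        back = tb.read_labels(p)
        np.testing.assert_array_equal(back.labels, res.labels)
        np.testing.assert_array_equal(back.final_labels(), res.final_labels())

    def test_other_at_root_leaves_deeper_level_blank(self, tmp_path):
        res = tb.LabelResult(
            cell_ids=["c1"],
            level_names=["global", "sub"],
            labels=np.array([["other", tb.NOT_EVALUATED]], dtype=object),
            best_scores=np.array([[0.01, np.nan]]),
            score_gaps=np.array([[0.0, np.nan]]),
        )
        p = tmp_path / "labels.csv"
        tb.write_labels(res, p)
        df = pd.read_csv(p, keep_default_na=False)
        assert df.loc[0, "final_label"] == "other"
        assert df.loc[0, "sub"] == ""
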