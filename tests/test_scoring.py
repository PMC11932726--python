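import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tribune as tb
from tribune.scoring import NodeMatrix

from .oracles import brute_force_cell_scores, brute_force_labels


def make_nm(values, markers=None, scaled=False):
    values = np.asarray(values, dtype=float)
    nm = NodeMatrix(
        node_ids=np.arange(len(values)),
        marker_names=markers or [f"m{j}" for j in range(values.shape[1])],
        values=values,
        occupancy=np.ones(len(values), dtype=int),
    )
    return tb.scale_node_matrix(nm) if scaled else nm


class TestNodeMatrix:
    def test_even_count_median(self):
        assign = tb.NodeAssignment(node_index=np.array([0, 0]),
                                   occupancy=np.array([2]))
        nm = tb.build_node_matrix(np.array([[1.0], [3.0]]), assign, ["A"])
        assert nm.values[0, 0] == 2.0

    def test_single_member_verbatim(self):
        assign = tb.NodeAssignment(node_index=np.array([0]), occupancy=np.array([1]))
        nm = tb.build_node_matrix(np.array([[0.3, 0.7]]), assign, ["A", "B"])
        np.testing.assert_array_equal(nm.values, [[0.3, 0.7]])

    def test_empty_nodes_dropped(self, rng):
        X = rng.uniform(size=(30, 2))
        node_index = rng.choice([0, 5, 11], size=30)
        occ = np.bincount(node_index, minlength=16)
        nm = tb.build_node_matrix(X, tb.NodeAssignment(node_index, occ), ["A", "B"])
        assert nm.n_nodes == 3
        np.testing.assert_array_equal(nm.node_ids, [0, 5, 11])


class TestScaling:
    def test_closed_form(self):
        nm = tb.scale_node_matrix(make_nm([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(nm.values[:, 0], [0, 0.5, 1])

    def test_constant_column_zero(self):
        nm = tb.scale_node_matrix(make_nm([[5.0], [5.0]]))
        np.testing.assert_array_equal(nm.values, 0.0)

    def test_single_node_all_zero(self):
        nm = tb.scale_node_matrix(make_nm([[3.0, 7.0]]))
        np.testing.assert_array_equal(nm.values, 0.0)


class TestReferenceVector:
    def test_p99_linear_interpolation(self):
        nm = make_nm([[0.0], [0.5], [1.0]])
        vhat = tb.reference_vector(nm, np.array([1]))
        assert vhat[0] == pytest.approx(0.99)  # between 0.5 and 1 at rank 1.98

    def test_negative_marker_is_minimum(self):
        nm = make_nm([[0.2], [0.7]], scaled=True)
        vhat = tb.reference_vector(nm, np.array([-1]))
        assert vhat[0] == 0.0

    def test_neutral_marker_excluded(self):
        nm = make_nm([[0.2, 0.8], [0.7, 0.1]])
        vhat = tb.reference_vector(nm, np.array([1, 0]))
        assert np.isnan(vhat[1])


class TestScoreNodes:
    def test_perfect_match_scores_one(self):
        logic = tb.LogicTable("L", "root", ["A"], ["m0", "m1"],
                              np.array([[1, -1]]))
        # positive column max has multiplicity 2, so P99 = 1 exactly;
        # node 1 sits exactly on (P99, min) and must score 1
        nm = make_nm([[0.0, 0.0], [1.0, 0.0], [1.0, 0.5]],
                     markers=["m0", "m1"])
        table = tb.score_nodes(nm, logic)
        assert table.scores[1, 0] == pytest.approx(1.0)

    def test_hand_computed_score(self):
        # v=(0.8, 0.3), logic (+1, -1), vhat=(0.9, 0) -> s = 0.95
        logic = tb.LogicTable("L", "root", ["A"], ["m0", "m1"],
                              np.array([[1, -1]]))
        # column m0 = [0, 0.8, 0.9, 0.9]: P99 = 0.9 exactly; m1 min = 0
        nm = make_nm([[0.0, 0.0], [0.8, 0.3], [0.9, 0.1], [0.9, 0.6]],
                     markers=["m0", "m1"])
        table = tb.score_nodes(nm, logic)
        assert table.scores[1, 0] == pytest.approx(0.95)

    def test_maximal_unit_error_scores_zero(self):
        logic = tb.LogicTable("L", "root", ["A"], ["m0"], np.array([[1]]))
        nm = make_nm([[0.0], [1.0]], markers=["m0"])
        table = tb.score_nodes(nm, logic)
        vhat = 0.99
        assert table.scores[0, 0] == pytest.approx(1 - vhat**2)

    def test_scores_bounded(self, rng):
        logic = tb.LogicTable("L", "root", ["A", "B"], ["m0", "m1", "m2"],
                              np.array([[1, -1, 0], [-1, 1, 1]]))
        nm = make_nm(rng.uniform(size=(40, 3)), markers=["m0", "m1", "m2"],
                     scaled=True)
        table = tb.score_nodes(nm, logic)
        assert (table.scores >= 0).all() and (table.scores <= 1).all()

    def test_permuting_cell_types_permutes_columns(self, rng):
        markers = ["m0", "m1", "m2"]
        entries = np.array([[1, -1, 0], [-1, 1, 1]])
        fwd = tb.LogicTable("L", "root", ["A", "B"], markers, entries)
        rev = tb.LogicTable("L", "root", ["B", "A"], markers, entries[::-1])
        nm = make_nm(rng.uniform(size=(25, 3)), markers=markers, scaled=True)
        t1, t2 = tb.score_nodes(nm, fwd), tb.score_nodes(nm, rev)
        np.testing.assert_allclose(t1.scores, t2.scores[:, ::-1])
        th = tb.Thresholds(other_threshold=0.0, undefined_threshold=0.0)
        np.testing.assert_array_equal(tb.assign_labels(t1, th),
                                      tb.assign_labels(t2, th))


class TestScoreCells:
    def test_two_cell_hand_computation(self):
        logic = tb.LogicTable("L", "root", ["A"], ["m0"], np.array([[1]]))
        table = tb.score_cells(np.array([[0.0], [10.0]]), logic, ["m0"])
        np.testing.assert_allclose(table.scores[:, 0], [0.0199, 0.9999])

    def test_single_cell_degenerate_all_types_tie(self):
        logic = tb.LogicTable("L", "root", ["A", "B"], ["m0", "m1"],
                              np.array([[1, -1], [-1, 1]]))
        table = tb.score_cells(np.array([[3.0, 9.0]]), logic, ["m0", "m1"])
        np.testing.assert_array_equal(table.scores, 1.0)
        labels = tb.assign_labels(table, tb.Thresholds(0.04, 0.001))
        assert labels[0] == tb.UNDEFINED_LABEL

    def test_equals_score_nodes_on_same_rows(self, rng):
        logic = tb.LogicTable("L", "root", ["A", "B"], ["m0", "m1", "m2"],
                              np.array([[1, -1, 0], [-1, 1, 1]]))
        V = rng.uniform(size=(50, 3))
        by_cells = tb.score_cells(V, logic, ["m0", "m1", "m2"])
        nm = tb.scale_node_matrix(make_nm(V, markers=["m0", "m1", "m2"]))
        by_nodes = tb.score_nodes(nm, logic)
        np.testing.assert_allclose(by_cells.scores, by_nodes.scores, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        entries = np.array([[1, -1, 0, 1], [-1, 1, 1, 0], [0, -1, 1, 1]])
        logic = tb.LogicTable("L", "root", ["A", "B", "C"],
                              ["m0", "m1", "m2", "m3"], entries)
        V = rng.uniform(size=(200, 4))
        table = tb.score_cells(V, logic, logic.markers)
        expected = brute_force_cell_scores(V, entries)
        np.testing.assert_allclose(table.scores, expected, atol=1e-12)
        th = tb.Thresholds(0.04, 0.001)
        np.testing.assert_array_equal(
            tb.assign_labels(table, th),
            brute_force_labels(expected, logic.cell_types, 0.04, 0.001),
        )


class TestAssignLabels:
    def table(self, rows, types=("A", "B")):
        return tb.ScoreTable(row_ids=np.arange(len(rows)),
                             cell_types=list(types),
                             scores=np.asarray(rows, dtype=float))

    def test_clear_winner(self):
        labels = tb.assign_labels(self.table([[0.9, 0.5]]), tb.Thresholds(0.04, 0.001))
        assert labels[0] == "A"

    def test_low_signal_is_other(self):
        labels = tb.assign_labels(self.table([[0.03, 0.02]]), tb.Thresholds(0.04, 0.001))
        assert labels[0] == tb.OTHER_LABEL

    def test_close_race_is_undefined(self):
        labels = tb.assign_labels(self.table([[0.9000, 0.8995]]),
                                  tb.Thresholds(0.04, 0.001))
        assert labels[0] == tb.UNDEFINED_LABEL

    def test_other_takes_precedence_over_undefined(self):
        labels = tb.assign_labels(self.table([[0.03, 0.0299]]), tb.Thresholds(0.04, 0.01))
        assert labels[0] == tb.OTHER_LABEL

    def test_single_type_gap_is_score_minus_zero(self):
        table = self.table([[0.5]], types=("A",))
        _, best, gap = table.best()
        assert gap[0] == best[0] == 0.5
        assert tb.assign_labels(table, tb.Thresholds(0.04, 0.001))[0] == "A"

    def test_every_row_gets_exactly_one_label(self, rng):
        table = self.table(rng.uniform(size=(100, 2)))
        labels = tb.assign_labels(table, tb.Thresholds(0.3, 0.05))
        valid = {"A", "B", tb.OTHER_LABEL, tb.UNDEFINED_LABEL}
        assert set(labels) <= valid

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_threshold_monotonicity(self, t_other, t_undef):
        rng = np.random.default_rng(99)
        table = self.table(rng.uniform(size=(60, 2)))
        lo = tb.assign_labels(table, tb.Thresholds(t_other * 0.5, t_undef * 0.5))
        hi = tb.assign_labels(table, tb.Thresholds(t_other, t_undef))
        assert (hi == tb.OTHER_LABEL).sum() >= (lo == tb.OTHER_LABEL).sum()
        undef_hi = ((hi == tb.UNDEFINED_LABEL) | (hi == tb.OTHER_LABEL)).sum()
        undef_lo = ((lo == tb.UNDEFINED_LABEL) | (lo == tb.OTHER_LABEL)).sum()
        assert undef_hi >= undef_lo
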