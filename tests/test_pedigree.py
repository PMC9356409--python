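import numpy as np
import pytest

from _oracles import lsap_brute
from budtrack.data_model import (
    AnnotationTable,
    LabelFrame,
    validate_annotation_table,
)
from budtrack.pedigree import (
    EligibilityError,
    PairingProblem,
    annotate_division,
    build_annotations,
    check_assignment_eligibility,
    correct_mother,
    pair_buds,
    pairing_problem,
    undo_division,
)


def _row(frame_i, cell, stage="G1", gen=2, rel=-1, relationship="mother",
         emerg=-1, division=-1, history=True):
    return dict(
        frame_i=frame_i, Cell_ID=cell, cell_cycle_stage=stage, generation_num=gen,
        relative_ID=rel, relationship=relationship, emerg_frame_i=emerg,
        division_frame_i=division, is_history_known=history,
    )


def budding_table(s_frames=range(5, 10), mother=1, bud=2, pre_frames=range(0, 5),
                  mother_gen=2):
    """Mother alone in G1, then an S/G2/M stretch with an attached bud."""
    rows = []
    for f in pre_frames:
        rows.append(_row(f, mother, gen=mother_gen))
    for f in s_frames:
        rows.append(_row(f, mother, stage="S/G2/M", gen=mother_gen, rel=bud))
        rows.append(_row(f, bud, stage="S/G2/M", gen=0, rel=mother,
                         relationship="bud", emerg=min(s_frames)))
    return AnnotationTable.from_rows(rows)


class TestPairBuds:
    def test_single_candidate_always_paired(self):
        problem = PairingProblem([10], [3], np.array([[250.0]]))
        res = pair_buds(problem)
        assert res.pairs == {10: 3}
        assert res.warnings == []

    def test_matches_brute_force_on_given_costs(self):
        cost = np.array([[2.0, 10.0], [9.0, 3.0]])
        res = pair_buds(PairingProblem([10, 11], [1, 2], cost))
        pairs, best = lsap_brute(cost)
        assert res.pairs == {10: 1, 11: 2}
        assert best == 5.0

    def test_insufficient_g1_warns_and_assigns_subset(self):
        cost = np.array([[1.0], [4.0]])
        res = pair_buds(PairingProblem([10, 11], [3], cost))
        assert len(res.pairs) == 1
        assert res.pairs == {10: 3}
        assert [w.kind for w in res.warnings] == ["insufficient_G1"]

    def test_empty_problem_is_empty_result(self):
        res = pair_buds(PairingProblem([], [1, 2], np.zeros((0, 2))))
        assert res.pairs == {} and res.warnings == []

    def test_lsap_equals_exhaustive_on_random_problems(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n_a = int(rng.integers(1, 6))
            n_b = int(rng.integers(1, 6))
            cost = rng.uniform(0, 100, size=(n_a, n_b))
            res = pair_buds(PairingProblem(list(range(100, 100 + n_a)),
                                           list(range(1, 1 + n_b)), cost))
            _, best = lsap_brute(cost)
            total = sum(
                cost[a - 100, res.pairs[a] - 1] for a in res.pairs
            )
            assert total == pytest.approx(best)

    def test_contour_cost_prefers_touching_cells(self):
        img = np.zeros((40, 60), np.int32)
        img[10:20, 10:20] = 1   # G1 cell, touching the bud
        img[10:20, 40:50] = 2   # distant G1 cell
        img[12:16, 20:24] = 5   # bud adjacent to cell 1
        problem = pairing_problem(LabelFrame(img), [5], [1, 2])
        assert problem.cost[0, 0] < problem.cost[0, 1]
        res = pair_buds(problem)
        assert res.pairs == {5: 1}


class TestEligibility:
    def _table(self):
        rows = [
            _row(0, 1), _row(0, 2), _row(0, 3),
            _row(1, 1, stage="S/G2/M", rel=4),
            _row(1, 2), _row(1, 3),
            _row(1, 4, stage="S/G2/M", gen=0, rel=1, relationship="bud", emerg=1),
            _row(2, 1, stage="S/G2/M", rel=4),
            _row(2, 2), _row(2, 3),
            _row(2, 4, stage="S/G2/M", gen=0, rel=1, relationship="bud", emerg=1),
        ]
        return AnnotationTable.from_rows(rows)

    def test_free_g1_mother_is_eligible(self):
        assert check_assignment_eligibility(self._table(), 4, 2) is None

    def test_mother_with_other_bud_rejected(self):
        table = self._table()
        # give cell 2 its own bud 5 at frame 2 (inside bud 4's lifetime)
        table.add_row(**_row(2, 5, stage="S/G2/M", gen=0, rel=2, relationship="bud", emerg=2))
        table.set_values(2, 2, cell_cycle_stage="S/G2/M", relative_ID=5)
        v = check_assignment_eligibility(table, 4, 2)
        assert v is not None and v.rule == "mother_already_has_bud"
        assert "5" in v.message

    def test_mother_in_s_at_pairing_frame_rejected(self):
        table = self._table()
        table.set_values(1, 3, cell_cycle_stage="S/G2/M", relative_ID=9)
        v = check_assignment_eligibility(table, 4, 3)
        assert v is not None and v.rule == "mother_not_G1"

    def test_unknown_labels_raise(self):
        with pytest.raises(KeyError):
            check_assignment_eligibility(self._table(), 99, 2)


class TestDivisionAnnotation:
    def test_annotate_propagates_to_future_s_frames(self):
        table = budding_table(s_frames=range(5, 10))
        out = annotate_division(table, 7, 1)
        for f in range(5, 7):
            assert out.get(f, 1)["cell_cycle_stage"] == "S/G2/M"
        for f in range(7, 10):
            assert out.get(f, 1)["cell_cycle_stage"] == "G1"
            assert int(out.get(f, 1)["division_frame_i"]) == 7
            assert out.get(f, 2)["cell_cycle_stage"] == "G1"
            assert out.get(f, 2)["relationship"] == "mother"
            assert int(out.get(f, 2)["generation_num"]) == 1
        assert validate_annotation_table(out) == []

    def test_annotate_at_last_frame_changes_only_that_frame(self):
        table = budding_table(s_frames=range(5, 10))
        out = annotate_division(table, 9, 1)
        assert out.get(8, 1)["cell_cycle_stage"] == "S/G2/M"
        assert out.get(9, 1)["cell_cycle_stage"] == "G1"

    def test_generation_increments_from_current_value(self):
        table = budding_table(s_frames=range(5, 10), mother_gen=2)
        out = annotate_division(table, 7, 1)
        assert int(out.get(7, 1)["generation_num"]) == 3

    def test_annotate_via_the_bud_is_equivalent(self):
        table = budding_table()
        assert annotate_division(table, 7, 2) == annotate_division(table, 7, 1)

    def test_annotate_on_g1_cell_rejected(self):
        table = budding_table()
        with pytest.raises(ValueError):
            annotate_division(table, 2, 1)


class TestUndoDivision:
    def test_undo_is_inverse_of_annotate(self):
        table = budding_table(s_frames=range(5, 10))
        annotated = annotate_division(table, 7, 1)
        restored = undo_division(annotated, 7, 1)
        assert restored == table

    def test_undo_in_middle_of_g1_stretch_reverts_whole_stretch(self):
        table = budding_table(s_frames=range(5, 10))
        annotated = annotate_division(table, 6, 1)
        restored = undo_division(annotated, 8, 1)  # click later in the stretch
        assert restored == table

    def test_undo_stops_at_rebudding(self):
        rows = []
        for f in range(0, 3):   # S with bud 2
            rows.append(_row(f, 1, stage="S/G2/M", gen=2, rel=2))
            rows.append(_row(f, 2, stage="S/G2/M", gen=0, rel=1, relationship="bud", emerg=0))
        for f in range(3, 6):   # divided at 3
            rows.append(_row(f, 1, gen=3, rel=2, division=3))
            rows.append(_row(f, 2, gen=1, rel=1, division=3, emerg=0))
        for f in range(6, 9):   # mother re-budded with 5
            rows.append(_row(f, 1, stage="S/G2/M", gen=3, rel=5, division=3))
            rows.append(_row(f, 2, gen=1, rel=1, division=3, emerg=0))
            rows.append(_row(f, 5, stage="S/G2/M", gen=0, rel=1, relationship="bud", emerg=6))
        table = AnnotationTable.from_rows(rows)
        out = undo_division(table, 4, 1)
        # frames 3-5 reverted to S/G2/M with the old bud
        for f in range(3, 6):
            assert out.get(f, 1)["cell_cycle_stage"] == "S/G2/M"
            assert int(out.get(f, 1)["relative_ID"]) == 2
        # the re-budded stretch is untouched
        for f in range(6, 9):
            assert int(out.get(f, 1)["relative_ID"]) == 5

    def test_undo_on_s_phase_cell_rejected(self):
        table = budding_table()
        with pytest.raises(ValueError):
            undo_division(table, 7, 1)


class TestCorrectMother:
    def _table_with_wrong_mother(self):
        rows = []
        for f in range(0, 2):
            rows.append(_row(f, 1))
            rows.append(_row(f, 3))
        for f in range(2, 6):
            rows.append(_row(f, 1, stage="S/G2/M", rel=4))  # wrongly assigned
            rows.append(_row(f, 3))                          # true mother, G1
            rows.append(_row(f, 4, stage="S/G2/M", gen=0, rel=1, relationship="bud", emerg=2))
        return AnnotationTable.from_rows(rows)

    def test_swap_restores_wrong_mother_and_links_new(self):
        table = self._table_with_wrong_mother()
        out = correct_mother(table, 4, 3)
        assert validate_annotation_table(out) == []
        for f in range(2, 6):
            assert out.get(f, 1)["cell_cycle_stage"] == "G1"
            assert int(out.get(f, 1)["relative_ID"]) == -1
            assert out.get(f, 3)["cell_cycle_stage"] == "S/G2/M"
            assert int(out.get(f, 3)["relative_ID"]) == 4
            assert int(out.get(f, 4)["relative_ID"]) == 3
        # wrong mother rows equal its pre-pairing rows
        for f in range(2, 6):
            before = table.get(0, 1)
            after = out.get(f, 1)
            assert after["cell_cycle_stage"] == before["cell_cycle_stage"]
            assert int(after["generation_num"]) == int(before["generation_num"])

    def test_ineligible_new_mother_rejected(self):
        table = self._table_with_wrong_mother()
        table.add_row(**_row(3, 6, stage="S/G2/M", gen=0, rel=3, relationship="bud", emerg=3))
        table.set_values(3, 3, cell_cycle_stage="S/G2/M", relative_ID=6)
        with pytest.raises(EligibilityError):
            correct_mother(table, 4, 3)


class TestBuildAnnotations:
    def test_colony_replay_is_valid_and_recovers_links(self, colony):
        table, results = build_annotations(colony.movie, divisions=colony.division_events)
        assert validate_annotation_table(table) == []
        truth = colony.truth_table.df
        truth_links = {
            int(r["Cell_ID"]): int(r["relative_ID"])
            for _, r in truth.iterrows()
            if r["relationship"] == "bud"
        }
        got = {}
        for r in results:
            got.update(r.pairs)
        assert got == truth_links

    def test_random_edit_sequences_keep_table_valid(self, colony):
        table, _ = build_annotations(colony.movie, divisions=colony.division_events)
        rng = np.random.default_rng(5)
        df = table.df
        n_ops = 0
        for _ in range(200):
            candidates = df[(df["relationship"] == "mother") & (df["relative_ID"] != -1)]
            row = candidates.iloc[int(rng.integers(len(candidates)))]
            f, cid = int(row["frame_i"]), int(row["Cell_ID"])
            try:
                if row["cell_cycle_stage"] == "S/G2/M":
                    table = annotate_division(table, f, cid)
                else:
                    table = undo_division(table, f, cid)
                n_ops += 1
            except (ValueError, KeyError):
                continue
            assert validate_annotation_table(table) == []
            df = table.df
        assert n_ops > 20
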