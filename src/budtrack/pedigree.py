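"""Mother-bud pairing and the cell-cycle annotation state machine.

In budding yeast the bud is segmented as its own object, and bud emergence
marks the G1 -> S transition of its mother.  Pairing therefore links every
newly appeared object (a candidate bud) to one of the cells currently in G1.
The cost of a (bud, candidate-mother) pair is the single-linkage distance:
the minimum Euclidean distance between the two cells' contour pixels.  The
globally optimal one-to-one assignment is the solution of the linear sum
assignment problem (LSAP), solved with SciPy's Jonker-Volgenant
implementation.  Pairing uses the emergence frame only — no look-ahead.

Annotation edits (division annotation and its undo, mother reassignment)
propagate automatically to all affected past and future frames, so a
correction made at any time point leaves the whole table consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .data_model import (
    BUD,
    G1,
    MOTHER,
    S_G2_M,
    AnnotationTable,
    LabelFrame,
    LabelMovie,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pairing (LSAP over single-linkage contour distances)
# ---------------------------------------------------------------------------

@dataclass
class PairingProblem:
    """Bipartite assignment of new cells to G1 cells at one frame.

    ``cost[i, j]`` is the minimum contour-to-contour Euclidean distance (in
    pixels) between new cell ``new_cells[i]`` and G1 cell ``g1_cells[j]``.
    """

    new_cells: list[int]
    g1_cells: list[int]
    cost: np.ndarray


@dataclass(frozen=True)
class PairingWarning:
    kind: str  # insufficient_G1 | washed_away_bud | mother_already_has_bud
    details: str


@dataclass
class PairingResult:
    pairs: dict[int, int] = field(default_factory=dict)  # bud -> mother
    warnings: list[PairingWarning] = field(default_factory=list)


def contour_pixels(mask: np.ndarray) -> np.ndarray:
    """(N, 2) coordinates of the mask's boundary pixels (8-connected rim)."""
    eroded = binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)
    rim = mask & ~eroded
    return np.argwhere(rim)


def pairing_problem(frame: LabelFrame, new_cells: list[int], g1_cells: list[int]) -> PairingProblem:
    """Build the single-linkage cost matrix for one frame."""
    cost = np.zeros((len(new_cells), len(g1_cells)))
    if new_cells and g1_cells:
        g1_trees = {g: cKDTree(contour_pixels(frame.mask(g))) for g in g1_cells}
        for i, a in enumerate(new_cells):
            pts = contour_pixels(frame.mask(a))
            for j, b in enumerate(g1_cells):
                d, _ = g1_trees[b].query(pts)
                cost[i, j] = float(np.min(d))
    return PairingProblem(list(new_cells), list(g1_cells), cost)


def pair_buds(problem: PairingProblem) -> PairingResult:
    """Minimum-total-cost injective assignment of new cells to G1 cells.

    With more new cells than G1 cells, only the lowest-total-cost subset is
    assigned (rectangular LSAP) and an ``insufficient_G1`` warning is
    emitted for the remainder.
    """
    result = PairingResult()
    if not problem.new_cells:
        return result
    if not np.all(np.isfinite(problem.cost)):
        raise ValueError("pairing cost matrix must be finite")
    if len(problem.new_cells) > len(problem.g1_cells):
        unassignable = len(problem.new_cells) - len(problem.g1_cells)
        result.warnings.append(
            PairingWarning(
                "insufficient_G1",
                f"{len(problem.new_cells)} new cells but only "
                f"{len(problem.g1_cells)} cells in G1; {unassignable} left unassigned",
            )
        )
    if problem.g1_cells:
        rows, cols = linear_sum_assignment(problem.cost)
        for i, j in zip(rows, cols):
            result.pairs[problem.new_cells[i]] = problem.g1_cells[j]
    return result


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EligibilityViolation:
    rule: str
    message: str


class EligibilityError(ValueError):
    def __init__(self, violation: EligibilityViolation):
        self.violation = violation
        super().__init__(f"[{violation.rule}] {violation.message}")


def check_assignment_eligibility(
    table: AnnotationTable,
    bud: int,
    mother: int,
    frames: range | None = None,
) -> EligibilityViolation | None:
    """Is ``mother`` an acceptable mother for ``bud`` over the bud's lifetime?

    Returns ``None`` when eligible, otherwise a violation descriptor.  The
    candidate must be in G1 at the pairing frame and must have no other
    reciprocated bud at any frame in which the bud is present.
    """
    bud_frames = table.cell_frames(bud)
    if bud_frames.size == 0:
        raise KeyError(f"unknown bud label {bud}")
    if table.cell_frames(mother).size == 0:
        raise KeyError(f"unknown mother label {mother}")
    if frames is None:
        bud_rel = table.df[(table.df["Cell_ID"] == bud) & (table.df["relationship"] == BUD)]
        life = np.sort(bud_rel["frame_i"].to_numpy()) if len(bud_rel) else bud_frames
        frames = range(int(life[0]), int(life[-1]) + 1)
    pairing_frame = frames.start
    m0 = table.get(pairing_frame, mother)
    if m0 is None:
        return EligibilityViolation("mother_absent", f"cell {mother} has no row at frame {pairing_frame}")
    if m0["cell_cycle_stage"] != G1:
        return EligibilityViolation(
            "mother_not_G1", f"cell {mother} is in {m0['cell_cycle_stage']} at frame {pairing_frame}"
        )
    for f in frames:
        m = table.get(f, mother)
        if m is None:
            continue
        r = int(m["relative_ID"])
        if r in (-1, bud):
            continue
        other = table.get(f, r)
        if other is not None and other["relationship"] == BUD and int(other["relative_ID"]) == mother:
            return EligibilityViolation(
                "mother_already_has_bud",
                f"cell {mother} already has bud {r} at frame {f}",
            )
    return None


# ---------------------------------------------------------------------------
# Division annotation and its undo
# ---------------------------------------------------------------------------

def _resolve_pair(table: AnnotationTable, frame: int, cell: int) -> tuple[int, int]:
    """Return (mother, bud) for the mother-bud pair `cell` belongs to at frame."""
    row = table.get(frame, cell)
    if row is None:
        raise KeyError(f"no row for cell {cell} at frame {frame}")
    partner = int(row["relative_ID"])
    if partner == -1:
        raise ValueError(f"cell {cell} has no partner at frame {frame}")
    if row["relationship"] == BUD:
        return partner, cell
    return cell, partner


def annotate_division(table: AnnotationTable, frame: int, cell: int) -> AnnotationTable:
    """Annotate a division event at ``frame`` for a mother-bud pair in S/G2/M.

    The mother returns to G1 with its generation number incremented; the bud
    becomes an independent G1 cell of generation 1 (relationship ``mother``),
    keeping ``relative_ID`` as the pedigree link.  The change is propagated
    to every later frame that was still annotated S/G2/M for this pair.
    """
    row = table.get(frame, cell)
    if row is None:
        raise KeyError(f"no row for cell {cell} at frame {frame}")
    if row["cell_cycle_stage"] == G1:
        raise ValueError(f"cell {cell} is in G1 at frame {frame}; use undo_division to revert one")
    out = table.copy()
    mother, bud = _resolve_pair(out, frame, cell)
    m_gen = int(out.get(frame, mother)["generation_num"])
    f = frame
    while True:
        m = out.get(f, mother)
        b = out.get(f, bud)
        if m is None or m["cell_cycle_stage"] != S_G2_M or int(m["relative_ID"]) != bud:
            break
        out.set_values(f, mother, cell_cycle_stage=G1, generation_num=m_gen + 1, division_frame_i=frame)
        if b is not None:
            out.set_values(
                f, bud,
                cell_cycle_stage=G1, relationship=MOTHER, generation_num=1, division_frame_i=frame,
            )
        f += 1
    return out


def undo_division(table: AnnotationTable, frame: int, cell: int) -> AnnotationTable:
    """Undo a division annotation: the pair goes back to S/G2/M.

    Both the cell and the bud of its previous cycle revert for all frames of
    the G1 stretch created by the division — forward until either cell
    re-enters S/G2/M (or the table ends) and backward to the division frame.
    Generation numbers and division frames are restored from the rows just
    before the division, making this the exact inverse of
    :func:`annotate_division`.
    """
    row = table.get(frame, cell)
    if row is None:
        raise KeyError(f"no row for cell {cell} at frame {frame}")
    if row["cell_cycle_stage"] != G1:
        raise ValueError(f"cell {cell} is in S/G2/M at frame {frame}; nothing to undo")
    d = int(row["division_frame_i"])
    if d < 0:
        raise ValueError(f"cell {cell} has no annotated division to undo at frame {frame}")
    out = table.copy()
    a, b = _resolve_pair(out, frame, cell)
    # after a division both members carry relationship "mother"; the bud of
    # the previous cycle is the member that emerged later
    emerg_a = int(out.get(frame, a)["emerg_frame_i"])
    emerg_b = int(out.get(frame, b)["emerg_frame_i"])
    mother, bud = (a, b) if emerg_a <= emerg_b else (b, a)

    # Pre-division values: a bud is always generation 0 with no division of
    # its own.  The mother's generation and previous-cycle division frame
    # come from her most recent S/G2/M row paired with this bud, or failing
    # that from her row just before the division (the S stretch carries
    # those values forward unchanged).
    b_prior = {"generation_num": 0, "division_frame_i": -1, "relationship": BUD}
    m_gen_now = int(out.get(frame, mother)["generation_num"])
    m_prior = {
        "generation_num": max(m_gen_now - 1, 0),
        "division_frame_i": -1,
        "relationship": MOTHER,
    }
    found = False
    for f in range(d - 1, -1, -1):
        r = out.get(f, mother)
        if r is None:
            break
        if r["cell_cycle_stage"] == S_G2_M and int(r["relative_ID"]) == bud:
            m_prior["generation_num"] = int(r["generation_num"])
            m_prior["division_frame_i"] = int(r["division_frame_i"])
            found = True
            break
    if not found:
        r = out.get(d - 1, mother)
        if r is not None and int(r["relative_ID"]) in (bud, -1) or (
            r is not None and r["cell_cycle_stage"] == G1
        ):
            m_prior["generation_num"] = int(r["generation_num"])
            m_prior["division_frame_i"] = int(r["division_frame_i"])

    # reversion window: stop as soon as either cell is back in S/G2/M
    last = int(out.df["frame_i"].max())
    end = last + 1
    for f in range(d, last + 1):
        for cid in (mother, bud):
            r = out.get(f, cid)
            if r is not None and r["cell_cycle_stage"] == S_G2_M:
                end = f
                break
        if end == f:
            break

    for f in range(d, end):
        if out.get(f, mother) is not None:
            out.set_values(
                f, mother,
                cell_cycle_stage=S_G2_M, relationship=m_prior["relationship"],
                generation_num=m_prior["generation_num"],
                division_frame_i=m_prior["division_frame_i"], relative_ID=bud,
            )
        if out.get(f, bud) is not None:
            out.set_values(
                f, bud,
                cell_cycle_stage=S_G2_M, relationship=b_prior["relationship"],
                generation_num=b_prior["generation_num"],
                division_frame_i=b_prior["division_frame_i"], relative_ID=mother,
            )
    return out


def correct_mother(table: AnnotationTable, bud: int, new_mother: int) -> AnnotationTable:
    """Reassign ``bud`` to ``new_mother`` over the bud's whole lifetime.

    The wrong mother is restored to the state it had before the bud was
    assigned to it (G1, its previous relative link); the new mother enters
    S/G2/M with a reciprocal link to the bud.  Applies to every frame in
    which the bud exists as a bud, past and future alike.
    """
    violation = check_assignment_eligibility(table, bud, new_mother)
    if violation is not None:
        raise EligibilityError(violation)
    out = table.copy()
    bud_rows = out.df[(out.df["Cell_ID"] == bud) & (out.df["relationship"] == BUD)]
    if bud_rows.empty:
        raise ValueError(f"cell {bud} is not a bud anywhere in the table")
    frames = np.sort(bud_rows["frame_i"].to_numpy())
    emerg = int(frames[0])
    wrong = int(bud_rows.iloc[0]["relative_ID"])

    def pre_assignment_relative(cid: int) -> int:
        r = out.get(emerg - 1, cid)
        return int(r["relative_ID"]) if r is not None else -1

    wrong_prior_rel = pre_assignment_relative(wrong) if wrong != -1 else -1
    for f in map(int, frames):
        if wrong != -1 and out.get(f, wrong) is not None:
            out.set_values(
                f, wrong,
                cell_cycle_stage=G1, relationship=MOTHER, relative_ID=wrong_prior_rel,
            )
        if out.get(f, new_mother) is None:
            raise ValueError(f"new mother {new_mother} has no row at frame {f}")
        out.set_values(f, new_mother, cell_cycle_stage=S_G2_M, relationship=MOTHER, relative_ID=bud)
        out.set_values(f, bud, relative_ID=new_mother)
    return out


# ---------------------------------------------------------------------------
# Automatic pedigree construction over a tracked movie
# ---------------------------------------------------------------------------

@dataclass
class _CellState:
    stage: str
    relationship: str
    generation: int
    relative: int
    emerg: int
    division: int
    history_known: bool
    prior_relative: int = -1  # mother's link before its current bud


def build_annotations(
    movie: LabelMovie,
    divisions: list[tuple[int, int]] | None = None,
) -> tuple[AnnotationTable, list[PairingResult]]:
    """Walk a tracked movie and build a consistent annotation table.

    Frame-0 cells are recorded with unknown history (generation 2 by
    convention, ``emerg_frame_i = -1``).  At every later frame, newly
    appeared labels are paired to G1 cells with :func:`pair_buds`; division
    events (``divisions``: (frame, cell) pairs, e.g. from visual inspection
    or a ground-truth pedigree) flip the pair back to G1 with the generation
    bookkeeping of :func:`annotate_division`.  Buds that disappear from the
    movie while still buds are closed as washed away (history flagged
    unknown at their last frame) and their mothers return to G1.
    """
    if len(movie) == 0:
        raise ValueError("empty movie")
    div_by_frame: dict[int, list[int]] = {}
    for f, c in divisions or []:
        div_by_frame.setdefault(int(f), []).append(int(c))

    state: dict[int, _CellState] = {}
    rows: list[dict] = []
    results: list[PairingResult] = []
    washed_unknown: set[tuple[int, int]] = set()

    for t in range(len(movie)):
        frame = movie[t]
        labels = set(map(int, frame.labels))
        res = PairingResult()

        if t == 0:
            for lab in sorted(labels):
                state[lab] = _CellState(G1, MOTHER, 2, -1, -1, -1, False)
        else:
            # washed-away buds: gone from the movie while still buds
            for lab in sorted(set(state) - labels):
                st = state.pop(lab)
                if st.relationship == BUD:
                    res.warnings.append(
                        PairingWarning("washed_away_bud", f"bud {lab} disappeared at frame {t}")
                    )
                    washed_unknown.add((t - 1, lab))
                    mom = state.get(st.relative)
                    if mom is not None and mom.relative == lab:
                        mom.stage = G1
                        mom.relative = mom.prior_relative
                elif state.get(st.relative) is not None and state[st.relative].relationship == BUD:
                    # a mother vanished: orphan its bud as unknown-history
                    orphan = state[st.relative]
                    orphan.relationship = MOTHER
                    orphan.stage = G1
                    orphan.history_known = False

            # division events scheduled at this frame
            for c in div_by_frame.get(t, []):
                st = state.get(c)
                if st is None or st.relative == -1:
                    raise KeyError(f"division at frame {t}: cell {c} unknown or unpaired")
                mother, bud = (st.relative, c) if st.relationship == BUD else (c, st.relative)
                state[mother].stage = G1
                state[mother].generation += 1
                state[mother].division = t
                b = state.get(bud)
                if b is not None:
                    b.stage = G1
                    b.relationship = MOTHER
                    b.generation = 1
                    b.division = t

            # pair newly appeared cells to G1 cells
            new_cells = sorted(labels - set(state))
            g1_cells = sorted(c for c, st in state.items() if st.stage == G1 and c in labels)
            if new_cells:
                problem = pairing_problem(frame, new_cells, g1_cells)
                res_pairs = pair_buds(problem)
                res.pairs.update(res_pairs.pairs)
                res.warnings.extend(res_pairs.warnings)
                for b, m in res_pairs.pairs.items():
                    mom = state[m]
                    mom.prior_relative = mom.relative
                    mom.stage = S_G2_M
                    mom.relative = b
                    state[b] = _CellState(S_G2_M, BUD, 0, m, t, -1, True)
                for b in set(new_cells) - set(res_pairs.pairs):
                    # no G1 cell available: record as unknown-history cell
                    state[b] = _CellState(G1, MOTHER, 2, -1, t, -1, False)

        for lab in sorted(labels):
            st = state[lab]
            rows.append(
                dict(
                    frame_i=t, Cell_ID=lab, cell_cycle_stage=st.stage,
                    generation_num=st.generation, relative_ID=st.relative,
                    relationship=st.relationship, emerg_frame_i=st.emerg,
                    division_frame_i=st.division, is_history_known=st.history_known,
                )
            )
        results.append(res)

    table = AnnotationTable.from_rows(rows)
    for f, lab in washed_unknown:
        if table.get(f, lab) is not None:
            table.set_values(f, lab, is_history_known=False)
    return table, results
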