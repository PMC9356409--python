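"""Deterministic budding-yeast-like label movies with known ground truth.

The generator emulates the geometry a tracker and pedigree annotator see in
a real colony: elliptical cells that grow a few percent per frame, emit a
small tangent bud after a fixed G1 residence time, divide a fixed number of
frames after bud emergence, and jostle each other as the colony gets
crowded.  Every dataset carries its ground-truth annotation table (which
always passes the data-model validator) and per-identity tracks, so
tracking, pairing, splitting and the MOT metrics can all be scored exactly.

Perturbation operators inject controlled errors — dropped object instances
(false negatives), spurious background blobs (false positives), permanent
identity reassignments (identity switches) and merged mother-bud pairs
(inputs for the object splitter) — while keeping the original truth, which
is what makes metric calibration tests exact.

It does not attempt photorealism: there is no intensity texture, no focus
drift, and cell outlines are perfect ellipses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import (
    BUD,
    G1,
    MOTHER,
    S_G2_M,
    AnnotationTable,
    LabelMovie,
)

MAX_RELAX_ITERS = 50


@dataclass
class ColonyConfig:
    """Growth and geometry parameters of the simulated colony.

    growth_rate is the fractional area increase per frame; attached buds
    grow at bud_growth_rate instead (most growth goes into the bud, which
    reaches roughly 60% of its mother's area by division); bud_period is
    the number of frames between bud emergence and division; g1_duration
    the G1 residence time before the next bud; bud_initial_ratio the
    bud/mother area ratio at emergence.
    """

    n_founders: int = 3
    frames: int = 30
    frame_shape: tuple[int, int] = (256, 256)
    growth_rate: float = 0.05
    bud_growth_rate: float = 0.20
    bud_period: int = 6
    g1_duration: int = 4
    bud_initial_ratio: float = 0.25
    jitter_px: float = 0.5
    founder_radius: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_founders, self.frames, self.bud_period, self.g1_duration) <= 0:
            raise ValueError("n_founders, frames, bud_period and g1_duration must be positive")
        if not 0 < self.bud_initial_ratio < 0.5:
            raise ValueError("bud_initial_ratio must be in (0, 0.5)")
        if min(self.growth_rate, self.bud_growth_rate) <= 0:
            raise ValueError("growth rates must be positive")
        if self.jitter_px < 0 or self.founder_radius <= 0:
            raise ValueError("founder_radius must be positive, jitter_px >= 0")


@dataclass
class SyntheticDataset:
    movie: LabelMovie
    truth_table: AnnotationTable
    truth_tracks: dict[int, dict[int, int]]  # identity -> {frame: label}
    division_events: list[tuple[int, int]] = field(default_factory=list)
    merged_pairs: list[tuple[int, int, int]] = field(default_factory=list)  # (frame, mother, bud)
    seed: int = 0


class OvercrowdedError(RuntimeError):
    """Colony geometry cannot be relaxed without overlaps."""


@dataclass
class _SimCell:
    cid: int
    cy: float
    cx: float
    ry: float
    rx: float
    theta: float
    stage: str = G1
    relationship: str = MOTHER
    generation: int = 2
    relative: int = -1
    emerg: int = -1
    division: int = -1
    history_known: bool = False
    prior_relative: int = -1
    g1_entry: int = 0
    bud_dir: tuple[float, float] | None = None  # unit vector mother -> bud

    @property
    def radius(self) -> float:
        return max(self.ry, self.rx)

    def radius_along(self, uy: float, ux: float) -> float:
        """Ellipse support radius along unit direction (uy, ux)."""
        ct, st = math.cos(self.theta), math.sin(self.theta)
        u = uy * ct + ux * st    # component along the ry axis
        v = -uy * st + ux * ct   # component along the rx axis
        return 1.0 / math.sqrt((u / self.ry) ** 2 + (v / self.rx) ** 2)


def _raster_ellipse(shape: tuple[int, int], cell: _SimCell) -> tuple[np.ndarray, np.ndarray]:
    r = int(math.ceil(cell.radius)) + 1
    y0 = max(0, int(cell.cy) - r)
    y1 = min(shape[0], int(cell.cy) + r + 1)
    x0 = max(0, int(cell.cx) - r)
    x1 = min(shape[1], int(cell.cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cell.cy
    dx = xx - cell.cx
    ct, st = math.cos(cell.theta), math.sin(cell.theta)
    u = (dy * ct + dx * st) / cell.ry
    v = (-dy * st + dx * ct) / cell.rx
    inside = u * u + v * v <= 1.0
    return yy[inside], xx[inside]


def _relax(cells: list[_SimCell], shape: tuple[int, int], bud_of: dict[int, int]) -> None:
    """Push overlapping cells apart; buds stay tangent to their mothers."""
    by_id = {c.cid: c for c in cells}
    pair_exempt = {(m, b) for b, m in bud_of.items()} | {(b, m) for b, m in bud_of.items()}
    for _ in range(MAX_RELAX_ITERS):
        moved = False
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                a, b = cells[i], cells[j]
                if (a.cid, b.cid) in pair_exempt:
                    continue
                dy, dx = b.cy - a.cy, b.cx - a.cx
                dist = math.hypot(dy, dx)
                if dist < 1e-9:
                    dy, dx, dist = 1.0, 0.0, 1.0
                uy0, ux0 = dy / dist, dx / dist
                min_dist = a.radius_along(uy0, ux0) + b.radius_along(uy0, ux0) + 1.0
                if dist >= min_dist:
                    continue
                push = (min_dist - dist) / 2.0
                uy, ux = dy / dist, dx / dist
                # pushing an attached bud moves the whole mother-bud unit
                ra = by_id.get(bud_of.get(a.cid, a.cid), a)
                rb = by_id.get(bud_of.get(b.cid, b.cid), b)
                ra.cy -= uy * push
                ra.cx -= ux * push
                rb.cy += uy * push
                rb.cx += ux * push
                moved = True
        for c in cells:
            r = c.radius + 1
            ny = min(max(c.cy, r), shape[0] - 1 - r)
            nx = min(max(c.cx, r), shape[1] - 1 - r)
            if (ny, nx) != (c.cy, c.cx):
                c.cy, c.cx = ny, nx
                moved = True
        # snap active buds back onto their mothers (tangent, 1 px bite)
        for bud_id, mother_id in bud_of.items():
            b, m = by_id[bud_id], by_id[mother_id]
            uy, ux = b.bud_dir
            d = m.radius_along(uy, ux) + b.radius_along(uy, ux) - 1.0
            ny, nx = m.cy + uy * d, m.cx + ux * d
            if abs(ny - b.cy) > 1e-9 or abs(nx - b.cx) > 1e-9:
                b.cy, b.cx = ny, nx
        if not moved:
            return
    # final overlap check (bud pairs are allowed to touch)
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            a, b = cells[i], cells[j]
            if (a.cid, b.cid) in pair_exempt:
                continue
            dy, dx = b.cy - a.cy, b.cx - a.cx
            dist = math.hypot(dy, dx)
            if dist < 1e-9:
                raise OvercrowdedError("coincident cells; use a larger frame_shape")
            uy0, ux0 = dy / dist, dx / dist
            if dist < a.radius_along(uy0, ux0) + b.radius_along(uy0, ux0):
                raise OvercrowdedError(
                    "could not resolve cell collisions; use a larger frame_shape"
                )


def grow_colony(config: ColonyConfig) -> SyntheticDataset:
    """Simulate a colony; identical config (incl. seed) gives identical data."""
    rng = np.random.default_rng(config.seed)
    shape = config.frame_shape
    cells: list[_SimCell] = []
    next_id = 1
    margin = config.founder_radius * 3
    for _ in range(config.n_founders):
        for _attempt in range(200):
            cy = rng.uniform(margin, shape[0] - margin)
            cx = rng.uniform(margin, shape[1] - margin)
            r = config.founder_radius * rng.uniform(0.9, 1.1)
            aspect = rng.uniform(1.0, 1.3)
            cand = _SimCell(next_id, cy, cx, r * aspect, r, rng.uniform(0, math.pi))
            if all(
                math.hypot(c.cy - cy, c.cx - cx) > c.radius + cand.radius + 2
                for c in cells
            ):
                cells.append(cand)
                next_id += 1
                break
        else:
            raise OvercrowdedError("could not place founders; use a larger frame_shape")

    rows: list[dict] = []
    tracks: dict[int, dict[int, int]] = {}
    division_events: list[tuple[int, int]] = []
    stack = np.zeros((config.frames, *shape), dtype=np.int32)
    scale = math.sqrt(1.0 + config.growth_rate)

    for t in range(config.frames):
        if t > 0:
            bud_scale = math.sqrt(1.0 + config.bud_growth_rate)
            for c in cells:
                s = bud_scale if c.relationship == BUD else scale
                c.ry *= s
                c.rx *= s
                if config.jitter_px > 0 and c.bud_dir is None:
                    c.cy += rng.uniform(-config.jitter_px, config.jitter_px)
                    c.cx += rng.uniform(-config.jitter_px, config.jitter_px)

            # divisions: buds that have been attached for bud_period frames
            by_id = {c.cid: c for c in cells}
            for c in list(cells):
                if c.relationship == BUD and t - c.emerg == config.bud_period:
                    mother = by_id[c.relative]
                    mother.stage = G1
                    mother.generation += 1
                    mother.division = t
                    mother.g1_entry = t
                    c.stage = G1
                    c.relationship = MOTHER
                    c.generation = 1
                    c.division = t
                    c.g1_entry = t
                    c.bud_dir = None
                    division_events.append((t, mother.cid))

            # bud emergence after the G1 residence time
            for c in list(cells):
                if c.stage == G1 and t - c.g1_entry == config.g1_duration:
                    br = c.radius * math.sqrt(config.bud_initial_ratio)
                    # try 8 emergence directions, keep the least crowded one
                    ang0 = rng.uniform(0, 2 * math.pi)
                    best_ang, best_clearance = ang0, -math.inf
                    for k in range(8):
                        ang = ang0 + k * math.pi / 4
                        uy, ux = math.sin(ang), math.cos(ang)
                        d = c.radius_along(uy, ux) + br - 1.0
                        by, bx = c.cy + uy * d, c.cx + ux * d
                        clearance = min(
                            (
                                math.hypot(o.cy - by, o.cx - bx) - o.radius - br
                                for o in cells
                                if o.cid != c.cid
                            ),
                            default=math.inf,
                        )
                        clearance = min(
                            clearance, by - br, bx - br,
                            shape[0] - 1 - by - br, shape[1] - 1 - bx - br,
                        )
                        if clearance > best_clearance:
                            best_ang, best_clearance = ang, clearance
                    ang = best_ang
                    uy, ux = math.sin(ang), math.cos(ang)
                    bud = _SimCell(
                        next_id,
                        c.cy + uy * (c.radius_along(uy, ux) + br - 1.0),
                        c.cx + ux * (c.radius_along(uy, ux) + br - 1.0),
                        br * (c.ry / c.radius if c.radius else 1.0),
                        br * (c.rx / c.radius if c.radius else 1.0),
                        c.theta,
                        stage=S_G2_M,
                        relationship=BUD,
                        generation=0,
                        relative=c.cid,
                        emerg=t,
                        division=-1,
                        history_known=True,
                        bud_dir=(uy, ux),
                    )
                    c.prior_relative = c.relative
                    c.stage = S_G2_M
                    c.relative = bud.cid
                    cells.append(bud)
                    next_id += 1

            bud_of = {c.cid: c.relative for c in cells if c.bud_dir is not None}
            _relax(cells, shape, bud_of)

        frame = stack[t]
        for c in sorted(cells, key=lambda c: c.cid):
            yy, xx = _raster_ellipse(shape, c)
            free = frame[yy, xx] == 0
            if not free.any():
                raise OvercrowdedError(f"cell {c.cid} fully occluded at frame {t}")
            frame[yy[free], xx[free]] = c.cid

        for c in sorted(cells, key=lambda c: c.cid):
            rows.append(
                dict(
                    frame_i=t, Cell_ID=c.cid, cell_cycle_stage=c.stage,
                    generation_num=c.generation, relative_ID=c.relative,
                    relationship=c.relationship, emerg_frame_i=c.emerg,
                    division_frame_i=c.division, is_history_known=c.history_known,
                )
            )
            tracks.setdefault(c.cid, {})[t] = c.cid

    return SyntheticDataset(
        movie=LabelMovie(stack),
        truth_table=AnnotationTable.from_rows(rows),
        truth_tracks=tracks,
        division_events=division_events,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

@dataclass
class PerturbSpec:
    drop: int = 0        # delete object instances -> false negatives
    spurious: int = 0    # inject background blobs -> false positives
    swap: int = 0        # permanent identity reassignments -> ID switches
    merge_pairs: int = 0  # merge a mother-bud pair at one frame


def perturb(data: SyntheticDataset, spec: PerturbSpec, seed: int = 0) -> SyntheticDataset:
    """Apply controlled errors to the movie; the ground truth is retained.

    The error kinds are constructed to be non-interacting so that the MOT
    report on (truth movie, perturbed movie) returns exactly ``spec.drop``
    false negatives, ``spec.spurious`` false positives and ``spec.swap``
    identity switches.
    """
    rng = np.random.default_rng(seed)
    stack = data.movie.stack.copy()
    T = stack.shape[0]
    next_label = int(stack.max()) + 1
    protected: set[int] = set()  # identities reserved by swaps/merges

    # --- permanent identity reassignments -------------------------------
    full_span = [
        cid for cid, fr in data.truth_tracks.items()
        if min(fr) == 0 and max(fr) == T - 1
    ]
    if spec.swap > len(full_span) or T < 3:
        if spec.swap > 0:
            raise ValueError("not enough full-length trajectories to swap")
    swapped = list(rng.choice(full_span, size=spec.swap, replace=False)) if spec.swap else []
    for cid in map(int, swapped):
        f = int(rng.integers(1, T - 1))
        stack[f:][stack[f:] == cid] = next_label
        protected.add(cid)
        next_label += 1

    # --- merged mother-bud pairs ----------------------------------------
    bud_rows = data.truth_table.df[data.truth_table.df["relationship"] == BUD]
    candidates = [
        (int(r["frame_i"]), int(r["relative_ID"]), int(r["Cell_ID"]))
        for _, r in bud_rows.iterrows()
        if int(r["relative_ID"]) not in protected and int(r["Cell_ID"]) not in protected
    ]
    merged: list[tuple[int, int, int]] = []
    seen_buds: set[int] = set()
    if spec.merge_pairs:
        order = rng.permutation(len(candidates))
        for k in order:
            f, m, b = candidates[int(k)]
            if b in seen_buds or len(merged) == spec.merge_pairs:
                continue
            if (stack[f] == m).any() and (stack[f] == b).any():
                stack[f][stack[f] == b] = m
                merged.append((f, m, b))
                seen_buds.add(b)
                protected.update({m, b})
        if len(merged) < spec.merge_pairs:
            raise ValueError("not enough coexisting mother-bud pairs to merge")

    # --- dropped object instances ---------------------------------------
    merged_frames = {(f, m) for f, m, _ in merged}
    instances = [
        (t, cid)
        for cid, fr in data.truth_tracks.items()
        if cid not in protected
        for t in fr
        if (t, cid) not in merged_frames
    ]
    if spec.drop > len(instances):
        raise ValueError("not enough object instances to drop")
    if spec.drop:
        idx = rng.choice(len(instances), size=spec.drop, replace=False)
        for k in idx:
            t, cid = instances[int(k)]
            stack[t][stack[t] == cid] = 0

    # --- spurious blobs ---------------------------------------------------
    H, W = stack.shape[1:]
    for _ in range(spec.spurious):
        for _attempt in range(500):
            t = int(rng.integers(0, T))
            y = int(rng.integers(2, H - 5))
            x = int(rng.integers(2, W - 5))
            region = stack[t, y - 1 : y + 4, x - 1 : x + 4]
            if (region == 0).all():
                stack[t, y : y + 3, x : x + 3] = next_label
                next_label += 1
                break
        else:
            raise ValueError("could not place a spurious blob in free background")

    return replace(
        data,
        movie=LabelMovie(stack, data.movie.pixel_size_um),
        merged_pairs=merged,
    )
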