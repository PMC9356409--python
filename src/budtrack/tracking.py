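"""Frame-to-frame continuous tracking by intersection-over-area (IoA).

Given the objects ``x = [x_0 ... x_n1]`` of frame ``n-1`` and
``y = [y_0 ... y_n2]`` of frame ``n``, the tracker builds the cost matrix
``C`` with ``c_ij = |y_i ∩ x_j| / |x_j|`` (overlap normalised by the
*previous* object's area).  Any current object whose maximal IoA over all
previous objects is below the new-object threshold (default 0.4, strict
``<``) is treated as newly appeared — e.g. an emerging bud — and receives a
fresh ID.  Each remaining object ``y_i`` inherits the ID of its best
predecessor ``argmax_j c_ij`` unless that predecessor overlaps some other
current object more strongly, in which case ``y_i`` is deferred and ends up
with a new ID (single-pass semantics: deferred objects do not retry with
their second-best predecessor).

Tie-breaking is deterministic: among equal best predecessors the lowest
previous label wins; when two current objects compete for one predecessor at
equal IoA, the lowest current label wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import LabelFrame, LabelMovie, ShapeError


@dataclass
class TrackerParams:
    """Tracker tuning knobs.

    new_object_threshold : float
        IoA cutoff below which (strictly) a current object is declared new.
    """

    new_object_threshold: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.new_object_threshold <= 1:
            raise ValueError("new_object_threshold must be in (0, 1]")


@dataclass
class IoAMatrix:
    """IoA cost matrix between two consecutive frames.

    ``cost[i, j]`` is the IoA of current object ``curr_ids[i]`` with previous
    object ``prev_ids[j]``: intersection pixels divided by the previous
    object's area.  Every entry lies in [0, 1] and each column sums to <= 1.
    """

    prev_ids: np.ndarray
    curr_ids: np.ndarray
    cost: np.ndarray


@dataclass
class IDMapping:
    """Per-frame-pair tracking decision.

    assignments : dict
        current label -> previous label it inherits.
    new_ids : dict
        current label -> freshly allocated label.
    lost_ids : list
        previous labels with no assigned successor.
    """

    assignments: dict[int, int] = field(default_factory=dict)
    new_ids: dict[int, int] = field(default_factory=dict)
    lost_ids: list[int] = field(default_factory=list)


def ioa_matrix(prev: LabelFrame, curr: LabelFrame) -> IoAMatrix:
    """Compute the IoA cost matrix ``c_ij = |y_i ∩ x_j| / |x_j|``."""
    if prev.pixels.shape != curr.pixels.shape:
        raise ShapeError(f"frame shapes differ: {prev.pixels.shape} vs {curr.pixels.shape}")
    prev_ids = prev.labels
    curr_ids = curr.labels
    cost = np.zeros((len(curr_ids), len(prev_ids)))
    if len(prev_ids) and len(curr_ids):
        p = prev.pixels.ravel()
        c = curr.pixels.ravel()
        both = (p > 0) & (c > 0)
        prev_index = {int(l): j for j, l in enumerate(prev_ids)}
        curr_index = {int(l): i for i, l in enumerate(curr_ids)}
        pairs, counts = np.unique(np.stack([c[both], p[both]]), axis=1, return_counts=True)
        inter = np.zeros_like(cost)
        for (ci, pj), n in zip(pairs.T, counts):
            inter[curr_index[int(ci)], prev_index[int(pj)]] = n
        prev_areas = np.array([(p == l).sum() for l in prev_ids], dtype=float)
        cost = inter / prev_areas[None, :]
    return IoAMatrix(prev_ids=prev_ids, curr_ids=curr_ids, cost=cost)


def track_pair(
    prev: LabelFrame,
    curr: LabelFrame,
    params: TrackerParams | None = None,
    next_id: int | None = None,
) -> IDMapping:
    """Assign current-frame objects to previous-frame objects by mutual-max IoA.

    ``next_id`` is the first label to hand out to new objects (defaults to
    ``max(all labels in both frames) + 1``); new labels are allocated in
    ascending current-label order.
    """
    params = params or TrackerParams()
    ioa = ioa_matrix(prev, curr)
    C, prev_ids, curr_ids = ioa.cost, ioa.prev_ids, ioa.curr_ids

    n_curr = len(curr_ids)
    assignments: dict[int, int] = {}
    unassigned: list[int] = []

    if n_curr:
        if len(prev_ids) == 0:
            unassigned = [int(l) for l in curr_ids]
        else:
            row_max = C.max(axis=1)
            eligible = row_max >= params.new_object_threshold
            for i in np.flatnonzero(~eligible):
                unassigned.append(int(curr_ids[i]))
            for i in np.flatnonzero(eligible):
                j = int(np.argmax(C[i]))  # ties -> lowest prev label (ids sorted)
                # y_i keeps x_j only if no other eligible current object
                # overlaps x_j more (ties won by the lower current label)
                col = C[:, j]
                winner = True
                for k in np.flatnonzero(eligible):
                    if k == i:
                        continue
                    if col[k] > col[i] or (col[k] == col[i] and curr_ids[k] < curr_ids[i]):
                        winner = False
                        break
                if winner:
                    assignments[int(curr_ids[i])] = int(prev_ids[j])
                else:
                    unassigned.append(int(curr_ids[i]))

    if next_id is None:
        next_id = int(max([0, *map(int, prev_ids), *map(int, curr_ids)])) + 1
    new_ids = {cid: next_id + k for k, cid in enumerate(sorted(unassigned))}

    used_prev = set(assignments.values())
    lost = [int(l) for l in prev_ids if int(l) not in used_prev]
    return IDMapping(assignments=assignments, new_ids=new_ids, lost_ids=lost)


def relabel_frame(frame: LabelFrame, mapping: dict[int, int]) -> LabelFrame:
    """Apply a label -> label mapping to a frame (identity for absent keys)."""
    pixels = frame.pixels
    if not mapping:
        return frame.copy()
    max_in = int(max(pixels.max(initial=0), max(mapping)))
    lut = np.arange(max_in + 1, dtype=np.int64)
    for src, dst in mapping.items():
        lut[src] = dst
    return LabelFrame(lut[pixels], frame.frame_index)


def track_movie(
    movie: LabelMovie, params: TrackerParams | None = None
) -> tuple[LabelMovie, list[IDMapping]]:
    """Track a whole movie; returns the relabelled movie and per-pair mappings.

    Frame 0 is kept verbatim.  Each later frame is relabelled so that
    assigned objects inherit their (possibly remapped) predecessor ID and new
    objects receive IDs never used before in the movie, allocated
    monotonically so identities are never recycled.
    """
    if len(movie) == 0:
        raise ValueError("cannot track an empty movie")
    params = params or TrackerParams()
    out = [movie[0].pixels.astype(np.int64, copy=True)]
    mappings: list[IDMapping] = []
    max_used = int(out[0].max(initial=0))
    for t in range(1, len(movie)):
        prev = LabelFrame(out[t - 1], t - 1)
        curr = movie[t]
        m = track_pair(prev, curr, params, next_id=max_used + 1)
        mappings.append(m)
        full = {**m.assignments, **m.new_ids}
        out.append(relabel_frame(curr, full).pixels.astype(np.int64))
        max_used = max(max_used, int(out[-1].max(initial=0)))
    return LabelMovie(np.stack(out), movie.pixel_size_um), mappings
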