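"""Mask-level corrections: merged-object splitting and false-positive removal.

The splitter targets the classic merged mother-bud case: two roughly convex
cells segmented as one object with a constriction (neck) between them.  The
object's outer contour is simplified with the Douglas-Peucker algorithm
(tolerance = 10% of the contour arc length by default, so small boundary
irregularities never create spurious cut planes), the convexity defects of
the simplified contour relative to its convex hull are located, and the
object is cut along the straight line through the two defect points — but
only if *exactly two* defects are found; any other defect count returns a
no-split signal and leaves the frame untouched.

The false-positive filter removes labels failing any of three cheap shape
tests: minimum area, minimum solidity (object pixels / convex-hull pixels)
and maximum elongation (major / minor axis of the second-moment ellipse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .data_model import LabelFrame


@dataclass
class SeparationParams:
    """Contour-approximation tolerance as a fraction of contour arc length."""

    epsilon_fraction: float = 0.10
    #: defects shallower than this (pixels) are raster noise, not necks
    min_defect_depth: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.epsilon_fraction < 1:
            raise ValueError("epsilon_fraction must be in (0, 1)")


@dataclass
class PostprocParams:
    """Thresholds of the size/solidity/elongation false-positive filter."""

    min_size: int = 0
    min_solidity: float = 0.0
    max_elongation: float = math.inf

    def __post_init__(self) -> None:
        if self.min_size < 0:
            raise ValueError("min_size must be >= 0")
        if not 0 <= self.min_solidity <= 1:
            raise ValueError("min_solidity must be in [0, 1]")
        if self.max_elongation < 1:
            raise ValueError("max_elongation must be >= 1")


@dataclass(frozen=True)
class ObjectProps:
    area: int
    solidity: float
    elongation: float


def _outer_contour(mask: np.ndarray) -> np.ndarray:
    """Ordered sub-pixel outer contour (row, col) of the largest component."""
    lab = measure.label(mask, connectivity=2)
    if lab.max() > 1:
        sizes = np.bincount(lab.ravel())
        keep = int(np.argmax(sizes[1:])) + 1
        mask = lab == keep
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len) - 1.0  # undo padding offset
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    return contour


def _arc_length(contour: np.ndarray) -> float:
    closed = np.vstack([contour, contour[:1]])
    return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


def _point_segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(pts - a, axis=1)
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def convexity_defects(contour: np.ndarray, min_depth: float = 1.0) -> list[tuple[np.ndarray, float]]:
    """Convexity defects of a closed contour relative to its own convex hull.

    For each pair of consecutive hull vertices (in contour traversal order)
    the deepest intermediate contour point is a defect point, provided its
    distance to the hull edge reaches ``min_depth``; shallower deviations
    are rasterization noise, not constrictions.  Returns one
    ``(point, depth)`` pair per qualifying hull edge.
    """
    n = len(contour)
    if n < 4:
        return []
    try:
        hull = ConvexHull(contour)
    except QhullError:
        return []
    hull_idx = np.unique(hull.vertices)
    defects: list[tuple[np.ndarray, float]] = []
    for k in range(len(hull_idx)):
        i1 = int(hull_idx[k])
        i2 = int(hull_idx[(k + 1) % len(hull_idx)])
        if i2 > i1:
            between = np.arange(i1 + 1, i2)
        else:  # wrap around the contour end
            between = np.concatenate([np.arange(i1 + 1, n), np.arange(0, i2)])
        if between.size == 0:
            continue
        pts = contour[between]
        d = _point_segment_distance(pts, contour[i1], contour[i2])
        deepest = int(np.argmax(d))
        if d[deepest] >= min_depth:
            defects.append((pts[deepest], float(d[deepest])))
    return defects


def split_object(
    frame: LabelFrame, target_id: int, params: SeparationParams | None = None
) -> LabelFrame | None:
    """Split ``target_id`` along its two-defect constriction, if it has one.

    Returns a new frame in which the target's pixels are partitioned into
    ``target_id`` and a fresh label (``max label + 1``) by the straight line
    through the two convexity-defect points, or ``None`` (no-split signal)
    when the defect count differs from two.  The foreground pixel set is
    conserved exactly: the cut reassigns pixels, it never erodes them.
    """
    params = params or SeparationParams()
    mask = frame.pixels == target_id
    if not mask.any():
        raise KeyError(f"label {target_id} not present in frame")
    contour = _outer_contour(mask)
    eps = params.epsilon_fraction * _arc_length(contour)
    approx = measure.approximate_polygon(contour, tolerance=eps)
    if len(approx) > 1 and np.allclose(approx[0], approx[-1]):
        approx = approx[:-1]
    # Defects are sought on the simplified contour first (irregular
    # boundaries cannot then spawn spurious separation planes); when the
    # simplification flattened every concavity, the full-resolution contour
    # decides, with the depth floor filtering raster noise.
    defects = convexity_defects(approx, min_depth=params.min_defect_depth)
    if not defects:
        defects = convexity_defects(contour, min_depth=params.min_defect_depth)
    if len(defects) != 2:
        return None
    p1, p2 = defects[0][0], defects[1][0]

    rr, cc = np.nonzero(mask)
    pts = np.stack([rr, cc], axis=1).astype(float)
    d = p2 - p1
    side = np.sign(np.round((pts[:, 0] - p1[0]) * d[1] - (pts[:, 1] - p1[1]) * d[0], 9))
    n_pos = int((side > 0).sum())
    n_neg = int((side < 0).sum())
    major = 1.0 if n_pos >= n_neg else -1.0
    # pixels exactly on the chord join the larger side
    side[side == 0] = major
    if n_pos == 0 or n_neg == 0:
        return None  # degenerate chord: everything on one side

    new_label = int(frame.pixels.max()) + 1
    out = frame.pixels.copy()
    minor_sel = side == (-major)
    out[rr[minor_sel], cc[minor_sel]] = new_label
    # the larger side keeps target_id (already labelled)
    return LabelFrame(out, frame.frame_index)


def object_props(frame: LabelFrame) -> dict[int, ObjectProps]:
    """Per-label area, solidity and elongation.

    Elongation of a degenerate object (zero minor axis) is ``inf`` so a
    finite ``max_elongation`` always removes single-pixel-wide lines.
    """
    props: dict[int, ObjectProps] = {}
    for rp in measure.regionprops(frame.pixels):
        minor = rp.axis_minor_length
        major = rp.axis_major_length
        if minor == 0:
            elong = 1.0 if major == 0 else math.inf
        else:
            elong = major / minor
        props[int(rp.label)] = ObjectProps(
            area=int(rp.area), solidity=float(rp.solidity), elongation=float(elong)
        )
    return props


def filter_false_positives(frame: LabelFrame, params: PostprocParams) -> LabelFrame:
    """Remove labels with area < min_size, solidity < min_solidity or
    elongation > max_elongation; surviving labels are untouched."""
    out = frame.pixels.copy()
    for label, p in object_props(frame).items():
        if p.area < params.min_size or p.solidity < params.min_solidity or p.elongation > params.max_elongation:
            out[out == label] = 0
    return LabelFrame(out, frame.frame_index)
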