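"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain Python loops over
pixels and exhaustive enumeration over assignments, so they can serve as
oracles for the vectorised implementations.
"""

import itertools
import math

import numpy as np


def ioa_brute(prev: np.ndarray, curr: np.ndarray) -> dict[tuple[int, int], float]:
    """IoA(curr object i, prev object j) by explicit pixel counting."""
    out = {}
    prev_ids = sorted(int(v) for v in np.unique(prev) if v > 0)
    curr_ids = sorted(int(v) for v in np.unique(curr) if v > 0)
    for ci in curr_ids:
        for pj in prev_ids:
            inter = int(((curr == ci) & (prev == pj)).sum())
            area = int((prev == pj).sum())
            out[(ci, pj)] = inter / area
    return out


def track_pair_brute(prev: np.ndarray, curr: np.ndarray, threshold: float = 0.4):
    """The mutual-max IoA rule, written as plain loops.

    Step 1: current objects whose best IoA is strictly below the threshold
    are new.  Step 2: a remaining object keeps its best previous object
    unless another remaining object overlaps that previous object more
    (strictly, or equally with a lower label); losers are new.  Ties among
    previous candidates go to the lower previous label.
    """
    ioa = ioa_brute(prev, curr)
    prev_ids = sorted(int(v) for v in np.unique(prev) if v > 0)
    curr_ids = sorted(int(v) for v in np.unique(curr) if v > 0)
    eligible = [
        ci for ci in curr_ids
        if prev_ids and max(ioa[(ci, pj)] for pj in prev_ids) >= threshold
    ]
    assignments = {}
    for ci in eligible:
        best = max(ioa[(ci, pj)] for pj in prev_ids)
        target = min(pj for pj in prev_ids if ioa[(ci, pj)] == best)
        column = [(ioa[(ck, target)], ck) for ck in eligible]
        col_best = max(v for v, _ in column)
        winners = sorted(ck for v, ck in column if v == col_best)
        if ioa[(ci, target)] == col_best and winners[0] == ci:
            assignments[ci] = target
    new = [ci for ci in curr_ids if ci not in assignments]
    lost = [pj for pj in prev_ids if pj not in assignments.values()]
    return assignments, new, lost


def lsap_brute(cost: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Exhaustive minimum-cost injective assignment of rows to columns."""
    n_rows, n_cols = cost.shape
    k = min(n_rows, n_cols)
    best, best_pairs = math.inf, []
    rows = range(n_rows)
    for chosen_rows in itertools.combinations(rows, k):
        for perm in itertools.permutations(range(n_cols), k):
            total = sum(cost[r, c] for r, c in zip(chosen_rows, perm))
            if total < best:
                best = total
                best_pairs = list(zip(chosen_rows, perm))
    return best_pairs, best


def sphere_volume(r: float) -> float:
    return 4.0 / 3.0 * math.pi * r**3


def cylinder_volume(r: float, h: float) -> float:
    return math.pi * r**2 * h
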