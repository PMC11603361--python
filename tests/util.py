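"""Shared builders and independent oracles for the test suite.

The oracles here are deliberately written from first principles (rank sums,
hypergeometric enumeration, BFS reachability, brute-force scans) so they stay
independent of the implementation paths they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from ntatlas.core_imaging import GridSpec, Mask3D
from ntatlas.tractography import OrientationField


def make_grid(shape=(10, 10, 10), voxel=1.0, origin=None) -> GridSpec:
    affine = np.diag([voxel, voxel, voxel, 1.0])
    if origin is None:
        origin = -(np.array(shape) - 1) / 2.0 * voxel
    affine[:3, 3] = origin
    return GridSpec(tuple(shape), affine)


def straight_tube_field(length=20, width=3, axis=0, kappa=np.inf):
    """Axis-aligned single-fiber tube on a unit grid: seed slab at one end,
    terminus slab at the other, fibers pointing along +axis."""
    shape = [width + 4] * 3
    shape[axis] = length
    grid = make_grid(shape, voxel=1.0)
    tube = np.zeros(grid.shape, dtype=bool)
    sl = [slice(2, 2 + width)] * 3
    sl[axis] = slice(0, length)
    tube[tuple(sl)] = True

    directions = np.zeros(grid.shape + (3,))
    d = np.zeros(3)
    d[axis] = 1.0
    directions[tube] = d

    seed = np.zeros(grid.shape, dtype=np.uint8)
    term = np.zeros(grid.shape, dtype=np.uint8)
    s_sl = list(sl)
    s_sl[axis] = slice(0, 2)
    seed[tuple(s_sl)] = 1
    t_sl = list(sl)
    t_sl[axis] = slice(length - 2, length)
    term[tuple(t_sl)] = 1
    seed &= tube
    term &= tube

    mask = Mask3D(tube.astype(np.uint8), grid.affine)
    field = OrientationField.single_fiber(directions, mask, grid, kappa=kappa)
    return field, Mask3D(seed, grid.affine), Mask3D(term, grid.affine)


def elbow_field(arm=12, width=3):
    """Axis-aligned L-shaped tube (+x then +z) with a detached dead block."""
    shape = (arm + 6, width + 4, arm + 6)
    grid = make_grid(shape, voxel=1.0)
    vox = np.zeros(shape, dtype=bool)
    directions = np.zeros(shape + (3,))
    ys = slice(2, 2 + width)
    # horizontal arm along +x at low z
    vox[2:2 + arm, ys, 2:2 + width] = True
    directions[2:2 + arm, ys, 2:2 + width] = [1.0, 0.0, 0.0]
    # vertical arm along +z at the far-x end
    xs = slice(2 + arm - width, 2 + arm)
    vox[xs, ys, 2:2 + arm] = True
    directions[xs, ys, 2:2 + arm] = [0.0, 0.0, 1.0]
    # disconnected block with fibers pointing out of the grid
    vox[0, 0, 0] = True
    directions[0, 0, 0] = [-1.0, 0.0, 0.0]

    seed = np.zeros(shape, dtype=np.uint8)
    seed[2:4, ys, 2:2 + width] = 1
    seed[0, 0, 0] = 1
    term = np.zeros(shape, dtype=np.uint8)
    term[xs, ys, 2 + arm - 2:2 + arm] = 1

    mask = Mask3D(vox.astype(np.uint8), grid.affine)
    field = OrientationField.single_fiber(directions, mask, grid, kappa=np.inf)
    return field, Mask3D(seed, grid.affine), Mask3D(term, grid.affine)


def reachability_oracle(field: OrientationField, terminus: Mask3D) -> np.ndarray:
    """BFS on the voxel graph: each fiber voxel points to the neighbour in its
    (axis-aligned) fiber direction; returns a boolean reaches-terminus array."""
    shape = field.grid.shape
    has_fiber = field.weights.sum(axis=-1) > 0
    succ = {}
    for idx in map(tuple, np.argwhere(has_fiber)):
        d = field.directions[idx][0]
        step = tuple(int(round(v)) for v in d)
        nxt = tuple(i + s for i, s in zip(idx, step))
        if all(0 <= n < s for n, s in zip(nxt, shape)):
            succ[idx] = nxt
    reaches = np.zeros(shape, dtype=bool)
    for start in succ:
        path = []
        cur = start
        seen = set()
        hit = False
        while True:
            path.append(cur)
            if terminus.data[cur]:
                hit = True
                break
            if cur in seen:
                break
            seen.add(cur)
            nxt = succ.get(cur)
            if nxt is None or not field.tracking_mask.data[nxt]:
                break
            cur = nxt
        if hit:
            reaches[start] = True
    return reaches


def kruskal_oracle(groups) -> float:
    """Tie-corrected Kruskal-Wallis H from the textbook rank-sum formula."""
    allv = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(allv)
    order = np.argsort(allv, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sv = allv[order]
    while i < n:
        j = i
        while j < n and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average rank (1-based)
        i = j
    h = 0.0
    start = 0
    for g in groups:
        gn = len(g)
        r = ranks[start:start + gn]
        h += r.sum() ** 2 / gn
        start += gn
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(allv, return_counts=True)
    denom = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    return h / denom if denom > 0 else float("nan")


def mann_whitney_auc(values, labels, direction) -> float:
    """AUC as the concordance fraction over all positive-negative pairs,
    with half credit for ties (all-pairs enumeration, no sweep)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    score = -values if direction == "low_is_positive" else values
    pos = score[labels == 1][:, None]
    neg = score[labels != 1][None, :]
    wins = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return float(wins) / (pos.size * neg.size)


def fisher_oracle(table) -> float:
    """Two-sided Fisher exact p via exact-rational hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(x):
        return (Fraction(math.comb(c1, x)) * math.comb(n - c1, r1 - x)
                / math.comb(n, r1))

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        if pmf(x) <= p_obs:
            total += pmf(x)
    return float(total)
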