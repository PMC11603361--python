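"""Simplified probabilistic streamline tractography.

Reproduces the seed-to-terminus statistic used to build per-subject hotspots:
for every voxel of the seed region (VIM), launch a fixed number of streamlines
from uniformly jittered positions inside the voxel and record the fraction
that reach the terminus region (precentral gyrus).

The fiber model is a per-voxel mixture of up to two unit directions with
mixture weights and an angular concentration ``kappa`` per fiber
(von-Mises-Fisher dispersion; ``kappa = inf`` means no dispersion).  Step
mechanics are Euler steps with nearest-voxel fiber lookup and a per-step
curvature limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_imaging import GridSpec, Mask3D, Volume3D, grids_match

__all__ = [
    "OrientationField",
    "TrackingParams",
    "Streamline",
    "HitFractionMap",
    "sample_direction",
    "propagate_streamline",
    "seed_to_terminus_fractions",
]


@dataclass
class OrientationField:
    """Per-voxel fiber mixture on a grid.

    directions : (X, Y, Z, F, 3) unit vectors (F fibers per voxel, F <= 2)
    weights    : (X, Y, Z, F) nonnegative, summing to 1 where any fiber exists
                 and to 0 where none does
    kappa      : (X, Y, Z, F) angular concentrations (> 0; inf = deterministic)
    tracking_mask : valid tracking territory
    grid       : the sampling grid shared by all arrays
    """

    directions: np.ndarray
    weights: np.ndarray
    kappa: np.ndarray
    tracking_mask: Mask3D
    grid: GridSpec

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        k = np.asarray(self.kappa, dtype=float)
        if d.ndim != 5 or d.shape[-1] != 3 or d.shape[3] > 2:
            raise ValueError("directions must have shape (X, Y, Z, F<=2, 3)")
        if w.shape != d.shape[:4] or k.shape != d.shape[:4]:
            raise ValueError("weights and kappa must have shape (X, Y, Z, F)")
        if d.shape[:3] != tuple(self.grid.shape):
            raise ValueError("field arrays must live on the stated grid")
        wsum = w.sum(axis=-1)
        has = wsum > 0
        if np.any(w < 0) or not np.allclose(wsum[has], 1.0):
            raise ValueError("weights must be nonnegative and sum to 1 where fibers exist")
        norms = np.linalg.norm(d, axis=-1)
        if not np.allclose(norms[w > 0], 1.0, atol=1e-6):
            raise ValueError("fiber directions must be unit norm where weighted")
        if np.any(k[w > 0] <= 0):
            raise ValueError("kappa must be positive where fibers exist")
        self.directions, self.weights, self.kappa = d, w, k

    @classmethod
    def single_fiber(cls, directions, mask: Mask3D, grid: GridSpec, kappa=np.inf):
        """Build a one-fiber field from an (X, Y, Z, 3) direction array."""
        d = np.asarray(directions, dtype=float)[..., None, :]
        w = (np.linalg.norm(d[..., 0, :], axis=-1) > 0).astype(float)[..., None]
        norms = np.linalg.norm(d, axis=-1, keepdims=True)
        d = np.divide(d, norms, out=np.zeros_like(d), where=norms > 0)
        k = np.full(w.shape, float(kappa))
        return cls(d, w, k, mask, grid)


@dataclass
class TrackingParams:
    """Tracker controls (declared defaults; the source protocol is not printed)."""

    step_mm: float = 0.5
    max_steps: int = 2000
    curvature_limit_deg: float = 80.0
    samples_per_seed_voxel: int = 100
    rng_seed: int = 0
    #: "as_stored" follows the stored fiber orientation on the first step;
    #: "random_sign" flips it with probability 1/2 (bidirectional tracking
    #: stays off either way — each sample fires a single streamline).
    initial_direction: str = "as_stored"

    def __post_init__(self):
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if self.samples_per_seed_voxel < 1:
            raise ValueError("samples_per_seed_voxel must be >= 1")
        if not (0 < self.curvature_limit_deg <= 180):
            raise ValueError("curvature_limit_deg must lie in (0, 180]")
        if self.initial_direction not in ("as_stored", "random_sign"):
            raise ValueError("initial_direction must be 'as_stored' or 'random_sign'")


@dataclass
class Streamline:
    points: np.ndarray  # (n, 3) world mm
    termination_reason: str  # terminus | left_mask | max_steps | curvature_stop | no_fiber


@dataclass
class HitFractionMap:
    """Per-seed-voxel fraction of streamlines reaching the terminus."""

    map: Volume3D
    n_samples: int


def _vmf_sample(mu, kappa: float, rng) -> np.ndarray:
    """Draw a unit vector from a von-Mises-Fisher density on S2 around mu."""
    if math.isinf(kappa):
        return np.asarray(mu, dtype=float)
    u = rng.random()
    # inverse-CDF for the cosine w of the polar angle on S2
    if kappa > 350.0:  # exp(-2k) underflows; exact tail form
        w = 1.0 + math.log(u) / kappa if u > 0 else -1.0
    else:
        w = 1.0 + math.log(u + (1.0 - u) * math.exp(-2.0 * kappa)) / kappa
    w = max(-1.0, min(1.0, w))
    phi = 2.0 * math.pi * rng.random()
    mu = np.asarray(mu, dtype=float)
    # orthonormal basis perpendicular to mu
    helper = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    s = math.sqrt(max(0.0, 1.0 - w * w))
    return s * math.cos(phi) * e1 + s * math.sin(phi) * e2 + w * mu


def _voxel_index(field: OrientationField, at) -> tuple[int, int, int] | None:
    vox = field.grid.world_to_vox(at)
    i, j, k = (int(round(v)) for v in vox)
    sx, sy, sz = field.grid.shape
    if not (0 <= i < sx and 0 <= j < sy and 0 <= k < sz):
        return None
    return i, j, k


def sample_direction(field: OrientationField, at, prev_dir, rng):
    """Draw one propagation direction at a world point; None signals a dead end.

    The fiber is chosen with probability proportional to its voxel weight, the
    direction is perturbed per its kappa, and the sign is flipped so the angle
    to ``prev_dir`` is at most 90 degrees.  With ``prev_dir`` None the stored
    orientation is kept.
    """
    idx = _voxel_index(field, at)
    if idx is None:
        return None
    w = field.weights[idx]
    total = w.sum()
    if total <= 0:
        return None
    nfib = int(np.count_nonzero(w))
    if nfib == 1:
        f = int(np.argmax(w))
    else:
        f = int(rng.choice(len(w), p=w / total))
    mu = field.directions[idx][f]
    d = _vmf_sample(mu, float(field.kappa[idx][f]), rng)
    if prev_dir is not None and float(np.dot(d, prev_dir)) < 0.0:
        d = -d
    return d


def _in_mask(mask: Mask3D, grid: GridSpec, at) -> bool:
    vox = grid.world_to_vox(at)
    i, j, k = (int(round(v)) for v in vox)
    sx, sy, sz = grid.shape
    if not (0 <= i < sx and 0 <= j < sy and 0 <= k < sz):
        return False
    return bool(mask.data[i, j, k])


def propagate_streamline(seed, field: OrientationField, params: TrackingParams, rng,
                         terminus: Mask3D | None = None) -> Streamline:
    """Euler-step a single streamline from a world seed point.

    Stops with reason ``terminus`` on first entry into the terminus mask,
    ``left_mask`` on exiting the tracking mask, ``curvature_stop`` when a step
    would turn more than the curvature limit, ``no_fiber`` at a voxel with no
    fiber, or ``max_steps``.

    The loop is written in scalar arithmetic on purpose: it is the package's
    hot path (millions of steps per atlas bank) and per-step numpy allocation
    would dominate the runtime.  Semantics match :func:`sample_direction`.
    """
    grid = field.grid
    inv = grid._inv_affine
    (a00, a01, a02, a03), (a10, a11, a12, a13), (a20, a21, a22, a23), _ = inv.tolist()
    sx, sy, sz = grid.shape
    mask = field.tracking_mask.data
    tdata = terminus.data if terminus is not None else None
    W, D, K = field.weights, field.directions, field.kappa
    nf = W.shape[3]
    step = params.step_mm
    cos_limit = math.cos(math.radians(params.curvature_limit_deg))
    random_sign = params.initial_direction == "random_sign"

    px, py, pz = (float(v) for v in np.asarray(seed, dtype=float))

    def _idx(x, y, z):
        i = int(round(a00 * x + a01 * y + a02 * z + a03))
        j = int(round(a10 * x + a11 * y + a12 * z + a13))
        k = int(round(a20 * x + a21 * y + a22 * z + a23))
        if 0 <= i < sx and 0 <= j < sy and 0 <= k < sz:
            return i, j, k
        return None

    idx = _idx(px, py, pz)
    if idx is None or not mask[idx]:
        raise ValueError("seed point lies outside the tracking mask")

    points = [(px, py, pz)]
    dx = dy = dz = 0.0
    have_prev = False
    reason = "max_steps"
    for _ in range(params.max_steps):
        i, j, k = _idx(px, py, pz)
        w0 = float(W[i, j, k, 0])
        w1 = float(W[i, j, k, 1]) if nf > 1 else 0.0
        total = w0 + w1
        if total <= 0.0:
            reason = "no_fiber"
            break
        if w0 > 0.0 and w1 > 0.0:
            f = 0 if rng.random() * total < w0 else 1
        else:
            f = 0 if w0 > 0.0 else 1
        kap = float(K[i, j, k, f])
        if math.isinf(kap):
            mx = float(D[i, j, k, f, 0])
            my = float(D[i, j, k, f, 1])
            mz = float(D[i, j, k, f, 2])
        else:
            mx, my, mz = _vmf_sample(D[i, j, k, f], kap, rng)
        if have_prev:
            dot = mx * dx + my * dy + mz * dz
            if dot < 0.0:
                mx, my, mz, dot = -mx, -my, -mz, -dot
            if dot < cos_limit:
                reason = "curvature_stop"
                break
        elif random_sign and rng.random() < 0.5:
            mx, my, mz = -mx, -my, -mz
        nx, ny, nz = px + step * mx, py + step * my, pz + step * mz
        nidx = _idx(nx, ny, nz)
        if tdata is not None and nidx is not None and tdata[nidx]:
            points.append((nx, ny, nz))
            reason = "terminus"
            break
        if nidx is None or not mask[nidx]:
            reason = "left_mask"
            break
        points.append((nx, ny, nz))
        px, py, pz = nx, ny, nz
        dx, dy, dz = mx, my, mz
        have_prev = True
    return Streamline(np.array(points, dtype=float), reason)


def seed_to_terminus_fractions(field: OrientationField, seed: Mask3D, terminus: Mask3D,
                               params: TrackingParams) -> HitFractionMap:
    """Per-seed-voxel fraction of streamlines that reach the terminus.

    Each seed voxel launches ``samples_per_seed_voxel`` streamlines from
    positions jittered uniformly within the voxel.  Every streamline consumes
    an independent, deterministically derived random substream, so results are
    bit-identical for a fixed ``rng_seed`` and unaffected by other streamlines'
    fates (common random numbers across terminus variations).
    """
    if not (grids_match(seed, field.grid) and grids_match(terminus, field.grid)):
        raise ValueError("seed and terminus must live on the field grid")
    if np.any((seed.data > 0) & (terminus.data > 0)):
        raise ValueError("seed and terminus masks overlap")
    seed_vox = np.argwhere(seed.data > 0)
    if seed_vox.shape[0] == 0:
        raise ValueError("seed mask is empty")

    n = params.samples_per_seed_voxel
    children = np.random.SeedSequence(params.rng_seed).spawn(seed_vox.shape[0] * n)
    A = field.grid.affine
    out = np.zeros(field.grid.shape, dtype=float)

    # inner loop kept scalar and allocation-light: it dominates runtime
    a = A[:3, :3]
    b = A[:3, 3]
    for vi, (i, j, k) in enumerate(seed_vox):
        hits = 0
        for s in range(n):
            rng = np.random.default_rng(children[vi * n + s])
            jitter = rng.random(3) - 0.5
            start = a @ (np.array([i, j, k], dtype=float) + jitter) + b
            if not _in_mask(field.tracking_mask, field.grid, start):
                continue  # jitter rounded off the tracking territory: a miss
            sl = propagate_streamline(start, field, params, rng, terminus=terminus)
            if sl.termination_reason == "terminus":
                hits += 1
        out[i, j, k] = hits / n
    return HitFractionMap(Volume3D(out, A), n)
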