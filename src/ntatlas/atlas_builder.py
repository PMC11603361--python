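"""Normative tractographic atlas (NTA) construction.

Each subject's hit-fraction hotspot is warped back to the template grid, the
subject maps are combined by a voxelwise median, and the result is divided by
its global maximum, so the atlas ranges from 0 to 1 with maximum exactly 1.
Voxels a subject's warped map cannot reach contribute 0 to the median rather
than being dropped (the hotspot is defined — zero — everywhere in the seed
region, and dropping would bias medians upward at the atlas rim).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_imaging import GridSpec, Volume3D, grids_match, resample, stereotactic_target
from .tractography import HitFractionMap
from .transforms import SpatialTransform

__all__ = [
    "SubjectHotspot",
    "NTAVolume",
    "warp_hotspot_to_template",
    "median_combine",
    "max_normalize",
    "build_nta",
    "medial_apex",
]


@dataclass
class SubjectHotspot:
    """A subject's hit-fraction map plus the template-to-subject transform."""

    map: HitFractionMap
    template_to_subject: SpatialTransform
    subject_id: str


@dataclass
class NTAVolume:
    """Template-space normative atlas in [0, 1] (max exactly 1 when nonzero)."""

    volume: Volume3D
    n_subjects: int
    pre_norm_max: float  # record-keeping: the maximum removed by normalization


def warp_hotspot_to_template(s: SubjectHotspot, template: GridSpec) -> Volume3D:
    """Trilinear pull-resampling of a subject map onto the template grid.

    The stored transform maps template world to subject world, i.e. it is the
    subject-to-template map's inverse, so it is passed to :func:`resample`
    inverted.  Outside the subject map's support the warped map reads 0.
    """
    return resample(s.map.map, s.template_to_subject.inverse(), template, interp="trilinear")


def median_combine(maps: list[Volume3D]) -> Volume3D:
    """Voxelwise median across same-grid maps (even counts use the midpoint)."""
    if not maps:
        raise ValueError("median of an empty map list is undefined")
    first = maps[0]
    for m in maps[1:]:
        if not grids_match(m, first):
            raise ValueError("all maps must share one grid")
    stack = np.stack([m.data for m in maps], axis=0)
    return Volume3D(np.median(stack, axis=0), first.affine)


def max_normalize(map: Volume3D) -> NTAVolume:
    """Divide by the global maximum so the output peaks at exactly 1."""
    mx = float(map.data.max())
    if mx <= 0:
        raise ValueError("cannot normalize an all-zero map; atlas undefined")
    return NTAVolume(Volume3D(map.data / mx, map.affine), n_subjects=1, pre_norm_max=mx)


def build_nta(subjects: list[SubjectHotspot], template: GridSpec) -> NTAVolume:
    """Warp every subject hotspot to the template, median-combine, max-normalize."""
    if not subjects:
        raise ValueError("atlas needs at least one subject")
    warped = [warp_hotspot_to_template(s, template) for s in subjects]
    nta = max_normalize(median_combine(warped))
    nta.n_subjects = len(subjects)
    return nta


def medial_apex(nta: NTAVolume, hot_fraction: float = 0.9, ac=None, pc=None):
    """Most medial voxel among the atlas's hottest voxels, as a targeting point.

    "Hottest" means value >= hot_fraction * max.  Ties in |lateral| are broken
    by the most anterior (largest y), then most superior (largest z) voxel.
    When AC and PC landmarks are supplied, the report includes the point's
    offsets in the intercommissural frame (lateral from the midcommissural
    point, anterior from PC as a fraction of the AC-PC distance, superior from
    the intercommissural plane).

    Returns ``(point, report)`` with the point in world mm.
    """
    if not (0 < hot_fraction <= 1):
        raise ValueError("hot_fraction must lie in (0, 1]")
    data = nta.volume.data
    mx = float(data.max())
    if mx <= 0:
        raise ValueError("atlas has no nonzero voxels")
    hot = np.argwhere(data >= hot_fraction * mx)
    if hot.shape[0] == 0:
        raise ValueError("hot set is empty")
    A = nta.volume.affine
    world = hot.astype(float) @ A[:3, :3].T + A[:3, 3]
    # lexicographic: min |x|, then max y, then max z
    order = np.lexsort((-world[:, 2], -world[:, 1], np.abs(world[:, 0])))
    point = world[order[0]]
    report = {
        "hot_fraction": hot_fraction,
        "n_hot_voxels": int(hot.shape[0]),
        "point_mm": [float(v) for v in point],
        "value": float(data[tuple(hot[order[0]])]),
    }
    if ac is not None and pc is not None:
        ac = np.asarray(ac, dtype=float)
        pc = np.asarray(pc, dtype=float)
        y_hat = (ac - pc) / np.linalg.norm(ac - pc)
        z_world = np.array([0.0, 0.0, 1.0])
        z_hat = z_world - np.dot(z_world, y_hat) * y_hat
        z_hat /= np.linalg.norm(z_hat)
        x_hat = np.cross(y_hat, z_hat)
        mid = 0.5 * (ac + pc)
        rel = point - mid
        report["acpc_offsets_mm"] = {
            "lateral_from_midcommissural": float(np.dot(rel, x_hat)),
            "anterior_from_pc": float(np.dot(point - pc, y_hat)),
            "superior_from_acpc_plane": float(np.dot(rel, z_hat)),
            "acpc_distance": float(np.linalg.norm(ac - pc)),
        }
    return point, report
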