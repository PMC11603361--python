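"""Patient fitting of the normative atlas and NTC computation.

The atlas is warped into the patient's preoperative T1 grid (the common
frame); the postoperative lesion mask is brought into that same grid by the
postop-to-preop rigid transform; the normative tractography coefficient (NTC)
is the arithmetic mean of the patient-fit atlas over the lesion voxels.  A
one-voxel lesion at the atlas maximum scores exactly 1; a lesion disjoint from
the atlas support scores exactly 0 (out-of-support voxels contribute 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas_builder import NTAVolume
from .core_imaging import (
    GridSpec,
    Mask3D,
    Volume3D,
    center_of_mass_mm,
    grids_match,
    mask_volume_mm3,
    resample,
)
from .transforms import RigidTransform, SpatialTransform

__all__ = [
    "PatientSpaces",
    "LesionMask",
    "NTCResult",
    "fit_nta_to_patient",
    "coregister_lesion",
    "compute_ntc",
    "lesion_report",
]


@dataclass
class PatientSpaces:
    """Grids and transforms tying template, preop and postop spaces together."""

    preop_grid: GridSpec
    postop_grid: GridSpec
    template_to_patient: SpatialTransform  # template world -> preop world (nonlinear allowed)
    postop_to_preop: SpatialTransform  # rigid


@dataclass
class LesionMask:
    """Ablation lesion segmentation in postoperative space (zones I+II)."""

    mask: Mask3D
    zone_note: str = "zones I+II (durable lesion); zone III excluded"


@dataclass
class NTCResult:
    ntc: float
    lesion_voxels: int
    lesion_volume_mm3: float
    distance_to_target_mm: float | None = None
    patient_id: str | None = None


def fit_nta_to_patient(nta: NTAVolume, spaces: PatientSpaces) -> Volume3D:
    """Warp the atlas onto the patient's preop grid (trilinear; stays in [0, 1])."""
    return resample(nta.volume, spaces.template_to_patient, spaces.preop_grid, interp="trilinear")


def coregister_lesion(lesion: LesionMask, spaces: PatientSpaces) -> Mask3D:
    """Move the postop lesion mask onto the preop grid (nearest-neighbour)."""
    out = resample(lesion.mask, spaces.postop_to_preop, spaces.preop_grid, interp="nearest")
    if not np.any(out.data):
        raise ValueError("lesion left the preop field of view during coregistration")
    return out


def compute_ntc(patient_nta: Volume3D, lesion: Mask3D, patient_id: str | None = None) -> NTCResult:
    """Mean of the patient-fit atlas over the lesion voxels (the NTC)."""
    if not grids_match(patient_nta, lesion):
        raise ValueError("patient-fit atlas and lesion must share one grid")
    sel = lesion.data > 0
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise ValueError("NTC of an empty lesion is undefined")
    ntc = float(patient_nta.data[sel].mean())
    return NTCResult(
        ntc=ntc,
        lesion_voxels=n,
        lesion_volume_mm3=mask_volume_mm3(lesion),
        patient_id=patient_id,
    )


def lesion_report(patient_nta: Volume3D, lesion: Mask3D, target=None,
                  patient_id: str | None = None) -> NTCResult:
    """NTC plus lesion volume and, when a target point is given, the distance
    from the target to the lesion center of mass (mm)."""
    res = compute_ntc(patient_nta, lesion, patient_id=patient_id)
    if target is not None:
        com = center_of_mass_mm(lesion)
        res.distance_to_target_mm = float(np.linalg.norm(com - np.asarray(target, dtype=float)))
    return res
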