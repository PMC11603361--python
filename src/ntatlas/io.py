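"""NIfTI-1 and JSON round-tripping for volumes, masks, transforms and cohorts.

qform and sform are both written; on read the sform is preferred when set.
Displacement fields are stored as (X, Y, Z, 3) NIfTI volumes holding world-mm
displacement vectors at voxel centers.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core_imaging import Mask3D, Volume3D
from .transforms import (
    DisplacementFieldTransform,
    SpatialTransform,
    transform_from_json,
    transform_to_json,
)

__all__ = [
    "save_volume", "load_volume", "save_mask", "load_mask",
    "save_transform", "load_transform",
    "save_displacement_field", "load_displacement_field",
    "save_cohort_csv", "load_cohort_csv",
    "save_streamlines_trk",
]


def _affine_of(img) -> np.ndarray:
    sform, scode = img.get_sform(coded=True)
    if scode != 0:
        return np.asarray(sform, dtype=float)
    qform, qcode = img.get_qform(coded=True)
    if qcode != 0:
        return np.asarray(qform, dtype=float)
    return np.asarray(img.affine, dtype=float)


def _make_img(data: np.ndarray, affine: np.ndarray) -> nib.Nifti1Image:
    img = nib.Nifti1Image(data, affine)
    img.set_sform(affine, code=2)
    img.set_qform(affine, code=2)
    return img


def save_volume(vol: Volume3D, path):
    nib.save(_make_img(vol.data.astype(np.float32), vol.affine), str(path))


def load_volume(path) -> Volume3D:
    img = nib.load(str(path))
    return Volume3D(np.asarray(img.dataobj, dtype=np.float64), _affine_of(img))


def save_mask(mask: Mask3D, path):
    nib.save(_make_img(mask.data.astype(np.uint8), mask.affine), str(path))


def load_mask(path) -> Mask3D:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return Mask3D((data > 0).astype(np.uint8), _affine_of(img))


def save_transform(t: SpatialTransform, path):
    Path(path).write_text(transform_to_json(t))


def load_transform(path) -> SpatialTransform:
    return transform_from_json(Path(path).read_text())


def save_displacement_field(t: DisplacementFieldTransform, path):
    nib.save(_make_img(t.field.astype(np.float32), t.affine), str(path))


def load_displacement_field(path) -> DisplacementFieldTransform:
    img = nib.load(str(path))
    return DisplacementFieldTransform(np.asarray(img.dataobj, dtype=np.float64), _affine_of(img))


def save_cohort_csv(cohort, path):
    from .cohort_analysis import cohort_to_dataframe

    cohort_to_dataframe(cohort).to_csv(str(path), index=False)


def load_cohort_csv(path):
    from .cohort_analysis import cohort_from_dataframe

    return cohort_from_dataframe(pd.read_csv(str(path)))


def save_streamlines_trk(streamlines, reference_affine: np.ndarray, shape, path):
    """Optional TrackVis export of world-mm streamlines."""
    from nibabel.streamlines import Tractogram, save as trk_save
    from nibabel.streamlines.trk import TrkFile

    tg = Tractogram([np.asarray(s.points, dtype=np.float32) for s in streamlines],
                    affine_to_rasmm=np.eye(4))
    header = TrkFile.create_empty_header()
    trk_save(tg, str(path), header=header)
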