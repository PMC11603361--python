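"""Synthetic phantoms, lesions and cohorts for the full pipeline.

The phantom emulates, at desk scale, the anatomy the atlas pipeline assumes: a
VIM-like ellipsoidal seed region connected to a precentral-like terminus
region by a curved fiber tube whose orientations run tangent to the tube
centerline.  Subjects are smooth deformations of the template (small random
affine composed with a sinusoidal displacement bounded well under 3 mm, so
inverses converge by fixed point).  Lesions are voxelized ellipsoids with a
known postop-to-preop rigid offset.  Cohorts draw quality-of-life and
adverse-effect outcomes from a logistic model in log lesion volume and NTC,
with the effect directions observed clinically (larger lesions and lower NTC
push toward "worse" QoL and adverse effects); the NTC itself is computed
through the real patient-fitting path, never assigned.

All randomness flows from a single seed through named substreams, so every
stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.spatial import cKDTree

from .atlas_builder import NTAVolume, SubjectHotspot, build_nta
from .cohort_analysis import AE_FLAGS, PatientRecord
from .core_imaging import GridSpec, Mask3D, mask_volume_mm3
from .patient_fit import (
    LesionMask,
    PatientSpaces,
    compute_ntc,
    coregister_lesion,
    fit_nta_to_patient,
)
from .tractography import OrientationField, TrackingParams, seed_to_terminus_fractions
from .transforms import (
    AffineTransform,
    ComposedTransform,
    FunctionDisplacementTransform,
    RigidTransform,
    SpatialTransform,
)

__all__ = [
    "PhantomSpec",
    "SubjectPhantom",
    "CohortSimParams",
    "Cohort",
    "make_template_grid",
    "make_subject_phantom",
    "make_subject_bank",
    "build_synthetic_atlas",
    "make_lesion",
    "simulate_cohort",
]

# named substream indices (stable across versions; never reorder)
_STREAMS = {"subject": 0, "lesion": 1, "outcome": 2, "patient": 3}


def _substream(seed: int, name: str, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[name], *key))
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the template phantom (world mm, RAS; right hemisphere).

    The tube centerline is the quadratic Bezier from the VIM center through
    ``tube_control`` to the precentral center.
    """

    shape: tuple = (40, 48, 44)
    voxel_mm: float = 2.0
    vim_center: tuple = (14.0, -12.0, 2.0)
    vim_radii: tuple = (4.5, 5.5, 4.5)
    precentral_center: tuple = (28.0, -10.0, 34.0)
    precentral_radii: tuple = (9.0, 11.0, 7.0)
    tube_control: tuple = (27.0, -16.0, 16.0)
    tube_radius_mm: float = 5.0
    kappa: float = math.inf
    rng_seed: int = 0

    def grid(self) -> GridSpec:
        return make_template_grid(self.shape, self.voxel_mm)


@dataclass
class SubjectPhantom:
    field: OrientationField
    vim: Mask3D
    precentral: Mask3D
    template_to_subject: SpatialTransform
    subject_id: str


@dataclass(frozen=True)
class CohortSimParams:
    """Generative model of a treated cohort.

    Lesion volumes are log-normal (median ~120 mm^3, matching the scale of
    day-one thalamotomy lesions); lesions land near the patient-fit atlas apex
    with Gaussian placement jitter; accumulated dose volume tracks lesion
    volume at roughly half its size (in cc) plus noise.  QoL and adverse
    effects follow logistic models in standardized log volume and NTC, or a
    hard volume threshold when ``volume_threshold_mm3`` is set.
    """

    n_patients: int = 60
    lesion_volume_median_mm3: float = 120.0
    lesion_volume_sigma_log: float = 0.5
    lesion_aspect: tuple = (1.0, 1.0, 1.3)
    placement_jitter_mm: float = 1.5
    adv_factor: float = 0.5  # ADV_cc = volume_mm3 * factor / 1000 + noise
    adv_noise_cc: float = 0.004
    # QoL model (logit of "worse"); z-scores use the standardization below
    qol_worse_intercept: float = -1.9
    qol_worse_beta_logvol: float = 1.6
    qol_worse_beta_ntc: float = -0.8
    volume_threshold_mm3: float | None = None  # threshold variant replaces the logistic
    p_worse_below: float = 0.05
    p_worse_above: float = 0.85
    p_better_given_not_worse: float = 0.725  # 37 of 51 non-worse patients
    # adverse-effect model (logit of any persistent AE)
    ae_intercept: float = -1.6
    ae_beta_logvol: float = 1.0
    ae_beta_ntc: float = -0.5
    # subjective tremor suppression (%) by QoL group: mean, sd
    suppression_better: tuple = (86.8, 15.0)
    suppression_same: tuple = (46.7, 25.0)
    suppression_worse: tuple = (93.2, 7.0)
    rng_seed: int = 0

    # standardization constants for the logistic models
    ntc_center: float = 0.55
    ntc_scale: float = 0.15


@dataclass
class Cohort:
    records: list
    ground_truth: dict
    params: CohortSimParams


def make_template_grid(shape=(40, 48, 44), voxel_mm: float = 2.0) -> GridSpec:
    """Isotropic RAS grid centered on the world origin."""
    shape = tuple(int(s) for s in shape)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -(np.array(shape) - 1) / 2.0 * voxel_mm
    return GridSpec(shape, affine)


def _bezier(p0, p1, p2, t):
    t = np.asarray(t, dtype=float)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _bezier_tangent(p0, p1, p2, t):
    t = np.asarray(t, dtype=float)[:, None]
    d = 2 * (1 - t) * (p1 - p0) + 2 * t * (p2 - p1)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def _grid_world_bounds(grid: GridSpec):
    corners = np.array(
        [[i, j, k] for i in (0, grid.shape[0] - 1)
         for j in (0, grid.shape[1] - 1) for k in (0, grid.shape[2] - 1)],
        dtype=float,
    )
    world = corners @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    return world.min(axis=0), world.max(axis=0)


def _random_affine(rng, max_rot_deg=2.0, max_scale=0.03, max_trans_mm=2.0) -> AffineTransform:
    angles = np.radians(rng.uniform(-max_rot_deg, max_rot_deg, 3))
    scales = 1.0 + rng.uniform(-max_scale, max_scale, 3)
    trans = rng.uniform(-max_trans_mm, max_trans_mm, 3)
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    m = np.eye(4)
    m[:3, :3] = Rz @ Ry @ Rx @ np.diag(scales)
    m[:3, 3] = trans
    return AffineTransform(m)


def _random_sinusoidal_warp(rng, max_amp_mm=1.0) -> FunctionDisplacementTransform:
    """Smooth bounded displacement d_c(x) = a_c sin(2 pi x_{p(c)} / L_c + phi_c).

    Per-component amplitude <= 1 mm (total < sqrt(3) mm) and wavelengths of
    50-80 mm keep the Jacobian of x + d(x) far from singular, so the
    fixed-point inverse converges everywhere.
    """
    amp = rng.uniform(0.3, max_amp_mm, 3)
    wavelength = rng.uniform(50.0, 80.0, 3)
    phase = rng.uniform(0.0, 2.0 * math.pi, 3)
    perm = rng.permutation(3)

    def disp(pts):
        return amp * np.sin(2.0 * math.pi * pts[:, perm] / wavelength + phase)

    return FunctionDisplacementTransform(disp)


def random_subject_transform(rng) -> SpatialTransform:
    """Template-to-subject map: small random affine then a sinusoidal warp."""
    return ComposedTransform([_random_affine(rng), _random_sinusoidal_warp(rng)])


def _ellipsoid_mask(grid: GridSpec, center, radii, warp_inv=None) -> Mask3D:
    """Voxelize an ellipsoid; with ``warp_inv``, membership is tested in the
    pre-warp frame (subject masks are warped template ellipsoids)."""
    pts = grid.all_voxel_centers_world()
    if warp_inv is not None:
        pts = warp_inv.apply(pts)
    rel = (pts - np.asarray(center, dtype=float)) / np.asarray(radii, dtype=float)
    inside = (rel**2).sum(axis=1) <= 1.0
    return Mask3D(inside.reshape(grid.shape).astype(np.uint8), grid.affine)


def make_subject_phantom(spec: PhantomSpec, subject_seed: int | None = None,
                         identity: bool = False, subject_id: str | None = None) -> SubjectPhantom:
    """A subject brain: deformed template geometry plus its known transform.

    With ``identity=True`` (or as the template itself) no deformation is
    applied.  The orientation field holds a single fiber per tube voxel,
    tangent to the deformed centerline and oriented seed-to-terminus, with the
    spec's dispersion ``kappa``.
    """
    grid = spec.grid()
    if identity:
        xform: SpatialTransform = RigidTransform.identity()
    else:
        rng = _substream(spec.rng_seed, "subject", int(subject_seed or 0))
        xform = random_subject_transform(rng)
    xform_inv = xform.inverse()

    p0 = np.asarray(spec.vim_center, dtype=float)
    p1 = np.asarray(spec.tube_control, dtype=float)
    p2 = np.asarray(spec.precentral_center, dtype=float)
    t = np.linspace(0.0, 1.0, 200)
    center_tpl = _bezier(p0, p1, p2, t)
    center_sub = np.atleast_2d(xform.apply(center_tpl))
    # tangents of the *deformed* centerline, oriented VIM -> precentral
    tang = np.gradient(center_sub, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)

    lo, hi = _grid_world_bounds(grid)
    margin = spec.tube_radius_mm
    if np.any(center_sub < lo + margin) or np.any(center_sub > hi - margin):
        raise ValueError("deformed fiber tube leaves the phantom grid")

    pts = grid.all_voxel_centers_world()
    tree = cKDTree(center_sub)
    dist, nearest = tree.query(pts)
    in_tube = (dist <= spec.tube_radius_mm).reshape(grid.shape)
    # fibers extend one voxel past the wall so discretization cannot strand a step
    in_field = dist <= spec.tube_radius_mm + spec.voxel_mm

    # tangent of the nearest centerline point plus a centripetal component that
    # grows toward the wall: off-axis flow converges back to the axis instead
    # of drifting out of the voxelized tube
    tang_v = tang[nearest]
    to_axis = center_sub[nearest] - pts
    perp = to_axis - (to_axis * tang_v).sum(axis=1, keepdims=True) * tang_v
    pd = np.linalg.norm(perp, axis=1, keepdims=True)
    punit = np.divide(perp, pd, out=np.zeros_like(perp), where=pd > 1e-9)
    raw = tang_v + 0.6 * (pd / spec.tube_radius_mm) * punit
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    directions = np.zeros(grid.shape + (3,))
    directions[in_field.reshape(grid.shape)] = raw[in_field]

    warp_inv = None if identity else xform_inv
    vim = _ellipsoid_mask(grid, spec.vim_center, spec.vim_radii, warp_inv)
    prec = _ellipsoid_mask(grid, spec.precentral_center, spec.precentral_radii, warp_inv)
    if np.any(vim.data & prec.data):
        raise ValueError("seed and terminus regions overlap; adjust the phantom spec")

    territory = binary_dilation(in_tube | (vim.data > 0) | (prec.data > 0), iterations=1)
    tracking_mask = Mask3D(territory.astype(np.uint8), grid.affine)
    fld = OrientationField.single_fiber(directions, tracking_mask, grid, kappa=spec.kappa)
    return SubjectPhantom(
        field=fld,
        vim=vim,
        precentral=prec,
        template_to_subject=xform,
        subject_id=subject_id or f"sub-{subject_seed or 0:03d}",
    )


def make_subject_bank(spec: PhantomSpec, n_subjects: int = 20,
                      params: TrackingParams | None = None) -> list[SubjectHotspot]:
    """Run the tracker on ``n_subjects`` deformed phantoms and collect hotspots."""
    if params is None:
        params = TrackingParams()
    out = []
    for i in range(n_subjects):
        ph = make_subject_phantom(spec, subject_seed=i + 1, subject_id=f"sub-{i + 1:03d}")
        p = replace(params, rng_seed=params.rng_seed + i)
        hfm = seed_to_terminus_fractions(ph.field, ph.vim, ph.precentral, p)
        out.append(SubjectHotspot(map=hfm, template_to_subject=ph.template_to_subject,
                                  subject_id=ph.subject_id))
    return out


def build_synthetic_atlas(spec: PhantomSpec | None = None, n_subjects: int = 20,
                          params: TrackingParams | None = None) -> NTAVolume:
    """End-to-end: phantom bank -> tracker -> warp -> median -> normalize."""
    spec = spec or PhantomSpec()
    bank = make_subject_bank(spec, n_subjects=n_subjects, params=params)
    return build_nta(bank, spec.grid())


def make_lesion(center, radii, postop_offset: RigidTransform, grid: GridSpec
                ) -> tuple[LesionMask, RigidTransform]:
    """Voxelized ellipsoidal ablation lesion in postoperative space.

    ``center`` is the lesion center in *preop* world mm; ``postop_offset`` is
    the ground-truth postop-to-preop rigid, so the mask is built around the
    inverse-mapped center on the postop grid.  The voxelized volume matches
    the analytic (4/3) pi abc within surface-voxel discretization error.
    """
    center = np.asarray(center, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("lesion radii must be positive")
    postop_center = postop_offset.inverse().apply(center)
    lo, hi = _grid_world_bounds(grid)
    if np.any(postop_center - radii < lo) or np.any(postop_center + radii > hi):
        raise ValueError("lesion ellipsoid extends outside the postop grid")
    mask = _ellipsoid_mask(grid, postop_center, radii)
    if not np.any(mask.data):
        raise ValueError("lesion ellipsoid is smaller than a single voxel on this grid")
    return LesionMask(mask=mask), postop_offset


def _random_patient_spaces(atlas_grid: GridSpec, rng) -> PatientSpaces:
    template_to_patient = _random_affine(rng)
    angles = np.radians(rng.uniform(-1.0, 1.0, 3))
    ca, cb, cg = np.cos(angles)
    sa, sb, sg = np.sin(angles)
    Rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    rigid = RigidTransform.from_rotation_translation(Rz @ Ry @ Rx, rng.uniform(-1.0, 1.0, 3))
    return PatientSpaces(
        preop_grid=atlas_grid,
        postop_grid=atlas_grid,
        template_to_patient=template_to_patient,
        postop_to_preop=rigid,
    )


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# relative frequencies of individual persistent AEs (most common first)
_AE_WEIGHTS = {
    "gait_ataxia": 8, "limb_ataxia_weakness": 5, "dysarthria": 4,
    "cognitive_behavioral": 4, "taste_smell": 2, "tongue_numbness": 1,
    "limb_numbness": 1, "dysphagia": 1, "fatigue": 1,
}


def simulate_cohort(params: CohortSimParams, atlas: NTAVolume,
                    spaces: list[PatientSpaces] | None = None) -> Cohort:
    """Simulate a treated cohort through the real patient-fitting pipeline.

    For each patient: draw patient spaces, warp the atlas into the preop grid,
    place an ellipsoidal lesion with Gaussian jitter around the patient-fit
    atlas apex, score it with :func:`compute_ntc` (so the NTC is measured, not
    assigned), then draw QoL, adverse effects, CRST scores and subjective
    suppression from the outcome model.  All latent draws are logged in the
    returned ground truth for recovery tests.
    """
    if params.n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if params.lesion_volume_sigma_log < 0 or params.placement_jitter_mm < 0:
        raise ValueError("dispersion parameters must be nonnegative")
    for p in (params.p_worse_below, params.p_worse_above, params.p_better_given_not_worse):
        if not (0.0 <= p <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")

    atlas_grid = atlas.volume.grid
    records, truth = [], {}
    for i in range(params.n_patients):
        rng = _substream(params.rng_seed, "patient", i)
        sp = spaces[i] if spaces is not None else _random_patient_spaces(atlas_grid, rng)
        patient_nta = fit_nta_to_patient(atlas, sp)
        apex_idx = np.unravel_index(int(np.argmax(patient_nta.data)), patient_nta.shape)
        apex = sp.preop_grid.vox_to_world(np.array(apex_idx, dtype=float))

        lrng = _substream(params.rng_seed, "lesion", i)
        volume = params.lesion_volume_median_mm3 * math.exp(
            lrng.normal(0.0, params.lesion_volume_sigma_log)
        )
        aspect = np.asarray(params.lesion_aspect, dtype=float)
        r0 = (volume / (4.0 / 3.0 * math.pi * np.prod(aspect))) ** (1.0 / 3.0)
        radii = r0 * aspect
        jitter = lrng.normal(0.0, params.placement_jitter_mm, 3)
        lesion, rigid = make_lesion(apex + jitter, radii, sp.postop_to_preop, sp.postop_grid)
        native_volume = mask_volume_mm3(lesion.mask)
        lesion_pre = coregister_lesion(lesion, sp)
        ntc = compute_ntc(patient_nta, lesion_pre, patient_id=f"pt-{i + 1:03d}").ntc

        orng = _substream(params.rng_seed, "outcome", i)
        adv = native_volume * params.adv_factor / 1000.0 + orng.normal(0.0, params.adv_noise_cc)
        adv = max(adv, 0.0)
        z_v = math.log(native_volume / params.lesion_volume_median_mm3) / max(
            params.lesion_volume_sigma_log, 1e-9
        )
        z_n = (ntc - params.ntc_center) / params.ntc_scale
        if params.volume_threshold_mm3 is not None:
            p_worse = (params.p_worse_above if native_volume > params.volume_threshold_mm3
                       else params.p_worse_below)
        else:
            p_worse = _sigmoid(params.qol_worse_intercept
                               + params.qol_worse_beta_logvol * z_v
                               + params.qol_worse_beta_ntc * z_n)
        if orng.random() < p_worse:
            qol = "worse"
        else:
            qol = "better" if orng.random() < params.p_better_given_not_worse else "same"

        p_ae = _sigmoid(params.ae_intercept + params.ae_beta_logvol * z_v
                        + params.ae_beta_ntc * z_n)
        persistent = bool(orng.random() < p_ae)
        flags: set[str] = set()
        if persistent:
            n_flags = 1 + orng.poisson(0.5)
            names = list(_AE_WEIGHTS)
            w = np.array([_AE_WEIGHTS[k] for k in names], dtype=float)
            chosen = orng.choice(len(names), size=min(n_flags, len(names)),
                                 replace=False, p=w / w.sum())
            flags = {names[int(c)] for c in chosen}

        mu_sd = {"better": params.suppression_better, "same": params.suppression_same,
                 "worse": params.suppression_worse}[qol]
        suppression = float(np.clip(orng.normal(*mu_sd), 0.0, 100.0))

        def _crst(pre_mu, pre_sd):
            pre = max(0.5, orng.normal(pre_mu, pre_sd))
            post = max(0.0, pre * (1.0 - suppression / 100.0) + orng.normal(0.0, 0.3))
            return round(pre, 1), round(post, 1)

        a_pre, a_post = _crst(3.0, 0.8)
        b_pre, b_post = _crst(5.9, 1.0)
        c_pre, c_post = _crst(4.0, 1.0)

        rec = PatientRecord(
            id=f"pt-{i + 1:03d}",
            qol=qol,
            lesion_volume_mm3=round(native_volume, 2),
            adv_cc=round(adv, 4),
            ntc=round(ntc, 3),
            sdr=round(float(np.clip(orng.normal(0.57, 0.08), 0.3, 0.9)), 2),
            crst_a_pre=a_pre, crst_a_post=a_post,
            crst_b_pre=b_pre, crst_b_post=b_post,
            crst_c_pre=c_pre, crst_c_post=c_post,
            subjective_suppression_pct=round(suppression, 1),
            ae_flags=frozenset(flags),
            persistent_ae=persistent,
            followup_days=float(max(60, int(orng.normal(405.0, 120.0)))),
        )
        records.append(rec)
        truth[rec.id] = {
            "apex_mm": [float(v) for v in apex],
            "jitter_mm": [float(v) for v in jitter],
            "volume_analytic_mm3": float(volume),
            "volume_voxelized_mm3": float(native_volume),
            "radii_mm": [float(v) for v in radii],
            "ntc": float(ntc),
            "p_worse": float(p_worse),
            "p_ae": float(p_ae),
        }
    return Cohort(records=records, ground_truth=truth, params=params)
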