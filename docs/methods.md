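# Methods

## Coordinate conventions

World space is RAS in millimetres. Voxel indices are 0-based; a voxel's
world position is its **center** under the 4×4 voxel-to-world affine
(NIfTI-1 convention). All resampling is pull-style: each target voxel center
is mapped through the inverse transform and the source is sampled there —
trilinear for scalar volumes, nearest-neighbour for masks (trilinear on a
mask is rejected). Sampling outside a volume's support returns 0, never NaN:
unreached territory means "no connectivity", and the atlas and NTC math
depend on that reading (a lesion outside the atlas support must average to
exactly 0).

## Spatial transforms

Rigid and affine transforms are 4×4 homogeneous matrices with exact
inverses; rigid rotations are constrained to determinant +1. Displacement
transforms map x ↦ x + d(x), with d either a dense (X,Y,Z,3) field of
world-mm vectors interpolated trilinearly (edge values extended outside the
grid) or an analytic callable. Their inverse is solved per point by
fixed-point iteration x_{k+1} = y − d(x_k), tolerance 10⁻³ mm, at most 50
iterations; non-convergence raises rather than warns, because a silently
inaccurate inverse would corrupt every downstream warp. Convergence is
guaranteed when d is a contraction (Lipschitz constant < 1), which the
synthetic warps satisfy by construction.

Rigid landmark registration is closed-form orthogonal Procrustes without
scaling: SVD of the centered cross-covariance, with the sign of the smallest
singular direction flipped when needed to force det(R) = +1. At least three
non-collinear pairs are required (rank of the centered landmark matrix ≥ 2).

The canonical stereotactic VIM coordinate is constructed from the AC/PC
landmarks: 11 mm lateral to the third-ventricle wall on the treated side,
one quarter of the AC–PC distance anterior to PC along the PC→AC axis, and
2 mm superior to the intercommissural plane. The superior axis is world +z
orthogonalized against the AC–PC axis; the construction is equivariant under
rigid motion of the head.

## Probabilistic tracker

The fiber model is a per-voxel mixture of up to two unit directions with
mixture weights and an angular concentration κ per fiber (κ = ∞ means no
dispersion). Directions are drawn from a von-Mises–Fisher density on the
sphere via the standard inverse-CDF of the polar cosine; for κ > 350 the
exact tail form w = 1 + log(u)/κ avoids underflow. The sign of a drawn
direction is flipped to keep the angle to the previous step ≤ 90°.

Propagation is Euler stepping with nearest-voxel fiber lookup (no
directional interpolation — chosen so the tracker can be checked exactly
against a voxel-graph reachability oracle). Tracking parameters (declared
defaults, since no upstream protocol is printed): step 0.5 mm, at most 2000
steps, per-step curvature limit 80°, 100 streamlines per seed voxel.
Streamlines stop on first entry into the terminus mask, on leaving the
tracking mask, on exceeding the curvature limit, at a voxel without fibers,
or at the step cap.

Each seed voxel launches its streamlines from positions jittered uniformly
within the voxel (removes grid artifacts and matches probabilistic
samplers). Every streamline consumes an independent random substream spawned
deterministically from the map seed, so hit-fraction maps are bit-identical
across runs and growing the terminus can only convert misses to hits
(common-random-numbers monotonicity), never the reverse.

Tracking is unidirectional: with no previous direction the tracker follows
the stored fiber orientation exactly. The synthetic fields orient fibers
seed-to-terminus, which makes a dispersion-free tube deterministic (hit
fraction exactly 1). A `random_sign` initial-direction policy is available
on `TrackingParams` for orientation-free fields; it halves hit fractions in
oriented tubes and is therefore not the default. The per-streamline loop is
deliberately written in scalar arithmetic — it runs millions of steps per
atlas bank and per-step numpy allocation would dominate the runtime.

## Atlas construction

Subject hotspots are pull-resampled onto the template grid through the
inverse of the stored template-to-subject transform, combined by a voxelwise
median (even counts use the midpoint of the two central order statistics),
and divided by the single global maximum, so the atlas lies in [0, 1] with
maximum exactly 1. Two deliberate readings:

- voxels a subject's warped map cannot reach contribute **0** to the median
  rather than being dropped — the hotspot is defined (zero) everywhere in
  the seed region, and dropping low-coverage subjects would bias the atlas
  rim upward;
- normalization is by one global maximum per atlas object, which is what
  makes "ranges from 0 to 1" a property of the object; per-slice
  normalization would not.

The targeting point is the **medial apex** of the hottest voxels: among
voxels with value ≥ `hot_fraction` × max (default 0.9 — no published
threshold exists, so the value is declared and configurable), the voxel with
the smallest |lateral| world coordinate, ties broken by most anterior, then
most superior. When AC/PC landmarks are supplied the report includes the
point's offsets in the intercommissural frame.

## Patient fitting and the NTC

The preoperative T1 grid is the common frame: the atlas is warped into it
(trilinear, values stay in [0, 1]) and the postoperative lesion mask is
moved into it by the postop-to-preop rigid (nearest-neighbour). The NTC is
the arithmetic mean of the patient-fit atlas over the lesion voxels, with
voxel-center lookup (no sub-voxel averaging — declared choice). Lesion
volume is computed in the mask's native postoperative grid before
coregistration, and the coregistered voxel count is reported alongside, so
discretization effects of the rigid are visible. NTC values are rounded to
3 decimals only in reports; classification against the 0.544 operating
point uses the strict ">".

## Cohort statistics

- **ROC / Youden.** Candidate cutoffs are the midpoints between consecutive
  distinct observed values plus sentinels beyond the extremes, with a strict
  comparison in the favorable direction — so reported cutoffs read exactly
  like the published ones ("<127.4", ">0.544") and are estimator-stable.
  AUC is the trapezoid over the swept curve, which equals the Mann–Whitney
  concordance fraction (half credit for ties) to machine precision; the
  test suite enforces 10⁻¹². The Youden optimum maximizes
  J = sensitivity + specificity − 1; ties go to the higher specificity,
  then to the cutoff predicting fewer positives.
- **Group tests.** Kruskal–Wallis uses the tie-corrected H with a χ²
  approximation on k−1 degrees of freedom (delegated to scipy; an
  independently coded rank-sum oracle guards it in the tests). An
  all-values-identical input returns H = 0, p = 1 rather than erroring. The
  mean-padding variant — padding a group with copies of its own mean up to a
  minimum size, a convention that appears in the clinical analysis being
  emulated — is statistically irregular and therefore opt-in
  (`pad_to_min_n`), never the default.
- **Association.** Fisher's exact test (two-sided, hypergeometric mass of
  tables no more probable than observed) is the declared choice for 2×2
  outcome tables; the test suite checks it against exact-rational
  enumeration for all small tables.
- **Missing data** are handled complete-case per analysis, with the
  analyzed-n reported, matching cohorts with varying denominators.

## Synthetic data: what it emulates, and what it does not

The phantom is a right-hemisphere caricature on a 40×48×44 grid of 2 mm
voxels: a VIM-like ellipsoid (center (14, −12, 2) mm, radii ≈ 4.5–5.5 mm)
joined to a precentral-like ellipsoid near the cortex by a tube of 5 mm
radius following a quadratic Bezier arc. Fibers inside the tube run tangent
to the deformed centerline plus a centripetal component growing toward the
wall (up to atan(0.6) ≈ 31° at the wall), so off-axis flow converges to the
axis instead of drifting out of the voxelized tube; the fiber field extends
one voxel past the wall so discretization cannot strand a step. With κ = ∞
every VIM voxel inside the tube reaches the terminus with fraction exactly 1.

Subject deformations are a small random affine (rotations ≤ 2°, scale ±3%,
translation ≤ 2 mm) composed with a sinusoidal displacement (≤ 1 mm per
component, wavelengths 50–80 mm), keeping the warp a contraction so the
fixed-point inverse is exact to tolerance — registration error is thereby
removed as a confounder in tests. Lesions are voxelized ellipsoids whose
volume matches (4/3)πabc within the surface-layer discretization bound.

Cohorts draw lesion volumes from a log-normal with median 120 mm³ (the
scale of day-one thalamotomy lesions) and σ_log 0.5; lesions land with
1.5 mm Gaussian jitter around the patient-fit atlas apex; ADV tracks lesion
volume at half its size in cc plus 0.004 cc noise. The NTC is *measured*
through the real patient-fitting path, never assigned. QoL follows a
logistic model in standardized log-volume (+1.6) and NTC (−0.8) around a
−1.9 intercept, reproducing the observed effect directions and an overall
worse rate near 15%; the non-worse group splits better:same at 0.725.
Adverse effects follow an analogous logistic (+1.0 volume, −0.5 NTC), with
individual flags drawn at the observed relative frequencies (gait ataxia
most common; dysarthria concentrated in the worse group). Subjective tremor
suppression is drawn per QoL group — better 86.8%, same 46.7%, worse 93.2%
on average — reproducing the counterintuitive clinical pattern in which the
"worse" group still perceives excellent tremor control. A
`volume_threshold_mm3` switch replaces the logistic with a hard threshold
(worse probability 0.85 above, 0.05 below) for cutoff-recovery studies.

All randomness flows from one seed through named substreams (subject,
lesion, outcome, patient), so any stage reruns independently and cohort CSVs
are byte-identical for a fixed seed.

What the phantom does **not** emulate: diffusion signal formation and
crossing-fiber estimation, anatomically constrained tracking, registration
error (transforms are known analytically), partial-volume lesion borders,
longitudinal lesion evolution, and real outcome heterogeneity. Passing
tests therefore validate the *pipeline's* arithmetic and invariances — not
the clinical accuracy of any atlas built from real data.

## Problem sizes

Desk-scale sizes keep the full suite and the acceptance script fast while
leaving every statistical check adequately powered: atlas banks of 5
subjects (20 for the normalization check) tracked at 25 streamlines per
seed voxel on the 2 mm grid; cohorts of 60 patients under the logistic
model and 500 under the threshold/null models; 200 random datasets (n ≤
200) for the ROC-oracle comparison. Bank size and sample counts are
configurable upward; the atlas bank default in the library is 20 subjects.

## Known limitations

- The tracker's nearest-voxel fiber lookup makes streamlines sensitive to
  voxelization at tube walls; the convergent field compensates inside the
  phantom, but fields built from other sources should be given a tracking
  mask slightly wider than their fiber support.
- The per-step curvature limit (80°) interacts with axis-aligned 90° turns:
  graph-oracle comparisons on elbow phantoms are run at a 100° limit.
- The displacement-field inverse assumes a contraction; strong warps
  (|∇d| ≥ 1) are rejected by non-convergence rather than solved.
- Published AUCs, sensitivities and H statistics from the 60-patient
  clinical cohort are not reproducible here — the raw data are not
  published — so cohort-level checks are property-based (effect directions,
  oracle agreement, generative-parameter recovery) rather than numerical
  replications.
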