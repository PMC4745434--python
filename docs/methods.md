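# Methods

This note documents the models, numerical choices and design decisions behind
`gaitkin`, and what the synthetic test bed does and does not establish about
real motion-capture data. Units are millimetres and degrees throughout;
sampling rates in Hz.

## Rigid-body layer

**Cluster pose.** Each segment carries a cluster of ≥ 3 noncollinear
technical markers. Its per-frame pose is the weighted least-squares
orthogonal Procrustes solution (SVD of the cross-covariance of centred point
sets) with a reflection guard: when the unconstrained optimum has a negative
determinant, the smallest singular direction is negated so the result is
always a proper rotation. The reference geometry is the mean marker
configuration of the static trial, so the cluster pose *is the identity
during the static trial* — landmark vectors registered there are directly
technical-frame coordinates, and dynamic poses map the static configuration
onto the current one. Degenerate references (second singular value below
1e−8 of the first) raise a geometry error; frames with any invalid cluster
marker produce an invalid pose, never a fit from partial data.

**Pointer.** The pointer's technical frame is its marker configuration at
the first fully visible pivot-trial frame. Pivot calibration solves
`[R_i  −I][p_tip; p_pivot] = −d_i` in least squares over all pivot poses and
stores the residual RMS with the model; a smallest singular value below 1e−6
of the largest (e.g. pure translations) means the tip offset is unobservable
and raises an error. At least 10 poses are required. Landmark registration
transforms the tip into the owning cluster's frame, `Rᵀ(tip − d)`, averaged
over the whole static window (default: all scheduled frames); the per-frame
scatter about the mean is reported as the registration residual. Averaging
over n frames reduces isotropic noise by ~1/√n; a single-instant
registration is available by passing a one-frame window.

## Anatomical frames

All segment frames use X anterior, Y superior, Z to the subject's right
(right limb; right-handed, det +1). The recipes, chosen where the convention
leaves freedom and overridable in configuration:

* **Pelvis** — origin mid-ASIS; Z along the inter-ASIS line; X anterior in
  the plane through the ASISs and the mid-PSIS (cluster protocol) or sacrum
  marker (HH).
* **Femur** — origin at the hip joint centre (HJC); Y from the mid-epicondyle
  point to the HJC; Z toward the lateral epicondyle.
* **Shank** — origin at the inter-malleolar point; Y toward the midpoint of
  the tibial tuberosity and the fibular head; Z toward the lateral malleolus.
  Using shank-owned proximal landmarks (rather than the femoral epicondyles)
  keeps shank and ankle kinematics independent of the thigh cluster, so a
  thigh-cluster artefact cannot leak into the ankle.
* **Foot** — the shank anatomical frame captured during the neutral static
  trial, rigidly attached to the foot technical frame thereafter. The ankle
  therefore reads exactly (0, 0, 0) in the neutral stance by construction.

**Hip joint centre.** Davis/Newington regression, used identically by both
protocols so protocol differences cannot originate there:
`C = 0.115·L − 15.3`; θ = 28.4°, β = 18°; ASIS-trochanter offset default
`0.1288·L − 48.56`; in the ISB pelvis frame the HJC is
(`C cosθ sinβ − (X_dis + r) cosβ`, `−C cosθ cosβ − (X_dis + r) sinβ`,
`±(d_ASIS/2 − C sinθ)`), posterior/inferior of the mid-ASIS origin and
lateral toward the requested side; `r` is the marker radius.

**Helen Hayes.** The thigh frame is built from the HJC, the lateral knee
marker and the thigh wand; the knee centre comes from the chord construction
(centre in the plane of the three points, at half knee width plus marker
radius from the lateral marker, centre→lateral perpendicular to the long
axis; of the two solutions the one opposite the wand — medial — is taken).
The shank repeats the construction with the knee centre, lateral malleolus
marker and shank wand. The HH foot axis runs heel → forefoot with the frame
completed against the shank's mediolateral axis, which reproduces the
conventional model's two-degrees-of-freedom ankle: inversion/eversion is
structurally absent from its output. The published "modified" variants of
this marker set are not fully specified anywhere, so the canonical
construction is implemented and deviations are configuration switches.

## Joint angles

Relative orientation `R_rel = R_proxᵀ R_dist` is decomposed in the intrinsic
Z–X–Y Cardan sequence (`R = Rz(α) Rx(β) Ry(γ)`): flexion about the proximal
mediolateral axis, ab/adduction about the floating anteroposterior axis,
axial rotation about the distal longitudinal axis — the
joint-coordinate-system-equivalent ordering. Pelvis angles use the same
sequence against the laboratory frame (tilt, obliquity, rotation). Signs for
the right limb: flexion, adduction/varus and internal rotation positive;
knee flexion is the one label whose clinical positive sense opposes the raw
Z rotation, handled by a single −1 in the sign table that both the analysis
and the forward simulator share. The middle angle is confined to
(−90°, 90°]; within 0.1° of gimbal lock only α ± γ is observable, so γ is
set to 0, α absorbs the remainder and the sample is flagged. Curves are
unwrapped per rotation to avoid ±180° jumps. Joint translations, which the
6DOF marker set would permit, are deliberately not emitted.

## Cycle processing

The "4th-order zero-lag Butterworth, 6 Hz" is realised as a forward-backward
pass of a 2nd-order filter whose cutoff is raised by the dual-pass correction
`(√2 − 1)^(−1/4) ≈ 1.2465`, so the *effective* filter is 4th order with its
−3 dB point at the requested cutoff (a per-pass-order mode is available).
Edges use reflective (even) padding of about three cutoff periods. Filtering
applies to marker trajectories before pose fitting, not to angle curves, and
refuses series with gaps — gaps may only be repaired by the explicit
cubic-interpolation operation, which fills interior gaps of at most 10 frames
(configurable) and never touches gaps at the trial ends.

Foot strikes are detected as local maxima of the heel position along the
progression axis relative to the pelvis origin (coordinate-based detection);
manually supplied events always take precedence, mirroring studies that
select cycles by inspection. A cycle runs foot strike → ipsilateral foot
strike and is linearly resampled onto 101 points with endpoints preserved
exactly.

## Variability statistics

Sample SDs use the n−1 denominator throughout (trial counts as small as 3
are typical). AIT averages each subject's intertrial SD curve over the 101
samples first, then over subjects; with equal trial counts per subject the
opposite order is identical. AIP is the SD across subjects' mean curves,
cycle-averaged. MAV is the cycle-mean absolute difference between the two
protocols' curves per subject, then subject-averaged; it is symmetric and
zero iff the curves coincide. Study-level ROM is the mean of per-cycle ROMs.

## Synthetic test bed

The generator drives an articulated right lower limb by forward kinematics
through *exactly the same* Cardan convention and sign table the analysis
uses, emitting cluster markers, skin/wand markers and true landmarks. Its
defaults are the package's reference study design: 4 subjects × 3 trials,
100 Hz, 1.1 s stride, injected intertrial SD 1.0° and between-subject SD
3.0°, clean markers (noise, soft-tissue artefact and wand misalignment are
explicit dials set to zero).

* **Templates.** The 12 rotation templates are truncated cosine series in
  cycle phase with documented coefficients (knee flexion spanning exactly
  0–60°, tibial rotation covarying internally with flexion, small
  out-of-sagittal excursions). They are fixtures shaped on normative gait,
  not claims about any cohort; as pure cosine series every rotation has zero
  time-derivative at cycle boundaries, which pins the heel's forward-position
  maximum exactly to the prescribed foot strikes regardless of the injected
  constant offsets — clean ground truth for the event detector.
* **Injected variation.** Subject and trial effects are constant
  per-rotation offsets *standardised to exact sample SD* (trial offsets of
  each subject sum to zero with sample SD precisely σ; subject offsets have
  sample SD precisely τ). The injected dispersion therefore equals the
  realised dispersion, so AIT recovers σ without the c4 small-sample bias of
  the mean-of-sample-SDs estimator, and AIP approaches √(τ² + σ²/m) with m
  trials per subject mean (the σ²/m term vanishes under the sum-zero
  convention, leaving τ — within 2% of the target for the default design).
  The i.i.d.-Gaussian behaviour, including the c4 bias itself, is covered by
  dedicated statistical tests.
* **Artefacts.** Measurement noise is i.i.d. isotropic Gaussian per marker
  sample. Soft-tissue artefact is a deterministic cycle-locked sinusoidal
  displacement of all markers of a segment along a fixed segment-specific
  direction — controllable, not physiological. Wand cross-talk rotates the
  thigh wand off the frontal plane about the femur long axis.
* **Geometry.** One idealised skeleton (segment frames aligned in neutral,
  symmetric landmarks, point markers of zero radius, femur attached at the
  Davis-predicted HJC) is shared by all subjects; subjects differ only in
  their angle offsets. This makes the analysis model's assumptions hold
  exactly, which is what gives the test bed its central identifiability
  property: with zero noise the complete cluster pipeline reproduces the
  prescribed angles to ~1e−9°.

**What passing tests show — and don't.** Exact end-to-end recovery
demonstrates the pipeline's internal consistency (pose estimation,
calibration, frames, decomposition, normalisation introduce no systematic
error), and the artefact dials demonstrate qualitative error propagation
(e.g. a 15° wand misalignment more than doubles the conventional model's
knee axial ROM while the cluster protocol stays at the true value). None of
this validates either protocol against real soft tissue, real anatomical
variation or real landmark-palpation error, whose structure the generator
does not attempt to model.

## Problem sizes and numerics

Default analyses run at 100 Hz with single-stride trials; exact-recovery
checks use one subject/one trial and compare pipeline output with the stored
ground-truth curve after identical 101-point normalisation, so discretisation
cancels. Statistic-recovery estimates use 500 replicate 4 × 3 studies at the
angle-curve level (the statistics operate on curves; the marker layer adds
nothing there). Tolerances: pose orthonormality 1e−9; Procrustes exactness
1e−10 on noise-free data; Cardan round trip 1e−10; end-to-end recovery 1e−6°;
C3D round trips are float32-limited (~1e−4 mm at metre-scale coordinates).
All randomness flows from explicit integer seeds recorded in every study
manifest.

## Known limitations

Right limb only (left-side support would mirror the sign table); no joint
translations or helical-axis output; no force-plate/analog channels; the C3D
codec writes only the subset it reads (Intel, float, POINT group); the
event detector assumes overground progression along a straight line;
intersession and inter-assessor designs are out of scope for the statistics
module.
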