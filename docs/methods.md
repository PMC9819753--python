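# Methods

## Model and assumptions

Both segments are treated as rigid bodies whose poses in a laboratory
frame are available as uniformly sampled time series of homogeneous
matrices (a pose maps body coordinates to reference coordinates; the
relative pose of tibia w.r.t. femur is therefore (T⁰fm)⁻¹ T⁰tb — the pose
convention is not intrinsic to the method but fixes the reading of all
formulas, and is stated here because upstream sources often leave it
implicit). The knee is assumed hinge-dominant over the analysed cycle:
the angular-velocity second-moment matrix must have a strictly dominant
eigenvalue, otherwise the functional axis is undefined and the pipeline
raises an ambiguous-axis error rather than guessing.

The method needs no anatomical calibration. Its defining property is
invariance: replacing either segment's body-fixed coordinate system by any
constant rigid re-definition (right-multiplication of that segment's pose
trajectory) leaves the invariant angle curves unchanged in exact
arithmetic, because every ingredient (twists, second-moment eigenvectors,
screw-axis pseudo-intersection) transforms equivariantly and the final
relative pose between the two ASA frames cancels the re-definitions.

## Pipeline and numerical choices

* **Differentiation.** Entry-wise finite differences on the 16 matrix
  entries: central differences (second order) at interior samples,
  3-point one-sided stencils at the endpoints. No smoothing by default; a
  quadratic Savitzky–Golay smoother is available behind
  `smooth_window` for noisy inputs and is off in every shipped test.
* **Twist extraction.** ω is read from the antisymmetric projection of the
  3×3 block of Ṫ T⁻¹ (femur frame) / T⁻¹ Ṫ (tibia frame); the raw block is
  skew only up to an O(dt²) symmetric differencing error. The linear
  velocities are then assembled from ṗ and the projected ω
  (v_fm = ṗ − ω×p, v_tb = Rᵀṗ) rather than read off the raw translation
  column. The raw column contains −W_raw·p, which re-injects the symmetric
  error that the projection removed; with the consistent form the ASA
  frames are equivariant under body-frame re-definitions to ~1e-14,
  at the cost of the hinge-origin recovery being limited by the O(dt²)
  error in ṗ (~5·10⁻⁵ m at 101 samples/cycle — far below marker noise).
  Full adjoint equivariance of the *linear* twist component under
  right-multiplications of the relative pose is likewise discretisation-
  limited; the angular component, and everything the angles depend on, is
  exact to round-off.
* **Second-moment matrix.** C = (1/N) Σ ωωᵀ, deliberately uncentred: for
  an oscillating joint the mean ω is near zero, and the uncentred moment
  captures the direction the rotation rate lives along regardless of sign.
* **Eigenvector sign conventions.** Any convention must be a function of
  frame-invariant statistics or the invariance property dies at the sign
  level. e1: sign of Σωᵢ·e1 (net rotation); when the net rotation is below
  1% of Σ|ωᵢ·e1| — the normal case for a joint that flexes and returns —
  the sign of the integrated excursion Σ cumsum(ω·e1) is used instead, so
  a knee that spends the cycle flexed towards +e1 gets a positive flexion
  axis. (A cubic-sum fallback Σ(ω·e1)³ is kept as a final tie-break, but it
  vanishes identically for time-symmetric profiles and cannot serve as the
  primary fallback.) e2: sign of Σ(ω·e2)³, falling back to the sample of
  maximum |ω·e2|. e2 is re-orthogonalised against e1 after the eigensolve.
* **ISA points and pseudo-intersection.** qᵢ = (ωᵢ×vᵢ)/|ωᵢ|² diverges as
  |ω|→0, so samples below 10% (configurable `omega_floor`) of the peak
  angular speed are excluded from the pseudo-intersection (not from C).
  The pseudo-intersection solves Σ wᵢ(I − uᵢuᵢᵀ) S = Σ wᵢ(I − uᵢuᵢᵀ) qᵢ
  with weights wᵢ = |ωᵢ|², cancelling the 1/|ω|² noise amplification in
  qᵢ. For near-parallel axes the normal matrix drops to rank 2; the
  pseudo-inverse (relative singular-value cutoff 1e-8) then returns the
  minimum-norm point and a rank-deficiency diagnostic. For a perfect hinge
  any point on the axis is optimal and only the axis direction — never the
  position along it — enters the angles.
* **Euler angles.** Intrinsic XYZ for the invariant curves (angle about
  the functional x-axis = flexion), intrinsic ZYX for the anatomical
  reference curves, both in degrees, unwrapped so consecutive samples
  never jump by ±360°. Within 0.5° of the middle-angle singularity a
  warning is emitted and the third angle is set to zero with the full
  rotation assigned to the first (deterministic and testable, but such
  poses do not occur in knee kinematics).
* **Offset removal.** ASA frames carry no anatomical zero, so each curve
  is shifted to start at exactly 0°. All reported RMS differences and
  ranges of motion are computed on offset-removed curves.
* **Invariance experiment.** Two distinct random rigid transforms
  (rotations uniform on SO(3) via normalised Gaussian quaternions,
  translations uniform in ±0.5 m per axis, seeded) right-multiply the two
  pose trajectories — a constant re-definition of each body-fixed frame,
  which is what "losing the anatomical reference" means physically. A
  `world_frame` mode that left-multiplies instead is provided for
  completeness: with distinct transforms it changes the relative motion
  itself and is *not* an anatomical re-definition, so its (large) RMS
  difference is reported, never asserted. The distribution of the random
  transforms is immaterial: invariance holds for every draw.

## Synthetic gait generator

The generator emulates the statistical structure the method assumes, with
defaults chosen to be a realistic single gait cycle:

| parameter | default | why |
|---|---|---|
| n_samples | 101 | one cycle at 0–100% in 1% steps |
| cycle_duration | 1.0 s | typical gait cycle |
| flexion_amplitude | 56.2° | typical peak knee flexion RoM in gait |
| flexion_profile | gait_double_hump | stance wave (~18% amplitude near 15% cycle) + swing peak (near 70%) |
| out_of_plane_amplitude | 2.0° | small ab/adduction and internal-rotation sinusoids (1× and 2× cycle frequency) |
| axis | +z through (0.03, 0.02, 0) m | knee axis ~ z of the femur frame, slightly offset from the origin |
| tibia_offset | (0, −0.40, 0) m | shank length below the knee |
| femur world motion | 1.2 m progression, 10° rotation sinusoids | both segments move in the lab |
| marker clusters | 4 markers, ~15 cm spread | clinical marker-plate scale; cluster size sets how marker noise maps to orientation noise |

All randomness flows through one explicit seeded generator. What the
generator does **not** model: tibiofemoral translation/rollback (the
relative motion is a pure rotation about a fixed axis plus out-of-plane
rotations), soft-tissue artifact (marker noise is isotropic and
uncorrelated), gait-event detection, and multi-cycle variability. Passing
tests therefore demonstrate the geometric/algorithmic properties of the
method — invariance, hinge recovery, pipeline agreement — not its clinical
accuracy on skin-marker data.

## Problem sizes and determinism

All shipped tests and the acceptance script run on 101-sample single-cycle
trials (the natural resolution of normalised gait data); the whole suite
completes in a few seconds. Every stochastic element (marker noise, random
frame re-definitions) is seeded; the acceptance script derives all
randomness from its `--seed` argument.

## Known limitations

* Variable sampling rates are not supported: resample first
  (`resample_trajectory` interpolates orientations on the rotation
  manifold and positions linearly).
* The ASA origin's position *along* the functional axis is weakly
  determined for near-perfect hinges (minimum-norm convention) and
  discretisation-limited in general; it does not affect any angle.
* Offset removal zeroes the first sample, so a trial that starts away from
  the reference posture biases all curves by that initial angle; a
  standing-calibration correction protocol is intentionally out of scope.
* No C3D reader; convert to TRC, wide marker CSV or the pose-CSV dialect.
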