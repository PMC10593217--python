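# Methods

## Measurement model

A movement is defined by a body segment: two endpoints, each either a
single landmark or the midpoint of two (e.g., the neck segment runs from
the midpoint of the two shoulders to the nose in the pose dialect, or to
the mid-forehead point in the mocap dialect). With endpoint positions
P₁, P₂ at frame *t*, the segment's unit vector is v⃗_t = (P₁ − P₂)/‖P₁ −
P₂‖ and the movement angle is the angle between v⃗_t and the
starting-frame vector v⃗₀:

    α_t = arccos(v⃗_t · v⃗₀) ∈ [0°, 180°],  α₀ = 0 by construction.

The ROM is the maximum α_t over non-anomalous frames. These are
segment-excursion angles, not clinical neutral-zero goniometry angles:
the zero reference is the subject's own starting posture of that trial.
Because only dot products of unit vectors enter, the measure is exactly
invariant to translation, rotation, and positive scaling of the capture
coordinates — the pose dialect's unitless "world coordinates" and the
mocap dialect's meters never need reconciling, and the two devices'
frames are never aligned.

Assumptions this model makes: the movement is a single slow deliberate
excursion away from the starting posture and back; the relevant segment
is rigid between its two endpoints; the starting frame is representative
(see Limitations).

## Movement registry

Eleven standing movements are built in, covering spine, neck, shoulder,
elbow and hip; the five bilateral rows expand to left/right variants, 16
sided specifications in all. Each row stores the recording orientation
(lateral-sagittal or anterior-coronal — metadata used by the simulator
and for documentation; the 3D angle math is orientation-agnostic) and the
endpoint pair per device dialect. Distal joints (wrist, ankle) are
excluded: single-camera pose estimation does not track hands and feet
reliably enough. Users can extend the registry from YAML without code
changes.

One registry row stores a composite "Flexion and Extension" movement as a
single spec; splitting an excursion into flexion versus extension phases
is the caller's labeling concern. The neck lateral-bending row is stored
exactly as specified (mid-shoulder vs head point under a lateral-sagittal
orientation) without resolving whether bending is observed laterally or
frontally — the angle definition is the same either way.

## Preprocessing

Pose-dialect samples carry a per-frame visibility index in [0, 1];
samples below the threshold (default **0.5**) are removed, without
interpolation. When a removed landmark is required by the movement's
segment, that frame is dropped from the angle series (per-frame
exclusion; the alternative of dropping only the landmark is moot, since
the segment needs both endpoints). A trial whose usable frames fall
below two is flagged unusable rather than raising. No smoothing is
applied anywhere: ROM extraction needs a single trajectory point, and
filtering a slow low-frequency movement risks attenuating exactly the
apex it needs.

## Anomaly masking

Tracking glitches can masquerade as the maximum angle. The angle series
is decomposed additively,

    α = trend + seasonal + residual,

with the trend a centered moving average (window = one nominal second of
frames by default, i.e. `period = round(fps)`; even windows use the
classical half-weight kernel) whose edges are extended with the nearest
interior value, and the seasonal component the per-phase mean of the
detrended series, re-centered to zero. Phase means use only interior
frames where the moving average is exact; edge-extended frames would
leak trend into the seasonal term. The three components reconstruct α
exactly on every frame. Series shorter than two periods skip the
seasonal term (residual = α − trend) with a logged warning.

Frames with |residual − mean| > `sd_multiplier` × SD (default **3**,
computed per trial) are masked. The trend is never used as the angle
estimate — decomposition can distort the apex — it only feeds the
residual; the maximum is taken over the original angles with masked
frames removed.

If two or more local maxima lie within 5% of the global maximum and are
separated by a trough deeper than 10% of it, the trial is flagged
`multi_peak` for review. This flag is an artifact policy standing in for
a human operator's visual inspection of ambiguous trials, not a
measurement rule; both thresholds are configurable.

## Reliability layer

The measurement matrix is subjects × repeated measurements: the trials
of one device (intra-device/test-retest mode) or the two devices'
per-subject measurements (inter-device mode). Complete cases only;
dropped subjects are counted and reported. From the two-way ANOVA mean
squares (MSR between subjects, MSE residual, n subjects, k
measurements), the consistency-form ICC is

    ICC(3,1) = (MSR − MSE) / (MSR + (k−1) MSE)      single measurement
    ICC(3,k) = (MSR − MSE) / MSR                     average of k

with F-based confidence intervals (F = MSR/MSE on (n−1, (n−1)(k−1))
degrees of freedom, transformed to the chosen form). The average-of-k
form is the default since the protocol scores multiple measurements;
both forms are selectable. Zero between-subject variance is degenerate
and reported as ICC 0 with a flag; ICC is clipped at 1 against float
drift when MSE ≈ 0.

    SEM = √(σ_T² (1 − ICC)),   σ_T² = population variance of all cells
    MDC = z₉₅% √2 SEM,          z₉₅% = 1.959964  ⇒  MDC = 2.771808 SEM

Interpretation bands are half-open upward — [0, 0.2) slight, [0.2, 0.4)
fair, [0.4, 0.6) moderate, [0.6, 0.8) substantial, [0.8, 1] almost
perfect — boundary values go to the upper band; negative ICCs read
slight.

Inter-device pairing defaults to averaging trials within device before
pairing (k = 2 columns); trial-index pairing (k = 2 × n_trials columns)
is available since protocols differ on which convention they intend.
The device regression is ordinary least squares of webcam ROM on mocap
ROM over per-subject device means (mocap as predictor); a flat response
returns slope 0, r² 0.

## Synthetic data

The simulator is the package's study-condition generator, not a test
fixture. A trial rotates the movement's distal endpoint about a fixed
axis from 0° up to the trial's true ROM and back, with a minimum-jerk
angular profile by default (smooth, single-excursion, zero velocity and
acceleration at the ends — the kinematic signature of a slow deliberate
movement; sinusoidal optional). Defaults: duration 6 s, 15 FPS for the
pose dialect and 120 FPS for mocap, segment length 0.4 m. The frame
grid always contains the apex time, so a noiseless trial's sampled
maximum equals the true ROM exactly. Midpoint endpoints emit their two
constituent markers symmetrically about the endpoint, so the midpoint is
exact; all remaining landmarks of the dialect are emitted as static
filler at fixed plausible positions, making files schema-complete.

Degradations: isotropic Gaussian landmark noise (σ in meters, applied to
every landmark); Bernoulli per-frame spike outliers displacing the
moving endpoint by a fixed magnitude in a random direction (injected in
landmark space so the residual detector is exercised end to end; frame 0
is exempt — corrupting the reference frame biases every angle and is a
distinct failure mode no residual rule can see); Bernoulli low-visibility
dropouts (pose dialect only) assigning a visibility below the 0.5 cut to
one required landmark.

A study draws subject i's true ROM ~ N(μ, σ_between²) and trial j's
realization ~ N(subject ROM, σ_within²), shared across devices since
both record the same physical performance; defaults 25 subjects × 3
trials. The pose dialect's apex can be clipped at a ceiling (emulating
reduced sensitivity to joint location at the movement apex, which
degrades inter-device correlation); the mocap dialect can receive a bias
and extra noise. The ground-truth table records every latent value.
All randomness flows through numpy's PCG64 `default_rng`; a fixed seed
reproduces trials byte for byte.

What the simulator does **not** emulate: whole-body kinematics (filler
landmarks are static), soft-tissue and suit-tension marker artifacts,
occlusion structure correlated with posture, pose-estimator biases that
depend on clothing contrast or lighting, or non-Gaussian heavy-tailed
landmark error. Passing tests therefore demonstrate that the pipeline's
algebra, cleaning and statistics behave as specified under controlled
degradations — not that a particular webcam setup achieves any given
SEM in the field.

## Numerical choices

- α is evaluated as atan2(‖v⃗_t × v⃗₀‖, v⃗_t · v⃗₀): identical to
  arccos of the clamped dot product but numerically stable near 0° and
  180°, where plain arccos loses half the available precision. The dot
  product is still clamped to [−1, 1].
- Coincident endpoints at a frame (degenerate segment) drop the frame
  with a warning rather than raising.
- The reference vector v⃗₀ is the first retained frame by default;
  `mean_first_n` (renormalized mean of the first 5 frames) is available
  because a noisy first frame biases every subsequent angle.
- Nominal fps is stored from metadata, not re-estimated from timestamps;
  only the decomposition assumes uniform spacing, at that nominal rate.
- Residual mean/SD are per trial (not pooled across trials); zero
  residual variance yields an empty mask.
- ICC confidence intervals use the F-based construction throughout.

## Problem sizes

The test suite runs the ICC parameter-recovery experiment at 200
replicates of 25 subjects × 3 trials through the full trajectory →
angle → ROM pipeline (~2.5 minutes), noisy ROM recovery at 100 trials
per movement, and spike robustness at 40 trials. The acceptance script
covers the same experiments at 60 replicates, 25 trials per movement,
and 40 trials respectively, keeping a full run near one minute.

## Limitations

- The 3-SD residual rule uses a non-robust scale estimate: several
  simultaneous large spikes inflate the SD and can let a moderate spike
  through. Spikes directed along the segment axis (or far out of the
  movement plane) barely change the angle and are invisible to any
  angle-residual detector — by the same token they barely change the
  ROM.
- A glitch on the reference frame corrupts v⃗₀ and biases the whole
  series; no within-trial residual test can detect it. The
  `mean_first_n` reference dampens but does not eliminate this.
- ROM is a maximum statistic, so landmark noise biases it upward (noise
  can only raise a maximum); at 5 mm noise on a 40 cm segment the median
  absolute error is near 1.5° with a positive mean error of similar
  size.
- The ANOVA ICC(3,1) estimator carries a small downward bias at n = 25
  (recovered means ≈ 0.906 against a theoretical 0.917 in the simulated
  design); the F-based CI covers the truth at roughly its nominal rate.
- The multi-peak flag replaces human review with a fixed 5%/10% rule;
  trials it flags still report the global maximum.
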