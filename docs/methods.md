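# Methods

This note documents the models, conventions and parameter choices behind
`imuheat`, and what the synthetic experiments do and do not demonstrate.

## Sensor model and calibration

Six sensors sit at the left/right wrist, left/right knee, head and lower back;
the lower-back (pelvis) sensor is the body root. The global frame is
right-handed, z-up; positions are meters; gravity is fixed at
g = (0, 0, −9.81) m/s². Vectors are columns and rotations act by left
multiplication; `R_imu` maps sensor frame → global frame.

Calibration follows the standard two-rotation scheme: `R_calib` aligns the
global frame to the calibration pose, `R_bone` accounts for how the sensor
case sits on the limb. Both are accepted as inputs; the synthetic convention
(`calibration_from_pose`) sets `R_calib = R_imu(calibration)⁻¹` and
`R_bone = I`. `R_root⁻¹` is computed as the transpose, with orthonormality
(to 1e-8) and det = +1 validated on entry; all rotation outputs are exact
products of validated rotations, so they remain proper rotations to the same
tolerance. Gravity is treated as constant over a recording — the calibrated
acceleration would otherwise need a per-frame gravity estimate the sensor
model does not provide. With calibration derived from a measured pose, the
whole chain is equivariant under a global frame change (rotating every
`R_imu` and `g` by the same `Q` leaves the normalized signal unchanged);
this is asserted by a property test.

The synthetic IMU reports `a_imu = R_imuᵀ (a_lin + g)` — the sensor-frame
acceleration with gravity added back — so that the calibration equations
recover the kinematic acceleration exactly and a stationary sensor with
identity orientation reads `g`. Linear acceleration is the second central
finite difference of position (endpoints copied from neighbors). Two
orientation models exist: `identity` and `velocity-tangent` (an orthonormal
frame whose first axis follows the velocity direction, falling back to the
previous frame when nearly stationary).

## Dead reckoning as a drift diagnostic

Double integration uses the semi-implicit update
`v_{t+Δt} = v_t + Δt·a_{t+Δt}`, `x_{t+Δt} = x_t + Δt·v_{t+Δt}`, with the
acceleration evaluated at the end of each step. Under a constant bias `b` the
closed form is `x_N = b Δt² N(N+1)/2`: velocity error grows linearly and
position error quadratically in elapsed time (log-log slope 2, verified to
±0.05). This is why the pipeline classifies trajectory *shapes* obtained from
pose rather than integrated sensor positions. The exact inverse of this
recurrence is the second central difference, which is why the round trip
trajectory → synthetic IMU → calibrated acceleration → dead reckoning
recovers a noiseless trajectory to machine precision when the initial
velocity is pinned from the first two positions (`v_0 = (x_1 − x_0)/Δt −
Δt·a_0`); with a generic initial velocity the error is bounded by
O(Δt²)·duration².

## Synthetic cohorts

The generator replaces an external full-body pose-estimation stage (a
pre-trained recurrent pose network over a licensed parametric body mesh,
neither of which can ship here) and produces what that stage would output:
per-vertex 3D trajectories. Thirteen activity archetypes map onto five
parametric motion families:

| family | canonical path | activities |
|---|---|---|
| planar-circle | ellipse, `(A cosθ, aspect·A sinθ)` | arm circles (aspect 1), chest/head crossings (0.25), lunges (0.5) |
| linear-oscillation | `A sinθ` along an axis | arm raises, stretches, leg raises |
| vertical-dip | one-sided `−A(1−cosθ)/2` | squats, sumo squats |
| lateral-zigzag | triangle sweep + double-rate bounce | side stepping (aspect 0.25), cross stepping (0.8) |
| composite-antiphase | ellipses with left/right limbs half a period out of phase | jumping jacks (0.9), walking (0.3) |

Each class also carries per-vertex participation weights (which body points
move, and how much) and a motion-plane rotation. After per-window PCA and
bounding-box rasterization the absolute amplitude, plane orientation and
pace are deliberately invisible; classes are separated by the *shape* of each
channel's trace (line / circle / flat arc / zigzag / noise blob for inactive
vertices) and by *which* channels are active — e.g. squats and sumo squats
share the dip but differ in wrist participation, and the two stepping
variants differ in zigzag aspect. Amplitudes are 0.25–0.35 m and frequencies
0.5–1.0 Hz, typical of calisthenic exercise.

Subject heterogeneity is a per-subject lognormal amplitude scale
(σ = 0.15 by default) plus a uniform phase offset, seeded by
(cohort seed, subject index); positional noise is iid Gaussian with
σ = 5 mm by default. Everything is drawn from named `numpy` generator
streams, so a cohort is a pure function of its config.

What this does *not* emulate: pose-estimator error structure (temporally
correlated, activity-dependent), soft-tissue and mounting artifacts, joint
limits, within-recording pace drift, or activities that differ only in
direction/speed (invisible to heatmaps by construction). A classifier score
on this cohort is a pipeline health check — the classes are separable by
design — not a forecast of accuracy on real recordings.

## Windows, PCA and heatmaps

Windows are 150 frames (2.5 s at 60 Hz) for the image path and 300 frames
(5 s) for raw-signal models, stride = window (no overlap). PCA is fit per
window *and per vertex* — each body part's motion gets its own maximal-spread
plane — with a shared-per-window basis available behind a flag. The
projection uses the SVD of the centered cloud; explained variances are the
sample-covariance eigenvalues (ddof = 1). Sign ambiguity is removed by
flipping each axis so its largest-magnitude loading is positive (ties to the
first coordinate), making outputs bit-reproducible. Windows of identical
points are flagged degenerate and rasterize to a single center pixel rather
than being dropped — stationary segments are legitimate data.

Rasterization maps the window's padded bounding box (5% padding by default)
onto the grid with one isotropic, centered scale — shapes are preserved and
the image is invariant to uniform scaling of the input. In the default
`segments` mode, each straight segment between consecutive samples increments
every pixel whose unit square it touches (a supercover count); in `points`
mode each sample increments its containing pixel, so the grid sum equals the
sample count. Point binning is half-open, `[r, r+1) × [c, c+1)`, with the
maximum coordinate clipped into the last pixel; segment coverage tests the
*closed* unit square, the standard supercover convention, which is what an
exact geometric intersection predicate (the test oracle) computes. The float
slab test resolves borderline corner grazes — structurally common, because
window extremes map onto pixel-boundary lattice points — with exact rational
arithmetic, so counts are stable and match the oracle pixel-for-pixel.
Counts are normalized by the grid maximum (all-zero grids pass through).

An image sample stacks 4 consecutive sub-windows × one channel per vertex:
`4 × 6 × 64 × 64` at the default raster, requiring 600-frame segments.

## Augmentation

Training sets are enlarged with horizontal/vertical flips and rotations
restricted to multiples of 90° — exact permutations of count grids, no
interpolation — applied identically to every sub-window and channel.
Augmented copies are generated per training fold from a seeded policy and
never enter validation or test folds (asserted on provenance flags). Flips
are label-safe for the synthetic archetypes because no pair of classes
differs only by mirror image; for direction-sensitive real activities the
policy should be restricted per class.

## Classifiers

Three architectures, all trained with Adam on the categorical cross-entropy
`L = −log(exp(s_p)/Σ_j exp(s_j))` (evaluated via log-sum-exp):

* **lstm_raw** — two stacked LSTM layers over the 300 × 60 feature sequence
  (5 non-root sensors × (3 accel + 9 rotation) root-normalized features),
  then a dense interpretation layer and softmax.
* **convlstm_1d** — the convolutional-recurrent topology with 1-D kernels
  sliding over the 60-feature axis; the 300-frame window is cut into 4
  sub-windows whose frames act as channels.
* **convlstm_image** — two ConvLSTM layers (16 filters of 5×5, then 32 of
  3×3, 'same' padding), each followed by spatial-only 2×2 max-pooling, then
  time-distributed flatten + dense (100 units, ReLU) and a softmax head over
  the concatenated per-step features. State is not carried across samples;
  the sequence axis is the sub-window axis.

No deep-learning framework is a dependency: the layers run on a small
reverse-mode autodiff engine (`_nn.py`, float64, im2col convolutions,
deterministic max-pool tie-breaks) whose gradients are checked against
central finite differences for all three architectures in the test suite.

Hyperparameters the architecture description leaves open are fixed at
conventional values and are config-overridable: LSTM widths (100, 100),
dense width 100, Glorot-uniform init (forget-gate bias 1), learning rate
1e-3, batch size 32, max 100 epochs, early-stopping patience 10 with
best-weight restoration. Validation for early stopping is one held-out
training subject per fold (seeded choice; with only one training subject, a
within-subject 80/20 split). Prediction is the probability argmax with ties
broken toward the lowest class index. Given the config seed, training is
bit-deterministic (single-threaded numpy, seeded shuffles and init).

## Evaluation protocol

Leave-one-person-out over sorted subject IDs: one fold per subject, test
subjects partition the roster. The summary is the arithmetic mean of fold
accuracies ± 1.96·SD(folds)/√n_folds (a 95% normal-approximation interval;
the formula is stated in the report header since "±" conventions vary).
The unit of evaluation is the window sample. Confusion matrices are
row-normalized over ground truth; empty rows stay zero and are identifiable
from the raw-count matrix stored alongside. The subject-count sweep redraws
random subject subsets without replacement (3 repetitions per size, seeded)
and collapses to plain LOPO at the full roster.

## Problem sizes of the shipped experiments

The end-to-end experiment (tests and `scripts/acceptance.py`) uses a
6-subject × 13-class cohort at 60 Hz with 20 s per recording (two 600-frame
segments each, 156 samples), a 16 × 16 raster, and training settings
lr = 2e-3, batch 16, ≤10 epochs, patience 3 with min-delta 1e-3 — sizes
chosen so the full double LOPO run (plain + augmented) completes in minutes
on a single CPU while leaving the architecture untouched. The raster default
elsewhere remains 64 × 64. The acceptance threshold (mean LOPO accuracy
≥ 0.9, augmentation shift within ±0.05) is a repository-level health bar for
the synthetic conditions, not a reproduction of any published accuracy.

## Known limitations

* Heatmaps discard direction and speed; activities distinguished only by
  those attributes are out of reach by construction.
* The per-window bounding-box normalization discards absolute amplitude; an
  activity pair differing only in range of motion would collapse.
* The 1-D ConvLSTM's sub-window/channel layout is one of several defensible
  readings of a "1-D kernels over features" architecture.
* The autodiff engine is built for clarity and determinism, not speed; very
  large rasters or cohorts are better served by a GPU framework.
* Synthetic separability means reported accuracies bound pipeline
  correctness, not real-world performance.
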