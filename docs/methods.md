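# Methods

This note records the model underlying `hybridarm`, the choices made where
the design was genuinely open, and what the simulator does and does not
show about real prosthesis use.

## Kinematic arm model

The arm is a seven-revolute-joint chain — three intersecting shoulder axes
(Sfe, Saa, Hr), one elbow axis (Efe), one forearm axis (Fps) and two
intersecting wrist axes (Wru, Wfe) — with three rigid segments (upper arm
0.31 m, forearm 0.27 m, hand 0.10 m by default; all configurable).  The
frame sits at the shoulder, trunk-aligned: +x rightward, +y upward, +z
forward; the zero posture is the arm hanging along −y.  Successive joint
axes are twisted by ±90°, equivalent to a standard anthropomorphic
Denavit–Hartenberg chain; the exact table is in `kinematics.CHAIN` and is
pinned by a test against an independently composed transform chain
(scipy rotations) to 10⁻⁹ m.  Sign conventions are chosen so that
flexion moves the limb forward and abduction laterally for a right arm.

The hand is summarised by its grasp point (the distal end of the hand
segment) and its *grasp axis*, the axis of a cylindrical object held in
the hand, taken as the hand segment's distal direction.  The axis
orientation is reported as two projection angles — α in the frontal (x–y)
plane and β in the sagittal (y–z) plane, both zero for a vertical,
downward axis, signed in (−180°, 180°].  Spin about the grasp axis is
deliberately unconstrained throughout (validation zones and the offline
orientation metric both compare axes, not full rotations), matching the
cylindrical objects of the task.  The projection-angle parameterisation is
singular only for exactly horizontal axes pointing sideways, which the
task geometry does not produce.

Full elbow extension is a classic singular arm posture; it is avoided at
the data-generation level (the elbow interval is shrunk to 85% of its span
when sampling target postures), not in the kinematics, which is
singularity-free.

## Synthetic movement data

Real deployments train the goal networks on recorded natural
pick-and-place movements.  The simulator emulates such a database:

* **Waypoint postures.** Proximal joints are drawn uniformly over the
  user's shoulder range of motion.  Distal joints are drawn uniformly
  over *functional* ranges (humeral rotation ±30°, elbow 30–130°,
  pronosupination ±50°, wrist deviation −10..15°, wrist flexion ±20°),
  following the upper-limb functional-ROM literature: natural reaching
  exercises nowhere near the anatomical extremes of every joint at once,
  and the inter-joint consistency of natural movements is what makes the
  inverse mapping learnable at all.
* **Movements.** Joint-space minimum-jerk profiles
  (10τ³ − 15τ⁴ + 6τ⁵) between consecutive waypoints, sampled at 90 Hz,
  durations uniform in 0.9–1.3 s (≈100 frames per movement).  Successive
  movements chain start-to-end, mimicking pick-then-place alternation.
* **Participants.** Twelve synthetic participants, each with joint limits
  independently jittered by up to 5% of the joint span, each contributing
  42 movements: ≈500 movements, ≈50,000 frames.

Each frame becomes a training sample by *morphology retargeting*: the
frame's seven angles are applied to an arm with the target user's segment
lengths, and the pose of a hypothetical object in that hand
(x, y, z, α, β) is recorded as the context.  Context/posture consistency
is therefore exact by construction, and a test asserts it.

What this generator does **not** emulate: measurement noise and marker
artifacts, individual kinematic idiosyncrasies and true human synergy
structure, grasp aperture, movement segmentation ambiguity, and dynamics
(no torques, no muscles).  Passing tests therefore show that the control
pipeline behaves correctly on clean, kinematically consistent natural-like
data — not that the networks would reach the same accuracy on motion
capture of real humans.

Two target-set constructions are provided: *plausible* targets are poses
of postures drawn uniformly inside a range of motion (elbow shrunk to
85%), and *possible* targets are poses of configurations actually visited
by a trajectory pool.  For a trans-humeral user, whose distal joints
cannot be measured, the evaluation range of motion combines the user's
shoulder limits with the 5–95% quantiles of the database's distal
excursions (`rom_from_database`).

## Goal-prediction networks

All three variants share one architecture: dense 256 → 256 → dropout 0.5
→ 64 → linear output, rectified-linear hidden units (the activation is
not printed in the original description; ReLU is the contemporary
default).  Training is plain SGD with momentum, 10 epochs, batch 128:
PC− uses lr 1.59×10⁻⁷ with momentum 0.95; PC+ and C+ use lr 10⁻⁴ with
momentum 0.  Weights are He-normal initialised from the run's seed;
shuffling and dropout masks derive from the same seed, so training is
bit-reproducible.

Two numerical conventions had to be fixed because they are not printed:

* **Input/output scaling.** Inputs are z-scored with statistics fitted on
  the training set.  Outputs are fitted on the z-scored scale as well and
  mapped back to degrees at prediction time; the statistics live in the
  saved predictor.
* **Loss reduction.** The loss is the squared error *summed* over each
  mini-batch.  Under this convention the printed learning rates fall in
  the classical stable regime for SGD (an averaged loss on raw-degree
  outputs would leave lr = 10⁻⁴ far too small to converge in 10 epochs,
  and the ≈640 ≈ batch×outputs ratio between the two printed learning
  rates is itself consistent with a summed reduction in the original
  training code).

PC−'s minuscule learning rate is reproduced verbatim for fidelity — it
yields a weak predictor, which is historically accurate for the variant's
role as the comparison control; `NetworkSpec.for_variant("pc-",
learning_rate=...)` allows an explicitly recorded practical override for
demonstrations.  Predictions are saturated to the per-joint range of
motion before use, as a physical prosthesis would enforce.

No early stopping and no train/validation split are used (10 fixed
epochs).  Predictors serialise to a single JSON file (spec, normalisation,
weights).

## Interpolation controller

The controller state holds the previous distal command, the previous hand
position, the previous timestamp, a per-joint latch flag and the current
target identity.  Per tick: the gap to the saturated prediction is
computed; the hand speed is estimated from *locked* positions (distal
joints frozen at their previous values) so that only user-driven proximal
motion contributes — this kills the spurious feedback loop in which the
controller's own output would accelerate its convergence; each unlatched
joint advances by gap × s/R (s = tick displacement of the locked hand,
R = remaining hand-target distance).  The timestamp-robust displacement
form is the canonical implementation; the frequency form
gap/(M̂T·Freq) is provided and tested equivalent when the tick interval
equals 1/Freq.

Open points resolved here, each with its rationale:

* **Zero speed.** When the locked hand does not move the joints hold
  still: the update is zero in the displacement form, and it keeps the
  user in command.
* **Overshoot.** s/R can exceed 1 when the hand is at (or past) the
  target; the fraction is clipped to [0, 1] so a joint lands on its goal
  and never oscillates around it.
* **Latching is per joint** (each joint compares its own gap to the 1°
  threshold) and a latched joint *tracks* the prediction continuously —
  under PC+ the prediction keeps adjusting to proximal motion, and
  snapping it only at target changes would reintroduce a discontinuity.
* **Remaining distance** is evaluated at the hand position current when
  the controller runs; since the distal joints still hold their previous
  values at that instant, this coincides with the locked position and one
  forward-kinematics evaluation serves both quantities.
* **Target identity.** Latches reset only on actual target changes.
  Targets carry an optional uid so that the same object expressed in a
  translated shoulder frame (trunk compensation) is not mistaken for a
  new goal.  Continuity across target changes is the method's point: the
  reset clears latches but preserves all joint values.

The direct control (PC− predictions applied straight to the distal
joints) is implemented stateless for comparison; its one-tick jump at a
target change, and the interpolation's bounded per-tick change under the
same scenario, are asserted in tests.

## Closed-loop simulation

A trial presents one target; the simulated user moves the proximal joints
along a minimum-jerk profile (default 1.5 s) toward the proximal pair of
the posture that generated the target, while the selected control drives
the distal joints at 90 Hz.  The trial succeeds at the first tick at
which the hand is inside the validation zone — position within the
distance tolerance *and* grasp axis within the angle tolerance (spin
free) — sustained for the user's reaction delay (default 0 s, making the
validation time identically zero; a nonzero delay models the human
button-press latency rather than predicting it).  Preset tolerance
configurations: 4 cm/10°/10 s, 3 cm/10°/6 s and 2 cm/5°/5 s.

After the main reach the user *corrects*, as humans visibly do: each tick
it takes the greedy step — ±0.25° on each proximal joint, and, because
trunk compensation is a documented feature of real use, ±1.5 mm of
shoulder translation per axis (capped at 15 cm) — that most reduces the
tolerance-weighted pose error.  A user familiar with the device
anticipates where the distal joints will settle for a candidate shoulder
state by querying the goal network (an internal model); when no candidate
improves the pose the user wiggles randomly rather than freezing, which
keeps the interpolation fed with hand displacement.  Shoulder translation
shifts the target's coordinates in the shoulder frame (the hand does not
move), exactly as trunk leaning does in reality, and the recorded
translations feed the shoulder-spread-volume metric.

Phases run targets in order, each trial starting at the previous trial's
final posture (first trial: mid-range posture), with seeded per-trial
randomness; a pluggable exclusion hook (default: drop trials whose hand
path jumps > 0.5 m between ticks) stands in for the motion-capture
artifact screening used on human recordings.  Offline, any control can be
re-applied tick-by-tick to the proximal angles recorded in a successful
natural trial, yielding reconstructed trajectories for the offline error
metrics.

## Metrics

* **SR** — percentage of validated trials.  **MT** — target appearance to
  validation.  **VT** — last validation-zone entry to validation.  MT, VT
  and the trajectory metrics use successful trials only; per-trial values
  aggregate across a phase by the median.
* **SV** — volume of the covariance-aligned ellipsoid covering 97% of the
  shoulder positions: (4/3)π√det(Σ)·q^{3/2} with q the 0.97 quantile of
  χ²₃, reported in dm³.  Verified against the isotropic-Gaussian closed
  form within 5% at n = 10⁴.
* **SAL** — spectral arc length of the hand speed profile: magnitude
  spectrum on a zero-padded FFT (padding factor 4), normalised by its DC
  value, restricted to [0, 20 Hz], arc length over the frequency axis
  scaled to [0, 1], negated.  This is the original fixed-cutoff
  parameterisation (not the later adaptive-cutoff SPARC variant); cutoff
  and padding are exposed and frozen in tests against an independent
  explicit-DFT oracle.  SAL ≤ −1 always.
* **CT** — maximum distance of the hand from the straight line through
  the first and last hand positions.  **DI** — path length over
  straight-line distance (≥ 1).
* **Offline**: per-trial mean absolute joint error over frames (proximal
  pair and distal five separately), per-trial median hand position
  distance, and per-trial median grasp-axis angle (atan2 of cross and dot
  products, exact at 0°); medians are taken over frames within a trial,
  then over trials.

## Problem sizes and determinism

Default experiment sizes — ≈50k training frames, 200 recovery targets,
100-trial phases — are the simulator's standard study conditions; every
random quantity (database, jitters, training, target draws, user noise
and exploration) derives from explicit integer seeds, and phase runs are
bit-reproducible.  `scripts/acceptance.py` reruns the standard experiment
end-to-end from a single seed.

## Known limitations

The simulated user is a model of corrective behaviour, not of human motor
learning: movement times and validation times should be read as
plumbing-level sanity values, not predictions of human performance.  The
synthetic database lacks real synergy structure, so network accuracies
here bound what clean data allows rather than forecast real-data
accuracy.  Grasping (hand open/close) and physical actuator limits beyond
range-of-motion saturation are out of scope.
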