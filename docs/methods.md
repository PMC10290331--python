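# Methods

This note records the models, the simulator, the numerical choices and the
known limits of `kinemg`, at the level of detail a maintainer or reviewer
needs to judge what the package's tests do and do not demonstrate.

## Scope and data model

The package predicts the *envelope* of 8-channel surface EMG (rectified,
200-ms windowed RMS, 60 Hz) from time-aligned motion features of the right
arm: six joint angles (shoulder abduction/adduction, shoulder
extension/flexion, elbow extension/flexion, elbow rotation, wrist
abduction/adduction, wrist extension/flexion, degrees) plus hand position
(m) and orientation (unit quaternion, w-first). The atomic unit of training
and evaluation is a cue-anchored **sequence pair** of exactly 457 frames
(~7.6 s at 60 Hz): one repetition of one movement task, rest-bracketed.

## The simulator

Real multi-subject sessions of this kind are not publicly distributable, so
the generator is a first-class component: its defaults *are* the study
conditions all tests run under, and all of its randomness derives from one
seed (bit-identical outputs per configuration).

**Session layout.** Per subject: for each of `n_tasks` (default 20) tasks,
4 s of rest followed by `n_repetitions` (default 18) instruction windows of
7.5 s, each holding one repetition; a rest tail closes the session. Default
rates: motion 60 Hz, EMG 2222 Hz. The 60-s inter-task rests of a live
protocol are compressed into the 4-s rest leads; they carry no signal
structure the models use.

**Tasks.** Built-in templates span three categories (simple / combined /
complex, allocated ≈ 11:3:7) as joint-space waypoint tables whose first and
last waypoints are the rest pose (arm hanging). Trajectories interpolate
waypoints with minimum-jerk profiles — the standard smoothness model for
voluntary reaching — with per-repetition amplitude jitter (±10 %, ±40 %
for "mix"-style tasks) and segment-duration jitter (±15 %). Anatomical
joint limits are a package constant (degrees), overridable. Hand pose comes
from a two-segment forward-kinematics chain (upper arm 0.30 m, forearm
0.25 m); quaternions keep hemisphere continuity across frames.

**Muscle model.** Channel c's drive is

    d_c(t) = Σ_j [w⁺_cj θ̇_j(t)]₊ + Σ_j [w⁻_cj (−θ̇_j(t))]₊ + Σ_j u_cj g(θ_j(t))

with fixed non-negative weight matrices pairing channels antagonistically
(deltoid anterior/posterior on shoulder flexion, biceps/triceps on elbow
flexion, wrist flexor/extensor on wrist flexion), and a tonic anti-gravity
term g(θ) = [sin θ]₊ (zero in the hanging rest pose). The drive passes a
first-order low-pass (τ = 60 ms — physiological activation dynamics), is
scaled by the subject's per-channel gain, mixed by the subject's crosstalk
matrix, and offset by a baseline tone. With zero noise and identity
crosstalk the 60-Hz activation is an exact deterministic function of the
kinematics; this is the oracle the parameter-recovery tests compare
against.

**Inter-subject variability** (the reason transfer learning exists here):
per-channel gains log-normal (σ = 0.35), baselines 0.01–0.04 envelope
units, a row-stochastic near-identity crosstalk matrix (diagonal ≥ 0.7,
off-diagonal mass 0.05–0.3 spread over neighbouring electrodes — the
embodiment of placement differences), sensor-noise scale 0.005–0.02 and a
DC electrode offset. Because normalization is per-subject min-max, pure
gain and offset differences cancel; what makes an unseen subject hard in
this simulator is the *crosstalk-shape* difference, which is also what
fine-tuning repairs.

**Raw EMG.** The upsampled envelope amplitude-modulates zero-mean Gaussian
noise, plus additive sensor noise and the DC offset. This carrier makes
windowed RMS an unbiased envelope estimator, so the preprocessing chain has
a known ground truth: with ~444 samples per 200-ms window the per-frame
relative error is ≈ (2·444)^(−1/2) ≈ 3.4 %, and the measured whole-session
relative RMSE of recovery is ≈ 4 % (asserted < 5 % in the tests).

**Recorded motion** adds white measurement noise (0.2° SD) to the true
angles; the muscle model is driven by the true angles. Without this, joints
the task set never moves (wrist abduction — deliberately excluded, matching
the known inaccuracy of IMU wrist-abduction tracking) would be constant
channels and min-max normalization would be undefined; it is also what the
Savitzky–Golay stage smooths.

**What the simulator does not emulate:** nonlinear electrode-skin effects,
fatigue and co-contraction drift, within-subject electrode re-placement,
impedance changes, motion-artifact spectra, and any true musculoskeletal
dynamics (no inertia, no force-length/velocity relations). Tests passing on
this generator show the *pipeline and models* behave as specified under the
assumed signal structure; they are not evidence about real recordings.

## Preprocessing

Fixed order — EMG: baseline correction (subtract each channel's mean over
the leading rest window) → 6-SD outlier repair → 200-ms centered RMS at the
60-Hz motion timestamps (boundary windows truncated, never padded) →
per-subject min-max to [0, 1] → 457-frame cue-anchored cuts. Motion:
third-order Savitzky–Golay on the angles (window 31 frames ≈ 0.5 s,
chosen to preserve movement-scale dynamics while denoising; configurable) →
forward-difference velocity and acceleration, Δf(n) = f(n+1) − f(n) scaled
by the rate, the final frame replicating the penultimate derivative to
preserve length → feature assembly → min-max to [−1, 1] → the same cuts.
Derivatives are computed in physical units before normalization and
normalized as channels of their own.

Feature configurations: ANG/VEL/ACC (6 each), ALL (18), EEF (3 position +
4 quaternion = 7), EEF⁺ (EEF plus its first and second forward differences,
21).

**Outlier repair.** Samples beyond 6 global SDs of the channel mean are
flagged; each flagged run ± 50 ms gets a cubic least-squares *trend* spline
(interior knots every 25 ms) fitted and subtracted — this removes slow
cable-movement excursions. A sample that afterwards remains beyond the
6-SD band *and* beyond 6 local SDs (local scale from the unflagged samples
of the same window) is bridged by linear interpolation. The local-scale
condition is essential: an amplitude-modulated burst legitimately contains
samples beyond 6 global SDs, and clamping them would corrupt the envelope
(doing so raised envelope-recovery error from 4 % to > 60 % in
development); a lone artifact spike, by contrast, is far outside its local
scale and is removed below the 6-SD bound. Note that with the 6-SD global
flag rule, Chebyshev's inequality caps the flagged fraction at 1/36, so the
">20 % flagged ⇒ corrupt input" guard can only trigger at user-lowered
thresholds.

**Segmentation** is cue-anchored (the cue is the only observable onset
marker); windows reaching past the end of the recording are right-padded
with rest-state frames. Normalization inside protocol runs is fitted on the
training repetitions only and applied with clipping (clipped fraction
logged) to validation/test data; the standalone pipeline fits on the full
session.

## Models and training

Five architectures, one contract: input (n_sequences, 457, n_features),
output (n_sequences, 457, 8). Hidden activations are ReLU for dense and
convolutional layers; LSTM layers use standard gating (forget-gate bias
initialized to 1, Glorot-uniform weights). All architectures have an input
dropout layer with a default rate of 0.1 for every architecture (a single
shared default rather than per-architecture tuned rates; configurable).
Output layers are linear.

* **RNN** — LSTM 256/128/64, stateful: hidden/cell states carry across
  consecutive sequences of one ordered pass (with mini-batches, lane-wise
  across batches), which is benign because every sequence starts and ends
  at rest; states reset between epochs and datasets, and on demand.
  Back-propagation truncates at sequence boundaries.
* **RNNseq** — the online variant: trained on overlapping 21-frame
  sub-sequences (20 warm-up frames restore the state from zero, loss on
  the final frame only; pre-sequence history replicates the rest-state
  frame 0). Training sub-sequences are shuffled with zero initial state —
  the warm-up, not batch statefulness, restores temporal context — and
  prediction uses exactly the same windowing, so train and predict are
  consistent by construction. The equivalence of this windowed prediction
  to the exact stateful recurrence (within 1e-4 after the warm-up, single
  LSTM layer at moderate weight scale) is asserted in the tests.
* **FNN** — frame-wise dense 512/256/128; batch 128 rows.
* **FNNseq** — dense with lag-augmented input. The lag set is
  {1, 2, 4, 8, 16, 32}: powers of two, capped at 32 frames (≈ 0.5 s of
  history), six lags — a geometric ladder that covers the envelope's
  dominant time constants at logarithmic cost.
* **CNN** — conv1d filters 128/128/128/128/64, kernels 32/8/8/4/4, 'same'
  padding so the output keeps 457 frames.

Training: Adam (lr 1e-3 default), MSE over all output elements, early
stopping with patience 5 on validation loss and best-epoch weight
restoration, max 100 epochs by default. Fine-tuning defaults: lr 1e-4,
max 20 epochs; subject-specific training keeps the from-scratch defaults.
Determinism contract: same seed + same BLAS build ⇒ identical training
logs and weights (one `numpy.random.Generator` drives initialization,
dropout and shuffling); cross-platform bit equality is not claimed.

The layer stack (dense, ReLU, inverted dropout, stateful LSTM, 1-D
convolution), backpropagation and Adam are implemented in numpy inside the
package and verified against central finite differences to < 1e-6 relative
error in the test suite.

## Experiment designs

Splits assign each (subject, task) cell's repetitions to
train/validation/test — 15/1/2 at the full 18 repetitions, scaled
proportionally (minimum 1 val and 1 test) for smaller sessions — with
disjointness asserted programmatically. Held-out tasks appear only in
new-motion test sets; held-out subjects only in new-subject/fine-tune
roles. All stage seeds derive from one master seed via named substreams.

Conditions: general (train on all but the held-out subject), fine-tuned
(weight-transfer + short training on the held-out subject), and
subject-specific (that subject only, random initialization); leave-one-out
repeats the triple per held-out subject and reports mean ± SD; the
repetition sweep retrains the general model from scratch at repetition
counts {1, 3, 5, 8, 10, 12, 15} with fixed val/test splits; the input
ablation trains one model per feature configuration on identical splits;
the added-general model trains on all subjects and is compared with the
per-subject models.

## Reduced-scale verification runs

The heavier integration tests run a reduced study chosen to fit a single
CPU core: 3 subjects × 8 tasks × 6 repetitions, RNN widths quartered to
64/32/16, at most 30 epochs, batch 4 sequences (scaled down with the
training-set size — 56 training sequences at a 16-sequence batch would
yield only 4 gradient updates per epoch), split 4/1/1 per task, subject 3
and the last task held out. Under these conditions the recurrent model
reaches a channel-averaged zero-line score ≈ 91 on held-out repetitions of
trained motions, and two orderings hold across seeds: fine-tuned beats the
unadapted general model on the new subject, and trained motions beat the
never-trained motion. New-motion scores on this simulator can be *deeply*
negative (large negative Z_s): quiet channels have tiny Σy², so modest
absolute errors produce large negative scores, and the models extrapolate
poorly to joint-velocity combinations outside the training envelope — the
qualitative known > new ordering is the meaningful statement, not the
magnitude.

## Known limitations

* Envelope-level simulation only; no raw-EMG spectral realism (the carrier
  is white), so filters that exploit spectral structure cannot be studied.
* Min-max normalization makes the inter-subject gap depend on crosstalk
  shape rather than gain — real inter-subject variability is richer.
* The numpy training loop is single-core; full-width models at full session
  scale are feasible but slow (minutes per epoch), which is why the
  verification runs use the reduced study above.
* `R²` and `Z_s` are undefined for constant / all-zero originals; the
  package raises rather than returning sentinels, so callers must filter
  degenerate channels.
* VAF and NRMSE are provided for cross-study comparison only and are not
  part of the standard report.
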