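# Methods

## Problem and model

The package classifies which of seven arm/hand movements produced a short
multi-channel surface-EMG recording. The classifier is a Sugeno fuzzy
inference system with Gaussian premises, trained as an ANFIS: an adaptive
network whose forward pass is exactly the fuzzy inference

γ(x) = Σ_i ω̄_i f_i(x), ω_i = Π_j exp(−(x_j − c_ij)² / 2σ_ij²), ω̄_i = ω_i / Σ_k ω_k,

over inputs x ∈ R^n (n = 2..8 per-channel RMS amplitudes). Classification is
by regression onto a single continuous output: each movement owns a fixed
code (0, 0.083, 0.166, 0.249, 0.333, 0.416, 0.499), the network is trained
to emit the code of the executed movement, and a prediction is the movement
with the nearest code (ties toward the lower code, so decision boundaries
sit at code midpoints). The codes are stored exactly as listed rather than
as an idealized k/12 grid so that the code table reproduces bit-exactly.

Assumptions: one RMS feature per channel is sufficient to separate the
movement classes (amplitude coding, no spectral features); the movements are
executed in isolation inside known cue windows; inter-class similarity shows
up as shared-muscle amplitude overlap, most prominently between forearm
flexion and forearm rotation.

## Preprocessing

Per channel: affine calibration (default: subtract the mean of a designated
rest segment, unit gain; configurable), mean removal, a 4th-order Butterworth
20–450 Hz band-pass, and a 60 Hz IIR notch (Q = 30), all applied
forward-backward (zero phase) so the cue-aligned window boundaries are not
skewed by group delay. The band edges reflect the usable surface-EMG band at
1 kHz sampling: the dominant signal energy lies around 70–300 Hz, drift and
motion artifacts below 20 Hz, and 450 Hz keeps the upper edge safely below
the 500 Hz Nyquist frequency. The analysis window spans cue + 0.4 s to
cue + 7.5 s — the active portion of the 8.3 s animation (2.9 s ramp up,
1.3 s hold, 2.9 s ramp down), excluding the final rest. The 1.3 s hold
absorbs the 0.05 s by which the nominal segment durations undershoot the
8.3 s animation total. An alternative energy-based onset detector (moving
RMS above k× the rest RMS, k = 3) is not enabled by default; the fixed
cue-aligned window is deterministic and matches the cued protocol.

## Subtractive clustering

Chiu's method on the min-max-normalized feature hypercube (constant
dimensions map to 0.5 and are restored exactly on denormalization). Defaults:
neighbourhood radius r_a = 0.5 in normalized units, squash radius
r_b = 1.5 r_a (the conventional ratio), accept ratio 0.5 and reject ratio
0.15 with the in-between distance test (accept iff d_min/r_a + D/D1 ≥ 1),
and an optional hard cap max_clusters (60 in the pipeline default,
reproducing the full-scale 60-rule network structure). Ties at equal density
break toward the lowest original point index, making the run deterministic
and order-invariant. On the synthetic feature sets the seven movement
classes produce seven density peaks, so far fewer than 60 rules are
typically selected.

## Rule seeding and hybrid training

Each cluster center becomes one rule; premise j of rule i is Gaussian with
center c_ij equal to the center's coordinate and width
σ_ij = r_a · range_j / √8, a seeding convention that scales the membership
overlap with each input's spread. Consequents start at zero. First-order
consequents are the training default (the least-squares form of the hybrid
rule is affine in the inputs); zero-order is available and used where
constant consequents make the premises identifiable.

Training alternates, per epoch: (1) an exact linear least-squares solve for
all consequents (minimum-norm via SVD when the system is underdetermined,
with a logged warning — the 35-sample training session against a 60-rule
first-order network is the canonical rank-deficient case); (2) one batch
gradient-descent step on all premise centers and widths, using analytic
gradients of the SSE (verified against central finite differences). A
premise step is accepted only if the error after re-solving the consequents
does not increase; otherwise the learning rate is halved and the step
retried, and training stops with converged = False if the rate falls below
1e-10. This backtracking acceptance makes the reported per-epoch error
sequence non-increasing by construction. Defaults: 50 epochs, learning rate
0.01, early stop when the RMSE change drops below 1e-6, σ clamped from below
at 1e-4 of each input's range.

A note on identifiability: with free per-rule widths, distinct
(center, width) configurations can realize identical input-output maps, so
premise "recovery" is only meaningful when the premises are anchored — in
this package, by seeding them from the data's cluster structure. The
recovery experiment in the tests (2-rule zero-order model over two input
clusters, observation noise 0.01, n = 500) exercises exactly that path and
relocates centers to within 0.05 normalized units of the truth.

## Synthetic sEMG

Each channel is dc + A_mains·sin(2π·60·t) + e(t)·ν(t), where ν(t) is 20–450 Hz
band-limited Gaussian noise normalized to unit RMS and the envelope is
e(t) = rest_rms + gain·a(t) with a(t) the trapezoidal activation profile of
the cue animation. The movement × channel gain matrix encodes the
channel/muscle assignment: the movement's primary channel at 1.0,
physiologically coupled channels at a crosstalk gain (default 0.4), all
others at a 0.05 co-activation baseline. The coupled set is the forearm
flexion/rotation pair's shared musculature — biceps (C0), pronator teres
(C4) and brachioradialis (C5) — with C4 as rotation's single primary
channel. Defaults: rest noise RMS 0.05, mains amplitude 0.1, DC offset 0.1,
in the same arbitrary volt-proportional units as the unit activation gain;
these place the active-window RMS more than an order of magnitude above the
rest floor, a strong-signal regime consistent with trained subjects and
careful electrode placement. An optional per-repetition amplitude jitter
(±20%) models unconstrained contraction force; it is off by default since
the protocol neither restricts nor measures force. Randomness derives from a
single master seed through SeedSequence spawning (per session, per
repetition), so every artifact is reproducible from (config, seed).

What the generator does *not* emulate: motor-unit action-potential
structure, electrode shift, skin-impedance drift, fatigue, inter-subject
anatomical variability, or user execution errors. Consequently the clean
default conditions separate perfectly (100% hold-out accuracy), and passing
the end-to-end tests demonstrates the pipeline's correctness and its
qualitative confusion structure — forearm flexion/rotation confusion rising
monotonically with shared-channel crosstalk — not field performance on real
recordings, where reported accuracies for this class of system are in the
85–90% range.

## Numerical choices and edge cases

- Least squares via `numpy.linalg.lstsq` (SVD, rcond = None); residual
  orthogonality to the design columns is asserted in tests.
- Filters are designed with `scipy.signal.butter` / `iirnotch` and applied
  with `filtfilt`, so the effective magnitude response is the square of the
  design response; tests compare measured tone attenuation against the
  squared `freqz` oracle.
- Density and revision computations are fully vectorized; equivalence with
  O(n²) double-loop references is asserted to 1e-12 relative.
- Degenerate inputs: empty signals/segments and zero calibration gain raise
  ValueError; all-zero firing strengths cannot occur with Gaussian MFs but
  are guarded for other MF families; a recording shorter than a cue window
  clips the window with a warning, and cues beyond the recording are
  skipped.
- Problem sizes: the default experiment trains on one 35-execution session
  and evaluates on four; multi-seed sweeps in tests and the acceptance
  script use 5–10 seeds, and the crosstalk sweep uses a 2-session protocol
  (train + one held-out session), sizes chosen to characterize the pipeline
  compactly.

## Known limitations

- The trainer is batch gradient descent with backtracking, not a
  second-order or adaptive-rate optimizer; very flat error surfaces (e.g.
  first-order consequents absorbing premise misplacement) converge to the
  noise floor without moving premises far.
- Nearest-code decoding has no rejection class: every window is assigned a
  movement.
- The CLI reads whole recordings into memory; streaming/real-time operation
  is out of scope.
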