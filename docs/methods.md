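# Methods

This note documents the models, conventions and numerical choices behind
`gaitwnn`, in the order data flows through the package.

## Synthetic gait cohorts (`synthetic_gait`)

The estimator is exercised on generated cohorts that emulate level walking
of healthy young adults at self-selected speed, sampled at 100 Hz.

**vGRF waveform.** The stance-phase vertical ground reaction force is the
sum of two compact-support Gaussian bumps (loading-response peak at 13 %
of the cycle, height 1.10 body weight; push-off peak at 48 %, height
1.15 BW; widths 9 % and 8 %), multiplied by smoothstep ramps (6 % long)
that force the curve to exactly zero at contact onset and at toe-off
(60 % nominal). Each bump's Gaussian tail is subtracted and renormalized
so the configured peak height is attained exactly and support is genuinely
compact. Swing-phase force is identically zero. The opposite foot carries
the same waveform offset by half a cycle. Forces are in body-weight units,
so no anthropometrics enter anywhere. Peak placements/heights are
normative defaults (all configurable via `VgrfParams`); no quantitative
waveform was available to copy from measured data.

**Angle curves.** Ankle, knee and hip sagittal templates are low-order
Fourier series (8 harmonics) of a periodic cubic spline through normative
anchor points, guaranteeing smoothness and exact cyclicity. Anchors are
chosen with margin inside the normal-gait envelopes ankle
[−24.779°, 16.126°], knee [−4.865°, 72.396°], hip [−24.104°, 33.245°]
(dorsiflexion/flexion positive); subject-level amplitude scaling is
shrink-only about the curve mean, so generated angles cannot leave the
envelope (up to additive noise).

**Latent coupling.** Each subject draws an amplitude ("vigor") latent,
a timing latent and a cadence scale. The vigor latent scales the vGRF
peaks *and* (monotonically) the per-joint angle amplitudes; the timing
latent shifts toe-off and the angle phase together. Because forces and
angles are deterministic functions of the same latents (plus noise), a
learnable vGRF → angle mapping exists by construction. This coupling is
the testability hook for the network: it is an idealization — real
inter-subject kinematic variation is not a one-dimensional monotone
function of force amplitude — so passing tests demonstrate the machinery
recovers a recoverable mapping, not motion-capture-grade accuracy on real
gait.

**Noise and jitter.** `noise_sd` (default 0.02 BW, a plausible
post-filtering force-plate noise level) is added to stance samples only
and floor-clipped at 1e−6 BW so stance stays strictly positive and swing
stays exactly zero; angle noise is `noise_sd × 25 °/BW` (0.5° at the
default), vanishing with `noise_sd = 0` so a "noiseless cohort" is truly
noiseless. Trial-level jitter (±1 % amplitude, ±0.3 % toe-off timing,
±1 % cadence SD) can be disabled, making a subject's trials identical in
the noiseless case. Event times are emitted as sample indexes with the
toe-off instant represented by adjacent ITO/NTO samples (strictly
increasing event order).

**What the generator does not model:** pathological gait, 3D/coronal/
transverse angles, forward dynamics, marker artifacts, force-plate
calibration error, gait-to-gait correlation beyond the latent structure.

## Preprocessing (`preprocess`)

* Phase grid fixed at 1 % resolution — 101 points, 0..100 inclusive — so
  event indexes can be integer percentages.
* First-order Butterworth low-pass; applied forward-backward (zero-phase)
  by default so filtering cannot shift event timings relative to the
  signals. The −3 dB point of the underlying filter is at the cutoff
  (single pass); the zero-phase application squares the magnitude
  response (−6 dB at cutoff), which is the standard trade-off.
* FFT-based cutoff selection returns the lowest frequency whose
  cumulative spectral power reaches a configured fraction (default 0.99)
  of the total, excluding the DC bin (the mean carries most vGRF power
  and says nothing about required bandwidth).
* Cycles are partitioned inclusively between boundary events and
  linearly resampled onto the phase grid; boundary events map to exactly
  0 % and 100 %.

## Gait-Intervals feature selection (`gi_features`)

* Predefined main-event percentages default to OTO 10, HR 30, OIC 50,
  FA 73, TV 87 — standard normative phase boundaries, configurable.
* Intermediate events: step `b_i = (t_end − t_start)/(n+1)`; the k-th
  event snaps to the nearest integer grid index of `t_start + k·b_i`
  with **round-half-up** as the tie rule; at 1 % resolution the snapped
  index always lies within the ±1 % buffer of the exact position.
* The stance/swing transition of an IC-initiated cycle is toe-off: when
  the measured ITO/NTO indexes round to the same or adjacent grid points
  they are treated as one common instant and split into (t−1, t+1). For
  ITO-initiated cycles the common instant is the contact (NIC/IC) and
  the sub-phase order rotates around it; the stance/swing blocks flip
  accordingly (features 1–11 swing, 12–22 stance).
* Duplicate removal scans in ascending feature number and shifts a
  repeated index +1 % until unique; escaping the grid or breaking the
  strictly-increasing order is an error (such a cycle is rejected rather
  than silently reordered).
* Swing-block features are sampled from the opposite-leg signal and
  multiplied by −1, keeping them disjoint from stance-phase patterns.

## Wavelet network (`wnn_core`)

* Mexican-hat mother wavelet ψ(z) = (1 − z²)e^(−z²/2); its derivative
  ψ′(z) = z(z² − 3)e^(−z²/2) enters the analytic gradients, which are
  exact for every parameter (including translations and dilations
  through the product over inputs, computed with exclusive cumulative
  products to avoid division by ψ-zeros).
* Initialization: translations ξ_k = 0.5(min_k + max_k) of each input;
  dilations ς_k = clip(0.25·(max_k − min_k), 1e−3, 1]. The 0.25 range
  factor places training inputs within the wavelet's active support
  (|z| ≲ 2) while honoring the ς ≤ 1 cap; a much smaller dilation
  saturates every wavelon (ψ ≈ 0 for all samples, zero gradient) and
  degrades the network to its linear path. A constant input row (e.g.
  the contact-onset feature, which is exactly 0 BW in every generated
  trial) gets the floor dilation and a warning. Weights are uniform in
  ±0.1; output biases start at the per-output target means, which
  centers the regression before the first step.
* Cost: per-sample squared error summed over the 66 output coordinates,
  averaged over samples; prediction risk is the same functional on
  held-out samples. This convention is used consistently in the cost,
  the gradients and the risk.
* Optimizer: full-batch gradient descent with momentum
  (velocity = μ·velocity − η·∇L; defaults η = 0.01, μ = 0.9, both
  configurable; neither value is prescribed by the protocol). The cost
  trace records L at the start of each epoch; training stops at the cost
  floor (default 1e−5) or the epoch cap (default 50). Non-finite cost
  raises with the trace attached.
* Hidden-node selection trains one model per candidate count on a fixed
  internal 70/30 split and picks the minimum prediction risk, ties to
  the smaller network.
* The MLP baseline has one sigmoid hidden layer, a linear output, no
  direct input→output path, and shares the initialization convention,
  optimizer and budget.

## Evaluation protocol (`evaluation`)

* Three independent shuffled 70/30 splits ("sequences"); with 300
  samples that is 210 train / 90 test each.
* Per sample and joint, the 22 estimated angle points are interpolated
  to the 101-point grid with a cubic spline through the sample's own
  event-schedule knots. **Not-a-knot** boundary conditions are used: they
  reproduce polynomials up to cubic exactly and avoid the artificial
  end-flattening of natural boundary conditions.
* Scores per profile: RMSE in degrees; NRMSE = RMSE normalized by the
  ground-truth profile's range (max − min), in percent; Pearson ρ. A
  constant ground-truth profile has no defined range or correlation and
  is rejected. Scores are averaged (mean ± SD) over all samples,
  In-Sample (training members) and Out-Sample (held-out members), per
  sequence; the sequence with the least mean RMSE across joints is the
  headline.
* The protocol's noise floor is the spline-reconstruction error of
  ground-truth-sampled points (sub-degree on the smooth generator
  curves), established by a dedicated test.

## Problem sizes

Default experiments use the protocol-shaped cohort (30 × 10 = 300
samples, 5 hidden nodes, 50 epochs, 3 sequences), which runs in a few
seconds; unit tests use smaller cohorts (2–6 subjects) chosen as the
smallest sizes that still exercise subject- and trial-level variability.
The teacher-student recovery check uses a 3-input/3-wavelon/2-output
teacher, 200 training and 100 test samples, noise SD 0.05, and a
3000-epoch fit — small enough to run in well under a minute.

## Known limitations

* The synthetic cohort is far more homogeneous than real gait data;
  absolute RMSE/ρ values on it are optimistic and not comparable to
  motion-capture studies.
* The estimator assumes valid measured IC/ITO/NTO/NIC events; no event
  detection from raw force signals is provided.
* Only sagittal-plane angles and normal adult gait are modeled.
* The ITO→NTO cycle mode is structurally supported (layout, labels,
  split), but the bundled generator emits stance-initiated trials, so
  that mode is only lightly exercised.
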