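# Methods

This document describes the detection model, the synthetic data generator,
the numerical choices, and the reference benchmark protocol used throughout
the tests and `scripts/acceptance.py`.

## Problem definition

A postictal recording is a multichannel scalp EEG that starts inside
generalized suppression (near-flat, low-amplitude signal) and at some time
`t_end` transitions to intermittent slow-wave activity. The task is to
estimate `t_end` from the signal alone. A detection is **timely** when it
falls in `[t_end, t_end + L]` with latency period `L = 10 s`; an earlier call
is a false alarm, a later or missing call is a miss.

## Preprocessing

- **Montage.** From 13 referential electrodes (10-20 system: Fp1, Fp2, O1,
  O2, F7, F8, T7, T8, P7, P8, Fz, Cz, Pz) the 10 standard bipolar
  derivations are formed (anode minus cathode): two temporal chains
  Fp1-F7-T7-P7-O1 and Fp2-F8-T8-P8-O2, plus the midline Fz-Cz and Cz-Pz.
  Bipolar derivations suppress the common reference and far-field noise.
- **Resampling.** Clinical acquisition rates vary (150–256 Hz); every
  recording is brought to 200 Hz by rational polyphase resampling
  (`scipy.signal.resample_poly`, anti-aliasing included, line padding at the
  edges). Mixed per-channel rates within one EDF file are rejected rather
  than silently harmonised.
- **Optional smoothing.** A unit-sum, zero-phase Hann kernel (default 11
  samples = 55 ms at 200 Hz) with reflection edge handling. Note: reflection
  biases the row mean by O(window/N) on non-constant signals; the mean is
  preserved exactly only for constant rows.

## Crop datasets

Windows of `w = 10 s` slide on a stride grid anchored at t = 0 (default
stride 100 ms; the reference training protocol uses 1 s to bound CPU cost).
The label rule is:

- label 1 ⇔ window end ≥ `t_end` (boundary inclusive, with a 1e-9 s epsilon
  guarding float grid arithmetic);
- windows whose end exceeds `t_end + L` are excluded from the dataset
  entirely, so no training content lies beyond the latency period.

The retained count for a recording equals `floor((min(duration, t_end + L) −
w)/stride) + 1`. Splits are made at the **recording** level (shuffled ids,
`floor(0.8·n)` to train), so overlapping windows of one recording can never
appear on both sides.

## Detectors

**Convolutional network** (numpy implementation, EEGNet-style):
temporal convolution (kernel 18 samples ≈ 90 ms at 200 Hz, 8 filters) →
spatial convolution whose 101 filters each span all montages and temporal
filters → batch-norm, ReLU, dropout 0.25, average-pool 4 → depthwise
temporal convolution (multiplier 2, kernel 16) → pointwise convolution (16
filters) → batch-norm, ReLU, dropout, average-pool 8 → dense → sigmoid.
Training: binary cross-entropy with inverse-frequency class weights, Adam
(lr 1e-3), mini-batches of 64, inputs scaled to unit global RMS; the weights
with the best validation AUC are retained. All convolutions are valid
cross-correlations realised with stride-tricks windows and einsum; gradients
are exact (verified against finite differences in the tests). Two stated
readings of the architecture: "18" is the temporal kernel *length* and "101"
the spatial filter *count*; both are single config fields
(`ArchConfig.temporal_kernel_len`, `ArchConfig.spatial_filters`).

**Feature classifier**: a random forest (default, 200 trees,
`class_weight="balanced_subsample"`) or gradient-boosted trees over a
315-dimensional feature bank per 10-montage crop:

- distribution moments: population variance, skewness `m3/m2^1.5`,
  non-excess kurtosis `m4/m2²`;
- periodogram band powers, power spectral intensities (sum of `|X(f)|`) and
  relative intensity ratios over the clinical bands delta 0.5–4, theta 4–8,
  alpha 8–13, beta 13–30, gamma 30–70 Hz, plus peak and median frequency and
  total energy (DC bin excluded throughout);
- Petrosian fractal dimension
  `log10(N) / (log10(N) + log10(N / (N + 0.4·N_δ)))` with `N_δ` the number
  of sign changes of the first difference;
- SVD entropy (bits) of the delay embedding (dimension 20, delay 1), i.e.
  Shannon entropy of the normalized singular values;
- Pearson correlation of every montage pair (45 values);
- second-half/first-half ratios of RMS, delta band power and line length
  (guarded by +1e-12), which spike on windows straddling the transition.

Every montage row is demeaned before extraction, making all features
invariant to constant amplitude offsets. Degenerate rows (constant/all-zero)
produce zeros plus a per-montage degeneracy flag instead of NaN.

## Inference and evaluation

At inference the whole recording is scanned at the 100 ms stride with no
exclusions. Each grid point is stamped with the window **end** time, so the
value reported at time t uses only samples at or before t; the tests audit
this causally (tampering with samples after t never changes values ≤ t). An
onset is called at the first run of `k = 3` consecutive probabilities
≥ 0.5. Reported metrics: pooled and per-recording crop AUC (Mann-Whitney
formulation with midranks, ties counted ½), timely-detection rate, false
alarm rate, and median/IQR latency error.

## Synthetic recordings

The simulator generates 13-channel referential EEG with known ground truth:

- **Suppression floor**: 1/f-spectrum (pink) noise at exactly 3 µV RMS per
  channel (flat below 0.5 Hz to bound drift). The 1/f floor matches the
  broadband character of real low-amplitude EEG and ensures the delta band
  is not trivially empty before the transition.
- **Slow-wave phase**: from the transition onward, band-limited 0.5–4 Hz
  noise (shared cohort-level source plus per-channel variation) at 30 µV RMS
  during bursts, gated by a two-state renewal process (exponential dwell
  times, duty 0.6, mean burst 3 s). The burst envelope is smoothed with a
  *causal* 0.3 s rising ramp and forced to zero before the transition, so no
  slow-wave energy ever precedes the annotation.
- **Artifacts** (optional): blink-like sub-1 Hz transients on frontal
  channels (20 µV), a global 0.3 Hz breathing oscillation (2 µV), and
  > 20 Hz muscle bursts on temporal channels (5 µV).
- Sampling rate per recording is drawn from {150, 200, 256} Hz; the
  transition time from U(20 s, duration − 30 s). Everything is keyed to a
  single seed (per-recording seeds are derived below 2³¹) and bitwise
  reproducible.

## Reference benchmark protocol

Fixed once in `pgesdet.benchmark` and shared by the tests and the acceptance
script (desk scale: one CPU, minutes not hours):

- **Recovery cohort**: 40 artifact-free recordings × 120 s, 3 µV floor,
  30 µV slow waves; bipolar montage + 200 Hz; training crops at 1 s stride
  (10 s window, 10 s latency); recording-level 80/20 split; inference traces
  at the 100 ms stride. The CNN runs in a reduced size (4 temporal/8 spatial
  filters, 5 epochs) for the same reason.
- **Negative control**: the feature detector is retrained on randomly
  permuted crop labels. Pooled AUC over overlapping crops of few long
  recordings has very few effective degrees of freedom (~16 independent
  suppression/slow groups at 8 test recordings), so a single permutation
  draw scatters far too widely to test chance behaviour. The control
  therefore runs on a dedicated null protocol — 64 recordings × 60 s, which
  gives near-balanced labels and roughly twice the independent groups — and
  reports the **mean AUC over 12 label permutations** (feature matrices
  extracted once). The balanced-subsample class weights in the random forest
  remove a class-imbalance bias that otherwise shifts permuted-label AUC
  well above 0.5.
- **Difficulty scaling**: held-out feature AUC is measured with the
  slow-wave RMS dialed from 12 to 6 to 3.6 µV against the 3 µV floor on a
  16-recording cohort; AUC must be non-increasing with a strict overall
  decrease. The degradation is gradual: even at a 2× amplitude ratio the
  in-band power contrast during bursts remains large, so the detector
  weakens only near the floor.

## Numerical choices

- AUC via midranks (`scipy.stats.rankdata`) — exact Mann-Whitney tie
  handling, validated against pairwise enumeration and scikit-learn.
- Crop grids and labels use a 1e-9 s epsilon on the second-valued grid; all
  window sample indices are computed by rounding `start × rate`.
- The CNN trains in float32 with float64 loss/probability computation;
  gradient checks run in float64.
- EDF writing uses a minimal in-repo 16-bit writer (one-second records,
  symmetric physical range with 0.1% headroom — quantization error ≤ about
  1e-3 µV at suppression amplitudes); reading goes through MNE with a direct
  header check that rejects mixed per-channel rates.

## Limitations

- The simulator emulates amplitude and spectral structure of postictal EEG,
  not real seizure morphology: no evolving ictal patterns, no electrode
  artifacts such as pops or detachment, no inter-subject variability beyond
  the seeded randomness. Results on it bound what the pipeline can do on
  ideal data; they say nothing about clinical performance.
- The reference benchmark is desk-scale: cohort sizes, recording lengths,
  training strides and CNN size were chosen once for single-CPU runtimes and
  are the package's own protocol, not a clinical study design.
- The CNN implementation favours clarity over speed; a full-size training
  run on hundreds of long recordings would want a GPU framework instead.
- The Hann smoother's reflection padding trades exact mean preservation for
  phase-neutral edges (see Preprocessing).
- `pgesdet.edf.write_edf` is not a general EDF+ writer (no annotations
  channel, uniform rate only).
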