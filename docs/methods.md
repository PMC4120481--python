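# Methods

## Signal model of the simulator

The generator emulates a supine subject with a sternal tri-axial
accelerometer, one ECG lead and a respiration belt, sampled synchronously at
`fs = 800 Hz`. It is a two-component model of the seismocardiogram:

**Respiration.** A phase oscillator `u(t)` (in cycles) whose frequency is
piecewise constant in time: within a protocol segment it equals the
segment's rate (default protocol: 120 s at 11.1 bpm, 60 s at 6.7 bpm, 60 s
at 23.3 bpm — normal, slow-paced, fast-paced), optionally perturbed per
cycle by Gaussian rate jitter. The frequency switches at segment boundaries
while the phase stays continuous — subjects change pace on command
mid-breath, so a cycle straddling a boundary has a blended duration. The
baseline waveform is `A·sin(2πu)`; the peak of cycle k is at phase k + 0.25
and is the ground-truth breath peak. Tidal amplitude `A` is per segment
(slow breaths slightly deeper, fast breaths shallower, applied per cycle).
The belt channel is the same waveform delayed by `belt_lag` (default
0.15 s, mechanical lag of a chest strap) with independent sensor noise.

**Cardiac.** R-peak times follow `RR_k = 60/mean_hr + ε`, ε Gaussian with sd
`hrv_sd` (default 0.03 s) clipped at ±3 sd — a fairly regular sinus rhythm.
The first beat sits half an RR after t = 0. AO follows each R by
`r_ao_delay` (default 0.05 s, a typical electromechanical delay); AC follows
AO by `ao_ac_interval` (default 0.30 s, a typical systole) plus small
per-beat jitter. Each fiducial deposits a Hann-windowed cosine wavelet of
1.5 carrier cycles at `wavelet_freq` (default 25 Hz, mid-band of the 20–40 Hz
analysis band): upright for AO (dip-rise-dip, global maximum at the AO
time), inverted and scaled by 0.6 for AC (rise-dip-rise, global minimum at
the AC time). Even symmetry about the center is deliberate: a zero-phase
band-pass filter preserves the extremum location exactly, making detector
recovery well defined. The ECG is a train of narrow (sd 5 ms) positive
Gaussian pulses at the R times.

**Axis mixing.** x and y carry the respiratory baseline at relative
amplitudes 1.0 / 0.8 with weak cardiac wavelets (0.12 / 0.10); z carries the
cardiac wavelets at amplitude 1.0 over a smaller respiratory baseline
(0.35). The axis amplitude ratios are free parameters of this model — real
recordings only establish which axis favors which component — and were fixed
once at values giving both components realistic visibility on every axis.
White Gaussian noise (default sd 0.02, i.e. ~2 % of the AO wavelet
amplitude) is added per channel.

What the simulator does **not** emulate: ECG P/T waves and QRS morphology,
arrhythmia and ectopy, inter-subject SCG morphology variation, baseline
drift and motion artifacts, sensor nonlinearity, and amplitude-coupled
respiratory modulation of the cardiac wavelets. Tests passing on this model
therefore demonstrate the correctness and internal consistency of the
processing chain under the stated signal model, not clinical performance on
patients.

## Processing chain and numerical choices

* **Normalization** uses the population sd (ddof 0), making `[-1, 1]` a
  fixed point and the operation idempotent; constant signals raise instead
  of returning NaNs.
* **Band-pass filtering** is a frequency-domain brick-wall projection (FFT
  bins outside `[lo, hi]` zeroed, inverse transform). It is zero phase — no
  group delay to bias fiducial timing — and idempotent. Edge ringing is
  accepted; accuracy analyses exclude the first/last second of a recording.
  Bands: SCG 20–40 Hz, ECG 1–40 Hz.
* **Peak detection** (shared by R peaks and breath peaks): local maxima at
  least `min_height` high, accepted greedily in descending amplitude while
  suppressing candidates within `min_separation` of an accepted peak
  (`scipy.signal.find_peaks` implements exactly this contract).
* **AO/AC windows** default to `pre_r` 0.10 s / `post_r` 0.20 s around R for
  AO, and `ac_search_start` 0.15 s after AO to `ac_search_end` 0.20 s before
  the next R for AC — "a few hundred milliseconds", the AC window longer
  because AC timing is less certain. Optionally all offsets scale with the
  local RR relative to 0.857 s (70 bpm). Argmax/argmin ties resolve to the
  earliest sample. Beats whose windows are empty or whose ordering violates
  `r < ao < ac < r_next` are *flagged* rejected, never dropped, so interval
  indices stay beat-aligned; the last beat is always rejected (no following
  R to bound its AC search).
* **HRV screening** rejects an RR interval deviating from an 11-beat running
  median by more than 20 % of that median (both values are design defaults;
  the tolerance is the kind of acceptable-variability range a gating
  workflow needs, and the window is long enough to be robust to a few
  ectopic-like gaps). A rejected interval rejects its terminating beat.
* **ADR extraction** is strictly time-domain: FFT filtering cannot separate
  the rate-varying respiratory band cleanly across three breathing patterns.
  Order is fixed — downsample (zero-phase 101-tap FIR anti-alias low-pass at
  the new Nyquist, then keep every 2nd sample), median filter (default
  0.5 s window, forced odd length, symmetric-reflection edges), moving
  average (default 0.75 s) — the median must precede the average so cardiac
  transients are removed, not smeared. Defaults pass ≤ 0.5 Hz breathing and
  crush > 5 Hz cardiac content; real subjects need per-recording tuning, so
  both windows are CLI-exposed. Peaks detected within 1 s of either
  recording edge are discarded (reflection padding can fabricate an edge
  extremum).
* **Per-pattern peak settings** (min height 0.3 sd after z-scoring; min
  separation 2.0 / 4.0 / 1.2 s for normal / slow / fast) keep the separation
  safely below the expected cycle length of each pattern.
* **Cycle matching** between two detectors (ADR vs belt) pairs peaks
  greedily by smallest time difference within 1.5 s and emits a duration
  pair wherever adjacent peaks on both sides are matched; unpaired peaks are
  dropped with a logged count. The pairing rule is this package's choice —
  any reasonable rule coincides on clean data.
* **Breathing rate** is the mean of per-cycle instantaneous rates
  (60/duration). A cycle counts toward a protocol segment only when *both*
  bounding peaks lie inside it, so boundary-straddling cycles never
  contaminate a pattern's rate.
* **Respiratory phases** are amplitude bands (the horizontal-split reading
  of the three-band scheme): per trough-to-trough cycle, amplitude is
  normalized to [0, 1] between the cycle minimum and its peak; thresholds
  default to 1/3 and 2/3 (equal bands). R1 is the crest band. A degenerate
  cycle (peak equals trough) is labeled R3 with a warning. The alternative
  directional reading (inspiration/expiration as rising/falling segments) is
  noted but not implemented.
* **Cardiac phases** anchor at AO by default — the mechanical fiducial is
  the point of the method; `anchor="r"` reproduces ECG-style triggering.
  Systole S is the mean accepted AO-AC ("auto") or a fixed value; phases
  1–3 are S/3 each, phase 4 runs to the next accepted anchor. The
  three-way systole split is a convention adopted from the gating scheme
  this follows. S ≥ the shortest cycle is an error. Spans are half-open
  `[start, end)` — deterministic, no double counting. Time between
  non-consecutive accepted beats (a rejected beat between them) stays
  unlabeled, hence its events land in the ungated file.
* **Gate index**: respiratory-major, `G(4·(i−1)+j)`; the mapping is a
  documented convention (only the 3 × 4 = 12 structure is fixed). All 12
  files are always written; conservation (gates + ungated = input) is
  asserted on every assignment.
* **Statistics**: limits of agreement use the sample sd (ddof 1) and the
  factor 1.96 — the standard Bland-Altman construction; "95 % confidence
  levels" on paired differences is read as limits of agreement. Mismatched
  pair lengths are errors, never truncated.

## Problem sizes

Synthetic validation uses 120–240 s recordings at 800 Hz (the protocol's
own length), 8–30 s recordings for oracle-equivalence checks, and 10–20
random seeds for the Monte-Carlo accuracy properties (AO localization
median error ≤ 5 ms; interval and cycle-duration correlations ≥ 0.99).
These sizes give stable statistics — e.g. ~140 beats and ~22 breathing
cycles per 2-minute segment — while the whole suite runs in seconds.

## Known limitations

* Offline only; the chain is not causal (zero-phase filters, global
  normalization), so it cannot produce prospective real-time triggers.
* No arrhythmia handling beyond the HRV screen; irregular rhythms would
  shed many beats into the ungated bin.
* The ADR filter defaults assume breathing ≤ ~30 bpm; very fast shallow
  breathing would be attenuated by the 0.75 s moving average.
* Subject-level results from real recordings (per-subject breathing-rate
  tables, cycle-percentage-vs-HR regressions across a cohort) are out of
  reach of the synthetic model by construction; the package validates the
  machinery, and `stats.linear_fit` is provided for applying the same
  analyses to real data.
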