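# scggate

Cardiac and respiratory **dual gating** for nuclear-medicine imaging from a
single sternal accelerometer (seismocardiography, SCG), with ECG and
respiration-belt reference channels for validation.

Respiratory and cardiac motion blur PET/CT images; gating — binning list-mode
events by the phase of both motions — suppresses the blur but normally needs
two separate devices (an ECG plus a respiration monitor). A tri-axial
accelerometer on the sternum records both motions at once: a large sub-Hz
baseline from chest-wall breathing motion, and sharp > 5 Hz wavelets from
aortic valve opening (AO, a dip-rise-dip wave) and closure (AC, a
rise-dip-rise wave). `scggate` implements the full offline chain that turns
such recordings into dual-gated list-mode files, plus a synthetic-signal
generator and the agreement statistics used to validate the method.

## Method

* **Cardiac chain** — channels are z-scored and band-pass filtered with a
  zero-phase brick-wall FFT filter (SCG 20–40 Hz, ECG 1–40 Hz). R peaks are
  detected on the ECG (minimum height + minimum separation, greedy
  descending-amplitude suppression). Per beat, AO is the SCG z-axis maximum
  in a window around R, and AC the minimum in a longer window between AO and
  the next R; windows can scale with the local R-R. From the fiducials the
  interval series R-R, R-AO, R-AC, AO-AO, AO-AC are derived, beats outside an
  acceptable heart-rate-variability range are flagged, and the cardiac-cycle
  percentage 100·(R-AC)/(R-R) is available.
* **Respiratory chain (ADR)** — the accelerometer-derived respiration signal
  is extracted in the time domain: downsample 800 → 400 Hz (anti-aliased),
  1-D median filter, then moving average. Respiratory cycles are
  peak-to-peak intervals from the same peak detector; per-pattern settings
  handle normal / slow / fast paced breathing.
* **Dual gating** — each breathing cycle's amplitude is normalized between
  trough and peak and split into three bands R1 (crest / inspiration), R2,
  R3 (trough / expiration); each cardiac cycle into three constant systole
  sub-phases of S/3 anchored at AO plus a time-varying diastole phase 4. An
  event in respiratory band *i* and cardiac phase *j* goes to gate
  G(4·(i−1)+j); all 12 gate files are written, plus an explicit ungated file.
* **Statistics** — Pearson r, Bland-Altman bias with 95 % limits of agreement
  (bias ± 1.96·sd of paired differences), and OLS fits.
* **Simulator** — generates synchronized SCG/ECG/belt recordings following a
  three-phase breathing protocol (default 2 min at 11.1 bpm, 1 min at
  6.7 bpm, 1 min at 23.3 bpm), with ground-truth R/AO/AC and breath-peak
  times, plus Poisson list-mode streams.

## Worked example

```python
from scggate import (SimConfig, simulate_recording, simulate_listmode, pearson_r,
                     breathing_rate, match_cycles, assign_dual_gates,
                     cardiac_phase_labels, respiratory_phase_labels)
from scggate.cardiac import process_recording as process_cardiac
from scggate.respiratory import process_recording as process_resp

cfg = SimConfig(seed=1)          # 2 min normal + 1 min slow + 1 min fast breathing
rec, truth = simulate_recording(cfg)

fid, iv = process_cardiac(rec)   # ECG R peaks -> windowed AO/AC on the SCG z-axis
print(f"beats accepted: {fid.accepted.sum()}/{fid.n_beats}")
print(f"r(R-R, AO-AO) = {pearson_r(iv['RR'].values, iv['AO_AO'].values):.4f}")

adr, fs2, cycles = process_resp(rec, segment_spans=cfg.segment_spans())
_, _, belt = process_resp(rec, axis="belt", segment_spans=cfg.segment_spans())
for pattern in ("normal", "slow", "fast"):
    mean, sd = breathing_rate(cycles, pattern)
    print(f"{pattern:6s} breathing: {mean:5.2f} +/- {sd:.2f} bpm")
da, db = match_cycles(cycles, belt)
print(f"r(ADR, belt cycle durations) = {pearson_r(da, db):.4f}")

lm = simulate_listmode(rec.duration, rate=100.0, seed=2)
gated = assign_dual_gates(lm, respiratory_phase_labels(adr, fs2, cycles),
                          cardiac_phase_labels(fid, "auto"))
print(f"events gated: {len(lm) - gated.counts()['ungated']}/{len(lm)} into 12 gates")
```

Output:

```
beats accepted: 278/279
r(R-R, AO-AO) = 0.9999
normal breathing: 11.10 +/- 0.01 bpm
slow   breathing:  6.70 +/- 0.01 bpm
fast   breathing: 23.30 +/- 0.06 bpm
r(ADR, belt cycle durations) = 1.0000
events gated: 23651/23889 into 12 gates
```

The interval correlation near 1 says the mechanical (SCG) beat timing tracks
the electrical (ECG) timing; the per-pattern breathing rates recover the
simulator's configured rates; the ADR–belt duration correlation validates the
accelerometer as a respiration monitor; and the gate counts show every event
landing in exactly one of the 12 dual gates or the explicit ungated bin
(events before the first beat or outside labeled breathing cycles).

The same chain is scriptable from a shell via the `scggate` CLI
(`simulate`, `process-cardiac`, `process-resp`, `gate`, `validate`, and the
end-to-end `run`); try `scggate run --seed 1 --out-dir out/`.

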