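"""Synthetic cardiorespiratory signal generator with ground-truth annotations.

Emulates a supine subject wearing a sternal tri-axial accelerometer, a
single-lead ECG and a respiration belt, following a three-phase breathing
protocol (2 min normal, 1 min slow-paced, 1 min fast-paced by default).  The
seismocardiogram is modeled as the sum of two components:

* a large sub-Hz respiratory baseline from chest-wall motion — a smooth
  quasi-sinusoid whose instantaneous rate follows the breathing protocol,
  phase-continuous across pattern switches;
* sharp high-frequency (> 5 Hz) cardiac wavelets from valve activity: a
  dip-rise-dip wavelet whose global maximum marks aortic opening (AO) at a
  fixed electromechanical delay after each R peak, and an inverted,
  lower-amplitude rise-dip-rise wavelet whose global minimum marks aortic
  closure (AC) at the end of systole.

The lateral/longitudinal axes (x, y) carry the respiratory baseline with the
largest relative amplitude and only weak cardiac wavelets; the dorsoventral
z-axis carries the cardiac wavelets best.  The ECG is a train of narrow
positive QRS pulses; the belt shares the respiratory timing, delayed by a
mechanical lag, with independent sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ListModeStream, Recording

#: Relative respiratory-baseline amplitude per accelerometer axis.
AXIS_RESP_AMP = {"scg_x": 1.0, "scg_y": 0.8, "scg_z": 0.35}
#: Relative cardiac-wavelet amplitude per accelerometer axis.
AXIS_CARDIAC_AMP = {"scg_x": 0.12, "scg_y": 0.10, "scg_z": 1.0}
#: AC wavelet amplitude relative to the AO wavelet.
AC_RELATIVE_AMP = 0.6
#: Gaussian QRS pulse width (sd, seconds).
QRS_SD = 0.005


@dataclass
class ProtocolSegment:
    """One breathing-protocol segment: constant target rate and tidal amplitude."""

    duration: float          # s
    rate_bpm: float          # breaths per minute
    amplitude: float = 1.0   # tidal amplitude, a.u.
    rate_jitter_bpm: float = 0.0  # per-cycle rate jitter sd
    label: str = ""


def default_protocol() -> list[ProtocolSegment]:
    """Three-phase breathing protocol at the per-pattern mean rates."""
    return [
        ProtocolSegment(120.0, 11.1, 1.0, 0.0, "normal"),
        ProtocolSegment(60.0, 6.7, 1.15, 0.0, "slow"),
        ProtocolSegment(60.0, 23.3, 0.75, 0.0, "fast"),
    ]


@dataclass
class SimConfig:
    """Generator configuration.

    ``hrv_sd`` is the per-beat Gaussian RR jitter sd (truncated at +/- 3 sd,
    assuming a fairly normal sinus rhythm); ``r_ao_delay`` the R-to-AO
    electromechanical delay; ``ao_ac_interval`` the mean systole length with
    per-beat jitter ``ao_ac_jitter_sd``; ``wavelet_freq`` the cardiac wavelet
    carrier (inside the 20-40 Hz analysis band); ``noise_sd`` a scalar or
    per-channel map of white-noise sd; ``belt_lag`` the belt's mechanical
    delay relative to chest-wall motion.
    """

    fs: float = 800.0
    protocol: list[ProtocolSegment] = field(default_factory=default_protocol)
    mean_hr: float = 70.0          # bpm
    hrv_sd: float = 0.03           # s
    r_ao_delay: float = 0.05       # s
    ao_ac_interval: float = 0.30   # s
    ao_ac_jitter_sd: float = 0.005  # s
    wavelet_freq: float = 25.0     # Hz
    noise_sd: float | dict[str, float] = 0.02
    belt_lag: float = 0.15         # s
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.protocol:
            raise ValueError("protocol must contain at least one segment")
        for seg in self.protocol:
            if seg.duration <= 0 or seg.rate_bpm <= 0:
                raise ValueError("segment durations and rates must be positive")
            if seg.amplitude < 0 or seg.rate_jitter_bpm < 0:
                raise ValueError("segment amplitude and jitter must be nonnegative")
        if self.mean_hr <= 0 or self.hrv_sd < 0 or self.ao_ac_jitter_sd < 0:
            raise ValueError("heart-rate parameters must be positive/nonnegative")
        if self.wavelet_freq <= 5:
            raise ValueError("wavelet_freq must exceed 5 Hz (cardiac band)")
        shortest_rr = 60.0 / self.mean_hr - 3.0 * self.hrv_sd
        if self.r_ao_delay + self.ao_ac_interval + 3.0 * self.ao_ac_jitter_sd >= shortest_rr:
            raise ValueError("infeasible cardiac timing: systole does not fit the shortest RR")

    def segment_spans(self) -> list[tuple[float, float, str]]:
        """(start, end, label) spans of the protocol segments."""
        spans = []
        t = 0.0
        for seg in self.protocol:
            spans.append((t, t + seg.duration, seg.label))
            t += seg.duration
        return spans

    def total_duration(self) -> float:
        return sum(seg.duration for seg in self.protocol)

    def channel_noise_sd(self, name: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd.get(name, 0.0))
        return float(self.noise_sd)


@dataclass
class GroundTruth:
    """True event times emitted by the generator."""

    r_times: np.ndarray
    ao_times: np.ndarray
    ac_times: np.ndarray
    resp_peak_times: np.ndarray
    resp_peak_labels: np.ndarray
    segments: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        for name in ("r_times", "ao_times", "ac_times", "resp_peak_times"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        self.resp_peak_labels = np.asarray(self.resp_peak_labels, dtype=object)
        if not (np.all(self.r_times < self.ao_times) and np.all(self.ao_times < self.ac_times)):
            raise ValueError("beat ordering r < ao < ac violated")


def _trunc_normal(rng: np.random.Generator, sd: float) -> float:
    """Zero-mean Gaussian draw clipped at +/- 3 sd (0 when sd == 0)."""
    if sd <= 0:
        return 0.0
    return float(np.clip(rng.normal(0.0, sd), -3.0 * sd, 3.0 * sd))


@dataclass
class _BreathingSchedule:
    """Piecewise-linear breathing phase u(t), in cycles, plus per-cycle amplitude.

    The oscillator frequency follows the protocol *in time*: it switches at
    segment boundaries (the subject changes pace on command) while the phase
    stays continuous, and per-cycle rate jitter is redrawn at each cycle
    start.  The waveform is ``amplitude * sin(2*pi*u)``: the peak of cycle k
    sits at phase k + 0.25 and the troughs at k - 0.25 / k + 0.75.
    """

    piece_t: np.ndarray   # piece start times
    piece_u: np.ndarray   # phase at piece start
    piece_f: np.ndarray   # cycles/s within the piece
    cycle_amps: np.ndarray  # amplitude of cycle k
    peak_times: np.ndarray

    def phase_at(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        idx = np.clip(np.searchsorted(self.piece_t, times, side="right") - 1,
                      0, self.piece_t.size - 1)
        return self.piece_u[idx] + self.piece_f[idx] * (times - self.piece_t[idx])

    def baseline_at(self, times) -> np.ndarray:
        u = self.phase_at(times)
        k = np.clip(np.floor(u).astype(int), 0, self.cycle_amps.size - 1)
        return self.cycle_amps[k] * np.sin(2.0 * np.pi * u)


def _schedule_breathing(cfg: SimConfig, rng: np.random.Generator) -> _BreathingSchedule:
    spans = cfg.segment_spans()
    total = cfg.total_duration()
    piece_t, piece_u, piece_f = [], [], []
    cycle_amps, peaks = [], []
    t, u = 0.0, 0.0
    seg_idx = 0
    seg = cfg.protocol[0]
    jitter = _trunc_normal(rng, seg.rate_jitter_bpm)
    cycle_amps.append(seg.amplitude)
    while t < total - 1e-12:
        rate = max(seg.rate_bpm + jitter, 0.25 * seg.rate_bpm)
        f = rate / 60.0
        t_cycle = t + (np.floor(u + 1e-12) + 1.0 - u) / f
        t_seg = spans[seg_idx][1] if seg_idx < len(spans) - 1 else np.inf
        t_next = min(t_cycle, t_seg, total)
        u_peak = np.floor(u + 1e-12) + 0.25
        if u < u_peak <= u + f * (t_next - t) and t + (u_peak - u) / f < total:
            peaks.append(t + (u_peak - u) / f)
        piece_t.append(t)
        piece_u.append(u)
        piece_f.append(f)
        u += f * (t_next - t)
        t = t_next
        if t >= total - 1e-12:
            break
        if t == t_seg:
            seg_idx += 1
            seg = cfg.protocol[seg_idx]
            jitter = _trunc_normal(rng, seg.rate_jitter_bpm)
        if t == t_cycle:
            u = round(u)  # exact cycle boundary
            here = cfg.protocol[-1]
            for (a, b, _), s in zip(spans, cfg.protocol):
                if a <= t < b:
                    here = s
                    break
            jitter = _trunc_normal(rng, here.rate_jitter_bpm)
            cycle_amps.append(here.amplitude)
    return _BreathingSchedule(np.asarray(piece_t), np.asarray(piece_u),
                              np.asarray(piece_f), np.asarray(cycle_amps),
                              np.asarray(peaks))


def simulate_recording(cfg: SimConfig) -> tuple[Recording, GroundTruth]:
    """Generate a synchronized recording plus its ground truth.

    Same config and seed always produce identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    total = cfg.total_duration()
    n = int(round(total * fs))
    t = np.arange(n) / fs

    # Respiration: phase schedule, shared by accelerometer baseline and belt.
    schedule = _schedule_breathing(cfg, rng)
    resp_peaks = schedule.peak_times
    spans = cfg.segment_spans()

    def span_label(x: float) -> str:
        for a, b, lab in spans:
            if a <= x < b:
                return lab
        return spans[-1][2]

    resp_labels = np.array([span_label(p) for p in resp_peaks], dtype=object)
    baseline = schedule.baseline_at(t)
    belt_baseline = schedule.baseline_at(t - cfg.belt_lag)

    # Cardiac beat schedule: Gaussian RR jitter around 60/mean_hr, clipped +/- 3 sd.
    rr0 = 60.0 / cfg.mean_hr
    w_half = 0.75 / cfg.wavelet_freq  # wavelet half-span: 1.5 carrier cycles total
    r_list, ao_list, ac_list = [], [], []
    r = 0.5 * rr0
    while True:
        ao = r + cfg.r_ao_delay
        ac = ao + cfg.ao_ac_interval + _trunc_normal(rng, cfg.ao_ac_jitter_sd)
        if ac + w_half >= total:
            break
        r_list.append(r)
        ao_list.append(ao)
        ac_list.append(ac)
        r += rr0 + _trunc_normal(rng, cfg.hrv_sd)
    r_times = np.asarray(r_list)
    ao_times = np.asarray(ao_list)
    ac_times = np.asarray(ac_list)

    # Cardiac wavelets: Hann-windowed cosine, 1.5 carrier cycles long.  Even
    # symmetry about the center puts the global extremum exactly at the
    # fiducial time and keeps it there under zero-phase band-pass filtering.
    cardiac = np.zeros(n)

    def add_wavelet(center: float, amp: float) -> None:
        i0 = max(0, int(np.ceil((center - w_half) * fs)))
        i1 = min(n - 1, int(np.floor((center + w_half) * fs)))
        if i0 > i1:
            return
        tau = t[i0:i1 + 1] - center
        window = np.cos(np.pi * tau / (2.0 * w_half)) ** 2
        cardiac[i0:i1 + 1] += amp * window * np.cos(2.0 * np.pi * cfg.wavelet_freq * tau)

    for ao, ac in zip(ao_times, ac_times):
        add_wavelet(ao, 1.0)
        add_wavelet(ac, -AC_RELATIVE_AMP)

    ecg = np.zeros(n)
    for r_t in r_times:
        i0 = max(0, int(np.ceil((r_t - 5 * QRS_SD) * fs)))
        i1 = min(n - 1, int(np.floor((r_t + 5 * QRS_SD) * fs)))
        tau = t[i0:i1 + 1] - r_t
        ecg[i0:i1 + 1] += np.exp(-0.5 * (tau / QRS_SD) ** 2)

    channels: dict[str, np.ndarray] = {}
    for axis in ("scg_x", "scg_y", "scg_z"):
        channels[axis] = (
            AXIS_RESP_AMP[axis] * baseline
            + AXIS_CARDIAC_AMP[axis] * cardiac
            + rng.normal(0.0, cfg.channel_noise_sd(axis), n)
        )
    channels["ecg"] = ecg + rng.normal(0.0, cfg.channel_noise_sd("ecg"), n)
    channels["belt"] = belt_baseline + rng.normal(0.0, cfg.channel_noise_sd("belt"), n)

    rec = Recording(fs=fs, channels=channels, units={k: "a.u." for k in channels})
    truth = GroundTruth(
        r_times=r_times,
        ao_times=ao_times,
        ac_times=ac_times,
        resp_peak_times=resp_peaks,
        resp_peak_labels=resp_labels,
        segments=spans,
    )
    return rec, truth


def simulate_listmode(duration: float, rate: float, seed: int) -> ListModeStream:
    """Homogeneous Poisson event stream on [0, duration) at `rate` events/s."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, n))
    return ListModeStream(times)


def ground_truth_frame(truth: GroundTruth) -> pd.DataFrame:
    """Long-format table of ground-truth events (event_type, time_s, segment_label)."""
    spans = truth.segments

    def label(x: float) -> str:
        for a, b, lab in spans:
            if a <= x < b:
                return lab
        return spans[-1][2]

    rows = []
    for kind, times in (("R", truth.r_times), ("AO", truth.ao_times), ("AC", truth.ac_times)):
        rows.extend({"event_type": kind, "time_s": x, "segment_label": label(x)} for x in times)
    rows.extend(
        {"event_type": "RESP_PEAK", "time_s": x, "segment_label": lab}
        for x, lab in zip(truth.resp_peak_times, truth.resp_peak_labels)
    )
    frame = pd.DataFrame(rows, columns=["event_type", "time_s", "segment_label"])
    return frame.sort_values("time_s", kind="stable").reset_index(drop=True)
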