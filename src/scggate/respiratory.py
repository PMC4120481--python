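"""Accelerometer-derived respiration (ADR) extraction and cycle features.

The sub-Hz chest-wall motion is separated from the cardiac wavelets in the
time domain: the channel is downsampled to half rate (800 -> 400 Hz) behind an
anti-alias low-pass, then a 1-D median filter strips the sharp high-frequency
cardiac transients, and a moving average smooths the remainder — a frequency-
domain filter handles the rate-varying breathing patterns poorly, which is why
the chain is time-domain.  Respiratory cycles are the peak-to-peak intervals
of the resulting ADR signal (or of the belt channel passed through the same
chain), detected with a minimum-height / minimum-separation peak detector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .cardiac import _greedy_peaks
from .core_io import Recording

logger = logging.getLogger(__name__)

#: Per-pattern peak-detection settings (min_height in z-units, min_separation s).
PATTERN_PEAK_SETTINGS = {
    "normal": (0.3, 2.0),
    "slow": (0.3, 4.0),
    "fast": (0.3, 1.2),
}


@dataclass
class AdrFilterConfig:
    """Median / moving-average window lengths, seconds (applied at the
    downsampled rate).  Defaults suppress the > 5 Hz cardiac content while
    passing breathing at up to ~0.5 Hz; real subjects need per-recording
    tuning, so both are exposed on the command line."""

    median_window: float = 0.5
    ma_window: float = 0.75

    def __post_init__(self) -> None:
        if self.median_window <= 0 or self.ma_window <= 0:
            raise ValueError("filter windows must be positive")


@dataclass
class RespCycleSet:
    """Respiratory peaks and the derived peak-to-peak cycle durations."""

    peak_times: np.ndarray
    peak_amplitudes: np.ndarray
    source: str = "adr_x"
    segments: np.ndarray | None = None  # per-peak protocol label

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if self.peak_amplitudes.size != self.peak_times.size:
            raise ValueError("amplitudes must match peak count")
        if self.peak_times.size > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")
        if self.segments is not None:
            self.segments = np.asarray(self.segments, dtype=object)
            if self.segments.size != self.peak_times.size:
                raise ValueError("segment labels must match peak count")

    @property
    def cycle_durations(self) -> np.ndarray:
        return np.diff(self.peak_times)

    def __len__(self) -> int:
        return self.peak_times.size


def downsample_half(x, fs: float) -> tuple[np.ndarray, float]:
    """Decimate by 2 behind a zero-phase FIR anti-alias low-pass.

    The explicit anti-alias stage keeps cardiac-band energy from folding into
    the respiratory band.  800 Hz input yields a 400 Hz output.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("signal too short to downsample")
    ntaps = min(101, ((x.size - 1) // 3) | 1)
    if ntaps < 5:
        return x[::2], fs / 2.0  # too short for filtering; decimate directly
    taps = signal.firwin(ntaps, 0.5)  # cutoff at the new Nyquist, fs/4
    y = signal.filtfilt(taps, [1.0], x)  # zero phase; odd extension at edges
    return y[::2], fs / 2.0


def median_filter_1d(x, window: float, fs: float) -> np.ndarray:
    """Sliding-window median, odd window length (rounded up), reflected edges."""
    x = np.asarray(x, dtype=float)
    k = max(1, int(round(window * fs)))
    if k % 2 == 0:
        k += 1
    return ndimage.median_filter(x, size=k, mode="reflect")


def moving_average(x, window: float, fs: float) -> np.ndarray:
    """Centered moving mean with reflection padding; output length preserved.

    For an even window of k samples the window covers ``[i, i + k - 1]``
    shifted left by ``(k - 1) // 2``, i.e. the extra sample sits on the right.
    """
    x = np.asarray(x, dtype=float)
    k = max(1, int(round(window * fs)))
    pad_left = (k - 1) // 2
    pad_right = k // 2
    padded = np.pad(x, (pad_left, pad_right), mode="symmetric")
    return np.convolve(padded, np.full(k, 1.0 / k), mode="valid")


def extract_adr(rec: Recording, axis: str = "scg_x",
                cfg: AdrFilterConfig | None = None) -> tuple[np.ndarray, float]:
    """ADR signal from one accelerometer axis (or the belt channel).

    Chain order is fixed: downsample -> median filter -> moving average; the
    median must run first so that sharp cardiac transients never smear into
    the average.
    """
    cfg = cfg or AdrFilterConfig()
    if axis not in rec.channels:
        raise ValueError(f"recording has no channel {axis!r}")
    y, fs2 = downsample_half(rec.channels[axis], rec.fs)
    y = median_filter_1d(y, cfg.median_window, fs2)
    y = moving_average(y, cfg.ma_window, fs2)
    return y, fs2


def detect_resp_peaks(x, fs: float, min_height: float = 0.3,
                      min_separation: float = 2.0, t0: float = 0.0,
                      source: str = "adr_x") -> RespCycleSet:
    """Respiratory peaks by minimum height and minimum separation.

    Same greedy contract as the R-peak detector; the input is expected to be
    z-score normalized so ``min_height`` is in sd units.
    """
    x = np.asarray(x, dtype=float)
    idx = _greedy_peaks(x, fs, min_height, min_separation)
    return RespCycleSet(t0 + idx / fs, x[idx], source=source)


def label_segments(cycles: RespCycleSet, segment_spans) -> RespCycleSet:
    """Attach a protocol label to each peak from ``(start, end, label)`` spans."""
    labels = np.full(len(cycles), None, dtype=object)
    for start, end, lab in segment_spans:
        inside = (cycles.peak_times >= start) & (cycles.peak_times < end)
        labels[inside] = lab
    cycles.segments = labels
    return cycles


def breathing_rate(cycles: RespCycleSet, segment: str | None = None) -> tuple[float, float]:
    """Mean and sample sd of the instantaneous breathing rate, bpm.

    Each cycle contributes ``60 / duration``.  When ``segment`` is given, only
    cycles with *both* bounding peaks inside that segment count, so a cycle
    straddling a pattern switch never contaminates either pattern's rate.
    """
    times = cycles.peak_times
    if segment is not None:
        if cycles.segments is None:
            raise ValueError("cycles carry no segment labels")
        keep = cycles.segments == segment
        times = times[keep]
    if times.size < 2:
        raise ValueError("need at least 2 peaks in the segment")
    rates = 60.0 / np.diff(times)
    sd = float(np.std(rates, ddof=1)) if rates.size > 1 else float("nan")
    return float(np.mean(rates)), sd


def match_cycles(a: RespCycleSet, b: RespCycleSet,
                 max_lag: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Pair cycle durations across two detectors of the same breathing.

    Peaks are paired greedily by smallest absolute time difference within
    ``max_lag`` seconds (each peak used at most once); a duration pair is
    emitted wherever two *adjacent* peaks of one set are matched to two
    adjacent peaks of the other.  Unpaired peaks are dropped with a logged
    count.  The two returned arrays have equal length.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both cycle sets must be nonempty")
    dt = np.abs(a.peak_times[:, None] - b.peak_times[None, :])
    ia, ib = np.nonzero(dt <= max_lag)
    order = np.argsort(dt[ia, ib], kind="stable")
    used_a: dict[int, int] = {}
    used_b: set[int] = set()
    for i, j in zip(ia[order], ib[order]):
        if i in used_a or j in used_b:
            continue
        used_a[i] = j
        used_b.add(j)
    dropped = (len(a) - len(used_a)) + (len(b) - len(used_b))
    if dropped:
        logger.info("match_cycles: %d unpaired peaks dropped", dropped)
    pairs = sorted(used_a.items())
    dur_a, dur_b = [], []
    for (i0, j0), (i1, j1) in zip(pairs[:-1], pairs[1:]):
        if i1 == i0 + 1 and j1 == j0 + 1:
            dur_a.append(a.peak_times[i1] - a.peak_times[i0])
            dur_b.append(b.peak_times[j1] - b.peak_times[j0])
    return np.asarray(dur_a), np.asarray(dur_b)


def process_recording(rec: Recording, axis: str = "scg_x",
                      cfg: AdrFilterConfig | None = None,
                      segment_spans=None,
                      pattern_settings: dict | None = None,
                      source: str | None = None,
                      edge_guard: float = 1.0):
    """Full respiratory chain: returns ``(adr_z, fs2, RespCycleSet)``.

    Extracts and z-scores the ADR signal, then detects peaks — per protocol
    segment with that pattern's settings when ``segment_spans`` (``(start,
    end, label)``) are given, otherwise globally with the normal-pattern
    defaults — and labels the peaks with their segment.  Peaks within
    ``edge_guard`` seconds of either end of the recording are discarded:
    reflection padding can fabricate an extremum against the signal edge.
    """
    from .core_io import normalize_zscore

    adr, fs2 = extract_adr(rec, axis=axis, cfg=cfg)
    z = normalize_zscore(adr)
    settings = pattern_settings or PATTERN_PEAK_SETTINGS
    source = source or (axis if axis == "belt" else f"adr_{axis.split('_')[-1]}")

    def trim(cycles: RespCycleSet) -> RespCycleSet:
        lo = rec.t0 + edge_guard
        hi = rec.t0 + z.size / fs2 - edge_guard
        keep = (cycles.peak_times >= lo) & (cycles.peak_times <= hi)
        return RespCycleSet(cycles.peak_times[keep], cycles.peak_amplitudes[keep],
                            source=cycles.source)

    if segment_spans is None:
        cycles = trim(detect_resp_peaks(z, fs2, *settings.get("normal", (0.3, 2.0)),
                                        t0=rec.t0, source=source))
        return z, fs2, cycles
    peak_times, peak_amps = [], []
    for start, end, lab in segment_spans:
        i0 = max(0, int(np.ceil((start - rec.t0) * fs2)))
        i1 = min(z.size, int(np.ceil((end - rec.t0) * fs2)))
        if i1 - i0 < 2:
            continue
        height, sep = settings.get(lab, (0.3, 2.0))
        part = detect_resp_peaks(z[i0:i1], fs2, height, sep,
                                 t0=rec.t0 + i0 / fs2, source=source)
        peak_times.append(part.peak_times)
        peak_amps.append(part.peak_amplitudes)
    times = np.concatenate(peak_times) if peak_times else np.empty(0)
    amps = np.concatenate(peak_amps) if peak_amps else np.empty(0)
    cycles = trim(RespCycleSet(times, amps, source=source))
    label_segments(cycles, segment_spans)
    return z, fs2, cycles
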