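"""Cardiac-channel processing: band-pass filtering, R-peak and AO/AC detection.

The electrical beat anchor (ECG R peak) is detected first; time-domain windows
around each R peak then localize the mechanical fiducials on the band-passed
seismocardiogram z-axis: aortic opening (AO) as the windowed maximum shortly
after R, aortic closure (AC) as the windowed minimum between AO and the next
R.  From the fiducials the electromechanical interval series R-R, R-AO, R-AC,
AO-AO and AO-AC are derived, plus the cardiac-cycle percentage
(100 * R-AC / R-R) and heart-rate-variability quality flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

logger = logging.getLogger(__name__)

#: Default analysis bands, Hz.
SCG_BAND = (20.0, 40.0)
ECG_BAND = (1.0, 40.0)


@dataclass
class WindowParams:
    """AO/AC search-window geometry, seconds.

    The AO window spans ``[r - pre_r, r + post_r]``; the AC window spans
    ``[ao + ac_search_start, r_next - ac_search_end]`` (longer, since AC
    timing after AO is more uncertain).  With ``scale_with_rr`` the offsets
    scale linearly with the local RR relative to ``ref_rr``, adapting window
    length to heart rate.
    """

    pre_r: float = 0.10
    post_r: float = 0.20
    ac_search_start: float = 0.15
    ac_search_end: float = 0.20
    scale_with_rr: bool = False
    ref_rr: float = 0.857  # 70 bpm

    def __post_init__(self) -> None:
        if min(self.pre_r, self.post_r, self.ac_search_start, self.ac_search_end) < 0:
            raise ValueError("window offsets must be nonnegative")
        if self.ref_rr <= 0:
            raise ValueError("ref_rr must be positive")


@dataclass
class FiducialSet:
    """Per-beat cardiac event times with a per-beat quality flag.

    ``ao_times`` / ``ac_times`` hold NaN where a fiducial could not be
    localized; such beats are flagged rejected rather than dropped so that
    beat indices stay aligned.
    """

    r_times: np.ndarray
    ao_times: np.ndarray
    ac_times: np.ndarray
    accepted: np.ndarray

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        self.ao_times = np.asarray(self.ao_times, dtype=float)
        self.ac_times = np.asarray(self.ac_times, dtype=float)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        n = self.r_times.size
        if not (self.ao_times.size == self.ac_times.size == self.accepted.size == n):
            raise ValueError("fiducial arrays must have equal length")
        if n > 1 and np.any(np.diff(self.r_times) <= 0):
            raise ValueError("r_times must be strictly increasing")
        for k in np.flatnonzero(self.accepted):
            r, ao, ac = self.r_times[k], self.ao_times[k], self.ac_times[k]
            if not (r < ao < ac):
                raise ValueError(f"accepted beat {k} violates r < ao < ac")
            if k + 1 < n and not ac < self.r_times[k + 1]:
                raise ValueError(f"accepted beat {k} has AC beyond the next R")

    @property
    def n_beats(self) -> int:
        return self.r_times.size

    def accepted_indices(self) -> np.ndarray:
        return np.flatnonzero(self.accepted)

    def reject(self, indices) -> None:
        self.accepted[np.asarray(indices, dtype=int)] = False


@dataclass
class IntervalSeries:
    """One named beat-to-beat interval sequence, seconds."""

    name: str
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and np.any(self.values <= 0):
            raise ValueError(f"{self.name} intervals must be positive")

    def __len__(self) -> int:
        return self.values.size


def fft_bandpass(x, fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase brick-wall band-pass: FFT bins with |f| outside [lo, hi] zeroed.

    A frequency-domain projection introduces no group delay, so fiducial
    timing is preserved; it is idempotent and passes exact-bin tones
    unchanged.  Edge ringing is accepted (analyses exclude the first/last
    second of a recording).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("signal too short to filter")
    if not (0 <= lo < hi):
        raise ValueError("need 0 <= lo < hi")
    if hi > fs / 2:
        raise ValueError("hi exceeds the Nyquist frequency")
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    spectrum[(freqs < lo) | (freqs > hi)] = 0.0
    return np.fft.irfft(spectrum, x.size)


def _greedy_peaks(x: np.ndarray, fs: float, min_height: float, min_separation: float) -> np.ndarray:
    """Local maxima >= min_height with greedy descending-amplitude suppression."""
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    distance = max(1, int(round(min_separation * fs)))
    idx, _ = signal.find_peaks(np.asarray(x, dtype=float), height=min_height, distance=distance)
    return idx


def detect_r_peaks(ecg, fs: float, min_height: float = 2.0, min_separation: float = 0.4,
                   t0: float = 0.0) -> np.ndarray:
    """R-peak times on a band-passed (1-40 Hz), z-scored ECG.

    Candidates are local maxima at least ``min_height`` high, accepted
    greedily in descending amplitude while suppressing any candidate within
    ``min_separation`` seconds of an already accepted peak.
    """
    idx = _greedy_peaks(ecg, fs, min_height, min_separation)
    return t0 + idx / fs


def detect_ao_ac(scg_z_filtered, fs: float, r_times, wp: WindowParams | None = None,
                 t0: float = 0.0) -> FiducialSet:
    """Windowed AO/AC detection on the band-passed SCG z-axis.

    Per beat, AO is the signal maximum on ``[r - pre_r, r + post_r]`` and AC
    the minimum on ``[ao + ac_search_start, r_next - ac_search_end]`` (window
    offsets optionally scaled by the local RR).  Beats whose windows are empty
    or whose ordering violates ``r < ao < ac < r_next`` are flagged rejected,
    never silently dropped.  Ties in argmax/argmin resolve to the earliest
    sample.
    """
    x = np.asarray(scg_z_filtered, dtype=float)
    wp = wp or WindowParams()
    r_times = np.asarray(r_times, dtype=float)
    n_beats = r_times.size
    if n_beats == 0:
        return FiducialSet(np.empty(0), np.empty(0), np.empty(0), np.empty(0, dtype=bool))
    if fs <= 0:
        raise ValueError("fs must be positive")

    def window_indices(lo_t: float, hi_t: float) -> tuple[int, int]:
        i0 = max(0, int(np.ceil((lo_t - t0) * fs)))
        i1 = min(x.size - 1, int(np.floor((hi_t - t0) * fs)))
        return i0, i1

    ao = np.full(n_beats, np.nan)
    ac = np.full(n_beats, np.nan)
    ok = np.zeros(n_beats, dtype=bool)
    for k in range(n_beats):
        r = r_times[k]
        r_next = r_times[k + 1] if k + 1 < n_beats else None
        if wp.scale_with_rr:
            if r_next is not None:
                rr = r_next - r
            elif k > 0:
                rr = r - r_times[k - 1]
            else:
                rr = wp.ref_rr
            scale = rr / wp.ref_rr
        else:
            scale = 1.0
        i0, i1 = window_indices(r - wp.pre_r * scale, r + wp.post_r * scale)
        if i0 > i1:
            continue
        ao_idx = i0 + int(np.argmax(x[i0:i1 + 1]))
        ao[k] = t0 + ao_idx / fs
        if r_next is None:
            continue  # no window for AC: beat stays rejected
        j0, j1 = window_indices(ao[k] + wp.ac_search_start * scale,
                                r_next - wp.ac_search_end * scale)
        if j0 > j1:
            continue
        ac_idx = j0 + int(np.argmin(x[j0:j1 + 1]))
        ac[k] = t0 + ac_idx / fs
        ok[k] = r < ao[k] < ac[k] < r_next
    rejected = int(n_beats - ok.sum())
    if rejected:
        logger.info("detect_ao_ac: %d of %d beats rejected", rejected, n_beats)
    return FiducialSet(r_times, ao, ac, ok)


def compute_intervals(fid: FiducialSet) -> dict[str, IntervalSeries]:
    """Electromechanical interval series over accepted beats.

    Pairwise series (RR, AO_AO) difference consecutive accepted beats and have
    one fewer entry than the per-beat series (R_AO, R_AC, AO_AC); with fewer
    than two accepted beats they are empty.
    """
    acc = fid.accepted_indices()
    r = fid.r_times[acc]
    ao = fid.ao_times[acc]
    ac = fid.ac_times[acc]
    return {
        "RR": IntervalSeries("RR", np.diff(r)),
        "AO_AO": IntervalSeries("AO_AO", np.diff(ao)),
        "R_AO": IntervalSeries("R_AO", ao - r),
        "R_AC": IntervalSeries("R_AC", ac - r),
        "AO_AC": IntervalSeries("AO_AC", ac - ao),
    }


def cardiac_cycle_percentage(r_ac: IntervalSeries, rr: IntervalSeries) -> np.ndarray:
    """Percentage of each cardiac cycle elapsed at aortic closure: 100 * R-AC / R-R."""
    n = len(rr)
    if len(r_ac) < n:
        raise ValueError("R_AC series shorter than RR series")
    return 100.0 * r_ac.values[:n] / rr.values


def flag_hrv_outliers(rr: IntervalSeries, tol_frac: float = 0.2,
                      window_beats: int = 11) -> np.ndarray:
    """Accept flags on an RR series based on an acceptable variability range.

    An interval is rejected when it deviates from the running median (window
    of ``window_beats`` beats, reflected edges) by more than ``tol_frac``
    times that median.  Returns a boolean accept mask aligned with the series.
    """
    if not 0 < tol_frac < 1:
        raise ValueError("tol_frac must lie in (0, 1)")
    values = rr.values
    if values.size == 0:
        return np.empty(0, dtype=bool)
    size = min(window_beats, values.size)
    if size % 2 == 0:
        size = max(1, size - 1)
    med = ndimage.median_filter(values, size=size, mode="reflect")
    return np.abs(values - med) <= tol_frac * med


def apply_hrv_flags(fid: FiducialSet, rr_accept: np.ndarray) -> None:
    """Merge RR-outlier flags into the fiducial quality flags.

    The interval ``RR_k`` spans accepted beats (k, k+1); an outlying interval
    rejects its terminating beat so that the remaining series stays causal.
    """
    acc = fid.accepted_indices()
    if rr_accept.size != max(acc.size - 1, 0):
        raise ValueError("flag length does not match the accepted RR series")
    fid.reject(acc[1:][~rr_accept])


def process_recording(rec, scg_band=SCG_BAND, ecg_band=ECG_BAND,
                      wp: WindowParams | None = None,
                      r_min_height: float = 2.0, r_min_separation: float = 0.4,
                      hrv_tol: float = 0.2, axis: str = "scg_z"):
    """Full cardiac chain on a recording: returns ``(FiducialSet, intervals)``.

    Normalizes and band-pass filters the ECG (1-40 Hz) and the SCG axis
    (20-40 Hz), detects R peaks, localizes AO/AC, applies the HRV quality
    screen, and recomputes the interval series over the surviving beats.
    """
    from .core_io import normalize_zscore

    if axis not in rec.channels:
        raise ValueError(f"recording has no channel {axis!r}")
    if "ecg" not in rec.channels:
        raise ValueError("recording has no channel 'ecg'")
    ecg = fft_bandpass(normalize_zscore(rec.channels["ecg"]), rec.fs, *ecg_band)
    ecg = normalize_zscore(ecg)
    scg = fft_bandpass(normalize_zscore(rec.channels[axis]), rec.fs, *scg_band)
    r_times = detect_r_peaks(ecg, rec.fs, r_min_height, r_min_separation, t0=rec.t0)
    fid = detect_ao_ac(scg, rec.fs, r_times, wp, t0=rec.t0)
    intervals = compute_intervals(fid)
    if len(intervals["RR"]):
        apply_hrv_flags(fid, flag_hrv_outliers(intervals["RR"], tol_frac=hrv_tol))
        intervals = compute_intervals(fid)
    return fid, intervals
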