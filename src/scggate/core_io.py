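"""Data model and plain-text I/O for synchronized recordings and list-mode streams.

A :class:`Recording` bundles equal-length channel vectors (tri-axial
seismocardiogram ``scg_x``/``scg_y``/``scg_z``, single-lead ``ecg``, and a
respiration-belt channel ``belt``) sampled at a common rate.  Sample ``i`` of
every channel maps to time ``t0 + i / fs`` (0-based).  A
:class:`ListModeStream` is a nondecreasing sequence of event timestamps, the
offline stand-in for PET list-mode coincidences.

Files are plain CSV: one header line, comma separated, ``.`` decimal, with the
sampling rate (and optionally ``t0`` / units) carried in leading ``# key=value``
comment lines.  List-mode files hold one ``time_s`` value per line; extra
payload columns are preserved verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Channel names with a defined physical meaning.  Any subset may be present.
KNOWN_CHANNELS = ("scg_x", "scg_y", "scg_z", "ecg", "belt")

#: Column names treated as a time axis and ignored on read (reconstructed from fs).
_TIME_COLUMNS = ("t", "time", "time_s")


@dataclass
class Recording:
    """Synchronized multichannel time series.

    Parameters
    ----------
    fs:
        Sampling rate in Hz, > 0.
    channels:
        Mapping of channel name to 1-D sample vector; all vectors must have
        identical length >= 1.
    t0:
        Time of sample 0 in seconds.
    units:
        Optional per-channel unit strings (informational only; amplitudes are
        treated as arbitrary units throughout).
    """

    fs: float
    channels: dict[str, np.ndarray]
    t0: float = 0.0
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError("sampling rate must be a positive finite number")
        if not self.channels:
            raise ValueError("recording has no channels")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {v.size for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"channel lengths differ: {sorted(lengths)}")
        if lengths == {0}:
            raise ValueError("channels must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration(self) -> float:
        """Total covered time span in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds: ``t0 + i / fs``."""
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class ListModeStream:
    """Timestamped event stream with optional opaque per-event payload."""

    event_times: np.ndarray
    payload: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.event_times.ndim != 1:
            raise ValueError("event_times must be 1-D")
        if self.event_times.size and not np.all(np.isfinite(self.event_times)):
            raise ValueError("event timestamps must be finite")
        if self.event_times.size > 1 and np.any(np.diff(self.event_times) < 0):
            raise ValueError("event timestamps must be nondecreasing")
        if self.payload is not None and len(self.payload) != self.event_times.size:
            raise ValueError("payload length does not match event count")

    def __len__(self) -> int:
        return self.event_times.size


def _read_meta(path) -> dict[str, str]:
    """Parse leading ``# key=value`` comment lines."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
    return meta


def read_recording(path, spec: dict | None = None) -> Recording:
    """Read a recording CSV.

    ``spec`` may supply ``fs`` / ``t0`` overrides and a ``columns`` mapping of
    CSV column name to channel name (columns mapped this way are always kept;
    otherwise only :data:`KNOWN_CHANNELS` are recognized).  Unknown columns are
    ignored with a logged warning.  A missing sampling rate or ragged columns
    raise :class:`ValueError`.
    """
    spec = spec or {}
    meta = _read_meta(path)
    if "fs" in spec:
        fs = float(spec["fs"])
    elif "fs" in meta:
        fs = float(meta["fs"])
    else:
        raise ValueError("sampling rate unspecified")
    t0 = float(spec.get("t0", meta.get("t0", 0.0)))

    units: dict[str, str] = {}
    if "units" in meta:
        for item in meta["units"].split(";"):
            if ":" in item:
                name, unit = item.split(":", 1)
                units[name.strip()] = unit.strip()

    df = pd.read_csv(path, comment="#")
    mapping = dict(spec.get("columns", {}))
    channels: dict[str, np.ndarray] = {}
    for col in df.columns:
        if col in mapping:
            name = mapping[col]
        elif col in KNOWN_CHANNELS:
            name = col
        elif col in _TIME_COLUMNS:
            continue
        else:
            logger.warning("ignoring unknown column %r in %s", col, path)
            continue
        values = df[col].to_numpy(dtype=float)
        if np.any(np.isnan(values)):
            raise ValueError(f"ragged or missing values in column {col!r}")
        channels[name] = values
    if not channels:
        raise ValueError("no recognized channels in file")
    return Recording(fs=fs, channels=channels, t0=t0, units=units)


def write_recording(rec: Recording, path) -> None:
    """Write a recording CSV (round-trips with :func:`read_recording`)."""
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(f"# t0={rec.t0!r}\n")
        if rec.units:
            fh.write("# units=" + ";".join(f"{k}:{v}" for k, v in rec.units.items()) + "\n")
        df = pd.DataFrame({"t": rec.times(), **rec.channels})
        df.to_csv(fh, index=False, float_format="%.12g")


def read_listmode(path) -> ListModeStream:
    """Read a list-mode stream (one timestamp per line, optional payload columns).

    Non-monotone input is sorted with a logged warning rather than rejected:
    acquisition glitches should not abort a gating pipeline.
    """
    try:
        with open(path) as fh:
            first = None
            for line in fh:
                stripped = line.strip()
                if stripped and not stripped.startswith("#"):
                    first = stripped
                    break
        if first is None:
            return ListModeStream(np.empty(0))
        has_header = any(c.isalpha() for c in first)
        df = pd.read_csv(path, comment="#", header=0 if has_header else None)
    except pd.errors.EmptyDataError:
        return ListModeStream(np.empty(0))
    if df.empty:
        return ListModeStream(np.empty(0))
    if not has_header:
        df.columns = ["time_s"] + [f"payload_{i}" for i in range(1, df.shape[1])]
    times = df.iloc[:, 0].to_numpy(dtype=float)
    payload = df.iloc[:, 1:] if df.shape[1] > 1 else None
    if times.size > 1 and np.any(np.diff(times) < 0):
        logger.warning("non-monotone list-mode timestamps in %s: sorting", path)
        order = np.argsort(times, kind="stable")
        times = times[order]
        if payload is not None:
            payload = payload.iloc[order].reset_index(drop=True)
    return ListModeStream(times, payload)


def write_listmode(stream: ListModeStream, path) -> None:
    """Write a list-mode stream CSV with a ``time_s`` column plus any payload."""
    df = pd.DataFrame({"time_s": stream.event_times})
    if stream.payload is not None:
        for col in stream.payload.columns:
            df[col] = stream.payload[col].to_numpy()
    df.to_csv(path, index=False, float_format="%.12g")


def normalize_zscore(x) -> np.ndarray:
    """Zero-mean, unit-variance normalization (population sd, ddof=0).

    Population sd is used so that e.g. ``[-1, 1]`` is a fixed point; the
    operation is idempotent.  Constant input has no defined scale and raises.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to normalize")
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate constant signal")
    return (x - x.mean()) / sd
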