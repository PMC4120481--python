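"""Dual gating: respiratory phases R1-R3 x cardiac phases 1-4 -> gates G1-G12.

Respiratory phases are amplitude bands: within each breathing cycle
(delimited trough-to-trough, containing one peak) the ADR amplitude is
normalized to [0, 1] and split at two thresholds — the top band R1 covers the
crest (inspiration), the middle band R2 the transition, the bottom band R3
the trough (expiration).  Cardiac phases anchor at aortic opening: three
constant systole sub-intervals of S/3 each, then a time-varying diastole
interval lasting until the next beat's anchor.  A list-mode event in
respiratory band i and cardiac phase j lands in gate G(4*(i-1)+j); events in
time not covered by both labelings are kept in an explicit ungated bin, and
the twelve gated streams are written to twelve list-mode files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cardiac import FiducialSet
from .core_io import ListModeStream, write_listmode
from .respiratory import RespCycleSet

logger = logging.getLogger(__name__)

N_RESP_PHASES = 3
N_CARDIAC_PHASES = 4
N_GATES = N_RESP_PHASES * N_CARDIAC_PHASES

RESP_LABELS = ("R1", "R2", "R3")


@dataclass
class PhaseLabeling:
    """Ordered, non-overlapping half-open time spans ``(start, end, label)``."""

    spans: list[tuple[float, float, object]]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end, _ in self.spans:
            if not start < end:
                raise ValueError("spans must have positive length")
            if start < prev_end:
                raise ValueError("spans must be ordered and non-overlapping")
            prev_end = end

    def label_at(self, times) -> np.ndarray:
        """Label of the span containing each time (None where unlabeled)."""
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, None, dtype=object)
        if not self.spans:
            return out
        starts = np.array([s for s, _, _ in self.spans])
        ends = np.array([e for _, e, _ in self.spans])
        labels = np.array([lab for _, _, lab in self.spans], dtype=object)
        idx = np.searchsorted(starts, times, side="right") - 1
        valid = (idx >= 0) & (times < ends[np.clip(idx, 0, None)])
        out[valid] = labels[idx[valid]]
        return out


@dataclass
class GatedListMode:
    """Events with a per-event gate id (1..12) or 0 for ungated."""

    event_times: np.ndarray
    gate_ids: np.ndarray
    payload: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.gate_ids = np.asarray(self.gate_ids, dtype=int)
        if self.gate_ids.size != self.event_times.size:
            raise ValueError("gate_ids must match event count")
        if self.gate_ids.size and not np.all((self.gate_ids >= 0) & (self.gate_ids <= N_GATES)):
            raise ValueError("gate ids must lie in 0..12")

    def counts(self) -> dict[str, int]:
        """Event count per gate (keys G01..G12 and 'ungated'); sums to the total."""
        out = {f"G{g:02d}": int(np.sum(self.gate_ids == g)) for g in range(1, N_GATES + 1)}
        out["ungated"] = int(np.sum(self.gate_ids == 0))
        return out

    def events_in_gate(self, gate: int) -> np.ndarray:
        return self.event_times[self.gate_ids == gate]


def respiratory_phase_labels(adr, fs: float, cycles: RespCycleSet,
                             thresholds: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
                             t0: float = 0.0) -> PhaseLabeling:
    """Amplitude-band respiratory phase labeling of an ADR (or belt) signal.

    Cycles are delimited trough-to-trough around each detected peak (the
    troughs flanking the first/last peak are taken at the signal edges).
    Within a cycle the amplitude is normalized to [0, 1] between the cycle
    minimum and the peak; samples at or above the upper threshold are R1,
    between the thresholds R2, below the lower threshold R3.  A degenerate
    cycle (peak == trough) is labeled R3 entirely, with a warning.
    """
    t1, t2 = thresholds
    if not 0 < t1 < t2 < 1:
        raise ValueError("need 0 < t1 < t2 < 1")
    x = np.asarray(adr, dtype=float)
    if len(cycles) == 0:
        raise ValueError("cycle set is empty")
    pk = np.clip(np.round((cycles.peak_times - t0) * fs).astype(int), 0, x.size - 1)

    troughs = [int(np.argmin(x[: pk[0] + 1]))]
    for a, b in zip(pk[:-1], pk[1:]):
        troughs.append(a + int(np.argmin(x[a:b + 1])))
    troughs.append(pk[-1] + int(np.argmin(x[pk[-1]:])))

    labels = np.full(x.size, None, dtype=object)
    for i, p in enumerate(pk):
        a, b = troughs[i], troughs[i + 1]
        stop = b + 1 if i == len(pk) - 1 else b  # last cycle keeps its final trough sample
        if stop <= a:
            continue
        lo = float(x[a:stop].min())
        hi = float(x[p])
        if hi <= lo:
            logger.warning("degenerate respiratory cycle at %.2f s: labeled R3", t0 + p / fs)
            labels[a:stop] = "R3"
            continue
        norm = (x[a:stop] - lo) / (hi - lo)
        cyc = np.where(norm >= t2, "R1", np.where(norm >= t1, "R2", "R3"))
        labels[a:stop] = cyc

    spans: list[tuple[float, float, object]] = []
    run_start = None
    run_label = None
    for i in range(x.size + 1):
        lab = labels[i] if i < x.size else None
        if lab != run_label:
            if run_label is not None:
                spans.append((t0 + run_start / fs, t0 + i / fs, run_label))
            run_start = i
            run_label = lab
    return PhaseLabeling(spans)


def cardiac_phase_labels(fid: FiducialSet, systole_len: float | str = "auto",
                         anchor: str = "ao") -> PhaseLabeling:
    """Cardiac phase spans per accepted beat.

    Phases 1-3 are three equal constant systole sub-intervals of length S/3
    starting at the beat anchor (AO by default; R optionally, for ECG-style
    triggering); phase 4 is the time-varying diastole lasting to the next
    accepted beat's anchor.  ``systole_len="auto"`` uses the mean accepted
    AO-AC interval.  Pairs separated by a rejected beat produce no spans, so
    that time stays ungated.
    """
    if anchor not in ("ao", "r"):
        raise ValueError("anchor must be 'ao' or 'r'")
    acc = fid.accepted_indices()
    if acc.size < 2:
        raise ValueError("need at least 2 accepted beats")
    anchors = (fid.ao_times if anchor == "ao" else fid.r_times)[acc]
    if systole_len == "auto":
        s_len = float(np.mean(fid.ac_times[acc] - fid.ao_times[acc]))
    else:
        s_len = float(systole_len)
    pairs = [(anchors[i], anchors[i + 1])
             for i in range(acc.size - 1) if acc[i + 1] == acc[i] + 1]
    if not pairs:
        raise ValueError("no consecutive accepted beat pairs")
    if s_len >= min(b - a for a, b in pairs):
        raise ValueError("systole exceeds cycle")
    spans: list[tuple[float, float, object]] = []
    for a0, a1 in pairs:
        third = s_len / 3.0
        spans.append((a0, a0 + third, 1))
        spans.append((a0 + third, a0 + 2 * third, 2))
        spans.append((a0 + 2 * third, a0 + s_len, 3))
        spans.append((a0 + s_len, a1, 4))
    return PhaseLabeling(spans)


def assign_dual_gates(lm: ListModeStream, resp: PhaseLabeling,
                      card: PhaseLabeling) -> GatedListMode:
    """Assign each event to its dual gate G(4*(i-1)+j) or the ungated bin."""
    times = lm.event_times
    resp_labels = resp.label_at(times)
    card_labels = card.label_at(times)
    gates = np.zeros(times.size, dtype=int)
    for k in range(times.size):
        rl, cl = resp_labels[k], card_labels[k]
        if rl is None or cl is None:
            continue
        i = RESP_LABELS.index(rl) + 1
        gates[k] = N_CARDIAC_PHASES * (i - 1) + int(cl)
    g = GatedListMode(times, gates, payload=lm.payload)
    assert sum(g.counts().values()) == times.size  # partition: disjoint + exhaustive
    return g


def write_gated_listmode(g: GatedListMode, out_dir, stem: str = "listmode") -> list[Path]:
    """Write the 12 gate files plus the ungated file and a count summary.

    All 12 gate files are always written (empty gates get a header-only file):
    ``<stem>_G01.csv`` ... ``<stem>_G12.csv``, ``<stem>_ungated.csv`` and
    ``<stem>_gate_counts.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for gate in range(1, N_GATES + 1):
        path = out_dir / f"{stem}_G{gate:02d}.csv"
        _write_gate(g, g.gate_ids == gate, path)
        paths.append(path)
    _write_gate(g, g.gate_ids == 0, out_dir / f"{stem}_ungated.csv")
    counts = g.counts()
    pd.DataFrame({"gate": list(counts), "count": list(counts.values())}).to_csv(
        out_dir / f"{stem}_gate_counts.csv", index=False)
    logger.info("wrote %d gate files to %s (counts: %s)", N_GATES, out_dir, counts)
    return paths


def _write_gate(g: GatedListMode, mask: np.ndarray, path: Path) -> None:
    payload = g.payload.loc[mask].reset_index(drop=True) if g.payload is not None else None
    write_listmode(ListModeStream(g.event_times[mask], payload), path)
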