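"""Acute-slice network analysis: ΔF/F, per-cell calcium events, miniature
synchronization events (mSEs), and per-cell-per-hour rate summaries.

A calcium event is any maximal run of the ΔF/F trace above the cell's own
mean + 2 SD (computed over the full trace).  An mSE is a chain of events
from >= 2 distinct neurons in which each successive peak follows the
previous one by less than 10 s.  Rates are normalized per cell and per hour
to control for the number of neurons visible in a slice (8-23 in practice),
measured over 12-min epochs (baseline / drug / wash) separated by 2-min
wash-in/out gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ROITraceSet",
    "CalciumEvent",
    "MiniSyncEvent",
    "EpochPlan",
    "RateSummary",
    "compute_dff",
    "detect_events",
    "detect_mses",
    "epoch_rates",
]

EVENT_SD_THRESHOLD = 2.0   # event: dff > mean + 2*SD of the trace
MSE_CHAIN_GAP_S = 10.0     # successive peaks < 10 s apart chain into one mSE
EPOCH_MEASUREMENT_S = 720.0
EPOCH_GAP_S = 120.0


@dataclass
class ROITraceSet:
    """Per-cell somatic fluorescence traces plus one background ROI, on a
    common regular time axis (seconds)."""

    time: np.ndarray
    cells: dict
    background: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if len(self.cells) < 2:
            raise ValueError("need >= 2 cells")
        for cid, tr in self.cells.items():
            tr = np.asarray(tr, dtype=float)
            if tr.shape != self.time.shape:
                raise ValueError(f"trace length mismatch for {cid}")
            self.cells[cid] = tr
        if self.background.shape != self.time.shape:
            raise ValueError("background length mismatch")


@dataclass
class CalciumEvent:
    cell_id: str
    peak_time: float
    peak_dff: float
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (self.start <= self.peak_time <= self.end):
            raise ValueError("peak_time outside event extent")


@dataclass
class MiniSyncEvent:
    member_events: list
    cells: set
    span: tuple  # (first peak, last peak) seconds

    def __post_init__(self) -> None:
        if len(self.cells) < 2:
            raise ValueError("an mSE requires >= 2 distinct cells")


@dataclass
class EpochPlan:
    """Ordered measurement epochs, each a (label, start, end) triple with a
    720-s measurement window; construction from drug metadata inserts 120-s
    transition gaps."""

    epochs: list

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for label, start, end in self.epochs:
            if start < prev_end:
                raise ValueError("epochs must be ordered and non-overlapping")
            if not np.isclose(end - start, EPOCH_MEASUREMENT_S):
                raise ValueError(f"epoch {label!r} is not {EPOCH_MEASUREMENT_S:.0f} s")
            prev_end = end

    @classmethod
    def from_drug_start(cls, drug_start: float) -> "EpochPlan":
        """Baseline / drug / wash plan aligned to drug application: baseline
        ends one gap before the drug goes on; the drug window starts one gap
        after; the wash window starts one gap after the drug window."""
        b_end = drug_start - EPOCH_GAP_S
        d_start = drug_start + EPOCH_GAP_S
        w_start = d_start + EPOCH_MEASUREMENT_S + EPOCH_GAP_S
        return cls([
            ("baseline", b_end - EPOCH_MEASUREMENT_S, b_end),
            ("drug", d_start, d_start + EPOCH_MEASUREMENT_S),
            ("wash", w_start, w_start + EPOCH_MEASUREMENT_S),
        ])


@dataclass
class RateSummary:
    events_per_cell_per_h: dict
    mses_per_cell_per_h: dict
    per_cell_participation: dict  # epoch -> {cell: mSEs containing it per hour}
    n_cells: int


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_dff(roi_set: ROITraceSet, f0_quantile: float = 20.0) -> dict:
    """Background-subtracted ΔF/F per cell.

    F' = F - background; ΔF/F = (F' - F0) / F0 with F0 the ``f0_quantile``-th
    percentile of F' (robust to sparse transients).  Cells whose F0 is not
    positive are degenerate and raise, naming the cell.
    """
    out = {}
    for cid, f in roi_set.cells.items():
        fprime = f - roi_set.background
        f0 = float(np.percentile(fprime, f0_quantile))
        if f0 <= 0:
            raise ValueError(f"degenerate cell {cid!r}: non-positive baseline "
                             f"fluorescence F0={f0:.3g}")
        out[cid] = (fprime - f0) / f0
    return out


def detect_events(dff: np.ndarray, time: np.ndarray, cell_id: str = "cell",
                  baseline_window: Optional[tuple] = None) -> list[CalciumEvent]:
    """Calcium events of one cell: maximal runs of ΔF/F above mean + 2 SD.

    The mean and SD are taken over the full trace, events included (set
    ``baseline_window`` to restrict them to a baseline period instead).
    Each supra-threshold run yields one event whose peak is the run maximum;
    runs separated by at least one sub-threshold sample are distinct.
    """
    dff = np.asarray(dff, dtype=float)
    time = np.asarray(time, dtype=float)
    if dff.size == 0:
        raise ValueError("empty trace")
    if baseline_window is not None:
        lo, hi = baseline_window
        ref = dff[(time >= lo) & (time <= hi)]
    else:
        ref = dff
    sd = ref.std()
    if sd == 0:
        warnings.warn(f"{cell_id}: zero SD, no events detectable", stacklevel=2)
        return []
    threshold = ref.mean() + EVENT_SD_THRESHOLD * sd
    above = dff > threshold
    events = []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [0] if above[0] else []
    starts += [int(e) + 1 for e in edges if not above[e]]
    ends = [int(e) for e in edges if above[e]]
    if above[-1]:
        ends.append(dff.size - 1)
    for s, e in zip(starts, ends):
        i_peak = s + int(np.argmax(dff[s:e + 1]))
        events.append(CalciumEvent(
            cell_id=cell_id, peak_time=float(time[i_peak]),
            peak_dff=float(dff[i_peak]), start=float(time[s]), end=float(time[e])))
    return events


def detect_events_all(dff_by_cell: Mapping[str, np.ndarray], time: np.ndarray,
                      baseline_window: Optional[tuple] = None) -> list[CalciumEvent]:
    """Run :func:`detect_events` per cell and return all events time-sorted."""
    events: list[CalciumEvent] = []
    for cid, tr in dff_by_cell.items():
        events.extend(detect_events(tr, time, cell_id=cid,
                                    baseline_window=baseline_window))
    return sorted(events, key=lambda e: e.peak_time)


def detect_mses(events: Sequence[CalciumEvent]) -> list[MiniSyncEvent]:
    """Chain-group events into miniature synchronization events.

    Starting at the earliest unconsumed event, a chain extends while the next
    event's peak follows the previous member's by less than 10 s; chains are
    therefore the maximal runs of the time-sorted events with successive peak
    gaps < 10 s.  Only chains spanning >= 2 distinct cells are emitted; each
    event belongs to at most one chain.  Same-cell consecutive peaks may sit
    inside a chain but do not by themselves satisfy the 2-neuron requirement.
    """
    ev = sorted(events, key=lambda e: e.peak_time)
    mses = []
    i = 0
    while i < len(ev):
        j = i
        while j + 1 < len(ev) and ev[j + 1].peak_time - ev[j].peak_time < MSE_CHAIN_GAP_S:
            j += 1
        chain = ev[i:j + 1]
        cells = {e.cell_id for e in chain}
        if len(cells) >= 2:
            mses.append(MiniSyncEvent(
                member_events=list(chain), cells=cells,
                span=(chain[0].peak_time, chain[-1].peak_time)))
        i = j + 1
    return mses


def epoch_rates(events: Sequence[CalciumEvent], mses: Sequence[MiniSyncEvent],
                plan: EpochPlan, n_cells: int,
                recording_span: Optional[tuple] = None) -> RateSummary:
    """Per-epoch event and mSE rates, normalized per cell and per hour.

    An mSE is assigned to the epoch containing its first peak.  Per-cell
    participation counts the mSEs containing that cell, per hour.
    """
    if recording_span is not None:
        lo, hi = recording_span
        for label, s, e in plan.epochs:
            if s < lo or e > hi:
                raise ValueError(f"epoch {label!r} outside recording")
    ev_rates, mse_rates, participation = {}, {}, {}
    for label, s, e in plan.epochs:
        hours = (e - s) / 3600.0
        n_ev = sum(1 for x in events if s <= x.peak_time < e)
        in_epoch = [m for m in mses if s <= m.span[0] < e]
        ev_rates[label] = n_ev / n_cells / hours
        mse_rates[label] = len(in_epoch) / n_cells / hours
        per_cell = {}
        for m in in_epoch:
            for c in m.cells:
                per_cell[c] = per_cell.get(c, 0) + 1
        participation[label] = {c: k / hours for c, k in per_cell.items()}
    return RateSummary(events_per_cell_per_h=ev_rates,
                       mses_per_cell_per_h=mse_rates,
                       per_cell_participation=participation,
                       n_cells=n_cells)
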