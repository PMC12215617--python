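"""Whole-cell and cell-attached response quantification.

Membrane-voltage responses to a 1-min bath drug application are read from a
1-s median-smoothed trace: the pre-drug voltage is the 60-s mean before the
application, the drug voltage is the minimum from application start to 120 s
past its end (responses can outlast the application), and a neuron is a
responder when the change is at least -5 mV (inclusive; the threshold sits
between the two observed response clusters).  Paired applications (NA1/NA2,
20 min apart) summarize antagonist efficacy as the percent reduction of the
group NA2 mean against the pooled NA1 mean.  Cell-attached firing-rate
changes compare the mean rate in the 60 s before application with the rate
0.5-1.5 min after application start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter

from .stats import percent_reduction

__all__ = [
    "VmTrace",
    "VoltageResponse",
    "PairedApplication",
    "SpikeTrain",
    "FiringRateResponse",
    "quantify_vmem_response",
    "classify_responder",
    "paired_application_summary",
    "firing_rate_change",
]

RESPONDER_THRESHOLD_MV = -5.0
PRE_WINDOW_S = 60.0
RESPONSE_OVERHANG_S = 120.0   # extremum searched to window end + this
WASHOUT_WINDOW_S = (420.0, 1020.0)   # 7-17 min after application end
RECOVERY_TOLERANCE_MV = 2.0
SMOOTHING_S = 1.0


@dataclass
class VmTrace:
    """Membrane voltage (mV) with labeled drug-application windows."""

    time: np.ndarray
    vmem: np.ndarray
    drug_windows: list  # (label, start, end) seconds
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.vmem = np.asarray(self.vmem, dtype=float)
        if self.time.shape != self.vmem.shape:
            raise ValueError("time/vmem length mismatch")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for label, s, e in self.drug_windows:
            if s >= e or s < self.time[0] or e > self.time[-1]:
                raise ValueError(f"drug window {label!r} outside recording")


@dataclass
class VoltageResponse:
    v_pre: float
    v_drug: float
    delta_vmem: float
    responder: bool
    washout_recovered: Optional[bool]

    def __post_init__(self) -> None:
        if self.responder != (self.delta_vmem <= RESPONDER_THRESHOLD_MV):
            raise ValueError("responder flag inconsistent with delta_vmem")


@dataclass
class PairedApplication:
    na1: VoltageResponse
    na2: VoltageResponse
    antagonist: str
    gap: float = 1200.0


@dataclass
class SpikeTrain:
    spike_times: np.ndarray
    application_windows: list  # (start, end) seconds
    duration: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)


@dataclass
class FiringRateResponse:
    rate_pre: float
    rate_post: float
    percent_reduction: Optional[float]  # None when rate_pre == 0 (flagged)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _smoothed(trace: VmTrace) -> np.ndarray:
    dt = float(np.median(np.diff(trace.time)))
    k = max(1, int(round(SMOOTHING_S / dt)))
    if k % 2 == 0:
        k += 1
    return median_filter(trace.vmem, size=k, mode="nearest")


def quantify_vmem_response(trace: VmTrace, window: Optional[tuple] = None) -> VoltageResponse:
    """Quantify one drug application on a voltage trace.

    ``window`` is the (start, end) of the application; defaults to the first
    labeled drug window of the trace.  Requires a full 60-s pre-window.
    Washout recovery is satisfied when the smoothed voltage comes within
    2 mV of the pre-drug level at any point 7-17 min after application end
    (None when the recording ends before that window opens).
    """
    if window is None:
        if not trace.drug_windows:
            raise ValueError("no drug window given")
        _, start, end = trace.drug_windows[0]
    else:
        start, end = window
    if start - PRE_WINDOW_S < trace.time[0]:
        raise ValueError("missing 60-s pre-application window")
    v = _smoothed(trace)
    t = trace.time
    pre = (t >= start - PRE_WINDOW_S) & (t < start)
    resp = (t >= start) & (t <= end + RESPONSE_OVERHANG_S)
    v_pre = float(v[pre].mean())
    v_drug = float(v[resp].min())
    delta = v_drug - v_pre
    wash = (t >= end + WASHOUT_WINDOW_S[0]) & (t <= end + WASHOUT_WINDOW_S[1])
    recovered = bool(np.any(np.abs(v[wash] - v_pre) < RECOVERY_TOLERANCE_MV)) \
        if wash.any() else None
    return VoltageResponse(v_pre=v_pre, v_drug=v_drug, delta_vmem=delta,
                           responder=classify_responder(delta),
                           washout_recovered=recovered)


def classify_responder(delta_vmem: float) -> bool:
    """True iff the voltage change is a hyperpolarization of at least 5 mV
    (inclusive at exactly -5 mV)."""
    if not np.isfinite(delta_vmem):
        raise ValueError("delta_vmem must be finite")
    return delta_vmem <= RESPONDER_THRESHOLD_MV


def paired_application_summary(pairs_by_antagonist: Mapping[str, Sequence[PairedApplication]],
                               pooled_na1: Sequence[float]) -> dict:
    """Per-antagonist NA2 summary against the pooled NA1 amplitudes.

    Percent reduction compares response magnitudes:
    100 * (|mean NA1| - |mean NA2|) / |mean NA1|.
    Returns {antagonist: {"mean_na2_mv", "mean_na1_mv", "percent_reduction",
    "n"}}.
    """
    pooled = np.asarray(pooled_na1, dtype=float)
    if pooled.size == 0:
        raise ValueError("pooled NA1 sample is empty")
    mean_na1 = float(pooled.mean())
    out = {}
    for antagonist, pairs in pairs_by_antagonist.items():
        if len(pairs) == 0:
            raise ValueError(f"empty group {antagonist!r}")
        na2 = np.array([p.na2.delta_vmem for p in pairs], dtype=float)
        mean_na2 = float(na2.mean())
        out[antagonist] = {
            "mean_na1_mv": mean_na1,
            "mean_na2_mv": mean_na2,
            "percent_reduction": percent_reduction(abs(mean_na1), abs(mean_na2)),
            "n": len(pairs),
        }
    return out


def firing_rate_change(train: SpikeTrain, pre_window: float = 60.0,
                       post_offset: tuple = (30.0, 90.0),
                       application_start: Optional[float] = None) -> FiringRateResponse:
    """Firing-rate change around one drug application.

    rate_pre: spikes in the ``pre_window`` seconds before application start;
    rate_post: spikes between ``application_start + post_offset[0]`` and
    ``application_start + post_offset[1]``.  Percent reduction is None
    (flagged) when the pre rate is zero.
    """
    if application_start is None:
        if not train.application_windows:
            raise ValueError("no application window given")
        application_start = train.application_windows[0][0]
    if application_start - pre_window < 0:
        raise ValueError("pre-window extends before recording start")
    lo, hi = post_offset
    if application_start + hi > train.duration:
        raise ValueError("post-window extends past recording end")
    st = train.spike_times
    n_pre = int(np.sum((st >= application_start - pre_window) & (st < application_start)))
    n_post = int(np.sum((st >= application_start + lo) & (st < application_start + hi)))
    rate_pre = n_pre / pre_window
    rate_post = n_post / (hi - lo)
    pct = percent_reduction(rate_pre, rate_post) if rate_pre > 0 else None
    return FiringRateResponse(rate_pre=rate_pre, rate_post=rate_post,
                              percent_reduction=pct)
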