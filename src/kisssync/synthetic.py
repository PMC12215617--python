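"""Synthetic photometry, slice-network, and electrophysiology data with
known ground truth.

Every simulator emulates the statistical structure the downstream analyses
assume, so that detection and quantification stages can be validated by
parameter recovery rather than against undeposited raw recordings:

* in-vivo fiber photometry: two demodulated channels (calcium-dependent
  465-490 nm and calcium-independent 405 nm) acquired at 10 Hz in a
  scheduled 5-s-on / 10-s-off duty cycle; population synchronization events
  (SEs) drawn from a gamma renewal process appear only in the calcium
  channel as GCaMP6s-like difference-of-exponential transients riding on
  bleaching drift; a shared artifact couples into both channels;
* acute-slice networks: per-cell Poisson calcium events superposed with
  latent network events that recruit each cell with a configurable
  probability, producing miniature synchronization events;
* whole-cell patch: a bimodal population in which a fraction of neurons
  hyperpolarize smoothly during a 1-min drug application and recover after
  a variable washout lag;
* cell-attached spike trains: Poisson firing whose rate is scaled inside
  drug-application windows.

All randomness flows from one integer seed; each simulator derives named
sub-streams so edits to one component leave the others' draws unchanged.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .photometry import DualChannelTrace
from .slice_network import ROITraceSet
from .patch import VmTrace, SpikeTrain

__all__ = [
    "DistSpec",
    "PhotometrySimConfig",
    "SliceSimConfig",
    "PatchSimConfig",
    "SpikeSimConfig",
    "GroundTruth",
    "simulate_photometry",
    "simulate_slice_network",
    "simulate_patch",
    "simulate_spiketrain",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def _substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-component generator keyed by (seed, component name)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Distribution specs
# ---------------------------------------------------------------------------

@dataclass
class DistSpec:
    """A small declarative distribution: kind in {fixed, normal, lognormal,
    gamma, uniform} with keyword parameters."""

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = {
            "fixed": {"value"},
            "normal": {"mean", "sd"},
            "lognormal": {"mean", "sigma"},
            "gamma": {"shape", "scale"},
            "uniform": {"low", "high"},
        }
        if self.kind not in allowed:
            raise ConfigurationError(f"unknown distribution kind {self.kind!r}")
        missing = allowed[self.kind] - set(self.params)
        if missing:
            raise ConfigurationError(
                f"distribution {self.kind!r} missing parameters {sorted(missing)}")

    def draw(self, rng: np.random.Generator, size: Optional[int] = None):
        p = self.params
        if self.kind == "fixed":
            return np.full(size, p["value"]) if size is not None else p["value"]
        if self.kind == "normal":
            return rng.normal(p["mean"], p["sd"], size)
        if self.kind == "lognormal":
            return rng.lognormal(p["mean"], p["sigma"], size)
        if self.kind == "gamma":
            return rng.gamma(p["shape"], p["scale"], size)
        return rng.uniform(p["low"], p["high"], size)


# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted parameters emitted by every simulator for recovery testing."""

    se_times: list = field(default_factory=list)
    se_amplitudes: list = field(default_factory=list)
    per_cell_event_times: dict = field(default_factory=dict)
    mse_memberships: list = field(default_factory=list)
    responder_flags: list = field(default_factory=list)
    true_delta_vmem: list = field(default_factory=list)
    true_rates: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "se_times": list(map(float, self.se_times)),
            "se_amplitudes": list(map(float, self.se_amplitudes)),
            "per_cell_event_times": {
                str(k): list(map(float, v)) for k, v in self.per_cell_event_times.items()
            },
            "mse_memberships": [
                [[str(c), float(t)] for c, t in grp] for grp in self.mse_memberships
            ],
            "responder_flags": list(map(bool, self.responder_flags)),
            "true_delta_vmem": list(map(float, self.true_delta_vmem)),
            "true_rates": {str(k): float(v) for k, v in self.true_rates.items()},
        }


# ---------------------------------------------------------------------------
# Photometry simulator
# ---------------------------------------------------------------------------

@dataclass
class PhotometrySimConfig:
    """Conditions of a 24-h scheduled dual-channel photometry recording.

    Defaults emulate a diestrous-stage recording: roughly 20 SEs per 24 h
    (gamma renewal, mean 4000 s), 10-Hz sampling in a 5-s-on / 10-s-off duty
    cycle, GCaMP6s-like kinetics (rise 1.5 s, decay 30 s), exponential
    bleaching plus slow wander, and additive sensor noise.  SE frequency and
    amplitude per physiological state are not published quantities; these
    defaults are conventions chosen to give realistic SNR and counts.
    """

    duration: float = 86400.0
    sample_rate: float = 10.0
    duty_on: float = 5.0
    duty_off: float = 10.0
    se_interval_mean: Optional[float] = 4000.0  # None disables SEs (zero hazard)
    se_interval_shape: float = 4.0
    se_amplitude: DistSpec = field(
        default_factory=lambda: DistSpec("normal", {"mean": 10.0, "sd": 1.5}))
    kernel_rise: float = 1.5
    kernel_decay: float = 30.0
    baseline_level: float = 100.0
    bleach_amplitude: float = 10.0
    bleach_tau: float = 43200.0
    wander_amplitude: float = 1.0
    noise_sd: float = 0.3
    isosbestic_artifact_gain: float = 0.0
    artifact_sd: float = 1.0
    injection_time: Optional[float] = None
    suppression_duration: float = 0.0
    suppression_factor: float = 1.0
    ovx_mode: bool = False
    ovx_cluster_interval_mean: float = 600.0
    ovx_quiescent_duration_mean: float = 7200.0
    ovx_cluster_duration_mean: float = 3600.0
    ovx_amplitude_gain: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ConfigurationError("duration and sample_rate must be positive")
        if not (0.0 <= self.suppression_factor <= 1.0):
            raise ConfigurationError("suppression_factor must lie in [0, 1]")
        if self.kernel_rise >= self.kernel_decay:
            raise ConfigurationError("kernel_rise must be < kernel_decay")
        if self.duty_on <= 0 or self.duty_off < 0:
            raise ConfigurationError("invalid duty cycle")
        if not isinstance(self.se_amplitude, DistSpec):
            raise ConfigurationError("se_amplitude must be a DistSpec")


def _duty_cycle_times(duration: float, rate: float, on: float, off: float) -> np.ndarray:
    """Sample timestamps of the on-duty segments only (gapped grid)."""
    dt = 1.0 / rate
    period = on + off
    times = []
    t0 = 0.0
    n_on = int(round(on * rate))
    while t0 < duration:
        seg = t0 + dt * np.arange(n_on)
        times.append(seg[seg < duration])
        t0 += period
    return np.concatenate(times) if times else np.empty(0)


def _hazard_rate_profile(cfg: PhotometrySimConfig, t: float) -> float:
    """Multiplicative hazard scale on the interval starting at wall-clock t
    (half-open on the left so breakpoints land in the window they open)."""
    if (cfg.injection_time is not None and cfg.suppression_duration > 0
            and cfg.injection_time <= t < cfg.injection_time + cfg.suppression_duration):
        return cfg.suppression_factor
    return 1.0


def _draw_se_times(cfg: PhotometrySimConfig, rng: np.random.Generator) -> list[float]:
    """Gamma-renewal SE times with a multiplicative hazard inside the
    post-injection suppression window, implemented by time rescaling: the
    renewal clock advances at the hazard scale, so a scale of zero freezes
    the process for the suppression duration."""
    if cfg.se_interval_mean is None:
        return []
    shape = cfg.se_interval_shape
    scale = cfg.se_interval_mean / shape

    def op_to_wall(op_elapsed: float, t_start: float) -> float:
        # integrate wall time until the operational (rescaled) clock has
        # advanced by op_elapsed, honoring the piecewise-constant hazard
        t = t_start
        remaining = op_elapsed
        while True:
            rate = _hazard_rate_profile(cfg, t)
            # next hazard breakpoint after t
            bps = []
            if cfg.injection_time is not None and cfg.suppression_duration > 0:
                bps = [cfg.injection_time,
                       cfg.injection_time + cfg.suppression_duration]
            nxt = min((b for b in bps if b > t), default=np.inf)
            if rate == 0.0:
                if nxt == np.inf:
                    return np.inf
                t = nxt
                continue
            span = (nxt - t) * rate
            if remaining <= span:
                return t + remaining / rate
            remaining -= span
            t = nxt

    times: list[float] = []
    t = 0.0
    if cfg.ovx_mode:
        # two-state modulated renewal: clustered high-frequency bouts
        # separated by quiescent stretches
        in_cluster = rng.random() < 0.5
        state_end = t + rng.exponential(
            cfg.ovx_cluster_duration_mean if in_cluster else cfg.ovx_quiescent_duration_mean)
        while t < cfg.duration:
            mean = cfg.ovx_cluster_interval_mean if in_cluster else cfg.se_interval_mean
            interval = rng.gamma(shape, mean / shape)
            t_next = op_to_wall(interval, t)
            if t_next > state_end:
                t = state_end
                in_cluster = not in_cluster
                state_end = t + rng.exponential(
                    cfg.ovx_cluster_duration_mean if in_cluster
                    else cfg.ovx_quiescent_duration_mean)
                continue
            t = t_next
            if t < cfg.duration:
                times.append(t)
        return times
    while True:
        interval = rng.gamma(shape, scale)
        t = op_to_wall(interval, t)
        if t >= cfg.duration:
            return times
        times.append(t)


def _gcamp_kernel_peak_offset(rise: float, decay: float) -> float:
    """Time from event origin to the maximum of exp(-t/decay) - exp(-t/rise)."""
    return float(np.log(decay / rise) * rise * decay / (decay - rise))


def _gcamp_transients(t: np.ndarray, event_times: Sequence[float],
                      amplitudes: Sequence[float], rise: float, decay: float) -> np.ndarray:
    """Sum of difference-of-exponential transients, unit peak per event,
    evaluated analytically at the (gapped) sample times."""
    out = np.zeros_like(t)
    tp = _gcamp_kernel_peak_offset(rise, decay)
    peak = np.exp(-tp / decay) - np.exp(-tp / rise)
    for t0, a in zip(event_times, amplitudes):
        rel = t - t0
        m = rel >= 0
        out[m] += (a / peak) * (np.exp(-rel[m] / decay) - np.exp(-rel[m] / rise))
    return out


def simulate_photometry(config: PhotometrySimConfig):
    """Simulate one dual-channel photometry recording.

    Returns (DualChannelTrace, GroundTruth).  GroundTruth.se_times holds the
    planted SE *peak* times (event origin plus the kernel rise-to-peak lag);
    SE transients enter only the calcium-dependent channel, while drift,
    noise, and the shared artifact enter per their couplings.
    """
    cfg = config
    t = _duty_cycle_times(cfg.duration, cfg.sample_rate, cfg.duty_on, cfg.duty_off)

    rng_se = _substream(cfg.seed, "se-times")
    rng_amp = _substream(cfg.seed, "se-amplitudes")
    rng_drift = _substream(cfg.seed, "drift")
    rng_noise = _substream(cfg.seed, "noise")
    rng_art = _substream(cfg.seed, "artifact")

    event_times = _draw_se_times(cfg, rng_se)
    amps = np.atleast_1d(np.asarray(
        cfg.se_amplitude.draw(rng_amp, len(event_times)) if event_times else [],
        dtype=float))
    amps = np.clip(amps, 0.5, None)
    if cfg.ovx_mode:
        amps = amps * cfg.ovx_amplitude_gain

    transients = _gcamp_transients(t, event_times, amps, cfg.kernel_rise, cfg.kernel_decay)

    # slow additive baseline: bleach exponential + low-frequency wander
    bleach = cfg.bleach_amplitude * np.exp(-t / cfg.bleach_tau)
    phases = rng_drift.uniform(0, 2 * np.pi, 3)
    weights = rng_drift.uniform(0.3, 1.0, 3)
    periods = np.array([0.9, 0.45, 0.23]) * max(cfg.duration, 1.0)
    wander = cfg.wander_amplitude * sum(
        w * np.sin(2 * np.pi * t / p + ph) for w, p, ph in zip(weights, periods, phases))

    artifact = cfg.isosbestic_artifact_gain * cfg.artifact_sd * _smooth_noise(
        rng_art, t.size, smooth=50)

    f465 = (cfg.baseline_level + bleach + wander + transients + artifact
            + rng_noise.normal(0.0, cfg.noise_sd, t.size))
    f405 = (0.6 * cfg.baseline_level + 0.6 * bleach + artifact
            + rng_noise.normal(0.0, cfg.noise_sd, t.size))

    tp = _gcamp_kernel_peak_offset(cfg.kernel_rise, cfg.kernel_decay)
    truth = GroundTruth(
        se_times=[et + tp for et in event_times],
        se_amplitudes=list(map(float, amps)),
        true_rates={"se_per_day": len(event_times) / (cfg.duration / 86400.0)},
    )
    trace = DualChannelTrace(
        time=t, f465=f465, f405=f405, mask=np.ones(t.size, dtype=bool),
        meta={"injection_time": cfg.injection_time,
              "recording_length": cfg.duration,
              "sample_rate": cfg.sample_rate},
    )
    return trace, truth


def _smooth_noise(rng: np.random.Generator, n: int, smooth: int) -> np.ndarray:
    """Unit-variance low-pass noise (moving-average smoothed white noise)."""
    if n == 0:
        return np.empty(0)
    x = rng.normal(0.0, 1.0, n + smooth)
    kernel = np.ones(smooth) / smooth
    y = np.convolve(x, kernel, mode="valid")[:n]
    sd = y.std()
    return y / sd if sd > 0 else y


# ---------------------------------------------------------------------------
# Slice network simulator
# ---------------------------------------------------------------------------

@dataclass
class SliceSimConfig:
    """Conditions of an acute-slice multi-ROI GCaMP recording: 2-Hz imaging
    of 8-23 cells, independent per-cell Poisson events at 22.9 events/cell/h
    baseline, and latent network events (the substrate of miniature
    synchronization events) recruiting each cell with probability
    ``sync_fraction``."""

    n_cells: int = 11
    duration: float = 3600.0
    sample_rate: float = 2.0
    cell_event_rate: float = 22.9        # independent events/cell/h
    network_event_rate: float = 5.3      # latent network events/h
    sync_fraction: float = 0.6
    recruit_jitter_sd: float = 1.5       # s; keeps recruited peaks within the 10-s chain
    drug_epoch: Optional[tuple] = None   # (start, end) seconds
    drug_rate_factor: float = 1.0
    dff_event_amplitude: DistSpec = field(
        default_factory=lambda: DistSpec("normal", {"mean": 0.5, "sd": 0.08}))
    kernel_rise: float = 0.8
    kernel_decay: float = 6.0
    f0_level: float = 100.0
    background_level: float = 30.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ConfigurationError("n_cells must be >= 2")
        if not (0.0 <= self.sync_fraction <= 1.0):
            raise ConfigurationError("sync_fraction must lie in [0, 1]")
        if self.drug_rate_factor < 0:
            raise ConfigurationError("drug_rate_factor must be >= 0")
        if self.drug_epoch is not None:
            s, e = self.drug_epoch
            if not (0 <= s < e <= self.duration):
                raise ConfigurationError("drug_epoch outside recording duration")


def _thinned_poisson(rng: np.random.Generator, rate_hz: float, duration: float,
                     drug_epoch, factor: float) -> np.ndarray:
    """Homogeneous Poisson times thinned to rate * factor inside drug_epoch."""
    n = rng.poisson(rate_hz * duration)
    times = np.sort(rng.uniform(0.0, duration, n))
    if drug_epoch is None or factor == 1.0:
        return times
    s, e = drug_epoch
    inside = (times > s) & (times <= e)
    keep = ~inside | (rng.random(times.size) < factor)
    return times[keep]


def simulate_slice_network(config: SliceSimConfig):
    """Simulate a multi-ROI slice recording; returns (ROITraceSet, GroundTruth).

    Event times are the superposition of independent per-cell Poisson events
    and latent network events recruiting each cell with probability
    ``sync_fraction`` (small per-cell jitter).  All rates are multiplied by
    ``drug_rate_factor`` inside ``drug_epoch``.  GroundTruth records every
    planted event time per cell and the latent-group memberships.
    """
    cfg = config
    dt = 1.0 / cfg.sample_rate
    t = np.arange(0.0, cfg.duration, dt)
    cell_ids = [f"cell_{i + 1:03d}" for i in range(cfg.n_cells)]

    per_cell: dict[str, list[float]] = {c: [] for c in cell_ids}
    for i, c in enumerate(cell_ids):
        rng_c = _substream(cfg.seed, f"cell-events-{i}")
        times = _thinned_poisson(rng_c, cfg.cell_event_rate / 3600.0, cfg.duration,
                                 cfg.drug_epoch, cfg.drug_rate_factor)
        per_cell[c].extend(times.tolist())

    rng_net = _substream(cfg.seed, "network-events")
    net_times = _thinned_poisson(rng_net, cfg.network_event_rate / 3600.0, cfg.duration,
                                 cfg.drug_epoch, cfg.drug_rate_factor)
    memberships: list[list[tuple]] = []
    for t0 in net_times:
        group = []
        for i, c in enumerate(cell_ids):
            if rng_net.random() < cfg.sync_fraction:
                jitter = abs(rng_net.normal(0.0, cfg.recruit_jitter_sd))
                te = min(t0 + jitter, cfg.duration - dt)
                per_cell[c].append(float(te))
                group.append((c, float(te)))
        if group:
            memberships.append(group)

    rng_amp = _substream(cfg.seed, "amplitudes")
    rng_noise = _substream(cfg.seed, "trace-noise")
    rng_bg = _substream(cfg.seed, "background")
    cells = {}
    for c in cell_ids:
        ev = np.sort(np.asarray(per_cell[c]))
        per_cell[c] = ev.tolist()
        amps = np.atleast_1d(np.asarray(
            cfg.dff_event_amplitude.draw(rng_amp, ev.size) if ev.size else [], dtype=float))
        amps = np.clip(amps, 0.05, None) * cfg.f0_level
        dff_trace = _gcamp_transients(t, ev, amps, cfg.kernel_rise, cfg.kernel_decay)
        cells[c] = (cfg.background_level + cfg.f0_level + dff_trace
                    + rng_noise.normal(0.0, cfg.noise_sd, t.size))
    background = cfg.background_level + rng_bg.normal(0.0, cfg.noise_sd * 0.5, t.size)

    hours = cfg.duration / 3600.0
    truth = GroundTruth(
        per_cell_event_times=per_cell,
        mse_memberships=memberships,
        true_rates={
            "events_per_cell_per_h": sum(len(v) for v in per_cell.values())
            / cfg.n_cells / hours,
            "network_events_per_h": len(net_times) / hours,
        },
    )
    roi = ROITraceSet(
        time=t, cells=cells, background=background,
        meta={"drug_epoch": cfg.drug_epoch, "n_cells": cfg.n_cells},
    )
    return roi, truth


# ---------------------------------------------------------------------------
# Patch-clamp simulator
# ---------------------------------------------------------------------------

@dataclass
class PatchSimConfig:
    """A bimodal whole-cell cohort: 40% of neurons respond to the drug with a
    smooth, transient hyperpolarization (mean -9.9 mV), recovering after a
    7-17-min washout lag; the remainder show noise only.  Antagonist scales
    shrink the second-application response (alpha block ~0.38 of control,
    beta block ~0.33, both ~0)."""

    n_neurons: int = 50
    responder_fraction: float = 0.40
    response_amplitude: DistSpec = field(
        default_factory=lambda: DistSpec("normal", {"mean": -9.9, "sd": 1.5}))
    antagonist: str = "none"
    antagonist_scale: dict = field(
        default_factory=lambda: {"none": 1.0, "alpha": 0.38, "beta": 0.33, "both": 0.0})
    membrane_noise_sd: float = 0.5
    baseline_vmem: float = -50.0
    drug_start: float = 120.0
    drug_duration: float = 60.0
    washout_lag_range: tuple = (420.0, 1020.0)  # 7-17 min
    duration: float = 1500.0
    sample_rate: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise ConfigurationError("responder_fraction must lie in [0, 1]")
        for k, v in self.antagonist_scale.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"antagonist scale {k!r} outside [0, 1]")
        if self.antagonist not in self.antagonist_scale:
            raise ConfigurationError(f"unknown antagonist {self.antagonist!r}")


def _response_waveform(t: np.ndarray, start: float, dur: float, amp: float,
                       washout_lag: float) -> np.ndarray:
    """Smooth hyperpolarization: exponential onset starting at application,
    plateau, and sigmoidal recovery completing after the washout lag.  Zero
    before the application so the pre-drug window stays uncontaminated."""
    onset_tau = 10.0
    rec_center = start + dur + washout_lag
    rec_tau = 60.0
    rel = t - start
    rise = np.where(rel >= 0, 1.0 - np.exp(-np.clip(rel, 0, None) / onset_tau), 0.0)
    fall = 1.0 / (1.0 + np.exp((t - rec_center) / rec_tau))
    return amp * rise * fall


def simulate_patch(config: PatchSimConfig):
    """Simulate a cohort of whole-cell recordings; returns (list[VmTrace],
    GroundTruth) with planted responder flags and true response amplitudes."""
    cfg = config
    rng_flags = _substream(cfg.seed, "responder-flags")
    rng_amp = _substream(cfg.seed, "response-amplitudes")
    t = np.arange(0.0, cfg.duration, 1.0 / cfg.sample_rate)
    scale = cfg.antagonist_scale[cfg.antagonist]

    traces, flags, deltas = [], [], []
    for i in range(cfg.n_neurons):
        rng_n = _substream(cfg.seed, f"neuron-{i}")
        is_resp = bool(rng_flags.random() < cfg.responder_fraction)
        amp = float(cfg.response_amplitude.draw(rng_amp)) * scale if is_resp else 0.0
        amp = min(amp, 0.0)
        washout = rng_n.uniform(*cfg.washout_lag_range)
        v = (cfg.baseline_vmem
             + _response_waveform(t, cfg.drug_start, cfg.drug_duration, amp, washout)
             + rng_n.normal(0.0, cfg.membrane_noise_sd, t.size))
        traces.append(VmTrace(
            time=t.copy(), vmem=v,
            drug_windows=[("drug", cfg.drug_start, cfg.drug_start + cfg.drug_duration)],
            meta={"neuron_id": f"neuron_{i + 1:03d}", "antagonist": cfg.antagonist},
        ))
        flags.append(is_resp)
        deltas.append(amp)
    truth = GroundTruth(responder_flags=flags, true_delta_vmem=deltas)
    return traces, truth


# ---------------------------------------------------------------------------
# Spike-train simulator
# ---------------------------------------------------------------------------

@dataclass
class SpikeSimConfig:
    """Cell-attached firing: Poisson spikes at ``baseline_rate`` (default the
    observed 1.48 Hz tonic rate), multiplied by ``cno_rate_factor`` inside
    each drug-application window (default ~0.14, i.e. 1.48 -> ~0.21 Hz)."""

    baseline_rate: float = 1.48
    cno_rate_factor: float = 0.142
    cno_application_windows: tuple = ((300.0, 600.0),)
    duration: float = 900.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.cno_rate_factor < 0:
            raise ConfigurationError("rates must be >= 0")
        wins = sorted(self.cno_application_windows)
        for (s, e) in wins:
            if not (0 <= s < e <= self.duration):
                raise ConfigurationError("application window outside recording")
        for (_, e1), (s2, _) in zip(wins, wins[1:]):
            if s2 < e1:
                raise ConfigurationError("overlapping application windows")


def simulate_spiketrain(config: SpikeSimConfig):
    """Simulate one cell-attached spike train; returns (SpikeTrain, GroundTruth)."""
    cfg = config
    rng = _substream(cfg.seed, "spikes")
    n = rng.poisson(cfg.baseline_rate * cfg.duration)
    times = np.sort(rng.uniform(0.0, cfg.duration, n))
    if cfg.cno_rate_factor != 1.0:
        inside = np.zeros(times.size, dtype=bool)
        for (s, e) in cfg.cno_application_windows:
            inside |= (times > s) & (times <= e)
        keep = ~inside | (rng.random(times.size) < cfg.cno_rate_factor)
        times = times[keep]
    truth = GroundTruth(true_rates={
        "baseline_hz": cfg.baseline_rate,
        "window_hz": cfg.baseline_rate * cfg.cno_rate_factor,
    })
    train = SpikeTrain(
        spike_times=times,
        application_windows=list(cfg.cno_application_windows),
        duration=cfg.duration,
    )
    return train, truth
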