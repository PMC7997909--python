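"""Hysteresis stimulation controller and closed-loop simulation.

The controller is a two-threshold switch on the decoded control variable
y: stimulation turns ON when y rises above ``on_threshold`` (0.7-0.8
range, default 0.75) and OFF when it falls below ``off_threshold``
(0.2-0.3 range, default 0.25).  Inside the dead band the state is held,
which prevents chatter.  The controller runs at bin resolution (10 ms);
the detection-to-stimulation latency contract is therefore <= 1 bin.

``closed_loop_simulate`` reproduces the initiation-latency phenomenology
of the three stimulation modes: no stimulation (slow, self-paced),
experimenter-triggered ("forced", fast) and brain-controlled (slow and
self-paced, with stimulation onset gated by the decoded intent and hence
never preceding the motor-cortex ramp onset).
"""
from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from . import mua, synthetic_data

MS = 1000.0

#: Initiation-latency distributions (mean_s, sd_s) per mode; log-normal.
LATENCY_DEFAULTS = {
    "off": (23.9, 13.2),
    "brain_controlled": (29.1, 12.2),
    "forced": (5.5, 2.6),
}


@dataclasses.dataclass
class ControllerConfig:
    on_threshold: float = 0.75
    off_threshold: float = 0.25
    stim_frequency_hz: float = 40.0
    pulse_width_us: float = 200.0
    amplitude_ua: float = 150.0

    def __post_init__(self) -> None:
        if not self.off_threshold < self.on_threshold:
            raise ValueError("off_threshold must be below on_threshold")
        if not 0.7 <= self.on_threshold <= 0.8:
            warnings.warn("on_threshold outside the 0.7-0.8 operating range")
        if not 0.2 <= self.off_threshold <= 0.3:
            warnings.warn("off_threshold outside the 0.2-0.3 operating range")
        if not 50.0 <= self.amplitude_ua <= 250.0:
            warnings.warn("amplitude outside the 50-250 uA operating range")


@dataclasses.dataclass
class StimLog:
    """Ordered, strictly alternating ON/OFF events; first event is ON."""

    events: list[tuple[float, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_t = -math.inf
        for i, (t, kind) in enumerate(self.events):
            if kind not in ("ON", "OFF"):
                raise ValueError(f"bad event kind {kind!r}")
            expected = "ON" if i % 2 == 0 else "OFF"
            if kind != expected:
                raise ValueError("events must strictly alternate starting with ON")
            if t < prev_t:
                raise ValueError("event times must be non-decreasing")
            prev_t = t

    @property
    def on_times_ms(self) -> np.ndarray:
        return np.asarray([t for t, k in self.events if k == "ON"])

    @property
    def off_times_ms(self) -> np.ndarray:
        return np.asarray([t for t, k in self.events if k == "OFF"])


def hysteresis_step(state: bool, y_value: float,
                    cfg: ControllerConfig | None = None) -> bool:
    """One controller update: OFF->ON iff y > theta_on; ON->OFF iff y < theta_off."""
    cfg = cfg or ControllerConfig()
    if not state:
        return y_value > cfg.on_threshold
    return not (y_value < cfg.off_threshold)


def predict_states(y: np.ndarray, cfg: ControllerConfig | None = None,
                   initial_state: bool = False) -> np.ndarray:
    """Fold the hysteresis rule over a control trace; True = stimulation ON."""
    cfg = cfg or ControllerConfig()
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("control trace must be finite")
    out = np.empty(y.size, dtype=bool)
    state = initial_state
    on, off = cfg.on_threshold, cfg.off_threshold
    # vectorized scan: state only changes at crossings of either threshold
    for i, v in enumerate(y):
        if state:
            if v < off:
                state = False
        elif v > on:
            state = True
        out[i] = state
    return out


def run_controller(y, cfg: ControllerConfig | None = None,
                   bin_ms: float = 10.0, t0_ms: float = 0.0) -> StimLog:
    """Hysteresis controller over a full control trace -> stimulation log."""
    yv = y.y if hasattr(y, "y") else np.asarray(y, dtype=float)
    if hasattr(y, "bin_ms"):
        bin_ms, t0_ms = y.bin_ms, y.t0_ms
    states = predict_states(yv, cfg)
    events: list[tuple[float, str]] = []
    prev = False
    for i, s in enumerate(states):
        if s != prev:
            events.append((t0_ms + i * bin_ms, "ON" if s else "OFF"))
            prev = s
    return StimLog(events)


# ---------------------------------------------------------------------------
# closed-loop simulation


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclasses.dataclass
class ClosedLoopResult:
    mode: str
    latencies_s: np.ndarray            # gait-initiation latency per trial
    mi_ramp_onsets_ms: np.ndarray      # per trial, NaN when not simulated
    stim_on_ms: np.ndarray             # first ON per trial, NaN when no stim
    stim_log: StimLog                  # global timeline across trials
    behaviors: list

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "n_trials": int(self.latencies_s.size),
            "latency_mean_s": float(self.latencies_s.mean()),
            "latency_sd_s": float(self.latencies_s.std(ddof=1))
            if self.latencies_s.size > 1 else 0.0,
        }


def closed_loop_simulate(session_params: synthetic_data.SessionParams | None = None,
                         mode: str = "brain_controlled",
                         cfg: ControllerConfig | None = None, seed: int = 0,
                         n_trials: int = 20, walk_bout_s: float = 8.0
                         ) -> ClosedLoopResult:
    """Per-trial gait-initiation latencies under the three stimulation modes.

    * ``off``: no stimulation; latency drawn from the slow self-paced
      distribution (mean 23.9 s).
    * ``forced``: stimulation switched on by the experimenter at trial
      start; latency from the fast stim-driven distribution (mean 5.5 s).
    * ``brain_controlled``: latency from the self-paced distribution
      (mean 29.1 s); the MI population is simulated for each trial, the
      cumulative locomotor ensemble normalized to [0, 1], and stimulation
      gated by the hysteresis controller — ON events follow the decoded
      intent and cannot precede the MI ramp onset.
    """
    if mode not in LATENCY_DEFAULTS:
        raise ValueError(f"unknown mode {mode!r}")
    cfg = cfg or ControllerConfig()
    params = session_params or synthetic_data.SessionParams()
    rng = np.random.default_rng(seed)
    mu, sigma = _lognormal_params(*LATENCY_DEFAULTS[mode])

    latencies = np.empty(n_trials)
    onsets = np.full(n_trials, np.nan)
    stim_on = np.full(n_trials, np.nan)
    events: list[tuple[float, str]] = []
    behaviors = []
    t_offset = 0.0
    for k in range(n_trials):
        lat_s = float(np.clip(rng.lognormal(mu, sigma), 1.0, 120.0))
        # round to the bin grid
        lat_s = round(lat_s * 100.0) / 100.0
        latencies[k] = lat_s
        duration_s = lat_s + walk_bout_s + 1.0
        p = dataclasses.replace(
            params, seed=int(rng.integers(0, 2 ** 31 - 1)),
            duration_s=round(duration_s * 100.0) / 100.0,
            idle_bout_s=(lat_s, lat_s), walk_bout_s=(walk_bout_s, walk_bout_s),
            walk_bout_prob=1.0)
        behavior = synthetic_data.generate_behavior(p)
        behaviors.append(behavior)
        if mode == "forced":
            events.append((t_offset, "ON"))
            events.append((t_offset + behavior.n_bins * p.bin_ms, "OFF"))
            stim_on[k] = t_offset
        elif mode == "brain_controlled":
            mi, _, labels = synthetic_data.generate_neural(behavior, p)
            loco = np.flatnonzero(labels["mi_locomotor"])
            ens = mua.ensemble_rate(mi, loco)
            p1, p99 = np.percentile(ens, [1.0, 99.0])
            y = (ens - p1) / max(p99 - p1, 1e-12)
            trial_log = run_controller(y, cfg, bin_ms=p.bin_ms)
            onsets[k] = t_offset + behavior.gait_initiations_ms[0] - p.mi_lead_ms
            for t, kind in trial_log.events:
                events.append((t_offset + t, kind))
            if trial_log.on_times_ms.size:
                stim_on[k] = t_offset + trial_log.on_times_ms[0]
            if trial_log.events and trial_log.events[-1][1] == "ON":
                events.append((t_offset + behavior.n_bins * p.bin_ms, "OFF"))
        t_offset += behavior.n_bins * p.bin_ms
    return ClosedLoopResult(mode, latencies, onsets, stim_on, StimLog(events),
                            behaviors)
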