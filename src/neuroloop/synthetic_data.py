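"""Seeded synthetic recording sessions.

Generates the statistical structure the downstream analyses assume, so the
whole pipeline is testable without any recorded data:

* behavior: alternating idle/walk bouts with an approximately even balance
  of idle and walking time, trapezoidal per-bout speed profiles and gait
  events (foot-off / foot-strike) at a configurable cadence;
* neural activity: 32 motor-cortex (MI) and 16 midbrain locomotor region
  (MLR) channels of per-10 ms-bin Poisson counts.  Locomotor-related MI
  channels ramp up ``mi_lead_ms`` before each bout's first foot-off (the
  gait initiation), locomotor MLR channels ramp ``mlr_lag_ms`` after it,
  and speed-coupled MLR channels have rates affine in locomotor speed;
* optional short raw 24 kHz segments with inserted biphasic waveforms, for
  exercising the spike detector;
* per-gait-cycle kinematic feature tables with condition effects (graded
  DBS intensity, etc.) and multi-animal cohorts with random effects.

Every generator is a pure function of its parameters and seed.
"""
from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np
import pandas as pd

from .mua import CountMatrix, RawTrace

log = logging.getLogger(__name__)

MS = 1000.0


# ---------------------------------------------------------------------------
# parameters


@dataclasses.dataclass
class SessionParams:
    """Knobs of the session generator.

    Channel counts, the 8-SD / 50 ms ramp, the MI lead and MLR lag, and the
    even idle/walk balance are the study conditions; bout statistics,
    baseline rate and cadence are recorded package defaults (the source
    experiments do not constrain them).
    """

    seed: int = 0
    duration_s: float = 240.0
    n_mi_channels: int = 32
    n_mlr_channels: int = 16
    bin_ms: float = 10.0
    frac_locomotor_mi: float = 0.5
    frac_locomotor_mlr: float = 0.5
    frac_speed_coupled_mlr: float = 0.53
    baseline_rate_hz: float = 20.0
    #: walk/idle mean-rate ratio of locomotor channels.  ``None`` derives it
    #: from ``ramp_amplitude_sd`` (plateau = baseline + 8 baseline-SD).
    walk_gain: float | None = None
    mi_lead_ms: float = 147.0
    mlr_lag_ms: float = 104.0
    ramp_rise_ms: float = 50.0
    ramp_amplitude_sd: float = 8.0
    rate_noise_cv: float = 0.1
    condition: str = "intact"
    # bout / gait structure
    walk_bout_prob: float = 1.0
    idle_bout_s: tuple[float, float] = (5.0, 10.0)
    walk_bout_s: tuple[float, float] = (5.0, 10.0)
    cycle_ms: float = 700.0
    swing_ms: float = 250.0
    peak_speed_mm_s: float = 200.0
    accel_s: float = 1.0
    #: peak speed-driven rate increase of coupled MLR channels, in baseline SDs
    speed_gain_sd: float = 6.0

    def __post_init__(self) -> None:
        for name in ("frac_locomotor_mi", "frac_locomotor_mlr",
                     "frac_speed_coupled_mlr", "walk_bout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.duration_s <= 0 or self.baseline_rate_hz <= 0 or self.bin_ms <= 0:
            raise ValueError("durations and rates must be strictly positive")
        n_bins = self.duration_s * MS / self.bin_ms
        if abs(n_bins - round(n_bins)) > 1e-6:
            raise ValueError("bin_ms must divide duration evenly")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration_s * MS / self.bin_ms))

    @property
    def baseline_counts_per_bin(self) -> float:
        return self.baseline_rate_hz * self.bin_ms / MS

    @property
    def effective_walk_gain(self) -> float:
        lam0 = self.baseline_counts_per_bin
        if self.walk_gain is not None:
            return self.walk_gain
        return 1.0 + self.ramp_amplitude_sd * math.sqrt(lam0) / lam0

    @property
    def ramp_amplitude_counts(self) -> float:
        """Plateau rate increase in counts/bin of locomotor channels."""
        return (self.effective_walk_gain - 1.0) * self.baseline_counts_per_bin

    @classmethod
    def for_condition(cls, condition: str, **overrides) -> "SessionParams":
        """Defaults for the intact or spinal-cord-injured (sci) condition.

        SCI is emulated minimally: longer MI lead (182 ms), shorter MLR lag
        (55 ms), larger trial-to-trial rate variability, and fewer
        speed-coupled MLR channels.
        """
        if condition == "intact":
            base: dict = {}
        elif condition == "sci":
            base = dict(mi_lead_ms=182.0, mlr_lag_ms=55.0, rate_noise_cv=0.3,
                        frac_speed_coupled_mlr=0.25)
        else:
            raise ValueError(f"unknown condition {condition!r}")
        base.update(condition=condition, **overrides)
        return cls(**base)


@dataclasses.dataclass
class BehaviorGroundTruth:
    """Per-bin behavioral state and the event times every analysis is scored against."""

    state_per_bin: np.ndarray        # 0 idle / 1 walk
    foot_off_times_ms: np.ndarray
    foot_strike_times_ms: np.ndarray
    speed_mm_s: np.ndarray
    trial_boundaries_ms: list[tuple[float, float]]
    bout_spans_ms: list[tuple[float, float]]   # (first foot-off, last foot-strike)
    bin_ms: float = 10.0

    @property
    def n_bins(self) -> int:
        return self.state_per_bin.size

    @property
    def gait_initiations_ms(self) -> np.ndarray:
        """First foot-off of each walk bout."""
        return np.asarray([s for s, _ in self.bout_spans_ms], dtype=float)

    @property
    def walk_fraction(self) -> float:
        return float(self.state_per_bin.mean())

    def complete_trials(self) -> list[tuple[float, float]]:
        """Trials that contain both idle and walk bins."""
        out = []
        for t0, t1 in self.trial_boundaries_ms:
            i0 = int(t0 // self.bin_ms)
            i1 = int(t1 // self.bin_ms)
            seg = self.state_per_bin[i0:i1]
            if seg.size and seg.min() == 0 and seg.max() == 1:
                out.append((t0, t1))
        return out


@dataclasses.dataclass
class SyntheticSession:
    params: SessionParams
    behavior: BehaviorGroundTruth
    mi_counts: CountMatrix
    mlr_counts: CountMatrix
    unit_labels: dict[str, np.ndarray]
    kinematics: pd.DataFrame | None = None
    animal_id: int | None = None

    def __post_init__(self) -> None:
        n = self.behavior.n_bins
        if self.mi_counts.n_bins != n or self.mlr_counts.n_bins != n:
            raise ValueError("count matrices and behavior trace disagree in length")


# ---------------------------------------------------------------------------
# behavior


def generate_behavior(params: SessionParams) -> BehaviorGroundTruth:
    """Alternating idle/walk bouts with trapezoidal speed and gait events.

    Idle and walk bout durations are drawn uniformly from their configured
    ranges (both default 5-10 s), which realises the even idle/walk balance
    of an overground trial.  Foot-offs are laid down every ``cycle_ms``
    within a walk bout, each followed by a foot-strike ``swing_ms`` later;
    walk bins span [first foot-off, last foot-strike).
    """
    rng = np.random.default_rng(params.seed)
    total_ms = params.duration_s * MS
    min_needed = params.idle_bout_s[0] + (
        params.walk_bout_s[0] if params.walk_bout_prob > 0 else 0.0)
    if params.duration_s < min_needed:
        raise ValueError(
            f"duration {params.duration_s} s too short for one bout "
            f"(needs >= {min_needed} s)")

    n_bins = params.n_bins
    state = np.zeros(n_bins, dtype=np.int8)
    speed = np.zeros(n_bins)
    centers = (np.arange(n_bins) + 0.5) * params.bin_ms
    foot_off: list[float] = []
    foot_strike: list[float] = []
    trials: list[tuple[float, float]] = []
    bouts: list[tuple[float, float]] = []

    t = 0.0
    while t < total_ms - 1e-9:
        trial_start = t
        idle_d = rng.uniform(*params.idle_bout_s) * MS
        do_walk = rng.uniform() < params.walk_bout_prob
        walk_d = rng.uniform(*params.walk_bout_s) * MS if do_walk else 0.0
        idle_end = min(t + idle_d, total_ms)
        t = idle_end
        if do_walk and idle_end < total_ms:
            bout_end = min(idle_end + walk_d, total_ms)
            n_cycles = int(math.floor((bout_end - idle_end - params.swing_ms)
                                      / params.cycle_ms)) + 1
            if n_cycles >= 1:
                offs = idle_end + np.arange(n_cycles) * params.cycle_ms
                strikes = offs + params.swing_ms
                foot_off.extend(offs)
                foot_strike.extend(strikes)
                span = (float(offs[0]), float(strikes[-1]))
                bouts.append(span)
                i0 = int(span[0] // params.bin_ms)
                i1 = int(span[1] // params.bin_ms)
                state[i0:i1] = 1
                sl = slice(i0, i1)
                up = (centers[sl] - span[0]) / (params.accel_s * MS)
                down = (span[1] - centers[sl]) / (params.accel_s * MS)
                speed[sl] = params.peak_speed_mm_s * np.clip(
                    np.minimum(np.minimum(up, down), 1.0), 0.0, None)
            t = bout_end
        trials.append((trial_start, t))

    return BehaviorGroundTruth(
        state_per_bin=state,
        foot_off_times_ms=np.asarray(foot_off),
        foot_strike_times_ms=np.asarray(foot_strike),
        speed_mm_s=speed,
        trial_boundaries_ms=trials,
        bout_spans_ms=bouts,
        bin_ms=params.bin_ms,
    )


# ---------------------------------------------------------------------------
# neural counts


def _ramp_profile(centers_ms: np.ndarray, onset_ms: float, offset_ms: float,
                  rise_ms: float) -> np.ndarray:
    """Linear rise over rise_ms, plateau to offset, linear fall over rise_ms."""
    up = (centers_ms - onset_ms) / rise_ms
    down = 1.0 - (centers_ms - offset_ms) / rise_ms
    return np.clip(np.minimum(up, down), 0.0, 1.0)


def _population_counts(rng: np.random.Generator, params: SessionParams,
                       behavior: BehaviorGroundTruth, n_channels: int,
                       frac_locomotor: float, frac_speed_coupled: float,
                       onset_shift_ms: float, noise: str
                       ) -> tuple[CountMatrix, np.ndarray, np.ndarray]:
    lam0 = params.baseline_counts_per_bin
    amp = params.ramp_amplitude_counts
    centers = (np.arange(behavior.n_bins) + 0.5) * params.bin_ms

    n_loco = int(round(frac_locomotor * n_channels))
    loco = np.zeros(n_channels, dtype=bool)
    loco[rng.choice(n_channels, size=n_loco, replace=False)] = True
    n_sc = int(round(frac_speed_coupled * n_channels))
    sc = np.zeros(n_channels, dtype=bool)
    if n_sc:
        sc[rng.choice(n_channels, size=n_sc, replace=False)] = True

    rate = np.full((n_channels, behavior.n_bins), lam0)
    k_speed = params.speed_gain_sd * math.sqrt(lam0) / params.peak_speed_mm_s

    prev_end = -np.inf
    for (span_start, span_end) in behavior.bout_spans_ms:
        onset = span_start + onset_shift_ms
        if onset < prev_end:
            log.warning("ramp onset %.0f ms truncated at previous bout end %.0f ms",
                        onset, prev_end)
            onset = prev_end
        prof = _ramp_profile(centers, onset, span_end, params.ramp_rise_ms)
        active = prof > 0
        if params.rate_noise_cv > 0:
            g = np.clip(1.0 + params.rate_noise_cv
                        * rng.standard_normal(n_channels), 0.0, None)
        else:
            g = np.ones(n_channels)
        rate[np.ix_(loco, active)] += amp * np.outer(g[loco], prof[active])
        # speed modulation rides on the population's locomotor activation:
        # the affine-in-speed term is gated by the same ramp profile, so
        # speed-coupled channels do not fire ahead of the population onset
        if np.any(sc) and np.any(active):
            rate[np.ix_(sc, active)] += k_speed * np.outer(
                g[sc], behavior.speed_mm_s[active] * prof[active])
        prev_end = span_end + params.ramp_rise_ms

    if noise == "poisson":
        counts = rng.poisson(rate).astype(float)
    elif noise == "none":
        counts = rate.copy()
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return CountMatrix(counts, params.bin_ms, 0.0), loco, sc


def generate_neural(behavior: BehaviorGroundTruth, params: SessionParams,
                    noise: str = "poisson"
                    ) -> tuple[CountMatrix, CountMatrix, dict[str, np.ndarray]]:
    """Per-bin Poisson counts for the MI and MLR arrays.

    Locomotor MI channels ramp up ``mi_lead_ms`` before each gait
    initiation; locomotor MLR channels ramp ``mlr_lag_ms`` after it; both
    plateau at baseline + ``ramp_amplitude_sd`` baseline-SDs until the
    bout's last foot-strike.  Speed-coupled MLR channels gain a rate term
    affine in the speed trace.  Per-bout, per-channel gain jitter has
    coefficient of variation ``rate_noise_cv``.
    """
    if behavior.n_bins != params.n_bins:
        raise ValueError("behavior trace inconsistent with params duration")
    ss = np.random.SeedSequence(params.seed)
    rng_mi, rng_mlr = (np.random.default_rng(s) for s in ss.spawn(2))
    mi, mi_loco, _ = _population_counts(
        rng_mi, params, behavior, params.n_mi_channels,
        params.frac_locomotor_mi, 0.0, -params.mi_lead_ms, noise)
    mlr, mlr_loco, mlr_sc = _population_counts(
        rng_mlr, params, behavior, params.n_mlr_channels,
        params.frac_locomotor_mlr, params.frac_speed_coupled_mlr,
        +params.mlr_lag_ms, noise)
    labels = {"mi_locomotor": mi_loco, "mlr_locomotor": mlr_loco,
              "mlr_speed_coupled": mlr_sc}
    return mi, mlr, labels


# ---------------------------------------------------------------------------
# raw traces


def _biphasic_waveform(rate_hz: float) -> tuple[np.ndarray, int]:
    """Unit-noise-referenced biphasic spike: -8 SD trough then small rebound.

    Returns the waveform and the index of the trough (the ground-truth
    spike time within the waveform).
    """
    t = np.arange(-0.4e-3, 1.0e-3, 1.0 / rate_hz)
    w = (-8.0 * np.exp(-(t ** 2) / (2 * (0.1e-3) ** 2))
         + 2.5 * np.exp(-((t - 0.45e-3) ** 2) / (2 * (0.18e-3) ** 2)))
    return w, int(np.argmin(w))


def generate_raw_segment(counts: CountMatrix, seed: int = 0,
                         rate_hz: float = 24000.0
                         ) -> tuple[RawTrace, list[np.ndarray]]:
    """24 kHz unit-variance Gaussian noise with one spike waveform per count.

    Spikes are placed at uniformly jittered times within their bin; the
    returned ground-truth lists hold the trough times (ms) per channel.
    Desk-scale only: refuses segments longer than 10 s.
    """
    if counts.n_bins * counts.bin_ms > 10_000.0 + 1e-9:
        raise ValueError("raw synthesis is limited to segments <= 10 s")
    rng = np.random.default_rng(seed)
    n_samples = int(round(counts.n_bins * counts.bin_ms / MS * rate_hz))
    trace = rng.standard_normal((counts.n_channels, n_samples))
    w, trough = _biphasic_waveform(rate_hz)
    truth: list[np.ndarray] = []
    for ch in range(counts.n_channels):
        times = []
        for b in range(counts.n_bins):
            c = int(round(counts.counts[ch, b]))
            for _ in range(c):
                t_ms = counts.t0_ms + (b + rng.uniform()) * counts.bin_ms
                i0 = int(round(t_ms / MS * rate_hz)) - trough
                sl = slice(max(i0, 0), min(i0 + w.size, n_samples))
                if sl.stop <= sl.start:
                    continue
                trace[ch, sl] += w[sl.start - i0: sl.stop - i0]
                times.append((i0 + trough) / rate_hz * MS)
        truth.append(np.sort(np.asarray(times)))
    return RawTrace(trace, rate_hz), truth


# ---------------------------------------------------------------------------
# kinematics


#: Default per-cycle gait feature set: (mean, SD) per feature, bipedal rat
#: scale (mm / deg / s).  Extensible: pass a custom table to
#: generate_kinematics or KinematicsConfig.
DEFAULT_FEATURES: dict[str, tuple[float, float]] = {
    "step_height": (25.0, 5.0),          # mm
    "hip_excursion": (20.0, 4.0),        # deg
    "whole_limb_oscillation": (35.0, 5.0),
    "thigh_amplitude": (25.0, 4.0),
    "leg_amplitude": (30.0, 5.0),
    "foot_amplitude": (40.0, 6.0),
    "knee_range": (60.0, 8.0),
    "ankle_range": (70.0, 9.0),
    "stride_length": (120.0, 15.0),      # mm
    "swing_duration": (0.25, 0.04),      # s
    "stance_duration": (0.45, 0.08),
    "cycle_duration": (0.70, 0.10),
    "drag_fraction": (0.20, 0.08),
    "max_toe_speed": (400.0, 60.0),      # mm/s
    "hip_height": (55.0, 5.0),           # mm
}

#: Graded DBS intensity levels (% of the maximal effective amplitude).
DBS_LEVELS = (0, 33, 66, 100)


def dbs_intensity_effects(max_gain: float = 1.5,
                          features: tuple[str, ...] = ("step_height",
                                                       "hip_excursion")
                          ) -> dict[int, dict[str, float]]:
    """Monotone multiplicative condition effects over the DBS level grid."""
    return {lvl: {f: 1.0 + (max_gain - 1.0) * lvl / 100.0 for f in features}
            for lvl in DBS_LEVELS}


@dataclasses.dataclass
class KinematicsConfig:
    features: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_FEATURES))
    mean_scale: float = 1.0   # per-animal random effect multiplier


def generate_kinematics(behavior: BehaviorGroundTruth,
                        condition_effects: dict | None = None,
                        seed: int = 0,
                        config: KinematicsConfig | None = None) -> pd.DataFrame:
    """Per-cycle feature vectors from condition-dependent Gaussians.

    One row per gait cycle and condition; condition effects are
    multiplicative shifts of the feature means.  Returns an empty frame
    (with a warning) when the behavior contains no gait cycle.
    """
    config = config or KinematicsConfig()
    n_cycles = int(behavior.foot_off_times_ms.size)
    conditions = condition_effects if condition_effects is not None else {"baseline": {}}
    names = list(config.features)
    if n_cycles == 0:
        warnings.warn("behavior contains no gait cycle; empty feature matrix")
        return pd.DataFrame(columns=names + ["condition"])
    rng = np.random.default_rng(seed)
    frames = []
    for cond, effects in conditions.items():
        data = {}
        for f in names:
            mu, sd = config.features[f]
            mu = mu * config.mean_scale * float(effects.get(f, 1.0))
            data[f] = rng.normal(mu, sd, size=n_cycles)
        df = pd.DataFrame(data)
        df["condition"] = cond
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_toe_trajectory(n_cycles: int = 10, rate_hz: float = 200.0,
                            cycle_s: float = 0.7, step_height: float = 30.0,
                            stride_length: float = 120.0, noise_mm: float = 0.0,
                            seed: int = 0) -> dict[str, np.ndarray]:
    """Sinusoidal toe/hip marker trajectories for exercising cycle detection.

    Toe height follows max(0, sin)**2 humps (one per cycle); x advances one
    stride per cycle.  Returns arrays ``t_ms``, ``toe_x``, ``toe_y``,
    ``hip_x``, ``hip_y``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(n_cycles * cycle_s * rate_hz))
    t = np.arange(n) / rate_hz
    phase = 2 * np.pi * t / cycle_s
    toe_y = step_height * np.clip(np.sin(phase), 0.0, None) ** 2
    toe_x = stride_length * t / cycle_s
    hip_y = np.full(n, 55.0)
    hip_x = toe_x + 10.0
    if noise_mm > 0:
        toe_y = toe_y + rng.normal(0, noise_mm, n)
    return {"t_ms": t * MS, "toe_x": toe_x, "toe_y": toe_y,
            "hip_x": hip_x, "hip_y": hip_y}


# ---------------------------------------------------------------------------
# sessions and cohorts


def generate_session(params: SessionParams, noise: str = "poisson",
                     with_kinematics: bool = True,
                     kin_config: KinematicsConfig | None = None,
                     animal_id: int | None = None) -> SyntheticSession:
    """Behavior + neural counts (+ kinematics) for one session."""
    behavior = generate_behavior(params)
    mi, mlr, labels = generate_neural(behavior, params, noise=noise)
    kin = None
    if with_kinematics and behavior.foot_off_times_ms.size:
        kin = generate_kinematics(behavior, {params.condition: {}},
                                  seed=params.seed + 1, config=kin_config)
    return SyntheticSession(params, behavior, mi, mlr, labels, kin, animal_id)


def generate_cohort(n_animals: int,
                    params_per_condition: SessionParams | dict[str, SessionParams] | None = None,
                    seed: int = 0, between_animal_rate_cv: float = 0.2,
                    between_animal_feature_cv: float = 0.1
                    ) -> list[SyntheticSession]:
    """Independent seeded sessions with per-animal random effects.

    Each animal scales its baseline firing rate and kinematic feature
    means by draws with the configured between-animal CVs.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if params_per_condition is None:
        params_per_condition = {"intact": SessionParams()}
    if isinstance(params_per_condition, SessionParams):
        params_per_condition = {params_per_condition.condition: params_per_condition}
    master = np.random.default_rng(seed)
    sessions: list[SyntheticSession] = []
    for a in range(n_animals):
        rate_f = float(np.clip(1.0 + between_animal_rate_cv * master.standard_normal(),
                               0.2, None))
        feat_f = float(np.clip(1.0 + between_animal_feature_cv * master.standard_normal(),
                               0.2, None))
        for p in params_per_condition.values():
            sub_seed = int(master.integers(0, 2 ** 31 - 1))
            pa = dataclasses.replace(p, seed=sub_seed,
                                     baseline_rate_hz=p.baseline_rate_hz * rate_f)
            sessions.append(generate_session(
                pa, kin_config=KinematicsConfig(mean_scale=feat_f), animal_id=a))
    return sessions
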