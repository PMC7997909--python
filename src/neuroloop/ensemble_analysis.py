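"""Population analyses of ensemble firing around gait initiation.

* ``select_locomotor_units``: channels whose per-bin rate is higher during
  walking than idling (one-sided rank-sum at alpha).
* ``onset_latency``: for each gait initiation, the time at which the
  cumulative ensemble firing first crosses 2 SD above its pre-initiation
  baseline, with sub-bin linear interpolation of the crossing.  Negative
  latencies mean activation before the first foot-off; motor-cortex (MI)
  ensembles lead, midbrain (MLR) ensembles lag.
* ``speed_encoding``: per-channel R^2 of smoothed rate against smoothed
  locomotor speed over walk bins (200 ms moving averages on both traces),
  and the fraction of channels with R^2 > 0.2.
* ``compare_populations``: paired one-tailed Wilcoxon signed-rank test of
  MI vs MLR latencies across animals/sessions.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

from .mua import CountMatrix, SmootherConfig, ensemble_rate, moving_average

#: Baseline window relative to each first foot-off (ms).
DEFAULT_BASELINE_MS = (-2500.0, -500.0)
#: Window searched for the 2-SD upward crossing, relative to initiation (ms).
DEFAULT_SEARCH_MS = (-1000.0, 1000.0)


@dataclasses.dataclass
class LatencyEstimate:
    """Crossing time relative to the first foot-off (negative = before)."""

    crossing_time_ms: float
    threshold_sd: float = 2.0
    baseline_window_ms: tuple[float, float] = DEFAULT_BASELINE_MS

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.crossing_time_ms)


@dataclasses.dataclass
class SpeedEncodingResult:
    r2_per_channel: np.ndarray
    fraction_above: float
    threshold: float = 0.2


def select_locomotor_units(counts: CountMatrix,
                           truth, alpha: float = 0.05) -> np.ndarray:
    """Channels with a locomotor-related increase in activity.

    Inclusion: walk-bin mean rate above idle-bin mean rate AND one-sided
    rank-sum (Mann-Whitney) p < alpha on the per-bin counts.
    """
    state = np.asarray(truth.state_per_bin if hasattr(truth, "state_per_bin")
                       else truth).astype(bool)
    if not state.any() or state.all():
        raise ValueError("both idle and walk states must be present")
    x = counts.counts
    if x.shape[1] != state.size:
        raise ValueError("counts and state trace differ in length")
    keep = []
    for ch in range(x.shape[0]):
        walk, idle = x[ch, state], x[ch, ~state]
        if walk.mean() <= idle.mean():
            continue
        p = stats.mannwhitneyu(walk, idle, alternative="greater").pvalue
        if p < alpha:
            keep.append(ch)
    return np.asarray(keep, dtype=int)


def _interp_crossing(t: np.ndarray, z: np.ndarray, thresh: float,
                     sustain_bins: int = 1) -> float:
    """Time of the first sustained upward crossing of ``thresh``; NaN if none.

    A crossing qualifies when the trace stays above the threshold for the
    next ``sustain_bins`` samples (or to the window end), which rejects
    transient noise excursions while leaving a ramp's crossing time
    untouched.  Linear interpolation between the bracketing samples, so a
    noiseless ramp of slope s starting at t0 crosses exactly at t0 +
    thresh/s.
    """
    above = z > thresh
    idx = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    for k in idx:
        stop = min(k + sustain_bins, z.size)
        if np.all(above[k:stop]):
            z0, z1 = z[k - 1], z[k]
            frac = (thresh - z0) / (z1 - z0)
            return float(t[k - 1] + frac * (t[k] - t[k - 1]))
    return float("nan")


def onset_latency(trace, gait_initiations_ms, threshold_sd: float = 2.0,
                  baseline_window_ms: tuple[float, float] = DEFAULT_BASELINE_MS,
                  search_window_ms: tuple[float, float] = DEFAULT_SEARCH_MS,
                  bin_ms: float | None = None, t0_ms: float = 0.0,
                  zscore: str = "per_initiation",
                  sustain_ms: float = 100.0) -> list[LatencyEstimate]:
    """Threshold-crossing latency of an ensemble trace per gait initiation.

    ``trace`` is an :class:`~neuroloop.mua.EnsembleTrace` or a plain array
    (summed smoothed ensemble rate).  With ``zscore='per_initiation'`` the
    trace is re-referenced to the mean/SD of the baseline window preceding
    each initiation; with ``'none'`` the values are taken as already being
    z-units.  Crossings must remain above threshold for ``sustain_ms``
    (noise rejection).  No qualifying crossing inside the search window
    -> missing estimate.
    """
    values = np.asarray(getattr(trace, "values", trace), dtype=float)
    if bin_ms is None:
        bin_ms = float(getattr(trace, "bin_ms", 10.0))
    t0_ms = float(getattr(trace, "t0_ms", t0_ms))
    centers = t0_ms + (np.arange(values.size) + 0.5) * bin_ms
    b0, b1 = baseline_window_ms
    s0, s1 = search_window_ms
    if b1 <= b0 or b0 >= 0:
        raise ValueError("baseline window must precede the initiation")
    out: list[LatencyEstimate] = []
    for init in np.atleast_1d(np.asarray(gait_initiations_ms, dtype=float)):
        if zscore == "per_initiation":
            bsel = (centers >= init + b0) & (centers < init + b1)
            if bsel.sum() < 2:
                raise ValueError("baseline window outside the trace")
            mu, sd = values[bsel].mean(), values[bsel].std()
            if sd == 0:
                raise ValueError("zero baseline variance")
            z = (values - mu) / sd
        elif zscore == "none":
            z = values
        else:
            raise ValueError(f"unknown zscore mode {zscore!r}")
        ssel = (centers >= init + s0) & (centers <= init + s1)
        t_cross = _interp_crossing(centers[ssel], z[ssel], threshold_sd,
                                   max(1, int(round(sustain_ms / bin_ms))))
        out.append(LatencyEstimate(t_cross - init if np.isfinite(t_cross)
                                   else float("nan"), threshold_sd,
                                   (b0, b1)))
    return out


def population_onset_latency(counts: CountMatrix, truth, alpha: float = 0.05,
                             threshold_sd: float = 2.0,
                             baseline_window_ms=DEFAULT_BASELINE_MS,
                             search_window_ms=DEFAULT_SEARCH_MS,
                             smoother: SmootherConfig | None = None,
                             sustain_ms: float = 100.0) -> dict:
    """Locomotor-unit selection + ensemble crossing latency for one session.

    Returns the per-initiation latencies (ms, relative to first foot-off),
    their mean/SD over non-missing estimates, and bookkeeping counts.
    """
    units = select_locomotor_units(counts, truth, alpha)
    if units.size == 0:
        raise ValueError("no locomotor-related units selected")
    ens = ensemble_rate(counts, units, smoother)
    inits = truth.gait_initiations_ms
    # drop initiations whose baseline window precedes the recording
    valid = inits + baseline_window_ms[0] >= 0
    ests = onset_latency(ens, inits[valid], threshold_sd, baseline_window_ms,
                         search_window_ms, bin_ms=counts.bin_ms,
                         t0_ms=counts.t0_ms, sustain_ms=sustain_ms)
    lat = np.asarray([e.crossing_time_ms for e in ests])
    ok = np.isfinite(lat)
    return {
        "unit_ids": units,
        "latencies_ms": lat,
        "n_initiations": int(lat.size),
        "n_missing": int((~ok).sum()),
        "mean_ms": float(lat[ok].mean()) if ok.any() else float("nan"),
        "sd_ms": float(lat[ok].std(ddof=1)) if ok.sum() > 1 else float("nan"),
    }


def speed_encoding(counts: CountMatrix, speed_mm_s: np.ndarray,
                   walk_mask: np.ndarray, window_ms: float = 200.0,
                   r2_threshold: float = 0.2) -> SpeedEncodingResult:
    """Per-channel R^2 of smoothed rate on smoothed speed over walk bins."""
    speed = np.asarray(speed_mm_s, dtype=float)
    walk = np.asarray(walk_mask).astype(bool)
    if speed.size != counts.n_bins or walk.size != counts.n_bins:
        raise ValueError("speed / mask length must match the count matrix")
    sm_speed = moving_average(speed, window_ms, counts.bin_ms)[walk]
    if sm_speed.size < 3 or np.var(sm_speed) == 0:
        raise ValueError("speed has zero variance over walk bins")
    sm_rate = moving_average(counts.counts, window_ms, counts.bin_ms)[:, walk]
    r2 = np.empty(counts.n_channels)
    for ch in range(counts.n_channels):
        if np.var(sm_rate[ch]) == 0:
            r2[ch] = 0.0
            continue
        r = stats.linregress(sm_speed, sm_rate[ch])
        r2[ch] = r.rvalue ** 2
    return SpeedEncodingResult(r2, float((r2 > r2_threshold).mean()),
                               r2_threshold)


def compare_populations(mi_latencies, mlr_latencies,
                        alternative: str = "less") -> dict:
    """Paired one-tailed Wilcoxon signed-rank test of MI vs MLR latencies.

    Default alternative 'less' tests that MI crossings occur earlier than
    the paired MLR crossings.  Degenerate below n=5 (warned, not refused).
    """
    mi = np.asarray(mi_latencies, dtype=float)
    mlr = np.asarray(mlr_latencies, dtype=float)
    if mi.size != mlr.size:
        raise ValueError("populations must be paired")
    if mi.size < 5:
        warnings.warn("n < 5: signed-rank test is degenerate", stacklevel=2)
    if np.allclose(mi, mlr):
        stat, p = 0.0, 1.0
    else:
        res = stats.wilcoxon(mi, mlr, alternative=alternative)
        stat, p = float(res.statistic), float(res.pvalue)
    return {
        "statistic": stat,
        "p_value": p,
        "alternative": alternative,
        "n": int(mi.size),
        "mi_mean_ms": float(mi.mean()), "mi_sd_ms": float(mi.std(ddof=1)),
        "mlr_mean_ms": float(mlr.mean()), "mlr_sd_ms": float(mlr.std(ddof=1)),
    }
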