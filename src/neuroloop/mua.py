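"""Multiunit-activity (MUA) signal processing.

Turns raw extracellular traces or binned spike counts into the smoothed
population signals every downstream analysis consumes:

* threshold-crossing spike detection on bandpassed, z-scored voltage
  (negative-going events at -3 SD, debounced by a refractory period),
* half-open 10 ms binning into a channels x bins :class:`CountMatrix`,
* causal Gaussian FIR smoothing whose kernel decays by 80% in 40 ms
  (sigma^2 = 8 / ln 5 bins^2, so k[4]/k[0] = 0.2 exactly),
* centered moving-average low-pass (200 ms default, shrinking edges),
* normalized cumulative ensemble firing: the population-summed smoothed
  rate of a unit set, z-scored against a baseline window.

No spike sorting is performed; MUA is deliberately unsorted.
"""
from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np
from scipy import signal as sps

log = logging.getLogger(__name__)

#: Gaussian kernel variance (bins^2) chosen so that the smoothing kernel
#: attenuates to 20% of its peak 4 bins (40 ms) away: exp(-16/(2*s2)) = 0.2.
GAUSSIAN_SIGMA_SQ_BINS = 8.0 / math.log(5.0)


# ---------------------------------------------------------------------------
# containers


@dataclasses.dataclass
class RawTrace:
    """Raw multichannel extracellular voltage, arbitrary units."""

    samples: np.ndarray  # (channels, n_samples)
    rate_hz: float = 24000.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("raw trace contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.samples.shape[1] / self.rate_hz * 1000.0


@dataclasses.dataclass
class CountMatrix:
    """Channels x bins spike counts on a half-open [t, t+bin_ms) grid."""

    counts: np.ndarray  # (channels, bins)
    bin_ms: float = 10.0
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def bin_starts_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_bins) * self.bin_ms

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return self.bin_starts_ms + self.bin_ms / 2.0

    def bin_index(self, time_ms: float) -> int:
        """Index of the half-open bin containing ``time_ms``."""
        return int(np.floor((time_ms - self.t0_ms) / self.bin_ms))

    def slice_ms(self, start_ms: float, end_ms: float) -> "CountMatrix":
        """Sub-matrix of all bins whose start lies in [start_ms, end_ms)."""
        i0 = max(0, int(np.ceil((start_ms - self.t0_ms) / self.bin_ms - 1e-9)))
        i1 = min(self.n_bins, int(np.ceil((end_ms - self.t0_ms) / self.bin_ms - 1e-9)))
        return CountMatrix(self.counts[:, i0:i1].copy(), self.bin_ms,
                           self.t0_ms + i0 * self.bin_ms)


@dataclasses.dataclass
class SmootherConfig:
    """Causal Gaussian FIR used throughout the decoding path.

    The width is not free: sigma^2 = 8/ln 5 bins^2 makes the kernel decay
    by exactly 80% four bins (40 ms) from its peak.  The kernel is
    truncated at ``kernel_halfwidth_bins`` (default 12; < 0.1% mass lost)
    and normalized to unit sum so constant inputs pass through unchanged.
    """

    kernel_sigma_bins: float = math.sqrt(GAUSSIAN_SIGMA_SQ_BINS)
    kernel_halfwidth_bins: int = 12
    normalize: bool = True
    causal: bool = True

    def __post_init__(self) -> None:
        if self.kernel_sigma_bins <= 0:
            raise ValueError("kernel_sigma_bins must be positive")
        if self.kernel_halfwidth_bins < 4:
            raise ValueError("kernel_halfwidth_bins must be >= 4")

    def kernel(self) -> np.ndarray:
        """One-sided kernel k[j] = exp(-j^2 / (2 sigma^2)), j = 0..halfwidth."""
        j = np.arange(self.kernel_halfwidth_bins + 1, dtype=float)
        k = np.exp(-(j ** 2) / (2.0 * self.kernel_sigma_bins ** 2))
        if self.normalize:
            if self.causal:
                k = k / k.sum()
            else:
                k = k / (2.0 * k.sum() - k[0])
        return k


@dataclasses.dataclass
class EnsembleTrace:
    """Cumulative population firing in z-units relative to a baseline window."""

    values: np.ndarray
    unit_ids: np.ndarray
    baseline_window_ms: tuple[float, float]
    bin_ms: float = 10.0
    t0_ms: float = 0.0

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return self.t0_ms + (np.arange(self.values.size) + 0.5) * self.bin_ms


# ---------------------------------------------------------------------------
# operations


def bandpass_zscore(trace: RawTrace, band: tuple[float, float] = (700.0, 3000.0),
                    order: int = 4) -> np.ndarray:
    """Zero-phase bandpass then per-channel z-score.

    Raises if the sampling rate is below twice the band top (aliasing).
    """
    lo, hi = band
    if trace.rate_hz < 2.0 * hi:
        raise ValueError(
            f"sampling rate {trace.rate_hz} Hz below 2x band top {hi} Hz (aliasing)")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=trace.rate_hz,
                     output="sos")
    filt = sps.sosfiltfilt(sos, trace.samples, axis=-1)
    mu = filt.mean(axis=-1, keepdims=True)
    sd = filt.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return (filt - mu) / sd


def detect_spikes(trace: RawTrace, band: tuple[float, float] = (700.0, 3000.0),
                  threshold_sd: float = 3.0,
                  refractory_ms: float = 1.0) -> list[np.ndarray]:
    """Negative threshold-crossing MUA event times (ms) per channel.

    The event time is the first sub-threshold sample of each crossing of
    -``threshold_sd`` on the bandpassed z-scored trace; crossings within
    ``refractory_ms`` of an accepted event are debounced.
    """
    z = bandpass_zscore(trace, band)
    th = -abs(threshold_sd)
    refractory = int(round(refractory_ms * trace.rate_hz / 1000.0))
    out: list[np.ndarray] = []
    for ch in range(z.shape[0]):
        zc = z[ch]
        idx = np.flatnonzero((zc[1:] < th) & (zc[:-1] >= th)) + 1
        if refractory > 1 and idx.size:
            kept = [idx[0]]
            for i in idx[1:]:
                if i - kept[-1] >= refractory:
                    kept.append(i)
            idx = np.asarray(kept)
        out.append(idx / trace.rate_hz * 1000.0)
    return out


def bin_counts(events: list[np.ndarray] | np.ndarray, bin_ms: float = 10.0,
               t0_ms: float = 0.0, duration_ms: float | None = None) -> CountMatrix:
    """Histogram per-channel event times into a half-open 10 ms grid.

    Every event must fall inside [t0_ms, t0_ms + duration_ms); offenders are
    reported in the raised error.  Column sums equal event counts.
    """
    if isinstance(events, np.ndarray) and events.ndim == 1:
        events = [events]
    if duration_ms is None:
        top = max((float(np.max(e)) for e in events if len(e)), default=0.0)
        duration_ms = (np.floor(top / bin_ms) + 1) * bin_ms
    n_bins = int(round(duration_ms / bin_ms))
    if abs(n_bins * bin_ms - duration_ms) > 1e-6:
        raise ValueError("bin_ms must divide duration_ms evenly")
    edges = t0_ms + np.arange(n_bins + 1) * bin_ms
    rows = []
    for ch, ev in enumerate(events):
        ev = np.asarray(ev, dtype=float)
        bad = ev[(ev < t0_ms) | (ev >= t0_ms + duration_ms)]
        if bad.size:
            raise ValueError(
                f"channel {ch}: {bad.size} event(s) outside "
                f"[{t0_ms}, {t0_ms + duration_ms}) ms: {bad[:10].tolist()}")
        rows.append(np.histogram(ev, bins=edges)[0])
    return CountMatrix(np.asarray(rows, dtype=float), bin_ms, t0_ms)


def _as_array(counts: CountMatrix | np.ndarray) -> np.ndarray:
    if isinstance(counts, CountMatrix):
        return counts.counts
    return np.atleast_2d(np.asarray(counts, dtype=float))


def fir_smooth(counts: CountMatrix | np.ndarray,
               cfg: SmootherConfig | None = None) -> np.ndarray:
    """Per-channel Gaussian FIR smoothing (causal by default).

    Edges are renormalized by the kernel mass actually applied, so a
    constant input maps to the same constant everywhere.  Linear and
    translation-equivariant away from the edges.
    """
    cfg = cfg or SmootherConfig()
    x = _as_array(counts)
    squeeze = isinstance(counts, np.ndarray) and np.asarray(counts).ndim == 1
    k = cfg.kernel()
    if cfg.causal:
        y = sps.lfilter(k, [1.0], x, axis=-1)
        # renormalize the warm-up region where only part of the kernel fits
        h = k.size - 1
        m = min(h, x.shape[1])
        denom = np.cumsum(k)[:m] / k.sum()
        y[:, :m] = y[:, :m] / denom
    else:
        full = np.concatenate([k[:0:-1], k])
        y = np.empty_like(x)
        ones = np.ones(x.shape[1])
        denom = np.convolve(ones, full, mode="same") / full.sum()
        for ch in range(x.shape[0]):
            y[ch] = np.convolve(x[ch], full, mode="same") / full.sum() / denom
    return y[0] if squeeze else y


def moving_average(x: np.ndarray, window_ms: float = 200.0,
                   bin_ms: float = 10.0) -> np.ndarray:
    """Centered moving mean with shrinking windows at the edges.

    For an even window of w bins the window at index i spans
    [i - w//2, i + w - w//2 - 1]; interior output of an alternating +-1
    input is therefore exactly zero.
    """
    w = max(1, int(round(window_ms / bin_ms)))
    if w == 1:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    x2 = np.atleast_2d(x)
    n = x2.shape[1]
    left = w // 2
    right = w - left - 1
    csum = np.concatenate([np.zeros((x2.shape[0], 1)), np.cumsum(x2, axis=1)], axis=1)
    i = np.arange(n)
    lo = np.clip(i - left, 0, n)
    hi = np.clip(i + right + 1, 0, n)
    out = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return out[0] if one_d else out


def ensemble_rate(counts: CountMatrix | np.ndarray,
                  unit_ids: np.ndarray | list[int],
                  cfg: SmootherConfig | None = None) -> np.ndarray:
    """Summed smoothed firing of a unit set (no baseline normalization)."""
    unit_ids = np.asarray(unit_ids, dtype=int)
    if unit_ids.size == 0:
        raise ValueError("unit_ids must be non-empty")
    x = _as_array(counts)[unit_ids]
    return fir_smooth(x, cfg).sum(axis=0)


def cumulative_firing(counts: CountMatrix, unit_ids: np.ndarray | list[int],
                      baseline_window_ms: tuple[float, float],
                      cfg: SmootherConfig | None = None) -> EnsembleTrace:
    """Normalized cumulative population firing.

    Sums the smoothed rates of ``unit_ids`` and z-scores the sum against
    the mean and SD inside ``baseline_window_ms`` (absolute session time).
    The result is invariant to channel ordering and to uniform positive
    rescaling of the counts.
    """
    s = ensemble_rate(counts, unit_ids, cfg)
    b0, b1 = baseline_window_ms
    if b1 <= b0:
        raise ValueError("baseline window must have positive length")
    if b1 - b0 < 1000.0:
        warnings.warn("baseline window shorter than 1 s; SD estimate may be noisy")
    i0 = max(0, counts.bin_index(b0))
    i1 = min(counts.n_bins, counts.bin_index(b1))
    if i1 - i0 < 2:
        raise ValueError("baseline window contains fewer than 2 bins")
    base = s[i0:i1]
    mu, sd = base.mean(), base.std()
    if sd == 0:
        raise ValueError("zero baseline variance: cannot z-score ensemble trace")
    return EnsembleTrace((s - mu) / sd, np.asarray(unit_ids, dtype=int),
                         (b0, b1), counts.bin_ms, counts.t0_ms)
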