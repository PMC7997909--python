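"""Unsupervised walk/idle state decoder.

Calibration pipeline (a few minutes of idle/walk behavior, no labels):

1. smooth the calibration counts with the causal Gaussian FIR;
2. cluster the per-bin population vectors with a 1-D self-organizing map
   (SOM) with four output nodes;
3. rank the nodes by the mean population spike count of their assigned
   bins and value them 1, 2/3, 1/3, 0 in descending rank;
4. build the target vector Y from the per-bin node values and smooth it
   with a 500 ms centered moving window;
5. fit the weight vector as the minimum-norm least-squares solution of
   w N = Y, i.e. w = Y N+ (Moore-Penrose pseudoinverse);
6. rescale the calibration-trial control trace so its 1st/99th
   percentiles map to 0/1; the same affine map is applied online.

Decoding is the per-bin inner product y = w n on the same smoothed
representation, normalized with the stored affine map.  Accuracy is
scored per bin after passing y through the hysteresis controller.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import warnings

import numpy as np

from . import stim_controller
from .mua import CountMatrix, SmootherConfig, fir_smooth, moving_average

log = logging.getLogger(__name__)

CLUSTER_VALUES = (1.0, 2.0 / 3.0, 1.0 / 3.0, 0.0)  # by descending rank


# ---------------------------------------------------------------------------
# containers


@dataclasses.dataclass
class SomModel:
    """Trained 1-D SOM: 4 code vectors on a chain plus the value map."""

    node_weights: np.ndarray            # (4, channels)
    node_order: np.ndarray              # node indices, best (value 1) first
    values: np.ndarray                  # value assigned to each node index
    seed: int = 0
    epochs: int = 200

    def assign(self, x: np.ndarray) -> np.ndarray:
        """Best-matching node per sample; ``x`` is (samples, channels)."""
        d = ((x[:, None, :] - self.node_weights[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)


@dataclasses.dataclass
class CalibrationLabels:
    """Smoothed target vector Y with values in [0, 1]."""

    y_target: np.ndarray
    smoothing_window_ms: float = 500.0

    def __post_init__(self) -> None:
        y = np.asarray(self.y_target, dtype=float)
        if y.min() < -1e-9 or y.max() > 1.0 + 1e-9:
            raise ValueError("Y values must lie in [0, 1]")
        self.y_target = y


@dataclasses.dataclass
class DecoderWeights:
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")


@dataclasses.dataclass
class ControlTrace:
    """Per-bin normalized control variable y."""

    y: np.ndarray
    bin_ms: float = 10.0
    t0_ms: float = 0.0


# ---------------------------------------------------------------------------
# SOM


def _smoothed_samples(calib: CountMatrix | np.ndarray,
                      cfg: SmootherConfig | None) -> np.ndarray:
    """FIR-smoothed population vectors, one row per bin."""
    if isinstance(calib, CountMatrix):
        return fir_smooth(calib, cfg).T
    x = np.asarray(calib, dtype=float)
    return x.T  # pre-smoothed channels x bins


def som_cluster(calib_counts: CountMatrix | np.ndarray, seed: int = 0,
                epochs: int = 200, n_nodes: int = 4,
                learning_rate: tuple[float, float] = (0.5, 0.01),
                neighborhood: tuple[float, float] = (1.0, 0.05),
                smoother: SmootherConfig | None = None
                ) -> tuple[np.ndarray, SomModel]:
    """Train a 1-D SOM on per-bin population vectors and assign every bin.

    Online training over ``epochs`` passes in seeded random order; the
    learning rate and the Gaussian neighborhood width both shrink
    linearly.  Code vectors are initialized from quantile bands of the
    samples ordered by population count, which makes training
    deterministic given the seed.
    """
    X = _smoothed_samples(calib_counts, smoother)
    n = X.shape[0]
    if n < n_nodes:
        raise ValueError(f"need at least {n_nodes} samples, got {n}")
    bin_ms = calib_counts.bin_ms if isinstance(calib_counts, CountMatrix) else 10.0
    if n * bin_ms < 60_000.0:
        warnings.warn("calibration trial shorter than 60 s; decoder quality "
                      "may suffer", stacklevel=2)

    order = np.argsort(X.sum(axis=1), kind="stable")
    bands = np.array_split(order, n_nodes)
    W = np.stack([X[b].mean(axis=0) for b in bands])

    rng = np.random.default_rng(seed)
    nodes = np.arange(n_nodes, dtype=float)
    lr0, lr1 = learning_rate
    sg0, sg1 = neighborhood
    denom = max(epochs - 1, 1)
    for e in range(epochs):
        lr = lr0 + (lr1 - lr0) * e / denom
        sg = sg0 + (sg1 - sg0) * e / denom
        two_sg2 = 2.0 * sg * sg
        for i in rng.permutation(n):
            x = X[i]
            d = ((W - x) ** 2).sum(axis=1)
            b = int(d.argmin())
            h = np.exp(-((nodes - b) ** 2) / two_sg2)
            W += (lr * h)[:, None] * (x - W)

    model = SomModel(W, node_order=np.arange(n_nodes), values=np.zeros(n_nodes),
                     seed=seed, epochs=epochs)
    assignments = model.assign(X)
    occupied = np.bincount(assignments, minlength=n_nodes)
    if np.any(occupied == 0):
        log.warning("SOM nodes %s received no samples",
                    np.flatnonzero(occupied == 0).tolist())
    return assignments, model


def order_clusters(assignments: np.ndarray,
                   calib_counts: CountMatrix | np.ndarray,
                   n_nodes: int = 4) -> np.ndarray:
    """Value map over SOM nodes: 1, 2/3, 1/3, 0 by descending mean count.

    Nodes are ranked by the mean population spike count (raw counts) of
    their assigned bins; the highest gets 1, the second 2/3, the third
    1/3, the last 0.  Empty nodes rank last; ties break toward the lower
    node index.  Always a bijection onto {0, 1/3, 2/3, 1}.
    """
    counts = calib_counts.counts if isinstance(calib_counts, CountMatrix) \
        else np.atleast_2d(np.asarray(calib_counts, dtype=float))
    pop = counts.sum(axis=0)
    assignments = np.asarray(assignments, dtype=int)
    keys = []
    for node in range(n_nodes):
        sel = assignments == node
        if sel.any():
            keys.append((0, -float(pop[sel].mean()), node))
        else:
            keys.append((1, 0.0, node))
    ranked = [node for _, _, node in sorted(keys)]
    values = np.empty(n_nodes)
    for rank, node in enumerate(ranked):
        values[node] = CLUSTER_VALUES[rank]
    return values


def build_labels(values_per_bin: np.ndarray, window_ms: float = 500.0,
                 bin_ms: float = 10.0) -> CalibrationLabels:
    """Smooth the per-bin cluster values with a centered moving window."""
    v = np.asarray(values_per_bin, dtype=float)
    allowed = np.array(CLUSTER_VALUES)
    if not np.all(np.min(np.abs(v[:, None] - allowed[None, :]), axis=1) < 1e-9):
        raise ValueError("values_per_bin must come from {0, 1/3, 2/3, 1}")
    return CalibrationLabels(moving_average(v, window_ms, bin_ms), window_ms)


# ---------------------------------------------------------------------------
# weights / decoding


def fit_weights(N: CountMatrix | np.ndarray,
                Y: CalibrationLabels | np.ndarray) -> DecoderWeights:
    """Minimum-norm least-squares solution of w N = Y (w = Y N+)."""
    X = N.counts if isinstance(N, CountMatrix) else np.atleast_2d(
        np.asarray(N, dtype=float))
    y = Y.y_target if isinstance(Y, CalibrationLabels) else np.asarray(
        Y, dtype=float).ravel()
    if X.shape[1] != y.size:
        raise ValueError("N bins and Y length differ")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    w, *_ = np.linalg.lstsq(X.T, y, rcond=None)
    return DecoderWeights(w)


@dataclasses.dataclass
class Decoder:
    """Calibrated decoder: weights, SOM, normalization and smoothing config."""

    weights: DecoderWeights
    som: SomModel
    norm_offset: float
    norm_scale: float
    smoother: SmootherConfig = dataclasses.field(default_factory=SmootherConfig)
    label_window_ms: float = 500.0

    def decode(self, counts: CountMatrix | np.ndarray) -> ControlTrace:
        """Normalized control trace on the fitted smoothed representation."""
        X = fir_smooth(counts, self.smoother) if isinstance(counts, CountMatrix) \
            else np.atleast_2d(np.asarray(counts, dtype=float))
        if X.shape[0] != self.weights.w.size:
            raise ValueError(
                f"channel mismatch: decoder has {self.weights.w.size}, "
                f"input has {X.shape[0]}")
        y = self.weights.w @ X
        y = (y - self.norm_offset) / self.norm_scale
        bin_ms = counts.bin_ms if isinstance(counts, CountMatrix) else 10.0
        t0 = counts.t0_ms if isinstance(counts, CountMatrix) else 0.0
        return ControlTrace(y, bin_ms, t0)

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.w.tolist(),
            "som_node_weights": self.som.node_weights.tolist(),
            "som_values": self.som.values.tolist(),
            "som_seed": self.som.seed,
            "som_epochs": self.som.epochs,
            "norm_offset": self.norm_offset,
            "norm_scale": self.norm_scale,
            "kernel_sigma_bins": self.smoother.kernel_sigma_bins,
            "kernel_halfwidth_bins": self.smoother.kernel_halfwidth_bins,
            "label_window_ms": self.label_window_ms,
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "Decoder":
        som = SomModel(np.asarray(d["som_node_weights"]),
                       node_order=np.argsort(-np.asarray(d["som_values"])),
                       values=np.asarray(d["som_values"]),
                       seed=d["som_seed"], epochs=d["som_epochs"])
        cfg = SmootherConfig(kernel_sigma_bins=d["kernel_sigma_bins"],
                             kernel_halfwidth_bins=d["kernel_halfwidth_bins"])
        return cls(DecoderWeights(np.asarray(d["weights"])), som,
                   d["norm_offset"], d["norm_scale"], cfg, d["label_window_ms"])

    @classmethod
    def load(cls, path: str) -> "Decoder":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def calibrate(calib_counts: CountMatrix, seed: int = 0, epochs: int = 200,
              smoother: SmootherConfig | None = None,
              label_window_ms: float = 500.0) -> Decoder:
    """Run the full unsupervised calibration on one trial of counts."""
    smoother = smoother or SmootherConfig()
    X = fir_smooth(calib_counts, smoother)
    assignments, som = som_cluster(X, seed=seed, epochs=epochs)
    values = order_clusters(assignments, calib_counts)
    som.values = values
    som.node_order = np.argsort(-values, kind="stable")
    labels = build_labels(values[assignments], label_window_ms,
                          calib_counts.bin_ms)
    weights = fit_weights(X, labels)
    y_cal = weights.w @ X
    p1, p99 = np.percentile(y_cal, [1.0, 99.0])
    scale = p99 - p1
    if scale <= 0:
        warnings.warn("degenerate calibration trace; skipping normalization")
        p1, scale = 0.0, 1.0
    return Decoder(weights, som, float(p1), float(scale), smoother,
                   label_window_ms)


# ---------------------------------------------------------------------------
# evaluation


def evaluate_accuracy(y: ControlTrace | np.ndarray, truth_states: np.ndarray,
                      on_thresh: float = 0.75, off_thresh: float = 0.25
                      ) -> tuple[float, float]:
    """Per-bin walk/idle detection accuracy through the hysteresis gate.

    Returns (walk accuracy %, idle accuracy %): the fraction of true-walk
    bins predicted walking and of true-idle bins predicted idle.
    """
    yv = y.y if isinstance(y, ControlTrace) else np.asarray(y, dtype=float)
    truth = np.asarray(truth_states).astype(bool)
    if truth.size == 0:
        raise ValueError("empty truth states")
    if truth.size != yv.size:
        raise ValueError("control trace and truth states differ in length")
    if not truth.any() or truth.all():
        raise ValueError("truth must contain both walk and idle bins")
    cfg = stim_controller.ControllerConfig(on_threshold=on_thresh,
                                           off_threshold=off_thresh)
    pred = stim_controller.predict_states(yv, cfg)
    walk_acc = 100.0 * pred[truth].mean()
    idle_acc = 100.0 * (~pred[~truth]).mean()
    return float(walk_acc), float(idle_acc)


def session_accuracy(session, calib_trial: int = 0, n_eval_trials: int = 5,
                     seed: int = 0, epochs: int = 200,
                     on_thresh: float = 0.75, off_thresh: float = 0.25
                     ) -> tuple[float, float]:
    """Calibrate on one trial of a synthetic session, score held-out trials.

    Uses the session's MI counts; trials are the behavior's complete
    idle+walk trials.  Held-out trials are decoded independently (the
    controller restarts OFF at each trial start) and their bins pooled.
    """
    trials = session.behavior.complete_trials()
    if len(trials) < n_eval_trials + 1:
        raise ValueError(
            f"session has {len(trials)} complete trials; need {n_eval_trials + 1}")
    t0, t1 = trials[calib_trial]
    dec = calibrate(session.mi_counts.slice_ms(t0, t1), seed=seed, epochs=epochs)
    preds, truths = [], []
    bin_ms = session.behavior.bin_ms
    for (s, e) in trials[calib_trial + 1: calib_trial + 1 + n_eval_trials]:
        sub = session.mi_counts.slice_ms(s, e)
        y = dec.decode(sub)
        i0 = int(s // bin_ms)
        truth = session.behavior.state_per_bin[i0:i0 + sub.n_bins]
        cfg = stim_controller.ControllerConfig(on_threshold=on_thresh,
                                               off_threshold=off_thresh)
        preds.append(stim_controller.predict_states(y.y, cfg))
        truths.append(truth.astype(bool))
    pred = np.concatenate(preds)
    truth = np.concatenate(truths)
    walk_acc = 100.0 * pred[truth].mean()
    idle_acc = 100.0 * (~pred[~truth]).mean()
    return float(walk_acc), float(idle_acc)
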