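"""Session, event-table and feature-table persistence.

Sessions go to HDF5 (datasets ``mi_counts``, ``mlr_counts``,
``state_per_bin``, ``speed``; generator parameters as JSON in the file
attributes), gait events and kinematic features to CSV.
"""
from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd

from .mua import CountMatrix
from .synthetic_data import (BehaviorGroundTruth, SessionParams,
                             SyntheticSession)


def write_session(session: SyntheticSession, path: str) -> None:
    b = session.behavior
    with h5py.File(path, "w") as f:
        f.create_dataset("mi_counts", data=session.mi_counts.counts)
        f.create_dataset("mlr_counts", data=session.mlr_counts.counts)
        f.create_dataset("state_per_bin", data=b.state_per_bin)
        f.create_dataset("speed", data=b.speed_mm_s)
        f.create_dataset("foot_off_times_ms", data=b.foot_off_times_ms)
        f.create_dataset("foot_strike_times_ms", data=b.foot_strike_times_ms)
        f.create_dataset("trial_boundaries_ms",
                         data=np.asarray(b.trial_boundaries_ms, dtype=float)
                         if b.trial_boundaries_ms else np.empty((0, 2)))
        f.create_dataset("bout_spans_ms",
                         data=np.asarray(b.bout_spans_ms, dtype=float)
                         if b.bout_spans_ms else np.empty((0, 2)))
        f.attrs["params"] = json.dumps(dataclasses.asdict(session.params))
        for name, arr in session.unit_labels.items():
            f.create_dataset(f"labels/{name}", data=np.asarray(arr, dtype=bool))


def read_session(path: str) -> SyntheticSession:
    with h5py.File(path, "r") as f:
        raw = json.loads(f.attrs["params"])
        for key in ("idle_bout_s", "walk_bout_s"):
            raw[key] = tuple(raw[key])
        params = SessionParams(**raw)
        behavior = BehaviorGroundTruth(
            state_per_bin=f["state_per_bin"][:].astype(np.int8),
            foot_off_times_ms=f["foot_off_times_ms"][:],
            foot_strike_times_ms=f["foot_strike_times_ms"][:],
            speed_mm_s=f["speed"][:],
            trial_boundaries_ms=[tuple(r) for r in f["trial_boundaries_ms"][:]],
            bout_spans_ms=[tuple(r) for r in f["bout_spans_ms"][:]],
            bin_ms=params.bin_ms,
        )
        mi = CountMatrix(f["mi_counts"][:], params.bin_ms)
        mlr = CountMatrix(f["mlr_counts"][:], params.bin_ms)
        labels = {name: f[f"labels/{name}"][:].astype(bool)
                  for name in f["labels"]} if "labels" in f else {}
    return SyntheticSession(params, behavior, mi, mlr, labels)


def events_to_csv(behavior: BehaviorGroundTruth, path: str) -> None:
    """Gait events as a long CSV: columns event_type, time_ms."""
    rows = ([("foot_off", t) for t in behavior.foot_off_times_ms]
            + [("foot_strike", t) for t in behavior.foot_strike_times_ms])
    df = pd.DataFrame(rows, columns=["event_type", "time_ms"])
    df.sort_values("time_ms").to_csv(path, index=False)


def read_events_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def features_to_csv(features: pd.DataFrame, path: str) -> None:
    features.to_csv(path, index=False)


def read_features_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def read_counts_csv(path: str, bin_ms: float = 10.0) -> CountMatrix:
    """Counts from CSV (rows = channels, columns = bins; no header)."""
    return CountMatrix(pd.read_csv(path, header=None).to_numpy(dtype=float),
                       bin_ms)


def stim_log_to_csv(log, path: str) -> None:
    pd.DataFrame(log.events, columns=["time_ms", "event"]).to_csv(
        path, index=False)
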