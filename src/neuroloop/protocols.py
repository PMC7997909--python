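"""Reference evaluation protocols on synthetic cohorts.

These functions tie the generator and the analyses together into the
standard benchmarks reported by this package: calibrate-then-test decoder
accuracy across sessions, and grand-mean ensemble onset latencies for the
MI and MLR populations under the intact and SCI conditions.
"""
from __future__ import annotations

import numpy as np

from . import ensemble_analysis, state_decoder, synthetic_data


def decoder_accuracy_protocol(seeds, epochs: int = 200,
                              n_eval_trials: int = 5) -> dict:
    """Per-bin decoder accuracy, calibrated on one trial per session.

    For each seed, generates a default session, calibrates the
    unsupervised decoder on the first complete idle+walk trial, scores
    per-bin walk/idle accuracy on the next ``n_eval_trials`` held-out
    trials through the hysteresis controller, and averages across
    sessions.
    """
    walk, idle = [], []
    for seed in seeds:
        session = synthetic_data.generate_session(
            synthetic_data.SessionParams(seed=int(seed)),
            with_kinematics=False)
        w, i = state_decoder.session_accuracy(session, seed=int(seed),
                                              epochs=epochs,
                                              n_eval_trials=n_eval_trials)
        walk.append(w)
        idle.append(i)
    return {
        "walk_accuracy_pct": float(np.mean(walk)),
        "idle_accuracy_pct": float(np.mean(idle)),
        "per_session_walk": walk,
        "per_session_idle": idle,
        "n_sessions": len(walk),
    }


def onset_latency_protocol(seeds, condition: str = "intact",
                           population: str = "mi") -> dict:
    """Grand-mean 2-SD ensemble crossing latency across sessions.

    Latencies are relative to each bout's first foot-off (negative =
    before); the grand mean averages session means.
    """
    session_means = []
    for seed in seeds:
        params = synthetic_data.SessionParams.for_condition(
            condition, seed=int(seed))
        session = synthetic_data.generate_session(params,
                                                  with_kinematics=False)
        counts = session.mi_counts if population == "mi" else session.mlr_counts
        rep = ensemble_analysis.population_onset_latency(counts,
                                                         session.behavior)
        session_means.append(rep["mean_ms"])
    session_means = np.asarray(session_means)
    return {
        "grand_mean_ms": float(np.nanmean(session_means)),
        "session_means_ms": session_means.tolist(),
        "n_sessions": int(session_means.size),
    }
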