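"""Gait-cycle kinematics: cycle detection, features, PCA, paired tests.

Markers follow the standard hindlimb set (iliac crest, greater trochanter,
lateral condyle, lateral malleolus, fifth metatarsal, toe).  Features are
computed per gait cycle; a cycle runs from a foot-off (toe leaves the
ground) to the subsequent foot-strike plus the following stance.  The
default feature set has 15 named parameters (step height, hip excursion,
segment oscillation amplitudes, stride length, timing, drag) and is
extensible; reproducing any particular published principal-component axis
from a different feature list is explicitly not claimed.

Condition analysis: z-score the feature columns, run a PCA, and compare
conditions by their centroid Euclidean distances in the first k principal
components (default k=2).  Paired condition contrasts use a one-tailed
paired t test, or the Wilcoxon signed-rank test when a Kolmogorov-Smirnov
screen rejects normality of the paired differences.  A Monte-Carlo power
simulation for the signed-rank design (paired per-animal means of
per-cycle features) is included.
"""
from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

MARKERS = ("crest", "hip", "knee", "ankle", "foot", "toe")


@dataclasses.dataclass
class GaitCycle:
    foot_off_ms: float
    foot_strike_ms: float
    markers: dict[str, np.ndarray] | None = None  # name -> (T, 2) x/y mm
    t_ms: np.ndarray | None = None                # sample times for markers
    features: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.foot_off_ms < self.foot_strike_ms:
            raise ValueError("foot_off must precede foot_strike")


# ---------------------------------------------------------------------------
# cycle detection


def detect_gait_cycles(toe_height: np.ndarray, rate_hz: float,
                       threshold: float | None = None,
                       min_swing_ms: float = 50.0) -> list[GaitCycle]:
    """Detect swing phases from a toe-height trajectory (>= 100 Hz).

    Foot-off is the upward crossing of a height threshold (default: the
    mid-range of the trajectory), foot-strike the subsequent downward
    return.  A flat trajectory yields no cycles (warned).
    """
    if rate_hz < 100.0:
        raise ValueError("trajectory must be sampled at >= 100 Hz")
    y = np.asarray(toe_height, dtype=float)
    lo, hi = float(y.min()), float(y.max())
    if hi - lo < 1e-9:
        warnings.warn("flat toe trajectory: no gait cycles detected")
        return []
    th = threshold if threshold is not None else (lo + hi) / 2.0
    above = y > th
    ups = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    downs = np.flatnonzero(~above[1:] & above[:-1]) + 1
    cycles: list[GaitCycle] = []
    min_gap = min_swing_ms * rate_hz / 1000.0
    for u in ups:
        d = downs[downs > u]
        if d.size == 0:
            continue
        if d[0] - u < min_gap:
            continue
        cycles.append(GaitCycle(u / rate_hz * 1000.0, d[0] / rate_hz * 1000.0))
    if not cycles:
        warnings.warn("no gait cycles detected")
    return cycles


# ---------------------------------------------------------------------------
# features


def _angle_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Orientation (deg) of the segment from marker a to marker b."""
    d = b - a
    return np.degrees(np.arctan2(d[:, 1], d[:, 0]))


def _joint_angle_deg(prox: np.ndarray, joint: np.ndarray,
                     dist: np.ndarray) -> np.ndarray:
    v1, v2 = prox - joint, dist - joint
    cosang = (v1 * v2).sum(axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1) + 1e-12)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def compute_gait_features(cycle: GaitCycle, drag_height_mm: float = 2.0
                          ) -> dict[str, float]:
    """Named kinematic features of one gait cycle.

    Step height is the maximal toe elevation during swing above the stance
    baseline (the minimum toe height of the cycle); excursions and segment
    oscillation amplitudes are peak-to-peak ranges.  Features are invariant
    to rigid translation of all markers.
    """
    if cycle.features is not None:
        return dict(cycle.features)
    if cycle.markers is None:
        raise ValueError("cycle has neither precomputed features nor markers")
    if cycle.foot_strike_ms - cycle.foot_off_ms <= 0:
        raise ValueError("degenerate zero-duration cycle")
    m = cycle.markers
    t = cycle.t_ms if cycle.t_ms is not None else np.arange(
        next(iter(m.values())).shape[0], dtype=float)
    swing = (t >= cycle.foot_off_ms) & (t <= cycle.foot_strike_ms)
    if not swing.any():
        swing = np.ones(t.size, dtype=bool)

    out: dict[str, float] = {}
    toe = m["toe"]
    baseline = float(toe[:, 1].min())
    out["step_height"] = float(toe[swing, 1].max() - baseline)
    out["stride_length"] = float(toe[:, 0].max() - toe[:, 0].min())
    out["swing_duration"] = (cycle.foot_strike_ms - cycle.foot_off_ms) / 1000.0
    out["cycle_duration"] = float((t[-1] - t[0]) / 1000.0) if t.size > 1 else 0.0
    out["stance_duration"] = max(out["cycle_duration"] - out["swing_duration"], 0.0)
    out["drag_fraction"] = float(
        (toe[swing, 1] < baseline + drag_height_mm).mean())
    if t.size > 1:
        dt = np.diff(t) / 1000.0
        v = np.linalg.norm(np.diff(toe, axis=0), axis=1) / np.maximum(dt, 1e-9)
        out["max_toe_speed"] = float(v.max())

    if "hip" in m:
        out["whole_limb_oscillation"] = float(np.ptp(_angle_deg(m["hip"], toe)))
        out["hip_height"] = float(m["hip"][:, 1].mean())
    if all(k in m for k in ("crest", "hip", "knee")):
        out["hip_excursion"] = float(np.ptp(
            _joint_angle_deg(m["crest"], m["hip"], m["knee"])))
    if all(k in m for k in ("hip", "knee", "ankle")):
        out["knee_range"] = float(np.ptp(
            _joint_angle_deg(m["hip"], m["knee"], m["ankle"])))
        out["thigh_amplitude"] = float(np.ptp(_angle_deg(m["hip"], m["knee"])))
        out["leg_amplitude"] = float(np.ptp(_angle_deg(m["knee"], m["ankle"])))
    if all(k in m for k in ("knee", "ankle", "foot")):
        out["ankle_range"] = float(np.ptp(
            _joint_angle_deg(m["knee"], m["ankle"], m["foot"])))
        out["foot_amplitude"] = float(np.ptp(_angle_deg(m["ankle"], m["foot"])))
    return out


def compute_features_table(cycles: list[GaitCycle],
                           condition: str | None = None) -> pd.DataFrame:
    rows = [compute_gait_features(c) for c in cycles]
    df = pd.DataFrame(rows)
    if condition is not None:
        df["condition"] = condition
    return df


# ---------------------------------------------------------------------------
# PCA condition analysis


@dataclasses.dataclass
class PCModel:
    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    components: np.ndarray           # (n_components, n_features), orthonormal
    explained_variance_ratio: np.ndarray
    scores: np.ndarray               # (n_cycles, n_components)
    conditions: np.ndarray

    def condition_centroids(self, k: int | None = 2) -> pd.DataFrame:
        k = self.scores.shape[1] if k is None else min(k, self.scores.shape[1])
        rows = {}
        for c in pd.unique(self.conditions):
            rows[c] = self.scores[self.conditions == c, :k].mean(axis=0)
        return pd.DataFrame(rows).T

    def centroid_distances(self, k: int | None = 2) -> pd.DataFrame:
        """Pairwise Euclidean distances between condition centroids."""
        cent = self.condition_centroids(k)
        conds = cent.index.tolist()
        d = pd.DataFrame(0.0, index=conds, columns=conds)
        for a, b in itertools.combinations(conds, 2):
            dist = float(np.linalg.norm(cent.loc[a] - cent.loc[b]))
            d.loc[a, b] = d.loc[b, a] = dist
        return d


def pca_conditions(features: pd.DataFrame, n_pcs: int = 2) -> PCModel:
    """Standardize, PCA, and per-condition centroids in PC space.

    ``features`` must carry a ``condition`` column with >= 2 conditions of
    >= 3 cycles each; constant feature columns are dropped with a warning.
    Distances over *all* PCs equal standardized-feature-space distances
    (orthogonal invariance).
    """
    if "condition" not in features.columns:
        raise ValueError("feature matrix needs a 'condition' column")
    cond = features["condition"].to_numpy()
    levels, counts = np.unique(cond, return_counts=True)
    if levels.size < 2 or counts.min() < 3:
        raise ValueError("need >= 2 conditions with >= 3 cycles each")
    X = features.drop(columns=["condition"]).astype(float)
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    keep = X.std(ddof=0) > 0
    if not keep.all():
        warnings.warn(f"dropping constant feature(s): "
                      f"{X.columns[~keep].tolist()}")
        X = X.loc[:, keep]
    names = X.columns.tolist()
    vals = X.to_numpy()
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=0)
    Z = (vals - mu) / sd
    pca = PCA(n_components=min(Z.shape))
    scores = pca.fit_transform(Z)
    _ = n_pcs  # default display dimensionality; distances take k explicitly
    return PCModel(names, mu, sd, pca.components_,
                   pca.explained_variance_ratio_, scores, cond)


# ---------------------------------------------------------------------------
# paired tests and power


def paired_condition_test(a, b, tail: str = "greater",
                          normality_alpha: float = 0.05) -> dict:
    """One-tailed paired contrast with a normality screen.

    Uses Student's paired t test when a one-sample Kolmogorov-Smirnov test
    on the standardized differences does not reject normality; otherwise
    the Wilcoxon signed-rank test.  Zero-variance differences fall back to
    the exact sign probability (1/2^n when all differences agree with the
    tested direction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError("need n >= 3 pairs")
    d = a - b
    n = d.size
    rep = {"n": n, "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
           "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)), "tail": tail}
    sign = 1.0 if tail == "greater" else -1.0
    if np.allclose(d, 0.0):
        rep.update(test="degenerate", statistic=0.0, p_value=1.0)
        return rep
    if d.std(ddof=1) == 0:
        # constant non-zero differences: exact sign-test probability
        p = 0.5 ** n if sign * d[0] > 0 else 1.0 - 0.5 ** n
        rep.update(test="exact_sign", statistic=float(np.sign(d[0]) * n),
                   p_value=float(p))
        return rep
    z = (d - d.mean()) / d.std(ddof=1)
    ks_p = stats.kstest(z, "norm").pvalue
    alt = "greater" if tail == "greater" else "less"
    if ks_p < normality_alpha:
        res = stats.wilcoxon(a, b, alternative=alt)
        rep.update(test="wilcoxon", statistic=float(res.statistic),
                   p_value=float(res.pvalue), ks_p=float(ks_p))
    else:
        res = stats.ttest_rel(a, b, alternative=alt)
        rep.update(test="t", statistic=float(res.statistic),
                   p_value=float(res.pvalue), ks_p=float(ks_p))
    return rep


def _signed_rank_null_sf(n: int) -> np.ndarray:
    """Exact null survival P(W+ >= w) of the signed-rank statistic, w=0..n(n+1)/2."""
    total = n * (n + 1) // 2
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in range(1, n + 1):
        nxt = pmf.copy()
        nxt[r:] += pmf[:-r] if r > 0 else pmf
        pmf = nxt / 2.0
    sf = np.cumsum(pmf[::-1])[::-1]
    return sf


def signed_rank_exact_p(diffs: np.ndarray, alternative: str = "greater"
                        ) -> float:
    """One-tailed exact signed-rank p for one sample of paired differences."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    sf = _signed_rank_null_sf(n)
    if alternative == "greater":
        return float(sf[int(round(w_plus))])
    total = n * (n + 1) // 2
    return float(sf[int(round(total - w_plus))])


def wilcoxon_power_sim(n_animals: int, cycles_per_animal: int = 20,
                       effect_frac: float = 0.5, within_sd: float = 1.0,
                       between_sd: float = 0.5, spontaneous_range: float = 4.0,
                       alpha: float = 0.05, reps: int = 1000,
                       seed: int = 0) -> float:
    """Monte-Carlo power of the one-tailed paired signed-rank design.

    Each replicate draws per-animal feature means (between-animal SD),
    ``cycles_per_animal`` cycles per condition per animal (within SD), an
    additive treatment effect of ``effect_frac * spontaneous_range``, and
    applies the one-tailed exact signed-rank test to the per-animal mean
    differences.  Returns the rejection fraction; equals alpha at zero
    effect and grows monotonically with effect size and n.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    effect = effect_frac * spontaneous_range
    se_within = within_sd / np.sqrt(cycles_per_animal)
    # per-animal mean difference: effect + noise from two condition means
    d = effect + np.sqrt(2.0) * se_within * rng.standard_normal(
        (reps, n_animals))
    _ = between_sd  # animal intercepts cancel in the paired difference
    ranks = stats.rankdata(np.abs(d), axis=1)
    w_plus = np.where(d > 0, ranks, 0.0).sum(axis=1)
    sf = _signed_rank_null_sf(n_animals)
    p = sf[np.round(w_plus).astype(int)]
    return float((p < alpha).mean())
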