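"""Generator behavior: determinism, bout balance, moments, round trips."""
import numpy as np
import pytest
from scipy import stats

from neuroloop import mua
from neuroloop import synthetic_data as sd


def _equal_behavior(a, b):
    return (np.array_equal(a.state_per_bin, b.state_per_bin)
            and np.array_equal(a.foot_off_times_ms, b.foot_off_times_ms)
            and np.array_equal(a.foot_strike_times_ms, b.foot_strike_times_ms)
            and np.array_equal(a.speed_mm_s, b.speed_mm_s))


class TestBehavior:
    def test_deterministic_given_seed(self):
        p = sd.SessionParams(seed=7)
        assert _equal_behavior(sd.generate_behavior(p), sd.generate_behavior(p))

    def test_zero_walk_probability_gives_all_idle(self):
        p = sd.SessionParams(seed=3, walk_bout_prob=0.0)
        b = sd.generate_behavior(p)
        assert b.state_per_bin.max() == 0
        assert b.foot_off_times_ms.size == 0
        assert b.foot_strike_times_ms.size == 0
        assert np.all(b.speed_mm_s == 0)

    def test_walk_fraction_balanced_across_seeds(self):
        fracs = [sd.generate_behavior(
            sd.SessionParams(seed=s, duration_s=300.0)).walk_fraction
            for s in range(100)]
        fracs = np.asarray(fracs)
        assert np.all((fracs > 0.35) & (fracs < 0.65))
        assert 0.45 < fracs.mean() < 0.55

    def test_event_and_state_invariants(self, intact_behavior):
        b = intact_behavior
        assert np.all(np.diff(b.foot_off_times_ms) > 0)
        assert np.all(np.diff(b.foot_strike_times_ms) > 0)
        # speed zero on idle bins, walk bins inside bout spans
        assert np.all(b.speed_mm_s[b.state_per_bin == 0] == 0)
        walk_bins = np.flatnonzero(b.state_per_bin == 1)
        centers = (walk_bins + 0.5) * b.bin_ms
        inside = np.zeros(centers.size, dtype=bool)
        for (s, e) in b.bout_spans_ms:
            # walk spans the bins containing [first foot-off, last foot-strike)
            inside |= (centers >= s - b.bin_ms / 2) & (centers <= e + b.bin_ms / 2)
        assert inside.all()
        # first foot-off of each bout is its gait initiation
        assert np.all(np.isin(b.gait_initiations_ms, b.foot_off_times_ms))

    def test_duration_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            sd.generate_behavior(sd.SessionParams(seed=0, duration_s=4.0))


class TestNeural:
    def test_channel_counts_match_recording_setup(self, intact_session):
        assert intact_session.mi_counts.n_channels == 32
        assert intact_session.mlr_counts.n_channels == 16

    def test_no_modulation_limit_is_constant_poisson(self):
        p = sd.SessionParams(seed=5, rate_noise_cv=0.0, walk_gain=1.0,
                             frac_speed_coupled_mlr=0.0, duration_s=120.0)
        b = sd.generate_behavior(p)
        mi, mlr, _ = sd.generate_neural(b, p)
        lam0 = p.baseline_counts_per_bin
        for cm in (mi, mlr):
            m = cm.counts.mean()
            se = np.sqrt(lam0 / cm.counts.size)
            assert abs(m - lam0) < 3 * se
            walk = cm.counts[:, b.state_per_bin == 1].mean()
            idle = cm.counts[:, b.state_per_bin == 0].mean()
            assert abs(walk - idle) < 0.02

    def test_locomotor_walk_idle_ratio_matches_gain(self, intact_session):
        s = intact_session
        loco = s.unit_labels["mi_locomotor"]
        centers = s.mi_counts.bin_centers_ms
        # idle bins clear of the ramp transients (lead + rise before a bout,
        # decay after); the ratio then reflects the configured gain
        clear_idle = s.behavior.state_per_bin == 0
        margin = s.params.mi_lead_ms + 2 * s.params.ramp_rise_ms
        for (b0, b1) in s.behavior.bout_spans_ms:
            clear_idle &= ~((centers >= b0 - margin) & (centers <= b1 + margin))
        walk = s.mi_counts.counts[loco][:, s.behavior.state_per_bin == 1].mean()
        idle = s.mi_counts.counts[loco][:, clear_idle].mean()
        gain = s.params.effective_walk_gain
        assert abs(walk / idle - gain) / gain < 0.05

    def test_walk_gain_monotonically_raises_modulation(self):
        ratios = []
        for g in (2.0, 5.0, 12.0):
            p = sd.SessionParams(seed=9, walk_gain=g, duration_s=120.0)
            b = sd.generate_behavior(p)
            mi, _, labels = sd.generate_neural(b, p)
            loco = labels["mi_locomotor"]
            walk = mi.counts[loco][:, b.state_per_bin == 1].mean()
            idle = mi.counts[loco][:, b.state_per_bin == 0].mean()
            ratios.append(walk / idle)
        assert ratios[0] < ratios[1] < ratios[2]

    def test_deterministic_given_seed(self):
        p = sd.SessionParams(seed=11, duration_s=60.0)
        b = sd.generate_behavior(p)
        a = sd.generate_neural(b, p)
        c = sd.generate_neural(b, p)
        assert np.array_equal(a[0].counts, c[0].counts)
        assert np.array_equal(a[1].counts, c[1].counts)


class TestRawSegment:
    def test_round_trip_conserves_and_recovers_spikes(self):
        rng = np.random.default_rng(0)
        counts = np.histogram(rng.uniform(0, 1000, 10), bins=100,
                              range=(0, 1000))[0][None, :]
        cm = mua.CountMatrix(counts)
        trace, truth = sd.generate_raw_segment(cm, seed=5)
        assert truth[0].size == int(cm.counts.sum())  # count conservation
        det = mua.detect_spikes(trace)[0]
        matched = sum(np.min(np.abs(det - t)) <= 0.5 for t in truth[0])
        assert matched >= 9

    def test_zero_counts_give_pure_noise(self):
        cm = mua.CountMatrix(np.zeros((2, 50)))
        trace, truth = sd.generate_raw_segment(cm, seed=1)
        assert all(t.size == 0 for t in truth)
        assert abs(trace.samples.std() - 1.0) < 0.02

    def test_deterministic_given_seed(self):
        cm = mua.CountMatrix(np.ones((1, 20)))
        t1, _ = sd.generate_raw_segment(cm, seed=3)
        t2, _ = sd.generate_raw_segment(cm, seed=3)
        assert np.array_equal(t1.samples, t2.samples)

    def test_segment_length_guard(self):
        with pytest.raises(ValueError, match="10 s"):
            sd.generate_raw_segment(mua.CountMatrix(np.zeros((1, 2000))))


@pytest.fixture(scope="module")
def long_behavior():
    return sd.generate_behavior(sd.SessionParams(seed=2, duration_s=420.0))


class TestKinematics:
    def test_null_effects_draw_from_same_distribution(self, long_behavior):
        """With zero effect sizes the condition samples are exchangeable."""
        effects = {"a": {}, "b": {}}
        n_sig = 0
        reps = 100
        for s in range(reps):
            df = sd.generate_kinematics(long_behavior, effects, seed=s)
            a = df.loc[df.condition == "a", "step_height"]
            b = df.loc[df.condition == "b", "step_height"]
            if stats.ks_2samp(a, b).pvalue < 0.01:
                n_sig += 1
        assert n_sig <= 5  # >= 95% non-significant at alpha = 0.01

    def test_multiplicative_effect_moment(self, long_behavior):
        effects = {"ctrl": {}, "dbs": {"step_height": 1.5}}
        df = sd.generate_kinematics(long_behavior, effects, seed=4)
        assert (df.condition == "dbs").sum() >= 200
        ratio = (df.loc[df.condition == "dbs", "step_height"].mean()
                 / df.loc[df.condition == "ctrl", "step_height"].mean())
        assert 1.4 < ratio < 1.6

    def test_dbs_grid_levels_and_monotonicity(self):
        eff = sd.dbs_intensity_effects()
        assert tuple(eff) == (0, 33, 66, 100)
        gains = [eff[lvl]["step_height"] for lvl in (0, 33, 66, 100)]
        assert gains == sorted(gains) and gains[0] == 1.0 and len(set(gains)) == 4

    def test_no_cycles_yields_empty_frame(self):
        b = sd.generate_behavior(sd.SessionParams(seed=0, walk_bout_prob=0.0))
        with pytest.warns(UserWarning, match="no gait cycle"):
            df = sd.generate_kinematics(b, seed=0)
        assert df.empty


class TestCohort:
    def _small(self):
        return sd.SessionParams(seed=0, duration_s=60.0, n_mi_channels=4,
                                n_mlr_channels=4)

    def test_cohort_size_and_distinct_seeds(self):
        cohort = sd.generate_cohort(6, self._small(), seed=1)
        assert len(cohort) == 6
        assert len({s.params.seed for s in cohort}) == 6

    def test_same_master_seed_reproduces_cohort(self):
        a = sd.generate_cohort(3, self._small(), seed=9)
        b = sd.generate_cohort(3, self._small(), seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.mi_counts.counts, y.mi_counts.counts)

    def test_between_animal_feature_variability(self):
        cohort = sd.generate_cohort(50, self._small(), seed=0,
                                    between_animal_feature_cv=0.1)
        means = np.array([s.kinematics["step_height"].mean() for s in cohort])
        rel_sd = means.std(ddof=1) / means.mean()
        assert 0.07 < rel_sd < 0.13  # within 30% of the configured 0.1
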