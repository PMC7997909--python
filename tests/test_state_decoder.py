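"""Unsupervised decoder: SOM, cluster values, labels, weights, accuracy."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroloop import mua
from neuroloop import state_decoder as dec
from neuroloop import synthetic_data as sd

DELTA = mua.SmootherConfig(kernel_sigma_bins=1e-6)


def _level_samples(seed=0, n_per=200, n_ch=8, levels=(1.0, 5.0, 12.0, 25.0)):
    """Population vectors drawn around 4 well-separated rate levels."""
    rng = np.random.default_rng(seed)
    X, lab = [], []
    for i, lv in enumerate(levels):
        X.append(lv + 0.1 * rng.standard_normal((n_per, n_ch)))
        lab.extend([i] * n_per)
    X = np.concatenate(X)
    order = rng.permutation(len(X))
    return X[order], np.asarray(lab)[order]


class TestSom:
    def test_recovers_separated_levels_vs_centroid_oracle(self):
        X, lab = _level_samples()
        assign, _ = dec.som_cluster(X.T, seed=1, epochs=60)
        # oracle: exhaustive nearest-centroid on the true level means
        centroids = np.stack([X[lab == i].mean(axis=0) for i in range(4)])
        oracle = ((X[:, None, :] - centroids[None]) ** 2).sum(2).argmin(1)
        # agreement up to relabeling: map each node to its majority level
        agree = 0
        for node in range(4):
            sel = assign == node
            if sel.any():
                agree += (oracle[sel] == np.bincount(
                    oracle[sel]).argmax()).sum()
        assert agree / len(X) >= 0.99

    def test_identical_samples_collapse_to_one_node(self):
        X = np.ones((50, 4))
        assign, _ = dec.som_cluster(X.T, seed=0, epochs=10)
        assert np.unique(assign).size == 1

    def test_deterministic_given_seed(self):
        X, _ = _level_samples(seed=2)
        a1, m1 = dec.som_cluster(X.T, seed=5, epochs=30)
        a2, m2 = dec.som_cluster(X.T, seed=5, epochs=30)
        assert np.array_equal(a1, a2)
        assert np.allclose(m1.node_weights, m2.node_weights)

    def test_fewer_samples_than_nodes_raises(self):
        with pytest.raises(ValueError, match="at least 4"):
            dec.som_cluster(np.ones((3, 2)).T, seed=0)


class TestOrderClusters:
    def _counts_for_means(self, means, n_per=10):
        assign = np.repeat(np.arange(len(means)), n_per)
        pop = np.repeat(np.asarray(means, dtype=float), n_per)
        return assign, mua.CountMatrix(pop[None, :])

    def test_hand_ranked_values(self):
        assign, cm = self._counts_for_means([30, 5, 12, 20])
        values = dec.order_clusters(assign, cm)
        assert values.tolist() == [1.0, 0.0, 1 / 3, 2 / 3]

    def test_second_ranked_node_gets_two_thirds(self):
        assign, cm = self._counts_for_means([30, 5, 12, 20])
        values = dec.order_clusters(assign, cm)
        assert values[3] == pytest.approx(2 / 3)  # node 3 has 2nd-highest mean

    def test_tied_means_break_to_lower_index(self):
        assign, cm = self._counts_for_means([10, 10, 10, 10])
        values = dec.order_clusters(assign, cm)
        assert values.tolist() == [1.0, 2 / 3, 1 / 3, 0.0]

    def test_empty_nodes_rank_last(self):
        assign = np.array([0, 0, 2, 2])
        cm = mua.CountMatrix(np.array([[1.0, 1.0, 9.0, 9.0]]))
        values = dec.order_clusters(assign, cm)
        assert values[2] == 1.0 and values[0] == pytest.approx(2 / 3)
        assert sorted(values.tolist()) == [0.0, 1 / 3, 2 / 3, 1.0]

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=4, max_size=60),
           st.integers(0, 10 ** 6))
    def test_value_map_is_always_a_bijection(self, assign, seed):
        rng = np.random.default_rng(seed)
        assign = np.asarray(assign)
        cm = mua.CountMatrix(rng.poisson(3.0, (2, assign.size)).astype(float))
        values = dec.order_clusters(assign, cm)
        assert sorted(values.tolist()) == [0.0, 1 / 3, 2 / 3, 1.0]


class TestBuildLabels:
    def test_constant_one_unchanged(self):
        lab = dec.build_labels(np.ones(200))
        assert np.allclose(lab.y_target, 1.0)

    def test_step_smooths_to_linear_ramp(self):
        v = np.zeros(300)
        b = 150
        v[b:] = 1.0
        y = dec.build_labels(v).y_target  # 500 ms window = 50 bins
        assert y[b] == pytest.approx(0.5)
        ramp = y[b - 25: b + 25]
        assert np.allclose(np.diff(ramp), 1 / 50)
        assert np.all(y[: b - 25] == 0) and np.all(y[b + 25:] == 1)

    def test_single_bin_window_is_identity(self):
        v = np.asarray([0, 1 / 3, 2 / 3, 1.0] * 10)
        assert np.array_equal(dec.build_labels(v, window_ms=10).y_target, v)

    def test_rejects_values_off_grid(self):
        with pytest.raises(ValueError, match="0, 1/3, 2/3, 1"):
            dec.build_labels(np.array([0.5, 0.5, 0.5, 0.5]))


class TestFitWeights:
    def test_orthonormal_rows_identity(self):
        N = np.eye(4)[:3]  # orthonormal rows
        w = dec.fit_weights(N, N[0]).w
        assert np.allclose(w, [1, 0, 0])

    def test_zero_target_zero_weights(self):
        rng = np.random.default_rng(0)
        w = dec.fit_weights(rng.normal(size=(5, 50)), np.zeros(50)).w
        assert np.allclose(w, 0)

    def test_recovers_planted_weights(self):
        rng = np.random.default_rng(1)
        N = rng.poisson(4.0, (32, 3000)).astype(float)
        v = rng.normal(size=32)
        w = dec.fit_weights(N, v @ N).w
        assert np.linalg.norm(w @ N - v @ N) <= 1e-8 * np.linalg.norm(v @ N)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="differ"):
            dec.fit_weights(np.ones((2, 10)), np.ones(9))


class TestDecode:
    def _decoder(self, w, c=None):
        som = dec.SomModel(np.zeros((4, len(w))), np.arange(4),
                           np.array(dec.CLUSTER_VALUES))
        return dec.Decoder(dec.DecoderWeights(np.asarray(w, float)), som,
                           0.0, 1.0, c or DELTA)

    def test_zero_weights_zero_output(self):
        d = self._decoder([0.0, 0.0])
        assert np.allclose(d.decode(np.ones((2, 30))).y, 0.0)

    def test_unit_weight_projects_single_channel(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(3, (3, 50)).astype(float)
        d = self._decoder([1.0, 0.0, 0.0], mua.SmootherConfig())
        assert np.allclose(d.decode(mua.CountMatrix(x)).y,
                           mua.fir_smooth(x)[0])

    def test_linearity(self):
        rng = np.random.default_rng(3)
        A, B = rng.normal(size=(2, 4, 80))
        d = self._decoder(rng.normal(size=4), mua.SmootherConfig())
        lhs = d.decode(2.0 * A + 3.0 * B).y
        rhs = 2.0 * d.decode(A).y + 3.0 * d.decode(B).y
        assert np.allclose(lhs, rhs)

    def test_channel_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            self._decoder([1.0, 1.0]).decode(np.ones((3, 10)))


class TestAccuracy:
    def test_perfect_indicator_scores_100_100(self):
        truth = np.array([0] * 50 + [1] * 50)
        walk, idle = dec.evaluate_accuracy(truth.astype(float), truth)
        assert walk == 100.0 and idle == 100.0

    def test_inverted_decoder_scores_zero_walk(self):
        truth = np.array([0] * 50 + [1] * 50)
        walk, _ = dec.evaluate_accuracy(1.0 - truth, truth)
        assert walk == 0.0

    def test_empty_truth_raises(self):
        with pytest.raises(ValueError, match="empty"):
            dec.evaluate_accuracy(np.ones(0), np.ones(0, dtype=int))


def _aligned_noiseless_params(seed=0):
    """Bout timing on the bin grid, instantaneous ramps, no noise sources."""
    return sd.SessionParams(seed=seed, duration_s=240.0, rate_noise_cv=0.0,
                            frac_speed_coupled_mlr=0.0, mi_lead_ms=0.0,
                            ramp_rise_ms=1.0, idle_bout_s=(5.0, 5.0),
                            walk_bout_s=(7.0, 7.0))


class TestCalibration:
    def test_noiseless_disjoint_rates_decode_perfectly(self):
        """Separability: disjoint idle/walk population rates, no noise."""
        p = _aligned_noiseless_params()
        s = sd.generate_session(p, noise="none", with_kinematics=False)
        trials = s.behavior.complete_trials()
        t0, t1 = trials[0]
        d = dec.calibrate(s.mi_counts.slice_ms(t0, t1), seed=0, epochs=60,
                          smoother=DELTA)
        for (a, b) in trials[1:6]:
            sub = s.mi_counts.slice_ms(a, b)
            y = d.decode(sub)
            i0 = int(a // 10)
            truth = s.behavior.state_per_bin[i0:i0 + sub.n_bins]
            walk, idle = dec.evaluate_accuracy(y, truth)
            assert walk == 100.0 and idle == 100.0

    def test_accuracy_invariant_to_count_rescaling(self):
        """y is normalized by calibration, so thresholds are absolute."""
        p = _aligned_noiseless_params(seed=4)
        s = sd.generate_session(p, noise="none", with_kinematics=False)
        t0, t1 = s.behavior.complete_trials()[0]
        cal = s.mi_counts.slice_ms(t0, t1)
        test = s.mi_counts.slice_ms(*s.behavior.complete_trials()[1])
        d1 = dec.calibrate(cal, seed=0, epochs=40, smoother=DELTA)
        scaled = mua.CountMatrix(cal.counts * 7.0, cal.bin_ms, cal.t0_ms)
        d2 = dec.calibrate(scaled, seed=0, epochs=40, smoother=DELTA)
        y1 = d1.decode(test).y
        y2 = d2.decode(mua.CountMatrix(test.counts * 7.0, test.bin_ms,
                                       test.t0_ms)).y
        assert np.allclose(y1, y2, atol=1e-8)

    def test_model_json_round_trip(self, tmp_path):
        p = _aligned_noiseless_params(seed=1)
        s = sd.generate_session(p, noise="none", with_kinematics=False)
        t0, t1 = s.behavior.complete_trials()[0]
        d = dec.calibrate(s.mi_counts.slice_ms(t0, t1), seed=0, epochs=20,
                          smoother=DELTA)
        path = tmp_path / "model.json"
        d.save(str(path))
        d2 = dec.Decoder.load(str(path))
        x = s.mi_counts.slice_ms(t0, t1)
        assert np.allclose(d.decode(x).y, d2.decode(x).y)
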