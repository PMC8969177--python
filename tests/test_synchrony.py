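import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meapipe import (
    ConnectivityMatrix,
    CorseParams,
    SpikeTrain,
    SttcParams,
    TrainModel,
    connectivity_map,
    corse,
    generate_correlated_trains,
    generate_train,
    spectral_entropy_series,
    sttc,
    sttc_matrix,
    well_corse,
)

from .oracles import sttc_brute_force

FS = 12_500.0


def train(times, duration=1.0):
    return SpikeTrain(np.asarray(times, dtype=float), duration)


class TestSttc:
    def test_identical_trains_give_one(self):
        t = train([0.1, 0.3, 0.7], 2.0)
        assert sttc(t, t) == pytest.approx(1.0)

    def test_empty_train_undefined(self):
        assert np.isnan(sttc(train([], 2.0), train([0.5], 2.0)))

    def test_small_example_matches_oracle(self):
        a, b = train([0.100, 0.200]), train([0.120, 0.500])
        expected = sttc_brute_force(a.times_s, b.times_s, 0.050, 0.0, 1.0)
        assert sttc(a, b, interval=(0.0, 1.0)) == pytest.approx(expected, abs=1e-3)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = train(np.sort(rng.uniform(0, 10, rng.integers(1, 20))), 10.0)
        b = train(np.sort(rng.uniform(0, 10, rng.integers(1, 20))), 10.0)
        v = sttc(a, b)
        assert sttc(b, a) == pytest.approx(v, abs=1e-12)
        shift = 3.0
        va = sttc(a.shifted(shift, 16.0), b.shifted(shift, 16.0),
                  interval=(shift, shift + 10.0))
        assert va == pytest.approx(v, abs=1e-9)

    def test_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = train(np.sort(rng.uniform(0, 5, 15)), 5.0)
            b = train(np.sort(rng.uniform(0, 5, 15)), 5.0)
            v = sttc(a, b)
            assert -1.0 <= v <= 1.0


class TestSttcMatrix:
    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(4)
        trains = {
            f"1{i}": train(np.sort(rng.uniform(0, 60, 50)), 60.0) for i in range(1, 4)
        }
        m = sttc_matrix(trains)
        np.testing.assert_allclose(m.values, m.values.T)
        np.testing.assert_allclose(np.diag(m.values), 1.0)

    def test_identical_trains_mean_one(self):
        t = train(np.linspace(1, 59, 30), 60.0)
        m = sttc_matrix({"11": t, "12": t})
        assert m.mean() == pytest.approx(1.0)

    def test_independent_sparse_trains_near_zero(self):
        trains = {}
        for i in range(4):
            t, _ = generate_train(TrainModel(tonic_rate_hz=0.5, seed=100 + i), 600.0)
            trains[f"2{i + 1}"] = t
        assert abs(sttc_matrix(trains).mean()) < 0.1

    def test_inactive_electrodes_excluded_by_default(self):
        busy = train(np.linspace(1, 59, 60), 60.0)
        quiet = train([1.0, 2.0], 60.0)  # 2 spikes/min: inactive
        m = sttc_matrix({"11": busy, "12": busy, "13": quiet})
        assert m.labels == ["11", "12"]


class TestSpectralEntropy:
    def test_white_noise_high_entropy(self):
        rng = np.random.default_rng(0)
        h = spectral_entropy_series(rng.normal(0, 1, int(10 * FS)), FS)
        assert h.mean() > 0.9

    def test_sinusoid_low_entropy(self):
        t = np.arange(int(10 * FS)) / FS
        h = spectral_entropy_series(np.sin(2 * np.pi * 1000 * t), FS)
        assert h.mean() < 0.3

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_entropy_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, rng.uniform(1e-6, 1.0), int(3 * FS))
        h = spectral_entropy_series(x, FS)
        assert np.all((h >= 0) & (h <= 1))

    def test_trace_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            spectral_entropy_series(np.zeros(100), FS)


class TestCorse:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1e-5, int(30 * FS))
        assert corse(x, x, FS) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1e-5, int(120 * FS))
        b = rng.normal(0, 1e-5, int(120 * FS))
        assert abs(corse(a, b, FS)) < 0.2

    def test_shared_envelope_beats_independent(self):
        rng = np.random.default_rng(3)
        n = int(60 * FS)
        t = np.arange(n) / FS
        envelope = 1.0 + 0.8 * np.sign(np.sin(2 * np.pi * 0.2 * t))
        a = rng.normal(0, 1e-5, n) * envelope
        b = rng.normal(0, 1e-5, n) * envelope
        c = rng.normal(0, 1e-5, n)
        d = rng.normal(0, 1e-5, n)
        assert abs(corse(a, b, FS)) > abs(corse(c, d, FS))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            corse(np.zeros(int(2 * FS)), np.zeros(int(3 * FS)), FS)


class TestWellCorse:
    def test_two_electrode_mean_is_pair_value(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1e-5, int(10 * FS))
        b = rng.normal(0, 1e-5, int(10 * FS))
        mean, matrix = well_corse({"11": a, "12": b}, FS)
        assert mean == pytest.approx(corse(a, b, FS))
        assert matrix.estimator == "CorSE"

    def test_permutation_invariant_mean(self):
        rng = np.random.default_rng(6)
        traces = {f"1{i}": rng.normal(0, 1e-5, int(5 * FS)) for i in range(1, 4)}
        m1, _ = well_corse(traces, FS)
        m2, _ = well_corse(dict(reversed(list(traces.items()))), FS)
        assert m1 == pytest.approx(m2)

    def test_dead_channel_leaves_mean_unchanged(self):
        rng = np.random.default_rng(7)
        traces = {f"1{i}": rng.normal(0, 1e-5, int(5 * FS)) for i in range(1, 4)}
        base, _ = well_corse(traces, FS)
        with_dead, _ = well_corse({**traces, "44": np.zeros(int(5 * FS))}, FS)
        assert with_dead == pytest.approx(base)


class TestConnectivityMap:
    def matrix(self, v12, v13, v23):
        values = np.array(
            [[1.0, v12, v13], [v12, 1.0, v23], [v13, v23, 1.0]]
        )
        return ConnectivityMatrix(["11", "12", "13"], values, "CorSE")

    def test_threshold_zero_keeps_all_defined(self):
        edges = connectivity_map(self.matrix(0.5, 0.2, 0.9), threshold=0.0)
        assert len(edges) == 3

    def test_threshold_one_generically_empty(self):
        assert connectivity_map(self.matrix(0.5, 0.2, 0.9), threshold=1.0) == []

    def test_exact_070_excluded_strict(self):
        edges = connectivity_map(self.matrix(0.70, 0.71, 0.2), threshold=0.7)
        assert [(e["a"], e["b"]) for e in edges] == [("11", "13")]

    def test_edges_carry_grid_positions(self):
        edges = connectivity_map(self.matrix(0.9, 0.0, 0.0), threshold=0.7)
        assert edges[0]["a_pos"] == (0, 0)
        assert edges[0]["b_pos"] == (0, 1)

    def test_negative_correlation_counts_by_magnitude(self):
        edges = connectivity_map(self.matrix(-0.9, 0.0, 0.0), threshold=0.7)
        assert edges[0]["strength"] == pytest.approx(0.9)

    def test_sttc_pair_of_correlated_exceeds_independent(self):
        model = TrainModel(tonic_rate_hz=1.0, seed=30)
        a, b = generate_correlated_trains(model, 2, 120.0, jitter_s=0.001,
                                          participation_prob=1.0, seed=30)
        i1, _ = generate_train(TrainModel(tonic_rate_hz=1.0, seed=31), 120.0)
        i2, _ = generate_train(TrainModel(tonic_rate_hz=1.0, seed=32), 120.0)
        assert sttc(a, b) > sttc(i1, i2)
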