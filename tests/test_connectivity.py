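import numpy as np
import pytest

from conftest import toy_scheme
from mseeg import preproc
from mseeg.connectivity import (
    ConnectivityMatrix,
    instantaneous_phase,
    mspli,
    pli,
    pli_matrix,
    pli_standard,
    reduce_to_regions,
)
from mseeg.preproc import Recording, make_epochs
from mseeg.synthgen import CouplingSpec, SynthConfig, generate_recording


def _pli_oracle(dphi):
    """Literal evaluation of PLI = (1/k)|sum sign(sin dphi)|."""
    total = 0.0
    for x in np.asarray(dphi, dtype=float):
        s = np.sin(x)
        total += int(s > 0) - int(s < 0)
    return abs(total) / len(dphi)


class TestInstantaneousPhase:
    fs = 500.0

    def _sine_rec(self, freq, n_ch=2, dur=20.0, delay=0):
        t = np.arange(int(dur * self.fs)) / self.fs
        x = np.sin(2 * np.pi * freq * t)
        rows = [np.roll(x, delay * i) for i in range(n_ch)]
        return Recording(data=np.vstack(rows), sampling_rate=self.fs)

    def test_phase_advances_at_signal_frequency(self):
        rec = self._sine_rec(6.0, n_ch=1)
        ph = instantaneous_phase(rec).phases[0]
        inner = slice(int(self.fs), -int(self.fs))
        slopes = np.diff(np.unwrap(ph))[inner]
        expected = 2 * np.pi * 6.0 / self.fs
        assert np.abs(slopes - expected).max() < 0.05

    def test_identical_signals_zero_phase_difference(self):
        rec = self._sine_rec(6.0, n_ch=2, delay=0)
        ph = instantaneous_phase(rec).phases
        np.testing.assert_allclose(ph[0], ph[1], atol=1e-12)

    def test_quarter_period_delay_is_half_pi(self):
        period = int(self.fs / 5.0)
        rec = self._sine_rec(5.0, n_ch=2, delay=period // 4)
        ph = instantaneous_phase(rec).phases
        dphi = np.angle(np.exp(1j * (ph[0] - ph[1])))
        inner = slice(int(self.fs), -int(self.fs))
        assert np.abs(np.median(dphi[inner])) == pytest.approx(np.pi / 2, abs=0.1)

    def test_short_recording_rejected(self):
        rec = Recording(data=np.zeros((2, 100)), sampling_rate=self.fs)
        with pytest.raises(ValueError, match="window"):
            instantaneous_phase(rec)


class TestPli:
    def test_constant_quarter_pi_lag(self):
        assert pli(np.full(1000, np.pi / 2)) == 1.0

    def test_zero_lag_insensitivity(self):
        assert pli(np.zeros(1000)) == 0.0

    def test_hand_computed_example(self):
        assert pli([0.1, -0.2, 0.3, 0.4]) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pli([])

    def test_matches_literal_formula_on_random_series(self, rng):
        for _ in range(25):
            dphi = rng.uniform(-np.pi, np.pi, size=rng.integers(5, 2000))
            assert pli(dphi) == pytest.approx(_pli_oracle(dphi), abs=1e-12)

    def test_symmetry_and_offset_invariance(self, rng):
        dphi = rng.uniform(-np.pi, np.pi, 500)
        assert pli(dphi) == pytest.approx(pli(-dphi), abs=1e-12)
        # common phase offset added to both channels leaves dphi unchanged
        a = rng.uniform(-np.pi, np.pi, 500)
        b = rng.uniform(-np.pi, np.pi, 500)
        assert pli(a - b) == pytest.approx(pli((a + 1.3) - (b + 1.3)), abs=1e-12)

    def test_null_decays_like_inverse_sqrt_k(self, rng):
        for k in (100, 400, 1600, 4000):
            vals = [pli(rng.uniform(-np.pi, np.pi, k)) for _ in range(200)]
            assert np.mean(vals) < 3.0 / np.sqrt(k)

    def test_bounds(self, rng):
        for _ in range(50):
            assert 0.0 <= pli(rng.uniform(-10, 10, 64)) <= 1.0


class TestPliStandard:
    def test_identical_epochs_average_to_single_matrix(self, rng):
        block = rng.normal(size=(4, 1000))
        epochs = preproc.EpochSet(epochs=np.tile(block, (12, 1, 1)),
                                  epoch_length=4.0, sampling_rate=250.0,
                                  channel_labels=[f"c{i}" for i in range(4)])
        cm = pli_standard(epochs, "theta")
        single = pli_standard(
            preproc.EpochSet(epochs=block[None], epoch_length=4.0,
                             sampling_rate=250.0,
                             channel_labels=[f"c{i}" for i in range(4)]),
            "theta", n_epochs=1)
        np.testing.assert_allclose(cm.weights, single.weights, atol=1e-12)

    def test_too_few_epochs_rejected(self, rng):
        epochs = preproc.EpochSet(epochs=rng.normal(size=(5, 3, 1000)),
                                  epoch_length=4.0, sampling_rate=250.0,
                                  channel_labels=["a", "b", "c"])
        with pytest.raises(ValueError, match="epochs"):
            pli_standard(epochs, "theta")

    def test_planted_pair_detected(self):
        cfg = SynthConfig(n_channels=16, duration=60.0, sampling_rate=500.0, seed=5,
                          coupling_specs=(CouplingSpec(pair=(1, 9)),))
        rec, _ = generate_recording(cfg)
        cm = pli_standard(make_epochs(rec), "theta")
        assert cm.weights[1, 9] >= 0.9
        # Uncoupled pairs sit at the estimator's narrowband finite-sample
        # floor (~sqrt(2/(pi*k_eff)) ~ 0.17 for theta-filtered noise in 4-s
        # epochs), far below the planted link.
        others = np.delete(np.delete(cm.weights, [1, 9], axis=0), [1, 9], axis=1)
        assert others[np.triu_indices_from(others, k=1)].mean() < 0.25
        assert cm.weights[1, 9] > 2 * others.max()

    def test_matrix_contract(self, rng):
        epochs = preproc.EpochSet(epochs=rng.normal(size=(12, 5, 1000)),
                                  epoch_length=4.0, sampling_rate=250.0,
                                  channel_labels=[f"c{i}" for i in range(5)])
        cm = pli_standard(epochs, "alpha1")
        w = cm.weights
        assert np.allclose(w, w.T) and np.all(np.diag(w) == 0)
        assert w.min() >= 0 and w.max() <= 1


class TestMspli:
    def test_single_class_equals_plain_pli_exactly(self, rng):
        rec = Recording(data=rng.normal(size=(4, 4000)), sampling_rate=250.0)
        labels = np.zeros(4000, dtype=int)
        class_mats, subject = mspli(rec, labels, "theta",
                                    periods_per_state=2, samples_per_period=1000)
        filtered = preproc.bandpass(rec, "theta")
        phases = instantaneous_phase(filtered).phases
        expected = np.mean([pli_matrix(phases[:, p * 1000:(p + 1) * 1000])
                            for p in range(2)], axis=0)
        np.testing.assert_allclose(class_mats[0].weights, expected, atol=1e-14)
        np.testing.assert_allclose(subject.weights, expected, atol=1e-14)

    def test_five_classes_give_twenty_period_matrices(self, rng):
        # subject average must equal the mean of the 5 class averages,
        # each itself a mean of 4 period matrices
        n = 5 * 4 * 1000 * 2
        rec = Recording(data=rng.normal(size=(3, n)), sampling_rate=250.0)
        labels = np.tile(np.repeat(np.arange(5), 1000), n // 5000)
        class_mats, subject = mspli(rec, labels, "theta",
                                    periods_per_state=4, samples_per_period=1000)
        assert len(class_mats) == 5
        assert {cm.scope for cm in class_mats} == {f"microstate:{c}" for c in range(5)}
        np.testing.assert_allclose(
            subject.weights, np.mean([cm.weights for cm in class_mats], axis=0),
            atol=1e-14)

    def test_insufficient_class_samples_named(self, rng):
        rec = Recording(data=rng.normal(size=(3, 5000)), sampling_rate=250.0)
        labels = np.zeros(5000, dtype=int)
        labels[:100] = 1
        with pytest.raises(ValueError, match="class 1"):
            mspli(rec, labels, "theta", periods_per_state=2, samples_per_period=1000)

    def test_confined_coupling_enhances_class_mspli(self):
        cfg = SynthConfig(
            n_channels=16, duration=120.0, sampling_rate=1000.0, seed=7,
            coupling_specs=(CouplingSpec(pair=(2, 9), active_states=(2,)),),
        )
        rec, truth = generate_recording(cfg)
        class_mats, _ = mspli(rec, truth.state_sequence, "theta")
        link = np.array([cm.weights[2, 9] for cm in class_mats])
        global_link = pli_standard(make_epochs(rec), "theta").weights[2, 9]
        assert link[2] > np.max(np.delete(link, 2))
        assert link[2] > global_link


class TestReduceToRegions:
    labels = [f"c{i:02d}" for i in range(44)]
    scheme = toy_scheme(labels)

    def test_all_ones_matrix(self):
        w = 1.0 - np.eye(44)
        cm = ConnectivityMatrix(weights=w, band="theta", node_labels=self.labels)
        out = reduce_to_regions(cm, self.scheme)
        assert out.weights.shape == (22, 22)
        off = out.weights[np.triu_indices(22, k=1)]
        np.testing.assert_allclose(off, 1.0)
        assert np.all(np.diag(out.weights) == 0)

    def test_block_means_match_hand_computation(self, rng):
        w = rng.uniform(0, 1, (44, 44))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        cm = ConnectivityMatrix(weights=w, band="theta", node_labels=self.labels)
        out = reduce_to_regions(cm, self.scheme)
        ra, rb = self.scheme.region_labels[0], self.scheme.region_labels[5]
        ia = [self.labels.index(c) for c in self.scheme.region_channels(ra)]
        ib = [self.labels.index(c) for c in self.scheme.region_channels(rb)]
        expected = np.mean([w[a, b] for a in ia for b in ib])
        assert out.weights[0, 5] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(out.weights, out.weights.T)

    def test_missing_region_channels_rejected(self):
        cm = ConnectivityMatrix(weights=np.zeros((21, 21)), band="theta",
                                node_labels=self.labels[:21])
        with pytest.raises(ValueError):
            reduce_to_regions(cm, self.scheme)


class TestConnectivityMatrixContract:
    def test_asymmetric_rejected(self):
        w = np.array([[0, 0.5], [0.4, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            ConnectivityMatrix(weights=w, band="theta")

    def test_out_of_range_rejected(self):
        w = np.array([[0, 1.5], [1.5, 0]])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ConnectivityMatrix(weights=w, band="theta")
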