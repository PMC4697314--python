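import numpy as np
import pytest

from mseeg.microstate import (
    MicrostateModel,
    _rle_decode,
    _rle_encode,
    cluster_topographies,
    find_gfp_peaks,
    fit_labels,
    fit_microstates,
    gfp,
    krzanowski_lai,
    select_k,
)
from mseeg.preproc import Recording


def _orthonormal(rng, k, p):
    q, _ = np.linalg.qr(rng.standard_normal((p, k)))
    return q.T


def _generator_maps(rng, k=5, p=16, m=400, noise=0.05):
    """Peak maps drawn from k orthonormal generators with random polarity."""
    gen = _orthonormal(rng, k, p)
    which = rng.integers(k, size=m)
    signs = rng.choice([-1.0, 1.0], size=m)
    maps = signs[:, None] * gen[which] + noise * rng.standard_normal((m, p))
    return maps * rng.uniform(0.5, 2.0, size=(m, 1)), gen, which


class TestGfp:
    def test_two_channel_example(self):
        rec = Recording(data=np.array([[1.0], [-1.0]]), sampling_rate=100.0,
                        reference="average")
        np.testing.assert_allclose(gfp(rec), [1.0])

    def test_zero_sample(self):
        rec = Recording(data=np.zeros((4, 3)), sampling_rate=100.0,
                        reference="average")
        np.testing.assert_allclose(gfp(rec), [0.0, 0.0, 0.0])

    def test_matches_formula_oracle(self, rng):
        data = rng.normal(size=(8, 50))
        data -= data.mean(axis=0, keepdims=True)
        rec = Recording(data=data, sampling_rate=100.0, reference="average")
        expected = np.sqrt((data ** 2).sum(axis=0) / 8)
        np.testing.assert_allclose(gfp(rec), expected, atol=1e-12)

    def test_unreferenced_input_warns_and_rereferences(self, rng):
        data = rng.normal(5.0, 1.0, (6, 40))
        rec = Recording(data=data, sampling_rate=100.0)
        with pytest.warns(UserWarning, match="average-referenced"):
            trace = gfp(rec)
        centred = data - data.mean(axis=0, keepdims=True)
        np.testing.assert_allclose(trace, np.sqrt((centred ** 2).mean(axis=0)))


class TestGfpPeaks:
    def test_simple_trace(self):
        np.testing.assert_array_equal(find_gfp_peaks([0, 1, 0, 2, 0]), [1, 3])

    def test_monotone_trace_has_no_peaks(self):
        assert find_gfp_peaks(np.arange(10.0)).size == 0

    def test_sinusoidal_gfp_peak_count(self):
        f, T, fs = 11.0, 10.0, 1000.0
        t = np.arange(int(T * fs)) / fs
        peaks = find_gfp_peaks(np.abs(np.sin(2 * np.pi * f * t)) + 0.5)
        assert peaks.size == pytest.approx(2 * f * T, abs=2)  # |sin| doubles the rate

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            find_gfp_peaks([1.0, 2.0])


class TestClusterTopographies:
    def test_polarity_blind_single_cluster(self, rng):
        m = rng.standard_normal(10)
        maps = np.vstack([m, -m])
        templates, _ = cluster_topographies(maps, k=1, seed=0, n_restarts=2)
        r = maps @ templates[0] / (np.linalg.norm(maps, axis=1)
                                   * np.linalg.norm(templates[0]))
        np.testing.assert_allclose(np.abs(r), 1.0, atol=1e-12)

    def test_exact_recovery_of_orthogonal_generators(self, rng):
        gen = _orthonormal(rng, 2, 12)
        maps = np.vstack([gen[i] * s for i in range(2) for s in (1, -1, 2, -3)])
        templates, gev = cluster_topographies(maps, k=2, seed=0)
        corr = np.abs(gen @ templates.T)
        assert np.all(corr.max(axis=1) >= 0.999)
        assert gev == pytest.approx(1.0, abs=1e-9)

    def test_gev_increases_with_k_on_multigenerator_data(self, rng):
        maps, _, _ = _generator_maps(rng, k=5, noise=0.3)
        _, gev2 = cluster_topographies(maps, k=2, seed=0)
        _, gev5 = cluster_topographies(maps, k=5, seed=0)
        assert gev5 > gev2

    def test_gev_monotone_over_k(self, rng):
        maps, _, _ = _generator_maps(rng, k=4, noise=0.4, m=200)
        gevs = [cluster_topographies(maps, k=k, seed=0)[1] for k in (2, 3, 4, 6)]
        assert all(b >= a - 1e-9 for a, b in zip(gevs, gevs[1:]))

    def test_bad_k_rejected(self, rng):
        maps = rng.standard_normal((5, 8))
        with pytest.raises(ValueError):
            cluster_topographies(maps, k=0)
        with pytest.raises(ValueError):
            cluster_topographies(maps, k=6)


class TestSelectK:
    def test_constructed_elbow_curve(self):
        # sharp elbow at k0=4: steep decrease before, flat after
        ks = np.arange(1, 10)
        w = np.where(ks < 4, 10.0 / ks, 10.0 / 4 * 0.99 ** ks)
        kl_k, kl = krzanowski_lai(w, ks, p=20)
        assert kl_k[np.argmax(kl)] == 4

    def test_recovers_five_generators(self, rng):
        maps, _, _ = _generator_maps(rng, k=5, m=300, noise=0.1)
        k_star, curve = select_k(maps, k_range=(2, 12), seed=0, n_restarts=8)
        assert k_star == 5
        assert set(curve) <= set(range(2, 13))

    def test_degenerate_identical_maps(self):
        maps = np.tile(np.ones(8), (40, 1))
        with pytest.warns(UserWarning, match="degenerate"):
            k_star, _ = select_k(maps, k_range=(2, 5), seed=0, n_restarts=2)
        assert k_star == 2

    def test_insufficient_maps_rejected(self, rng):
        with pytest.raises(ValueError, match="insufficient"):
            select_k(rng.standard_normal((10, 6)), k_range=(2, 20))


class TestFitLabels:
    fs = 1000.0

    def _recording_from_labels(self, templates, labels, noise=0.0, rng=None):
        data = templates[labels].T.copy()
        if noise and rng is not None:
            data += noise * rng.standard_normal(data.shape)
        return Recording(data=data, sampling_rate=self.fs, reference="average")

    def test_noiseless_labels_recovered_exactly(self, rng):
        templates = _orthonormal(rng, 4, 10)
        truth = rng.integers(4, size=5000)
        rec = self._recording_from_labels(templates, truth)
        labels = fit_labels(rec, templates, smoothing_window=None)
        np.testing.assert_array_equal(labels, truth)

    def test_brief_blip_removed_by_smoothing(self, rng):
        templates = _orthonormal(rng, 3, 10)
        truth = np.zeros(300, dtype=int)
        truth[100:200] = 1
        noisy = truth.copy()
        noisy[148:152] = 2  # 4 ms spurious label inside a 100 ms segment
        rec = self._recording_from_labels(templates, noisy)
        labels = fit_labels(rec, templates, smoothing_window=12.0)
        np.testing.assert_array_equal(labels, truth)

    def test_window_below_one_sample_rejected(self, rng):
        templates = _orthonormal(rng, 3, 10)
        rec = Recording(data=rng.standard_normal((10, 100)), sampling_rate=40.0,
                        reference="average")
        with pytest.raises(ValueError, match="< 1 sample"):
            fit_labels(rec, templates, smoothing_window=12.0)

    def test_channel_space_mismatch_rejected(self, rng):
        templates = _orthonormal(rng, 3, 12)
        rec = Recording(data=rng.standard_normal((10, 100)), sampling_rate=250.0)
        with pytest.raises(ValueError, match="channel spaces"):
            fit_labels(rec, templates)

    def test_every_sample_labelled_and_switch_rate_bounded(self, rng):
        templates = _orthonormal(rng, 4, 10)
        rec = Recording(data=rng.standard_normal((10, 4000)), sampling_rate=self.fs,
                        reference="average")
        labels = fit_labels(rec, templates, smoothing_window=12.0)
        assert labels.shape == (4000,)
        assert set(np.unique(labels)) <= set(range(4))
        switches_per_s = np.count_nonzero(np.diff(labels)) / 4.0
        assert switches_per_s <= self.fs / 12


class TestPolarityInvariance:
    def test_negated_recording_same_segmentation(self, rng):
        from mseeg.synthgen import SynthConfig, generate_recording
        from mseeg.preproc import average_reference

        rec, _ = generate_recording(SynthConfig(n_channels=12, duration=20.0,
                                                sampling_rate=250.0, seed=9))
        rec = average_reference(rec)
        neg = Recording(data=-rec.data, sampling_rate=rec.sampling_rate,
                        reference="average")
        m1 = fit_microstates(rec, k=4, seed=0, n_restarts=5)
        m2 = fit_microstates(neg, k=4, seed=0, n_restarts=5)
        np.testing.assert_array_equal(m1.labels, m2.labels)
        np.testing.assert_allclose(np.abs(m1.templates), np.abs(m2.templates),
                                   atol=1e-9)


def test_rle_roundtrip(rng):
    labels = rng.integers(5, size=1000)
    assert np.array_equal(_rle_decode(_rle_encode(labels)), labels)


def test_model_json_roundtrip(tmp_path, rng):
    model = MicrostateModel(
        templates=rng.standard_normal((3, 8)), k=3,
        labels=rng.integers(3, size=500), smoothing_window=12.0,
        kl_curve={2: 1.0, 3: 4.5},
    )
    path = tmp_path / "model.json"
    model.to_json(path)
    back = MicrostateModel.from_json(path)
    assert back.k == 3
    np.testing.assert_allclose(back.templates, model.templates)
    np.testing.assert_array_equal(back.labels, model.labels)
    assert back.kl_curve == {2: 1.0, 3: 4.5}
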