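import numpy as np
import pytest

from lpstopo.connectivity import (
    BANDS,
    ConnectivityMatrix,
    EpochSet,
    RoiSignal,
    coherency_spectrum,
    lagged_phase_synchronization,
    lps_all_bands,
    normalize_by_max,
    overall_fc,
    segment_epochs,
)

from conftest import sinusoid_epochs


class TestSegmentEpochs:
    def test_five_minutes_at_256hz_gives_150_epochs(self):
        signal = RoiSignal("s", np.zeros((3, 300 * 256)), sampling_rate=256)
        epochs = segment_epochs(signal, 2.0)
        assert epochs.data.shape == (150, 3, 512)

    @pytest.mark.parametrize("n_samples,expected_epochs", [(512, 1), (1023, 1), (1024, 2)])
    def test_trailing_partial_epoch_discarded(self, n_samples, expected_epochs):
        signal = RoiSignal("s", np.arange(2 * n_samples, dtype=float).reshape(2, -1),
                           sampling_rate=256)
        epochs = segment_epochs(signal, 2.0)
        assert epochs.n_epochs == expected_epochs
        # content preserved in order
        np.testing.assert_array_equal(epochs.data[0, 0], signal.samples[0, :512])

    def test_signal_shorter_than_one_epoch_rejected(self):
        signal = RoiSignal("s", np.zeros((2, 100)), sampling_rate=256)
        with pytest.raises(ValueError, match="shorter than one epoch"):
            segment_epochs(signal, 2.0)


class TestCoherency:
    def test_self_coherency_is_one_at_powered_bins(self):
        epochs = sinusoid_epochs([16.0, 16.0], [0.0, 0.0], noise_sd=0.3, seed=1)
        c = coherency_spectrum(epochs, (0, 0))
        np.testing.assert_allclose(c, np.ones_like(c), atol=1e-9)

    def test_quadrature_sinusoids_give_imaginary_coherency(self):
        # 16 Hz is bin-centred for 2-s epochs; 90 deg lag => c = +/- i
        epochs = sinusoid_epochs([16.0, 16.0], [0.0, -np.pi / 2])
        c = coherency_spectrum(epochs, (0, 1))
        carrier = np.argmin(np.abs(epochs.frequencies - 16.0))
        assert abs(c[carrier].real) < 1e-6
        assert abs(abs(c[carrier].imag) - 1.0) < 1e-6

    def test_independent_noise_coherency_decays_with_epochs(self):
        rng = np.random.default_rng(0)
        n_epochs = 400
        data = rng.standard_normal((n_epochs, 2, 512))
        epochs = EpochSet(data=data, sampling_rate=256)
        c = coherency_spectrum(epochs, (0, 1))
        assert np.abs(c).max() < 3 / np.sqrt(n_epochs) + 0.05


class TestLaggedPhaseSynchronization:
    def test_quadrature_pair_reaches_perfect_synchronization(self):
        epochs = sinusoid_epochs([16.0, 16.0], [0.0, -np.pi / 2])
        m = lagged_phase_synchronization(epochs, "beta1")
        assert m.weights[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_identical_signals_have_zero_lagged_synchronization(self):
        # purely real coherency: the zero-lag component carries no LPS
        epochs = sinusoid_epochs([16.0, 16.0], [0.0, 0.0], noise_sd=0.0)
        m = lagged_phase_synchronization(epochs, "beta1")
        assert m.weights[0, 1] == 0.0

    def test_independent_noise_lps_is_small(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((500, 3, 512))
        epochs = EpochSet(data=data, sampling_rate=256)
        for band in BANDS:
            m = lagged_phase_synchronization(epochs, band)
            iu = np.triu_indices(3, k=1)
            assert m.weights[iu].max() < 0.05

    def test_matches_direct_equation_evaluation_on_toy_signals(self):
        """Pipeline LPS equals brute-force evaluation from explicit DFTs."""
        epochs = sinusoid_epochs([14.0, 14.0, 17.0], [0.0, -1.1, 0.4],
                                 n_epochs=6, noise_sd=0.4, seed=3)
        band = BANDS["beta1"]
        # independent oracle: explicit DFT matrix, Hann taper, direct ratio
        ns = epochs.data.shape[2]
        taper = np.hanning(ns)
        k = np.arange(ns // 2 + 1)
        dft = np.exp(-2j * np.pi * np.outer(k, np.arange(ns)) / ns)
        spectra = np.einsum("fs,ecs->ecf", dft, epochs.data * taper)
        freqs = k * epochs.sampling_rate / ns
        mask = (freqs >= band.lo) & (freqs <= band.hi)
        expected = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                sxy = (spectra[:, i, :] * np.conj(spectra[:, j, :])).mean(0)
                sxx = (np.abs(spectra[:, i, :]) ** 2).mean(0)
                syy = (np.abs(spectra[:, j, :]) ** 2).mean(0)
                c = sxy / np.sqrt(sxx * syy)
                phi2 = np.imag(c) ** 2 / (1 - np.real(c) ** 2)
                expected[i, j] = phi2[mask].max()
        m = lagged_phase_synchronization(epochs, "beta1")
        np.testing.assert_allclose(m.weights, expected, atol=1e-10)

    def test_symmetric_bounded_and_zero_diagonal(self):
        epochs = sinusoid_epochs([14.0, 15.0, 16.0, 18.0], [0.0, 0.5, 1.0, 2.0],
                                 noise_sd=1.0, seed=4)
        for band in ("delta", "alpha1", "beta1"):
            m = lagged_phase_synchronization(epochs, band)
            np.testing.assert_array_equal(m.weights, m.weights.T)
            assert np.all(np.diag(m.weights) == 0)
            assert m.weights.min() >= 0 and m.weights.max() <= 1

    def test_null_lps_quantile_shrinks_with_more_epochs(self):
        rng = np.random.default_rng(5)

        def q95(n_epochs):
            data = rng.standard_normal((n_epochs, 4, 512))
            m = lagged_phase_synchronization(EpochSet(data=data, sampling_rate=256),
                                             "beta1")
            return np.quantile(m.weights[np.triu_indices(4, 1)], 0.95)

        assert q95(400) < q95(25)

    def test_unknown_band_and_unresolvable_band_rejected(self):
        epochs = sinusoid_epochs([16.0], [0.0])
        with pytest.raises(ValueError, match="unknown band"):
            lagged_phase_synchronization(epochs, "gamma")
        from lpstopo.connectivity import BandSpec
        with pytest.raises(ValueError, match="not resolvable"):
            lagged_phase_synchronization(epochs, BandSpec("hf", 100.0, 200.0))

    def test_all_bands_shortcut_matches_per_band_calls(self):
        epochs = sinusoid_epochs([14.0, 9.0, 16.0], [0.0, 0.7, -0.7],
                                 noise_sd=0.5, seed=6)
        shared = lps_all_bands(epochs)
        for band in BANDS:
            single = lagged_phase_synchronization(epochs, band)
            np.testing.assert_array_equal(shared[band].weights, single.weights)


class TestNormalizeByMax:
    def test_scales_to_unit_maximum_and_preserves_order(self):
        w = np.array([[0.0, 0.5, 0.1], [0.5, 0.0, 0.25], [0.1, 0.25, 0.0]])
        m = ConnectivityMatrix("s", "beta1", w)
        normalized = normalize_by_max(m)
        assert normalized.weights.max() == 1.0
        np.testing.assert_allclose(normalized.weights, w * 2)
        assert normalized.normalized

    def test_idempotent_on_normalized_matrix(self):
        w = np.array([[0.0, 1.0, 0.1], [1.0, 0.0, 0.25], [0.1, 0.25, 0.0]])
        m = normalize_by_max(ConnectivityMatrix("s", "beta1", w))
        np.testing.assert_array_equal(m.weights, w)

    def test_all_zero_matrix_refused(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_by_max(ConnectivityMatrix("s", "beta1", np.zeros((3, 3))))


class TestOverallFc:
    def test_constant_weights(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0.0)
        assert overall_fc(ConnectivityMatrix("s", "b", w)) == 0.5

    def test_zero_matrix(self):
        assert overall_fc(ConnectivityMatrix("s", "b", np.zeros((4, 4)))) == 0.0

    def test_hand_computed_mean(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        w = np.zeros((4, 4))
        w[np.triu_indices(4, 1)] = vals
        w = w + w.T
        assert overall_fc(ConnectivityMatrix("s", "b", w)) == pytest.approx(0.35)
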