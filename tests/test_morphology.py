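"""DWT subband decomposition and ICA reduction of beat morphology."""

import warnings

import numpy as np
import pytest
import pywt
from scipy.optimize import linear_sum_assignment

import ecgbeats as eb


def _sine_beat(freq, n=200, fs=360.0, phase=0.7):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


class TestDWT:
    def test_zero_beat_gives_zero_coefficients(self):
        c = eb.dwt_level4(np.zeros(200))
        assert np.allclose(c.a4, 0) and np.allclose(c.d4, 0)
        assert len(c.a4) > 0 and len(c.d4) > 0

    def test_reconstruction_oracle(self, mixed_dataset):
        """Inverse 4-level DWT of all retained levels reproduces the beat.

        The dmey filter is a 62-tap FIR *approximation* of the Meyer
        wavelet and is only near-orthogonal (sum of squared taps 1.0022),
        so reconstruction carries an inherent ~0.6% relative error floor;
        the oracle checks invertibility at that approximation level.
        """
        for seg in mixed_dataset.beats[:25]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                coeffs = pywt.wavedec(seg.samples, "dmey", mode="symmetric", level=4)
                back = pywt.waverec(coeffs, "dmey", mode="symmetric")[: len(seg.samples)]
            err = np.linalg.norm(back - seg.samples) / np.linalg.norm(seg.samples)
            assert err < 0.02

    def test_reconstruction_exact_for_orthogonal_wavelet(self, mixed_dataset):
        """With a truly orthogonal filter (db4) the same round trip is exact,
        isolating the residual above as the dmey approximation error."""
        seg = mixed_dataset.beats[0]
        coeffs = pywt.wavedec(seg.samples, "db4", mode="symmetric", level=4)
        back = pywt.waverec(coeffs, "db4", mode="symmetric")[: len(seg.samples)]
        assert np.linalg.norm(back - seg.samples) < 1e-8 * np.linalg.norm(seg.samples)

    def test_subband_energy_dominance(self):
        def energies(freq):
            c = eb.dwt_level4(_sine_beat(freq, n=2048))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                full = pywt.wavedec(_sine_beat(freq, n=2048), "dmey",
                                    mode="symmetric", level=4)
            total = sum(np.sum(ci**2) for ci in full)
            return np.sum(c.a4**2) / total, np.sum(c.d4**2) / total

        a4_frac, _ = energies(5.0)      # inside 0-11.25 Hz
        assert a4_frac >= 0.90
        a4_16, d4_16 = energies(16.0)   # inside 11.25-22.5 Hz
        assert d4_16 > a4_16 and d4_16 >= 0.80

    def test_coefficient_lengths_constant_across_beats(self, mixed_dataset):
        assert mixed_dataset.a4.ndim == 2 and mixed_dataset.d4.ndim == 2
        # symmetric extension with the 62-tap dmey filter on 200-sample beats
        assert mixed_dataset.a4.shape[1] == mixed_dataset.d4.shape[1] == 69

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            eb.dwt_level4(np.zeros(8))


@pytest.fixture(scope="module")
def known_mixture():
    rng = np.random.default_rng(42)
    S = rng.uniform(-1, 1, size=(2000, 6))
    A = rng.normal(size=(6, 20))
    return S, S @ A


class TestICA:
    def test_source_recovery(self, known_mixture):
        S, X = known_mixture
        model = eb.fit_ica(X, n_components=6, seed=3)
        rec = eb.project_ica(model, X)
        C = np.abs(np.corrcoef(S.T, rec.T)[:6, 6:])
        rows, cols = linear_sum_assignment(-C)
        assert C[rows, cols].min() >= 0.95

    def test_deterministic_for_fixed_seed(self, known_mixture):
        _, X = known_mixture
        m1 = eb.fit_ica(X, seed=5)
        m2 = eb.fit_ica(X, seed=5)
        assert np.array_equal(m1.components_, m2.components_)
        assert np.array_equal(m1.order_, m2.order_)

    def test_rank_guard(self, rng):
        low_rank = rng.normal(size=(200, 3)) @ rng.normal(size=(3, 20))
        with pytest.raises(ValueError, match="rank"):
            eb.fit_ica(low_rank, n_components=6, seed=0)

    def test_too_few_beats_rejected(self, rng):
        with pytest.raises(ValueError):
            eb.fit_ica(rng.normal(size=(4, 20)), n_components=6, seed=0)

    def test_projection_is_affine(self, known_mixture, rng):
        _, X = known_mixture
        model = eb.fit_ica(X, seed=1)
        assert eb.project_ica(model, model.mean_) == pytest.approx(np.zeros(6), abs=1e-9)
        a, b = rng.normal(size=20), rng.normal(size=20)
        lhs = eb.project_ica(model, a + b)
        rhs = (eb.project_ica(model, a) + eb.project_ica(model, b)
               - eb.project_ica(model, np.zeros(20)))
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_projection_shape(self, known_mixture):
        _, X = known_mixture
        model = eb.fit_ica(X, seed=1)
        assert eb.project_ica(model, X[0]).shape == (6,)
        assert eb.project_ica(model, X[:7]).shape == (7, 6)
        with pytest.raises(ValueError):
            eb.project_ica(model, np.zeros(13))

    def test_transform_consistent_with_training_sources(self, known_mixture):
        _, X = known_mixture
        model = eb.fit_ica(X, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            refit = eb.SubbandICAReducer(random_state=2).fit(X)
        sources = refit.ica_.transform(X)[:, refit.order_]
        assert np.allclose(model.transform(X), sources, atol=1e-8)

    def test_leakage_guard(self, known_mixture):
        _, X = known_mixture
        flags = np.zeros(len(X), dtype=bool)
        flags[0] = True
        with pytest.raises(RuntimeError, match="leakage"):
            eb.fit_ica(X, seed=0, is_test=flags)

    def test_save_load_roundtrip(self, known_mixture, tmp_path):
        _, X = known_mixture
        model = eb.fit_ica(X, seed=4, subband_tag="d4")
        model.save(tmp_path / "ica.npz")
        back = eb.SubbandICAReducer.load(tmp_path / "ica.npz")
        assert back.subband_tag == "d4"
        assert np.allclose(back.transform(X[:5]), model.transform(X[:5]))


@pytest.fixture(scope="module")
def fitted_models(mixed_dataset):
    m_a4 = eb.fit_ica(mixed_dataset.a4, seed=0, subband_tag="a4")
    m_d4 = eb.fit_ica(mixed_dataset.d4, seed=0, subband_tag="d4")
    return m_a4, m_d4


class TestMorphologicalFeatures:
    def test_twelve_features_per_beat(self, mixed_dataset, fitted_models):
        F = eb.morphological_features(mixed_dataset.beats[:10], *fitted_models)
        assert F.shape == (10, 12)

    def test_first_six_depend_only_on_a4(self, mixed_dataset, fitted_models):
        m_a4, m_d4 = fitted_models
        beats = mixed_dataset.beats[:5]
        F = eb.morphological_features(beats, m_a4, m_d4)
        # perturb the d4 model: the a4-derived half must not move
        perturbed = eb.fit_ica(mixed_dataset.d4, seed=99, subband_tag="d4")
        F2 = eb.morphological_features(beats, m_a4, perturbed)
        assert np.allclose(F[:, :6], F2[:, :6])
        assert not np.allclose(F[:, 6:], F2[:, 6:])

    def test_subband_edges_analytic(self):
        assert eb.subband_edges(360.0) == (11.25, 22.5)
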