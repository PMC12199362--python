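import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from havokrisk.embedding import (
    build_hankel,
    delay_embed,
    dominant_period,
    forcing_signal,
    line_length_envelope,
    svd_embedding,
)


class TestHankel:
    def test_definition_small_example(self):
        emb = build_hankel([1, 2, 3, 4], d=2)
        np.testing.assert_array_equal(emb.H, [[1, 2, 3], [2, 3, 4]])

    def test_shape_at_default_depth(self):
        emb = build_hankel(np.arange(1000.0), d=100)
        assert emb.H.shape == (100, 901)

    def test_full_depth_single_column(self):
        x = np.arange(5.0)
        emb = build_hankel(x, d=5)
        np.testing.assert_array_equal(emb.H[:, 0], x)
        assert emb.H.shape == (5, 1)

    def test_too_short_series_errors(self):
        with pytest.raises(ValueError):
            build_hankel([1, 2, 3], d=5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(2, 10), st.integers(0, 1000))
    def test_each_row_one_step_delayed(self, d, seed):
        x = np.random.default_rng(seed).standard_normal(d + 17)
        H = build_hankel(x, d).H
        for i in range(d):
            np.testing.assert_array_equal(H[i], x[i : i + H.shape[1]])


class TestSvdEmbedding:
    def test_constant_series_rank_one(self):
        emb = svd_embedding(build_hankel(np.full(50, 2.0), d=5))
        assert emb.S[0] > 0
        assert np.all(emb.S[1:] < 1e-10 * emb.S[0])
        v1 = emb.V[:, 0]
        np.testing.assert_allclose(v1, v1[0], atol=1e-12)

    def test_orthonormal_factors_and_reconstruction(self, rng):
        x = rng.standard_normal(400)
        emb = svd_embedding(build_hankel(x, d=20))
        np.testing.assert_allclose(emb.U.T @ emb.U, np.eye(20), atol=1e-10)
        np.testing.assert_allclose(emb.V.T @ emb.V, np.eye(20), atol=1e-10)
        H_rec = emb.U @ np.diag(emb.S) @ emb.V.T
        assert np.linalg.norm(H_rec - emb.H) / np.linalg.norm(emb.H) < 1e-10

    def test_pure_sinusoid_has_two_components(self):
        x = np.sin(2 * np.pi * np.arange(24 * 40) / 24)
        emb = svd_embedding(build_hankel(x, d=24))
        assert emb.S[2] / emb.S[0] < 1e-6

    def test_sign_convention_deterministic(self, rng):
        x = rng.standard_normal(300)
        a = svd_embedding(build_hankel(x, d=10))
        b = svd_embedding(build_hankel(x, d=10))
        np.testing.assert_array_equal(a.U, b.U)
        for j in range(a.k):
            assert a.U[np.argmax(np.abs(a.U[:, j])), j] > 0

    def test_truncation_bounds_checked(self):
        emb = build_hankel(np.arange(50.0), d=5)
        with pytest.raises(ValueError):
            svd_embedding(emb, k=6)

    def test_time_shift_shifts_coordinates(self, rng):
        """Shifting the input by s samples shifts every V column by s."""
        x = np.sin(2 * np.pi * np.arange(600.0) / 50) + 0.1 * rng.standard_normal(600)
        s = 7
        a = delay_embed(x, d=20, k=4)
        b = delay_embed(x[s:], d=20, k=4)
        n = b.V.shape[0]
        for j in range(4):
            corr = np.corrcoef(a.V[s : s + n, j], b.V[:, j])[0, 1]
            assert abs(corr) > 0.995


class TestDominantPeriod:
    def test_exact_tone(self):
        u = np.sin(2 * np.pi * np.arange(100) / 25)
        assert dominant_period(u) == pytest.approx(25.0, abs=0.5)

    def test_constant_column_flags_infinity(self):
        assert dominant_period(np.full(64, 1.0)) == np.inf

    def test_largest_amplitude_tone_wins(self):
        t = np.arange(100)
        u = np.sin(2 * np.pi * t / 10) + 3 * np.sin(2 * np.pi * t / 50)
        assert dominant_period(u) == pytest.approx(50.0, abs=1.0)

    def test_all_zero_column_errors(self):
        with pytest.raises(ValueError):
            dominant_period(np.zeros(32))

    def test_period_ordering_on_patient_basis(self, patient_embedding):
        """Dominant periods of the U basis decrease with the column index
        (ties allowed within the FFT resolution of a d-sample window)."""
        emb = patient_embedding["emb"]
        # only modes above the numerical noise floor carry a meaningful
        # frequency; deep modes of the smooth low-passed series do not
        strong = [j for j in range(emb.k) if emb.S[j] > 1e-5 * emb.S[0]]
        periods = [min(dominant_period(emb.U[:, j]), 1e6) for j in strong]
        for a, b in zip(periods[:-1], periods[1:]):
            assert b <= a * 1.05 + a * a / emb.d  # one-bin slack


class TestLineLength:
    def test_constant_input_zero_envelope(self):
        ll, _ = line_length_envelope(np.full(200, 1.3), window_hours=72)
        np.testing.assert_array_equal(ll, 0.0)

    def test_linear_ramp_steady_state(self):
        c = 0.37
        ll, _ = line_length_envelope(c * np.arange(300.0), window_hours=72)
        np.testing.assert_allclose(ll[72:], 72 * c, rtol=1e-10)

    def test_sinusoid_matches_brute_force(self):
        v = np.sin(2 * np.pi * np.arange(400.0) / 24)
        ll, nll = line_length_envelope(v, window_hours=72)
        brute = [
            np.abs(np.diff(v[t - 72 : t + 1])).sum() for t in range(72, 400)
        ]
        np.testing.assert_allclose(ll[72:], brute, atol=1e-10)
        assert np.ptp(ll[72:]) < 1e-6  # steady over full cycles
        assert abs(nll[72:].mean()) < 1e-9

    def test_window_longer_than_series_errors(self):
        with pytest.raises(ValueError):
            line_length_envelope(np.zeros(50), window_hours=72)

    def test_forcing_signal_bundles_envelope(self, patient_embedding):
        fs = forcing_signal(patient_embedding["emb"], r=4)
        assert fs.line_length.min() >= 0
        assert abs(fs.normalized_line_length[~fs.warmup_mask].mean()) < 1e-6
        assert fs.active.dtype == bool
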