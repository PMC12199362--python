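import numpy as np
import pytest

from havokrisk.havok import (
    HavokSystem,
    fit_havok,
    prediction_accuracy,
    predict_test_span,
    simulate_havok,
    streaming_forcing,
    sweep_forcing_accuracy,
)


def _forced_linear_system(n, seed=0, noise=0.0):
    """Ground-truth 3-D discrete system driven by white-noise forcing."""
    rng = np.random.default_rng(seed)
    A = np.array([[0.98, 0.05, 0.0], [-0.05, 0.97, 0.02], [0.0, -0.02, 0.96]])
    B = np.array([0.5, -0.3, 0.2])
    f = rng.standard_normal(n)
    V = np.zeros((n, 4))
    v = np.zeros(3)
    for t in range(1, n):
        v = A @ v + B * f[t - 1]
        V[t, :3] = v
    V[:, 3] = f
    if noise:
        V = V + rng.normal(0.0, noise, V.shape)
    return A, B, V


class TestFit:
    def test_recovers_known_system_exactly(self):
        A, B, V = _forced_linear_system(5000, seed=1)
        sys_ = fit_havok(V, r=4)
        assert np.abs(sys_.A - A).max() < 1e-6
        assert np.abs(sys_.B - B).max() < 1e-6

    def test_recovery_degrades_gracefully_with_noise(self):
        A, B, V = _forced_linear_system(5000, seed=1, noise=1e-3)
        sys_ = fit_havok(V, r=4)
        assert np.abs(sys_.A - A).max() < 0.05
        assert np.abs(sys_.B - B).max() < 0.05

    def test_zero_variance_forcing_is_rank_deficient(self):
        V = np.ones((500, 4))
        with pytest.raises(np.linalg.LinAlgError, match="deficient"):
            fit_havok(V, r=4)

    def test_short_training_span_rejected(self):
        _, _, V = _forced_linear_system(500, seed=0)
        with pytest.raises(ValueError, match="10\\*r"):
            fit_havok(V, r=4, train_span=(0, 35))


class TestSimulate:
    def _system(self, A, B, r):
        return HavokSystem(
            A=np.asarray(A, float),
            B=np.asarray(B, float),
            r=r,
            train_span=(0, 0),
            fit_residual=np.zeros(r - 1),
            condition_number=1.0,
        )

    def test_identity_system_holds_state(self):
        sys_ = self._system(np.eye(2), np.zeros(2), r=3)
        sim = simulate_havok(sys_, [1.5, -2.0], np.zeros(10))
        np.testing.assert_allclose(sim.V_pred, np.tile([1.5, -2.0], (10, 1)))

    def test_pure_delay_reproduces_forcing(self):
        sys_ = self._system([[0.0]], [1.0], r=2)
        f = np.arange(5.0)
        sim = simulate_havok(sys_, [9.0], f)
        np.testing.assert_allclose(sim.V_pred[:, 0], f)  # output(t) = forcing(t-1)

    def test_divergence_flagged_with_partial_output(self):
        sys_ = self._system([[1e8]], [0.0], r=2)
        sim = simulate_havok(sys_, [1.0], np.zeros(100))
        assert sim.diverged_at is not None
        assert np.isnan(sim.V_pred[-1, 0])

    def test_round_trip_on_noiseless_system(self):
        _, _, V = _forced_linear_system(4000, seed=2)
        sys_ = fit_havok(V, r=4, train_span=(0, 2000))
        sim, truth = predict_test_span(sys_, V)
        mse = np.mean((sim.V_pred - truth) ** 2, axis=0)
        assert np.all(mse < 1e-8)


class TestStreamingForcing:
    def test_matches_svd_column_on_training_series(self, patient_embedding):
        emb = patient_embedding["emb"]
        x = patient_embedding["pp"].filtered.values
        for r in (1, 11, 22):
            v = streaming_forcing(emb.U[:, r - 1], emb.S[r - 1], x)
            assert np.abs(v - emb.V[:, r - 1]).max() < 1e-8

    def test_self_window_gives_inverse_singular_value_peak(self, patient_embedding):
        emb = patient_embedding["emb"]
        u = emb.U[:, 3]
        padded = np.concatenate([np.zeros(50), u, np.zeros(50)])
        v = streaming_forcing(u, emb.S[3], padded)
        assert v[50] == pytest.approx(1.0 / emb.S[3], rel=1e-10)

    def test_orthogonal_window_gives_zero(self, patient_embedding):
        emb = patient_embedding["emb"]
        padded = np.concatenate([np.zeros(50), emb.U[:, 5], np.zeros(50)])
        v = streaming_forcing(emb.U[:, 3], emb.S[3], padded)
        assert abs(v[50]) < 1e-12

    def test_end_alignment_pads_causally(self, patient_embedding):
        emb = patient_embedding["emb"]
        x = patient_embedding["pp"].filtered.values
        v = streaming_forcing(emb.U[:, 10], emb.S[10], x, align="end")
        assert v.size == x.size
        assert np.isnan(v[: emb.d - 1]).all()
        np.testing.assert_allclose(v[emb.d - 1 :], emb.V[:, 10], atol=1e-8)

    def test_tiny_singular_value_rejected(self):
        with pytest.raises(ValueError, match="identifiable"):
            streaming_forcing(np.ones(10), 1e-15, np.ones(100))


class TestAccuracy:
    def test_constant_offset(self):
        truth = np.zeros((50, 3))
        pred = truth + 0.5
        np.testing.assert_allclose(prediction_accuracy(pred, truth), 4.0)

    def test_perfect_prediction_is_infinite(self):
        truth = np.ones((50, 2))
        acc = prediction_accuracy(truth, truth, dims=[1, 2])
        assert np.all(np.isinf(acc))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            prediction_accuracy(np.zeros((5, 2)), np.zeros((6, 2)))

    def test_forcing_sweep_completes(self, patient_embedding):
        emb = patient_embedding["emb"]
        sweep = sweep_forcing_accuracy(emb, range(4, 23), train_span=(0, 4380))
        assert sorted(sweep) == list(range(4, 23))
        for acc in sweep.values():
            assert np.all(acc > 0)
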