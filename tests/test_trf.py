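"""TRF estimation: lag designs, ridge solutions, cross-validation, statistics."""

import numpy as np
import pytest

import trfnet
from trfnet.exceptions import DegenerateVarianceError, FitError
from trfnet.synth import roi_response
from trfnet.trf import advance_matrix

FS = 250.0


class TestLagMatrix:
    def test_single_zero_lag_is_identity_copy(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(trfnet.lag_matrix(x, [0.0], FS)[:, 0], x)

    def test_impulse_shifts(self):
        x = np.zeros(8)
        x[0] = 1.0
        lags = np.array([0.0, 4.0, 8.0])  # 0, 1, 2 samples at 250 Hz
        out = trfnet.lag_matrix(x, lags, FS)
        for k in range(3):
            expected = np.zeros(8)
            expected[k] = 1.0
            np.testing.assert_array_equal(out[:, k], expected)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20, 2))
        lags_samp = [0, 1, 3]
        lags_ms = [s * 1000.0 / FS for s in lags_samp]
        out = trfnet.lag_matrix(x, lags_ms, FS)
        for f in range(2):
            for k, lag in enumerate(lags_samp):
                for t in range(20):
                    expected = x[t - lag, f] if t - lag >= 0 else 0.0
                    assert out[t, f * 3 + k] == expected

    def test_advance_matrix_uses_future_samples(self):
        x = np.zeros(8)
        x[5] = 1.0
        out = advance_matrix(x, [0.0, 4.0], FS)  # 0 and 1 samples ahead
        assert out[5, 0] == 1.0
        assert out[4, 1] == 1.0

    def test_invalid_lags_rejected(self):
        with pytest.raises(ValueError):
            trfnet.lag_matrix(np.zeros(10), [-4.0], FS)
        with pytest.raises(ValueError):
            trfnet.lag_matrix(np.zeros(10), [1000.0], FS)
        with pytest.raises(ValueError):
            trfnet.lag_matrix(np.zeros(10), [3.0], FS)  # not a sample multiple


class TestFitEncoder:
    def test_recovers_planted_kernel_from_broadband_stimulus(self):
        rng = np.random.default_rng(1)
        env = trfnet.Envelope(values=np.abs(rng.standard_normal(5000)) + 0.1, fs=FS)
        lags = trfnet.default_lag_grid(FS)
        true_k = np.sin(2 * np.pi * 4 * (lags / 1000 - 0.1)) * np.exp(
            -np.clip(lags / 1000 - 0.1, 0, None) / 0.15
        ) * (lags / 1000 >= 0.1)
        resp = roi_response(true_k[None, :], env, lags)
        model = trfnet.fit_encoder(env, resp, lags_ms=lags, ridge=1e-8)
        assert np.corrcoef(model.weights[0], true_k)[0, 1] >= 0.99

    def test_large_ridge_shrinks_weights_to_zero(self):
        rng = np.random.default_rng(2)
        env = trfnet.Envelope(values=np.abs(rng.standard_normal(500)) + 0.1, fs=FS)
        y = rng.standard_normal((1, 500))
        small = trfnet.fit_encoder(env, y, lags_ms=[0.0, 4.0, 8.0], ridge=1e-4)
        huge = trfnet.fit_encoder(env, y, lags_ms=[0.0, 4.0, 8.0], ridge=1e9)
        assert np.abs(huge.weights).max() < 1e-6 * np.abs(small.weights).max()

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        env = rng.standard_normal(50) + 2.0
        y = rng.standard_normal((1, 50))
        lags_ms = [0.0, 4.0, 8.0, 12.0]
        ridge = 0.5
        model = trfnet.fit_encoder(env, y, lags_ms=lags_ms, ridge=ridge, fs=FS)
        x = trfnet.lag_matrix(env, lags_ms, FS)
        xc = x - x.mean(0)
        yc = y.ravel() - y.mean()
        lam = ridge * np.mean(np.diag(xc.T @ xc))
        w = np.linalg.solve(xc.T @ xc + lam * np.eye(4), xc.T @ yc)
        np.testing.assert_allclose(model.weights[0], w, atol=1e-10)

    def test_zero_variance_envelope_rejected(self):
        with pytest.raises(FitError):
            trfnet.fit_encoder(np.ones(100), np.zeros((1, 100)), lags_ms=[0.0], fs=FS)


class TestFitDecoder:
    def test_identity_channel_reconstructs_exactly(self):
        env = trfnet.make_envelope(2.0, FS, seed=4)
        dec = trfnet.fit_decoder(env.values[None, :], env, lags_ms=[0.0], ridge=0.0)
        pred = trfnet.predict_envelope(dec, env.values[None, :])
        assert np.corrcoef(pred, env.values)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_full_decoder_no_worse_than_single_roi(self):
        rng = np.random.default_rng(5)
        env = trfnet.make_envelope(4.0, FS, seed=6)
        rois = np.stack([
            np.roll(env.values, 5) + 0.5 * rng.standard_normal(len(env)),
            np.roll(env.values, 10) + 0.5 * rng.standard_normal(len(env)),
            rng.standard_normal(len(env)),
        ])
        lags = [0.0, 20.0, 40.0]

        def train_mse(r):
            d = trfnet.fit_decoder(r, env, lags_ms=lags, ridge=0.0)
            return np.mean((trfnet.predict_envelope(d, r) - env.values) ** 2)

        full = train_mse(rois)
        for i in range(3):
            assert full <= train_mse(rois[i][None, :]) + 1e-9

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        env = rng.standard_normal(60)
        rois = rng.standard_normal((2, 60))
        lags_ms = [0.0, 4.0]
        ridge = 0.3
        dec = trfnet.fit_decoder(rois, env, lags_ms=lags_ms, ridge=ridge, fs=FS)
        x = advance_matrix(rois.T, lags_ms, FS)
        xc = x - x.mean(0)
        yc = env - env.mean()
        lam = ridge * np.mean(np.diag(xc.T @ xc))
        w = np.linalg.solve(xc.T @ xc + lam * np.eye(4), xc.T @ yc)
        np.testing.assert_allclose(dec.weights.ravel(), w, atol=1e-10)


class TestLooCrossval:
    def _signal_trials(self, n_trials, seed, snr=10.0):
        rng = np.random.default_rng(seed)
        lags = trfnet.default_lag_grid(FS)
        k = np.cos(2 * np.pi * 5 * (lags / 1000 - 0.3)) * np.exp(
            -0.5 * ((lags / 1000 - 0.3) / 0.1) ** 2
        )
        trials = []
        for i in range(n_trials):
            env = trfnet.make_envelope(3.0, FS, seed=seed + 10 + i)
            resp = roi_response(np.tile(k, (4, 1)), env, lags)
            noise = rng.standard_normal(resp.shape)
            resp = resp + noise * resp.std() / (10 ** (snr / 20)) / noise.std()
            trials.append((env, resp))
        return trials

    def test_duplicated_high_snr_trial_generalizes_perfectly(self):
        rng = np.random.default_rng(8)
        env = trfnet.make_envelope(3.0, FS, seed=18)
        rois = np.stack([np.roll(env.values, 2), np.roll(env.values, 5)])
        rois = rois + 1e-4 * rng.standard_normal(rois.shape)
        trials = [(env, rois)] * 4
        res = trfnet.loo_crossval(trials, lags_ms=[0.0, 8.0, 16.0, 24.0], fs=FS)
        assert all(r.r >= 0.99 for r in res)

    def test_null_roi_series_give_chance_accuracy(self):
        rng = np.random.default_rng(9)
        trials = []
        for i in range(4):
            env = trfnet.make_envelope(10.0, FS, seed=100 + i)  # 2500 samples x 4 = 10k
            trials.append((env, rng.standard_normal((3, len(env)))))
        res = trfnet.loo_crossval(trials, lags_ms=[0.0, 40.0, 80.0], fs=FS)
        assert abs(np.mean([r.r for r in res])) < 0.05

    def test_fold_count_matches_trial_count(self):
        trials = self._signal_trials(24, seed=10, snr=5.0)
        res = trfnet.loo_crossval(trials, lags_ms=[0.0, 40.0], fs=FS)
        assert len(res) == 24
        assert sorted(r.trial for r in res) == list(range(24))

    def test_constant_test_envelope_recorded_missing(self):
        rng = np.random.default_rng(11)
        good = [(trfnet.make_envelope(2.0, FS, seed=i), rng.standard_normal((2, 500))) for i in range(3)]
        flat = (trfnet.Envelope(values=np.ones(500), fs=FS), rng.standard_normal((2, 500)))
        with pytest.warns(UserWarning, match="constant envelope"):
            res = trfnet.loo_crossval(good + [flat], lags_ms=[0.0, 4.0], fs=FS)
        assert np.isnan(res[3].r)
        assert all(np.isfinite(res[i].r) for i in range(3))


class TestFisherZ:
    def test_values_and_symmetry(self):
        assert trfnet.fisher_z(0.0) == 0.0
        assert trfnet.fisher_z(0.5) == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert trfnet.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        for r in (0.1, 0.7, 0.99):
            assert trfnet.fisher_z(-r) == -trfnet.fisher_z(r)

    @pytest.mark.parametrize("bad", [1.0, -1.0, 1.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            trfnet.fisher_z(bad)


class TestCompareTrfWindows:
    LAGS = trfnet.default_lag_grid(FS)

    def test_identical_sets_give_zero(self):
        rng = np.random.default_rng(12)
        a = rng.standard_normal((5, self.LAGS.size))
        out = trfnet.compare_trf_windows(a, a.copy(), (300.0, 450.0), self.LAGS)
        assert out == {"t": 0.0, "p": 1.0, "cohen_d": 0.0}

    def test_matches_textbook_paired_t_oracle(self):
        rng = np.random.default_rng(13)
        n = 6
        a = rng.standard_normal((n, self.LAGS.size))
        b = a + rng.standard_normal((n, self.LAGS.size)) * 0.3 + 0.1
        out = trfnet.compare_trf_windows(a, b, (0.0, 800.0), self.LAGS)
        d = a.mean(axis=1) - b.mean(axis=1)
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        assert out["t"] == pytest.approx(t_oracle, abs=1e-10)
        assert out["cohen_d"] == pytest.approx(d.mean() / d.std(ddof=1), abs=1e-10)

    def test_constant_nonzero_shift_is_degenerate(self):
        a = np.tile(np.linspace(0, 1, self.LAGS.size), (4, 1))
        with pytest.raises(DegenerateVarianceError):
            trfnet.compare_trf_windows(a, a + 1.0, (0.0, 800.0), self.LAGS)

    def test_window_outside_grid_rejected(self):
        a = np.zeros((3, self.LAGS.size))
        with pytest.raises(ValueError):
            trfnet.compare_trf_windows(a, a, (700.0, 900.0), self.LAGS)
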