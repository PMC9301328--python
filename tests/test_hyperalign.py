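"""MCCA: covariance assembly, eigenstructure, and denoising averages."""

import numpy as np
import pytest

import trfnet
from trfnet.hyperalign import MCCAModel, between_set_covariance


def _two_set_cca_oracle(x, y):
    """Leading canonical correlation via QR/SVD (independent of MCCA path)."""
    qx, _ = np.linalg.qr(x - x.mean(0))
    qy, _ = np.linalg.qr(y - y.mean(0))
    return np.linalg.svd(qx.T @ qy, compute_uv=False)[0]


class TestBetweenSetCovariance:
    def test_self_covariance_symmetric_psd(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((30, 4))
        v = between_set_covariance(x, x)
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(v) > -1e-10)

    def test_constant_columns_give_zero(self):
        x = np.ones((10, 3))
        y = np.full((10, 2), 7.0)
        np.testing.assert_array_equal(between_set_covariance(x, y), np.zeros((3, 2)))

    def test_matches_direct_loop(self):
        x = np.array([[1.0, 2.0], [3.0, 0.0], [-1.0, 4.0]])
        y = np.array([[0.5, -1.0], [2.0, 2.0], [1.0, 0.0]])
        expected = np.zeros((2, 2))
        for t in range(3):
            expected += np.outer(x[t] - x.mean(0), y[t] - y.mean(0))
        np.testing.assert_allclose(between_set_covariance(x, y), expected, atol=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            between_set_covariance(np.zeros((5, 2)), np.zeros((6, 2)))


class TestFitMCCA:
    def test_identical_datasets_give_unit_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((200, 4))
        model = trfnet.fit_mcca([x, x.copy(), x.copy(), x.copy()])
        assert model.canonical_correlations[0] == pytest.approx(1.0, abs=1e-6)

    def test_two_sets_match_classical_cca(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((50, 3))
        y = x @ rng.standard_normal((3, 3)) + 0.3 * rng.standard_normal((50, 3))
        model = trfnet.fit_mcca([x, y], ridge=1e-10)
        assert model.canonical_correlations[0] == pytest.approx(
            _two_set_cca_oracle(x, y), abs=1e-6
        )

    def test_independent_noise_has_low_leading_correlation(self):
        rng = np.random.default_rng(3)
        sets = [rng.standard_normal((10_000, 4)) for _ in range(3)]
        model = trfnet.fit_mcca(sets)
        assert model.canonical_correlations[0] < 0.2

    def test_correlations_non_increasing_and_in_unit_interval(self):
        rng = np.random.default_rng(4)
        shared = rng.standard_normal((300, 2))
        sets = [
            shared @ rng.standard_normal((2, 5)) + rng.standard_normal((300, 5))
            for _ in range(4)
        ]
        rho = trfnet.fit_mcca(sets).canonical_correlations
        assert np.all(np.diff(rho) <= 1e-12)
        assert np.all(rho >= -1e-9) and np.all(rho <= 1 + 1e-9)

    def test_generalized_eigen_residual(self):
        rng = np.random.default_rng(5)
        sets = [rng.standard_normal((100, 3)) for _ in range(3)]
        ridge = 1e-6
        model = trfnet.fit_mcca(sets, ridge=ridge)
        dims = [3, 3, 3]
        offs = np.concatenate([[0], np.cumsum(dims)])
        full = np.zeros((9, 9))
        for i in range(3):
            for j in range(3):
                full[offs[i]:offs[i + 1], offs[j]:offs[j + 1]] = between_set_covariance(
                    sets[i], sets[j]
                )
        r_mat = np.zeros_like(full)
        for i in range(3):
            sl = slice(offs[i], offs[i + 1])
            r_mat[sl, sl] = full[sl, sl]
        b_mat = full - r_mat
        r_reg = r_mat + ridge * np.mean(np.diag(r_mat)) * np.eye(9)
        for k in range(model.n_components):
            w = np.concatenate([p[:, k] for p in model.projections])
            lam = model.eigenvalues[k]
            resid = np.linalg.norm(b_mat @ w - lam * (r_reg @ w))
            assert resid / np.linalg.norm(b_mat @ w) < 1e-8

    def test_too_few_or_misaligned_datasets_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            trfnet.fit_mcca([rng.standard_normal((10, 2))])
        with pytest.raises(ValueError):
            trfnet.fit_mcca([rng.standard_normal((10, 2)), rng.standard_normal((11, 2))])


class TestDenoiseAndAverage:
    def _single_subject_model(self, w, n_ch):
        return MCCAModel(
            projections=[w],
            eigenvalues=np.ones(w.shape[1]),
            canonical_correlations=np.ones(w.shape[1]),
            n_subjects=1,
            normalizer=1,
            channel_means=[np.zeros(n_ch)],
            ridge=0.0,
        )

    def test_full_rank_single_subject_reconstruction_is_identity(self):
        rng = np.random.default_rng(7)
        n_ch, n_t = 5, 40
        w = rng.standard_normal((n_ch, n_ch))  # invertible w.p. 1
        model = self._single_subject_model(w, n_ch)
        data = rng.standard_normal((1, 1, n_ch, n_t))
        eeg = trfnet.MultiSubjectEEG(data=data, fs=100.0, condition_labels=["natural"], subject_ids=["S0"])
        rec = trfnet.denoise_and_average(model, eeg, 0, n_components=n_ch, space="electrode-subject")
        np.testing.assert_allclose(rec, data[0, 0], atol=1e-8)

    def test_average_tracks_shared_signal_better_than_single_subjects(self):
        gt = trfnet.make_ground_truth(
            n_roi=6, n_channels=12, n_sources=24, misalignment=0.3, seed=8, n_subjects=5
        )
        envs = [trfnet.make_envelope(3.0, 250.0, seed=40 + i) for i in range(4)]
        study = trfnet.simulate_study(gt, envs, n_subjects=5, n_trials_per_condition=2, snr_db=-5, seed=9)
        clean = trfnet.simulate_study(gt, envs, n_subjects=5, n_trials_per_condition=2, snr_db=np.inf, seed=9)
        datasets = [study.data[i].transpose(0, 2, 1).reshape(-1, 12) for i in range(5)]
        model = trfnet.fit_mcca(datasets)
        avg = trfnet.denoise_and_average(model, study, 0)

        def quality(x):
            # correlation with the strongest shared-signal channel course
            ref = clean.data[0, 0]
            cors = [abs(np.corrcoef(x[c], ref[c])[0, 1]) for c in range(x.shape[0])]
            return np.nanmean(cors)

        # compare in a common frame: subject's raw data vs consensus average
        avg_q = np.nanmean(
            [max(abs(np.corrcoef(avg[c], clean.data[0, 0][k])[0, 1]) for k in range(12)) for c in range(avg.shape[0])]
        )
        single_q = np.nanmean(
            [quality(np.asarray(study.data[i, 0], dtype=float)) for i in range(5)]
        )
        assert avg_q > single_q

    def test_noise_only_average_suppressed_by_subject_count(self):
        rng = np.random.default_rng(10)
        n_sub, n_ch, n_t = 6, 8, 3000
        data = rng.standard_normal((n_sub, 1, n_ch, n_t))
        eeg = trfnet.MultiSubjectEEG(
            data=data, fs=100.0, condition_labels=["natural"], subject_ids=[f"S{i}" for i in range(n_sub)]
        )
        model = trfnet.fit_mcca([data[i, 0].T for i in range(n_sub)])
        out = trfnet.denoise_and_average(model, eeg, 0, n_components=n_ch, space="electrode-subject")
        single_rms = np.mean([data[i, 0].std() for i in range(n_sub)])
        assert out.std() <= single_rms / np.sqrt(n_sub) * 1.5

    def test_trial_out_of_range(self, small_study):
        _, _, study = small_study
        datasets = [study.data[i].transpose(0, 2, 1).reshape(-1, 16) for i in range(4)]
        model = trfnet.fit_mcca(datasets)
        with pytest.raises(ValueError):
            trfnet.denoise_and_average(model, study, 99)


class TestNaiveAverage:
    def test_identical_subjects_preserved(self):
        x = np.random.default_rng(0).standard_normal((1, 1, 4, 20))
        data = np.repeat(x, 3, axis=0)
        eeg = trfnet.MultiSubjectEEG(data=data, fs=100.0, condition_labels=["natural"], subject_ids=list("abc"))
        np.testing.assert_allclose(trfnet.naive_average(eeg, 0), x[0, 0])

    def test_opposite_signals_cancel(self):
        x = np.random.default_rng(1).standard_normal((4, 20))
        data = np.stack([x[None], -x[None]])
        eeg = trfnet.MultiSubjectEEG(data=data, fs=100.0, condition_labels=["natural"], subject_ids=["a", "b"])
        np.testing.assert_allclose(trfnet.naive_average(eeg, 0), np.zeros((4, 20)), atol=1e-15)

    def test_matches_elementwise_mean_oracle(self, small_study):
        _, _, study = small_study
        out = trfnet.naive_average(study, 2)
        expected = np.zeros_like(out)
        for i in range(study.n_subjects):
            expected += study.data[i, 2]
        np.testing.assert_allclose(out, expected / study.n_subjects, atol=1e-12)
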