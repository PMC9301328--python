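"""Shared fixtures.

The two expensive session fixtures run the default synthetic study once:
``pipeline_report`` executes all three denoising pathways end-to-end
(decoding + network separability), and ``recovery_result`` re-simulates the
study at +10 dB sensor SNR to measure planted-kernel recovery through
hyperalignment, source reconstruction and TRF estimation.
"""

from __future__ import annotations

import numpy as np
import pytest

import trfnet
from trfnet._utils import child_seed

STUDY_SEED = 777
RECOVERY_SEED = 901


@pytest.fixture(scope="session")
def pipeline_report():
    """Default-conditions study (21 subjects, 48 trials), all pathways."""
    cfg = trfnet.RunConfig(seed=STUDY_SEED, kmeans_reps=100)
    return trfnet.run_pipeline(cfg, multiscale=False)


@pytest.fixture(scope="session")
def recovery_result():
    """Kernel recovery at +10 dB through the hyperaligned pathway."""
    seed = RECOVERY_SEED
    gt = trfnet.make_ground_truth(seed=child_seed(seed, "ground-truth"), n_subjects=21)
    envs = [
        trfnet.make_envelope(5.0, 250.0, seed=child_seed(seed, f"envelope-{k}"))
        for k in range(48)
    ]
    study = trfnet.simulate_study(gt, envs, snr_db=10.0, seed=child_seed(seed, "study"))
    datasets = [
        study.data[i].transpose(0, 2, 1).reshape(-1, study.n_channels)
        for i in range(study.n_subjects)
    ]
    model = trfnet.fit_mcca(datasets)
    inv = trfnet.make_inverse_operator(gt.leadfield, alpha=0.05)
    roi_cat, env_cat = [], []
    for tr in study.trials_of("natural"):
        sens = trfnet.denoise_and_average(model, study, tr)
        src = trfnet.apply_inverse(inv, sens)
        roi_cat.append(trfnet.aggregate_roi(src, gt.parcellation, study.fs).values)
        env_cat.append(envs[tr].values)
    enc = trfnet.fit_encoder(
        np.concatenate(env_cat), np.concatenate(roi_cat, axis=1),
        lags_ms=gt.lag_grid_ms, ridge=0.01, fs=study.fs,
    )
    corrs = np.array(
        [
            np.corrcoef(enc.weights[i], gt.kernels["natural"][i])[0, 1]
            for i in range(gt.n_roi)
        ]
    )
    return {"correlations": corrs, "ground_truth": gt, "encoder": enc}


@pytest.fixture()
def small_study():
    """A tiny but complete study for structural unit tests."""
    gt = trfnet.make_ground_truth(
        n_roi=12, n_channels=16, n_sources=60, n_communities=3, seed=5, n_subjects=4
    )
    envs = [trfnet.make_envelope(2.0, 250.0, seed=10 + i) for i in range(8)]
    study = trfnet.simulate_study(
        gt, envs, n_subjects=4, n_trials_per_condition=4, snr_db=5.0, seed=6
    )
    return gt, envs, study
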