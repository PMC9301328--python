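"""Temporal response functions: forward encoders, backward decoders,
leave-one-out stimulus-reconstruction evaluation, and TRF window statistics.

The brain is treated as a linear time-invariant system: the response of a
region is the speech envelope convolved with a causal lag kernel (the TRF),

    x(t, ROI_n) = sum_tau r(tau, ROI_n) s(t - tau),

with lags tau spanning 0–800 ms (the window containing the common
language-related evoked components).  The backward decoder inverts the map,
reconstructing the envelope from all regions' lagged responses,

    s(t) = sum_n sum_tau r_inv(tau, ROI_n) x(t - tau, ROI_n),

fit by ridge regression (minimum mean-squared envelope error).  Decoding
accuracy — the Pearson correlation between reconstructed and true envelopes
on held-out trials, Fisher-z transformed — is the standard figure of merit
for comparing denoising pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .exceptions import DegenerateVarianceError, FitError
from .inverse import ROISeries
from .synth import Envelope

__all__ = [
    "TRFModel",
    "Decoder",
    "PredictionResult",
    "default_lag_grid",
    "lag_matrix",
    "fit_encoder",
    "fit_decoder",
    "advance_matrix",
    "predict_envelope",
    "loo_crossval",
    "fisher_z",
    "compare_trf_windows",
]

DEFAULT_RIDGE_GRID = tuple(10.0**k for k in range(-3, 4))


def default_lag_grid(fs: float, tmin_ms: float = 0.0, tmax_ms: float = 800.0,
                     step_ms: float | None = None) -> np.ndarray:
    """Lag grid from ``tmin_ms`` to ``tmax_ms`` inclusive.

    The default step is the sampling step 1000/fs; a coarser step must be an
    integer multiple of it.
    """
    base = 1000.0 / fs
    if step_ms is None:
        step_ms = base
    ratio = step_ms / base
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError("step_ms must be a positive integer multiple of the sampling step")
    n = int(round((tmax_ms - tmin_ms) / step_ms))
    return tmin_ms + step_ms * np.arange(n + 1)


@dataclass
class TRFModel:
    """Per-ROI forward kernels r(tau, ROI): weights is (n_roi, n_lags)."""

    weights: np.ndarray
    lags_ms: np.ndarray
    ridge: float
    intercepts: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        if self.weights.shape[1] != self.lags_ms.size:
            raise ValueError("one weight column per lag required")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def n_roi(self) -> int:
        return self.weights.shape[0]


@dataclass
class Decoder:
    """Backward kernel r_inv(tau, ROI): weights is (n_roi, n_lags)."""

    weights: np.ndarray
    lags_ms: np.ndarray
    ridge: float
    intercept: float
    fs: float

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


@dataclass
class PredictionResult:
    """Held-out reconstruction accuracy for one trial."""

    trial: int
    r: float
    z: float
    ridge: float
    method_tag: str = ""


def lag_matrix(series: np.ndarray, lags_ms: np.ndarray, fs: float) -> np.ndarray:
    """Causal lagged design matrix.

    ``series`` is (time,) or (time, features); the output is
    (time, features * n_lags) with feature-major column order (all lags of
    feature 0 first, lags ascending), zero-padded before the series start.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n_t, n_f = x.shape
    lags_ms = np.asarray(lags_ms, dtype=float)
    if np.any(lags_ms < 0):
        raise ValueError("lags must be nonnegative (causal model)")
    lag_samp_f = lags_ms * fs / 1000.0
    lag_samp = np.round(lag_samp_f).astype(int)
    if np.max(np.abs(lag_samp_f - lag_samp)) > 1e-6:
        raise ValueError("lags must be multiples of the sampling step 1000/fs")
    if np.any(lag_samp >= n_t):
        raise ValueError("a lag exceeds the series length")
    n_l = lag_samp.size
    out = np.zeros((n_t, n_f * n_l))
    for f in range(n_f):
        for k, lag in enumerate(lag_samp):
            col = f * n_l + k
            if lag == 0:
                out[:, col] = x[:, f]
            else:
                out[lag:, col] = x[:-lag, f]
    return out


def advance_matrix(series: np.ndarray, lags_ms: np.ndarray, fs: float) -> np.ndarray:
    """Anti-causal design matrix for backward models.

    Column (f, k) holds ``series[t + lag_k, f]``: the neural response
    ``lag_k`` ms *after* the stimulus sample being reconstructed, since the
    response follows the stimulus.  Zero-padded past the series end; same
    feature-major column order as :func:`lag_matrix`.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return lag_matrix(x[::-1], lags_ms, fs)[::-1]


def _as_values(obj, kind: str) -> np.ndarray:
    if isinstance(obj, Envelope):
        return obj.values
    if isinstance(obj, ROISeries):
        return obj.values
    arr = np.asarray(obj, dtype=float)
    return arr


def _ridge_solve(x: np.ndarray, y: np.ndarray, ridge: float) -> tuple:
    """Centered ridge solution; returns (weights, intercept(s)).

    ``ridge`` is trace-normalized: the penalty added to the Gram diagonal is
    ridge * mean(diag(X'X)) of the centered design.  ridge = 0 falls back to
    a least-squares solve.
    """
    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    xc = x - x_mean
    yc = y - y_mean
    gram = xc.T @ xc
    xty = xc.T @ yc
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    if ridge == 0:
        w, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    else:
        lam = ridge * np.mean(np.diag(gram))
        try:
            w = linalg.solve(gram + lam * np.eye(gram.shape[0]), xty, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise FitError("ridge system is numerically singular") from exc
    intercept = y_mean - x_mean @ w
    return w, intercept


def fit_encoder(
    envelope,
    roi_series,
    lags_ms: np.ndarray | None = None,
    ridge: float = 0.01,
    fs: float | None = None,
) -> TRFModel:
    """Fit one forward TRF per ROI by ridge regression on the lagged envelope.

    All ROIs share the same design matrix, so the normal equations are
    factorized once.  ``ridge = 0`` reduces to ordinary least squares.
    """
    env = _as_values(envelope, "envelope").ravel()
    if fs is None:
        fs = envelope.fs if isinstance(envelope, Envelope) else None
    if fs is None:
        raise ValueError("fs must be given when envelope is a bare array")
    y = _as_values(roi_series, "roi").T  # (time, n_roi)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != env.size:
        raise ValueError("envelope and ROI series must share the same length")
    if np.std(env) == 0:
        raise FitError("zero-variance envelope: TRF is unidentifiable")
    if lags_ms is None:
        lags_ms = default_lag_grid(fs)
    x = lag_matrix(env, lags_ms, fs)
    w, intercepts = _ridge_solve(x, y, ridge)
    return TRFModel(
        weights=w.T, lags_ms=np.asarray(lags_ms, float), ridge=ridge,
        intercepts=np.atleast_1d(intercepts), fs=fs,
    )


def fit_decoder(
    roi_series,
    envelope,
    lags_ms: np.ndarray | None = None,
    ridge: float = 0.01,
    fs: float | None = None,
) -> Decoder:
    """Fit the backward stimulus-reconstruction model.

    A single multivariate ridge regression of the envelope on every ROI's
    lagged time course (the double sum over regions and lags).
    """
    env = _as_values(envelope, "envelope").ravel()
    if fs is None:
        fs = envelope.fs if isinstance(envelope, Envelope) else None
    if fs is None and isinstance(roi_series, ROISeries):
        fs = roi_series.fs
    if fs is None:
        raise ValueError("fs must be given for bare-array inputs")
    r = _as_values(roi_series, "roi")
    if r.ndim == 1:
        r = r[None, :]
    if r.shape[1] != env.size:
        raise ValueError("envelope and ROI series must share the same length")
    if np.std(env) == 0:
        raise FitError("zero-variance envelope: decoder is unidentifiable")
    if lags_ms is None:
        lags_ms = default_lag_grid(fs)
    lags_ms = np.asarray(lags_ms, dtype=float)
    x = advance_matrix(r.T, lags_ms, fs)
    w, intercept = _ridge_solve(x, env, ridge)
    return Decoder(
        weights=w.reshape(r.shape[0], lags_ms.size), lags_ms=lags_ms,
        ridge=ridge, intercept=float(intercept), fs=fs,
    )


def predict_envelope(decoder: Decoder, roi_series) -> np.ndarray:
    """Reconstruct the envelope from ROI time courses with a fitted decoder."""
    r = _as_values(roi_series, "roi")
    if r.ndim == 1:
        r = r[None, :]
    x = advance_matrix(r.T, decoder.lags_ms, decoder.fs)
    return x @ decoder.weights.ravel() + decoder.intercept


def fisher_z(r):
    """Fisher's variance-stabilizing transform z = atanh(r); |r| must be < 1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr[np.isfinite(arr)]) >= 1):
        raise ValueError("|r| must be < 1 for Fisher's z")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def _trial_arrays(trials, fs):
    """Normalize (envelope, roi_series) pairs to centered float arrays."""
    envs, rois = [], []
    for env, roi in trials:
        e = _as_values(env, "envelope").ravel()
        r = _as_values(roi, "roi")
        if fs is None and isinstance(env, Envelope):
            fs = env.fs
        if r.shape[1] != e.size:
            raise ValueError("trial envelope and ROI series lengths differ")
        envs.append(e)
        rois.append(r)
    if fs is None:
        raise ValueError("fs could not be inferred; pass it explicitly")
    return envs, rois, fs


def loo_crossval(
    trials: list,
    lags_ms: np.ndarray | None = None,
    ridge_grid: tuple = DEFAULT_RIDGE_GRID,
    fs: float | None = None,
    n_inner: int = 2,
    method_tag: str = "",
) -> list:
    """Leave-one-out envelope-reconstruction evaluation.

    For each fold one trial is held out; a decoder is fit on the remaining
    trials (concatenated), with the ridge parameter chosen among
    ``ridge_grid`` by mean reconstruction correlation over ``n_inner``
    round-robin inner splits of the training trials.  Per-trial designs are
    centered trial-wise (Pearson accuracy is shift-invariant), which lets
    training Gram matrices be pooled and downdated instead of recomputed.

    Returns one :class:`PredictionResult` per trial; a constant held-out
    envelope yields ``r = nan`` with a warning.
    """
    if len(trials) < 2:
        raise ValueError("leave-one-out needs at least 2 trials")
    envs, rois, fs = _trial_arrays(trials, fs)
    if lags_ms is None:
        lags_ms = default_lag_grid(fs)
    lags_ms = np.asarray(lags_ms, dtype=float)
    n_trials = len(trials)

    designs, grams, xtys, ys = [], [], [], []
    for e, r in zip(envs, rois):
        x = advance_matrix(r.T, lags_ms, fs)
        x -= x.mean(axis=0)
        y = e - e.mean()
        designs.append(x)
        grams.append(x.T @ x)
        xtys.append(x.T @ y)
        ys.append(y)

    n_feat = designs[0].shape[1]
    s_all = np.zeros((n_feat, n_feat))
    b_all = np.zeros(n_feat)
    for g, b in zip(grams, xtys):
        s_all += g
        b_all += b
    groups = [list(range(g0, n_trials, n_inner)) for g0 in range(n_inner)]
    s_group = [sum(grams[t] for t in grp) for grp in groups]
    b_group = [sum(xtys[t] for t in grp) for grp in groups]

    def _solve_all(s_mat, b_vec, ridges):
        evals, evecs = np.linalg.eigh(s_mat)
        evals = np.clip(evals, 0.0, None)
        vb = evecs.T @ b_vec
        mean_diag = np.mean(np.diag(s_mat))
        return {lam: evecs @ (vb / (evals + lam * mean_diag)) for lam in ridges}

    results = []
    for t in range(n_trials):
        s_train = s_all - grams[t]
        b_train = b_all - xtys[t]

        # Inner ridge selection on round-robin splits of the training set.
        scores = {lam: [] for lam in ridge_grid}
        for grp, s_g, b_g in zip(groups, s_group, b_group):
            val = [v for v in grp if v != t]
            if not val:
                continue
            s_in = s_train - s_g + (grams[t] if t in grp else 0)
            b_in = b_train - b_g + (xtys[t] if t in grp else 0)
            w_by_ridge = _solve_all(s_in, b_in, ridge_grid)
            for lam, w in w_by_ridge.items():
                rs = []
                for v in val:
                    pred = designs[v] @ w
                    denom = np.linalg.norm(pred) * np.linalg.norm(ys[v])
                    rs.append((pred @ ys[v]) / denom if denom > 0 else 0.0)
                scores[lam].append(np.mean(rs))
        best = max(ridge_grid, key=lambda lam: np.mean(scores[lam]) if scores[lam] else -np.inf)

        w = _solve_all(s_train, b_train, (best,))[best]
        pred = designs[t] @ w
        y = ys[t]
        if np.std(y) == 0:
            warnings.warn(f"constant envelope in held-out trial {t}: r undefined")
            r_val = np.nan
            z_val = np.nan
        else:
            denom = np.linalg.norm(pred) * np.linalg.norm(y)
            r_val = float(np.clip((pred @ y) / denom, -1.0, 1.0)) if denom > 0 else np.nan
            z_val = float(np.arctanh(np.clip(r_val, -1 + 1e-12, 1 - 1e-12))) if np.isfinite(r_val) else np.nan
        results.append(PredictionResult(trial=t, r=r_val, z=z_val, ridge=best, method_tag=method_tag))
    return results


def trf_window_amplitude(weights: np.ndarray, lags_ms: np.ndarray, window_ms: tuple) -> np.ndarray:
    """Mean signed kernel amplitude within a lag window, per row."""
    lo, hi = window_ms
    lags_ms = np.asarray(lags_ms, dtype=float)
    if lo < lags_ms.min() - 1e-9 or hi > lags_ms.max() + 1e-9 or lo >= hi:
        raise ValueError("window must lie within the lag grid")
    mask = (lags_ms >= lo) & (lags_ms <= hi)
    return np.atleast_2d(weights)[:, mask].mean(axis=1)


def compare_trf_windows(
    trf_set_a: np.ndarray,
    trf_set_b: np.ndarray,
    window_ms: tuple,
    lags_ms: np.ndarray,
) -> dict:
    """Paired t-test and Cohen's d on mean TRF amplitude within a lag window.

    ``trf_set_a`` and ``trf_set_b`` are paired (n_obs, n_lags) kernel sets,
    e.g. one region's per-trial TRFs under two conditions.  Identical sets
    return t = 0, d = 0; nonzero constant differences (zero within-pair
    variance) are rejected as degenerate.
    """
    a = np.atleast_2d(np.asarray(trf_set_a, dtype=float))
    b = np.atleast_2d(np.asarray(trf_set_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("paired TRF sets must have equal shapes")
    amp_a = trf_window_amplitude(a, lags_ms, window_ms)
    amp_b = trf_window_amplitude(b, lags_ms, window_ms)
    diff = amp_a - amp_b
    if diff.size < 2:
        raise ValueError("need at least 2 pairs")
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return {"t": 0.0, "p": 1.0, "cohen_d": 0.0}
        raise DegenerateVarianceError(
            "constant nonzero within-pair difference: paired t is unbounded"
        )
    t_stat, p_val = stats.ttest_rel(amp_a, amp_b)
    d = diff.mean() / sd
    return {"t": float(t_stat), "p": float(p_val), "cohen_d": float(d)}
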