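"""Synthetic multi-subject speech-EEG study generator.

Emulates the statistical structure a cross-subject entrainment analysis
assumes: every subject receives the same stimulus-driven cortical response
(linear kernels per region of interest convolved with the speech envelope,
projected through a shared lead field), on top of which each subject
contributes an individual electrode-space misalignment (a small orthogonal
channel mixing, the analog of cap-placement differences) and individual
1/f-shaped sensor noise.  Two stimulus conditions — "natural" and "reversed"
speech — are planted with different region-level community structure in
their kernels, so downstream network analyses have a known ground truth.

All generation is seeded and bitwise reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from ._utils import child_rng, child_seed

__all__ = [
    "Envelope",
    "GroundTruth",
    "MultiSubjectEEG",
    "CONDITIONS",
    "make_envelope",
    "extract_envelope",
    "make_ground_truth",
    "simulate_study",
    "make_windowed_trf_trials",
]

#: The two planted stimulus conditions (natural speech and its time reversal).
CONDITIONS = ("natural", "reversed")


@dataclass
class Envelope:
    """A nonnegative slow amplitude-modulation series s(t).

    Parameters
    ----------
    values : ndarray, shape (n_samples,)
        Nonnegative amplitude samples (arbitrary units).
    fs : float
        Sampling rate in Hz.
    """

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope values must be finite")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.values.size / self.fs

    def __len__(self) -> int:
        return self.values.size


@dataclass
class GroundTruth:
    """Planted generative state of a synthetic study.

    Holds everything parameter-recovery tests need: the community labels and
    region kernels per condition, the lead field, the source-to-ROI
    parcellation, and the per-subject channel-mixing (misalignment)
    transforms.
    """

    n_roi: int
    community_labels: dict  # condition -> (n_roi,) int array, 1-based
    kernels: dict  # condition -> (n_roi, n_lags) array
    lag_grid_ms: np.ndarray
    leadfield: np.ndarray  # (n_channels, n_sources)
    parcellation: np.ndarray  # (n_sources,) int array of ROI indices, 0-based
    subject_transforms: np.ndarray  # (n_subjects, n_channels, n_channels)
    misalignment: float
    seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parcellation = np.asarray(self.parcellation, dtype=int)
        counts = np.bincount(self.parcellation, minlength=self.n_roi)
        if self.parcellation.min() < 0 or self.parcellation.max() >= self.n_roi:
            raise ValueError("parcellation labels must lie in [0, n_roi)")
        if np.any(counts == 0):
            raise ValueError("every ROI must contain at least one source")

    @property
    def n_channels(self) -> int:
        return self.leadfield.shape[0]

    @property
    def n_sources(self) -> int:
        return self.leadfield.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.subject_transforms.shape[0]


@dataclass
class MultiSubjectEEG:
    """Electrode-space recordings for all subjects and trials.

    data has shape (n_subjects, n_trials, n_channels, n_samples); all
    subjects share the montage, trial count and sampling rate.
    """

    data: np.ndarray
    fs: float
    condition_labels: list
    subject_ids: list

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be (subjects, trials, channels, time)")
        if len(self.condition_labels) != self.data.shape[1]:
            raise ValueError("one condition label per trial required")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("one subject id per subject required")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def n_samples(self) -> int:
        return self.data.shape[3]

    def trials_of(self, condition: str) -> np.ndarray:
        """Indices of the trials belonging to one condition."""
        return np.flatnonzero(np.asarray(self.condition_labels) == condition)


def make_envelope(
    duration_s: float,
    fs: float,
    modulation_band_hz: tuple = (2.0, 8.0),
    seed: int | None = None,
    depth: float = 0.5,
) -> Envelope:
    """Generate a band-limited nonnegative modulation signal.

    The signal is unit-mean with modulation restricted to
    ``modulation_band_hz`` (default 2–8 Hz, the syllabic-rate band speech
    envelopes concentrate in): band-passed Gaussian noise of modulation depth
    ``depth`` around a DC pedestal, clipped at zero.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    lo, hi = modulation_band_hz
    if not 0 < lo < hi:
        raise ValueError("modulation band must satisfy 0 < lo < hi")
    if fs <= 2 * hi:
        raise ValueError("fs must exceed twice the upper modulation frequency")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    sd = x.std()
    if sd > 0:
        x = x / sd
    values = np.clip(1.0 + depth * x, 0.0, None)
    return Envelope(values=values, fs=float(fs))


def _erb_bandwidth(cf_hz: np.ndarray) -> np.ndarray:
    # Glasberg & Moore equivalent rectangular bandwidth.
    return 24.7 * (4.37 * cf_hz / 1000.0 + 1.0)


def _erb_space(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    # Center frequencies uniformly spaced on the ERB-number scale.
    def erb_number(f):
        return 21.4 * np.log10(4.37 * f / 1000.0 + 1.0)

    def inv_erb_number(e):
        return (10 ** (e / 21.4) - 1.0) * 1000.0 / 4.37

    return inv_erb_number(np.linspace(erb_number(f_lo), erb_number(f_hi), n))


def extract_envelope(
    audio: np.ndarray,
    audio_fs: float,
    n_bands: int = 24,
    power_exponent: float = 0.6,
    target_fs: float = 250.0,
    band_range_hz: tuple = (50.0, 8000.0),
) -> Envelope:
    """Broadband speech-envelope extraction.

    An ERB-spaced bandpass filterbank (default 50 Hz – 8 kHz) decomposes the
    audio; each band's magnitude (analytic-signal modulus) is compressed with
    a power law (default exponent 0.6, approximating perceived loudness),
    bands are averaged, low-passed and decimated to ``target_fs``.
    """
    audio = np.asarray(audio, dtype=float).ravel()
    f_lo, f_hi = band_range_hz
    if audio_fs < 2 * f_hi:
        raise ValueError("audio_fs must be at least twice the top filterbank frequency")
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if np.allclose(audio, 0.0):
        warnings.warn("silent (all-zero) audio: returning an all-zero envelope")
        n_out = int(round(audio.size * target_fs / audio_fs))
        return Envelope(values=np.zeros(n_out), fs=float(target_fs))

    if n_bands == 1:
        cfs = np.array([np.sqrt(f_lo * f_hi)])
    else:
        cfs = _erb_space(f_lo, f_hi, n_bands)
    bws = _erb_bandwidth(cfs)
    env = np.zeros_like(audio)
    nyq = audio_fs / 2.0
    for cf, bw in zip(cfs, bws):
        lo = max(cf - bw, 1.0)
        hi = min(cf + bw, 0.99 * nyq)
        sos = signal.butter(2, [lo, hi], btype="bandpass", fs=audio_fs, output="sos")
        band = signal.sosfiltfilt(sos, audio)
        mag = np.abs(signal.hilbert(band))
        env += mag**power_exponent
    env /= n_bands

    # Anti-alias lowpass, then polyphase decimation to the target rate.
    cutoff = 0.4 * target_fs
    sos_lp = signal.butter(4, cutoff, btype="lowpass", fs=audio_fs, output="sos")
    env = signal.sosfiltfilt(sos_lp, env)
    ratio = Fraction(target_fs / audio_fs).limit_denominator(10000)
    env = signal.resample_poly(env, ratio.numerator, ratio.denominator)
    return Envelope(values=np.clip(env, 0.0, None), fs=float(target_fs))


def _damped_oscillation(
    lags_s: np.ndarray, latency_s: float, freq_hz: float, width_s: float, polarity: float
) -> np.ndarray:
    """Gaussian-damped oscillation (Gabor-shaped evoked kernel).

    The spectrum is a Gaussian of width 1/(2*pi*width_s) Hz centered at
    freq_hz, so with theta-rate frequencies and width ~0.12 s the kernel
    lives inside the 2-8 Hz modulation band of the stimulus envelope and is
    identifiable from band-limited input.
    """
    t = lags_s - latency_s
    k = np.cos(2 * np.pi * freq_hz * t) * np.exp(-0.5 * (t / width_s) ** 2)
    peak = np.max(np.abs(k))
    return polarity * k / peak if peak > 0 else k


def _random_rotation(n: int, angle: float, rng: np.random.Generator) -> np.ndarray:
    """Rotation by exactly ``angle`` in floor(n/2) random orthogonal planes.

    Q = V B V' with random orthogonal V and B block-diagonal 2x2 rotations,
    so the expected overlap with identity is cos(angle) in every direction
    and ||Q - I||_2 = 2 sin(angle/2) <= angle.
    """
    if angle == 0.0:
        return np.eye(n)
    v, _ = np.linalg.qr(rng.standard_normal((n, n)))
    b = np.eye(n)
    c, s = np.cos(angle), np.sin(angle)
    for k in range(n // 2):
        i, j = 2 * k, 2 * k + 1
        b[i, i] = c
        b[j, j] = c
        b[i, j] = -s
        b[j, i] = s
    return v @ b @ v.T


def make_ground_truth(
    n_roi: int = 68,
    n_channels: int = 128,
    n_sources: int = 500,
    n_communities: int = 4,
    lag_grid_ms: np.ndarray | None = None,
    misalignment: float = 0.5,
    seed: int | None = None,
    n_subjects: int = 21,
    cond_number_bound: float = 20.0,
    kernel_jitter: float = 0.1,
) -> GroundTruth:
    """Plant the generative state of a synthetic study.

    Regions are partitioned into communities; regions in the same community
    share a damped-oscillation response kernel (community-specific latency,
    frequency and polarity) plus a small smooth per-region perturbation, so
    within-community kernel correlations exceed between-community ones by
    construction.  The "reversed" condition redraws both the community
    assignment and the templates.  The lead field is a smooth random mixing
    over a 2-D source sheet with its condition number clipped to
    ``cond_number_bound``; per-subject misalignment transforms are random
    rotations ``expm(misalignment * K)`` with unit-spectral-norm
    antisymmetric ``K``, so their deviation from identity is bounded by the
    misalignment level and signal power is preserved.
    """
    if n_sources < n_roi:
        raise ValueError("n_sources must be >= n_roi")
    if n_communities < 2:
        raise ValueError("n_communities must be >= 2")
    if n_roi < n_communities:
        raise ValueError("n_roi must be >= n_communities")
    if lag_grid_ms is None:
        lag_grid_ms = np.arange(0.0, 804.0, 4.0)
    lag_grid_ms = np.asarray(lag_grid_ms, dtype=float)
    lags_s = lag_grid_ms / 1000.0

    seeds = {
        "kernels": child_seed(seed, "gt-kernels"),
        "leadfield": child_seed(seed, "gt-leadfield"),
        "transforms": child_seed(seed, "gt-transforms"),
        "labels": child_seed(seed, "gt-labels"),
    }
    rng_k = np.random.default_rng(seeds["kernels"])
    rng_lab = np.random.default_rng(seeds["labels"])

    community_labels: dict = {}
    kernels: dict = {}
    for icond, cond in enumerate(CONDITIONS):
        # Spatially coherent balanced partition: contiguous blocks of ROIs
        # form communities (functional communities of real cortex are
        # spatially clustered, and coherence keeps the inverse solution's
        # short-range point-spread mostly within-community).  The second
        # condition shifts the block boundaries by half a block and permutes
        # the community identities, so the two planted partitions differ.
        shift = 0 if icond == 0 else n_roi // (2 * n_communities)
        block = ((np.arange(n_roi) + shift) * n_communities) // n_roi % n_communities
        perm = rng_lab.permutation(n_communities)
        labels = perm[block] + 1
        community_labels[cond] = labels

        # Community templates: distinct latencies, theta-rate frequencies,
        # alternating polarity.  Latencies sit mid-grid and widths keep the
        # Gaussian support inside the 0-800 ms lag window.
        latencies = np.linspace(0.30, 0.50, n_communities)
        latencies = latencies[rng_k.permutation(n_communities)]
        freqs = rng_k.uniform(4.6, 5.4, n_communities)
        polarities = np.where(np.arange(n_communities) % 2 == 0, 1.0, -1.0)
        width_s = 0.12
        k = np.empty((n_roi, lags_s.size))
        for roi in range(n_roi):
            c = labels[roi] - 1
            # ROI jitter: mostly amplitude scatter with tiny latency and
            # frequency scatter.  Kernels stay in-band and highly correlated
            # within a community, and the stimulus-driven signal keeps a low
            # effective rank (about one dimension per community and
            # condition), matching the premise that the shared response
            # occupies a compact subspace of sensor space.
            lat = latencies[c] + kernel_jitter * rng_k.uniform(-0.02, 0.02)
            frq = freqs[c] + kernel_jitter * rng_k.uniform(-2.0, 2.0)
            amp = 1.0 + kernel_jitter * rng_k.uniform(-1.5, 1.5)
            k[roi] = amp * _damped_oscillation(lags_s, lat, frq, width_s, polarities[c])
        kernels[cond] = k

    # Lead field over a 2-D source sheet: each channel has a Gaussian
    # receptive field centered on a grid over the sheet (localized but
    # overlapping sensitivity, the desk-scale analog of sensors over a
    # cortical surface) plus a smooth random gain component; the condition
    # number is clipped so the mixing stays invertible in practice.
    rng_l = np.random.default_rng(seeds["leadfield"])
    nx = int(np.ceil(np.sqrt(n_sources)))
    ny = int(np.ceil(n_sources / nx))
    sx, sy = np.meshgrid(np.linspace(0, 1, nx), np.linspace(0, 1, ny), indexing="ij")
    src_pos = np.column_stack([sx.ravel(), sy.ravel()])[:n_sources]
    gx = int(np.ceil(np.sqrt(n_channels)))
    gy = int(np.ceil(n_channels / gx))
    cx, cy = np.meshgrid(np.linspace(0.05, 0.95, gx), np.linspace(0.05, 0.95, gy), indexing="ij")
    ch_pos = np.column_stack([cx.ravel(), cy.ravel()])[:n_channels]
    ch_pos += 0.02 * rng_l.standard_normal(ch_pos.shape)
    rf_width = 0.6 / np.sqrt(n_channels)
    d2 = ((ch_pos[:, None, :] - src_pos[None, :, :]) ** 2).sum(-1)
    L = np.exp(-0.5 * d2 / rf_width**2)
    from scipy.ndimage import gaussian_filter

    g = gaussian_filter(rng_l.standard_normal((n_channels, nx, ny)), sigma=(0.0, 2.0, 2.0), mode="nearest")
    L += 0.2 * g.reshape(n_channels, nx * ny)[:, :n_sources]
    u, s, vt = np.linalg.svd(L, full_matrices=False)
    s = np.maximum(s, s.max() / cond_number_bound)
    L = (u * s) @ vt
    L /= np.linalg.norm(L) / np.sqrt(n_channels)  # unit RMS row scale

    # Even contiguous partition of the source sheet into ROIs.
    parcellation = (np.arange(n_sources) * n_roi) // n_sources

    rng_t = np.random.default_rng(seeds["transforms"])
    transforms = np.stack(
        [_random_rotation(n_channels, misalignment, rng_t) for _ in range(n_subjects)]
    )

    return GroundTruth(
        n_roi=n_roi,
        community_labels=community_labels,
        kernels=kernels,
        lag_grid_ms=lag_grid_ms,
        leadfield=L,
        parcellation=parcellation,
        subject_transforms=transforms,
        misalignment=misalignment,
        seeds=seeds,
    )


def make_windowed_trf_trials(
    n_trials_per_condition: int = 24,
    n_roi: int = 68,
    fs: float = 250.0,
    difference_window_ms: tuple = (300.0, 450.0),
    noise_level: float = 0.3,
    seed: int | None = None,
) -> tuple:
    """Per-trial TRF sets whose condition difference is confined to one lag
    window.

    Every region carries an early base kernel (identical in both
    conditions); in the second condition half the regions additionally carry
    a narrow deflection centered inside ``difference_window_ms``.  Per-trial
    estimation noise (smooth, amplitude ``noise_level`` relative to the base
    kernel) is added independently.  Returns ``(trf_sets, condition_labels,
    lags_ms)`` with ``trf_sets`` of shape (2*n_trials_per_condition, n_roi,
    n_lags) — the testbed for window-wise condition clustering.
    """
    rng = np.random.default_rng(seed)
    lags_ms = np.arange(0.0, 804.0, 1000.0 / fs)
    lags_s = lags_ms / 1000.0
    lo, hi = difference_window_ms
    center_s = (lo + hi) / 2000.0
    base = np.stack(
        [
            _damped_oscillation(lags_s, 0.12, rng.uniform(4.5, 5.5), 0.05, 1.0)
            * rng.uniform(0.8, 1.2)
            for _ in range(n_roi)
        ]
    )
    bump = np.stack(
        [
            _damped_oscillation(lags_s, center_s, rng.uniform(4.5, 5.5), 0.03, 1.0)
            * rng.uniform(0.8, 1.2)
            for _ in range(n_roi)
        ]
    )
    affected = rng.permutation(n_roi)[: n_roi // 2]
    n_trials = 2 * n_trials_per_condition
    out = np.empty((n_trials, n_roi, lags_ms.size))
    labels = [CONDITIONS[0]] * n_trials_per_condition + [CONDITIONS[1]] * n_trials_per_condition
    for t in range(n_trials):
        k = base.copy()
        if labels[t] == CONDITIONS[1]:
            k[affected] += bump[affected]
        noise = rng.standard_normal(k.shape)
        kernel_smooth = np.exp(-0.5 * (np.arange(-8, 9) / 3.0) ** 2)
        noise = np.apply_along_axis(
            lambda m: np.convolve(m, kernel_smooth / kernel_smooth.sum(), mode="same"), -1, noise
        )
        out[t] = k + noise_level * noise * np.abs(base).max()
    return out, labels, lags_ms


def _one_over_f_noise(shape: tuple, fs: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise along the last axis, unit variance per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0  # no DC drift
    pink = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _sensor_noise(
    n_channels: int, n_samples: int, fs: float, rng: np.random.Generator, pink_fraction: float = 0.5
) -> np.ndarray:
    pink = _one_over_f_noise((n_channels, n_samples), fs, rng)
    white = rng.standard_normal((n_channels, n_samples))
    return np.sqrt(pink_fraction) * pink + np.sqrt(1 - pink_fraction) * white


def roi_response(kernels: np.ndarray, envelope: Envelope, lag_grid_ms: np.ndarray) -> np.ndarray:
    """Causal convolution of each ROI kernel with the stimulus envelope.

    Returns an (n_roi, n_samples) array on the envelope's time base.  The
    kernel lag grid must match the envelope sampling step.
    """
    step_ms = 1000.0 / envelope.fs
    if not np.allclose(np.diff(lag_grid_ms), step_ms):
        raise ValueError("kernel lag grid step must equal the envelope sampling step")
    n = len(envelope)
    out = np.empty((kernels.shape[0], n))
    e = envelope.values - envelope.values.mean()  # modulation around the pedestal drives the response
    for i, k in enumerate(kernels):
        out[i] = signal.fftconvolve(e, k, mode="full")[:n]
    return out


def simulate_study(
    ground_truth: GroundTruth,
    envelopes: list,
    n_subjects: int = 21,
    n_trials_per_condition: int = 24,
    snr_db: float = -5.0,
    seed: int | None = None,
) -> MultiSubjectEEG:
    """Simulate electrode-space EEG for the whole study.

    Per trial, every subject receives the same source activity (the
    condition's kernels convolved with that trial's envelope, broadcast to
    each ROI's sources), mixed to the sensors through the shared lead field
    and the subject's misalignment transform, plus per-subject sensor noise
    (half 1/f-shaped, half white) scaled to ``snr_db``.  The first
    ``n_trials_per_condition`` trials are "natural", the rest "reversed".
    ``snr_db = inf`` is the noiseless sentinel (no sensor noise).
    """
    n_trials = 2 * n_trials_per_condition
    if len(envelopes) != n_trials:
        raise ValueError(f"expected {n_trials} envelopes, got {len(envelopes)}")
    if not np.isfinite(snr_db) and not snr_db == np.inf:
        raise ValueError("snr_db must be finite or +inf")
    if n_subjects > ground_truth.n_subjects:
        raise ValueError("ground truth holds fewer subject transforms than requested")
    lengths = {len(e) for e in envelopes}
    if len(lengths) != 1:
        raise ValueError("all envelopes must share a common length")
    n_samples = lengths.pop()
    fs = envelopes[0].fs

    condition_labels = [CONDITIONS[0]] * n_trials_per_condition + [
        CONDITIONS[1]
    ] * n_trials_per_condition

    L = ground_truth.leadfield
    parc = ground_truth.parcellation
    n_channels = L.shape[0]
    data = np.empty((n_subjects, n_trials, n_channels, n_samples))
    rng_noise = child_rng(seed, "study-noise")

    for trial in range(n_trials):
        cond = condition_labels[trial]
        resp = roi_response(ground_truth.kernels[cond], envelopes[trial], ground_truth.lag_grid_ms)
        sources = resp[parc]  # (n_sources, T): each source follows its ROI
        clean = L @ sources  # shared sensor-space signal before misalignment
        p_signal = np.mean(clean**2)
        for subj in range(n_subjects):
            x = ground_truth.subject_transforms[subj] @ clean
            if np.isfinite(snr_db):
                noise = _sensor_noise(n_channels, n_samples, fs, rng_noise)
                p_noise = np.mean(noise**2)
                target = p_signal / (10.0 ** (snr_db / 10.0))
                noise *= np.sqrt(target / p_noise)
                x = x + noise
            data[subj, trial] = x

    return MultiSubjectEEG(
        data=data,
        fs=fs,
        condition_labels=condition_labels,
        subject_ids=[f"S{i:02d}" for i in range(n_subjects)],
    )
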