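"""Distributed source reconstruction (sLORETA) and ROI aggregation.

The minimum-norm inverse kernel is T = L'(LL' + aI)^-1 for lead field L and
sensor-space Tikhonov regularizer a (expressed as a fraction of the mean
eigenvalue of LL', i.e. trace(LL')/n_channels).  sLORETA standardizes each
source estimate by the square root of the corresponding diagonal entry of
the resolution matrix TL, which gives exactly zero localization error for a
noiseless point source.  Sources have fixed (scalar) orientations, so the
standardization factors are scalars rather than 3x3 blocks.

ROI time series are plain means over each region's member sources.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["InverseOperator", "ROISeries", "make_inverse_operator", "apply_inverse", "aggregate_roi"]


@dataclass
class InverseOperator:
    """Minimum-norm kernel plus sLORETA standardization factors."""

    kernel: np.ndarray  # (n_sources, n_channels), unstandardized
    standardization: np.ndarray  # (n_sources,), sqrt of resolution diagonal
    alpha: float  # regularization as a fraction of mean sensor eigenvalue
    alpha_abs: float  # absolute regularization actually applied

    @property
    def n_sources(self) -> int:
        return self.kernel.shape[0]

    @property
    def n_channels(self) -> int:
        return self.kernel.shape[1]


@dataclass
class ROISeries:
    """Region-of-interest time courses (n_roi, n_samples) at rate fs."""

    values: np.ndarray
    roi_ids: list
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (roi, time)")
        if len(self.roi_ids) != self.values.shape[0]:
            raise ValueError("one roi_id per row required")

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


def make_inverse_operator(leadfield: np.ndarray, alpha: float = 0.05) -> InverseOperator:
    """Build the regularized minimum-norm kernel with sLORETA standardization.

    ``alpha`` scales the identity noise term relative to the mean eigenvalue
    of the sensor covariance LL'; it must be positive.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    L = np.asarray(leadfield, dtype=float)
    if L.ndim != 2:
        raise ValueError("leadfield must be 2-D (channels, sources)")
    n_channels = L.shape[0]
    gram = L @ L.T
    alpha_abs = alpha * np.trace(gram) / n_channels
    # T = L' (LL' + aI)^-1, computed via a symmetric solve.
    kernel = np.linalg.solve(gram + alpha_abs * np.eye(n_channels), L).T
    resolution_diag = np.einsum("sc,cs->s", kernel, L)
    if np.any(resolution_diag <= 0):
        raise ValueError("non-positive resolution diagonal; leadfield may be rank deficient")
    return InverseOperator(
        kernel=kernel,
        standardization=np.sqrt(resolution_diag),
        alpha=float(alpha),
        alpha_abs=float(alpha_abs),
    )


def apply_inverse(op: InverseOperator, eeg_trial: np.ndarray) -> np.ndarray:
    """Standardized source estimates (n_sources, n_samples); linear in input."""
    x = np.asarray(eeg_trial, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != op.n_channels:
        raise ValueError(
            f"channel mismatch: operator expects {op.n_channels}, got {x.shape[0]}"
        )
    return (op.kernel @ x) / op.standardization[:, None]


def aggregate_roi(
    source_activity: np.ndarray,
    parcellation: np.ndarray,
    fs: float,
    roi_ids: list | None = None,
) -> ROISeries:
    """Average member-source time courses within each ROI.

    ``parcellation`` maps each source to a 0-based ROI index; every ROI must
    have at least one member source.
    """
    src = np.asarray(source_activity, dtype=float)
    parc = np.asarray(parcellation, dtype=int)
    if src.shape[0] != parc.size:
        raise ValueError("one parcellation label per source required")
    n_roi = parc.max() + 1
    counts = np.bincount(parc, minlength=n_roi)
    if np.any(counts == 0):
        raise ValueError("parcellation contains an empty ROI")
    out = np.zeros((n_roi, src.shape[1]))
    np.add.at(out, parc, src)
    out /= counts[:, None]
    if roi_ids is None:
        roi_ids = [f"ROI{i:02d}" for i in range(n_roi)]
    return ROISeries(values=out, roi_ids=list(roi_ids), fs=float(fs))
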