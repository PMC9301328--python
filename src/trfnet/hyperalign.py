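"""Multi-set CCA hyperalignment and cross-subject additive averaging.

Subjects wear their EEG caps slightly differently, so the same cortical
response appears under a different channel mixing for every subject and a
plain cross-subject average partially cancels the shared signal.  Multi-set
canonical correlation analysis (MCCA) finds, for each subject i, a
projection w_i such that the projected signals are maximally correlated
across subjects.  The summed between-set over within-set covariance ratio

    rho = 1/(N-1) * sum_{i != j} w_i' V_ij w_j  /  sum_i w_i' V_ii w_i

is maximised by the generalized eigenproblem ``B w = lambda R w`` where B
collects the between-set covariance blocks (zero diagonal) and R is the
block diagonal of within-set covariances.  With the normalizer N equal to
the number of datasets I, identical datasets give rho = 1 for the leading
component, so rho lives on a 0–1 scale.

Denoising truncates each subject to the leading canonical components,
back-projects into that subject's channel space, and averages the
reconstructions across subjects ("additive averaging"), suppressing
independent noise roughly as 1/sqrt(I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import FitError
from .synth import MultiSubjectEEG

__all__ = ["MCCAModel", "between_set_covariance", "fit_mcca", "denoise_and_average", "naive_average"]


@dataclass
class MCCAModel:
    """Fitted MCCA projections and spectra.

    projections[i] has shape (n_channels_i, n_components); eigenvalues are
    sorted descending and canonical_correlations = eigenvalues / (I - 1).
    """

    projections: list
    eigenvalues: np.ndarray
    canonical_correlations: np.ndarray
    n_subjects: int
    normalizer: int
    channel_means: list
    ridge: float

    @property
    def n_components(self) -> int:
        return int(self.eigenvalues.size)

    def default_n_components(
        self, method: str = "noise-floor", energy: float = 0.9, floor_factor: float = 2.0
    ) -> int:
        """Data-driven choice of how many canonical components to retain.

        ``"noise-floor"`` (default) keeps the components whose canonical
        correlation exceeds ``floor_factor`` times the median correlation:
        chance-level components of independent noise form a flat low floor,
        while genuinely shared components stand well above it, so the rule
        adapts to the SNR of the recordings.  ``"energy"`` instead keeps the
        smallest K whose eigenvalues carry ``energy`` of the total — simple,
        but at low SNR the eigenvalue mass of the noise floor makes it
        retain nearly everything, which defeats the denoising.
        """
        if method == "noise-floor":
            floor = floor_factor * np.median(self.canonical_correlations)
            return max(1, int(np.sum(self.canonical_correlations > floor)))
        if method == "energy":
            lam = np.clip(self.eigenvalues, 0.0, None)
            total = lam.sum()
            if total == 0:
                return self.n_components
            frac = np.cumsum(lam) / total
            return int(np.searchsorted(frac, energy) + 1)
        raise ValueError("method must be 'noise-floor' or 'energy'")


def between_set_covariance(x_i: np.ndarray, x_j: np.ndarray) -> np.ndarray:
    """Centered cross-covariance (X_i - mean)' (X_j - mean).

    Both inputs are time x channel; with ``x_j is x_i`` this is the
    within-set covariance.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.ndim != 2 or x_j.ndim != 2:
        raise ValueError("inputs must be 2-D time x channel arrays")
    if x_i.shape[0] != x_j.shape[0]:
        raise ValueError("datasets must share the same number of time samples")
    xc = x_i - x_i.mean(axis=0)
    yc = x_j - x_j.mean(axis=0)
    return xc.T @ yc


def fit_mcca(datasets: list, ridge: float = 1e-6) -> MCCAModel:
    """Fit MCCA over I >= 2 time-aligned datasets.

    Assembles the between-set block matrix B and the block-diagonal
    within-set matrix R (ridge-stabilized by ``ridge`` times the mean of
    R's diagonal), solves the generalized eigenproblem, and splits each
    eigenvector into per-subject projection blocks.  Components with
    non-positive eigenvalues are dropped and at most min_i(channels_i)
    components are retained, so every reported canonical correlation lies
    in [0, 1].
    """
    if len(datasets) < 2:
        raise ValueError("MCCA needs at least 2 datasets")
    datasets = [np.asarray(d, dtype=float) for d in datasets]
    t_lens = {d.shape[0] for d in datasets}
    if len(t_lens) != 1:
        raise ValueError("all datasets must share the same number of time samples")
    n_sets = len(datasets)
    n_ch = [d.shape[1] for d in datasets]
    offsets = np.concatenate([[0], np.cumsum(n_ch)])
    dim = offsets[-1]

    means = [d.mean(axis=0) for d in datasets]
    centered = [d - m for d, m in zip(datasets, means)]
    stacked = np.hstack(centered)  # (T, sum channels)
    full_cov = stacked.T @ stacked

    r_mat = np.zeros((dim, dim))
    for i in range(n_sets):
        sl = slice(offsets[i], offsets[i + 1])
        r_mat[sl, sl] = full_cov[sl, sl]
    b_mat = full_cov - r_mat

    r_reg = r_mat + ridge * np.mean(np.diag(r_mat)) * np.eye(dim)
    try:
        eigvals, eigvecs = linalg.eigh(b_mat, r_reg)
    except linalg.LinAlgError as exc:  # pragma: no cover - rare numerical path
        raise FitError(
            "generalized eigensolver failed on a near-singular within-set "
            "covariance; raise the ridge parameter"
        ) from exc

    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    keep = min(int(np.sum(eigvals > 0)), min(n_ch))
    if keep == 0:
        raise FitError("no positive-eigenvalue components found")
    eigvals = eigvals[:keep]
    eigvecs = eigvecs[:, :keep]

    projections = [eigvecs[offsets[i] : offsets[i + 1]] for i in range(n_sets)]
    rho = eigvals / (n_sets - 1)

    return MCCAModel(
        projections=projections,
        eigenvalues=eigvals,
        canonical_correlations=rho,
        n_subjects=n_sets,
        normalizer=n_sets,
        channel_means=means,
        ridge=ridge,
    )


def _reconstruct(w: np.ndarray, x_centered: np.ndarray) -> np.ndarray:
    """Project channels x time onto span(w) (truncated back-projection)."""
    comps = w.T @ x_centered
    gram = w.T @ w
    return w @ np.linalg.solve(gram, comps)


def denoise_and_average(
    model: MCCAModel,
    eeg: MultiSubjectEEG,
    trial: int,
    n_components: int | None = None,
    space: str = "electrode",
) -> np.ndarray:
    """Canonical-component denoising followed by cross-subject averaging.

    Each subject's trial is centered with the means stored at fit time and
    projected onto its leading ``n_components`` canonical projections.
    Because MCCA aligns the components across subjects, the component time
    courses add coherently even when every subject's montage is differently
    mixed — this is where the hyperalignment compensates electrode-placement
    differences that would partially cancel a plain average.

    ``space`` controls how the average is returned:

    * ``"electrode"`` (default): the cross-subject mean of the component
      time courses is rendered back into a consensus montage via the
      pseudoinverse of the subject-averaged truncated projection, giving a
      (n_channels, n_samples) array suitable for source reconstruction.
    * ``"electrode-subject"``: each subject's components are back-projected
      into that subject's own channel space first and the reconstructions
      are averaged (plain additive averaging of denoised recordings).
    * ``"component"``: the averaged (n_components, n_samples) canonical
      time courses themselves.
    """
    if not 0 <= trial < eeg.n_trials:
        raise ValueError(f"trial index {trial} out of range")
    if model.n_subjects != eeg.n_subjects:
        raise ValueError("model was fit on a different number of subjects")
    if n_components is None:
        n_components = model.default_n_components()
    if not 1 <= n_components <= model.n_components:
        raise ValueError("n_components out of range")
    if space not in ("electrode", "electrode-subject", "component"):
        raise ValueError("space must be 'electrode', 'electrode-subject' or 'component'")

    if space == "electrode-subject":
        out = None
        for i in range(eeg.n_subjects):
            xc = np.asarray(eeg.data[i, trial], dtype=float) - model.channel_means[i][:, None]
            w = model.projections[i][:, :n_components]
            rec = _reconstruct(w, xc) + model.channel_means[i][:, None]
            out = rec if out is None else out + rec
        return out / eeg.n_subjects

    comps = None
    w_mean = None
    for i in range(eeg.n_subjects):
        xc = np.asarray(eeg.data[i, trial], dtype=float) - model.channel_means[i][:, None]
        w = model.projections[i][:, :n_components]
        c = w.T @ xc
        comps = c if comps is None else comps + c
        w_mean = w if w_mean is None else w_mean + w
    comps /= eeg.n_subjects
    if space == "component":
        return comps
    w_mean /= eeg.n_subjects
    # consensus montage: pinv(mean_i W_i') maps aligned components back to
    # channel space without the signal attenuation of incoherent averaging
    return np.linalg.pinv(w_mean.T) @ comps


def naive_average(eeg: MultiSubjectEEG, trial: int) -> np.ndarray:
    """Plain additive average over subjects, no alignment or denoising."""
    if not 0 <= trial < eeg.n_trials:
        raise ValueError(f"trial index {trial} out of range")
    return np.asarray(eeg.data[:, trial], dtype=float).mean(axis=0)
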