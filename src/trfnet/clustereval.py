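"""Condition-separability evaluation of trial-level brain networks.

Each trial's network (or windowed TRF profile) becomes a feature vector;
the trials are embedded in two dimensions (t-SNE by default, PCA as a
deterministic alternative) and clustered with k-means over many random
initializations.  Agreement between the clusters and the true condition
labels is scored with the F1 measure after matching cluster ids to labels
by the assignment that maximizes F1, averaged over repetitions — so a high
mean F1 means the two stimulus conditions produce separably different
networks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from ._utils import child_seed, pearson
from .network import ConnectivityMatrix

__all__ = [
    "TrialFeatureMatrix",
    "vectorize_network",
    "unvectorize_network",
    "embed_2d",
    "kmeans_f1",
    "window_cluster",
    "coupling_correlation",
    "DEFAULT_WINDOWS_MS",
]

#: The four TRF lag windows used for window-wise clustering (ms).
DEFAULT_WINDOWS_MS = ((0.0, 150.0), (150.0, 300.0), (300.0, 450.0), (450.0, 600.0))


@dataclass
class TrialFeatureMatrix:
    """Trials-by-features matrix with per-trial condition labels."""

    values: np.ndarray
    condition_labels: list

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.condition_labels) != self.values.shape[0]:
            raise ValueError("one condition label per trial required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing values")


def vectorize_network(C) -> np.ndarray:
    """Upper-triangle (excluding diagonal) of a symmetric matrix, row-major.

    A 68-region network yields the canonical 2,278-dimensional vector.
    """
    v = C.values if isinstance(C, ConnectivityMatrix) else np.asarray(C, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("input must be square")
    if np.nanmax(np.abs(v - v.T)) > 1e-10:
        raise ValueError("input must be symmetric")
    iu = np.triu_indices(v.shape[0], 1)
    return v[iu]


def unvectorize_network(vec: np.ndarray, n: int, diag: float = 1.0) -> np.ndarray:
    """Inverse packing of :func:`vectorize_network`."""
    vec = np.asarray(vec, dtype=float)
    out = np.full((n, n), diag)
    iu = np.triu_indices(n, 1)
    if vec.size != iu[0].size:
        raise ValueError("vector length does not match n")
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


def embed_2d(
    features: np.ndarray,
    method: str = "tsne",
    seed: int | None = None,
    perplexity: float = 10.0,
) -> np.ndarray:
    """Two-dimensional embedding of the trial feature matrix.

    t-SNE (PCA-initialized, deterministic given ``seed``) by default; PCA
    projection onto the top two principal axes as a deterministic linear
    alternative.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    n = x.shape[0]
    if method == "pca":
        return PCA(n_components=2, random_state=0).fit_transform(x)
    if method != "tsne":
        raise ValueError("method must be 'tsne' or 'pca'")
    if n < 5:
        raise ValueError("t-SNE needs at least 5 trials")
    if perplexity >= n:
        raise ValueError("perplexity must be smaller than the number of trials")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=0 if seed is None else int(seed) % (2**31),
        max_iter=1000,
        method="exact",  # trial counts are small; the exact gradient also
        # maps duplicate trials to coincident points, unlike Barnes-Hut
    )
    return tsne.fit_transform(x)


def _binary_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = np.sum((y_true == 1) & (y_pred == 1))
    fp = np.sum((y_true == 0) & (y_pred == 1))
    fn = np.sum((y_true == 1) & (y_pred == 0))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def kmeans_f1(
    embedded: np.ndarray,
    true_labels,
    k: int = 2,
    n_reps: int = 1000,
    seed: int | None = None,
) -> float:
    """Mean best-assignment F1 of k-means clusters against binary labels.

    Each repetition runs k-means from a fresh random initialization; its
    clusters are mapped onto the two condition labels by the assignment
    maximizing F1 (so the score is invariant to cluster-id permutation) and
    the F1 values are averaged over repetitions.
    """
    x = np.atleast_2d(np.asarray(embedded, dtype=float))
    labels = np.asarray(true_labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("true_labels must contain exactly 2 classes")
    if labels.size != x.shape[0]:
        raise ValueError("one label per row required")
    y = (labels == classes[1]).astype(int)
    if k < 2:
        raise ValueError("k must be >= 2")
    maps = [m for m in itertools.product((0, 1), repeat=k) if len(set(m)) == 2]
    scores = np.empty(n_reps)
    for rep in range(n_reps):
        km = KMeans(
            n_clusters=k,
            init="random",
            n_init=1,
            random_state=child_seed(seed, f"kmeans-{rep}"),
        ).fit(x)
        pred = km.labels_
        scores[rep] = max(_binary_f1(y, np.asarray(m)[pred]) for m in maps)
    return float(scores.mean())


def window_cluster(
    trf_sets: np.ndarray,
    condition_labels,
    lags_ms: np.ndarray,
    windows_ms: tuple = DEFAULT_WINDOWS_MS,
    method: str = "tsne",
    seed: int | None = None,
    n_reps: int = 1000,
    perplexity: float = 10.0,
) -> dict:
    """Per-window clustering F1 of trial TRF profiles.

    ``trf_sets`` is (n_trials, n_roi, n_lags); for each lag window the
    feature vector of a trial is the per-region mean TRF amplitude in that
    window.  Returns {window: mean F1}.
    """
    from .trf import trf_window_amplitude

    trf_sets = np.asarray(trf_sets, dtype=float)
    if trf_sets.ndim != 3:
        raise ValueError("trf_sets must be (trials, roi, lags)")
    out = {}
    for w_idx, window in enumerate(windows_ms):
        feats = np.stack([trf_window_amplitude(t, lags_ms, window) for t in trf_sets])
        emb = embed_2d(feats, method=method, seed=child_seed(seed, f"embed-w{w_idx}"), perplexity=perplexity)
        out[tuple(window)] = kmeans_f1(
            emb, condition_labels, n_reps=n_reps, seed=child_seed(seed, f"f1-w{w_idx}")
        )
    return out


def coupling_correlation(trf_a: np.ndarray, trf_b: np.ndarray, lags_ms: np.ndarray,
                         lag_range_ms: tuple | None = None) -> float:
    """Pearson correlation between two regions' TRF lag-courses.

    Restricted to ``lag_range_ms`` when given; NaN (with a warning) if
    either kernel is constant over the range.
    """
    a = np.asarray(trf_a, dtype=float).ravel()
    b = np.asarray(trf_b, dtype=float).ravel()
    lags_ms = np.asarray(lags_ms, dtype=float)
    if a.size != lags_ms.size or b.size != lags_ms.size:
        raise ValueError("kernels must share the lag grid")
    if lag_range_ms is not None:
        lo, hi = lag_range_ms
        mask = (lags_ms >= lo) & (lags_ms <= hi)
        a, b = a[mask], b[mask]
    r = pearson(a, b)
    if np.isnan(r):
        warnings.warn("degenerate (constant) TRF over the lag range: correlation undefined")
    return r
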