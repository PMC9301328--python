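"""TRF-correlation brain networks, density thresholding, and signed
community detection.

Network nodes are cortical regions; the edge weight between two regions is
the Pearson correlation between their TRF lag-courses, so the graph is
signed: correlated regions (cooperating during speech processing) carry
positive edges and anti-correlated ones negative edges.  A density
threshold t keeps the ceil(t * n(n-1)/2) strongest edges by magnitude with
their signs.  Community structure is scored with the asymmetric signed
modularity

    Q = Q+ - v- / (v+ + v-) * Q-,

where Q+/Q- are Newman modularities of the positive/negative subgraphs and
v+/v- their total weights: positive edges reward within-community placement
at full strength while negative within-community edges penalize it only in
proportion to their share of the total weight.  Optimization is a
Louvain-style greedy local-move/aggregate scheme with random restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._utils import child_seed

__all__ = [
    "ConnectivityMatrix",
    "ThresholdedGraph",
    "Partition",
    "trf_connectivity",
    "edge_count",
    "threshold_density",
    "modularity_signed",
    "detect_communities",
    "mean_connectivity",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric signed correlation matrix over regions, unit diagonal."""

    values: np.ndarray
    roi_ids: list
    tag: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity must be square")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T]):
            raise ValueError("connectivity must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(v)) > 1 + 1e-9:
                raise ValueError("correlations must lie in [-1, 1]")
        self.values = v

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


@dataclass
class ThresholdedGraph:
    """Sparse signed graph kept at a fixed edge density."""

    values: np.ndarray
    density: float
    binarized: bool
    roi_ids: list

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_nodes, 1)
        return int(np.count_nonzero(self.values[iu]))


@dataclass
class Partition:
    """Community assignment: labels are contiguous integers from 1."""

    labels: np.ndarray
    n_communities: int
    quality: float
    gamma: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
            raise ValueError("labels must be contiguous from 1")
        if self.n_communities != uniq.size:
            raise ValueError("n_communities inconsistent with labels")


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities as 1..K in order of first appearance."""
    labels = np.asarray(labels)
    out = np.empty(labels.size, dtype=int)
    mapping: dict = {}
    for i, lab in enumerate(labels):
        mapping.setdefault(lab, len(mapping) + 1)
        out[i] = mapping[lab]
    return out


def trf_connectivity(trf_model, roi_ids: list | None = None, tag: str = "") -> ConnectivityMatrix:
    """Pairwise Pearson correlation between region TRF lag-courses.

    Accepts a :class:`~trfnet.trf.TRFModel` or a bare (n_roi, n_lags)
    array.  Zero-variance rows get missing (NaN) correlations; more than
    10% degenerate rows is an error.
    """
    w = np.asarray(getattr(trf_model, "weights", trf_model), dtype=float)
    if w.ndim != 2 or w.shape[0] < 2:
        raise ValueError("need a 2-D kernel set with at least 2 regions")
    if w.shape[1] < 3:
        raise ValueError("need at least 3 lag points")
    sd = w.std(axis=1)
    degenerate = sd == 0
    if degenerate.mean() > 0.10:
        raise ValueError("more than 10% of TRF rows have zero variance")
    c = np.full((w.shape[0],) * 2, np.nan)
    ok = ~degenerate
    if ok.sum() >= 2:
        sub = np.corrcoef(w[ok])
        c[np.ix_(ok, ok)] = np.clip(sub, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    if roi_ids is None:
        roi_ids = getattr(trf_model, "roi_ids", None) or [f"ROI{i:02d}" for i in range(w.shape[0])]
    return ConnectivityMatrix(values=c, roi_ids=list(roi_ids), tag=tag)


def edge_count(n_nodes: int) -> int:
    """Number of undirected pairwise edges, n(n-1)/2."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return n_nodes * (n_nodes - 1) // 2


def threshold_density(C, t: float, binarize: bool = False) -> ThresholdedGraph:
    """Keep the ceil(t * E) largest-magnitude edges, signs preserved.

    Ties at the cutoff magnitude are broken deterministically by (i, j)
    lexicographic order.  ``binarize`` maps retained edges to +/-1.
    """
    if not 0 < t <= 1:
        raise ValueError("density t must lie in (0, 1]")
    if isinstance(C, ConnectivityMatrix):
        values, roi_ids = C.values, C.roi_ids
    else:
        values = np.asarray(C, dtype=float)
        roi_ids = [f"ROI{i:02d}" for i in range(values.shape[0])]
    n = values.shape[0]
    n_keep = math.ceil(t * edge_count(n))
    iu, ju = np.triu_indices(n, 1)
    w = values[iu, ju]
    mag = np.abs(np.where(np.isfinite(w), w, -np.inf))
    # stable sort on (-|w|, i, j): lexsort last key is primary
    order = np.lexsort((ju, iu, -mag))
    keep = order[:n_keep]
    out = np.zeros((n, n))
    kept_w = w[keep]
    if binarize:
        kept_w = np.sign(kept_w)
    out[iu[keep], ju[keep]] = kept_w
    out += out.T
    return ThresholdedGraph(values=out, density=float(t), binarized=bool(binarize), roi_ids=roi_ids)


def _graph_values(graph) -> np.ndarray:
    if isinstance(graph, ThresholdedGraph):
        return graph.values
    if isinstance(graph, ConnectivityMatrix):
        w = graph.values.copy()
        np.fill_diagonal(w, 0.0)
        return np.nan_to_num(w)
    w = np.asarray(graph, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("graph must be a square matrix")
    return w


def _signed_q(w: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """Asymmetric signed modularity for a dense signed adjacency."""
    labels = np.asarray(labels)
    w_pos = np.clip(w, 0.0, None)
    w_neg = np.clip(-w, 0.0, None)
    v_pos = w_pos.sum()
    v_neg = w_neg.sum()
    if v_pos + v_neg == 0:
        raise ValueError("graph has zero total weight")
    same = labels[:, None] == labels[None, :]

    def newman(ws, vs):
        if vs == 0:
            return 0.0
        k = ws.sum(axis=1)
        within = ws[same].sum()
        null = gamma * sum(
            k[labels == c].sum() ** 2 for c in np.unique(labels)
        ) / vs
        return (within - null) / vs

    q_pos = newman(w_pos, v_pos)
    q_neg = newman(w_neg, v_neg)
    return q_pos - (v_neg / (v_pos + v_neg)) * q_neg


def modularity_signed(graph, partition, gamma: float = 1.0) -> float:
    """Quality Q of a partition under the asymmetric signed null model."""
    w = _graph_values(graph)
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    if labels.size != w.shape[0]:
        raise ValueError("partition must cover every node")
    return float(_signed_q(w, labels, gamma))


def _louvain_level(w: np.ndarray, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """One Louvain level: greedy local moves until no gain. Returns labels."""
    n = w.shape[0]
    w_pos = np.clip(w, 0.0, None)
    w_neg = np.clip(-w, 0.0, None)
    v_pos = w_pos.sum()
    v_neg = w_neg.sum()
    neg_scale = v_neg / (v_pos + v_neg)
    k_pos = w_pos.sum(axis=1)
    k_neg = w_neg.sum(axis=1)
    labels = np.arange(n)
    comm_kpos = k_pos.copy()
    comm_kneg = k_neg.copy()

    # off-diagonal rows (self-loops stay within the node's community)
    wp_off = w_pos.copy()
    wn_off = w_neg.copy()
    np.fill_diagonal(wp_off, 0.0)
    np.fill_diagonal(wn_off, 0.0)

    def gain(i, a, b, l_pos, l_neg):
        """Delta Q for moving node i from community a to b."""
        dq = 0.0
        if v_pos > 0:
            d_within = 2.0 * (l_pos[b] - l_pos[a])
            d_null = 2.0 * k_pos[i] * (comm_kpos[b] - (comm_kpos[a] - k_pos[i]))
            dq += d_within / v_pos - gamma * d_null / v_pos**2
        if v_neg > 0:
            d_within = 2.0 * (l_neg[b] - l_neg[a])
            d_null = 2.0 * k_neg[i] * (comm_kneg[b] - (comm_kneg[a] - k_neg[i]))
            dq -= neg_scale * (d_within / v_neg - gamma * d_null / v_neg**2)
        return dq

    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            a = labels[i]
            l_pos = np.bincount(labels, weights=wp_off[i], minlength=n)
            l_neg = np.bincount(labels, weights=wn_off[i], minlength=n)
            candidates = np.unique(labels[(wp_off[i] > 0) | (wn_off[i] > 0)])
            best_b, best_gain = a, 0.0
            for b in candidates:
                if b == a:
                    continue
                g = gain(i, a, b, l_pos, l_neg)
                if g > best_gain + 1e-14:
                    best_gain, best_b = g, b
            if best_b != a:
                comm_kpos[a] -= k_pos[i]
                comm_kneg[a] -= k_neg[i]
                comm_kpos[best_b] += k_pos[i]
                comm_kneg[best_b] += k_neg[i]
                labels[i] = best_b
                improved = True
    return labels


def _louvain_once(w: np.ndarray, gamma: float, rng: np.random.Generator) -> np.ndarray:
    n = w.shape[0]
    node_labels = np.arange(n)
    w_level = w.copy()
    while True:
        level = _louvain_level(w_level, gamma, rng)
        level = canonical_labels(level) - 1
        n_comm = level.max() + 1
        if n_comm == w_level.shape[0]:
            break
        # aggregate: supernode adjacency keeps signed weights and self-loops
        m = np.zeros((w_level.shape[0], n_comm))
        m[np.arange(w_level.shape[0]), level] = 1.0
        w_level = m.T @ w_level @ m
        node_labels = level[node_labels]
    return canonical_labels(node_labels)


def detect_communities(
    graph, gamma: float = 1.0, n_runs: int = 100, seed: int | None = None
) -> Partition:
    """Signed-modularity Louvain with random restarts; best-Q partition wins.

    Deterministic given ``seed``.  The single-community partition is always
    included as a baseline candidate, so the returned Q never falls below
    it.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    w = _graph_values(graph)
    n = w.shape[0]
    if n == 0 or not np.any(w):
        raise ValueError("empty graph")
    best_labels = np.ones(n, dtype=int)
    best_q = _signed_q(w, best_labels, gamma)
    for run in range(n_runs):
        rng = np.random.default_rng(child_seed(seed, f"louvain-{run}"))
        labels = _louvain_once(w, gamma, rng)
        q = _signed_q(w, labels, gamma)
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels
    best_labels = canonical_labels(best_labels)
    return Partition(
        labels=best_labels,
        n_communities=int(best_labels.max()),
        quality=float(best_q),
        gamma=float(gamma),
    )


def mean_connectivity(matrices: list, tag: str = "") -> ConnectivityMatrix:
    """Condition-level network: Fisher-z mean of trial matrices, tanh back."""
    if not matrices:
        raise ValueError("need at least one matrix")
    stack = np.stack([m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m) for m in matrices])
    clipped = np.clip(stack, -1 + 1e-10, 1 - 1e-10)
    with np.errstate(invalid="ignore"):
        mean_z = np.nanmean(np.arctanh(clipped), axis=0)
    out = np.tanh(mean_z)
    np.fill_diagonal(out, 1.0)
    roi_ids = matrices[0].roi_ids if isinstance(matrices[0], ConnectivityMatrix) else None
    return ConnectivityMatrix(values=out, roi_ids=roi_ids or [f"ROI{i:02d}" for i in range(out.shape[0])], tag=tag)
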