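"""Multi-scale density scanning and variation-of-information scale selection.

Thresholding a correlation network at different densities yields a family
of partitions.  The variation of information

    VI(X, Y) = H(X) + H(Y) - 2 I(X; Y)

(plug-in entropies in nats from the community co-membership confusion
table) is an information-theoretic metric between partitions: it is zero
iff the partitions coincide, symmetric, and obeys the triangle inequality.
A low VI between partitions at neighbouring densities marks a scale range
where the community structure is stable; the selected density is the one
with minimal VI among the densities whose condition-separability F1 is
within tolerance of the maximum (smallest density on ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._utils import child_seed
from .network import Partition, detect_communities, threshold_density

__all__ = ["PartitionComparison", "DensityScan", "variation_of_information", "scan_densities", "select_scale", "default_density_grid"]


@dataclass
class PartitionComparison:
    """Entropies, mutual information, and VI for two partitions (nats)."""

    H_X: float
    H_Y: float
    I_XY: float
    VI: float


@dataclass
class DensityScan:
    """Partitions, modularity, and VI stability along a density grid."""

    densities: np.ndarray
    partitions: list
    Q: np.ndarray
    vi: np.ndarray  # VI between partitions at consecutive densities
    f1: np.ndarray | None = None
    gamma: float = 1.0
    extras: dict = field(default_factory=dict)

    def partition_at(self, density: float) -> Partition:
        idx = int(np.argmin(np.abs(self.densities - density)))
        if abs(self.densities[idx] - density) > 1e-9:
            raise ValueError(f"density {density} not on the scanned grid")
        return self.partitions[idx]

    def density_vi(self, window: int = 2) -> np.ndarray:
        """Per-density stability: mean VI to the partitions within ``window``
        neighbouring densities on either side.

        A windowed measure (rather than only the two adjacent VI values)
        distinguishes a broad stability plateau from a short accidental one:
        only densities whose partition persists across the whole
        neighbourhood score zero.
        """
        n = self.densities.size
        out = np.empty(n)
        for i in range(n):
            vals = [
                variation_of_information(self.partitions[i], self.partitions[j]).VI
                for j in range(max(0, i - window), min(n, i + window + 1))
                if j != i
            ]
            out[i] = float(np.mean(vals)) if vals else 0.0
        return out


def _labels_of(p) -> np.ndarray:
    return p.labels if isinstance(p, Partition) else np.asarray(p, dtype=int)


def variation_of_information(p1, p2) -> PartitionComparison:
    """VI between two partitions of the same node set (natural log).

    Identical partitions (up to relabeling) return exactly 0.
    """
    x = _labels_of(p1)
    y = _labels_of(p2)
    if x.size != y.size:
        raise ValueError("partitions must cover the same node set")
    if x.size == 0:
        raise ValueError("empty partitions")
    n = x.size
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    kx = xi.max() + 1
    ky = yi.max() + 1
    joint = np.zeros((kx, ky))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)

    def entropy(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    h_x = entropy(px)
    h_y = entropy(py)
    nz = joint > 0
    i_xy = float((joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])).sum())
    from .network import canonical_labels

    if kx == ky and np.array_equal(canonical_labels(xi), canonical_labels(yi)):
        # same partition up to relabeling -> VI is exactly zero
        return PartitionComparison(H_X=h_x, H_Y=h_y, I_XY=h_x, VI=0.0)
    vi = max(h_x + h_y - 2.0 * i_xy, 0.0)
    return PartitionComparison(H_X=h_x, H_Y=h_y, I_XY=i_xy, VI=vi)


def default_density_grid() -> np.ndarray:
    """Density grid 0.01, 0.02, ..., 0.50."""
    return np.round(np.arange(1, 51) * 0.01, 2)


def scan_densities(
    C,
    t_grid: np.ndarray | None = None,
    gamma: float = 1.0,
    n_runs: int = 20,
    seed: int | None = None,
) -> DensityScan:
    """Threshold and detect communities at every density on the grid.

    Records the best-Q partition and modularity per density, plus the VI
    between partitions at consecutive densities.
    """
    if t_grid is None:
        t_grid = default_density_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any((t_grid <= 0) | (t_grid > 1)):
        raise ValueError("densities must lie in (0, 1]")
    partitions = []
    q_vals = []
    for t in t_grid:
        try:
            g = threshold_density(C, float(t))
            part = detect_communities(g, gamma=gamma, n_runs=n_runs, seed=child_seed(seed, f"scan-{t:.4f}"))
        except Exception as exc:
            raise RuntimeError(f"community detection failed at density t={t:.3f}") from exc
        partitions.append(part)
        q_vals.append(part.quality)
    vi = np.array(
        [variation_of_information(partitions[i], partitions[i + 1]).VI for i in range(len(partitions) - 1)]
    )
    return DensityScan(densities=t_grid, partitions=partitions, Q=np.asarray(q_vals), vi=vi, gamma=gamma)


def select_scale(scan: DensityScan, f1_curve: np.ndarray | None = None, f1_tol: float = 0.02) -> float:
    """Pick the optimal density: minimal VI among near-maximal-F1 densities.

    Feasible densities are those whose F1 is within ``f1_tol`` of the
    maximum (all densities if no F1 curve is given); among them the density
    with the smallest per-density VI (mean of adjacent consecutive-density
    VI values) wins, ties going to the smallest density.
    """
    if f1_curve is None:
        f1_curve = scan.f1
    density_vi = scan.density_vi()
    if f1_curve is not None:
        f1_curve = np.asarray(f1_curve, dtype=float)
        if f1_curve.size != scan.densities.size:
            raise ValueError("f1 curve must align with the density grid")
        if np.all(np.isnan(f1_curve)):
            feasible = np.zeros(scan.densities.size, dtype=bool)
        else:
            feasible = f1_curve >= np.nanmax(f1_curve) - f1_tol
    else:
        feasible = np.ones(scan.densities.size, dtype=bool)
    if not np.any(feasible):
        warnings.warn("empty feasible set; falling back to the global VI minimum")
        feasible = np.ones(scan.densities.size, dtype=bool)
    masked = np.where(feasible, density_vi, np.inf)
    idx = int(np.argmin(masked))  # argmin takes the first (smallest density) on ties
    return float(scan.densities[idx])
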