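"""Signed TRF-correlation networks and multi-scale community detection.

Builds a signed connectivity matrix with planted block structure,
scans edge densities, detects communities with the signed-modularity
Louvain, and selects the optimal scale by variation of information.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import trfnet

rng = np.random.default_rng(8)
truth = np.repeat(np.arange(1, 5), 10)  # four planted communities of 10
c = np.where(truth[:, None] == truth[None, :], 0.8, -0.2)
sym = rng.standard_normal((40, 40))
c = c + 0.03 * (sym + sym.T) / 2
np.fill_diagonal(c, 1.0)

print(f"all-pairs edge count for 40 nodes: {trfnet.edge_count(40)}")
scan = trfnet.scan_densities(c, n_runs=10, seed=9)
selected = trfnet.select_scale(scan)
partition = scan.partition_at(selected)
print(f"density grid: {scan.densities[0]:.2f}..{scan.densities[-1]:.2f} "
      f"({scan.densities.size} values, {scan.vi.size} consecutive VI values)")
print(f"selected density (min windowed VI): {selected:.2f}")
print(f"communities found: {partition.n_communities}, signed modularity Q = {partition.quality:.3f}")
print(f"adjusted Rand index vs planted blocks: "
      f"{adjusted_rand_score(truth, partition.labels):.3f}")
print("(Q between 0.3 and 0.8 signals genuine community structure; the")
print(" VI minimum marks the density range where the partition is stable)")
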