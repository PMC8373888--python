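"""Build the three connectivity matrices for a single subject.

Constructs a tiny 6-region example by hand: a streamline-count matrix, a
per-edge FA matrix and a short ROI time-series table, then derives the
edge-weight (EW), FA and Fisher-z functional connectivity (FC) matrices.
"""

import numpy as np

from glioconn import (FAEdgeMatrix, RoiTimeSeries, StreamlineCountMatrix,
                      edge_weight_matrix, fa_connectivity, fc_matrix)

rng = np.random.default_rng(0)
n = 6

# streamline counts on a few region pairs (ids 1..6; odd left, even right)
counts = np.zeros((n, n), dtype=int)
for i, j, c in [(0, 2, 40), (0, 4, 25), (1, 3, 35), (3, 5, 20), (0, 1, 8)]:
    counts[i, j] = counts[j, i] = c
counts = StreamlineCountMatrix(counts, "demo")

ew = edge_weight_matrix(counts)
print("edge weight between regions 1 and 3 (fibers / mean region strength):")
print(f"  N13 = 40, S1 = 73, S3 = 75  ->  EW = {ew.values[0, 2]:.4f}")

# per-edge FA wherever a streamline exists
fa = np.where(counts.counts > 0, 0.45, np.nan)
np.fill_diagonal(fa, np.nan)
fa = fa_connectivity(FAEdgeMatrix(fa, "demo"), counts)
print(f"FA defined on {np.isfinite(fa.values).sum() // 2} edges "
      "(exactly the streamline-connected pairs)")

# functional connectivity from a 120-volume time series with a shared signal
shared = rng.standard_normal(120)
ts = 0.6 * shared[:, None] + 0.8 * rng.standard_normal((120, n))
fc = fc_matrix(RoiTimeSeries(ts, "demo"))
print("Fisher-z FC between regions 1 and 2 "
      f"(shared-signal construction): {fc.values[0, 1]:.3f}")
print("matrices are symmetric with missing diagonals; shapes:",
      ew.values.shape, fa.values.shape, fc.values.shape)
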