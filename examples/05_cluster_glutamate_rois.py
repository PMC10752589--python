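"""Functional clustering of glutamate-imaging ROIs.

Draws a synthetic population of 120 ROIs from the seven-cluster ON
library at SNR 10, aligns each ROI's two motion-direction responses on
their mean half-rise time, clusters the aligned waveforms (Ward linkage),
and picks the cluster count from the elbow of the within-cluster-variance
curve.  Ground-truth labels let us score the recovery.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from starburst import (NoiseModel, cluster_rois, gen_cluster_library,
                       gen_roi_dataset)

library = gen_cluster_library("ON7")
rois, truth = gen_roi_dataset(library, n_rois=120,
                              noise=NoiseModel(sd=0.1), seed=0)
clusters = cluster_rois(rois)

print(f"elbow chose k = {clusters.k} (library has {library.n_clusters})")
ari = adjusted_rand_score(truth, clusters.labels)
print(f"adjusted Rand index vs ground truth: {ari:.3f}")
print("cluster sizes (C1 = most transient):",
      np.bincount(clusters.labels).tolist())
print("\nAn ARI near 1 means the aligned-waveform clustering recovers the "
      "generating release types almost perfectly at this noise level.")
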