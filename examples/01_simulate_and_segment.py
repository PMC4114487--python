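"""Simulate a small labeled genome and recover its chromatin states.

Generates a 1.6 Mb two-arm genome with a known four-state annotation,
fits Gaussian HMMs on the first two principal components of the
interband-protein tracks, selects the state count with the
Calinski-Harabasz criterion under the anchor constraint, and compares
the decoded states with the truth.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

from chromband import pca_scores, select_state_count, viterbi_decode
from chromband.synthetic import INTERBAND_DATASETS, SimConfig, simulate_signals, simulate_truth

config = SimConfig(
    chrom_sizes={"chrX": 1_000_000, "chr2L": 600_000},
    n_hh_pairs=60, n_hh_pairs_far=8, n_single_genes=80,
)
truth = simulate_truth(config, seed=0)
signals = simulate_signals(truth)
view = pca_scores(signals, list(INTERBAND_DATASETS), n_components=2)
print(f"PC1+PC2 explain {100 * view.explained_variance_ratio.sum():.1f}% of variance")

model, record = select_state_count(
    view, truth.anchors, seed=0, k_range=range(2, 8), train_chromosomes=["chrX"])
print(record.table.to_string(index=False))
print(f"chosen state count: {record.chosen_K} "
      "(CH maximum among anchor-consistent candidates)")

path = viterbi_decode(model, view)
ok = (~truth.mask) & (path.states >= 0)
conf = np.zeros((4, model.K))
np.add.at(conf, (truth.path.states[ok], path.states[ok]), 1)
r, c = linear_sum_assignment(-conf)
acc = conf[r, c].sum() / conf.sum()
print(f"bin-level accuracy after label alignment: {acc:.3f}")
print("A value near 1 means the decoded segmentation reproduces the "
      "hidden annotation almost bin for bin.")
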