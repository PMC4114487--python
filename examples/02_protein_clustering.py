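"""Find the interband-protein cluster from correlated binding tracks.

Computes the Spearman correlation matrix of 18 simulated protein tracks
on the training chromosome, clusters them on correlation distance, cuts
the dendrogram with the Mojena stopping rule, and picks the cluster
containing the known interband markers (CHRIZ, RNA polymerase II, ...).
"""

from chromband import cluster_datasets, mojena_partition, select_interband_cluster, spearman_matrix
from chromband.synthetic import (
    CHRIZ_DATASETS,
    POLII_DATASETS,
    SimConfig,
    simulate_signals,
    simulate_truth,
)

config = SimConfig(chrom_sizes={"chrX": 1_000_000, "chr2L": 400_000},
                   n_hh_pairs=40, n_hh_pairs_far=4, n_single_genes=60)
truth = simulate_truth(config, seed=1)
signals = simulate_signals(truth)

corr = spearman_matrix(signals, "chrX")

tree = cluster_datasets(corr)
partition = mojena_partition(tree, k_sd=2.0)
print(f"Mojena cut: {partition.n_clusters} protein clusters")

markers = list(CHRIZ_DATASETS + POLII_DATASETS)
cluster = select_interband_cluster(partition, markers)
print(f"selected interband cluster ({len(cluster)} datasets):")
print("  " + ", ".join(cluster))
print("These are the tracks whose principal components feed the HMM; "
      "the repressive datasets (H1, SUUR, lamin, ...) fall in the other cluster.")
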