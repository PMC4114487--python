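"""Identification of the interband-associated protein cluster.

Datasets (protein x cell line tracks) are compared by Spearman rank
correlation over the bins of one reference chromosome, clustered
agglomeratively on the correlation distance d = 1 - rho, and the
dendrogram is cut with the Mojena stopping rule: merging stops at the
first fusion level a_i satisfying a_i >= a-bar + k * s_a, where a-bar and
s_a are the mean and standard deviation of all fusion levels.  The
cluster containing the known interband markers (CHRIZ, RNA polymerase II,
nucleosome remodelers, ...) is then selected for downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genomic_io import SignalMatrix

__all__ = [
    "CorrelationMatrix",
    "Dendrogram",
    "ProteinPartition",
    "spearman_matrix",
    "cluster_datasets",
    "mojena_partition",
    "select_interband_cluster",
]


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise Spearman rho between datasets."""

    datasets: list[str]
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        n = len(self.datasets)
        if self.rho.shape != (n, n):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.rho, self.rho.T, atol=1e-10, equal_nan=True):
            raise ValueError("correlation matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.datasets, columns=self.datasets)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over datasets (scipy linkage encoding)."""

    datasets: list[str]
    Z: np.ndarray
    method: str = "average"

    @property
    def fusion_levels(self) -> np.ndarray:
        """Merge heights a_1..a_{n-1} in merge order."""
        return self.Z[:, 2].copy()

    @property
    def n_leaves(self) -> int:
        return len(self.datasets)


@dataclass
class ProteinPartition:
    """Flat clustering of datasets with an optional selected cluster."""

    n_clusters: int
    assignments: dict[str, int]
    selected: int | None = None

    def members(self, cluster: int) -> list[str]:
        return sorted(d for d, c in self.assignments.items() if c == cluster)

    @property
    def clusters(self) -> list[int]:
        return sorted(set(self.assignments.values()))


def spearman_matrix(
    signals: SignalMatrix, chromosome: str, min_bins: int = 3
) -> CorrelationMatrix:
    """Pairwise Spearman rho over one chromosome's bins.

    Masked bins are handled pairwise-complete: each pair of datasets uses
    the bins where both are observed.  A pair with fewer than `min_bins`
    jointly observed bins raises a ValueError naming the pair.
    """
    if len(signals.datasets) < 2:
        raise ValueError("need at least 2 datasets")
    lo, hi = signals.bins.chrom_range(chromosome)
    df = pd.DataFrame(signals.values[lo:hi], columns=signals.datasets)
    present = df.notna().to_numpy().astype(np.int64)
    joint = present.T @ present
    ii, jj = np.where(joint < min_bins)
    for i, j in zip(ii, jj):
        if i < j:
            raise ValueError(
                f"datasets {signals.datasets[i]!r} and {signals.datasets[j]!r} share "
                f"only {joint[i, j]} unmasked bins on {chromosome} (need {min_bins})"
            )
    rho = df.corr(method="spearman", min_periods=min_bins).to_numpy()
    return CorrelationMatrix(list(signals.datasets), rho)


def cluster_datasets(corr: CorrelationMatrix, method: str = "average") -> Dendrogram:
    """Agglomerative clustering on correlation distance d = 1 - rho."""
    if not np.isfinite(corr.rho).all():
        raise ValueError("correlation matrix contains non-finite entries")
    dist = 1.0 - corr.rho
    np.fill_diagonal(dist, 0.0)
    # guard tiny asymmetries before condensing
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method=method)
    return Dendrogram(list(corr.datasets), Z, method)


def mojena_partition(tree: Dendrogram, k_sd: float = 2.0) -> ProteinPartition:
    """Cut the dendrogram with the Mojena stopping rule.

    Scanning fusion levels in merge order, merging stops at the first
    level a_i >= a-bar + k_sd * s_a (mean and sd, ddof=1, over all n-1
    fusion levels); the clusters are the components just before that
    merge.  If the rule never fires -- including the degenerate case
    s_a = 0 (all fusion levels equal) -- everything merges into one
    cluster.
    """
    levels = tree.fusion_levels
    n = tree.n_leaves
    if n < 2 or len(levels) < 2:
        return ProteinPartition(1, {d: 1 for d in tree.datasets})
    abar = float(np.mean(levels))
    s_a = float(np.std(levels, ddof=1))
    n_clusters = 1
    if s_a > 0:
        threshold = abar + k_sd * s_a
        hits = np.where(levels >= threshold)[0]
        if hits.size:
            n_clusters = n - int(hits[0])
    labels = fcluster(tree.Z, t=n_clusters, criterion="maxclust")
    return ProteinPartition(n_clusters, dict(zip(tree.datasets, (int(x) for x in labels))))


def select_interband_cluster(
    partition: ProteinPartition, markers: list[str]
) -> list[str]:
    """Return the datasets of the cluster best covering the marker list.

    The cluster with maximal marker overlap wins; ties are broken by the
    larger cluster, then lexicographically by membership.  Raises when no
    cluster contains any marker.
    """
    if not markers:
        raise ValueError("marker list must be non-empty")
    candidates = []
    for cluster in partition.clusters:
        members = partition.members(cluster)
        overlap = len(set(members) & set(markers))
        candidates.append((-overlap, -len(members), tuple(members), cluster))
    candidates.sort()
    overlap, _, _, best_cluster = candidates[0]
    if -overlap == 0:
        raise ValueError("no cluster contains any interband marker dataset")
    partition.selected = best_cluster
    return partition.members(best_cluster)
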