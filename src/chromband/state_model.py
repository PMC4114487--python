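"""The segmentation core: PCA, Gaussian HMM, model selection, state naming.

The selected interband-protein signal columns are reduced to their first
two principal components (centered, not variance-scaled), a hidden Markov
model with multivariate normal emissions is fitted by Baum-Welch on a
designated training chromosome for each candidate state count K, and K is
chosen by maximizing the Calinski-Harabasz variance-ratio criterion

    CH(K) = [B / (K - 1)] / [W / (n - K)]

among the K for which all reference anchor points (the 12 interband
P-element insertion sites) decode to a single state.  The genome is then
decoded with the Viterbi algorithm, the anchor state is named "cyan"
(interbands) and the remaining states blue / magenta / green by their
marker-signal profile, and consecutive same-state bins are merged into
genomic fragments.

Missing bins break the Markov chain: every contiguous run of usable bins
is decoded independently, and genome fractions are computed over the
data-covered genome only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .genomic_io import GenomeBins, SignalMatrix

__all__ = [
    "PCView",
    "HMMModel",
    "StatePath",
    "ReferenceAnchors",
    "StateFragments",
    "ModelSelectionRecord",
    "pca_scores",
    "fit_hmm",
    "viterbi_decode",
    "calinski_harabasz",
    "select_state_count",
    "anchor_and_extract",
]

logger = logging.getLogger(__name__)

STATE_NAMES = ("cyan", "blue", "green", "magenta")


@dataclass
class PCView:
    """Principal-component scores of the selected signal columns.

    scores holds NaN for bins flagged unusable (any missing source value
    among the selected columns).
    """

    bins: GenomeBins
    scores: np.ndarray
    mask: np.ndarray  # True = unusable
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    datasets: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    @property
    def n_usable(self) -> int:
        return int((~self.mask).sum())

    def usable_scores(self) -> np.ndarray:
        return self.scores[~self.mask]

    def restrict(self, chromosomes: list[str]) -> "PCView":
        """View masked outside the given chromosomes (bin grid unchanged)."""
        keep = np.ones(self.bins.n_bins, dtype=bool)
        for c in self.bins.chromosomes:
            if c not in chromosomes:
                lo, hi = self.bins.chrom_range(c)
                keep[lo:hi] = False
        mask = self.mask | ~keep
        scores = np.where(mask[:, None], np.nan, self.scores)
        return PCView(self.bins, scores, mask, self.loadings,
                      self.explained_variance_ratio, self.datasets)


def pca_scores(
    signals: SignalMatrix, columns: list[str] | None = None, n_components: int = 2
) -> PCView:
    """Project the selected columns onto their first principal components.

    Columns are centered (mean 0) but not variance-scaled, matching the
    convention for pre-normalized log2 ratio data.  Bins with any masked
    value among the selected columns are excluded from the fit and
    flagged unusable.
    """
    sub = signals if columns is None else signals.subset(columns)
    if len(sub.datasets) < 2:
        raise ValueError("need at least 2 usable columns for PCA")
    mask = sub.mask.any(axis=1)
    usable = sub.values[~mask]
    if usable.shape[0] < n_components:
        raise ValueError(
            f"only {usable.shape[0]} usable bins for {n_components} components"
        )
    pca = PCA(n_components=n_components)
    fitted = pca.fit_transform(usable)
    scores = np.full((signals.bins.n_bins, n_components), np.nan)
    scores[~mask] = fitted
    return PCView(
        signals.bins, scores, mask, pca.components_.T,
        pca.explained_variance_ratio_, list(sub.datasets),
    )


@dataclass
class HMMModel:
    """Fitted Gaussian HMM: K states over PC-score dimensions."""

    K: int
    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray
    covars: np.ndarray
    log_likelihood: float
    seed: int
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isclose(self.startprob.sum(), 1.0):
            raise ValueError("initial probabilities must sum to 1")
        if not np.allclose(self.transmat.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")

    def to_hmmlearn(self) -> GaussianHMM:
        m = GaussianHMM(n_components=self.K, covariance_type="full")
        m.startprob_ = self.startprob
        m.transmat_ = self.transmat
        m.means_ = self.means
        m.covars_ = self.covars
        return m

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "means": self.means.tolist(),
            "covars": self.covars.tolist(),
            "log_likelihood": self.log_likelihood,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMModel":
        return cls(
            K=d["K"],
            startprob=np.array(d["startprob"]),
            transmat=np.array(d["transmat"]),
            means=np.array(d["means"]),
            covars=np.array(d["covars"]),
            log_likelihood=d["log_likelihood"],
            seed=d["seed"],
        )


@dataclass
class StatePath:
    """Per-bin decoded state indices; -1 marks missing bins."""

    states: np.ndarray
    K: int
    model_seed: int = 0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        usable = self.states[self.states >= 0]
        if usable.size and usable.max() >= self.K:
            raise ValueError("state index out of range")

    @property
    def missing(self) -> np.ndarray:
        return self.states < 0


@dataclass
class ReferenceAnchors:
    """Genomic reference points known to lie in interbands."""

    points: list[tuple[str, int, str]]  # (chrom, pos, name)

    def bin_indices(self, bins: GenomeBins) -> np.ndarray:
        return np.array([bins.bin_index(c, p) for c, p, _ in self.points])

    def __len__(self) -> int:
        return len(self.points)


def _usable_runs(view: PCView, chromosomes: list[str] | None = None):
    """Yield (global_start_bin, X) for contiguous runs of usable bins.

    Runs never span a chromosome boundary, so each chromosome is decoded
    independently and masked bins break the chain.
    """
    chroms = chromosomes or view.bins.chromosomes
    for c in chroms:
        lo, hi = view.bins.chrom_range(c)
        usable = ~view.mask[lo:hi]
        if not usable.any():
            continue
        bounds = np.flatnonzero(np.diff(np.concatenate(([0], usable.view(np.int8), [0]))))
        for s, e in zip(bounds[::2], bounds[1::2]):
            yield lo + s, view.scores[lo + s:lo + e]


def _init_model(X: np.ndarray, K: int, seed: int, tol: float, max_iter: int,
                min_covar: float) -> GaussianHMM:
    """K-means-seeded GaussianHMM with sticky uniform transitions."""
    d = X.shape[1]
    m = GaussianHMM(
        n_components=K, covariance_type="full", tol=tol, n_iter=max_iter,
        init_params="", params="stmc", random_state=seed, min_covar=min_covar,
    )
    m.startprob_ = np.full(K, 1.0 / K)
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9 if K > 1 else 1.0)
    m.transmat_ = A
    if K == 1:
        m.means_ = X.mean(axis=0, keepdims=True)
        m.covars_ = np.cov(X.T).reshape(1, d, d) + min_covar * np.eye(d)
        return m
    km = KMeans(n_clusters=K, n_init=3, random_state=seed).fit(X)
    m.means_ = km.cluster_centers_
    covs = []
    for k in range(K):
        pts = X[km.labels_ == k]
        c = np.cov(pts.T) if len(pts) > d else np.eye(d)
        if not np.all(np.linalg.eigvalsh(c) > 0):
            c = c + 0.1 * np.eye(d)
        covs.append(c + min_covar * np.eye(d))
    m.covars_ = np.array(covs)
    return m


def fit_hmm(
    view: PCView,
    K: int,
    seed: int,
    n_restarts: int = 5,
    tol: float = 1e-4,
    max_iter: int = 500,
    min_covar: float = 1e-6,
    chromosomes: list[str] | None = None,
) -> HMMModel:
    """Fit a K-state Gaussian HMM by Baum-Welch with seeded restarts.

    Each restart is initialized from k-means on the PC scores with a seed
    derived from `seed`; the model with the best final log-likelihood is
    returned.  Contiguous usable runs are treated as independent
    sequences.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    runs = list(_usable_runs(view, chromosomes))
    if not runs:
        raise ValueError("no usable bins to fit")
    X = np.concatenate([x for _, x in runs])
    lengths = [len(x) for _, x in runs]
    if X.shape[0] < 10 * K:
        raise ValueError(f"{X.shape[0]} usable bins < 10*K for K={K}")
    best = None
    for r in range(n_restarts):
        m = _init_model(X, K, seed + r, tol, max_iter, min_covar)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                m.fit(X, lengths)
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("restart %d failed for K=%d: %s", r, K, exc)
                continue
        trace = list(m.monitor_.history)
        score = m.score(X, lengths)
        if best is None or score > best[0]:
            best = (score, m, trace)
    if best is None:
        raise RuntimeError(f"Baum-Welch failed for all {n_restarts} restarts at K={K}")
    score, m, trace = best
    return HMMModel(
        K=K, startprob=m.startprob_, transmat=m.transmat_, means=m.means_,
        covars=m.covars_, log_likelihood=float(score), seed=seed,
        loglik_trace=[float(t) for t in trace],
    )


def viterbi_decode(
    model: HMMModel, view: PCView, chromosomes: list[str] | None = None
) -> StatePath:
    """Maximum-probability state sequence per contiguous usable run.

    Chromosomes are decoded independently; masked bins break the chain
    and receive the missing marker (-1).
    """
    if model.means.shape[1] != view.n_components:
        raise ValueError("model dimensionality does not match view")
    m = model.to_hmmlearn()
    states = np.full(view.bins.n_bins, -1, dtype=np.int64)
    chroms = chromosomes or view.bins.chromosomes
    any_usable = False
    for start, X in _usable_runs(view, chroms):
        states[start:start + len(X)] = m.predict(X)
        any_usable = True
    if not any_usable:
        warnings.warn("all bins masked; returning all-missing path")
    return StatePath(states, model.K, model.seed)


def calinski_harabasz(view: PCView, path: StatePath) -> float:
    """Variance-ratio criterion on PC scores with decoded labels.

    CH = [B/(K-1)] / [W/(n-K)] with between-cluster dispersion
    B = sum_k n_k ||c_k - c||^2 and within-cluster dispersion
    W = sum_k sum_{i in k} ||x_i - c_k||^2.  Returns +inf when W == 0.
    """
    usable = ~view.mask & ~path.missing
    X = view.scores[usable]
    labels = path.states[usable]
    K = path.K
    if K < 2:
        raise ValueError("Calinski-Harabasz requires K >= 2")
    n = len(X)
    counts = np.bincount(labels, minlength=K)
    if (counts == 0).any():
        empty = np.flatnonzero(counts == 0).tolist()
        raise ValueError(f"empty state(s) {empty}: criterion undefined")
    c = X.mean(axis=0)
    B = W = 0.0
    for k in range(K):
        pts = X[labels == k]
        ck = pts.mean(axis=0)
        B += len(pts) * float(((ck - c) ** 2).sum())
        W += float(((pts - ck) ** 2).sum())
    if W == 0.0:
        return np.inf
    if n <= K:
        raise ValueError(f"need more points ({n}) than states ({K})")
    return (B / (K - 1)) / (W / (n - K))


@dataclass
class ModelSelectionRecord:
    """Per-K Calinski-Harabasz scores and anchor-consistency flags."""

    table: pd.DataFrame  # columns: K, ch, anchor_consistent, n_anchor_states, log_likelihood
    chosen_K: int


def select_state_count(
    view: PCView,
    anchors: ReferenceAnchors,
    seed: int,
    k_range: range = range(2, 16),
    train_chromosomes: list[str] | None = None,
    n_restarts: int = 1,
    tol: float = 1e-2,
    max_iter: int = 30,
) -> tuple[HMMModel, ModelSelectionRecord]:
    """Choose the state count K by anchor-constrained CH maximization.

    For each K in `k_range` an HMM is fitted and decoded on the training
    chromosome(s); CH(K) is recorded together with whether all anchor
    bins share one decoded state.  The chosen K maximizes CH among
    anchor-consistent candidates.  Raises, listing the per-K anchor
    spread, when no candidate is anchor-consistent.
    """
    train = view if train_chromosomes is None else view.restrict(train_chromosomes)
    anchor_bins = anchors.bin_indices(view.bins)
    if train.mask[anchor_bins].any():
        bad = [anchors.points[i] for i in np.flatnonzero(train.mask[anchor_bins])]
        raise ValueError(f"anchors not resolvable to usable training bins: {bad}")
    rows, models = [], {}
    for K in k_range:
        try:
            model = fit_hmm(train, K, seed, n_restarts=n_restarts, tol=tol,
                            max_iter=max_iter)
            path = viterbi_decode(model, train)
            anchor_states = np.unique(path.states[anchor_bins])
            consistent = len(anchor_states) == 1 and anchor_states[0] >= 0
            ch = calinski_harabasz(train, path)
        except (ValueError, RuntimeError) as exc:
            logger.warning("K=%d skipped: %s", K, exc)
            rows.append({"K": K, "ch": np.nan, "anchor_consistent": False,
                         "n_anchor_states": -1, "log_likelihood": np.nan})
            continue
        models[K] = model
        rows.append({
            "K": K, "ch": ch, "anchor_consistent": bool(consistent),
            "n_anchor_states": int(len(anchor_states)),
            "log_likelihood": model.log_likelihood,
        })
    table = pd.DataFrame(rows)
    ok = table[table["anchor_consistent"] & table["ch"].notna()]
    if ok.empty:
        spread = table[["K", "n_anchor_states"]].to_dict("records")
        raise ValueError(f"no anchor-consistent state count; anchor spread per K: {spread}")
    chosen_K = int(ok.loc[ok["ch"].idxmax(), "K"])
    return models[chosen_K], ModelSelectionRecord(table, chosen_K)


@dataclass
class StateFragments:
    """Merged same-state genomic intervals with summary statistics."""

    df: pd.DataFrame  # chrom, start, end, state (sorted, non-overlapping)
    bins: GenomeBins | None = None

    @property
    def states(self) -> list[str]:
        return sorted(self.df["state"].unique())

    def summary(self) -> pd.DataFrame:
        """Per-state fragment count, genome fraction and size statistics.

        Genome fractions are computed over the data-covered genome (the
        total span of all fragments), so they sum to 1.
        """
        df = self.df.assign(size=self.df["end"] - self.df["start"])
        covered = df["size"].sum()
        rows = []
        for state, g in df.groupby("state"):
            rows.append({
                "state": state,
                "n_fragments": len(g),
                "genome_fraction": g["size"].sum() / covered,
                "min_size": int(g["size"].min()),
                "mean_size": float(g["size"].mean()),
                "max_size": int(g["size"].max()),
            })
        return pd.DataFrame(rows).set_index("state")

    def genome_fractions_pct(self) -> dict[str, float]:
        s = self.summary()["genome_fraction"] * 100.0
        return s.to_dict()

    def to_bed(self, path) -> None:
        from .genomic_io import write_state_track

        write_state_track(self, path)


def path_to_fragments(
    path: StatePath, bins: GenomeBins, names: dict[int, str]
) -> StateFragments:
    """Run-length merge consecutive same-state bins into fragments."""
    rows = []
    ends = bins.bin_ends()
    for c in bins.chromosomes:
        lo, hi = bins.chrom_range(c)
        s = path.states[lo:hi]
        if not len(s):
            continue
        change = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate(([0], change))
        stops = np.concatenate((change, [len(s)]))
        for a, b in zip(starts, stops):
            if s[a] < 0:
                continue
            rows.append({
                "chrom": c,
                "start": int(a * bins.width),
                "end": int(ends[lo + b - 1]),
                "state": names[int(s[a])],
            })
    return StateFragments(pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]), bins)


def name_states(
    path: StatePath,
    anchors: ReferenceAnchors,
    signals: SignalMatrix,
    interband_markers: list[str],
    polii_markers: list[str],
) -> dict[int, str]:
    """Map decoded state indices to color names.

    The state containing all anchors is "cyan".  Among the rest, the
    state with the lowest mean over the interband-marker columns is
    "magenta"; of the remaining two, the one with the higher RNA
    polymerase II mean is "blue" (transcribed gene bodies lacking CHRIZ)
    and the last is "green".  Ties break by state index.
    """
    anchor_bins = anchors.bin_indices(signals.bins)
    anchor_states = np.unique(path.states[anchor_bins])
    anchor_states = anchor_states[anchor_states >= 0]
    if len(anchor_states) != 1:
        raise ValueError(
            f"anchors decode to {len(anchor_states)} states {anchor_states.tolist()}; "
            "selection/decoding inconsistency"
        )
    cyan = int(anchor_states[0])
    if path.K == 1:
        return {cyan: "cyan"}

    def state_mean(k: int, cols: list[str]) -> float:
        sel = path.states == k
        vals = [np.nanmean(signals.column(c)[sel]) for c in cols]
        return float(np.nanmean(vals))

    rest = [k for k in range(path.K) if k != cyan]
    magenta = min(rest, key=lambda k: (state_mean(k, interband_markers), k))
    rest = [k for k in rest if k != magenta]
    names = {cyan: "cyan", magenta: "magenta"}
    if rest:
        blue = max(rest, key=lambda k: (state_mean(k, polii_markers), -k))
        names[blue] = "blue"
        for k in rest:
            if k != blue:
                names[k] = f"green{k}" if len(rest) > 2 else "green"
    # with K=4 exactly one green remains; larger K keeps indexed names
    if len(rest) > 2:
        greens = sorted(k for k in rest if names.get(k, "").startswith("green"))
        for i, k in enumerate(greens):
            names[k] = f"green{i + 1}"
    return names


def anchor_and_extract(
    path: StatePath,
    bins: GenomeBins,
    anchors: ReferenceAnchors,
    signals: SignalMatrix,
    interband_markers: list[str],
    polii_markers: list[str],
) -> StateFragments:
    """Name states by the anchor/marker convention and extract fragments."""
    names = name_states(path, anchors, signals, interband_markers, polii_markers)
    for k in range(path.K):
        names.setdefault(k, f"state{k}")
    return path_to_fragments(path, bins, names)
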