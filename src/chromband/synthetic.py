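"""Truth-labeled synthetic inputs with the statistical structure the
pipeline assumes.

The generator emulates a small (default 10 Mb, five-arm) genome:

* a Markovian four-state chromatin annotation over 200-bp bins whose
  stationary fractions (12.7 / 16.8 / 22.5 / 48.0 %) and mean segment
  lengths (2.7 / 4.9 / 3.1 / 11.2 kb for cyan / blue / green / magenta)
  follow the genome-wide statistics of the reference segmentation;
* correlated multi-protein log2 signal tracks (12 interband-cluster
  "proteins" across two pseudo cell lines plus 6 repressive datasets)
  with state-specific multivariate normal emissions and shared missing
  data gaps;
* state-dependent genomic features: transposon insertions (cyan
  intensity 6.2x the genome baseline), DHS / ORC2 / H1-dip sites,
  domain-boundary points, promoters with broad/peaked shape classes;
* gene models including divergent head-to-head pairs whose 5' ends are
  placed in states at the reference proportions, plus a curated list of
  interband intervals and of large "intercalary heterochromatin"
  fragments;
* a genes x tissues expression table in which interband/cyan genes are
  broadly and highly expressed and IH/magenta genes narrowly and lowly
  expressed (configured per-class medians follow the reference values).

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genomic_io import (
    FeatureSet,
    GeneModels,
    GenomeBins,
    SignalMatrix,
    build_bins,
)
from .state_model import ReferenceAnchors, StateFragments, StatePath, path_to_fragments

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimAnnotations",
    "transition_matrix",
    "simulate_truth",
    "simulate_signals",
    "simulate_annotations",
    "simulate_all",
    "write_sim_dir",
]

STATES = ("cyan", "blue", "green", "magenta")

# interband-cluster datasets: 6 proteins x 2 pseudo cell lines
INTERBAND_DATASETS = (
    "CHRIZ_S2", "CHRIZ_Kc", "RNAPII_S2", "RNAPII_Kc", "NURF301_S2", "ISWI_Kc",
    "WDS_S2", "JIL1_Kc", "MLE_S2", "MOF_Kc", "MRG15_S2", "MBD_Kc",
)
REPRESSIVE_DATASETS = ("H1_Kc", "H1_S2", "SUUR_S2", "LAMIN_Kc", "D1_S2", "HP1A_Kc")
CHRIZ_DATASETS = ("CHRIZ_S2", "CHRIZ_Kc")
POLII_DATASETS = ("RNAPII_S2", "RNAPII_Kc")

# latent 2-D state positions, in units of the projected noise sd: a
# diamond whose nearest-neighbor distance 3.9 puts the per-bin Bayes
# error near 5% (each state has two neighbors at 2 * Phi(-3.9/2) ~ 0.05);
# axis 1 is overall interband-protein occupancy (cyan high, magenta low),
# axis 2 the polII-vs-CHRIZ contrast separating blue from green
_LATENT = {
    "cyan": (2.76, 0.0),
    "blue": (0.0, 2.76),
    "green": (0.0, -2.76),
    "magenta": (-2.76, 0.0),
}


def default_state_means() -> pd.DataFrame:
    """Per-dataset, per-state log2 emission means (datasets x states).

    Interband-cluster datasets load on an "occupancy" axis (all high in
    cyan, all low in magenta) and a CHRIZ-vs-polII contrast axis that
    gives the blue state its polII-rich, CHRIZ-poor profile; repressive
    datasets run against the occupancy axis.
    """
    occ = 1.0 / np.sqrt(len(INTERBAND_DATASETS))
    rows = {}
    for d in INTERBAND_DATASETS:
        if d in CHRIZ_DATASETS:
            contrast = -0.5
        elif d in POLII_DATASETS:
            contrast = 0.5
        else:
            contrast = 0.0
        rows[d] = [_LATENT[s][0] * occ + _LATENT[s][1] * contrast for s in STATES]
    for d in REPRESSIVE_DATASETS:
        rows[d] = [-0.25 * _LATENT[s][0] for s in STATES]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(STATES))


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults mirror the reference segmentation's state statistics and
    feature distributions; see the per-field comments.
    """

    # five euchromatic pseudo-arms, 10 Mb total
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {
        "chrX": 2_200_000, "chr2L": 2_300_000, "chr2R": 1_800_000,
        "chr3L": 1_900_000, "chr3R": 1_800_000,
    })
    bin_width: int = 200
    states: tuple[str, ...] = STATES
    # stationary genome fractions and mean fragment sizes per state
    fractions: tuple[float, ...] = (0.127, 0.168, 0.225, 0.480)
    mean_segment_kb: tuple[float, ...] = (2.7, 4.9, 3.1, 11.2)
    # emission model
    noise_sd: float = 1.0
    shared_factor_sd: float = 0.3
    # missing-data gaps shared by all datasets
    gap_fraction: float = 0.02
    mean_gap_kb: float = 1.0
    # reference anchors (interband P-element insertion sites)
    n_anchors: int = 12
    train_chromosome: str = "chrX"
    # features: intensity relative to the genome baseline, or state shares
    n_insertions: int = 3889
    insertion_intensity: tuple[float, ...] = (6.2, 1 / 6.0, 1 / 2.0, 1 / 9.1)
    n_dhs: int = 800
    dhs_shares: tuple[float, ...] = (85.6, 8.0, 4.4, 2.0)
    n_orc2: int = 600
    orc2_shares: tuple[float, ...] = (91.4, 5.0, 2.6, 1.0)
    n_h1_dips: int = 800
    h1_dip_shares: tuple[float, ...] = (46.9, 25.0, 18.1, 10.0)
    n_boundaries: int = 300
    boundary_shares: tuple[float, ...] = (45.0, 24.0, 16.0, 15.0)
    # promoters
    n_broad_promoters: int = 770
    broad_shares: tuple[float, ...] = (83.6, 6.4, 5.5, 4.5)
    n_peaked_promoters: int = 450
    peaked_shares: tuple[float, ...] = (25.0, 15.0, 20.0, 40.0)
    n_unknown_promoters: int = 80
    promoter_width: int = 150
    # curated interval lists
    n_curated_interbands: int = 32
    n_interbands_with_broad: int = 26
    n_ih_bands: int = 40
    # gene models
    n_hh_pairs: int = 600          # head-to-head pairs within the gap window
    n_hh_pairs_far: int = 40       # divergent pairs beyond the window
    hh_tss_shares: tuple[float, ...] = (60.4, 1.4, 13.4, 22.6)
    n_single_genes: int = 550
    single_tss_shares: tuple[float, ...] = (42.0, 15.0, 18.0, 25.0)
    max_gap: int = 2000
    # expression
    n_adult_tissues: int = 17
    n_larval_tissues: int = 8
    expr_median_interband: float = 112.0
    expr_median_cyan: float = 100.4
    expr_median_ih: float = 4.2
    expr_median_magenta: float = 4.8
    expr_median_other: float = 30.0
    presence_prob: dict[str, float] = field(default_factory=lambda: {
        "cyan": 0.95, "blue": 0.6, "green": 0.6, "magenta": 0.25,
    })
    gene_sd: float = 0.6           # log-normal sd of per-gene level
    tissue_sd: float = 0.5         # log-normal sd of per-tissue factor
    absent_median: float = 0.5     # value scale when a gene is off in a tissue

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.fractions), 1.0):
            raise ValueError("state fractions must sum to 1")
        if any(m * 1000 < self.bin_width for m in self.mean_segment_kb):
            raise ValueError("mean segment lengths must be >= bin width")
        if not all(0 <= p <= 1 for p in self.presence_prob.values()):
            raise ValueError("presence probabilities must lie in [0, 1]")

    @property
    def datasets(self) -> list[str]:
        return list(INTERBAND_DATASETS) + list(REPRESSIVE_DATASETS)

    def state_means(self) -> pd.DataFrame:
        return default_state_means()

    def bins(self) -> GenomeBins:
        return build_bins(self.chrom_sizes, self.bin_width)


def transition_matrix(
    fractions: np.ndarray, mean_segment_bins: np.ndarray, n_iter: int = 300
) -> np.ndarray:
    """Markov transition matrix with given mean run lengths and
    stationary occupancy.

    Self-transition probabilities are fixed at 1 - 1/m_k (geometric run
    lengths with the requested means); the jump distribution is solved by
    fixed-point iteration so the stationary distribution matches the
    requested fractions.
    """
    pi = np.asarray(fractions, dtype=float)
    m = np.asarray(mean_segment_bins, dtype=float)
    K = len(pi)
    if np.any(m < 1):
        raise ValueError("mean segment length below one bin")
    leave = 1.0 / m

    def stationary(A: np.ndarray) -> np.ndarray:
        M = np.vstack([A.T - np.eye(K), np.ones(K)])
        b = np.concatenate([np.zeros(K), [1.0]])
        return np.linalg.lstsq(M, b, rcond=None)[0]

    w = pi * leave
    for _ in range(n_iter):
        A = np.zeros((K, K))
        for k in range(K):
            others = np.delete(np.arange(K), k)
            A[k, others] = leave[k] * w[others] / w[others].sum()
            A[k, k] = 1.0 - leave[k]
        stat = stationary(A)
        if np.allclose(stat, pi, rtol=0, atol=1e-12):
            break
        w = w * (pi / stat)
    if not np.allclose(stat, pi, rtol=0, atol=1e-6):
        raise ValueError(
            f"infeasible fraction/length combination: stationary {stat} vs target {pi}"
        )
    return A


@dataclass
class SimTruth:
    """Ground truth of one simulated genome."""

    config: SimConfig
    bins: GenomeBins
    path: StatePath                       # true per-bin states (0..K-1)
    fragments: StateFragments             # true merged fragments
    anchors: ReferenceAnchors
    mask: np.ndarray                      # True = missing-data bin
    seed: int

    def state_fractions(self) -> dict[str, float]:
        widths = self.bins.bin_widths()
        total = widths.sum()
        return {
            s: float(widths[self.path.states == i].sum() / total)
            for i, s in enumerate(STATES)
        }


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def simulate_truth(config: SimConfig, seed: int) -> SimTruth:
    """Sample the true state path, fragments, gaps and anchors."""
    rng = _rng(seed, 0)
    bins = config.bins()
    K = len(config.states)
    fractions = np.array(config.fractions)
    active = np.flatnonzero(fractions > 0)
    states = np.empty(bins.n_bins, dtype=np.int64)
    if len(active) == 1:
        states[:] = active[0]
    else:
        m_bins = np.array(config.mean_segment_kb) * 1000.0 / config.bin_width
        A = transition_matrix(fractions[active], m_bins[active])
        jump = A.copy()
        np.fill_diagonal(jump, 0.0)
        jump = jump / jump.sum(axis=1, keepdims=True)
        for c in bins.chromosomes:
            lo, hi = bins.chrom_range(c)
            pos = lo
            a = rng.choice(len(active), p=fractions[active])
            while pos < hi:
                length = rng.geometric(1.0 / m_bins[active[a]])
                states[pos:min(pos + length, hi)] = active[a]
                pos += length
                a = rng.choice(len(active), p=jump[a])
    # shared missing-data gaps
    mask = np.zeros(bins.n_bins, dtype=bool)
    mean_gap_bins = config.mean_gap_kb * 1000.0 / config.bin_width
    n_gaps = int(round(config.gap_fraction * bins.n_bins / mean_gap_bins))
    if n_gaps:
        gap_starts = rng.integers(0, bins.n_bins, size=n_gaps)
        gap_lens = rng.geometric(1.0 / mean_gap_bins, size=n_gaps)
        for g0, gl in zip(gap_starts, gap_lens):
            mask[g0:g0 + gl] = True
    path = StatePath(states, K, model_seed=seed)
    names = {i: s for i, s in enumerate(config.states)}
    fragments = path_to_fragments(path, bins, names)
    anchors = _place_anchors(config, bins, states, mask, rng)
    return SimTruth(config, bins, path, fragments, anchors, mask, seed)


def _place_anchors(config, bins, states, mask, rng) -> ReferenceAnchors:
    """Put anchors at the midpoints of the largest unmasked cyan
    fragments of the training chromosome."""
    lo, hi = bins.chrom_range(config.train_chromosome)
    cyan = 0
    s = states[lo:hi]
    change = np.flatnonzero(np.diff(s)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(s)]))
    frags = [(b - a, a, b) for a, b in zip(starts, stops) if s[a] == cyan]
    frags.sort(reverse=True)
    points = []
    for length, a, b in frags:
        mid = lo + (a + b) // 2
        cand = [mid] + list(range(lo + a, lo + b))
        usable = next((i for i in cand if not mask[i]), None)
        if usable is None:
            continue
        chrom, bs, be = bins.interval(usable)
        points.append((chrom, (bs + be) // 2, f"anchor{len(points) + 1:02d}"))
        if len(points) == config.n_anchors:
            break
    if len(points) < config.n_anchors:
        raise ValueError("too few usable cyan fragments for the requested anchors")
    return ReferenceAnchors(sorted(points, key=lambda p: p[1]))


def simulate_signals(truth: SimTruth, config: SimConfig | None = None,
                     seed: int | None = None) -> SignalMatrix:
    """Per-bin multivariate normal log2 emissions for every dataset.

    The state covariance is noise_sd^2 * I plus a rank-one shared-factor
    term (shared_factor_sd^2) correlating all datasets within a bin, the
    kind of common track-wide variation array platforms produce.
    """
    config = config or truth.config
    seed = truth.seed if seed is None else seed
    rng = _rng(seed, 1)
    means = config.state_means().loc[config.datasets].to_numpy()  # datasets x states
    if config.noise_sd < 0 or config.shared_factor_sd < 0:
        raise ValueError("emission sds must be non-negative")
    n, d = truth.bins.n_bins, len(config.datasets)
    mu = means.T[truth.path.states]  # n x d
    shared = rng.normal(0.0, 1.0, size=(n, 1)) * config.shared_factor_sd
    noise = rng.normal(0.0, config.noise_sd, size=(n, d))
    values = mu + shared + noise
    mask = np.repeat(truth.mask[:, None], d, axis=1)
    return SignalMatrix(truth.bins, config.datasets, values, mask)


# ---------------------------------------------------------------------------
# annotations


@dataclass
class SimAnnotations:
    """Feature sets, gene models, curated lists and expression table."""

    insertions: FeatureSet
    dhs: FeatureSet
    orc2: FeatureSet
    h1_dips: FeatureSet
    boundaries: FeatureSet
    promoters: FeatureSet
    interbands: FeatureSet
    ih_bands: FeatureSet
    genes: GeneModels
    gene_labels: pd.DataFrame  # gene_id, tss_state, band_class
    expression: "ExpressionTableProxy"


def _state_bin_weights(truth: SimTruth, shares: np.ndarray | None,
                       intensity: np.ndarray | None) -> np.ndarray:
    """Per-bin sampling weights from state shares or relative intensity.

    With `shares`, the expected fraction of features per state equals the
    share exactly; with `intensity`, each state's per-bp rate is the
    given multiple of the genome-average rate.
    """
    states = truth.path.states
    if shares is not None:
        shares = np.asarray(shares, dtype=float)
        counts = np.bincount(states, minlength=len(STATES)).astype(float)
        w = shares / np.maximum(counts, 1)
    else:
        w = np.asarray(intensity, dtype=float)
    return w[states]


def _sample_points(truth: SimTruth, n: int, rng, shares=None, intensity=None,
                   width: int = 1, prefix: str = "f", attr: str = "",
                   exclude: FeatureSet | None = None) -> FeatureSet:
    """Inhomogeneous sampling of point/interval features by state weights."""
    w = _state_bin_weights(truth, shares, intensity)
    if w.sum() <= 0:
        warnings.warn("zero total feature intensity; returning empty feature set")
        return FeatureSet(pd.DataFrame(columns=FeatureSet.COLUMNS))
    p = w / w.sum()
    ends = truth.bins.bin_ends()
    starts_bp = truth.bins.bin_starts()
    chroms = truth.bins.bin_chrom()
    excl = []
    if exclude is not None:
        excl = list(exclude.df[["chrom", "start", "end"]].itertuples(index=False))
    rows = []
    while len(rows) < n:
        take = n - len(rows)
        idx = rng.choice(truth.bins.n_bins, size=take, p=p)
        offs = rng.integers(0, np.maximum(ends[idx] - starts_bp[idx], 1))
        for b, o in zip(idx, offs):
            pos = int(starts_bp[b] + o)
            chrom = chroms[b]
            if any(c == chrom and s <= pos < e for c, s, e in excl):
                continue
            size = truth.bins.chrom_sizes[chrom]
            end = min(pos + width, size)
            if end <= pos:
                continue
            rows.append((chrom, pos, end, ".", f"{prefix}{len(rows) + 1:05d}", attr))
    df = pd.DataFrame(rows, columns=FeatureSet.COLUMNS)
    return FeatureSet(df.sort_values(["chrom", "start"]).reset_index(drop=True))


def _top_fragments(truth: SimTruth, state: str, n: int, prefix: str) -> FeatureSet:
    df = truth.fragments.df
    g = df[df["state"] == state].copy()
    g["size"] = g["end"] - g["start"]
    g = g.sort_values(["size", "chrom", "start"], ascending=[False, True, True]).head(n)
    g = g.sort_values(["chrom", "start"]).reset_index(drop=True)
    return FeatureSet(pd.DataFrame({
        "chrom": g["chrom"], "start": g["start"], "end": g["end"],
        "strand": ".", "name": [f"{prefix}{i + 1:02d}" for i in range(len(g))],
        "attr": "",
    }))


class _Occupancy:
    """Per-chromosome sorted interval lists for overlap-free placement.

    `conflicts` checks the candidate span expanded by `margin` so that
    independently placed genes keep at least `margin` bp of clearance;
    keeping the margin at the bidirectional-promoter gap window prevents
    unintended divergent pairs from arising between unrelated genes.
    """

    def __init__(self):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def conflicts(self, chrom: str, start: int, end: int, margin: int = 0) -> bool:
        starts = self._starts.get(chrom, [])
        if not starts:
            return False
        i = bisect.bisect_left(starts, end + margin)
        return i > 0 and self._ends[chrom][i - 1] > start - margin

    def add(self, chrom: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect.bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


def _gene_length(rng, lo: int = 400, hi: int = 6000) -> int:
    return int(np.clip(rng.lognormal(np.log(1200), 0.7), lo, hi))


def _fragments_of_state(truth: SimTruth, state_idx: int) -> list[tuple[str, int, int]]:
    name = STATES[state_idx]
    df = truth.fragments.df
    g = df[df["state"] == name]
    return list(g[["chrom", "start", "end"]].itertuples(index=False, name=None))


def simulate_genes(truth: SimTruth, config: SimConfig, rng) -> tuple[GeneModels, pd.DataFrame]:
    """Gene models with head-to-head pairs and state-targeted 5' ends.

    Head-to-head pairs are placed so that both facing 5' ends fall inside
    one fragment of the target state, with the intergenic gap inside
    (or, for the flagged far pairs, beyond) the bidirectional-promoter
    window; remaining genes are singles whose bodies fit inside a
    fragment of their target state.
    """
    occ = _Occupancy()
    frag_by_state = {k: _fragments_of_state(truth, k) for k in range(len(STATES))}
    frag_w = {k: np.array([e - s for _, s, e in v], dtype=float)
              for k, v in frag_by_state.items()}
    rows, label_rows = [], []
    gid = 0

    def new_id() -> str:
        nonlocal gid
        gid += 1
        return f"g{gid:05d}"

    def add_gene(chrom, start, end, strand, tss_state):
        g = new_id()
        rows.append({"gene_id": g, "chrom": chrom, "start": int(start),
                     "end": int(end), "strand": strand})
        occ.add(chrom, int(start), int(end))
        label_rows.append({"gene_id": g, "tss_state": STATES[tss_state]})
        return g

    hh_shares = np.array(config.hh_tss_shares) / sum(config.hh_tss_shares)
    for far in (False, True):
        n_pairs = config.n_hh_pairs_far if far else config.n_hh_pairs
        for _ in range(n_pairs):
            placed = False
            # target state drawn once so placement failure cannot bias
            # the realized state shares toward roomier states
            s_idx = rng.choice(len(STATES), p=hh_shares)
            for _attempt in range(500):
                frags = frag_by_state[s_idx]
                if not frags:
                    break
                gap = int(rng.integers(2200, 6000)) if far else int(rng.integers(150, 1800))
                w = frag_w[s_idx]
                ok = w >= gap + 400
                if far:
                    # far pairs cannot share one fragment of most states;
                    # anchor only the left 5' end in the target state
                    ok = w >= 400
                if not ok.any():
                    continue
                pw = w * ok
                fi = rng.choice(len(frags), p=pw / pw.sum())
                chrom, fs, fe = frags[fi]
                if far:
                    p1 = int(rng.integers(fs + 100, fe - 100))
                    p2 = p1 + gap
                    if p2 >= truth.bins.chrom_sizes[chrom] - 100:
                        continue
                else:
                    p1 = int(rng.integers(fs + 100, fe - gap - 100))
                    p2 = p1 + gap
                L1, L2 = _gene_length(rng), _gene_length(rng)
                b1 = (max(0, p1 - L1 + 1), p1 + 1)          # - strand, 5' at p1
                b2 = (p2, min(p2 + L2, truth.bins.chrom_sizes[chrom]))  # + strand
                if b1[1] - b1[0] < 400 or b2[1] - b2[0] < 400:
                    continue
                if occ.conflicts(chrom, b1[0], b2[1]):
                    continue
                add_gene(chrom, b1[0], b1[1], "-", s_idx)
                s2 = s_idx if not far else int(truth.path.states[truth.bins.bin_index(chrom, p2)])
                add_gene(chrom, b2[0], b2[1], "+", s2)
                if b2[0] > b1[1]:
                    # reserve the intergenic gap: no gene body may come
                    # between the members of a divergent pair
                    occ.add(chrom, b1[1], b2[0])
                placed = True
                break
            if not placed:
                warnings.warn("could not place a head-to-head pair; genome too crowded")
    single_shares = np.array(config.single_tss_shares) / sum(config.single_tss_shares)
    n_failed = 0
    for _ in range(config.n_single_genes):
        # the 5' end anchors in the target state; the gene body extends
        # outward (interband genes keep only their regulatory 5' part in
        # open chromatin), except magenta genes which sit fully inside a
        # fragment, emulating genes buried in heterochromatin bands
        s_idx = rng.choice(len(STATES), p=single_shares)
        body_inside = STATES[s_idx] == "magenta"
        placed = False
        for _attempt in range(500):
            frags = frag_by_state[s_idx]
            L = _gene_length(rng)
            w = frag_w[s_idx]
            ok = w >= (L + 200 if body_inside else 400)
            if not ok.any():
                continue
            pw = w * ok
            fi = rng.choice(len(frags), p=pw / pw.sum())
            chrom, fs, fe = frags[fi]
            # singles sit on the + strand so no unintended divergent
            # (-,+) adjacency can form between independently placed genes
            strand = "+"
            if body_inside:
                start = int(rng.integers(fs + 100, fe - L - 100 + 1))
                end = start + L
            else:
                tss = int(rng.integers(fs + 100, fe - 100))
                start, end = tss, min(tss + L, truth.bins.chrom_sizes[chrom])
                if end - start < 400:
                    continue
            if occ.conflicts(chrom, start, end):
                continue
            add_gene(chrom, start, end, strand, s_idx)
            placed = True
            break
        n_failed += not placed
    if n_failed:
        warnings.warn(f"could not place {n_failed} single genes; genome too crowded")
    genes = GeneModels(pd.DataFrame(rows).sort_values(
        ["chrom", "start"], kind="stable").reset_index(drop=True))
    labels = pd.DataFrame(label_rows)
    return genes, labels


def _band_class(genes: GeneModels, interbands: FeatureSet, ih_bands: FeatureSet) -> pd.Series:
    """Label genes as interband (5' inside a curated interband), IH_band
    (body fully inside an IH fragment) or other."""
    tss = genes.tss()
    out = pd.Series("other", index=genes.df["gene_id"])
    for iv in interbands.df.itertuples(index=False):
        sel = (genes.df["chrom"] == iv.chrom).to_numpy()
        pos = tss.to_numpy()
        hit = sel & (pos >= iv.start) & (pos < iv.end)
        out.iloc[np.flatnonzero(hit)] = "interband"
    for iv in ih_bands.df.itertuples(index=False):
        sel = (genes.df["chrom"] == iv.chrom).to_numpy()
        inside = sel & (genes.df["start"].to_numpy() >= iv.start) \
            & (genes.df["end"].to_numpy() <= iv.end)
        hit = inside & (out == "other").to_numpy()
        out.iloc[np.flatnonzero(hit)] = "IH_band"
    return out


class _MedianCalibrator:
    """Solve per-class scale parameters so the median of per-gene mean
    expression hits its configured target.

    The per-gene mean across a tissue panel is a skewed functional of
    the presence process and tissue noise, so the inversion is done
    against a fixed reference sample (deterministic internal draws): for
    scale m, per-gene means are m * exp(sigma_g Z) * S/n + T/n with S
    the sum of present-tissue factors and T the off-tissue background.
    """

    N = 60_000

    def __init__(self, config: "SimConfig"):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([987654321]))
        n_t = config.n_adult_tissues + config.n_larval_tissues
        self.Z = rng.normal(size=self.N)
        self.factors = rng.lognormal(-config.tissue_sd ** 2 / 2, config.tissue_sd,
                                     size=(self.N, n_t))
        self.off = rng.lognormal(np.log(config.absent_median), config.tissue_sd,
                                 size=(self.N, n_t))
        self.present = {
            round(p, 6): rng.random((self.N, n_t)) < p
            for p in set(config.presence_prob.values())
        }
        self.n_t = n_t

    def per_gene_means(self, m: float, p: float) -> np.ndarray:
        pres = self.present[round(p, 6)]
        level = m * np.exp(self.config.gene_sd * self.Z)
        on = (self.factors * pres).sum(axis=1)
        offsum = (self.off * ~pres).sum(axis=1)
        return (level * on + offsum) / self.n_t

    def solve(self, target: float, p: float) -> float:
        f = lambda logm: np.median(self.per_gene_means(np.exp(logm), p)) - target
        return float(np.exp(brentq(f, np.log(target) - 9, np.log(target) + 9)))

    def solve_rest(self, pool_target: float, m_sub: float, w_sub: float,
                   p: float) -> float:
        """Scale for the non-curated remainder of a state class so the
        pooled (sub + rest) median matches the class target."""
        if w_sub <= 0:
            return self.solve(pool_target, p)
        if w_sub >= 1:
            return self.solve(pool_target, p)
        n_sub = int(round(w_sub * self.N))
        sub_vals = self.per_gene_means(m_sub, p)[:n_sub]

        def f(logm):
            rest = self.per_gene_means(np.exp(logm), p)[n_sub:]
            return np.median(np.concatenate([sub_vals, rest])) - pool_target

        lo, hi = np.log(pool_target) - 9, np.log(pool_target) + 9
        if f(lo) * f(hi) > 0:
            return self.solve(pool_target, p)
        return float(np.exp(brentq(f, lo, hi)))


from .expression_analysis import ExpressionTable as ExpressionTableProxy  # noqa: E402


def simulate_expression(config: SimConfig, gene_labels: pd.DataFrame, rng
                        ) -> ExpressionTableProxy:
    """Genes x tissues table with class-dependent level and breadth.

    Per-gene levels are log-normal around class medians chosen so that
    the median of per-gene mean expression reproduces the configured
    class values (including the curated interband / IH subsets nested
    inside the cyan / magenta classes); presence in each tissue is
    Bernoulli with the class probability, absent tissues showing only
    background-level values.
    """
    adult = [f"adult{i + 1:02d}" for i in range(config.n_adult_tissues)]
    larval = [f"larval{i + 1:02d}" for i in range(config.n_larval_tissues)]
    conds = adult + larval
    cal = _MedianCalibrator(config)
    lbl = gene_labels.set_index("gene_id")
    tss_state = lbl["tss_state"]
    band = lbl["band_class"]
    p_cyan = config.presence_prob["cyan"]
    p_mag = config.presence_prob["magenta"]
    # nested-class solve: curated subsets keep their own medians, the rest
    # of the state class is adjusted so the pooled median hits its target
    targets: dict[str, tuple[float, float]] = {}
    for state, p, sub_label, sub_target, pool_target in (
        ("cyan", p_cyan, "interband", config.expr_median_interband, config.expr_median_cyan),
        ("magenta", p_mag, "IH_band", config.expr_median_ih, config.expr_median_magenta),
    ):
        in_state = tss_state == state
        w_sub = float((band[in_state] == sub_label).mean()) if in_state.any() else 0.0
        sub_mu = cal.solve(sub_target, p)
        rest_mu = cal.solve_rest(pool_target, sub_mu, w_sub, p)
        targets[state] = (sub_mu, rest_mu)
    mu_other = {
        s: cal.solve(config.expr_median_other, config.presence_prob[s])
        for s in ("blue", "green")
    }
    values = np.empty((len(lbl), len(conds)))
    for i, (gene, state) in enumerate(tss_state.items()):
        p = config.presence_prob[state]
        if state == "cyan":
            mu = targets["cyan"][0] if band.loc[gene] == "interband" else targets["cyan"][1]
        elif state == "magenta":
            mu = targets["magenta"][0] if band.loc[gene] == "IH_band" else targets["magenta"][1]
        else:
            mu = mu_other[state]
        level = rng.lognormal(np.log(mu), config.gene_sd)
        present = rng.random(len(conds)) < p
        tissue = rng.lognormal(-config.tissue_sd ** 2 / 2, config.tissue_sd, len(conds))
        off = rng.lognormal(np.log(config.absent_median), config.tissue_sd, len(conds))
        values[i] = np.where(present, level * tissue, off)
    table = pd.DataFrame(values, index=tss_state.index, columns=conds)
    return ExpressionTableProxy(table, {"adult": adult, "larval": larval})


def simulate_annotations(truth: SimTruth, config: SimConfig | None = None,
                         seed: int | None = None) -> SimAnnotations:
    """Generate all feature sets, gene models and the expression table."""
    config = config or truth.config
    seed = truth.seed if seed is None else seed
    rng = _rng(seed, 2)
    insertions = _sample_points(
        truth, config.n_insertions, rng,
        intensity=np.array(config.insertion_intensity), prefix="ins")
    dhs = _sample_points(truth, config.n_dhs, rng,
                         shares=np.array(config.dhs_shares), prefix="dhs")
    orc2 = _sample_points(truth, config.n_orc2, rng,
                          shares=np.array(config.orc2_shares), prefix="orc")
    h1 = _sample_points(truth, config.n_h1_dips, rng,
                        shares=np.array(config.h1_dip_shares), prefix="h1d")
    boundaries = _sample_points(truth, config.n_boundaries, rng,
                                shares=np.array(config.boundary_shares), prefix="bnd")
    interbands = _top_fragments(truth, "cyan", config.n_curated_interbands, "IB")
    ih_bands = _top_fragments(truth, "magenta", config.n_ih_bands, "IH")
    promoters = _simulate_promoters(truth, config, interbands, rng)
    genes, labels = simulate_genes(truth, config, rng)
    band = _band_class(genes, interbands, ih_bands)
    labels["band_class"] = band.reindex(labels["gene_id"]).to_numpy()
    expr_rng = _rng(seed, 3)
    expression = simulate_expression(config, labels, expr_rng)
    return SimAnnotations(insertions, dhs, orc2, h1, boundaries, promoters,
                          interbands, ih_bands, genes, labels, expression)


def _simulate_promoters(truth: SimTruth, config: SimConfig,
                        interbands: FeatureSet, rng) -> FeatureSet:
    """Broad/peaked/unknown promoters; exactly `n_interbands_with_broad`
    of the curated interbands receive a broad promoter, the remainder
    none (random broad placement avoids the curated intervals)."""
    broad = _sample_points(
        truth, config.n_broad_promoters, rng,
        shares=np.array(config.broad_shares), width=config.promoter_width,
        prefix="pbr", attr="broad", exclude=interbands)
    peaked = _sample_points(truth, config.n_peaked_promoters, rng,
                            shares=np.array(config.peaked_shares),
                            prefix="ppk", attr="peaked")
    unknown = _sample_points(
        truth, config.n_unknown_promoters, rng,
        shares=np.array([f * 100 for f in config.fractions]),
        prefix="pun", attr="unknown")
    dedicated = []
    chosen = interbands.df.sample(
        n=config.n_interbands_with_broad,
        random_state=int(rng.integers(0, 2**31 - 1))) \
        .sort_values(["chrom", "start"])
    for i, iv in enumerate(chosen.itertuples(index=False)):
        mid = (iv.start + iv.end) // 2
        half = config.promoter_width // 2
        dedicated.append((iv.chrom, max(iv.start, mid - half),
                          min(iv.end, mid + half + 1), ".",
                          f"pib{i + 1:03d}", "broad"))
    ded = pd.DataFrame(dedicated, columns=FeatureSet.COLUMNS)
    df = pd.concat([broad.df, ded, peaked.df, unknown.df], ignore_index=True)
    return FeatureSet(df.sort_values(["chrom", "start"]).reset_index(drop=True))


@dataclass
class SimBundle:
    truth: SimTruth
    signals: SignalMatrix
    annotations: SimAnnotations


def simulate_all(config: SimConfig | None = None, seed: int = 0) -> SimBundle:
    """Convenience wrapper: truth + signals + annotations in one call."""
    config = config or SimConfig()
    truth = simulate_truth(config, seed)
    signals = simulate_signals(truth)
    annotations = simulate_annotations(truth)
    return SimBundle(truth, signals, annotations)


def write_sim_dir(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text genomic files (bedGraph, BED, TSV).

    Returns a mapping of logical names to paths, suitable for feeding the
    pipeline configuration.
    """
    out = Path(outdir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    bins = bundle.truth.bins
    cs = out / "chrom.sizes"
    cs.write_text("".join(f"{c}\t{n}\n" for c, n in bins.chrom_sizes.items()))
    paths["chrom_sizes"] = cs
    chroms = bins.bin_chrom()
    starts = bins.bin_starts()
    ends = bins.bin_ends()
    usable = ~bundle.truth.mask
    for j, name in enumerate(bundle.signals.datasets):
        p = out / "tracks" / f"{name}.bedGraph"
        vals = bundle.signals.values[:, j]
        df = pd.DataFrame({
            "chrom": chroms[usable], "start": starts[usable],
            "end": ends[usable], "value": np.round(vals[usable], 4),
        })
        df.to_csv(p, sep="\t", header=False, index=False)
        paths[f"track:{name}"] = p
    ab = out / "anchors.bed"
    with open(ab, "w") as fh:
        for chrom, pos, name in bundle.truth.anchors.points:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{name}\n")
    paths["anchors"] = ab
    feature_files = {
        "insertions": bundle.annotations.insertions,
        "dhs": bundle.annotations.dhs,
        "orc2": bundle.annotations.orc2,
        "h1_dips": bundle.annotations.h1_dips,
        "boundaries": bundle.annotations.boundaries,
        "promoters": bundle.annotations.promoters,
        "interbands": bundle.annotations.interbands,
        "ih_bands": bundle.annotations.ih_bands,
    }
    for key, fs in feature_files.items():
        p = out / f"{key}.bed"
        cols = ["chrom", "start", "end", "name"]
        df = fs.df.copy()
        df["score"] = 0
        bed = df[["chrom", "start", "end", "name", "score", "strand", "attr"]]
        bed.to_csv(p, sep="\t", header=False, index=False)
        paths[key] = p
    gp = out / "genes.tsv"
    bundle.annotations.genes.to_table(gp)
    paths["genes"] = gp
    lp = out / "gene_labels.tsv"
    bundle.annotations.gene_labels.to_csv(lp, sep="\t", index=False)
    paths["gene_labels"] = lp
    ep = out / "expression.tsv"
    bundle.annotations.expression.to_tsv(ep)
    paths["expression"] = ep
    tb = out / "truth.bed"
    bundle.truth.fragments.to_bed(tb)
    paths["truth"] = tb
    return paths
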