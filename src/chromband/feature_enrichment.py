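"""Distribution of genomic features across chromatin states.

Features (transposon insertions, DHS, ORC2 sites, H1 dips, promoters,
gene 5'-ends) are assigned to the state fragment that fully contains
them.  Features overlapping two or more states are excluded as
"multi-state"; features falling (partly) into regions without model
output are excluded as "no-data" -- both exclusions are tallied, never
silently dropped.  Enrichment is summarized as

    fold = feature fraction / genome fraction

per state, with a chi-square test of the observed state counts against
an expectation proportional to the per-state genome fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import FeatureSet, GeneModels
from .state_model import StateFragments
from ._util import round_half_away

__all__ = [
    "StateAssignment",
    "EnrichmentReport",
    "assign_features_to_states",
    "fold_enrichment",
    "enrichment_report",
    "classify_gene_pairs",
    "orientation_state_summary",
    "promoter_class_distribution",
    "overlap_percentages",
]

MULTI_STATE = "multi-state"
NO_DATA = "no-data"


@dataclass
class StateAssignment:
    """Per-feature state label or exclusion reason."""

    labels: pd.Series  # state name, MULTI_STATE or NO_DATA, aligned to feature index

    def counts(self) -> pd.Series:
        """Assigned-feature count per state (exclusions not included)."""
        assigned = self.labels[~self.labels.isin([MULTI_STATE, NO_DATA])]
        return assigned.value_counts().sort_index()

    @property
    def n_assigned(self) -> int:
        return int((~self.labels.isin([MULTI_STATE, NO_DATA])).sum())

    @property
    def exclusions(self) -> dict[str, int]:
        return {
            MULTI_STATE: int((self.labels == MULTI_STATE).sum()),
            NO_DATA: int((self.labels == NO_DATA).sum()),
        }

    def __len__(self) -> int:
        return len(self.labels)


def assign_features_to_states(
    features: FeatureSet, fragments: StateFragments
) -> StateAssignment:
    """Assign each feature to the single state fragment containing it.

    A feature fully inside one fragment takes that fragment's state.
    Overlap with fragments of >= 2 distinct states excludes the feature
    as multi-state; no overlap at all, or partial overlap with an
    uncovered gap, excludes it as no-data.
    """
    labels = np.full(len(features), NO_DATA, dtype=object)
    fdf = features.df
    frag = fragments.df
    for chrom, g in frag.groupby("chrom"):
        g = g.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        states = g["state"].to_numpy()
        sel = np.flatnonzero((fdf["chrom"] == chrom).to_numpy())
        if not sel.size:
            continue
        fs = fdf["start"].to_numpy()[sel]
        fe = fdf["end"].to_numpy()[sel]
        # fragments overlapping [fs, fe): indices in [i0, i1)
        i0 = np.searchsorted(ends, fs, side="right")
        i1 = np.searchsorted(starts, fe, side="left")
        for pos, a, b, s, e in zip(sel, i0, i1, fs, fe):
            if b <= a:
                continue  # no overlapping fragment
            overlapped = set(states[a:b])
            if len(overlapped) > 1:
                labels[pos] = MULTI_STATE
            else:
                # covered only when the single overlapped span contains the
                # feature without an intervening gap
                covered = sum(
                    min(e, ends[j]) - max(s, starts[j]) for j in range(a, b)
                )
                labels[pos] = overlapped.pop() if covered == e - s else NO_DATA
    return StateAssignment(pd.Series(labels, index=fdf.index))


def fold_enrichment(feature_fraction: float, genome_fraction: float) -> float:
    """Ratio of feature percentage to genome percentage for one state."""
    if genome_fraction <= 0:
        raise ValueError("genome fraction must be positive")
    return feature_fraction / genome_fraction


@dataclass
class EnrichmentReport:
    """Per-state feature counts, percentages and fold enrichments."""

    table: pd.DataFrame  # state, count, feature_pct, genome_pct, fold
    statistic: float
    pvalue: float
    exclusions: dict[str, int]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def enrichment_report(
    assignment: StateAssignment, genome_fractions_pct: dict[str, float]
) -> EnrichmentReport:
    """Summarize an assignment against per-state genome fractions.

    The chi-square statistic compares observed state counts with the
    expectation proportional to genome fractions over the same states.
    """
    counts = assignment.counts()
    total = counts.sum()
    if total == 0:
        raise ValueError("no assignable features")
    states = sorted(genome_fractions_pct)
    obs = np.array([counts.get(s, 0) for s in states], dtype=float)
    gf = np.array([genome_fractions_pct[s] for s in states], dtype=float)
    exp = total * gf / gf.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    pval = float(stats.chi2.sf(chi2, df=len(states) - 1))
    rows = []
    for s, o, g in zip(states, obs, gf):
        rows.append({
            "state": s,
            "count": int(o),
            "feature_pct": round_half_away(100.0 * o / total, 1),
            "genome_pct": round_half_away(g, 1),
            "fold": round_half_away(fold_enrichment(100.0 * o / total, g), 1),
        })
    return EnrichmentReport(pd.DataFrame(rows), chi2, pval, assignment.exclusions)


HEAD_TO_HEAD = "head-to-head"
TAIL_TO_TAIL = "tail-to-tail"
HEAD_TO_TAIL = "head-to-tail"


def classify_gene_pairs(genes: GeneModels, max_gap: int = 2000) -> pd.DataFrame:
    """Classify adjacent gene pairs by transcriptional orientation.

    Pairs are consecutive gene bodies on a chromosome with no annotated
    gene between them.  Divergent strands with facing 5' ends (- then +)
    are head-to-head, convergent (+ then -) tail-to-tail, equal strands
    head-to-tail.  The intergenic gap is the span between the two bodies;
    pairs with gap >= `max_gap` are retained but flagged out-of-window.
    Overlapping gene bodies are skipped with a warning.

    Returns a frame with columns chrom, left, right, orientation, gap,
    in_window.
    """
    rows = []
    n_overlap = 0
    for chrom, g in genes.df.groupby("chrom", sort=False):
        g = g.sort_values(["start", "end"])
        recs = list(g.itertuples(index=False))
        for a, b in zip(recs, recs[1:]):
            if b.start < a.end:
                n_overlap += 1
                continue
            gap = int(b.start - a.end)
            if a.strand == "-" and b.strand == "+":
                orient = HEAD_TO_HEAD
            elif a.strand == "+" and b.strand == "-":
                orient = TAIL_TO_TAIL
            else:
                orient = HEAD_TO_TAIL
            rows.append({
                "chrom": chrom, "left": a.gene_id, "right": b.gene_id,
                "orientation": orient, "gap": gap, "in_window": gap < max_gap,
            })
    if n_overlap:
        warnings.warn(f"skipped {n_overlap} pairs with overlapping gene bodies")
    return pd.DataFrame(
        rows, columns=["chrom", "left", "right", "orientation", "gap", "in_window"]
    )


def orientation_state_summary(
    pairs: pd.DataFrame,
    genes: GeneModels,
    fragments: StateFragments,
    genome_fractions_pct: dict[str, float] | None = None,
) -> EnrichmentReport:
    """Distribution of head-to-head gene 5' ends across states.

    Only head-to-head pairs within the gap window contribute; each
    member gene's 5'-end point is assigned to a state, and the observed
    state counts are tested (chi-square) against an expectation
    proportional to the genome fractions.
    """
    hh = pairs[(pairs["orientation"] == HEAD_TO_HEAD) & pairs["in_window"]]
    gene_ids = pd.unique(hh[["left", "right"]].to_numpy().ravel())
    if not len(gene_ids):
        raise ValueError("no in-window head-to-head genes")
    tss = genes.tss_features(list(gene_ids))
    assignment = assign_features_to_states(tss, fragments)
    if genome_fractions_pct is None:
        genome_fractions_pct = fragments.genome_fractions_pct()
    if assignment.n_assigned == 0:
        raise ValueError("no head-to-head gene 5' ends assignable to a state")
    return enrichment_report(assignment, genome_fractions_pct)


PROMOTER_CLASSES = ("broad", "peaked", "unknown")


@dataclass
class PromoterDistribution:
    """Per-class, per-state promoter counts plus interband coverage."""

    table: pd.DataFrame  # class, state, count, pct (pct within class)
    interband_summary: dict | None = None


def promoter_class_distribution(
    promoters: FeatureSet,
    fragments: StateFragments,
    interbands: FeatureSet | None = None,
) -> PromoterDistribution:
    """Distribution of promoter shape classes across chromatin states.

    `promoters` carries the shape class ("broad"/"peaked"/"unknown") in
    its attr column.  When a curated interband interval list is given,
    the fraction of intervals containing at least one broad promoter is
    reported as well.
    """
    classes = promoters.df["attr"]
    bad = sorted(set(classes) - set(PROMOTER_CLASSES))
    if bad:
        offending = promoters.df[classes.isin(bad)].head(10)
        raise ValueError(f"unknown promoter class labels {bad}; e.g.\n{offending}")
    assignment = assign_features_to_states(promoters, fragments)
    rows = []
    for cls in PROMOTER_CLASSES:
        sel = classes == cls
        if not sel.any():
            continue
        labels = assignment.labels[sel.to_numpy()]
        assigned = labels[~labels.isin([MULTI_STATE, NO_DATA])]
        n_cls = len(assigned)
        for state in fragments.states:
            n = int((assigned == state).sum())
            rows.append({
                "class": cls, "state": state, "count": n,
                "pct": round_half_away(100.0 * n / n_cls, 1) if n_cls else 0.0,
            })
    table = pd.DataFrame(rows, columns=["class", "state", "count", "pct"])
    summary = None
    if interbands is not None:
        broad = FeatureSet(promoters.df[classes == "broad"])
        n_with = 0
        for iv in interbands.df.itertuples(index=False):
            inside = (
                (broad.df["chrom"] == iv.chrom)
                & (broad.df["start"] >= iv.start)
                & (broad.df["end"] <= iv.end)
            )
            n_with += bool(inside.any())
        n_total = len(interbands)
        summary = {
            "n_interbands": n_total,
            "n_with_broad": n_with,
            "n_without_broad": n_total - n_with,
            "pct_with_broad": round_half_away(100.0 * n_with / n_total, 1),
            "pct_without_broad": round_half_away(100.0 * (n_total - n_with) / n_total, 1),
        }
    return PromoterDistribution(table, summary)


def overlap_percentages(
    features: FeatureSet, fragments: StateFragments
) -> tuple[pd.Series, dict[str, int]]:
    """Percentage of features per state among assigned features.

    Returns (percentages indexed by state, exclusion tally).
    """
    assignment = assign_features_to_states(features, fragments)
    counts = assignment.counts()
    total = counts.sum()
    pct = pd.Series(
        {s: round_half_away(100.0 * counts.get(s, 0) / total, 1) if total else 0.0
         for s in fragments.states},
        name="pct",
    )
    return pct, assignment.exclusions
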