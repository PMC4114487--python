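"""Expression breadth and level comparisons between gene classes.

Two comparisons mirror the downstream biology: genes whose 5' ends lie in
open "cyan" (interband) chromatin are expected to be broadly expressed
housekeeping-like genes, while genes buried in repressive "magenta"
chromatin (intercalary heterochromatin) are narrowly and lowly expressed.
Breadth is the number of panel tissues where a gene is called present;
level comparisons use per-gene means across conditions summarized by
class medians, with a two-sided Mann-Whitney rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._util import format_fold

__all__ = [
    "ExpressionTable",
    "GeneClassLabels",
    "tissue_breadth",
    "class_medians_and_fold",
    "rank_compare",
]


@dataclass
class ExpressionTable:
    """Genes x conditions expression values with panel metadata.

    values: DataFrame indexed by gene id, one column per condition
    (microarray intensity or RPKM; NaN = condition not measured).
    panels: named condition subsets, e.g. {"adult": [...17 tissues...],
    "larval": [...8 tissues...]}.
    """

    values: pd.DataFrame
    panels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("condition identifiers must be unique")
        finite = self.values.to_numpy(dtype=float)
        if np.nanmin(finite, initial=0.0) < 0:
            raise ValueError("expression values must be >= 0 or missing")
        for name, conds in self.panels.items():
            missing = set(conds) - set(self.values.columns)
            if missing:
                raise ValueError(f"panel {name!r} references unknown conditions {missing}")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            tags = {c: "" for c in self.values.columns}
            for name, conds in self.panels.items():
                for c in conds:
                    tags[c] = name
            fh.write("#panel\t" + "\t".join(tags[c] for c in self.values.columns) + "\n")
            self.values.rename_axis("gene_id").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionTable":
        text = Path(path).read_text().splitlines()
        panel_line = None
        if text and text[0].startswith("#panel"):
            panel_line = text[0].split("\t")[1:]
            text = text[1:]
        from io import StringIO

        values = pd.read_csv(StringIO("\n".join(text)), sep="\t", index_col=0)
        panels: dict[str, list[str]] = {}
        if panel_line:
            for cond, tag in zip(values.columns, panel_line):
                if tag:
                    panels.setdefault(tag, []).append(cond)
        return cls(values, panels)


@dataclass
class GeneClassLabels:
    """Mapping gene id -> class within one classification scheme."""

    labels: pd.Series  # index gene_id, values class names

    def genes(self, cls: str) -> list[str]:
        return list(self.labels.index[self.labels == cls])


def tissue_breadth(
    table: ExpressionTable,
    panel: list[str] | str,
    presence_threshold: float = 1.0,
) -> pd.DataFrame:
    """Number of panel tissues where each gene is called present.

    A gene is present in a condition when its value exceeds
    `presence_threshold` (use 0 for RPKM presence-at-any-level).
    Missing conditions are excluded from the count and tallied in the
    n_missing column.  Genes absent from the table are simply not in the
    result -- absence is a missing record, not a zero.
    """
    conds = table.panels[panel] if isinstance(panel, str) else list(panel)
    if not conds:
        raise ValueError("panel must be non-empty")
    sub = table.values[conds]
    present = (sub > presence_threshold).sum(axis=1)
    missing = sub.isna().sum(axis=1)
    return pd.DataFrame({"n_present": present, "n_missing": missing})


def class_medians_and_fold(
    table: ExpressionTable,
    labels: GeneClassLabels,
    class_a: str,
    class_b: str,
    summarize: str = "mean",
) -> tuple[float, float, float]:
    """Class medians of per-gene average expression, and their ratio.

    Each gene is first summarized across conditions (arithmetic mean by
    default, or median); the two classes are then compared by the median
    of those per-gene summaries.  Returns (median_a, median_b, fold)
    with fold = median_a / median_b (inf when median_b == 0).
    """
    if summarize not in ("mean", "median"):
        raise ValueError("summarize must be 'mean' or 'median'")
    per_gene = getattr(table.values, summarize)(axis=1, skipna=True)
    out = []
    for cls in (class_a, class_b):
        ids = [g for g in labels.genes(cls) if g in per_gene.index]
        if not ids:
            raise ValueError(f"class {cls!r} has no genes in the expression table")
        out.append(float(per_gene.loc[ids].median()))
    median_a, median_b = out
    fold = np.inf if median_b == 0 else median_a / median_b
    return median_a, median_b, fold


def fold_label(fold: float) -> str:
    """Printed form of a fold: integer when >= 10, else one decimal."""
    return format_fold(fold)


def rank_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test between two samples.

    Uses the exact null distribution when both samples are small and
    untied, otherwise the normal approximation.  Returns (U statistic of
    the first sample, p-value).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
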