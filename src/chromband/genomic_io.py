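"""Genomic file I/O, fixed-width binning and coordinate conventions.

Internally every coordinate is 0-based, half-open (BED convention).
Annotation tables declared 1-based inclusive (FlyBase-style) are converted
at read time.  The genome is tiled with consecutive, non-overlapping bins
(default 200 bp); the terminal bin of each chromosome may be shorter than
the nominal width and is flagged partial rather than dropped, so genome
fractions are computed against true chromosome lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBins",
    "SignalMatrix",
    "FeatureSet",
    "GeneModels",
    "STATE_COLORS",
    "build_bins",
    "read_chrom_sizes",
    "read_signal_track",
    "build_signal_matrix",
    "read_features",
    "write_state_track",
    "read_state_track",
]

#: itemRgb values used in BED9 state tracks, keyed by state name.
STATE_COLORS = {
    "cyan": "0,255,255",
    "blue": "0,0,255",
    "green": "0,255,0",
    "magenta": "255,0,255",
}


class MalformedRecordError(ValueError):
    """A line of a genomic text file could not be parsed."""


@dataclass(frozen=True)
class GenomeBins:
    """Fixed-width tiling of a genome.

    Parameters
    ----------
    chrom_sizes
        Ordered mapping of chromosome name to length in bp.  The mapping
        order defines the global bin ordering.
    width
        Bin width in bp (default 200).
    """

    chrom_sizes: dict[str, int]
    width: int = 200
    _offsets: dict[str, int] = field(init=False, repr=False, compare=False)
    _counts: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"bin width must be positive, got {self.width}")
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {size}")
        counts = {c: -(-size // self.width) for c, size in self.chrom_sizes.items()}
        offsets, total = {}, 0
        for c, n in counts.items():
            offsets[c] = total
            total += n
        object.__setattr__(self, "_counts", counts)
        object.__setattr__(self, "_offsets", offsets)

    @property
    def n_bins(self) -> int:
        return sum(self._counts.values())

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_sizes)

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        """Half-open global bin index range of one chromosome."""
        off = self._offsets[chrom]
        return off, off + self._counts[chrom]

    def n_chrom_bins(self, chrom: str) -> int:
        return self._counts[chrom]

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing bp position `pos`."""
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom} [0, {self.chrom_sizes[chrom]})")
        return self._offsets[chrom] + pos // self.width

    def bin_chrom(self) -> np.ndarray:
        """Chromosome name of every bin (object array, length n_bins)."""
        out = np.empty(self.n_bins, dtype=object)
        for c in self.chromosomes:
            lo, hi = self.chrom_range(c)
            out[lo:hi] = c
        return out

    def bin_starts(self) -> np.ndarray:
        """bp start coordinate of every bin within its chromosome."""
        out = np.empty(self.n_bins, dtype=np.int64)
        for c in self.chromosomes:
            lo, hi = self.chrom_range(c)
            out[lo:hi] = np.arange(hi - lo, dtype=np.int64) * self.width
        return out

    def bin_ends(self) -> np.ndarray:
        """bp end coordinate (exclusive, clipped to chromosome length)."""
        ends = self.bin_starts() + self.width
        for c in self.chromosomes:
            lo, hi = self.chrom_range(c)
            ends[hi - 1] = min(ends[hi - 1], self.chrom_sizes[c])
        return ends

    def bin_widths(self) -> np.ndarray:
        return self.bin_ends() - self.bin_starts()

    def partial_mask(self) -> np.ndarray:
        """Boolean array flagging terminal bins shorter than `width`."""
        return self.bin_widths() < self.width

    def interval(self, i: int) -> tuple[str, int, int]:
        """(chrom, start, end) of global bin `i`."""
        for c in self.chromosomes:
            lo, hi = self.chrom_range(c)
            if lo <= i < hi:
                start = (i - lo) * self.width
                return c, start, min(start + self.width, self.chrom_sizes[c])
        raise IndexError(i)


def build_bins(chrom_sizes: Mapping[str, int], width: int = 200) -> GenomeBins:
    """Tile each chromosome from coordinate 0 with consecutive `width`-bp bins."""
    return GenomeBins(dict(chrom_sizes), width)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom.sizes file (name, length)."""
    sizes: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise MalformedRecordError(f"{path}:{ln}: expected two columns, got {line!r}")
        sizes[parts[0]] = int(parts[1])
    return sizes


@dataclass
class SignalMatrix:
    """Bins x datasets table of log2 enrichment values with a missing mask.

    `mask` is True where a value is missing; masked entries carry no
    numeric meaning (they are stored as NaN for convenience).
    """

    bins: GenomeBins
    datasets: list[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape != (self.bins.n_bins, len(self.datasets)):
            raise ValueError("matrix shape does not match bins x datasets")
        if len(set(self.datasets)) != len(self.datasets):
            raise ValueError("dataset identifiers must be unique")
        self.values = np.where(self.mask, np.nan, self.values)

    def column(self, dataset: str) -> np.ndarray:
        return self.values[:, self.datasets.index(dataset)]

    def subset(self, datasets: Sequence[str]) -> "SignalMatrix":
        idx = [self.datasets.index(d) for d in datasets]
        return SignalMatrix(self.bins, list(datasets), self.values[:, idx], self.mask[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.datasets)


def _tracks_to_intervals(path: Path) -> Iterable[tuple[str, int, int, float]]:
    """Yield (chrom, start, end, value) from a bedGraph or WIG file."""
    mode = "bedgraph"
    chrom, start, step, span = None, None, None, 1
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(p.split("=", 1) for p in line.split()[1:])
                mode, chrom = "fixed", kv["chrom"]
                start = int(kv["start"]) - 1  # WIG declarations are 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            if line.startswith("variableStep"):
                kv = dict(p.split("=", 1) for p in line.split()[1:])
                mode, chrom = "variable", kv["chrom"]
                span = int(kv.get("span", 1))
                continue
            parts = line.split()
            try:
                if mode == "bedgraph":
                    if len(parts) != 4:
                        raise ValueError("expected 4 bedGraph columns")
                    yield parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                elif mode == "fixed":
                    yield chrom, start, start + span, float(parts[0])
                    start += step
                else:  # variable
                    pos = int(parts[0]) - 1
                    yield chrom, pos, pos + span, float(parts[1])
            except (ValueError, IndexError) as exc:
                raise MalformedRecordError(f"{path}:{ln}: {exc}: {line!r}") from None


def _read_intervals(path: Path) -> list[tuple[str, int, int, float]]:
    """Load track intervals; plain 4-column bedGraph takes a fast path."""
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
        return list(df.itertuples(index=False, name=None))
    except (ValueError, TypeError):
        return list(_tracks_to_intervals(path))


def read_signal_track(
    path: str | Path, bins: GenomeBins, min_coverage: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate one bedGraph/WIG track onto the bin grid.

    Each bin's value is the coverage-weighted mean of overlapping track
    intervals.  A bin is masked when less than `min_coverage` of its length
    is covered by data.  Records on chromosomes absent from `bins` are
    skipped with a warning.

    Returns
    -------
    (values, mask)
        Two arrays of length ``bins.n_bins``; mask True = missing.
    """
    width = bins.width
    wsum = np.zeros(bins.n_bins)
    cov = np.zeros(bins.n_bins)
    recs = _read_intervals(Path(path))
    if not recs:
        return np.full(bins.n_bins, np.nan), np.ones(bins.n_bins, dtype=bool)
    chroms = np.array([r[0] for r in recs], dtype=object)
    all_start = np.array([r[1] for r in recs], dtype=np.int64)
    all_end = np.array([r[2] for r in recs], dtype=np.int64)
    all_value = np.array([r[3] for r in recs], dtype=float)
    known = np.isin(chroms, list(bins.chrom_sizes))
    if not known.all():
        unknown = sorted(set(chroms[~known]))
        warnings.warn(f"{path}: skipped records on unknown chromosomes {unknown}")
    for chrom in bins.chromosomes:
        sel = chroms == chrom
        if not sel.any():
            continue
        lo, _ = bins.chrom_range(chrom)
        size = bins.chrom_sizes[chrom]
        start = all_start[sel].clip(0, size)
        end = all_end[sel].clip(0, size)
        value = all_value[sel]
        ok = start < end
        start, end, value = start[ok], end[ok], value[ok]
        b0, b1 = start // width, (end - 1) // width
        # first-bin and last-bin overlaps, vectorized (covers spans of 1-2 bins)
        ov0 = np.minimum(end, (b0 + 1) * width) - start
        np.add.at(wsum, lo + b0, value * ov0)
        np.add.at(cov, lo + b0, ov0)
        multi = b1 > b0
        ov1 = end[multi] - b1[multi] * width
        np.add.at(wsum, lo + b1[multi], value[multi] * ov1)
        np.add.at(cov, lo + b1[multi], ov1)
        # interior bins of long intervals (rare): full-width contribution
        for s, e, v, a, b in zip(start[multi], end[multi], value[multi], b0[multi], b1[multi]):
            if b - a > 1:
                idx = np.arange(a + 1, b)
                wsum[lo + idx] += v * width
                cov[lo + idx] += width
    binw = bins.bin_widths()
    mask = cov < min_coverage * binw
    with np.errstate(invalid="ignore"):
        values = np.where(mask, np.nan, wsum / np.where(cov > 0, cov, 1.0))
    return values, mask


def build_signal_matrix(
    tracks: Mapping[str, str | Path], bins: GenomeBins, min_coverage: float = 0.5
) -> SignalMatrix:
    """Read several tracks (dataset name -> path) into one SignalMatrix."""
    names = list(tracks)
    values = np.empty((bins.n_bins, len(names)))
    mask = np.empty((bins.n_bins, len(names)), dtype=bool)
    for j, name in enumerate(names):
        values[:, j], mask[:, j] = read_signal_track(tracks[name], bins, min_coverage)
    return SignalMatrix(bins, names, values, mask)


@dataclass
class FeatureSet:
    """Strand-aware point/interval genomic features.

    Backed by a DataFrame with columns chrom, start, end, strand, name,
    attr (class attribute, may be empty).  Coordinates are 0-based
    half-open; point features are stored as width-1 intervals.
    """

    df: pd.DataFrame

    COLUMNS = ["chrom", "start", "end", "strand", "name", "attr"]

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col, default in (("strand", "."), ("name", ""), ("attr", "")):
            if col not in df.columns:
                df[col] = default
        self.df = df[self.COLUMNS].reset_index(drop=True)
        bad = self.df["start"] >= self.df["end"]
        if bad.any():
            raise ValueError(f"{int(bad.sum())} records with start >= end")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "FeatureSet":
        """Build from (chrom, start, end[, strand[, name[, attr]]]) tuples."""
        rows = []
        for rec in records:
            rec = list(rec) + ["."] * (3 - len(rec) + 3)
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            strand = rec[3] if len(rec) > 3 and rec[3] in "+-." else "."
            name = rec[4] if len(rec) > 4 else ""
            attr = rec[5] if len(rec) > 5 else ""
            rows.append((chrom, start, end, strand, name, attr))
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    @classmethod
    def points(cls, records: Iterable[tuple]) -> "FeatureSet":
        """Build point features from (chrom, pos[, strand[, name[, attr]]])."""
        rows = []
        for rec in records:
            rec = list(rec)
            chrom, pos = rec[0], int(rec[1])
            strand = rec[2] if len(rec) > 2 else "."
            name = rec[3] if len(rec) > 3 else ""
            attr = rec[4] if len(rec) > 4 else ""
            rows.append((chrom, pos, pos + 1, strand, name, attr))
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))


def read_features(
    path: str | Path,
    format: str = "bed",
    one_based: bool = False,
    columns: Mapping[str, int] | None = None,
    sep: str = "\t",
) -> FeatureSet:
    """Read a BED3/BED6 file or a delimited table into a FeatureSet.

    Parameters
    ----------
    format
        "bed" (columns chrom/start/end[/name/score/strand], 0-based) or
        "tsv" (column roles given by `columns`, 0-indexed positions for
        keys chrom/start/end/strand/name/attr).
    one_based
        Declare the input 1-based inclusive; converted to 0-based
        half-open on read (start-1, end unchanged).  A 1-based point
        (p, p) becomes [p-1, p).
    """
    rows = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split(sep) if format == "tsv" else line.split()
            try:
                if format == "bed":
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    name = parts[3] if len(parts) > 3 else ""
                    strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
                    attr = parts[6] if len(parts) > 6 else ""
                elif format == "tsv":
                    if columns is None:
                        raise ValueError("tsv format requires a columns mapping")
                    chrom = parts[columns["chrom"]]
                    start = int(parts[columns["start"]])
                    end = int(parts[columns["end"]])
                    strand = parts[columns["strand"]] if "strand" in columns else "."
                    name = parts[columns["name"]] if "name" in columns else ""
                    attr = parts[columns["attr"]] if "attr" in columns else ""
                else:
                    raise ValueError(f"unknown format {format!r}")
            except (IndexError, ValueError) as exc:
                raise MalformedRecordError(f"{path}:{ln}: {exc}") from None
            if one_based:
                start -= 1
            if start >= end:
                warnings.warn(f"{path}:{ln}: rejected record with empty interval")
                continue
            rows.append((chrom, start, end, strand, name, attr))
    return FeatureSet(pd.DataFrame(rows, columns=FeatureSet.COLUMNS))


def write_state_track(fragments, path: str | Path) -> None:
    """Write state fragments as a BED9 track with itemRgb per state name.

    Accepts a StateFragments object or a DataFrame with columns
    chrom/start/end/state.  Fragments must be sorted and non-overlapping
    per chromosome.
    """
    df = getattr(fragments, "df", fragments)
    prev: dict[str, int] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        c = row["chrom"]
        if c not in prev:
            if order and c in order[:-1]:
                raise ValueError("fragments not grouped by chromosome")
            order.append(c)
        elif row["start"] < prev[c]:
            raise ValueError(f"unsorted or overlapping fragments on {c} at {row['start']}")
        prev[c] = row["end"]
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            rgb = STATE_COLORS.get(row["state"], "0,0,0")
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{row['state']}"
                f"\t0\t.\t{row['start']}\t{row['end']}\t{rgb}\n"
            )


def read_state_track(path: str | Path) -> pd.DataFrame:
    """Read a BED9 state track back into a chrom/start/end/state frame."""
    fs = read_features(path, format="bed")
    df = fs.df.rename(columns={"name": "state"})
    return df[["chrom", "start", "end", "state"]]


@dataclass
class GeneModels:
    """Gene models with strand and 5'-end.

    Backed by a DataFrame with columns gene_id, chrom, start, end, strand
    (0-based half-open bodies).  The 5'-end (TSS) equals `start` on the +
    strand and `end - 1` on the - strand.
    """

    df: pd.DataFrame

    COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]

    def __post_init__(self) -> None:
        self.df = self.df[self.COLUMNS].reset_index(drop=True)
        if self.df["gene_id"].duplicated().any():
            raise ValueError("gene identifiers must be unique")
        if not self.df["strand"].isin(["+", "-"]).all():
            raise ValueError("gene strand must be + or -")
        if (self.df["start"] >= self.df["end"]).any():
            raise ValueError("gene body start must precede end")

    def __len__(self) -> int:
        return len(self.df)

    def tss(self) -> pd.Series:
        """5'-end bp coordinate per gene (index = gene_id)."""
        pos = np.where(self.df["strand"] == "+", self.df["start"], self.df["end"] - 1)
        return pd.Series(pos, index=self.df["gene_id"], name="tss")

    def tss_features(self, gene_ids: Sequence[str] | None = None) -> FeatureSet:
        """Point FeatureSet of 5'-ends (optionally a subset of genes)."""
        df = self.df if gene_ids is None else self.df[self.df["gene_id"].isin(gene_ids)]
        pos = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
        return FeatureSet(
            pd.DataFrame(
                {
                    "chrom": df["chrom"].to_numpy(),
                    "start": pos,
                    "end": pos + 1,
                    "strand": df["strand"].to_numpy(),
                    "name": df["gene_id"].to_numpy(),
                    "attr": "",
                }
            )
        )

    @classmethod
    def from_table(cls, path: str | Path, one_based: bool = False) -> "GeneModels":
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.rename(columns={c: c.lower() for c in df.columns})
        if one_based:
            df["start"] = df["start"] - 1
        return cls(df)

    def to_table(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)
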