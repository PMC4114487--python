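"""End-to-end orchestration: bin -> cluster -> segment -> enrich -> express.

A single YAML-serializable RunConfig drives the full analysis.  Every
stage persists its artifacts (state BED, model JSON, selection table,
enrichment and expression TSVs) and the run finishes with a
machine-readable summary JSON carrying per-state fragment statistics,
all enrichment percentages/folds and the expression comparisons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import genomic_io as gio
from . import protein_selection as ps
from . import state_model as sm
from . import feature_enrichment as fe
from . import expression_analysis as ea
from ._util import round_half_away
from .synthetic import (
    CHRIZ_DATASETS,
    INTERBAND_DATASETS,
    POLII_DATASETS,
    SimConfig,
    simulate_all,
    write_sim_dir,
)

__all__ = ["RunConfig", "run_pipeline", "simulate_and_run"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    chrom_sizes: Path
    tracks: dict[str, Path]            # dataset name -> bedGraph/WIG path
    anchors: Path                      # BED of reference interband points
    markers: list[str]                 # known interband marker datasets
    polii_markers: list[str]           # RNA polymerase II datasets
    outdir: Path
    features: dict[str, Path] = field(default_factory=dict)
    genes: Path | None = None
    expression: Path | None = None
    gene_labels: Path | None = None
    interbands: Path | None = None
    bin_width: int = 200
    train_chromosome: str = "chrX"
    k_min: int = 2
    k_max: int = 15
    seed: int = 0
    max_gap: int = 2000
    presence_threshold: float = 1.0
    mojena_k_sd: float = 2.0

    def validate(self) -> None:
        missing = [str(p) for p in [self.chrom_sizes, self.anchors, *self.tracks.values()]
                   if not Path(p).exists()]
        missing += [str(p) for p in self.features.values() if not Path(p).exists()]
        for p in (self.genes, self.expression, self.gene_labels, self.interbands):
            if p is not None and not Path(p).exists():
                missing.append(str(p))
        if missing:
            raise FileNotFoundError(f"missing input paths: {missing}")
        if not self.markers:
            raise ValueError("marker list must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["tracks"] = {k: Path(v) for k, v in raw["tracks"].items()}
        raw["features"] = {k: Path(v) for k, v in raw.get("features", {}).items()}
        for key in ("chrom_sizes", "anchors", "outdir", "genes", "expression",
                    "gene_labels", "interbands"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Path):
                d[k] = str(v)
            elif isinstance(v, dict):
                d[k] = {kk: str(vv) for kk, vv in v.items()}
            else:
                d[k] = v
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _read_anchors(path: Path) -> sm.ReferenceAnchors:
    fs = gio.read_features(path, format="bed")
    points = [(r.chrom, (r.start + r.end) // 2, r.name or f"anchor{i}")
              for i, r in enumerate(fs.df.itertuples(index=False), 1)]
    return sm.ReferenceAnchors(points)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the summary dictionary.

    Stage order: signal binning, protein clustering and marker-cluster
    selection, PCA + anchor-constrained HMM state-count selection,
    genome-wide Viterbi decoding and fragment extraction, feature
    enrichment, gene-orientation and expression analyses.  Artifacts are
    written to `config.outdir`; any stage error aborts with the stage
    name while earlier artifacts remain on disk.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    logger.info(
        "run seed=%d, bin width=%d (mask if <50%% covered), training chromosome=%s, "
        "K in [%d, %d] (scan: 1 k-means start, tol 1e-2, <=30 EM iterations, "
        "covariance floor 1e-6), average linkage, Mojena k_sd=%.1f, "
        "max head-to-head gap=%d bp, expression presence threshold=%.2f",
        config.seed, config.bin_width, config.train_chromosome,
        config.k_min, config.k_max, config.mojena_k_sd, config.max_gap,
        config.presence_threshold)
    summary: dict = {"seed": config.seed}
    stage = "binning"
    try:
        bins = gio.build_bins(gio.read_chrom_sizes(config.chrom_sizes), config.bin_width)
        signals = gio.build_signal_matrix(config.tracks, bins)
        summary["n_bins"] = bins.n_bins
        summary["n_datasets"] = len(signals.datasets)

        stage = "protein_selection"
        corr = ps.spearman_matrix(signals, config.train_chromosome)
        tree = ps.cluster_datasets(corr)
        partition = ps.mojena_partition(tree, k_sd=config.mojena_k_sd)
        cluster = ps.select_interband_cluster(partition, config.markers)
        (out / "partition.json").write_text(json.dumps({
            "n_clusters": partition.n_clusters,
            "assignments": partition.assignments,
            "selected_cluster": partition.selected,
            "selected_datasets": cluster,
        }, indent=2))
        summary["n_protein_clusters"] = partition.n_clusters
        summary["selected_cluster_size"] = len(cluster)

        stage = "state_model"
        view = sm.pca_scores(signals, cluster, n_components=2)
        summary["pc_variance_pct"] = round_half_away(
            100 * float(view.explained_variance_ratio.sum()), 1)
        anchors = _read_anchors(config.anchors)
        model, record = sm.select_state_count(
            view, anchors, seed=config.seed,
            k_range=range(config.k_min, config.k_max + 1),
            train_chromosomes=[config.train_chromosome])
        record.table.to_csv(out / "state_count_selection.tsv", sep="\t", index=False)
        (out / "model.json").write_text(json.dumps(model.to_dict(), indent=2))
        path = sm.viterbi_decode(model, view)
        fragments = sm.anchor_and_extract(
            path, bins, anchors, signals,
            interband_markers=cluster, polii_markers=config.polii_markers)
        fragments.to_bed(out / "hmm_states.bed")
        frag_summary = fragments.summary()
        frag_summary.to_csv(out / "fragment_summary.tsv", sep="\t")
        genome_pct = fragments.genome_fractions_pct()
        summary["selected_K"] = model.K
        summary["states"] = {
            s: {
                "n_fragments": int(frag_summary.loc[s, "n_fragments"]),
                "genome_fraction_pct": round_half_away(genome_pct[s], 1),
                "mean_size_kb": round_half_away(frag_summary.loc[s, "mean_size"] / 1000, 1),
                "min_size_kb": frag_summary.loc[s, "min_size"] / 1000,
                "max_size_kb": frag_summary.loc[s, "max_size"] / 1000,
            }
            for s in frag_summary.index
        }

        stage = "feature_enrichment"
        summary["features"] = {}
        for key, fpath in config.features.items():
            fs = gio.read_features(fpath, format="bed")
            if key == "promoters":
                continue
            assignment = fe.assign_features_to_states(fs, fragments)
            report = fe.enrichment_report(assignment, genome_pct)
            report.to_tsv(out / f"enrichment_{key}.tsv")
            row = report.table.set_index("state")
            summary["features"][key] = {
                "n_input": len(fs),
                "n_assigned": assignment.n_assigned,
                "exclusions": assignment.exclusions,
                "pct": row["feature_pct"].to_dict(),
                "fold": row["fold"].to_dict(),
                "chi2": report.statistic,
                "pvalue": report.pvalue,
            }
        if "promoters" in config.features:
            promoters = gio.read_features(config.features["promoters"], format="bed")
            interbands = (gio.read_features(config.interbands, format="bed")
                          if config.interbands else None)
            dist = fe.promoter_class_distribution(promoters, fragments, interbands)
            dist.table.to_csv(out / "promoter_distribution.tsv", sep="\t", index=False)
            broad = dist.table[dist.table["class"] == "broad"].set_index("state")
            summary["promoters"] = {"broad_pct": broad["pct"].to_dict()}
            if dist.interband_summary:
                summary["promoters"]["interbands"] = dist.interband_summary

        stage = "gene_orientation"
        if config.genes is not None:
            genes = gio.GeneModels.from_table(config.genes)
            pairs = fe.classify_gene_pairs(genes, max_gap=config.max_gap)
            pairs.to_csv(out / "gene_pairs.tsv", sep="\t", index=False)
            report = fe.orientation_state_summary(pairs, genes, fragments, genome_pct)
            report.to_tsv(out / "orientation_enrichment.tsv")
            row = report.table.set_index("state")
            hh = pairs[(pairs["orientation"] == fe.HEAD_TO_HEAD) & pairs["in_window"]]
            summary["head_to_head"] = {
                "n_pairs": len(hh),
                "n_genes": int(row["count"].sum()),
                "pct": row["feature_pct"].to_dict(),
                "chi2": report.statistic,
                "pvalue": report.pvalue,
            }

        stage = "expression"
        if config.expression is not None and config.gene_labels is not None:
            table = ea.ExpressionTable.from_tsv(config.expression)
            lbl = (pd.read_csv(config.gene_labels, sep="\t")
                   .set_index("gene_id"))
            summary["expression"] = {}
            # curated interband vs IH-band genes
            band = ea.GeneClassLabels(lbl["band_class"])
            med_a, med_b, fold = ea.class_medians_and_fold(table, band, "interband", "IH_band")
            summary["expression"]["interband_vs_ih"] = _expr_entry(
                table, band, "interband", "IH_band", med_a, med_b, fold)
            # genome-wide, by decoded state of the gene 5' end
            tss_states = _decoded_tss_states(genes, fragments) if config.genes else None
            if tss_states is not None:
                cls = ea.GeneClassLabels(tss_states)
                med_a, med_b, fold = ea.class_medians_and_fold(table, cls, "cyan", "magenta")
                summary["expression"]["cyan_vs_magenta"] = _expr_entry(
                    table, cls, "cyan", "magenta", med_a, med_b, fold)
                breadth = ea.tissue_breadth(table, "adult", config.presence_threshold)
                summary["expression"]["breadth_adult_median"] = {
                    c: float(breadth.loc[[g for g in cls.genes(c)
                                          if g in breadth.index], "n_present"].median())
                    for c in ("cyan", "magenta")
                }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _decoded_tss_states(genes: gio.GeneModels, fragments) -> pd.Series:
    tss = genes.tss_features()
    assignment = fe.assign_features_to_states(tss, fragments)
    s = assignment.labels.copy()
    s.index = genes.df["gene_id"]
    return s


def _expr_entry(table, labels, a, b, med_a, med_b, fold) -> dict:
    va = table.values.loc[[g for g in labels.genes(a) if g in table.values.index]] \
        .mean(axis=1)
    vb = table.values.loc[[g for g in labels.genes(b) if g in table.values.index]] \
        .mean(axis=1)
    stat, pval = ea.rank_compare(va, vb)
    return {
        "median_a": round_half_away(med_a, 1),
        "median_b": round_half_away(med_b, 1),
        "fold": float(fold),
        "fold_printed": ea.fold_label(fold),
        "n_a": int(len(va)), "n_b": int(len(vb)),
        "mannwhitney_u": stat, "pvalue": pval,
    }


def simulate_and_run(seed: int, outdir: str | Path,
                     sim_config: SimConfig | None = None,
                     k_max: int = 15) -> dict:
    """Generate a synthetic study directory and run the pipeline on it.

    Writes the simulation under `outdir`/sim and the analysis under
    `outdir`/run; returns the summary augmented with truth-derived
    context (true state fractions, number of genes).
    """
    out = Path(outdir)
    bundle = simulate_all(sim_config or SimConfig(), seed=seed)
    paths = write_sim_dir(bundle, out / "sim")
    tracks = {name: paths[f"track:{name}"] for name in bundle.signals.datasets}
    config = RunConfig(
        chrom_sizes=paths["chrom_sizes"],
        tracks=tracks,
        anchors=paths["anchors"],
        markers=[d for d in INTERBAND_DATASETS
                 if d in CHRIZ_DATASETS + POLII_DATASETS] + ["ISWI_Kc", "WDS_S2"],
        polii_markers=list(POLII_DATASETS),
        outdir=out / "run",
        features={k: paths[k] for k in
                  ("insertions", "dhs", "orc2", "h1_dips", "boundaries", "promoters")},
        genes=paths["genes"],
        expression=paths["expression"],
        gene_labels=paths["gene_labels"],
        interbands=paths["interbands"],
        seed=seed,
        k_max=k_max,
        train_chromosome=bundle.truth.config.train_chromosome,
    )
    config.to_yaml(out / "run_config.yaml")
    summary = run_pipeline(config)
    summary["truth"] = {
        "state_fractions_pct": {s: round_half_away(100 * f, 1)
                                for s, f in bundle.truth.state_fractions().items()},
        "n_genes": len(bundle.annotations.genes),
    }
    (Path(config.outdir) / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
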