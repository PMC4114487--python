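"""Classify adjacent gene pairs and test where divergent 5' ends sit.

Head-to-head pairs (divergent transcription, facing 5' ends, < 2 kb
apart) typically share a bidirectional promoter; the analysis shows
their 5' ends concentrate in cyan (interband-like) chromatin.
"""

from chromband import classify_gene_pairs, orientation_state_summary
from chromband.synthetic import SimConfig, simulate_truth, simulate_annotations

truth = simulate_truth(SimConfig(), seed=0)
ann = simulate_annotations(truth)

pairs = classify_gene_pairs(ann.genes, max_gap=2000)
counts = pairs.groupby(["orientation", "in_window"]).size()
print("pair classification (orientation, within 2 kb):")
print(counts.to_string())

report = orientation_state_summary(pairs, ann.genes, truth.fragments)
print("\nhead-to-head gene 5' ends by chromatin state:")
print(report.table.to_string(index=False))
print(f"chi-square vs genome fractions = {report.statistic:.1f}, p = {report.pvalue:.1e}")
row = report.table.set_index("state").loc["cyan"]
print(f"\n{row['feature_pct']}% of divergent gene 5' ends map to cyan chromatin "
      f"({row['genome_pct']}% of genome): bidirectional promoters cluster in "
      "open interband-like regions.")
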