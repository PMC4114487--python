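"""Measure how transposon insertions distribute across chromatin states.

Insertions are simulated with an open-chromatin preference (6.2x the
genome-average rate in the cyan state), assigned to state fragments, and
summarized as per-state percentages and fold enrichments.
"""

import numpy as np

from chromband import assign_features_to_states, enrichment_report
from chromband.synthetic import SimConfig, simulate_truth, simulate_annotations

config = SimConfig()
truth = simulate_truth(config, seed=0)
ann = simulate_annotations(truth)

assignment = assign_features_to_states(ann.insertions, truth.fragments)
report = enrichment_report(assignment, truth.fragments.genome_fractions_pct())

print(report.table.to_string(index=False))
print(f"exclusions: {report.exclusions}")
print(f"chi-square = {report.statistic:.1f}, p = {report.pvalue:.2e}")
cyan = report.table.set_index("state").loc["cyan"]
print(f"\n{cyan['feature_pct']}% of insertions land in cyan chromatin, which "
      f"covers only {cyan['genome_pct']}% of the genome: a {cyan['fold']}-fold "
      "preference for the open interband-like state.")
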