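# chromband

Hidden-Markov-model segmentation of a genome into four chromatin states
from multi-protein binding tracks, built around the biology of
*Drosophila* polytene chromosomes: the **cyan** state marks interbands —
constantly decondensed, open chromatin harboring the 5′ regulatory parts
of broadly active genes — while **blue** matches transcribed gene bodies
(loosely compacted "grey" bands), **magenta** matches dense intercalary
heterochromatin, and **green** carries no specific protein signature.
Downstream modules quantify how transposon insertions, DNase I
hypersensitive sites, ORC2 binding, histone-H1 dips, promoter shape
classes, divergent ("head-to-head") gene pairs and gene expression
distribute across the states.

The package is aimed at genome biologists who want a tested, scriptable
re-implementation of this style of chromatin annotation — and at method
developers, since every stage can be exercised on truth-labeled
synthetic data without downloading anything.

## The method

1. **Binning.** Signals (pre-normalized log2 ChIP ratios) are averaged
   over consecutive 200-bp bins; bins with under half their length
   covered by data are masked.
2. **Protein selection.** Datasets are compared by Spearman correlation
   ρ over the training chromosome's bins and clustered agglomeratively
   on the distance d = 1 − ρ. The dendrogram is cut by the **Mojena
   stopping rule**: merging stops at the first fusion level
   aᵢ ≥ ā + 2·s_a (mean and SD over all fusion levels). The cluster
   containing known interband markers (CHRIZ, RNA polymerase II,
   nucleosome remodelers…) is carried forward.
3. **Segmentation.** The selected columns are reduced to two principal
   components (centered, not scaled). For each candidate state count
   K = 2…15 a Gaussian-emission HMM is fitted by Baum–Welch on the
   training chromosome and decoded by Viterbi. K is chosen by maximizing
   the **Calinski–Harabasz criterion**

        CH(K) = [B/(K−1)] / [W/(n−K)]

   among the K for which all reference anchor points (interband
   P-element insertion sites) decode into a single state. The genome is
   then decoded with the chosen model; the anchor state is named *cyan*
   and the rest *blue*/*magenta*/*green* by marker profile, and
   same-state bins are merged into fragments (BED9 output).
4. **Feature analyses.** Features fully inside one state's fragment are
   assigned to it; features spanning two states or falling into no-data
   gaps are excluded (and tallied). Enrichment is
   `fold = feature% / genome%`, with a χ² test against genome fractions.
   Adjacent gene pairs are classified head-to-head / tail-to-tail /
   head-to-tail with a 2 kb window for bidirectional promoters.
   Expression breadth counts tissues above a presence threshold; level
   comparisons use class medians of per-gene means and a Mann–Whitney
   test.

A synthetic-data module (`chromband.synthetic`) generates complete study
inputs — Markovian state paths, correlated multi-protein emission
tracks, state-dependent features, gene models and expression tables —
whose defaults encode the reference study conditions (state fractions
12.7/16.8/22.5/48.0 %, mean fragment sizes 2.7/4.9/3.1/11.2 kb, 6.2-fold
insertion preference for cyan, …).

## Worked example

```bash
python examples/01_simulate_and_segment.py
```

prints, for a 1.6 Mb simulated genome:

```
PC1+PC2 explain 49.7% of variance
 K          ch  anchor_consistent  n_anchor_states  log_likelihood
 2 2155.574430               True                1   -19100.191683
 3 3096.144675               True                1   -17496.995806
 4 3383.469308               True                1   -16629.896112
 5 2632.233632               True                1   -16628.494011
 6 2434.804037               True                1   -16624.579022
 7 2378.428198               True                1   -16614.834797
chosen state count: 4 (CH maximum among anchor-consistent candidates)
bin-level accuracy after label alignment: 0.995
```

The CH column peaks at the true state count; the accuracy line says the
Viterbi segmentation reproduces the hidden annotation almost bin for
bin. The other examples (`examples/02…06`) demonstrate protein-cluster
selection, insertion enrichment (≈78 % of insertions in cyan, ≈6-fold),
gene orientation (≈60 % of head-to-head 5′ ends in cyan), expression
(≈21-fold cyan-over-magenta median), and the full pipeline; each prints
a short interpretation with its numbers.

Shell usage goes through one thin entry point:

```bash
chromband simulate --seed 1 --outdir sim/         # write synthetic study files
chromband run --config run.yaml                   # analyze any study directory
chromband simulate-and-run --seed 1 --outdir out/ # both, printing summary JSON
```

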