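# Methods

## Model and procedure

The segmentation treats a genome, tiled with consecutive 200-bp bins, as
the output of a hidden Markov chain whose states are chromatin types and
whose emissions are the first two principal-component scores of a panel
of protein-binding log2 tracks. Four states carry biological names:
*cyan* (decondensed interband-like chromatin, 5′ ends of broadly active
genes), *blue* (transcribed gene bodies, RNA-polymerase-II-rich but
CHRIZ-poor), *magenta* (dense intercalary-heterochromatin-like regions
devoid of interband proteins) and *green* (no protein specificity).

The pipeline stages and their assumptions:

1. **Binning** (`genomic_io`). Track values are aggregated per bin as a
   coverage-weighted mean; a bin is masked when less than 50 % of its
   length has data (the aggregation rule is this package's choice — the
   upstream convention is not fixed by the analysis design). Internal
   coordinates are 0-based half-open; 1-based-inclusive annotation
   tables are converted at read time. Terminal partial bins are kept and
   flagged so genome-fraction denominators equal true chromosome
   lengths.
2. **Protein selection** (`protein_selection`). Pairwise Spearman ρ over
   the training chromosome's bins (pairwise-complete on masked data; a
   pair sharing < 3 bins is an error), average-linkage agglomeration on
   d = 1 − ρ, and the Mojena stopping rule with k = 2: merging stops at
   the first fusion level ≥ ā + 2·s_a, where ā and s_a (ddof = 1) are
   taken over all n − 1 fusion levels. When all fusion levels are equal
   (s_a = 0) the rule is treated as never firing — one cluster — rather
   than firing immediately, which matches the rule's intent of flagging
   a *jump* above the background level. The interband cluster is the one
   with maximal overlap with a user-supplied marker list; ties break
   toward the larger, then lexicographically first, cluster.
3. **Segmentation** (`state_model`). PCA is computed on centered,
   unscaled columns (appropriate for pre-normalized log2 ratios; scores
   for bins missing any selected column are flagged unusable). For each
   K in 2…15 a full-covariance Gaussian HMM is fitted by Baum–Welch on
   the training chromosome and decoded by Viterbi; the state count
   maximizes the Calinski–Harabasz variance ratio
   CH(K) = [B/(K−1)]/[W/(n−K)] computed on PC scores with Viterbi
   labels, restricted to K where all reference anchors decode into one
   state. Masked bins break the Markov chain: each contiguous usable run
   is an independent sequence for fitting and decoding, and missing bins
   propagate as gaps in the fragment track. Genome fractions are
   reported over the data-covered genome.
4. **Enrichment** (`feature_enrichment`). A feature is assigned to a
   state only when fully contained in one fragment; overlap with ≥ 2
   states excludes it as *multi-state*, absence of model output (wholly
   or partly) as *no-data*; point features can only be assigned or
   no-data. A gene's state is that of its 5′-end bin. The head-to-head
   window is 2000 bp of intergenic span; wider divergent pairs are kept
   but flagged out-of-window. Percentages are printed to one decimal,
   rounding half away from zero (so 6/32 → 18.8 and 26/32 → 81.3; note
   that a complement pair can then print as 18.8/81.3).
5. **Expression** (`expression_analysis`). Breadth is the count of panel
   conditions whose value exceeds a presence threshold (default 1.0 on
   the synthetic scale; configurable for array/RPKM data), with missing
   conditions excluded and tallied. Level comparisons summarize each
   gene by its arithmetic mean across conditions (configurable to
   median), compare class medians, and report the median ratio with a
   two-sided Mann–Whitney test (exact null for small untied samples).

## Parameters that matter

| parameter | default | why |
|---|---|---|
| bin width | 200 bp | resolution of the binned comparison grid |
| mask threshold | 50 % of bin covered | balances data retention vs trusting sparse probes |
| linkage | average | standard for correlation-distance protein clustering; keeps fusion levels monotone |
| Mojena k | 2 | the stopping rule's conventional sensitivity |
| PCA components | 2 | the two leading axes carry the promoter/decompaction contrast; configurable |
| K range | 2–15 | candidate state counts for model selection |
| Baum–Welch (final fits) | 5 k-means-seeded restarts, tol 1e-4, ≤ 500 iter, covariance floor 1e-6 | EM is multimodal; seeded k-means plus restarts makes fits reproducible and stable |
| Baum–Welch (selection scan) | 1 k-means-seeded start, tol 1e-2, ≤ 30 iter | the scan compares 14 models; k-means initialization already sits near the optimum, so a short run ranks K reliably at a fraction of the cost |
| head-to-head window | 2000 bp | bidirectional-promoter definition |
| presence threshold | 1.0 | separates the synthetic on-level (≥ 4 units) from background (~0.5) |

## The synthetic generator

`chromband.synthetic` produces truth-labeled inputs whose defaults *are*
the study conditions: a 10 Mb five-arm genome (training arm chrX,
2.2 Mb); state fractions 12.7/16.8/22.5/48.0 % with mean segment lengths
2.7/4.9/3.1/11.2 kb (geometric, Markov-consistent — the full empirical
size ranges are not modeled); 12 interband-cluster datasets across two
pseudo cell lines plus 6 repressive datasets; 2 % shared missing-data
gaps of mean 1 kb; insertions at 6.2×/0.17×/0.5×/0.11× the genome
baseline per state; DHS/ORC2/H1-dip/boundary/promoter state shares set
to the reference percentages; 600 in-window head-to-head pairs with 5′
ends at shares 60.4/1.4/13.4/22.6 %; expression medians 112 (curated
interband genes), 100.4 (cyan class), 4.2 (IH genes), 4.8 (magenta
class) with presence probabilities 0.95/0.6/0.6/0.25.

Design choices inside the generator:

- **Emission geometry.** The four state means live on a 2-D latent plane
  (occupancy × polII-vs-CHRIZ contrast) arranged as a diamond with
  nearest-neighbor distance 3.9 projected noise SDs, putting the per-bin
  Bayes error near 5 % — recovery at ≥ 90 % bin accuracy is meaningful,
  not trivial. A rank-one shared factor (SD 0.3) correlates datasets
  within a bin, emulating common track-wide variation. One side effect
  of the contrast axis: the CHRIZ and polII tracks anticorrelate
  mildly despite belonging to the same cluster.
- **Transition matrix.** Self-transitions are fixed by the mean segment
  lengths (1 − 1/m); the jump distribution is solved by fixed-point
  iteration so the stationary occupancy matches the target fractions to
  machine precision.
- **Gene placement.** Pair/single target states are drawn *before*
  placement retries so crowding cannot bias realized state shares; the
  intergenic gap of a divergent pair is reserved so no gene body can
  intrude; single genes sit on the + strand so no unintended divergent
  adjacency can arise; magenta singles are placed fully inside a
  fragment (genes buried in heterochromatin), other singles anchor only
  their 5′ end in the target state with the body extending outward, as
  interband genes do. On crowded realizations a handful of genes
  (< 1 %) may fail placement, with a warning.
- **Expression calibration.** The median of per-gene mean expression is
  a skewed functional of presence and tissue noise, so per-class scale
  parameters are solved numerically against a fixed internal reference
  sample; curated subsets (interband / IH genes) keep their own medians
  while the rest of the state class is adjusted so the pooled class
  median also lands on target.
- **Gene density** is higher than a literal scale-down (≈ 1.8 k genes on
  10 Mb, 600 divergent pairs) so that percentage estimates carry useful
  precision at the small genome size.

What the generator does **not** emulate: probe-level array noise,
sequence context, replication timing, per-cell-line differences between
tracks of the same protein, non-geometric segment-length tails, and
chromosome-specific composition. Passing tests therefore show the
pipeline recovers the *statistical design* it assumes — they cannot
certify behavior on real data, whose upstream preprocessing genome-scale numbers are sensitive to.

## Numerical choices

- State fractions and all percentages round half away from zero to one
  decimal; folds are reported as floats (a display helper prints
  integers for folds ≥ 10).
- CH returns +∞ when the within-cluster dispersion is exactly zero, and
  is an error for K < 2 or an empty state.
- Viterbi ties (measure-zero for continuous emissions) resolve to the
  lower state index via the underlying max.
- Covariance degeneracy during EM is handled by a diagonal floor (1e-6);
  a failed restart is logged and skipped, and only a K whose every
  restart fails is dropped from the selection table.
- State naming ties break by state index.
- Identical configuration and seed give byte-identical outputs; every
  random draw descends from the run seed through named seed sequences.

## Scope of the command-line interface

The library-plus-examples surface is the primary interface; one thin
console script (`chromband simulate | run | simulate-and-run`) covers
the shell-level workflow of running a whole study from a YAML config.
Per-stage operations (binning, cluster selection, segmentation,
enrichment, pair classification) are Python functions demonstrated in
`examples/`; wrapping each in its own subcommand would duplicate the
pipeline config without adding capability.

## Known limitations

- The selection scan's short EM runs rank candidate state counts; they
  are not converged maximum-likelihood fits (the chosen model's
  parameters are fit the same way — refit with `fit_hmm` defaults if
  publication-grade parameters are needed).
- Percentage printing cannot reproduce inconsistent source conventions
  (18.8 vs 81.2 for complements of 6/32).
- On a 10 Mb genome the per-realization magenta fraction has ≈ 1.9 pp
  sampling SD, so single-run fractions can sit ~3 pp from their targets
  even though seed-averaged fractions match within 0.5 pp.
- `select_state_count` assumes anchors lie on the training chromosome
  and in usable bins; anchors in masked bins are an error, not silently
  dropped.
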