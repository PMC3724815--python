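# Methods

`mirforest` classifies candidate miRNA binding sites as functional targets
or pseudo-targets. The pipeline has three stages: a miRanda-style duplex
aligner that proposes binding-site alignments, a feature extractor that
summarizes each duplex in 34 descriptors, and a random-forest classifier
evaluated with repeated cross-validation, Gini-importance analysis and
permutation significance tests. This note records the models, the defaults
and the design choices that were genuinely open.

## Duplex alignment

The miRNA (5'→3') is aligned against the reversed target sequence, so the
two strands run antiparallel as in a physical RNA:RNA hybrid. Alignment is
local (Smith–Waterman/Gotoh with affine gaps) under the miRanda scoring
matrix: +5 for G:C, +5 for A:U, +2 for the non-canonical G:U wobble, −3 for
every other residue pairing. Each column is categorized as G:C match, A:U
match, G:U wobble, mismatch, or gap.

**Gap model.** Gap penalties for this scoring scheme are not standardized;
we default to affine `gap_open = −8`, `gap_extend = −2` (a run of *g* gaps in
one row costs `open + extend·(g−1)`), severe enough that gaps are rare in
accepted duplexes, as they are in real miRNA:mRNA hybrids. Both penalties
are configurable.

**Empirical site rules.** Counting alignment columns 1-based from the miRNA
5' end (gap columns included, matching how duplexes are displayed and
numbered), a candidate site must satisfy: (i) no mismatches at columns 2–4;
(ii) fewer than five mismatches at columns 3–12; (iii) at least one mismatch
between column 9 and column L−5; (iv) fewer than two mismatches in the last
five columns. Alignments shorter than 14 columns are rejected with a
distinct code. For rule purposes a "mismatch" is a mismatch or gap column;
a G:U wobble counts as pairing, because it is positively scored and drawn
as a pair in duplex displays. Whether the original miRanda rules count
wobbles as mismatches is not documented; this is the package's choice.

**Suboptimal-window rescue.** The score-optimal local window sometimes
violates a rule only at its edge (a seed-window mismatch in column 2–4, or
two mismatches among the last five columns). Because the rules describe
acceptable *sites*, not optimal windows, the aligner then searches the
window's trimmed sub-windows (length ≥ 14, boundary columns pairing, score
still above threshold) and accepts the best-scoring sub-window that passes
all rules. Without this rescue a large fraction of genuine sites is
discarded for edge effects.

**Thresholds.** A candidate must score at or above `score_threshold`
(default 30) and have duplex ΔG at or below `energy_threshold` (default −5
kcal/mol). The defaults are deliberately permissive: a minimal rule-passing
site of 14 columns scores in the low 30s, so the filter keeps essentially
everything that satisfies the rules and leaves refinement to the
classifier. Stricter, screening-style values can be configured.

**Multiple sites.** Non-overlapping sites on one target are found greedily
by descending score: each candidate above the score threshold masks its
target span (whether or not it is accepted), and alignment repeats on the
masked target until scores fall below threshold.

## Duplex free energy

Two backends compute ΔG (kcal/mol, 37 °C) of the hybrid.

`BUILTIN_NN` (default) is a self-contained nearest-neighbor model: Xia/Turner
ΔG°37 stack terms for the ten Watson–Crick stacks and literature-style
values for G:U-containing stacks (shipped as a versioned JSON table), a
small duplex initiation term (+0.5), and a +0.5 penalty per interrupting
(mismatch/gap) column. The energy of an alignment is the minimum over
contiguous column windows of `initiation + Σ stacks + loop penalties`,
floored at 0 — mimicking how a folding engine pairs only the favourable
core of a site, and guaranteeing that an alignment with at least one
stacked Watson–Crick step is never reported as destabilizing. The small
initiation term is a deliberate departure from the Turner absolute value
(+4.09): the classifier needs a consistent relative stability score, not a
calibrated absolute free energy, and the absolute initiation would make
single-stack duplexes positive.

`EXTERNAL_DUPLEX` delegates to an RNAduplex-compatible command-line engine
on the gap-stripped sequences of the alignment, for users who want
Turner-calibrated energies.

Seed energy is the same computation applied to alignment columns 2–8 with
gap columns removed first (energy is a property of the hybridizing
sequences, not of gapped display rows).

## Features

34 descriptors in five categories: alignment (score, length);
thermodynamic (total ΔG); structural (absolute frequencies of G:C, A:U,
G:U, gap and mismatch columns); 20 nominal position features (the pairing
category of columns 1–20 from the miRNA 5' end, with the distinguished
level `ABSENT` for columns beyond a short alignment); and six seed features
(ΔG and the five frequencies over columns 2–8). Positions index alignment
columns — a gap column consumes a position — matching the way numbered
duplex figures are read. The five total counts always sum to the alignment
length and the five seed counts to 7.

Optional utilities standardize the 14 numeric features (mean 0, sd 1;
parameters stored for reuse on held-out data) and compute their Pearson
correlation matrix. Nominal position features are excluded from
correlation, where Pearson is undefined; zero-variance features yield NaN
markers.

## Random forest

A bagging ensemble of fully grown decision trees (default 500), each tree
trained on a bootstrap sample (~2/3 unique rows) with `mtry` random
candidate features per split (default ⌊√p⌋ over the encoded matrix).
Nominal position features are one-hot encoded with a fixed level set;
reported Gini importance sums a feature's dummy columns, so rankings keep
per-feature semantics. The tree learner is scikit-learn's
`RandomForestClassifier`; the protocol around it (OOB scoring under the
strict decision rule, importance aggregation, tuning, selection,
dependence) is implemented here.

* **Prediction.** P(TARGET) is the fraction of trees voting TARGET; the
  hard class is TARGET only when the probability strictly exceeds the
  decision threshold (default 0.5) — a tied vote is NON_TARGET.
* **OOB estimates.** Out-of-bag probabilities come from each row's
  out-of-bootstrap trees; OOB error is computed under the same strict
  decision rule, overall and per class.
* **mtry tuning.** Each grid value (default {2, ⌊√p⌋, ⌊p/3⌋, ⌊p/2⌋}) is
  profiled by repeated stratified cross-validated AUC; the chosen value is
  the smallest mtry whose mean lies within one standard error of the best
  mean (simplest model near the optimum). The resampling scheme is fixed
  as repeated CV; forward selection reuses the globally tuned value rather
  than retuning per prefix.
* **Class weights.** Imbalance penalties are per-class sample weights in
  impurity and vote aggregation; the preset {TARGET: 0.3, NON_TARGET: 0.7}
  emphasizes the negative class.
* **Forward feature selection.** Forests are grown on prefixes of the
  Gini ranking, most to least relevant; each prefix is scored on OOB data
  (ACC/SEN/SPE/MCC) and the recommended size maximizes OOB MCC, ties going
  to the smaller model.
* **Partial dependence.** For each level (nominal) or decile-grid value
  (numeric) the feature is forced to that value in every row and the mean
  predicted probability recorded.

## Evaluation

ACC, SEN and SPE are percentages; MCC is the Matthews coefficient; metrics
with vanishing denominators are NaN markers. Confusion matrices may hold
fractional cells: repeated cross-validation sums the per-fold matrices
within a repetition (the folds partition the data) and averages across
repetitions. Cross-validation is stratified by class, 10 folds × 5
repetitions by default, fully seeded.

Printed-precision reporting **truncates toward zero** rather than rounding
(87.208…% → 87.20). This convention exactly reproduces the published
worked-example metrics from their printed confusion matrices, which
rounding does not; internal computation always uses full precision.

AUC is computed by an explicit threshold sweep and equals the probability
that a random positive outscores a random negative with ties counted ½; a
brute-force pairwise implementation is kept as an internal cross-check.
The label-permutation test reports the plain fraction of permutations
whose AUC reaches the observed value (2000 permutations by default); a
`(r+1)/(n+1)`-corrected variant is available by flag. Probability vectors
are compared with a two-sided Mann–Whitney U test, and per-resample AUC
vectors with a paired t-test (zero-variance differences yield NaN markers).

## Synthetic benchmark

The generator emulates seed-driven animal-style target recognition so every
stage is testable without downloads. Each target (default 500 nt, GC
content 0.5) embeds one site built from the reverse complement of its
miRNA (default 22 nt) at a uniform random position, then degraded
column-wise and independently: seed columns (miRNA positions 2–8) pair
Watson–Crick with probability 0.95 in positives and 0.4 in negatives;
out-seed columns with probability 0.6 and 0.3; a planted pair is flipped to
a G:U wobble with probability 0.08 where chemically possible. One central
non-pairing column (miRNA positions 10 to L−6) is always planted, in both
classes: perfect duplexes are not biological and are rejected by the
central-bulge rule, and planting it in both classes keeps class-identical
configurations exactly exchangeable for null calibration. No indels are
planted by default — gaps are rare in real duplexes — so gap features are
exercised by dedicated fixtures instead.

`generate_feature_table` composes generation, alignment and extraction and
emits **one row per pair: the best-scoring accepted alignment that overlaps
the planted site**. This matters: 500 nt of random flank contains chance
alignments whose best local score rivals a degraded genuine site, so
attaching the pair label to every accepted site (or to the global best
site) would mislabel a large fraction of rows in both classes and destroy
the benchmark's signal. The pair label describes the planted site and is
attached only there; pairs whose planted site yields no accepted alignment
are dropped and logged. Chance-site discovery remains available through
`align_duplex` and the CLI.

What the benchmark does *not* model: UTR context and site accessibility,
conservation, multiple genuine sites per target, expression-derived
negative selection, or tissue specificity. Passing tests therefore show
that the machinery recovers planted statistical structure under the filter
chain — not that the classifier matches its published real-data accuracy.

**Problem sizes.** Tests and the acceptance script use 200 positive + 200
negative pairs for end-to-end checks (of which ~250 survive the filter
chain), 10×5 repeated CV with 500-tree forests, 2000 permutations for the
significance example and 100×200 for null calibration; the alignment
oracle cross-check enumerates all matched-pair alignments for sequences up
to 8×12 nt.

## Known limitations

* Conditioning on the filter chain makes surviving negatives the
  high-scoring tail of their class; their out-of-bag error stays around
  25–30% (overall OOB error ≈ 12–14% at the default conditions) no matter
  the forest configuration, although ranking quality remains high
  (repeated-CV AUC ≈ 0.93).
* The builtin energy model is a relative score; absolute ΔG values differ
  from RNAduplex by the initiation offset and loop-model details.
* The alignment-report dialect is defined by this package's fixtures; the
  classic miRanda display (Query 3'→5') is parsed, but other variants of
  miRanda output are not guaranteed.
* Position features beyond column 20 are ignored by design; alignments
  longer than 20 columns lose per-column detail in the tail.
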