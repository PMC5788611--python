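# Methods

## Problem and model

The task is binary classification of DNA sequences into DNase I
hypersensitive sites (DHSs; accessible, nucleosome-depleted chromatin) versus
non-DHSs, from primary sequence alone. The pipeline has four stages, each a
separate module with a stable interface:

1. **Encoding** (`encoders`, `properties`). Sequences become fixed-width
   vectors: overlapping *k*-mer compositions (*k* = 1..5) plus dinucleotide
   (DPCP) and trinucleotide (TPCP) physicochemical profiles. A *k*-mer block
   is a point on the 4^k-simplex (counts over *L−k+1* windows, so every block
   sums to 1). A physicochemical feature is count(n-mer) × normalized
   property / *N_res*. We take *N_res* to be the sequence length *L*,
   reading the definition literally; the alternative window count *L−n+1*
   only rescales the block by (L−n+1)/L and is available as
   `nres="windows"`. DPCP is fixed at 16 × 6 = 96 features — together with
   the other blocks this makes the full encoding 4+16+64+256+1024+96+768 =
   2228 columns. Feature names and their canonical block order
   (MNC, DNC, TNC, TeNC, PNC, DPCP, TPCP) are part of the public contract,
   since a saved model is only valid against the exact column order it was
   trained on.

2. **Selection** (`featselect`). Feature importance scores (FIS) are
   ensemble-averaged Gini (mean decrease in impurity) importances: per
   stratified CV round a forest is grown on the training part with the
   variables-tried-per-split drawn uniformly from 1..min(100, D) — one draw
   per round, which is the closest single-FIS-vector reading of a
   "randomly chosen between one and 100" protocol — and the per-forest
   importance vectors (each summing to 1) are averaged over rounds and
   renormalized. Candidate subsets come from an inclusive threshold sweep,
   by default 0.0003 ≤ FIS ≤ 0.0021 in 0.0001 steps (19 nested subsets);
   the subset with the highest downstream cross-validated MCC wins, ties
   going to the smaller subset. Gini importance rather than permutation
   importance is deliberate: "ensemble average over all trees" describes
   impurity importance, and rank stability — not the absolute scores — is
   what the selection consumes.

3. **Training** (`train`). Four families: RBF-SVM, random forest, extra
   trees, k-NN. The evaluation protocol is repeats × stratified k-fold CV
   (default 5 × 10) with *nested* hyperparameter tuning: the grid is searched
   by inner CV on the nine training folds of every outer split, so no
   held-out fold ever influences tuning. The SVM grid is C = 2^−15..2^10,
   γ = 2^−10..2^10 at integer log2 steps (546 points); since published
   optima are not always on an integer-exponent grid, an optional
   second-stage refinement searches the 2^±0.5 neighbourhood of the winner
   at 2^0.25 resolution (off by default). Ties in tuning MCC resolve to the
   smallest parameter values (smallest C, then smallest γ), making the
   search deterministic. Per-repeat metrics are computed on the pooled
   out-of-fold predictions and averaged across repeats; the median of the
   chosen hyperparameters (mode for categorical ones) is reported as the
   stable value and used to refit the final model on all data. No class
   reweighting is applied despite the 280:737 imbalance — the imbalance-aware
   metrics Pt and Py carry that burden. SVM probabilities come from a Platt
   calibration layer (`CalibratedClassifierCV`, `ensemble=False`, 2-fold)
   fitted strictly inside the training partition.

4. **Metrics** (`metrics`). Sn, Sp, ACC, MCC, Pt = Sn·Sp and
   Py = Sn + Sp − 1 from the counts N⁺, N⁻, N₋⁺, N₊⁻. MCC uses the
   rearranged error-rate form; it is algebraically identical to the
   classical TP/FP/TN/FN formula, and the test suite proves this
   exhaustively for every confusion matrix with ≤ 20 samples. Degenerate
   denominators (one-class predictor or truth) return MCC = 0 with a
   `degenerate` flag — the common convention, since the formula is 0/0
   there. AUC is the Mann–Whitney statistic with ties counted half; the
   ROC table uses the standard staircase. Reports carry full precision and
   round to 3 decimals for display, matching published tables.

## Compositional statistics

`compstats` compares per-sequence *k*-mer compositions between classes with
Welch's unequal-variance t-test (Welch–Satterthwaite df, two-sided p), the
statistic implemented from its formula with only the t-distribution CDF
delegated to scipy — scipy's own test then serves as an independent oracle in
the tests. Default α = 0.01 with no multiple-testing correction (an optional
Benjamini–Hochberg flag exists). Compositions are reported on the percent
scale by default: for *k* ≥ 3 an absolute-difference display filter like
"> 0.20" is only meaningful on that scale, because fractional compositions
over 64+ categories are individually far below 0.2. K-mers absent from every
sequence (zero variance in both classes) are reported as t = 0, p = 1 when
the class means agree — they carry no signal and the Welch statistic is
undefined there.

## Synthetic benchmarks

`synthdata` draws i.i.d. sequences per class with nucleotide probabilities
((1−gc)/2, gc/2, gc/2, (1−gc)/2), uniform lengths, and optional motifs
overwritten at uniform positions with per-class insertion rates (overwriting
rather than inserting keeps lengths fixed, which keeps the invariants
simple). Defaults encode the study conditions: 280 positives vs 737
negatives, GC 0.6 vs 0.4 (the direction of the known G/C enrichment in
DHSs), lengths uniform on 200–400 nt — the real benchmark's length
distribution is unpublished, so this is a package choice: long enough that a
0.2 GC gap is decisive, short enough to keep encoding cheap. What passing
tests on these data show is that the machinery — encoding, ranking,
selection, nested CV, metrics — is correct and unbiased (null data yield
|MCC| ≈ 0); they do not show that real DHSs are predictable at any
particular accuracy, because i.i.d. composition-only sequences lack the
positional structure, CpG islands and higher-order dependencies of real
chromatin.

## Property tables

The original supplementary tables of measured physicochemical parameters are
not redistributable here, so the bundled defaults are stand-ins labelled
synthetic in their filenames. The dinucleotide table carries representative
crystallographic base-pair-step averages (twist, tilt, roll, shift, slide,
rise) with reverse-complement symmetry (twist/roll/slide/rise equal,
tilt/shift negated between complementary steps). In the trinucleotide table,
GC content and the two molecular-weight columns are computed exactly; the
nine experimental scales (bendability ×2, nucleosome positioning/affinity
×3, DNase I sensitivity ×2, consensus roll/rigidity) are seeded synthetic
values with a mild GC correlation where real compilations show one. Because
every column is min-max renormalized to [0,1] on load and users can supply
measured tables in the same two-file TSV schema, no algorithmic behaviour —
and no test — depends on the raw values; analyses of real data should swap
in measured tables.

## Numerical and design choices

* All counts use overlapping windows; the *k*-mer denominator is the window
  count *L−k+1*, the only reading that yields 4^k-dimensional fractional
  compositions.
* The FIS sweep grid is inclusive on both ends and built by integer
  stepping, so the default grid has exactly 19 cut-offs with no
  floating-point fencepost drift.
* All stochastic operations take an explicit seed and are reproducible to
  the byte (dataset generation, fold partitions, forest growth); repeated-CV
  derives per-repeat seeds deterministically from the root seed.
* Sequence validation is strict by default (any non-ACGT character is an
  error naming the record and position) with an opt-in drop policy, because
  every encoder is defined only on the four standard bases. Lowercase
  (soft-masked) input is uppercased silently. Minimum lengths are enforced
  at encoding time, per block (PNC needs L ≥ 5).
* Model persistence includes a schema version and the ordered feature-name
  contract; prediction refuses matrices whose columns differ or are merely
  reordered.

## Default problem sizes

Library defaults are the full published protocol (10,000-tree importance
forests over 10 rounds, 5 × 10-fold CV, 546-point SVM grid) — sized for real
studies. The test suite and the worked example run the same code paths at
desk scale as the package's own reduced profile: importance forests of
150–200 trees over 2–3 rounds, sweep scoring at 1 × 3-fold, final CV at
2 × 5-fold, and fixed or single-point SVM grids. On the 1017-sequence
synthetic benchmark this keeps an end-to-end fit in seconds while preserving
every contract being tested (rank recovery, nesting, stratification,
determinism, null calibration).

## Known limitations

* The synthetic trinucleotide scales are placeholders: feature *values* in
  TPCP are realistic in structure but not physically meaningful until a
  measured table is supplied.
* The generator's i.i.d. model cannot probe positional effects, and its
  separable default wildly overstates real-world accuracy by construction.
* The FIS protocol inherits impurity importance's known bias toward
  high-cardinality/high-variance features; with all features on comparable
  [0,1] scales this is mild, but permutation importance is not offered.
* Reproducing the published benchmark accuracies requires the original
  sequence files, which are an optional external input; nothing in the
  package depends on their availability.
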