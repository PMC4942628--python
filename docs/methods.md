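# Methods

This note records the model, its assumptions, the defaults, and the
design choices made where the design was genuinely open.

## The encoder

A protein over the 20 standard residues (alphabetical one-letter order
`ACDEFGHIKLMNPQRSTVWY` is the canonical index everywhere) is mapped to
`400 + n·δ` features.

**g-gap dipeptide block.** For gap `g`, ordered pair `(a, b)` gets
`count{t : seq[t]=a, seq[t+g+1]=b} / (L − g − 1)`. All `L − g − 1`
positions are counted, so the closed-form denominator equals the total
pair count and the block always sums to 1. Pair indexing is
first-residue-major: `(a, b) → 20·idx(a) + idx(b)`. The convention is
arbitrary but fixed, and feature names (`dipeptide:AB:gap2`) make it
auditable in every exported table.

**Correlation block.** Each of the nine property scales is standardized
over the 20 amino acids with the *population* standard deviation
(divisor 20) — implemented exactly as defined, not with the sample
divisor 19. The lag-`d` factor for property `j` is the plain average of
the products `ρj(R_t)·ρj(R_{t+d})` — the raw product form, not the
squared-difference correlation of classic pseudo amino acid composition.
Layout is lag-major (all nine properties at lag 1, then lag 2, ...), so
a δ-truncation is a prefix of any larger δ. No weighting factor is
applied between the two blocks; they are concatenated as-is.

**Admissibility.** Ingestion requires length ≥ 8 and rejects (or skips,
per policy) sequences with residues outside the 20-letter alphabet,
including `B J O U X Z` and `*`. The encoder additionally requires
`L ≥ max(g + 2, δ + 1)` per parameter choice, which is stricter than the
global rule for `g > 6` or `δ > 7`.

**Property table.** The built-in nine-scale table is embedded as a
versioned constant and exportable/replaceable via TSV. It gives
asparagine and arginine identical pI/pK triples (10.76/2.18/9.09), which
is chemically suspicious for asparagine; the value is reproduced
verbatim as the scale this predictor family was defined with, and is
flagged here rather than corrected.

## Feature selection

The per-feature score is the two-group one-way ANOVA F statistic with
numerator df 1 and denominator df N − 2 (for two groups it equals the
squared pooled-variance t statistic; the test suite asserts both this
identity and agreement with an independent textbook implementation).
Degenerate features with zero pooled within-class variance get F = 0
when the class means are also equal (uninformative, ranked last) and
`max finite F + 1` with a logged warning when the means differ
(perfectly separating — discarding them would be worse than any ranking
artifact). Ties rank by original column index (stable sort).

Incremental feature selection evaluates nested prefixes of the ranking
and keeps the smallest size attaining the criterion maximum (fewer
features, less overfitting risk). Two evaluation modes exist:

* `incremental_feature_selection(matrix, ranking, evaluator)` — the
  generic primitive: a fixed ranking, any evaluator callback.
* `cv_incremental_feature_selection(matrix, cv, ...)` — the default used
  by grid search and the pipeline. Within each CV fold the ranking is
  **recomputed on the training samples only**, and prefix subsets of the
  fold-local ranking are evaluated on the held-out fold.

The second mode is a deliberate design choice. Ranking once on all
samples and then cross-validating the prefixes leaks the held-out labels
into the selection step; with 400+ candidate features and ~100 samples
this selection bias is large (on signal-free synthetic data it inflates
the best cross-validated balanced accuracy from ~50 % to ~80 %). The
fold-internal variant keeps null data at chance, which is the behaviour
the rest of the pipeline's guarantees (and its tests) are built on. The
reported `best_features` are the winning-size prefix of the full-data
ranking, since that is the subset the final all-data model uses.

## Classifier and protocol

* **SVM**: RBF kernel via scikit-learn's libsvm binding. Defaults
  `C = 1`, `gamma = "scale"`. A coarse grid search
  (`C ∈ 2^−5..2^15`, `γ ∈ 2^−15..2^3`, steps of 4×) is available as
  `tune_svm_hyperparams` for a chosen feature subset (typically the
  final model); it is not nested inside IFS or the (g, δ) grid, where it
  would multiply cost ~100-fold for no benefit at the problem sizes this
  package targets.
* **Scaling**: per-feature min-max to [−1, 1], fit on training folds
  only (the standard libsvm preprocessing recipe); constant features map
  to a constant and are harmless.
* **Cross-validation**: stratified, shuffled k-fold (default 5) for
  parameter/subset search; jackknife (leave-one-out) for final
  verification. Fold assignment derives from the single top-level seed;
  given (inputs, config, seed) every number is reproducible bit for bit.
* **Imbalance**: no class weighting. Instead, after jackknife scoring of
  the selected subset, the decision threshold is swept over all midpoints
  of consecutive distinct decision values (plus sentinels) and the value
  maximizing average accuracy AA is kept; ties break by higher MCC, then
  higher OA, then the smaller threshold. A sample is called positive when
  its decision value is ≥ the threshold.
* **(g, δ) grid**: default ranges g = 0..9, δ = 1..10 (100 cells). The
  winning cell maximizes cross-validated OA with ties to the smallest
  subset size, then the smaller (g, δ). The full grid with per-cell IFS
  over all 400 + 9δ prefixes is expensive; `max_size`/`stride` options
  cap or thin the IFS curve, and examples in this repository use reduced
  grids (e.g. g = 0..3, δ = 1) with subset sizes capped at 15–30, which
  keeps full runs in the seconds-to-minutes range.

## Metrics

Sn, Sp, OA, AA are exact ratios kept in percent at full precision;
rounding to 2 dp (rates) and 3 dp (MCC) happens only in display
formatting. MCC with a zero denominator factor is reported as 0 with a
degeneracy flag. auROC uses the rank-sum (Mann–Whitney) convention with
ties credited 1/2, identical to trapezoidal integration of the tie-aware
curve; the ROC is plotted as Sn against 1 − Sp.

`counts_from_rates` inverts printed Sn/Sp percentages to integer
confusion counts by exhaustive search over feasible counts (tolerance:
half a unit in the last printed decimal). It exists for consistency
checking of published summary tables: for the reference 68/307 benchmark
rows it recovers unique counts that reproduce every printed OA, AA and
MCC, confirming the summaries are internally coherent. This arithmetic
check is all the real benchmark contributes here — the dataset itself
(UniProt query, evidence filtering, fragment removal, CD-HIT at 40 %
identity) is documented but deliberately not reconstructed, so the
published headline numbers (AA 84.82 %, auROC 0.926, a 63-feature
optimal subset at g = 4, δ = 7) are not reproduction targets: they
depend on that dataset and on unstated SVM hyperparameters.

## Synthetic data

The generator emulates only what the pipeline needs to be testable:
two classes of realistic size (defaults 68 vs 307, matching the real
benchmark's imbalance), lengths 60–200 residues, sequences from a
first-order Markov chain whose near-uniform transition rows are drawn
once per seed and shared by both classes. A first-order chain (rather
than i.i.d. residues) was chosen so lagged correlation features can
carry signal that is not reducible to single-residue composition.

Signal is planted in positives only, as a mixture with weight
`effect_size ∈ [0, 1]` (0 ⇒ the classes are generated by the identical
law; values > 1 would leave the probability simplex and are rejected):

* *dipeptide*: when the residue `g+1` back is the first member of one of
  K designated pairs (default 3: KE, WC, PG), the successor distribution
  is tilted toward the pair's second member — enriching exactly K g-gap
  dipeptides.
* *property_correlation*: successors are tilted toward residues with
  similar normalized hydrophobicity (Gaussian affinity, bandwidth 0.5 on
  the standardized scale), raising lag-1 correlation factors.

What passing tests on this generator do **not** show: performance on
real lyases. Real sequences have domain architecture, signal peptides,
compositional heterogeneity and homology structure that a first-order
chain cannot express; synthetic results validate the machinery
(encoding, selection, CV hygiene, threshold tuning), not biological
accuracy.

## Numerical and degenerate-input conventions

* Property normalization refuses constant rows (division by zero).
* Encoder errors name the offending record and the violated bound.
* All decision values identical ⇒ threshold sweep warns and returns that
  value with metrics computed.
* ROC with a single class present is an error, not a NaN.
* The property matrix is forced C-contiguous before normalization so the
  summation order — and hence the last bits of every downstream number —
  does not depend on how the table was constructed (this makes model
  save/load round trips bit-identical).
* Model archives are a zip of a JSON manifest (parameters, feature
  names, threshold, property table, provenance) plus the serialized
  scaler+SVM state.

## Known limitations

* Jackknife threshold tuning happens after subset selection on the full
  data, mirroring the verification protocol this predictor family uses;
  its reported numbers are therefore mildly optimistic and should be
  read as verification, not as an unbiased generalization estimate (the
  grid-search CV numbers, which are fold-honest end to end, are the
  conservative ones).
* Only binary classification; no probability calibration (raw decision
  values); no alternative descriptor families (CTD, PSSM profiles) and
  no alternative learners bundled — the evaluator interface accepts
  external ones.
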