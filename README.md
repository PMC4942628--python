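# lypred

Predict **bacterial cell wall lyases** — phage endolysins and bacterial
autolysins that degrade peptidoglycan and are promising antibacterial
agents — from protein sequence alone.

Wet-lab identification of lyases is slow and expensive; `lypred`
implements a sequence-based machine-learning predictor for the problem,
aimed at computational biologists who want either a ready-to-run
classifier or the individual building blocks (feature encoder, feature
selection, evaluation) as a library.

## Method

A protein `P = R1 R2 ... RL` is encoded by an improved **pseudo amino
acid composition** in `400 + n·δ` dimensions:

* **g-gap dipeptide composition** (400 values): the frequency of every
  ordered residue pair `(a, b)` separated by exactly `g` positions,
  `φ(a,b) = n_g(a,b) / (L − g − 1)`, capturing local sequence order.
* **Lagged physicochemical correlation factors** (`n·δ` values): for each
  of `n = 9` property scales (hydrophobicity, hydrophilicity, rigidity,
  flexibility, irreplaceability, side-chain mass, pI, pK α-COOH,
  pK α-NH3+; each standardized to zero mean and unit population variance
  over the 20 amino acids) and each lag `d = 1..δ`,
  `ε = (1/(L−d)) Σ_t ρ(R_t)·ρ(R_{t+d})`, capturing global sequence order.

Features are ranked by the two-group **ANOVA F-score**
`F = SSB / (SSW/(N−2))` and pruned by **incremental feature selection**
(IFS): nested prefixes of the ranking are scored with a cross-validated
RBF-kernel **SVM** (min-max scaled to [−1, 1], scaling fit on training
folds only), and the best prefix wins, ties going to fewer features. The
two encoder parameters are searched on the 10 × 10 grid `0 ≤ g ≤ 9`,
`1 ≤ δ ≤ 10`. Because lyase benchmarks are imbalanced, the final decision
threshold is swept over the jackknife (leave-one-out) decision values to
maximize the **average accuracy** `AA = (Sn + Sp)/2`; Sn, Sp, MCC, OA, AA
and auROC are reported.

A built-in synthetic-data module generates two-class protein sets from a
first-order Markov chain with signal planted either in specific g-gap
dipeptides or in hydrophobicity runs, so the whole pipeline is testable
without any external database. See `docs/methods.md` for modelling
details and design choices.

## Worked example

Generate a synthetic benchmark with dipeptide signal planted at gap 2,
then run the full pipeline at `(g = 2, δ = 1)`:

```bash
lypred --seed 13 simulate --n-pos 22 --n-neg 22 --length-min 60 \
    --length-max 100 --planted-g 2 --effect-size 0.8 -o demo
lypred --seed 13 --g 2 --delta 1 run demo.fasta demo.labels.tsv \
    -o demo_run --max-size 15
```

The run prints the evaluation summary (abridged):

```json
{
  "cv_best": {
    "Sn": 100.0, "Sp": 100.0, "MCC": 1.0, "OA": 100.0, "AA": 100.0,
    "auROC": 1.0, "TP": 22, "FN": 0, "TN": 22, "FP": 0
  },
  "jackknife_at_threshold": {
    "Sn": 100.0, "Sp": 100.0, "MCC": 1.0, "OA": 100.0, "AA": 100.0,
    "auROC": 1.0, "TP": 22, "FN": 0, "TN": 22, "FP": 0
  },
  "n_selected_features": 3,
  "threshold": 0.15835907389052284
}
```

Reading: 5-fold cross-validated IFS found that the three top-ranked
features — exactly the three planted gap-2 dipeptides (KE, WC, PG) —
separate the classes perfectly already in cross-validation; jackknife
verification with the tuned decision threshold confirms it (all 22
lyases and 22 nonlyases correct, MCC = 1, auROC = 1). Real sequence data
is far harder than this strongly-planted toy; the point of the example is
the workflow and the report format.
`demo_run/` contains the feature matrix, F-score ranking, IFS curve,
evaluation report and the serialized model; `lypred predict model.zip
query.fasta -o preds.tsv` applies the model to new sequences (length ≥ 8,
20 standard residues only).

The `grid` subcommand reproduces the full 100-cell `(g, δ)` search and
writes a table directly renderable as a heat map.

## Scope notes

The curated real benchmark (UniProt-derived, evidence-filtered, CD-HIT
redundancy-reduced at 40 % identity) is *not* bundled or downloaded;
dataset construction of that kind is out of scope here, and the synthetic
module stands in for it during testing. No web front end is provided —
the CLI replaces it.
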