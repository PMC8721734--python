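# snare-sap

Recognition of SNARE proteins from PSI-BLAST PSSM profiles with a kernel
support vector machine.

SNARE (soluble N-ethylmaleimide-sensitive-factor attachment protein
receptor) proteins drive vesicle–membrane fusion and exocytosis;
distinguishing them from other vesicular-transport proteins is a
strongly imbalanced binary classification problem. `snare-sap`
implements the full recognition pipeline as a reusable, tested library
plus CLI:

1. **PSSM-400 encoding** — each protein's PSI-BLAST position-specific
   scoring matrix (L×20 log-odds scores) is collapsed to a fixed
   400-dimensional vector: cell (a, b) is the sum over all positions
   occupied by residue *a* of the score in column *b*.
2. **Scaling** — min-max normalization x* = (x − min)/(max − min) to
   [0, 1] by default (z-score and row-wise L2 available), fitted on the
   training split only and reused on test data.
3. **Feature selection** — SVM-RFE with correlation-bias reduction
   (CBR): a linear SVM is retrained on the surviving features each
   round, feature *i* is scored by its squared primal weight w_i², and
   the lowest-scoring feature is eliminated — except that mutually
   correlated features (|Pearson r| ≥ τ, grouped by transitive closure)
   may lose at most one member per round, preventing a redundant group
   whose shared weight depresses each member's score from being unfairly
   eliminated together.
4. **Classification** — soft-margin SVM, decision value
   f(x) = Σᵢ αᵢ yᵢ K(xᵢ, x) + b, with linear, polynomial, RBF and
   sigmoid kernels. Tuned defaults: RBF, C = 11, γ = 0.1, top-350
   features.
5. **Evaluation** — Sn, Sp, Acc, MCC, F-score, ROC/AUC, and stratified
   10-fold cross-validation, the metric suite for heavily imbalanced
   data (the reference splits are 644/2,234 positives/negatives for
   training and 38/349 for independent testing).

A synthetic-fixture generator produces profiles in the same ASCII
dialect the parser reads, with class signal planted in known
(residue, column) cells, so every stage — including recovery of the
informative features by RFE-CBR — is testable without PSI-BLAST runs or
database downloads.

## Worked example

Generate 160 synthetic profiles (40 SNARE-like positives, strong
signal), encode, rank, train on the top 50 features and evaluate:

```sh
$ snare-sap make-fixtures --out fx --n-pos 40 --n-neg 120 --delta 3.0 --seed 7
wrote 160 profiles + labels.csv to fx
$ snare-sap encode --pssm-dir fx --labels fx/labels.csv --out features.csv
wrote 160 x 400 feature table to features.csv
$ snare-sap encode --pssm-dir fx --labels fx/labels.csv --out scaled.csv --scale minmax
wrote scaler params to scaled.scaler.json
wrote 160 x 400 feature table to scaled.csv
$ snare-sap rank --features scaled.csv --out ranking.csv --step 20
wrote ranking of 400 features to ranking.csv
$ snare-sap cv --features scaled.csv --folds 5 --seed 1
5-fold CV: acc=0.8750 sn=0.5000 sp=1.0000 mcc=0.6533 auc=0.9958
$ snare-sap train --features features.csv --ranking ranking.csv --top-k 50 --out model.json
trained rbf SVM on 160 x 50; 43 support vectors; saved to model.json
$ snare-sap evaluate --model model.json --features features.csv --out report.json
acc=1.0000 sn=1.0000 sp=1.0000 mcc=1.0000 auc=1.0000
```

The CV line reports fold-averaged metrics on held-out folds (Sn lags Sp
because positives are the 1:3 minority and the per-fold positive count
is small); the final line is training-set performance of the saved
model, whose JSON stores the kernel configuration, support vectors, dual
coefficients, bias, the fitted scaler and the selected feature ids, so
`evaluate`/`predict` can start from raw, unscaled feature tables.
`snare-sap run` chains every stage from a YAML config and writes all
artifacts (`ranking.csv`, `model.json`, `cv_report.json`,
`test_report.json`) deterministically — re-running the same config
reproduces them bit-for-bit.

The library mirrors the CLI one-to-one:

```python
import snaresap as ss

train, test = ss.generate_table1_shape(seed=1, delta=3.0)  # 2878 + 387 samples
report = ss.run_pipeline(ss.RunConfig(out_dir="run"), train=train, test=test)
print(report.acc, report.mcc)
```

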