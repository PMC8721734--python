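# Methods

## The model

`snare-sap` treats SNARE recognition as binary classification of
evolutionary profiles. The input object is a PSI-BLAST position-specific
scoring matrix (PSSM): for a protein of length L, an L×20 matrix of
integer log-odds scores, one column per canonical amino acid in
PSI-BLAST order (`A R N D C Q E G H I L K M F P S T V W Y`). Labels are
+1 (SNARE) and −1 (non-SNARE, typically other vesicular-transport
proteins).

### PSSM-400 encoding

The variable-length profile is mapped to a fixed 400-dimensional
composition vector: cell (a, b) is the sum of column-b scores over all
positions occupied by residue a, flattened as index `20·a + b`. This is
the standard residue-grouped column-sum construction ("PSSM-400").
Properties that the tests pin down: output dimension is always 400; the
encoding is invariant to row order and additive over profile
concatenation; positions carrying non-canonical letters (X, B, Z, U, O)
contribute to no cell, and a profile with no canonical position is
rejected. Raw log-odds values are summed with no per-position squashing
and no division by length — downstream min-max scaling absorbs overall
scale, and a `length_normalize` flag (default off) exists for
exploration. Feature magnitudes therefore grow with sequence length,
which is deliberate: scaling, not the encoder, owns normalization.

### Scaling

Three methods are provided; min-max is the pipeline default:

* **min-max**: x* = (x − min)/(max − min) per feature, fitted on the
  training split; applied values are clipped to [0, 1] so unseen data
  cannot leave the contract range. A constant feature maps to 0, never
  NaN.
* **z-score**: (x − mean)/σ with population σ; σ = 0 maps to 0.
* **L2**: each row divided by its Euclidean norm; all-zero rows pass
  through unchanged (stateless, nothing fitted).

Scalers are fitted on training data only and reused on test data. The
suite contains a leakage guard: fitting on train ∪ test measurably
changes the scaled training statistics whenever the test split widens a
feature's range, so the train-only discipline is detectable, not just
asserted.

### Feature selection: SVM-RFE with correlation-bias reduction

Recursive feature elimination with a **linear** soft-margin SVM
(penalty `ranking_C`, default 1.0) regardless of the final classifier's
kernel, because the ranking criterion c_i = w_i² needs a primal weight
vector (ω = Σ αᵢ yᵢ xᵢ over the surviving columns). Each iteration:

1. fit the linear SVM on the survivors and score each by w_i²;
2. partition survivors into correlated groups — connected components of
   the graph with edges |Pearson r| ≥ τ (default τ = 0.7);
3. eliminate up to `step` features (default 1) in ascending criterion
   order, skipping any feature whose group already lost a member this
   iteration; criterion ties break toward the lower original feature
   index.

The guard in (3) is the correlation-bias-reduction step: features that
duplicate each other split their discriminative weight, so each looks
individually weak; forbidding whole-group elimination within one round
keeps at least one representative alive until the group is genuinely
uninformative. When no correlation reaches τ the procedure reduces
exactly to vanilla SVM-RFE, verified against scikit-learn's `RFE` order
bit-for-bit. Pairwise Pearson correlations between two columns do not
depend on which other columns survive, so the correlation matrix is
computed once up front and subset per iteration. Constant features
correlate with nothing (NaN → 0). The returned ranking is the reverse
elimination order together with the full trace (round and criterion per
feature), which replays to the surviving set at any iteration.

The default cut keeps the **top 350** of 400 features, the tuned
operating point of the pipeline; `sweep_top_k` recomputes stratified-CV
accuracy over any list of cuts to re-derive such a point.

### Classifier

Soft-margin SVM (minimize ½‖ω‖² + CΣεᵢ) with four kernels:

* linear: xᵢᵀxⱼ
* polynomial: (γ xᵢᵀxⱼ + r)^d
* RBF: exp(−γ‖xᵢ − xⱼ‖²)
* sigmoid: tanh(γ xᵢᵀxⱼ + r)

The quadratic program is delegated to scikit-learn's libsvm backend
(solver tolerance and caching at that backend's defaults); this package
owns the kernel formulas (tested against hand values and against the
solver), configuration validation, persistence and the decision
contract: f(x) = Σ αᵢ yᵢ K(xᵢ, x) + b computed from the stored support
vectors with the package's own kernel code, label = sign(f) with ties to
+1. Every fit is checked against the KKT conditions (0 ≤ αᵢ ≤ C,
|Σ αᵢ yᵢ| ≤ 1e−6) and the kernel-expansion decision values must match
the solver's to 1e−6. γ is always explicit (default 0.1) — the LIBSVM
1/K fallback convention is documented but never used. Defaults are the
tuned operating point: RBF, C = 11, γ = 0.1. No class weighting by
default; `class_weight="balanced"` is available for exploration. Models
serialize to versioned JSON carrying the kernel config, support vectors,
dual coefficients, bias, fitted scaler and selected feature ids, so a
loaded model reproduces scores bit-for-bit from raw features.

### Evaluation

With +1 the positive class: Sn = TP/(TP+FN), Sp = TN/(TN+FP),
Acc = (TP+TN)/N, F = 2TP/(2TP+FN+FP), and
MCC = (TP·TN − FP·FN)/√((TP+FN)(TN+FN)(TP+FP)(TN+FP)). Any 0/0
denominator defines the metric as 0. MCC is implemented over its full
mathematical range [−1, 1] (a perfectly inverted classifier scores −1),
although the slogan range is sometimes misprinted as [0, 1]. All
intermediate products are exact Python integers, so each metric is a
single correctly-rounded division; the acceptance suite checks 10⁵
random tables against rational-arithmetic oracles exactly. ROC/AUC uses
threshold sweeping and the trapezoidal rule on decision scores (not
probabilities), equal to the Mann-Whitney pair-ranking probability with
ties counted ½, verified against an O(n²) pair-counting oracle to
1e−12.

Cross-validation is stratified (seeded shuffle) — necessary because the
reference-scale independent test split holds only 38 positives, and
unstratified folds could go single-class. The headline CV report is the
unweighted mean of per-fold metrics; pooled confusion counts and the
pooled-counts report are attached alongside because both conventions
appear in practice, and per-fold reports are retained.

## Synthetic data: what it emulates and what it does not

The generator emulates the *statistical interface* of the real problem:
integer log-odds profiles in the PSI-BLAST ASCII dialect, uniform
residues, background scores ~ round(Normal(0, noise_sd)), and a class
difference confined to chosen (residue, column) cells — the exact
coordinates the encoder sums — so feature-selection recovery has planted
ground truth. Defaults, chosen once as plausible for this problem class:
sequence lengths uniform on [50, 300] (typical SNARE scale), noise_sd 2
(log-odds are small integers), 10 informative cells on distinct
residues, effect size δ = 3 per occupied position for strong-signal
runs. `generate_table1_shape` reproduces the reference splits' exact
class counts (644/2,234 train, 38/349 test).

What it does **not** emulate: residue composition bias, positional
dependence along the chain, homology between sequences, and the diffuse
many-weak-features signal of real evolutionary profiles. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
it recovers signal of the planted form under realistic imbalance — they
do not certify real-data accuracy figures, which depend on the
UniProt-derived corpus. On the strong-signal synthetic splits the
end-to-end run is expected to perform near ceiling (test Acc ≳ 0.99),
far above what heavily-overlapping real classes allow; the acceptance
thresholds (Acc ≥ 0.90, MCC ≥ 0.4) are correctness floors for the
machinery, not real-data claims.

## Numerical and design choices

* **File formats.** The PSSM parser targets the `-out_ascii_pssm`
  format family rather than one emitter version: both 40-column
  (log-odds + percentages) and 20-column variants are accepted, always
  taking the first 20 numeric columns; the Lambda/K footer and trailing
  whitespace are ignored. Positions are 1-based in files, 0-based
  internally. Feature tables are CSV (`label,f0,...`) written with
  shortest-round-trip float representations and parsed with numpy's
  correctly-rounded reader, so write∘read is bit-identical.
* **Determinism.** Ranking is deterministic given its inputs; CV folds
  and fixtures derive from explicit integer seeds; pipeline artifacts
  contain no timestamps, so identical configs reproduce identical bytes.
* **Tie-breaking.** Lower original feature index wins everywhere a
  criterion ties, for reproducibility.
* **Degenerate inputs.** Single-class matrices are rejected by ranking,
  training and CV with actionable messages; constant features are legal
  throughout (scale to 0, correlate with nothing, carry zero weight).
* **Imbalance regime.** At weak signal, models trained under the ~1:3.5
  train imbalance favour the majority class, so specificity ≥
  sensitivity on the 1:9 test split — asserted as a property of the
  generator + pipeline at δ = 1.

## Problem sizes

The test suite and the acceptance script run the full reference-shaped
pipeline (2,878 training samples × 400 features, complete 400-round
RFE-CBR ranking, 10-fold CV, 387-sample test) in about a minute on one
CPU; smaller property tests use 40–200 samples. The top-k sweep
defaults (`50:400:50`) match the granularity at which the 350-feature
operating point was originally located.

## Known limitations

* The exact mechanics of the original CBR proposal are not fully
  specified in the source material for this pipeline; the group-guard
  variant implemented here captures its stated purpose and reduces to
  plain RFE in the uncorrelated limit, but may order features
  differently from other CBR implementations when τ-groups are large.
* The ranking SVM is always linear; nonlinear-kernel RFE criteria are
  out of scope.
* No probability calibration; decision scores feed ROC directly.
* Real PSSM generation (PSI-BLAST against NR) is consumed, not
  performed.
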