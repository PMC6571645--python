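# Methods

## Problem setting

Anticancer peptides (ACPs) are short (here 2–60 residues, typically 30–50)
sequences over the 20 canonical amino acids whose anticancer activity is to
be predicted from primary sequence alone. The package treats this as binary
classification with `ACP` the positive class and `nonACP` the negative
class, and covers the whole desk workflow: curation, encoding, modelability
screening, tuned classification, rigorous validation, and interpretation.

## Curation

Sequences are restricted to the canonical alphabet; any ambiguity letter
(B, J, O, U, X, Z), gap, digit or other symbol is a hard validation error
naming the offending character. Redundancy reduction replaces an external
clustering binary with an internal greedy scheme: within each class,
sequences are visited longest-first and a sequence joins the first retained
representative with which its identity exceeds the threshold (default 0.9),
otherwise it becomes a representative. Identity between two sequences is the
maximum number of identically aligned positions under a global alignment
scored match=1 / mismatch=0 / gap=0 (equivalently the longest common
subsequence), divided by the shorter length — the convention of the widely
used clustering tools. The filter is applied within each class because
cross-class near-duplicates are informative rather than redundant; this
choice matters to anyone comparing retained counts across implementations.

## Descriptors

All encoders are deterministic and use the fixed residue order
`ACDEFGHIKLMNPQRSTVWY`.

* **AAC** (20-D) and **DPC** (400-D): residue and overlapping adjacent-pair
  frequencies; each row sums to 1. DPC requires length ≥ 2.
* **PCP**: one column per property scale — the mean over residues of the
  scale standardized to mean 0 / SD 1 (population SD) over the 20 residues.
  The exact historical encoding of "531 AAindex properties" is not uniquely
  defined anywhere we could pin down; this per-property standardized mean is
  the simplest interpretable choice and is flagged as a design decision. Ten
  informative AAindex scales (hydrophobicity, helix/sheet propensity,
  volume, accessibility, flexibility) plus Hopp-Woods hydrophilicity are
  bundled; arbitrary scales load from AAindex1 flat files, skipping entries
  with NA values.
* **PseAAC** (type 1, 20+λ): sequence-order factors
  `θ_j = mean_i Θ(R_i, R_{i+j})` with
  `Θ(a,b) = ⅓ Σ_p (H_p(b) − H_p(a))²` over three standardized base scales
  (hydrophobicity, hydrophilicity, side-chain mass); components
  `f_u/(1 + w Σθ)` and `w θ_j/(1 + w Σθ)`, so the vector is non-negative
  and sums to 1.
* **Am-PseAAC** (20+2λ): per gap j, two factors
  `τ_{2j−1} = mean_i H1(R_i)H1(R_{i+j})` and the same with H2. Because the
  τ are products of standardized scales they can legitimately be negative;
  only the sum-to-1 property holds for this encoder.

Defaults λ=30, w=0.05 (the defaults of the standard descriptor software for
these encodings); any sequence with length ≤ λ raises a validation error
naming the constraint, and the bundled generator defaults to lengths 31–60
precisely so λ=30 is always valid. A stated "20 + λ×ϖ" dimension in the
source literature for type-1 PseAAC is treated as a typographical slip for
the standard 20+λ.

## Modelability (MODI)

For each class, the fraction of its samples whose single nearest neighbour —
Euclidean distance on per-column standardized features, self excluded — has
the same label; MODI is the unweighted mean of the two fractions, and a
dataset is called modelable when MODI > 0.65. The published recipe does not
state whether features were standardized first; standardization is adopted
(and configurable) because it makes the score invariant to per-column
rescaling. Ties are broken by lowest sample index; an exact duplicate row
(distance 0) is a legitimate neighbour; zero-variance columns are dropped
with a warning.

## Classifiers

Both algorithms are tuned by stratified 5-fold grid search on accuracy
(shuffled folds seeded from `random_state`) and refit on the full data:

* **RF**: n_estimators ∈ {100, 200, 300, 400, 500} × max_features ∈ 1..10
  (clipped to the feature count). Features are used raw.
* **SVM**: RBF kernel, C ∈ {0.25, 0.5, 1, 2, 4}. Features are standardized
  with train-set mean/SD (frozen into the model); the kernel width is fixed
  before the C search by the median-pairwise-distance heuristic
  γ = 1/(2·median²) on the standardized training data (deterministic
  subsample of 500 rows when larger). Kernel, scaling and calibration are
  not specified by the original modelling protocol, so these conventional
  choices are explicit substitutes. Probabilities come from Platt scaling
  fit on the training data.

Scores are P(ACP) (RF: averaged tree leaf probabilities, i.e. vote fraction
for pure leaves); predicted labels are exactly `score > 0.5`, so label and
score outputs can never disagree. Models persist to a single joblib artifact
with an embedded schema version; loading a mismatched version is refused.

## Evaluation

Ac, Sn, Sp are percentages; MCC uses the standard square-root denominator
and is reported as 0 with a `degenerate` flag when any denominator factor is
zero (the sources are silent on this edge case). auROC is the Mann-Whitney
probability that a random positive outscores a random negative with ties
counted ½, which equals the trapezoidal area under the ROC curve; 1 is
perfect, 0.5 is chance.

5-fold CV uses class-stratified folds assigned from the seeded RNG;
the jackknife leaves out each sample in turn. In both protocols the full
grid search is re-run inside every outer training split (no leakage), and
the held-out predictions are pooled into a single confusion matrix —
pooling rather than per-fold averaging is adopted because the jackknife
forces it anyway, keeping the two protocols comparable; `kfold_cv` with
k = N reduces exactly to the jackknife.

## Interpretation

* **MDGI**: per feature, the sum over splits of (node sample fraction ×
  Gini decrease), averaged over trees — the unnormalized impurity
  importance, reported with ranks.
* **Composition differences**: per residue, mean per-sequence composition
  (%) in each class, the ACP − nonACP difference, |difference| rank, and a
  two-sided p-value from Welch's t-test on per-sequence compositions
  (Mann-Whitney available); the t-test is the default because the quantity
  tabulated is a difference of means.
* **Rules**: every root-to-leaf path of the first 100 trees becomes a
  candidate rule predicting the leaf majority class. Duplicate bounds on
  the same feature/direction are merged to the tightest; conditions whose
  removal does not reduce training-set accuracy are greedily pruned;
  identical rules are de-duplicated; rules are ranked by accuracy then
  coverage. Rules are evaluated on the extraction (training) set —
  coverage/accuracy are descriptive of what the forest memorized, not
  held-out estimates. Reports take a per-class top-N (default 8);
  thresholds print at 4 decimals; the text form
  `C > 0.1145 and P ≤ 0.073 → ACP` round-trips through the parser.
  Rule-based prediction returns the class of the first firing rule and
  abstains when none fires.

## Balancing

SMOTE with the classic percentage semantics: `floor(n_min·perc_over/100)`
synthetic minority rows, each `x + u·(x_nn − x)` with u ~ U(0,1) and x_nn
one of x's k nearest minority neighbours (defaults k=9, perc_over=50,
perc_under=300); the majority class is then downsampled to
`floor(n_syn·perc_under/100)` rows — without replacement when enough rows
exist, topping up with replacement otherwise (the percentage arithmetic can
demand more rows than exist: 138/205 inputs yield 207/207, two more than
the 205 available majority samples, matching the reference implementation's
with-replacement behaviour). An explicit `target_counts` override bypasses
the percentages for workflows needing exact sizes such as 205/205. All
randomness is seeded.

## Synthetic data

The generator draws peptide lengths uniformly from a range and residues
i.i.d. from a class-specific composition vector. `table5_spec` uses the
published mean residue compositions of the curated 138 ACP / 205 non-ACP
benchmark (renormalized from percentages), so the generated classes differ
in composition exactly where the real classes do; `contrasted_spec`
interpolates between identical-uniform and a strong KLFIW-vs-ADGSE
contrast. The i.i.d. model deliberately has no positional structure, motifs
or secondary-structure signal: passing tests demonstrate that the pipeline
recovers compositional class contrast correctly, not that it would reach
the same numbers on real peptides, where sequence order carries additional
information. On these synthetic sets the AAC block is the causally
informative descriptor family, which is why tuned models approach or exceed
real-benchmark accuracy levels.

## Problem sizes and tolerances

The shipped tests and the acceptance script use desk-scale problems chosen
to probe each property at adequate statistical power: encoder oracles on
100 random peptides at 1e-10; MODI null behaviour over 50 seeds at n=400
(3-SE band); jackknife protocol fidelity at n=40 against an independent
retrain loop; benchmark-contrast recovery at the published class sizes
138/205 with the full SVM grid; SMOTE arithmetic at the same sizes.
Floating-point assertions use absolute tolerances between 1e-12 and 1e-9
except where a check is exact by construction (counts, dimensions,
round-trips).

## Known limitations

* The PCP encoding is a stand-in (see above); with the bundled 11 scales it
  is 11-D, not 531-D, unless a full AAindex1 file is supplied.
* The identity filter is a faithful greedy stand-in for external clustering
  tools, not a reimplementation of any specific one; retained counts can
  differ from theirs on ties.
* Rule quality metrics are training-set quantities by design.
* The synthetic generator cannot validate claims that depend on sequence
  order (DPC and the pseudo-composition tails carry only weak signal under
  the i.i.d. model).
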