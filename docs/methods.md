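# Methods

This note documents the models, numerical choices and limitations of
`arpcm`. It describes what the code computes; every number quoted in the
README's example is printed by the code itself.

## Curve-to-phenotype rules

A dose–response curve is an 11-point series of percent-of-wild-type
activation values on a fixed concentration grid: the 0 μM vehicle control
followed by 0.0025, 0.0076, 0.023, 0.069, 0.206, 0.617, 1.852, 5.556,
16.667 and 50 μM. Non-default grids are accepted; "response at 0 μM / at
50 μM" then generalises to the first/last grid point.

Classification uses three thresholds (percent of WT activity, all
comparisons strict):

* `nonresponsive_mean_max` = 5 — mean activation over **all** points,
  vehicle control included, below this → non-responsive (code 0);
* `antagonist_top_max` = 10 — a curve with a decreasing trend
  (a(50) < a(0)) ending below this → antagonist (1); a decreasing curve
  ending at or above it is the u-shaped mixed-response (3);
* `agonist_min_floor` = 50 — a non-decreasing curve whose minimum stays
  above this → agonist (2).

Precedence is non-responsive → trend split → agonist: the later rules
presuppose a mean ≥ 5%. Two degenerate situations are resolved explicitly:

* **Endpoint tie.** a(50) = a(0) counts as non-decreasing, because a
  decreasing trend is defined strictly as "lower than".
* **Residual case.** A non-decreasing curve whose minimum is ≤ 50% (partial
  activation) is covered by none of the four rules. It is assigned
  mixed-response — the closest phenotype in meaning — with a warning; a
  strict mode raises instead so audits can surface such curves.

An independently coded restatement of these rules serves as a test oracle
and agrees with the engine on 10,000 random curves including
boundary-hard cases.

## Featurization

**Protein block.** Substitutions are applied to the full canonical sequence
(1-based numbering, wild-type residue verified at every position), and the
mutated sequence is then trimmed to one shared window
[min mutated position, max mutated position] (padding configurable,
default 0) computed over the whole dataset — one window so all vectors have
equal length; it is stored in the model manifest and re-applied verbatim at
prediction time. A prediction-time mutant outside the window raises: the
model cannot represent it. Each residue contributes the five z-scale scores
(lipophilicity, steric bulk, polarity, two electronic components). The
table ships as a versioned JSON data file
(`arpcm/data/zscales.json`, version `sandberg1998-5`, values of the
published five-component set) so the lookup has no runtime dependency.

**Drug block.** 2048-bit binary Morgan fingerprint, radius 2 (RDKit).
Hash collisions are accepted as standard behaviour; counts are binarized.

**Standardization.** Only the z-scale block is standardized to zero mean
and unit variance; fingerprint bits are left as one-hot features. The
scaler is fitted on the training partition only (consistent with keeping
the oversampler inside training folds); zero-variance columns map to 0.

## Borderline-SMOTE

Implemented from the algorithm's published description, borderline-1
variant: a minority sample is in the *danger* set when, among its
m = 10 nearest neighbours in the whole training set, at least m/2 but fewer
than m belong to other classes (exactly m foreign neighbours marks noise and
is excluded). Danger samples seed synthesis: each synthetic row is
x + u·(x_nn − x), u ~ U(0,1), toward one of the seed's k = 5 same-class
nearest neighbours, until every class reaches the majority count. Original
rows are preserved verbatim and always come first in the output.

Choices the algorithm statement leaves open:

* sampling target — equalize to the majority class count;
* empty danger set — fall back to plain SMOTE over the whole class (with a
  warning) so the balance contract still holds;
* singleton classes are an error: interpolation needs two samples;
* synthetic rows may take fractional values in fingerprint columns; they
  are deliberately left un-rounded (interpolation lives in feature space).
  This is a known modelling quirk, not a bug.

## Models

**DNN.** Input → 128 (ReLU, dropout 0.01) → 32 (ReLU, dropout 0.01) → 4
(softmax); categorical cross-entropy; mini-batch ADAM (batch 16, step
10⁻³, β₁ = 0.9, β₂ = 0.999); at most 500 epochs with early stopping when
the inner-validation loss has not improved for 20 epochs, restoring the
best weights. The inner validation split is a stratified 10% of the
training partition. The network is a compact numpy implementation
(`arpcm.nn.MLPNet`): inverted dropout at train time only, He
initialisation, fully deterministic given its seed. The 500-epoch cap and
the 10⁻³ step size are canonical ADAM-era defaults, exposed in
`DNNConfig`.

**Baselines.** RBF-kernel SVM with γ = 0.001 (C = 1.0, probability
outputs) and a random forest of 50 trees with depth ≤ 10, both via
scikit-learn.

**Decision rule.** The DNN predicts by argmax. For the shallow baselines a
per-class cutoff set is calibrated by maximizing Youden's J on out-of-fold
training predictions (5-fold); at prediction time a class "passes" when its
score reaches its cutoff, the highest-scoring passing class wins, ties
break toward the lower class code, and if no class passes the global argmax
is used. With all cutoffs at zero the rule reduces to argmax. The
calibration data choice (out-of-fold training predictions) keeps the test
partition untouched.

## Evaluation protocol

* **Split.** Stratified 80/20 by (class, drug) strata, proportional ±1 per
  stratum; singleton strata stay in training with a warning; a repair pass
  guarantees every drug with ≥ 2 samples appears on both sides. On very
  small datasets where per-stratum rounding empties the test side, a
  per-class proportional draw is used instead.
* **Cross-validation.** Stratified k-fold (k = 5) by class; per fold the
  scaler is fitted and borderline-SMOTE applied on the training portion
  only, and the validation fold is scored untouched. Fold stratification is
  by class alone; the drug-presence constraint applies to the initial
  train/test split.
* **ROC.** One-vs-rest per class, trapezoidal AUC; a class with a single
  outcome yields an undefined (NaN) AUC rather than an error. The mean
  curve is the vertical (macro) average of per-class TPR on a fixed
  101-point FPR grid, with a ±1 sd band; fold averaging uses the same grid.
* **Youden cutoffs.** Candidate thresholds are 0, 1 and all midpoints
  between adjacent sorted unique scores; a sample counts positive at
  score ≥ threshold; ties resolve to the lowest threshold; degenerate
  classes get the neutral cutoff 0.5 with a warning.
* **Report.** Precision/recall/F1 per class with the 0/0 → 0 convention
  (so never-predicted classes report zeros instead of NaN), support-weighted
  averages (weighted recall therefore equals accuracy), confusion matrix
  with true classes on rows, and multiclass MCC in the covariance
  (Gorodkin) form, which reduces to the familiar binary formula for two
  classes and returns 0 with a warning when degenerate.

## Synthetic data

The simulator emulates the four curve families of the reporter assay:

* antagonist: b + (100 − b)/(1 + (c/IC50)^h), b ~ U(0, 8),
  IC50 ~ logU(0.01, 5) μM, h ~ U(0.5, 2);
* mixed-response: the antagonist form plus a recovery hump r·c/(c + K),
  r ~ U(20, 60), K ~ U(1, 20) μM;
* agonist: 100 + (t − 100)·c/(c + E), t ~ U(120, 200),
  E ~ logU(0.01, 5) μM;
* non-responsive: constant U(0, 4).

Gaussian noise (sd 2% by default, far from rule boundaries) is added, and
parameters are re-drawn (up to 100 tries) until the rule classifier applied
to the noisy curve returns the requested phenotype — the generator can
therefore never contradict the rule engine. A `hard` mode samples near the
thresholds (antagonist floor near 10%, recovery hump near the boundary) to
stress tie handling.

Datasets assign each synthetic mutant one phenotype and pair it with a
panel of drugs (three structurally distinct real small molecules by
default, chosen only so fingerprints differ). With feature coupling
(default) the four phenotypes draw their substitution positions from four
disjoint quarters of the sequence window, which plants a clean z-scale
signal; the recovery test (DNN weighted F1 ≥ 0.9 on a held-out 20% of 120
pairs) certifies that the pipeline can extract a learnable signal, **not**
that real AR data is this separable. Real assay data has correlated
mutations, drug-specific phenotype switches and replicate noise that the
simulator does not model; absolute metric values on real data will be
lower.

Problem sizes used by the test suite and acceptance script — 10,000 random
curves for the rule oracle, 25 noise-free curves per family for the class
coverage battery, 120 pairs for pipeline recovery — were chosen as the
smallest sizes at which the checked properties are statistically
unambiguous.

## Known limitations

* The z-scale table is fixed to the five-component set; alternative
  descriptor sets are out of scope.
* No parametric dose–response fitting (IC50/EC50): the rule engine works
  directly on the summary statistics, as the phenotype definitions do.
* SVM/RF determinism holds given a seed; DNN determinism additionally
  assumes single-threaded BLAS (floating-point reduction order).
* The prediction workflow refuses mutants outside the training trim window
  rather than attempting extrapolation.
* Replicate-level assay statistics (n = 4 technical, n = 3 biological
  averaging) happen upstream of this package's inputs.
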