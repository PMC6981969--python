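# Methods

This note documents the models, numerical choices and limitations behind
`qsarstack`, in the order the pipeline runs.

## Curation model

Assay records are (compound, relation, Ki nM) triples. The activity
threshold is 1000 nM (the field's usual active/inactive cut): exact
records are active iff Ki < 1000. Censored records are admitted only when
the bound forces a class — `> v` with v ≥ threshold (inactive), `< v` with
v ≤ threshold (active); every other censored record is ambiguous and
discarded. The boundary case `< 1000` is active because Ki < 1000 is
forced.

Duplicate detection is exact string equality on the SMILES field. Real
pipelines should canonicalise SMILES with a cheminformatics toolkit first;
structural deduplication beyond string identity (tautomers, salt forms) is
out of scope. Merging averages the exact (`=`) Ki values arithmetically and
reports the relative SD of the merged values; a censored record that
contradicts the exact-value consensus flags the compound but never
overrides it (exact measurements carry more information than bounds — this
precedence was an open design choice). Censored-only compounds keep their
forced class with no Ki value.

## Preprocessing

Order is fixed: quasi-constant filter → correlation filter → clipped
standardisation. A column is quasi-constant when fewer than 1% of entries
differ from its mode. The correlation filter repeatedly drops, among the
columns still in an offending pair (|Pearson r| > 0.9), the one with the
highest mean absolute correlation to all remaining columns; ties break by
column order, making removal deterministic. Which member of a pair is
dropped is statistically arbitrary; this rule is standard practice.

Standardisation uses training mean and sample SD (ddof = 1) and clips
z-scores symmetrically at ±2. Clipping both tails is a deliberate reading
of "capped to 2": a one-sided cap would leave the low tail unbounded and
break the symmetry the applicability-domain methods assume. The fitted
recipe (columns, means, SDs, thresholds) serialises to YAML and is frozen:
applying it never re-estimates anything, so screening libraries are always
transformed in the training geometry.

Gower dissimilarity: continuous features contribute |Δ|/range, binary
features simple matching (0/1), equal weights. Because binary mismatches
contribute a full 1 while continuous differences are range-normalised,
binary variables dominate — the reason the matrix is optionally rescaled
so its maximum off-diagonal entry is 1. All-identical data makes rescaling
a division by zero; it is skipped with a warning.

## Feature ranking

Thirteen methods share one interface and return a full descending ranking.
Contingency-based filters (χ², information gain, gain ratio, symmetrical
uncertainty, OneR) discretise each column into deciles — a deterministic,
standard binning; the original study does not state its binning. ReliefF
uses all n instances and k = 10 neighbours per class on range-normalised
features. The AUC filter scores max(AUC, 1 − AUC) so anti-correlated
descriptors rank as informative. Random-forest importances (impurity and
permutation, 200 trees) and a univariate 3-fold CV logistic score stand in
for the five R-package-specific importance variants of the original
17-method battery; the methods largely agree on top features, so the
collapse loses little.

## Nested cross-validation and gating

Outer loop: stratified 10-fold (5 for the BART stand-in, which is an order
of magnitude slower); inner loop: 5-fold, reserved for hyperparameter
tuning. Library defaults are used for all classifiers (no tuning is
performed), so the inner loop is effectively idle — feature selection, the
step that leaks most easily, is refit inside every outer training fold.
Stratification is our choice (the source procedure is silent): with 27.6%
positives, plain 10-fold risks folds without actives.

Confusion counts are pooled over outer folds (not averaged per fold),
matching result tables that report single TP/TN-derived values. PPV is
reported as missing — never 0 — when no compound is predicted active.

Classifier stand-ins: "C5.0" → `GradientBoostingClassifier`, "BART" →
`HistGradientBoostingClassifier`. Both are boosted tree ensembles sharing
the originals' inductive bias but not their exact algorithms; the
workflow's claims rest on the gated ensemble, not any single learner.

The gate keeps models with BA > 70% and PPV > 70%, both strict. Among
k-variants of one classifier + selection pair, the best is the argmax of
(BA + PPV)/2 with ties going to the higher PPV.

Y-randomization permutes labels uniformly, then reruns preprocessing-aware
selection and nested CV per repeat (default 10 repeats with fresh
permutations). A single uniform permutation is equivalent to any number of
composed shuffles, so the repeat count — not a shuffle count — is the
meaningful parameter.

## Vote stacking

The 50% tier is a strict majority (vote fraction > 50), the 75% and 90%
tiers are inclusive (≥) — an asymmetry mirroring "more than 50%" vs "at
least 75%" phrasing; tiers nest by construction. With an
applicability-domain mask, a model votes only where the compound is
in-domain and the denominator becomes the in-domain model count; compounds
covered by no model are reported separately, never tiered. Screening
entries sharing a structure collapse to the best vote fraction, and
training-set members are excluded from hit lists.

## Applicability domain

All four methods work in a model's own preprocessed feature space with
Euclidean distances — an AD statement is about the training geometry the
model actually saw.

* **Roy standardization**: |z| profile against training mean/SD; inside if
  all ≤ 3; outside if all > 3; otherwise inside iff mean + 1.28·SD ≤ 3
  (the 90th percentile of the profile, assuming normality, stays within
  3 SD). The source text describes this method once as "mean ± SD" and
  once as "three standard deviations"; the 3-SD decision tree is the
  method's published form and is what is implemented. Note that after ±2-SD
  clipping in preprocessing, nothing can exceed 3 SD — the method is
  retained for unclipped spaces and completeness.
* **Sahigara kNN**: mean k-NN distance per training point; reference
  threshold Q3 + 1.5·IQR of that distribution; each training point admits
  test compounds within the mean distance of its Ki neighbours inside the
  reference (isolated points admit only exact duplicates). The published
  method offers variants; the simplest (mean k-NN distance, Tukey fence)
  is used.
* **KDEOS**: for each k in [3, 10], Gaussian-kernel density at the point
  (bandwidth = its own k-distance, floored at 1e−12) is z-scored against
  its k training neighbours' densities; scores average over k. Higher =
  more outlying. The kernel is applied to scalar distances (not a
  d-dimensional product kernel); since scores are z-scored within one
  feature space, the normalisation constant is immaterial.
* **INFLO**: density = 1/k-distance (same floor); score = mean density of
  the influence space (kNN ∪ reverse-kNN within training) over the point's
  own density; ≈1 for inliers.

KDEOS and INFLO are scores; no thresholds are published. Default verdicts
(KDEOS z > 2, INFLO > 1.5) are configurable, and the ensemble's AD-masked
voting uses Sahigara verdicts, the method used for the published final hit
list.

## Docking calibration

Convention: active iff energy ≤ cutoff (more negative = better binder).
Candidate cutoffs are midpoints between adjacent sorted unique energies
plus sentinels, which reproduces exhaustive-search behaviour without
floating-point edge cases. The optimal cutoff maximises
sensitivity + specificity; the objective is compared in exact integer
arithmetic (tp·N₋ + tn·N₊) because percent-scale floating sums can differ
in the last ulp between tied thresholds; ties break toward higher
specificity, then the more stringent cutoff. The empirical maximizer is a
noisy estimator: at the calibration conditions used in the tests
(class means −8.02 / −7.29 kcal/mol, SD 0.8, n = 175) its sampling SD is
about 0.25 kcal/mol, so individual replicates routinely land outside the
inter-mean interval even though the estimate is centred on the class
density intersection.

The 100%-specificity cutoff is the least stringent threshold strictly
below the minimum inactive energy; an inactive tying the active minimum
raises an error with a diagnostic.

Ligand efficiency divides the energy by an input property column
(molecular weight, heavy atoms, carbons, logP, logP², Wiener index, total
surface area, McGowan or van der Waals volume); properties are inputs, not
computed. RMSD is the plain root-mean-square deviation over corresponding
atoms with no superposition (docked poses share the receptor frame) and no
symmetry correction (graph-automorphism matching is out of scope).

## Synthetic data

The generator emulates the curated study conditions: a 286/752 class
split; informative descriptors as unit-variance Gaussians with a planted
standardized class shift (default effect size 1.0); correlated pairs as
base + noise scaled to r ≈ 0.95; quasi-constant columns with exactly
⌊0.005·n⌋ off-mode entries so the <1% rule holds deterministically;
duplicate assay records with lognormal Ki jitter (relative SD ≈ 12%,
matching the low replicate variability of curated assay data); docking
energies class-conditionally normal with means −8.02 / −7.29 kcal/mol and
SD 0.8, the calibration-set values. Identical spec + seed is bit-identical.

What it does **not** emulate: real descriptor distributions (heavy tails,
counts, block correlation structure), activity cliffs, scaffold
clustering, or any chemistry — SMILES are opaque tokens. Passing tests
therefore demonstrate that the machinery is correct under its statistical
assumptions, not that the models would reach any particular performance on
real kinase data.

## Problem sizes

The y-randomization reproduction (acceptance script and test) runs 10
scrambling repeats of the full nested 10×5 CV at the study's 1038-compound
scale with a two-model battery (logistic regression and a 100-tree random
forest, both on ANOVA-selected features) — a deliberate reduction from the
350-model battery, chosen because chance-level balanced accuracy is a
property of the scrambling, not of the battery size; the two families
bracket linear and nonlinear learners. End-to-end pipeline tests use a
200-compound dataset with ~50 descriptors.

## Known limitations

* Duplicate handling is string-exact; no structure standardisation.
* The inner CV loop tunes nothing under default hyperparameters.
* AD verdict thresholds for KDEOS/INFLO are conventions, not calibrated.
* The synthetic generator's independence assumptions make feature
  selection easier than on real, block-correlated descriptor matrices.
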