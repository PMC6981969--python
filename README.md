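# qsarstack

QSAR classification ensembles with applicability-domain filtering and
docking-score calibration, for ligand-based virtual screening of kinase
inhibitors.

## The problem

Given a curated set of compounds with measured inhibition constants
(Ki, nM) against a target enzyme — here modeled on c-src tyrosine kinase,
with a 1000 nM activity threshold and a 286 active / 752 inactive class
split — the goal is to screen a large chemical library for new candidate
inhibitors. `qsarstack` implements the full workflow:

1. **Curation** — assay records with relation codes (`=`, `<`, `>`) are
   labeled *active* (Ki < 1000 nM) or *inactive* (Ki ≥ 1000 nM); censored
   records are kept only when the bound forces the class (`> v` with
   v ≥ 1000 → inactive, `< v` with v ≤ 1000 → active); duplicates (same
   canonical SMILES) are merged by averaging their exact Ki values.
2. **Preprocessing** — quasi-constant descriptors (< 1% of entries off the
   mode) and one member of every descriptor pair with |r| > 0.9 are
   removed; survivors are centered, scaled, and clipped at ±2 SD. Gower
   dissimilarity summarises chemical diversity for mixed
   continuous/binary descriptors.
3. **Feature selection** — thirteen filter and importance methods (ANOVA F,
   Kruskal–Wallis, per-descriptor AUC, variance, binned χ², information
   gain, gain ratio, symmetrical uncertainty, ReliefF, OneR,
   random-forest impurity and permutation importance, univariate CV score)
   under one ranking interface, with a cross-method top-k frequency report.
4. **Modeling** — stratified nested cross-validation (10 outer / 5 inner
   folds; 5 outer for the slow boosted-tree BART stand-in) of
   classifier × selection × k configurations; metric suite
   BA = (TPR + TNR)/2, PPV, MMCE, AUC, Q₂ = 100 − MMCE, and the most
   probable random accuracy Q₂,rnd = (n₊² + n₋²)/N². Models pass the gate
   only with BA > 70% **and** PPV > 70%. Y-randomization reruns the whole
   pipeline on permuted labels; real signal must collapse to BA ≈ 50%.
5. **Ensemble** — gated models are stacked by simple majority vote;
   screening compounds are ranked by vote fraction with nested decision
   tiers (> 50%, ≥ 75%, ≥ 90%), optionally counting only votes from models
   in whose applicability domain the compound falls.
6. **Applicability domain** — four algorithms: Roy 3-SD standardization,
   Sahigara per-training-point kNN thresholds, KDEOS (Gaussian-kernel
   density z-scores over 3–10 neighbours), and INFLO (influence-space
   density ratio, k = 5).
7. **Docking post-processing** — sensitivity+specificity-optimal and
   100%-specificity binding-energy cutoffs (active iff energy ≤ cutoff),
   ligand-efficiency variants (energy / MW, heavy atoms, logP, logP², ...),
   and pose RMSD.

A synthetic-data generator (`qsarstack.synthetic`) reproduces the
statistical structure the analysis assumes — class imbalance, informative /
noise / quasi-constant / correlated descriptors, duplicate records with
jittered Ki, class-conditional docking energies — so every stage is
testable without external data.

## Worked example

```python
import numpy as np
from qsarstack import modeling, preprocess, synthetic

spec = synthetic.SyntheticSpec(n_active=286, n_inactive=752,
                               n_informative=20, n_noise=60,
                               n_quasi_constant=10, n_correlated_pairs=5,
                               effect_size=1.0, seed=17)
ds = synthetic.generate_labeled_dataset(spec)
recipe = preprocess.fit_scaler(ds.X)          # drops 10 quasi-constant
clean = synthetic.LabeledDataset(X=recipe.apply(ds.X), y=ds.y)  # + 5 correlated

print(round(modeling.random_accuracy(286, 752), 2))
# 60.08   <- chance accuracy of the 286/752 split

perf = modeling.nested_cv(clean, modeling.ModelSpec("rf", "anova", 10, seed=17))
print(round(perf.ba, 2), round(perf.ppv, 2))
# 87.96 92.56   <- balanced accuracy / precision, pooled over outer folds

res = modeling.y_scramble(clean,
                          [modeling.ModelSpec("logistic", "anova", 10, seed=17)],
                          n_repeats=10, seed=17)
print(round(res.metric_values("ba").mean(), 2))
# 49.98   <- label-scrambled models collapse to chance
```

The pipeline can also run end to end from the shell:

```bash
qss all --seed 11 --out run/        # synthetic end-to-end run
qss dockcal --seed 5 --out run/     # docking cutoff calibration only
```

Each run directory receives every stage artifact (curated table, recipe,
rankings, CV results, gated models, vote tables, AD masks, docking
calibration) plus a manifest with the config hash and seed.

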