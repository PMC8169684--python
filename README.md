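# herbiscreen

Virtual screening toolkit for **herbicide-likeness and phytotoxicity
characterisation** of small molecules. Herbicide discovery and the fight
against weed resistance both lean on two classifications: the **mode of
action** (MoA — the biochemical process a herbicide perturbs, HRAC/WSSA
letter codes) and **weed selectivity** (BL = broadleaf-selective, G =
grass-selective, NS = non-selective). `herbiscreen` builds multi-class QSAR
models for both, gates their predictions with applicability domains, and
composes them with a rule-based herbicide-likeness filter into a stepwise
screening cascade for prioritising candidate phytotoxic compounds such as
natural products.

## What it computes

* **Structure handling** — SMILES cleaning (salt stripping, charge
  neutralisation, canonicalisation), 166-bit MACCS key fingerprints, and
  frequency-based key selection (keep keys present in more than *m* training
  compounds; default *m* = 5).
* **Chemical space** — Tanimoto similarity TC = |A∩B|/|A∪B|, Jaccard
  distance 1 − TC, Ward minimum-variance clustering on the distance matrix,
  and the Dunn, Dunn2, average-silhouette and adjusted-Rand validation
  indices.
* **QSAR models** — random forest (default; alternatives: XGBoost, RBF-SVM,
  naive Bayes) tuned by grid search under repeated stratified k-fold CV.
  MoA models use retained MACCS keys; selectivity models use nine scaled
  whole-molecule descriptors (logDiff, logSw, ShapeIndex, Cat, sp3At, TPSA,
  HBA, HBD, clogP). Stratified 80:20 splits, 50:50 for classes of 3–5
  members, classes under 3 members excluded to the unclassified "Z" pool.
* **Applicability domains** — a prediction is reliable iff the maximum class
  probability exceeds 0.6 **and** the compound is near the training set:
  minimum Jaccard distance < 0.4 (structural AD, MoA) or minimum Euclidean
  distance < 2.0 in the training-scaled descriptor space (physicochemical
  AD, selectivity). All inequalities strict.
* **Herbicide-likeness** — six descriptor families: HBD ≤ 2; HBA ≤ 6 (7
  lenient); 0.5 < clogP ≤ 3.5 (4.5 lenient); 20 Å² < TPSA ≤ 120 Å²;
  0.1 < RelPSA ≤ 0.5; net charge ≤ 0. A compound is herbicide-like when it
  satisfies ≥ 4 of the six.
* **Screening cascade** — likeness filter → selectivity prediction with
  physicochemical-AD gating → MoA prediction with structural-AD gating, one
  report row per compound (audit mode computes every stage for everyone).
* **Synthetic data** — scaffold-decoration generators producing MoA-style
  classes (separable in fingerprint space) and BL/G/NS classes (separable
  only in descriptor space), so the whole pipeline is testable without any
  external download.

## Worked example

```python
import numpy as np
import herbiscreen as hs
from herbiscreen import workflows as wf

# train a mode-of-action model on synthetic scaffold classes
compounds = hs.generate_scaffold_classes(
    hs.SyntheticSpec(n_classes=4, n_per_class=25, seed=7)
)
bundle, test_ids, _ = wf.train_moa_bundle(
    compounds, split=hs.SplitSpec(seed=7),
    cv={"folds": 5, "repeats": 2}, n_trees=200,
)
X_test = wf.moa_features_for(compounds.subset(test_ids), bundle)
probs, max_p, y_pred = bundle.predict_with_probabilities(X_test.to_numpy())
y_true = np.asarray(compounds.subset(test_ids).labels("moa_label"))
report = hs.multiclass_report(y_true, y_pred)
print(f"CV accuracy:     {bundle.estimator.cv_accuracy_:.3f}")
print(f"test accuracy:   {report.overall_accuracy:.3f}")
print(f"test kappa:      {report.kappa:.3f}")
print(f"prob > 0.6:      {np.mean(max_p > 0.6):.3f}")

# gate a structurally foreign compound set
novel = hs.generate_novel_scaffold_set(20, seed=8)
X_novel = wf.moa_features_for(novel, bundle).to_numpy()
_, novel_p, _ = bundle.predict_with_probabilities(X_novel)
verdicts = hs.StructuralAD(bundle).verdicts(X_novel, novel_p)
print(f"novel rejected:  {np.mean([not v.in_domain for v in verdicts]):.2f}")

# herbicide-likeness of one compound
flags, count = hs.likeness_evaluate(hs.physchem_profile("CCNc1nc(NC(C)C)nc(Cl)n1"))
print(f"atrazine-like criteria satisfied: {count}/6")
```

prints

```
CV accuracy:     1.000
test accuracy:   1.000
test kappa:      1.000
prob > 0.6:      1.000
novel rejected:  0.90
atrazine-like criteria satisfied: 6/6
```

The four scaffold classes are structurally separable, so the forest
classifies the held-out fifth perfectly and every test compound clears the
0.6 probability cutoff; compounds built from scaffold families the model
never saw are rejected by the structural applicability domain at 90%; and
atrazine sits inside the herbicide-like descriptor box on all six criteria.

## Command line

```bash
herbiscreen synth --kind moa --n-classes 4 --n-per-class 25 --seed 7 --out syn.csv
herbiscreen ingest --input raw.csv --id-col ID --smiles-col SMILES --out clean.csv
herbiscreen fingerprint --input clean.csv --out fp.csv --min-count 5
herbiscreen cluster --fp fp.csv --k 15 --out clusters.csv --indices indices.yaml
herbiscreen train --input syn.csv --labels moa_label --seed 17 --out bundle/
herbiscreen screen --input queries.csv --train-input labelled.csv --audit --out report.csv
```

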