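# miecsvm

Structure-based virtual screening with **M**olecular **I**nteraction
**E**nergy **C**omponents and support vector machines.

Scoring functions rank docking poses by a single number; classifiers built
on chemical fingerprints recognize only chemotypes they have seen. This
package implements the middle road for people running structure-based
screens against a target with known actives (e.g. kinase inhibitors): it
describes each receptor–ligand complex by the *vector* of per-residue
interaction energies — the binding specificity pattern — and trains an
RBF-SVM to separate inhibitors from background molecules in that space,
then uses the model to rank screening libraries.

## The method

For every receptor residue *r*, the interaction energy with the ligand is
decomposed into four additive terms at a single optimized geometry

&nbsp;&nbsp;&nbsp;&nbsp;ΔG(r) = ΔG_vdW + ΔG_ele + ΔG_GB + ΔG_SA,

where ΔG_ele is Coulomb with interior dielectric ε_in = 4, ΔG_vdW is 12-6
Lennard-Jones, ΔG_GB is the generalized Born (OBC-rescaled radii)
polar-solvation cross-term, and ΔG_SA is γ·ΔSASA surface burial sampled on
icosphere points. Residues are ranked by their mean total energy over the
known inhibitors; the top k ∈ {20, 25, 30} residues × five component
combinations × two docking-pose strategies define 30 model protocols. Each
protocol's RBF-SVM is tuned by exhaustive grid search over
cost = 2^c, c ∈ [−2, 10] and gamma = 2^g, g ∈ [−10, 2] (step 0.5, 625
cells), scored by mean Matthews correlation coefficient over 5 stratified
CV folds with the inhibitor class up-weighted by 1.2, and evaluated on a
held-out half by SE/SP/Q±/MCC, ROC AUC and the true-positive rate at 1%
false-positive rate. Screening is hierarchical: docking-score prefilter →
SVM probability ranking → Lipinski rule-of-five filter (≥ 2 violations
eliminated) → Tanimoto leader clustering at 0.80 → top-50 cluster leaders.

See `docs/methods.md` for the full model description, conventions and
limitations.

## Worked example

Train and evaluate one protocol (top-20 residues, all four components) on a
synthetic dataset with the package's default study conditions — 25
inhibitors vs 500 background molecules (1:20), ten signal residues with a
2 kcal/mol planted energy gap:

```python
from miecsvm import (
    GridConfig, TrainConfig, MIECSVMClassifier, SyntheticSpec,
    inflection_point, make_miec_dataset, rank_residues, roc_from_scores,
    select_top_k, stratified_half_split,
)
from miecsvm.modeling import metrics_from_predictions

ds = make_miec_dataset(SyntheticSpec(seed=42))
inhibitor_tables = [t for t, y in zip(ds.tables, ds.labels) if y == 1]
ranking = rank_residues(inhibitor_tables)
matrix = ds.matrix(select_top_k(ranking, 20), "all4")   # 525 x 80

train, test = stratified_half_split(matrix, TrainConfig(seed=42))
clf = MIECSVMClassifier(grid=GridConfig(step=2.0), random_state=42)
clf.fit(train.features, train.labels)
print(clf.best_c_exp_, clf.best_gamma_exp_, clf.best_mcc_)

proba = clf.inhibitor_probability(test.features)
roc = roc_from_scores(proba, test.labels)
m = metrics_from_predictions(test.labels, clf.predict(test.features))
print(roc.auc, m.MCC, inflection_point(roc, int((test.labels == -1).sum())))
```

Output:

```
4.0 -8.0 1.0
1.0 1.0 1.0
```

The tuned model selects cost 2⁴ and gamma 2⁻⁸ with a cross-validated MCC of
1.0 on the training half, and classifies the held-out half perfectly (test
AUC 1.0, MCC 1.0, all 12 held-out inhibitors recovered within the 1%-FPR
budget of 2 false positives on the 250 held-out negatives). The same training half under the library-default
parameters (cost 2⁰, gamma 1/80) reaches only CV MCC 0.815 — the reason the
protocol always tunes the kernel. At a 2 kcal/mol planted gap over
1 kcal/mol noise the classes are cleanly separable; shrink
`SyntheticSpec(effect_size=...)` to watch the metrics degrade.

The same stages are scriptable from the shell:

```bash
miecsvm simulate miec --seed 42 --out fixtures/
miecsvm build-miec --energies fixtures/ --labels fixtures/labels.tsv \
    --k 20 --combo all4 --out matrix.csv
miecsvm train --matrix matrix.csv --combo all4 --seed 42 --grid-step 2 \
    --out model_report.json
miecsvm screen --seed 1 --n-library 1000 --n-actives 5 --out screening.tsv
```

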