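# Methods

## The model

`miecsvm` classifies small molecules as inhibitors or non-inhibitors of a
receptor from the *pattern* of their per-residue interaction energies rather
than from their chemical structure. For each receptor residue *r* and a
docked ligand pose the interaction free energy is decomposed into four
additive molecular interaction energy components (MIEC):

    dG(r) = dG_vdw(r) + dG_ele(r) + dG_GB(r) + dG_SA(r)

* **dG_ele** – Coulomb sum over residue–ligand atom pairs,
  k·q_i·q_j/(ε_in·r_ij), with k = 332.0637 kcal·Å/(mol·e²) and a uniform
  interior dielectric ε_in = 4 (the raised value that behaves well for
  kinase binding sites).
* **dG_vdw** – 12-6 Lennard-Jones with Lorentz–Berthelot-style combination
  (Rmin_ij = Rmin/2_i + Rmin/2_j, ε_ij = √(ε_i ε_j)).
* **dG_GB** – generalized Born polar-solvation cross-term
  −(1/ε_in − 1/ε_out)·k·Σ q_i q_j / f_GB(r_ij, R_i, R_j), with the standard
  f_GB = √(r² + R_i R_j e^(−r²/4R_iR_j)). Effective Born radii R come from
  pairwise (HCT) descreening integrals rescaled by the OBC tanh correction,
  R_i⁻¹ = ρ̃_i⁻¹ − ρ_i⁻¹ tanh(αΨ − βΨ² + γΨ³), Ψ = I_i ρ̃_i,
  ρ̃_i = ρ_i − 0.09 Å, with the OBC-II coefficients α = 1.0, β = 0.8,
  γ = 4.85. No heavy-atom screening scale factors are applied (S_j = 1) and
  no salt screening term is included.
* **dG_SA** – nonpolar solvation from buried solvent-accessible surface
  area: γ_SA·ΔSASA with γ_SA = 0.0072 kcal/(mol·Å²), SASA sampled with 320
  points per atom placed at the face centroids of a twice-subdivided
  icosahedron projected onto the solvent-expanded sphere (ρ + 1.4 Å).

Two deliberate scope choices make every component read as an *interaction*
energy that vanishes at infinite separation:

1. **GB cross-pairs only.** dG_GB sums residue↔ligand pairs evaluated at
   complex geometry with complex Born radii; atomic self-energies and the
   desolvation shift of the radii between bound and free states are
   excluded. (Decomposition schemes that include half-pair self terms give
   different absolute per-residue values; the cross-pair contract is the one
   this package guarantees.)
2. **Receptor-side burial only.** dG_SA(r) charges each residue for its own
   atoms' SASA loss on complex formation. Ligand-side burial is a
   whole-complex quantity with no natural residue attribution and is
   reported separately (`ligand_sa_term`).

## Pose handling and minimization

Docking poses and scores are inputs. Two strategies select the pose that is
decomposed: `top1` (the docking program's first pose) and `best_of_top3`
(rescore the first three poses by the summed decomposition total and take
the most favourable; ties go to the lower original rank).

The restrained minimizer relaxes a complex under a toy force field —
nonbonded Coulomb (ε_in) + Lennard-Jones with an 8 Å cutoff, plus harmonic
bond terms supplied by the caller — in three phases of decreasing backbone
restraint (50, 10, 0 kcal/(mol·Å²)), each phase split into steepest-descent
then conjugate-gradient cycles (500 + 500, 500 + 500, 1500 + 1500 by
default). Steepest descent uses a backtracking line search that only ever
accepts energy-lowering steps; conjugate gradient is delegated to
`scipy.optimize.minimize(method="CG")` and its iterates are kept only while
they continue to lower the energy, so the recorded trajectory is
non-increasing by construction. The positional restraint references the
coordinates at entry. The energy decomposition itself applies **no**
distance cutoff — residue rankings must not depend on a truncation radius;
the cutoff exists only inside the minimizer where it mimics the usual
simulation setup.

## Feature construction

Residues are ranked by their mean total interaction energy averaged over
the known inhibitors only (most negative first, ties to the lower residue
index), and the top k ∈ {20, 25, 30} are kept. Feature vectors concatenate
the selected residues' components residue-major in the fixed order
(ele, vdw, gb, sa), filtered to one of five combinations: ele+vdw, gb+sa,
ele+gb, vdw+sa, or all four — giving 40/50/60 features for the
two-component combinations and 80/100/120 for the four-component one.
Features stay raw kcal/mol energies; no scaling or dimension reduction is
applied, so every column keeps its physical meaning. Three k values × five
combinations × two pose strategies = 30 model protocols per target.

## Classifier and selection

`MIECSVMClassifier` is a scikit-learn estimator wrapping an RBF-kernel SVM
(libsvm via `sklearn.svm.SVC`). Hyper-parameters are searched exhaustively
on a base-2 exponent lattice: cost exponent −2…10, gamma exponent −10…2,
spacing 0.5 → 25 × 25 = 625 cells. (The coarser `GridConfig.coarse()`
lattices keep the same ranges with a wider step for desk-scale runs.) Every
cell is scored by the mean Matthews correlation coefficient over 5 seeded
stratified CV folds on the training half; the inhibitor class carries a
misclassification-cost weight of 1.2 to offset the ~1:20 class imbalance. A
fold that ends up single-class contributes MCC = 0 with a warning. The best
cell — ties broken toward smaller cost, then smaller gamma, i.e. the
smoother model — is refit on the full training half with libsvm's Platt
probability calibration. Selection uses the CV-mean MCC (not the resubstitution
training MCC) because the protocol validates each grid cell by 5-fold CV,
and selecting on resubstitution MCC would trivially favour overfit cells.

Datasets are split in stratified halves (per class, seeded shuffle; an odd
class count puts the extra sample in training). Evaluation reports SE, SP,
Q+, Q−, MCC (zero-denominator metrics are reported as *undefined* and
flagged, never coerced to 0), the trapezoidal ROC AUC, and the enrichment
"inflection point": the true-positive rate at the threshold admitting
floor(0.01 · n_negatives) false positives — 35 for a 3500-negative test set.

## Hierarchical screening

1. Keep the `prefilter_n` (default 30 000) best docking scores.
2. Decompose/score the pool with the fitted model; keep the top
   `rank_pool_n` (default 300) by inhibitor probability (or by docking
   score, for the baseline arm).
3. Remove compounds with ≥ 2 violations of Lipinski's rules of five
   (MW > 500 Da, logP > 5, H-bond donors > 5, acceptors > 10); missing
   descriptors are an error, never a silent pass. A hook accepts an
   external per-compound drug-likeness score if one is available.
4. Cluster survivors by MACCS-style 166-bit fingerprint Tanimoto similarity
   at 0.80. The default is a **leader algorithm on the ranked list**: a
   compound joins the first cluster whose *leader* exceeds the threshold,
   else founds a new cluster. This was chosen over single-linkage (available
   via `cluster_method="single"`) because the selection step needs a
   canonical "top molecule in each group", which the leader construction
   provides by definition; single-linkage chains can merge dissimilar
   compounds and leave the group representative ambiguous.
5. Return the best `final_n` (default 50) cluster leaders.

Ranking happens before the drug-likeness filter (take top 300, then
filter), matching the stated order of the screening protocol.

## Synthetic data: what it emulates, and what it does not

All fixtures are generated, seeded, and deterministic.

* `make_toy_complex` builds a pseudo-pocket — residues on a hemisphere
  around a central ligand, half at contact range (4.5–6 Å), half distal
  (9–15 Å) — with bounded random charges, Born radii and LJ parameters.
  It exercises the physics path (distance decay, burial, pose rescoring)
  but has no real pocket geometry, no bonded topology beyond caller-supplied
  bonds, and no chemically meaningful charge distribution.
* `make_miec_dataset` plants the class signal at the feature level: every
  residue gets a baseline mean total energy from U(−2, 0) kcal/mol shared
  by both classes; `k_informative` = 10 randomly chosen residues contribute
  an extra −2 kcal/mol (the `effect_size`) to inhibitors only, split evenly
  over the four components, with 1 kcal/mol total Gaussian noise per
  residue. Defaults are 25 inhibitors vs 500 background (the 1:20 imbalance
  of the modelled screening scenario) so the 1.2 class weight is exercised
  realistically.
* `make_screening_library` draws background descriptors straddling the
  Lipinski boundaries, gives planted actives drug-like descriptors, better
  docking scores and inhibitor-distribution MIEC features, and can emit
  blocks of near-duplicate fingerprints to exercise clustering.

Passing tests on these fixtures demonstrate that the pipeline recovers
signal it was told is there under controlled noise; they say nothing about
how well MM/GBSA energies separate real actives from real decoys, which
depends on docking quality, force-field parameterization and assay noise
that the generators deliberately do not model.

## Numerical notes

* **SASA rotation sensitivity.** The sphere-point lattice is fixed in the
  laboratory frame, so point-sampled SASA is exactly translation invariant
  but rotation invariant only to the sampling resolution (≈ 0.01–0.02
  kcal/mol per residue at 320 points for the SA term). This is inherent to
  Shrake–Rupley-type sampling; raise `sasa_points` where tighter rotational
  stability is needed. The analytic terms are invariant to 1e-6.
* Grid exponent lattices are built by integer stepping and rounded to 10
  decimals so 0.5-spaced grids contain exact endpoints.
* Coincident atom pairs (r = 0) raise a singular-geometry error for
  Coulomb/LJ; the GB pair function is finite at r = 0 (f_GB → √(R_iR_j))
  and is left defined there.
* Born radii: gb_radius ≤ 0.09 Å or a non-positive rescaled radius raise,
  naming the atom.
* A point exactly on another atom's expanded sphere counts as exposed
  (strict inequality), which makes the fully-coincident two-atom edge case
  well defined.
* Minimization aborts with the failing phase on non-finite energies or
  gradients.

## Problem sizes used by the shipped tests and acceptance script

Oracle comparisons run on ≤ 30-atom complexes where double-loop references
are exact to 1e-9 (1e-6 for SASA at matched point sets). Statistical
checks run at the generator defaults (525 samples, 1:20) with the
(c, gamma) lattice coarsened to step 2.0 over the unchanged ranges; the
permutation-null check uses 50 label shuffles and the tuned-vs-default
check 10 seeds. The end-to-end screen uses a 1000-compound library with a
200-compound prefilter, a 60-compound rank pool and a final selection of
10. These sizes are the package's desk-scale defaults for its own test
harness; the screening-stage defaults (30 000 / 300 / 50) remain the
production values.

## Known limitations

* No docking, force-field parameterization, charge derivation, protonation,
  explicit solvent, PME, entropy terms or PB reference — poses, charges,
  radii and LJ parameters are inputs.
* The GB/SA decomposition contract (cross-pairs only, receptor-side burial)
  is a defined convention, not the only possible one; absolute per-residue
  values are not comparable to decompositions that include self terms.
* The grid search refits the selected cell on the full training half;
  no nested CV is performed, so the reported CV-mean MCC of the selected
  cell is an optimistically biased estimate (the held-out half provides the
  unbiased assessment).
* Probability calibration is libsvm's Platt scaling; probabilities and
  decision values rank-agree, but absolute probabilities on heavily
  imbalanced data should be read with care.
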