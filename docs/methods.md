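# Methods

## Problem setting and model

The package implements a ligand-plus-structure screening pipeline for
TRPV1 modulators.  Three ideas carry the method:

1. **Scaffold-activity transfer.**  Potency clusters in structural
   families.  Each Bemis–Murcko skeleton (the ring-and-linker graph with
   atom and bond types erased), each plain ring system (one fused/spiro
   ring assembly keeping elements and aromaticity) and each similarity
   cluster receives the arithmetic mean of the activity values of the
   library compounds that carry it, with non-target-class compounds
   contributing 0.  Means are plain (no shrinkage): a scaffold seen once
   in a potent antagonist scores that compound's full pIC50, and a
   scaffold shared with many inactives is diluted toward 0.  A compound's
   average activity score is the mean of its three component scores;
   components whose key is absent (acyclic molecules, unseen rings, no
   cluster match) contribute 0.  Scores are computed twice, once against
   antagonist potencies and once against agonist potencies.

2. **Descriptor-threshold rules.**  Sixteen interpretable descriptors
   with fixed univariate cutoffs, eight per class.  The shipped rule sets
   are hard-coded defaults (also available as YAML); the count of
   satisfied rules is used as an ordinal feature, which empirically
   carries more information than the thresholded binary label.

3. **Docking rescoring.**  Binding energies are *ingested*, never
   computed: the package consumes a CSV of ΔG values per compound per
   receptor conformation.  The closed-conformation energy is used as an
   antagonist feature.  For agonists, raw open-conformation energies
   discriminate poorly, so the ligand-efficiency-dependent lipophilicity
   index is used instead: LE = −ΔG/n_heavy (positive for favorable
   binding), LELP = logP/LE.  The sign convention makes LELP positive
   for lipophilic binders and negative for negative-logP compounds.

The integrator is a 6–4–3 multilayer perceptron: min-max-normalized
inputs, one tanh hidden layer of four units (the geometric mean of input
and output widths), softmax output over (inactive, antagonist, agonist).
Training is full-batch gradient descent on mean cross-entropy with
momentum.  Defaults — learning rate 0.5, momentum 0.7, 25 epochs,
uniform(−0.5, 0.5) initialization — are deliberately simple and fully
seed-controlled; all are configurable.  Prediction uses a 0.5
probability threshold for calling an active class, falling back to the
argmax, with ties broken in class order (IN, ANT, AG).

## Curation conventions

* Potencies arrive in nM; pX = −log10(value·10⁻⁹).  Compounds measured
  in several assays are merged by the arithmetic mean on the nM scale
  *before* the log transform (a `duplicate_mean="pX"` switch averages on
  the log scale instead, since sources rarely state which convention a
  curated mean used).
* Structure identity everywhere is the canonical SMILES of the largest
  organic fragment (desalted).
* Actives with pX < 5 are demoted to the inactive class with pX reset to
  0.  Percent-activity/inhibition and Ki/potency entries contribute only
  their declared-inactive flag; no percent-to-potency conversion is
  attempted.
* Compounds appearing in both the antagonist and agonist sets are
  desensitizers, not true antagonists: they are removed from the
  antagonist set and keep their agonist potency.
* Decoys are chosen by greedy maximin diversity (seeded, path-based
  hashed fingerprint) among candidates whose MW/logP/HBD/HBA fall inside
  the windows spanned by the actives.

## Similarity backend

The clustering stage was designed around a flexible-pharmacophore
similarity concept.  The similarity descriptor here is a
pharmacophore-typed atom-pair fingerprint: atoms are typed as
donor/acceptor/aromatic/lipophilic/positively/negatively ionizable by
SMARTS, every typed pair contributes a (type, type, binned topological
distance) feature, and similarity is the Tanimoto coefficient on feature
sets.  It preserves the pharmacophoric intent at desk scale, and the
backend is pluggable (a plain RDKit path fingerprint is included)
without touching scoring.  Clustering is leader clustering — scan in
input order, join the first cluster whose leader matches at or above the
threshold, else found a new cluster — chosen because it is
deterministic, O(n·k) and trivially reproducible given a stated input
order.  Thresholds: 0.80 for scoring clusters, 0.75 for pruning
structurally redundant compounds before docking-set assembly (most
potent compound per cluster retained, ties broken by compound id).  The
0.80 threshold is interpreted as similarity ≥ 0.80.  External molecules
join the first cluster (in leader order) whose leader they match at the
threshold; otherwise their cluster score is 0.

## Descriptor definitions and reconstructions

Count and ratio descriptors follow their standard published meanings
(halogen count, nitrogen count, hydroxyl groups, six-membered
heterorings, an explicit H-bond-acceptor rule, hybridization ratio
nSp3C/(nSp3C+nSp2C), AMW = MW / all atoms including hydrogens).  Three
choices deserve note:

* **nAtomLAC** (longest aliphatic chain) counts acyclic non-aromatic
  carbons of any hybridization — carbonyl and alkene carbons included —
  with chains broken by heteroatoms and ring atoms; a chain needs at
  least one C–C bond, so isolated methyls score 0.  The capsaicin value
  of 9 fixes this reading.
* **nAtomP** (largest pi system) takes aromatic and multiple-bond atoms
  as the core and adds lone-pair heteroatoms (N, O, S) directly bonded
  to the core, so phenolic and ether oxygens on a ring conjugate.  The
  capsaicin value of 8 (ring + two oxygens) fixes this reading.
* **E-states** use the Kier–Hall formalism (intrinsic state
  I = ((2/N)²δᵛ+1)/δ perturbed by Σ(Iᵢ−Iⱼ)/(d+1)²) via RDKit;  SssNH
  sums E-states over secondary-amine nitrogens.  **maxHother** — the
  maximum hydrogen E-state over aromatic CH, =CH₂ and =CH− hydrogens —
  has no RDKit implementation, so it is reconstructed as the hydrogen
  intrinsic state (δᵛ−δ)/δ of the bearing carbon *minus* that carbon's
  field perturbation: hydrogens on electron-poor carbons (near N, F)
  score high, plain benzene scores 0.5.  This reproduces the reference
  antagonist's criteria outcome.
* **MDEN22** is the molecular distance-edge statistic over degree-2
  nitrogens: λ = n_pairs/(∏ d_ij)^(1/n_pairs), 0 with fewer than two
  such nitrogens.
* **ETA_BetaP_s** is realized as a sigma-bond polarity sum: each
  heavy-heavy bond contributes 0.75 if the bonded atoms' ε
  electronegativities (ε = −α + 0.3Zᵛ, α the core-electron measure)
  differ by more than 0.3, else 0.5, divided by the heavy-atom count.
* **fragC** = |B²−A²+A| + H/100 over heavy atoms A, bonds B and
  heteroatoms H.
* **logP** is Wildman–Crippen (`crippen_like`).  Atom-additive logP
  flavors differ by up to ~1 log unit, so the backend is recorded in
  descriptor-matrix metadata and the lipophilicity cutoff should be
  interpreted with the backend in mind; capsaicin's Crippen value
  (3.79) sits on the same side of the 3.023 agonist cutoff as the
  published XLogP value (3.98).

## Cutoff selection and descriptor screening

New rule thresholds are selected from the empirical ROC curve at the
operating point maximizing min(sensitivity, specificity) — the
"balanced" point; ties are broken by maximal Youden's J, then by the
smaller threshold.  Candidate descriptors for new rule sets must pass a
Welch two-sample t-test at α = 0.05 (a pooled-variance switch exists),
an ROC AUC floor (default 0.8, orientation-corrected), and greedy
decorrelation: descriptors are visited in decreasing AUC order and
dropped if Pearson |R| > 0.75 with any kept survivor.  The AUC floor
applies to candidate screening only; the shipped default rule sets are
fixed and include members slightly below 0.8.

## Synthetic data: what it emulates, what it does not

The generator plants exactly the structure the method exploits:
scaffold templates (format strings with substituent slots, so validity
is guaranteed by construction) are split into antagonist, agonist and
held-out pools; each active family has a latent mean pX ~ U(5.5, 9.5)
with within-family noise (sd 0.5, clipped at the 5.0 activity cutoff);
inactives and decoys take pX 0 and come only from held-out scaffolds.
Docking energies are drawn from class-conditional normal distributions
for both receptor conformations (closed state: antagonists
N(−9.56, 1.10), agonists N(−8.27, 1.26), inactives N(−8.12, 1.21),
decoys N(−7.54, 1.17); open state: agonists N(−8.51, 1.41), antagonists
N(−9.20, 0.93), inactives N(−8.13, 1.19), decoys N(−7.52, 1.09)
kcal/mol) — the observed per-class moments for the two conformations,
so enrichment-ROC behavior is quantitatively comparable.  Default
library size is 250/200/450/300 (ANT/AG/IN/DCY), i.e. roughly the
1:1:2 active/active/inactive balance of a pruned docking set at a
desk-scale 1200 compounds.

Because active and inactive scaffold pools are disjoint and potency is
family-correlated, activity scores separate classes almost perfectly on
this benchmark; held-out accuracy ≈ 0.99 and score AUCs ≈ 1.0 measure
recovery of the planted structure under the stated noise, not expected
performance on real libraries, where scaffolds overlap between classes
and assay noise is not Gaussian.  The generator also makes no attempt
to mimic real chemical-space coverage or descriptor distributions.

## Numerical conventions and degenerate inputs

* ROC AUC is Mann–Whitney U/(n₊n₋) with midrank ties (equivalent to
  trapezoidal integration); E-state perturbations cancel pairwise, so
  the per-molecule sum of E-states equals the sum of intrinsic states
  (used as an exact conservation test).
* Undefined metric denominators (e.g. TNR with no negatives) are
  reported as NaN, never zeroed.  LELP is undefined at LE = 0; such
  compounds are reported missing and dropped from feature rows with a
  warning.
* HybRatio is 0 for molecules without sp2/sp3 carbons; acyclic
  molecules have no Bemis–Murcko skeleton (score component 0) and an
  empty plain-ring set.
* Plain-ring extraction restores the H on aromatic nitrogens that lost
  their substituent (the plain ring of an N-methylated azole is the NH
  azole); ring systems whose valence model is irrecoverable after
  excision fall back to the parent's canonical fragment serialization,
  which is still an isomorphism-invariant key.
* All stochastic steps (decoy picking, splits, weight initialization,
  permutation importance, the generator) take explicit seeds;
  clustering is deterministic given input order.

## Known limitations

* The similarity surrogate is topological; conformational flexibility
  is not modeled, so cluster composition will differ from 3D
  pharmacophore tools even at the same threshold.
* maxHother and ETA_BetaP_s are documented reconstructions of sparsely
  specified descriptors; their values are internally consistent and
  reproduce the reference-compound criteria counts, but are not
  numerically interchangeable with other software's output.
* Scaffold means carry no uncertainty: singleton scaffolds transfer
  potency with full confidence by design (faithful to the method, but a
  known overfitting channel on small libraries).
* The MLP is intentionally minimal — no regularization, no early
  stopping; with 37 parameters overfitting is limited, but the training
  protocol is not tuned for difficult, overlapping feature
  distributions.
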