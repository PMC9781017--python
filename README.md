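# trpv1screen

A virtual-screening toolkit for predicting modulators of TRPV1, the
capsaicin-activated cation channel targeted by candidate analgesics.
Given a curated bioactivity library (antagonists, agonists and inactive
molecules), an unlabeled screening library and externally computed
docking scores, the package predicts for each screening compound the
probability of being a TRPV1 **antagonist**, **agonist/desensitizer** or
**inactive**.  It is aimed at computational chemists running
ligand-plus-structure repurposing screens who want every stage — scoring,
rule-based classification, rescoring, integration — as inspectable,
file-mediated steps rather than a black box.

## Method

Six features are computed per compound and integrated by a small neural
network:

1. **Average activity scores** (`Score-ANT`, `Score-AG`).  Every
   Bemis–Murcko skeleton *BM*, plain ring system *PR* and
   pharmacophore-similarity cluster in the reference library is assigned
   the arithmetic mean of its members' activity values
   (pX = pIC50/pEC50 for the target class, 0 otherwise).  A compound's
   score is

   `Score = (BMS + PRS + SCS) / 3`

   where BMS is its skeleton's mean (0 if acyclic or unseen), PRS the
   mean over its distinct ring systems of their table means, and SCS its
   similarity cluster's mean (clusters formed by leader clustering at
   Tanimoto ≥ 0.80 on a pharmacophore-typed atom-pair fingerprint).

2. **Criteria counts** (`Crit-ANT`, `Crit-AG`).  Sixteen molecular
   descriptors with univariate thresholds — eight antagonist rules (e.g.
   `SssNH > 2.962`, `nX ≥ 2`, `nHBAcc2 > 5`) and eight agonist rules
   (e.g. `logP > 3.023`, `nsOH > 0`, `nX = 0`, `AMW < 7.25`).  The number
   of satisfied rules (0–8) enters the model as an ordinal feature; ≥ 5
   (antagonist) or ≥ 4 (agonist) gives the standalone binary classifier.

3. **Docking-derived features**.  Binding energies ΔG (kcal/mol) from an
   external docking program against the closed (antagonist-bound) and
   open (agonist-bound) channel conformations.  The closed-state ΔG is
   used directly; the open-state score is converted to the
   ligand-efficiency-dependent lipophilicity index
   `LELP = logP / LE`, `LE = −ΔG / n_heavy`.

The integrator is a 6–4–3 multilayer perceptron (tanh hidden layer,
softmax output) trained by batch gradient descent with momentum
(learning rate 0.5, momentum 0.7, 25 epochs) on min-max-normalized
inputs with a stratified 70/30 train/test split.

## Worked example

The two reference ligands are built in as fixtures.  Capsaicin (the
canonical agonist) and AMG-517 (a potent antagonist):

```python
>>> from trpv1screen import (fixture_molecules, compute_descriptors,
...                          count_satisfied, AGONIST_RULES, ANTAGONIST_RULES, to_pX)
>>> cap = compute_descriptors(fixture_molecules()["capsaicin"])
>>> round(cap["AMW"], 3), cap["HybRatio"], cap["nsOH"], cap["nAtomLAC"], cap["nAtomP"]
(6.233, 0.5, 1, 9, 8)
>>> count_satisfied(cap, AGONIST_RULES)
8
>>> amg = compute_descriptors(fixture_molecules()["AMG-517"])
>>> amg["nX"], amg["n6HeteroRing"], amg["nHBAcc2"]
(3, 1, 9)
>>> count_satisfied(amg, ANTAGONIST_RULES)
7
>>> round(to_pX(15850), 4)   # 15.85 uM potency in -log10 molar units
4.8
```

Capsaicin satisfies all eight agonist criteria (lipophilic, sp3-rich,
one hydroxyl, a nine-atom aliphatic chain, halogen-free, a small
eight-atom pi system).  AMG-517 satisfies seven of the eight antagonist
criteria; the only miss is the secondary-amine E-state minimum.

An end-to-end screen on synthetic data, from the shell:

```bash
trpv1screen synth --seed 11 --out-dir run/data
trpv1screen train --library run/data/library.csv --docking run/data/docking.csv \
                  --model-out run/model/model.json --seed 11
# -> test accuracy 1.000 on 360 held-out compounds; model -> run/model/model.json
```

`trpv1screen screen` then ranks any `compound_id,smiles` CSV against the
frozen reference tables and the trained model, emitting a table with the
six features, per-class probabilities and the predicted class.

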