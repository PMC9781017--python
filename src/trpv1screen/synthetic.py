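"""Synthetic bioactivity libraries with scaffold-correlated potencies.

Emulates the statistical structure the screening framework assumes: a
ChEMBL-style labeled library in which potency runs in families (each
scaffold has a latent mean pX, members scatter around it) and in which
inactive molecules and decoys come from scaffolds the actives never use,
plus per-class docking scores drawn from the class-conditional normal
distributions observed for the two receptor conformations.  Molecules
are built by decorating scaffold templates with enumerated substituents,
so chemical validity is guaranteed by construction; no generative model
is involved.  Docking scores are always simulated, never computed.

The generator makes no attempt to mimic real ChEMBL chemical-space
coverage; what passing tests show is that the framework recovers planted
scaffold-activity structure, not that it generalizes to real screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chemio import ActivityRecord, ACTIVITY_CUTOFF_PX
from .docking import DockingRecord

# scaffold templates: python format strings with {r0}/{r1} substituent slots.
# The first group is used for antagonist families (heteroaromatic amides,
# halogenated aryls), the second for agonist families (vanilloid-like
# hydroxylated lipophiles), the third is held out for inactives/decoys.
ANT_SCAFFOLDS = [
    "O=C(C{r0})Nc1nc2cc({r1})ccc2s1",
    "FC(F)(F)c1ccc(-c2cc(N{r0})ncn2)cc1",
    "O=C(Nc1ccc(Cl)c({r0})c1)c1ccc({r1})nc1",
    "Clc1ccc(CN2CCN(CC2)C{r0})cc1",
    "Cn1c(C{r0})nc2cc({r1})ccc21",
]
AG_SCAFFOLDS = [
    "COc1cc(CNC(=O)CCCC{r0})ccc1O",
    "Oc1ccc(CC(O)C{r0})c({r1})c1",
    "CC(C)CCCC(=O)NCc1ccc(O)c({r0})c1",
    "OC(CNC{r0})c1ccc(O)c(O)c1",
    "CC({r0})CCC(=O)OCC(O)c1ccc(O)cc1",
]
INACTIVE_SCAFFOLDS = [
    "c1cc({r0})c(-c2ccc({r1})cc2)cc1",
    "O=C(O)c1ccc(C{r0})cc1",
    "c1cc({r1})cc(OCC{r0})c1",
    "O=S(=O)(NC{r0})c1ccc(C{r1})cc1",
    "Cc1ccnc(NC{r0})c1",
]

SUBSTITUENTS = ["C", "CC", "CCC", "CCCC", "O", "OC", "N", "CO", "CCO",
                "C(C)C", "CCN", "C=C"]


@dataclass(frozen=True)
class DockingModel:
    """Per-class (mean, sd) of simulated binding energies, kcal/mol."""

    closed: dict = field(default_factory=lambda: {
        "ANT": (-9.56, 1.096), "AG": (-8.27, 1.260),
        "IN": (-8.12, 1.213), "DCY": (-7.54, 1.171)})
    open: dict = field(default_factory=lambda: {
        "ANT": (-9.20, 0.934), "AG": (-8.51, 1.412),
        "IN": (-8.13, 1.187), "DCY": (-7.52, 1.088)})


@dataclass
class SyntheticSpec:
    n_ant: int = 250
    n_ag: int = 200
    n_in: int = 450
    n_dcy: int = 300
    ant_scaffolds: list[str] = field(default_factory=lambda: list(ANT_SCAFFOLDS))
    ag_scaffolds: list[str] = field(default_factory=lambda: list(AG_SCAFFOLDS))
    inactive_scaffolds: list[str] = field(default_factory=lambda: list(INACTIVE_SCAFFOLDS))
    potency_mean_range: tuple[float, float] = (5.5, 9.5)
    potency_sd: float = 0.5
    docking_model: DockingModel = field(default_factory=DockingModel)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_ant, self.n_ag, self.n_in, self.n_dcy) < 0:
            raise ValueError("counts must be non-negative")
        if self.potency_sd <= 0:
            raise ValueError("potency sd must be positive")
        if self.n_ant and not self.ant_scaffolds:
            raise ValueError("antagonist scaffold pool is empty")
        if self.n_ag and not self.ag_scaffolds:
            raise ValueError("agonist scaffold pool is empty")
        for tmpl in (self.ant_scaffolds + self.ag_scaffolds + self.inactive_scaffolds):
            smi = tmpl.format(r0="C", r1="C")
            if Chem.MolFromSmiles(smi) is None:
                raise ValueError(f"invalid scaffold template {tmpl!r}")


def _decorate(template: str, rng: np.random.Generator) -> str:
    smi = template.format(r0=rng.choice(SUBSTITUENTS), r1=rng.choice(SUBSTITUENTS))
    mol = Chem.MolFromSmiles(smi)
    assert mol is not None, f"template decoration produced invalid SMILES {smi!r}"
    return Chem.MolToSmiles(mol)


def generate_library(spec: SyntheticSpec | None = None
                     ) -> tuple[list[ActivityRecord], list[DockingRecord], "pd.DataFrame"]:
    """Labeled library + simulated docking table + ground truth.

    Fully reproducible from ``spec.seed``.  Active potencies are drawn
    from the compound's scaffold family mean (itself uniform over
    ``potency_mean_range``) with within-family noise, clipped at the
    activity cutoff; inactives/decoys have pX = 0 and come from the
    held-out scaffold pool.
    """
    import pandas as pd

    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)

    family_mean = {
        tmpl: rng.uniform(*spec.potency_mean_range)
        for tmpl in spec.ant_scaffolds + spec.ag_scaffolds
    }

    records: list[ActivityRecord] = []
    rows = []
    plan = [("ANT", spec.n_ant, spec.ant_scaffolds),
            ("AG", spec.n_ag, spec.ag_scaffolds),
            ("IN", spec.n_in, spec.inactive_scaffolds),
            ("DCY", spec.n_dcy, spec.inactive_scaffolds)]
    for cls, count, pool in plan:
        for i in range(count):
            tmpl = pool[int(rng.integers(len(pool)))]
            smi = _decorate(tmpl, rng)
            cid = f"{cls}-{i:04d}"
            if cls in ("ANT", "AG"):
                px = rng.normal(family_mean[tmpl], spec.potency_sd)
                px = float(max(px, ACTIVITY_CUTOFF_PX))
            else:
                px = 0.0
            records.append(ActivityRecord(cid, smi, cls, px))
            rows.append((cid, smi, cls, px, tmpl))

    docking: list[DockingRecord] = []
    for rec in records:
        mu, sd = spec.docking_model.closed[rec.activity_class]
        docking.append(DockingRecord(rec.compound_id, "closed_antagonist_bound",
                                     float(rng.normal(mu, sd)), 1))
        mu, sd = spec.docking_model.open[rec.activity_class]
        docking.append(DockingRecord(rec.compound_id, "open_agonist_bound",
                                     float(rng.normal(mu, sd)), 1))

    truth = pd.DataFrame(rows, columns=["compound_id", "smiles", "activity_class",
                                        "pX", "scaffold_template"])
    return records, docking, truth


# -------------------------------------------------- worked-example fixtures

_FIXTURE_SMILES = {
    # (E)-N-[(4-hydroxy-3-methoxyphenyl)methyl]-8-methylnon-6-enamide
    "capsaicin": r"COc1cc(CNC(=O)CCCC/C=C/C(C)C)ccc1O",
    # N-[4-[6-[4-(trifluoromethyl)phenyl]pyrimidin-4-yl]oxy-1,3-benzothiazol-2-yl]acetamide
    "AMG-517": "CC(=O)Nc1nc2c(Oc3cc(-c4ccc(C(F)(F)F)cc4)ncn3)cccc2s1",
    # the classical competitive antagonist (thiourea-linked dihydroxy benzazepine)
    "capsazepine": "Oc1ccc2c(c1O)CN(C(=S)NCCc1ccc(Cl)cc1)CCC2",
    # catechol beta2-agonist with a benzodioxole tail
    "protokylol": "CC(Cc1ccc2c(c1)OCO2)NCC(O)c1ccc(O)c(O)c1",
}


def fixture_molecules() -> dict[str, Chem.Mol]:
    """Named reference structures used in the worked examples."""
    out = {}
    for name, smi in _FIXTURE_SMILES.items():
        mol = Chem.MolFromSmiles(smi)
        assert mol is not None
        out[name] = mol
    return out
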