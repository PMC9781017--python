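"""Chemical library I/O and bioactivity curation.

Reads SMILES/SDF libraries with bioactivity annotations (ChEMBL-style),
converts nanomolar potencies to the -log10 molar (pIC50/pEC50) scale,
merges duplicate structures, applies the pX < 5 inactivity rule, resolves
antagonist/agonist overlaps (desensitizers are kept as agonists), and
selects property-matched diverse decoys.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import math

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit import DataStructs
from rdkit.Chem import Crippen, Descriptors, Lipinski

log = logging.getLogger(__name__)

ASSAY_KINDS = ("IC50", "EC50", "Ki", "potency", "activity_pct", "inhibition_pct")

#: assay kinds that carry a usable concentration-response potency
POTENCY_KINDS = ("IC50", "EC50")

#: minimum pX (in -log10 molar units) for a compound to count as active
ACTIVITY_CUTOFF_PX = 5.0

AssayKind = Literal["IC50", "EC50", "Ki", "potency", "activity_pct", "inhibition_pct"]
ActivityClass = Literal["ANT", "AG", "IN", "DCY"]


@dataclass(frozen=True)
class RawActivityEntry:
    """One uncurated bioactivity measurement."""

    compound_id: str
    smiles: str
    assay_kind: AssayKind = "IC50"
    value_nM: float | None = None
    declared_inactive: bool = False

    def __post_init__(self):
        if self.assay_kind not in ASSAY_KINDS:
            raise ValueError(f"unknown assay kind {self.assay_kind!r}")
        if self.value_nM is not None and not self.value_nM > 0:
            raise ValueError(f"value_nM must be positive, got {self.value_nM}")


@dataclass(frozen=True)
class ActivityRecord:
    """One curated compound with class label and potency.

    ``pX`` is pIC50 for antagonists, pEC50 for agonists and 0 for
    inactive molecules and decoys.
    """

    compound_id: str
    smiles: str
    activity_class: ActivityClass
    pX: float = 0.0

    def __post_init__(self):
        if self.activity_class in ("IN", "DCY") and self.pX != 0.0:
            raise ValueError("inactive/decoy records must have pX = 0")
        if self.activity_class in ("ANT", "AG") and self.pX < ACTIVITY_CUTOFF_PX:
            raise ValueError("active records must have pX >= 5")


@dataclass(frozen=True)
class DecoyWindow:
    """Drug-likeness property windows spanned by the active molecules."""

    mw_range: tuple[float, float]
    logp_range: tuple[float, float]
    hba_range: tuple[int, int]
    hbd_range: tuple[int, int]

    def __post_init__(self):
        for lo, hi in (self.mw_range, self.logp_range, self.hba_range, self.hbd_range):
            if lo > hi:
                raise ValueError("window low bound exceeds high bound")

    @classmethod
    def from_actives(cls, mols: Sequence[Chem.Mol]) -> "DecoyWindow":
        mw = [Descriptors.MolWt(m) for m in mols]
        lp = [Crippen.MolLogP(m) for m in mols]
        hba = [Lipinski.NumHAcceptors(m) for m in mols]
        hbd = [Lipinski.NumHDonors(m) for m in mols]
        return cls((min(mw), max(mw)), (min(lp), max(lp)),
                   (min(hba), max(hba)), (min(hbd), max(hbd)))

    def contains(self, mol: Chem.Mol) -> bool:
        return (self.mw_range[0] <= Descriptors.MolWt(mol) <= self.mw_range[1]
                and self.logp_range[0] <= Crippen.MolLogP(mol) <= self.logp_range[1]
                and self.hba_range[0] <= Lipinski.NumHAcceptors(mol) <= self.hba_range[1]
                and self.hbd_range[0] <= Lipinski.NumHDonors(mol) <= self.hbd_range[1])


@dataclass
class ParseReport:
    """Outcome of reading a chemical library: failures are reported, never dropped silently."""

    n_read: int = 0
    n_failed: int = 0
    failures: list[str] = field(default_factory=list)


def canonical_structure(smiles: str) -> str | None:
    """Canonical SMILES of the largest organic fragment (desalted).

    Structure identity throughout the package: salts/counterions are
    stripped and the largest fragment (by heavy atom count) canonicalized.
    Returns None for unparsable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    largest = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return Chem.MolToSmiles(largest)


def read_library(path: str | Path, format: str = "smiles_csv"
                 ) -> tuple[list[RawActivityEntry], ParseReport]:
    """Read a chemical library from CSV (smiles_csv) or SDF.

    The CSV contract: header columns ``compound_id, smiles`` and optional
    ``assay_kind, value_nM, declared_inactive``.  SDF records use molecule
    titles (or _Name) as compound ids and SD tags of the same names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = ParseReport()
    entries: list[RawActivityEntry] = []

    if format == "smiles_csv":
        df = pd.read_csv(path)
        if "smiles" not in df.columns or "compound_id" not in df.columns:
            raise ValueError(f"{path}: CSV must have 'compound_id' and 'smiles' columns")
        for _, row in df.iterrows():
            smi = str(row["smiles"])
            if Chem.MolFromSmiles(smi) is None:
                report.n_failed += 1
                report.failures.append(str(row["compound_id"]))
                continue
            value = row.get("value_nM", None)
            if value is not None and (pd.isna(value)):
                value = None
            entries.append(RawActivityEntry(
                compound_id=str(row["compound_id"]),
                smiles=smi,
                assay_kind=str(row.get("assay_kind", "IC50")),
                value_nM=float(value) if value is not None else None,
                declared_inactive=bool(row.get("declared_inactive", False)),
            ))
            report.n_read += 1
    elif format == "sdf":
        RDLogger.DisableLog("rdApp.error")
        try:
            supplier = Chem.SDMolSupplier(str(path), sanitize=True)
            for i, mol in enumerate(supplier):
                if mol is None:
                    report.n_failed += 1
                    report.failures.append(f"record {i}")
                    continue
                cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"record_{i}"
                kind = mol.GetProp("assay_kind") if mol.HasProp("assay_kind") else "IC50"
                value = float(mol.GetProp("value_nM")) if mol.HasProp("value_nM") else None
                inactive = (mol.GetProp("declared_inactive").lower() in ("1", "true")
                            if mol.HasProp("declared_inactive") else False)
                entries.append(RawActivityEntry(cid, Chem.MolToSmiles(mol), kind, value, inactive))
                report.n_read += 1
        finally:
            RDLogger.EnableLog("rdApp.error")
    else:
        raise ValueError(f"unknown format {format!r}")

    if report.n_failed:
        log.warning("%s: %d records failed to parse (%s)", path, report.n_failed,
                    ", ".join(report.failures[:10]))
    return entries, report


def to_pX(value_nM: float) -> float:
    """Convert a nanomolar potency to the -log10 molar scale.

    to_pX(1000) = 6.0 (1 uM); to_pX(1) = 9.0 (1 nM).
    """
    if not value_nM > 0:
        raise ValueError(f"potency must be positive, got {value_nM}")
    return -math.log10(value_nM * 1e-9)


def curate(entries: Iterable[RawActivityEntry],
           role: str,
           duplicate_mean: str = "nM") -> list[ActivityRecord]:
    """Curate raw entries for one assay role into activity records.

    * antagonist_assay / agonist_assay: duplicate structures are merged by
      averaging on the nanomolar scale (``duplicate_mean="nM"``, the default)
      or on the pX scale (``"pX"``) before conversion; compounds ending up
      with pX < 5 are demoted to the inactive class with pX reset to 0.
    * inactivity_assay: declared-inactive entries (Ki / potency / percent
      assays) are emitted as IN records.
    """
    if role not in ("antagonist_assay", "agonist_assay", "inactivity_assay"):
        raise ValueError(f"unknown role {role!r}")
    if duplicate_mean not in ("nM", "pX"):
        raise ValueError("duplicate_mean must be 'nM' or 'pX'")

    active_class = {"antagonist_assay": "ANT", "agonist_assay": "AG"}.get(role)

    by_structure: dict[str, list[RawActivityEntry]] = {}
    for e in entries:
        canon = canonical_structure(e.smiles)
        if canon is None:
            log.warning("curate: dropping unparsable SMILES for %s", e.compound_id)
            continue
        by_structure.setdefault(canon, []).append(e)

    records: list[ActivityRecord] = []
    for canon, group in by_structure.items():
        cid = min(e.compound_id for e in group)
        if role == "inactivity_assay":
            if any(e.declared_inactive for e in group):
                records.append(ActivityRecord(cid, canon, "IN", 0.0))
            continue
        values = [e.value_nM for e in group if e.value_nM is not None]
        if not values:
            if any(e.declared_inactive for e in group):
                records.append(ActivityRecord(cid, canon, "IN", 0.0))
            continue
        if duplicate_mean == "nM":
            px = to_pX(float(np.mean(values)))
        else:
            px = float(np.mean([to_pX(v) for v in values]))
        if px < ACTIVITY_CUTOFF_PX:
            records.append(ActivityRecord(cid, canon, "IN", 0.0))
        else:
            records.append(ActivityRecord(cid, canon, active_class, px))
    return records


def resolve_ant_ag_overlap(ant: Sequence[ActivityRecord],
                           ag: Sequence[ActivityRecord]
                           ) -> tuple[list[ActivityRecord], list[ActivityRecord]]:
    """Remove desensitizers from the antagonist set.

    Compounds present in both sets (agonists with a desensitizing IC50)
    are not true antagonists: they are dropped from ANT and retained in AG
    with their agonist potency.
    """
    ag_structures = {r.smiles for r in ag}
    ant_kept = [r for r in ant if r.smiles not in ag_structures]
    return ant_kept, list(ag)


def select_decoys(pool: Sequence[ActivityRecord], window: DecoyWindow,
                  n: int, seed: int = 0) -> list[ActivityRecord]:
    """Pick <= n structurally diverse presumed-inactive decoys inside the window.

    Greedy maximin diversity selection on a path-based hashed fingerprint:
    a seeded random start, then repeatedly the candidate farthest (lowest
    maximal Tanimoto) from the already chosen set.
    """
    from rdkit.Chem import rdFingerprintGenerator
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=1024)

    candidates, fps = [], []
    for r in pool:
        mol = Chem.MolFromSmiles(r.smiles)
        if mol is None or not window.contains(mol):
            continue
        candidates.append(r)
        fps.append(gen.GetFingerprint(mol))
    if len(candidates) <= n:
        if len(candidates) < n:
            warnings.warn(f"only {len(candidates)} decoy candidates inside window, wanted {n}")
        return [ActivityRecord(r.compound_id, r.smiles, "DCY", 0.0) for r in candidates]

    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(len(candidates)))]
    # min over chosen of similarity, maximized
    minsim = np.array(DataStructs.BulkTanimotoSimilarity(fps[chosen[0]], fps))
    while len(chosen) < n:
        minsim[chosen] = np.inf
        nxt = int(np.argmin(minsim))
        chosen.append(nxt)
        minsim = np.minimum(minsim, DataStructs.BulkTanimotoSimilarity(fps[nxt], fps))
    return [ActivityRecord(candidates[i].compound_id, candidates[i].smiles, "DCY", 0.0)
            for i in chosen]


def write_records(records: Sequence[ActivityRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.compound_id, r.smiles, r.activity_class, r.pX) for r in records],
        columns=["compound_id", "canonical_smiles", "activity_class", "pX"],
    ).to_csv(path, index=False)


def read_records(path: str | Path) -> list[ActivityRecord]:
    df = pd.read_csv(path)
    return [ActivityRecord(str(r.compound_id), r.canonical_smiles, r.activity_class, float(r.pX))
            for r in df.itertuples()]
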