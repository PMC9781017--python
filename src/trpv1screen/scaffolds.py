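"""Bemis-Murcko skeletons and plain ring systems.

Two scaffold reductions are used as dictionary keys for activity scoring:

* BM skeleton: the ring-and-linker framework with atom types, bond types
  and side chains removed (every atom carbon, every bond single).  Acyclic
  molecules have no skeleton.
* Plain ring (PR): one ring system (fused/spiro rings merged) retaining
  elements, bond orders and aromaticity, with substituents, linkers and
  side chains removed.  Atoms double-bonded to a ring atom (e.g. an oxo
  group) are retained as part of the ring system.
"""

from __future__ import annotations

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold


def canonical_key(mol: Chem.Mol) -> str:
    """Isomorphism-invariant string key for a connected molecular graph."""
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ValueError("canonical_key requires a connected graph")
    return Chem.MolToSmiles(mol)


def bm_skeleton(mol: Chem.Mol) -> str | None:
    """Canonical key of the Bemis-Murcko skeleton, or None for acyclic molecules.

    The Murcko framework (rings plus ring-ring linker paths) is reduced to
    a graph with every atom carbon and every bond single; exocyclic
    terminal atoms (former side-chain attachment or carbonyl oxygens) are
    pruned iteratively so only ring and linker atoms remain.
    """
    if mol.GetRingInfo().NumRings() == 0:
        return None
    framework = MurckoScaffold.GetScaffoldForMol(mol)
    generic = MurckoScaffold.MakeScaffoldGeneric(framework)
    rw = Chem.RWMol(generic)
    # prune terminal atoms not on a ring-ring linker path
    while True:
        terminal = [a.GetIdx() for a in rw.GetAtoms()
                    if a.GetDegree() <= 1 and not a.IsInRing()]
        if not terminal:
            break
        for idx in sorted(terminal, reverse=True):
            rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return canonical_key(out)


def _ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Atom-index sets of ring systems: rings sharing an atom are merged."""
    systems: list[set[int]] = []
    for ring in mol.GetRingInfo().AtomRings():
        ring = set(ring)
        merged = [s for s in systems if s & ring]
        for s in merged:
            systems.remove(s)
            ring |= s
        systems.append(ring)
    return systems


def plain_rings(mol: Chem.Mol) -> set[str]:
    """Canonical keys of the molecule's distinct plain ring systems.

    Within-molecule duplicates collapse to one key (a biphenyl contributes
    benzene once).  Exocyclic atoms double-bonded to a ring atom are kept
    with the system; all single-bonded substituents and linkers are cut.
    """
    keys: set[str] = set()
    for system in _ring_systems(mol):
        keep = set(system)
        for idx in system:
            atom = mol.GetAtomWithIdx(idx)
            for bond in atom.GetBonds():
                other = bond.GetOtherAtom(atom)
                if (other.GetIdx() not in system
                        and bond.GetBondType() != Chem.BondType.SINGLE
                        and not other.IsInRing()):
                    keep.add(other.GetIdx())
        keys.add(_extract_fragment_key(mol, keep))
    return keys


def _extract_fragment_key(mol: Chem.Mol, atom_indices: set[int]) -> str:
    """Canonical key of the induced subgraph on ``atom_indices``."""
    from rdkit import RDLogger

    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
        # mark atoms about to lose a neighbor: survives index renumbering
        atom.SetBoolProp("_cut", atom.GetIdx() in atom_indices and any(
            n.GetIdx() not in atom_indices for n in atom.GetNeighbors()))
    for idx in sorted((a.GetIdx() for a in rw.GetAtoms() if a.GetIdx() not in atom_indices),
                      reverse=True):
        rw.RemoveAtom(idx)
    RDLogger.DisableLog("rdApp.error")
    try:
        frag = Chem.RWMol(rw.GetMol())
        try:
            Chem.SanitizeMol(frag)
            return Chem.MolToSmiles(frag)
        except Exception:
            pass
        # aromatic N that lost its substituent needs the H back (e.g. the
        # plain ring of an N-methylated azole is the parent NH azole)
        frag = Chem.RWMol(rw.GetMol())
        for atom in frag.GetAtoms():
            if (atom.GetIsAromatic() and atom.GetAtomicNum() == 7
                    and atom.GetBoolProp("_cut")
                    and atom.GetDegree() == 2 and atom.GetTotalNumHs() == 0):
                atom.SetNumExplicitHs(1)
        try:
            out = frag.GetMol()
            Chem.SanitizeMol(out)
            return Chem.MolToSmiles(out)
        except Exception:
            # valence model irrecoverable after excision: canonical
            # fragment serialization of the parent is still a stable key
            return Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atom_indices),
                                            canonical=True)
    finally:
        RDLogger.EnableLog("rdApp.error")


def scaffold_table(smiles_list: list[str]) -> "pd.DataFrame":
    """Frequency table of BM and PR keys over a library (CSV-ready)."""
    import pandas as pd
    from collections import Counter

    bm_counts: Counter = Counter()
    pr_counts: Counter = Counter()
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        key = bm_skeleton(mol)
        if key is not None:
            bm_counts[key] += 1
        pr_counts.update(plain_rings(mol))
    rows = [(k, "BM", n) for k, n in bm_counts.most_common()]
    rows += [(k, "PR", n) for k, n in pr_counts.most_common()]
    return pd.DataFrame(rows, columns=["key", "kind", "frequency"])
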