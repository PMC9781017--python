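"""Pharmacophore-aware similarity, threshold clustering and representative picking.

A pharmacophore-typed atom-pair fingerprint (donor / acceptor / aromatic /
lipophilic / positively and negatively ionizable types, binned topological
distances) with Tanimoto similarity stands in for a flexible-pharmacophore
descriptor; the descriptor is pluggable so a different backend can be
swapped without touching the scoring stage.  Clustering is deterministic
leader clustering: compounds are scanned in input order and join the first
cluster whose leader is at least as similar as the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from rdkit import Chem

# pharmacophore feature definitions (SMARTS)
_FEATURES = {
    "D": Chem.MolFromSmarts("[$([N;!H0;v3]),$([O;H1;+0]),$([S;H1;+0])]"),   # H-bond donor
    "A": Chem.MolFromSmarts("[$([O;H0;v2]),$([O;H1;v2]),$([O;-]),$([N;v3;!$(N-*=[O,N,P,S])]),$([n;H0]),F]"),  # acceptor
    "R": Chem.MolFromSmarts("[a]"),                                          # aromatic
    "L": Chem.MolFromSmarts("[C;!$(C=[O,N,S]);!$(C#N)]"),                    # lipophilic carbon
    "P": Chem.MolFromSmarts("[+,$([N;H2;v3]),$([N;H1;v3;!$(N-a);!$(N-C=[O,N,S])])]"),  # pos. ionizable
    "N": Chem.MolFromSmarts("[-,$([C,S,P](=O)[O;H1])]"),                     # neg. ionizable
}

#: topological distance bins for atom pairs (upper edges, inclusive)
_DISTANCE_BINS = (1, 2, 3, 4, 5, 7, 9, 12, 16, 99)


@dataclass(frozen=True)
class SimilarityConfig:
    descriptor: str = "pharmacophore_pairs"  # or "path_fingerprint"
    cluster_threshold: float = 0.80

    def __post_init__(self):
        if not 0 < self.cluster_threshold <= 1:
            raise ValueError("cluster_threshold must be in (0, 1]")
        if self.descriptor not in ("pharmacophore_pairs", "path_fingerprint"):
            raise ValueError(f"unknown descriptor {self.descriptor!r}")


def _pharmacophore_types(mol: Chem.Mol) -> dict[int, set[str]]:
    types: dict[int, set[str]] = {}
    for label, patt in _FEATURES.items():
        for match in mol.GetSubstructMatches(patt):
            types.setdefault(match[0], set()).add(label)
    return types


def _bin_distance(d: int) -> int:
    for i, edge in enumerate(_DISTANCE_BINS):
        if d <= edge:
            return i
    return len(_DISTANCE_BINS)


def pharmacophore_fingerprint(mol: Chem.Mol) -> frozenset[tuple[str, str, int]]:
    """Set of (type, type, distance-bin) pharmacophore pair features."""
    types = _pharmacophore_types(mol)
    if not types:
        return frozenset()
    dmat = Chem.GetDistanceMatrix(mol)
    feats = set()
    idxs = sorted(types)
    for ii, i in enumerate(idxs):
        for j in idxs[ii:]:
            d = int(dmat[i][j])
            if i != j and d == 0:  # disconnected fragments
                continue
            b = _bin_distance(d)
            for ti in types[i]:
                for tj in types[j]:
                    lo, hi = sorted((ti, tj))
                    feats.add((lo, hi, b))
    return frozenset(feats)


def _path_fingerprint(mol: Chem.Mol):
    from rdkit.Chem import rdFingerprintGenerator
    return rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048).GetFingerprint(mol)


def fingerprint(mol: Chem.Mol, cfg: SimilarityConfig | None = None):
    cfg = cfg or SimilarityConfig()
    if cfg.descriptor == "pharmacophore_pairs":
        return pharmacophore_fingerprint(mol)
    return _path_fingerprint(mol)


def _tanimoto(fa, fb) -> float:
    if isinstance(fa, frozenset):
        if not fa and not fb:
            return 1.0
        union = len(fa | fb)
        return len(fa & fb) / union if union else 1.0
    from rdkit import DataStructs
    return DataStructs.TanimotoSimilarity(fa, fb)


def similarity(a: Chem.Mol, b: Chem.Mol, cfg: SimilarityConfig | None = None) -> float:
    """Tanimoto similarity in [0, 1]; symmetric, 1 for identical structures."""
    cfg = cfg or SimilarityConfig()
    return _tanimoto(fingerprint(a, cfg), fingerprint(b, cfg))


@dataclass
class ClusterAssignment:
    """Partition of compounds into similarity clusters with per-cluster leaders."""

    cluster_of: dict[str, int]
    leaders: list[str]               # compound_id of each cluster leader, by cluster id
    leader_fingerprints: list[object]
    config: SimilarityConfig

    @property
    def n_clusters(self) -> int:
        return len(self.leaders)

    def assign_external(self, mol: Chem.Mol) -> int | None:
        """Cluster of an unseen molecule: first leader (in leader order) with
        similarity >= threshold, else None."""
        fp = fingerprint(mol, self.config)
        for cid, lfp in enumerate(self.leader_fingerprints):
            if _tanimoto(fp, lfp) >= self.config.cluster_threshold:
                return cid
        return None


def cluster(ids: Sequence[str], mols: Sequence[Chem.Mol],
            cfg: SimilarityConfig | None = None) -> ClusterAssignment:
    """Leader clustering at the configured similarity threshold.

    Deterministic given input order: each compound joins the first existing
    cluster whose leader it matches at >= threshold, otherwise it opens a
    new cluster and becomes its leader.
    """
    cfg = cfg or SimilarityConfig()
    if len(ids) != len(mols):
        raise ValueError("ids and mols length mismatch")
    if len(mols) == 0:
        raise ValueError("cluster requires at least one molecule")
    cluster_of: dict[str, int] = {}
    leaders: list[str] = []
    leader_fps: list[object] = []
    for cid_str, mol in zip(ids, mols):
        fp = fingerprint(mol, cfg)
        for k, lfp in enumerate(leader_fps):
            if _tanimoto(fp, lfp) >= cfg.cluster_threshold:
                cluster_of[cid_str] = k
                break
        else:
            cluster_of[cid_str] = len(leaders)
            leaders.append(cid_str)
            leader_fps.append(fp)
    return ClusterAssignment(cluster_of, leaders, leader_fps, cfg)


def pick_representatives(assignment: ClusterAssignment, records) -> list:
    """Most potent compound (max pX) per cluster; ties broken by smaller id.

    Used to prune structurally redundant compounds before docking-set
    assembly.
    """
    best: dict[int, object] = {}
    for r in records:
        k = assignment.cluster_of[r.compound_id]
        cur = best.get(k)
        if cur is None or (r.pX, ) > (cur.pX, ) or (r.pX == cur.pX and r.compound_id < cur.compound_id):
            best[k] = r
    return [best[k] for k in sorted(best)]
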