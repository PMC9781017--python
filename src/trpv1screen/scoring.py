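"""Scaffold- and cluster-based activity scores.

For a chosen target class (ANT or AG), each Bemis-Murcko skeleton, plain
ring system and similarity cluster is assigned the arithmetic mean of the
activity values (pX for target-class members, 0 for everything else) of
the dataset compounds that carry it.  A compound's average activity score
is then

    Score = (BMS + PRS + SCS) / 3

where BMS is its skeleton's mean (0 for acyclic molecules or unseen
skeletons), PRS the mean over its distinct plain rings of their table
means (unseen rings contribute 0), and SCS its cluster's mean (0 when it
joins no cluster).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from rdkit import Chem

from .chemio import ActivityRecord
from .scaffolds import bm_skeleton, plain_rings
from .similarity import ClusterAssignment


@dataclass
class ScoreTable:
    """key -> (mean activity value, member count) for one scaffold kind."""

    kind: str                     # BM | PR | CLUSTER
    target: str                   # ANT | AG
    means: dict[object, float] = field(default_factory=dict)
    counts: dict[object, int] = field(default_factory=dict)

    def lookup(self, key) -> float:
        return self.means.get(key, 0.0)


@dataclass
class ScoreTables:
    target: str
    bm: ScoreTable
    pr: ScoreTable
    cluster: ScoreTable
    clustering: ClusterAssignment


@dataclass(frozen=True)
class CompoundScores:
    compound_id: str
    target: str
    BMS: float
    PRS: float
    SCS: float

    @property
    def Score(self) -> float:
        return (self.BMS + self.PRS + self.SCS) / 3.0


def _target_px(record: ActivityRecord, target: str) -> float:
    return record.pX if record.activity_class == target else 0.0


def _mean_table(kind: str, target: str, pairs) -> ScoreTable:
    sums: dict[object, float] = {}
    counts: dict[object, int] = {}
    for key, px in pairs:
        sums[key] = sums.get(key, 0.0) + px
        counts[key] = counts.get(key, 0) + 1
    return ScoreTable(kind, target,
                      {k: sums[k] / counts[k] for k in sums}, counts)


def build_tables(records: Sequence[ActivityRecord],
                 mols: Sequence[Chem.Mol],
                 clustering: ClusterAssignment,
                 target: str) -> ScoreTables:
    """Group-by means over BM skeletons, plain rings and clusters.

    Every dataset member contributes to each key it carries; non-target
    classes contribute activity 0, diluting scaffolds shared with
    inactives.
    """
    if target not in ("ANT", "AG"):
        raise ValueError(f"target must be ANT or AG, got {target!r}")
    if not records:
        raise ValueError("empty dataset")

    bm_pairs, pr_pairs, cl_pairs = [], [], []
    for rec, mol in zip(records, mols):
        px = _target_px(rec, target)
        key = bm_skeleton(mol)
        if key is not None:
            bm_pairs.append((key, px))
        for ring in plain_rings(mol):
            pr_pairs.append((ring, px))
        cl_pairs.append((clustering.cluster_of[rec.compound_id], px))

    return ScoreTables(
        target=target,
        bm=_mean_table("BM", target, bm_pairs),
        pr=_mean_table("PR", target, pr_pairs),
        cluster=_mean_table("CLUSTER", target, cl_pairs),
        clustering=clustering,
    )


def score_compound(compound_id: str, mol: Chem.Mol, tables: ScoreTables,
                   cluster_id: int | None = ...) -> CompoundScores:
    """Average activity score of one compound against frozen tables.

    ``cluster_id``: pass the known cluster for training-set compounds;
    leave at the default to assign by leader similarity (None = no cluster
    matched, SCS = 0).
    """
    key = bm_skeleton(mol)
    bms = tables.bm.lookup(key) if key is not None else 0.0

    rings = plain_rings(mol)
    prs = sum(tables.pr.lookup(r) for r in rings) / len(rings) if rings else 0.0

    if cluster_id is ...:
        cluster_id = tables.clustering.assign_external(mol)
    scs = tables.cluster.lookup(cluster_id) if cluster_id is not None else 0.0
    return CompoundScores(compound_id, tables.target, bms, prs, scs)


def score_library(records: Sequence[ActivityRecord], mols: Sequence[Chem.Mol],
                  tables: ScoreTables) -> pd.DataFrame:
    """Scores for the training library itself (known cluster memberships)."""
    rows = []
    for rec, mol in zip(records, mols):
        cs = score_compound(rec.compound_id, mol, tables,
                            cluster_id=tables.clustering.cluster_of[rec.compound_id])
        rows.append((rec.compound_id, cs.BMS, cs.PRS, cs.SCS, cs.Score))
    return pd.DataFrame(rows, columns=["compound_id", "BMS", "PRS", "SCS", "Score"]
                        ).set_index("compound_id")


def score_external_library(ids: Sequence[str], mols: Sequence[Chem.Mol],
                           tables_ant: ScoreTables, tables_ag: ScoreTables
                           ) -> pd.DataFrame:
    """Score-ANT and Score-AG for unseen molecules against frozen reference
    tables; unseen scaffolds, rings and clusters contribute 0."""
    rows = []
    for cid, mol in zip(ids, mols):
        s_ant = score_compound(cid, mol, tables_ant)
        s_ag = score_compound(cid, mol, tables_ag)
        rows.append((cid, s_ant.Score, s_ag.Score))
    return pd.DataFrame(rows, columns=["compound_id", "Score-ANT", "Score-AG"]
                        ).set_index("compound_id")
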