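import numpy as np
import pytest
from rdkit import Chem

from trpv1screen.chemio import ActivityRecord
from trpv1screen.scaffolds import bm_skeleton, plain_rings
from trpv1screen.scoring import (
    CompoundScores,
    ScoreTable,
    ScoreTables,
    build_tables,
    score_compound,
    score_external_library,
    score_library,
)
from trpv1screen.similarity import ClusterAssignment, SimilarityConfig, cluster

from conftest import mol


def _library(spec):
    """spec: list of (id, smiles, class, pX)."""
    records = [ActivityRecord(c, Chem.CanonSmiles(s), k, p) for c, s, k, p in spec]
    mols = [Chem.MolFromSmiles(r.smiles) for r in records]
    clustering = cluster([r.compound_id for r in records], mols,
                         SimilarityConfig(cluster_threshold=0.8))
    return records, mols, clustering


class TestBuildTables:
    def test_singleton_antagonist(self):
        records, mols, clustering = _library([("a", "c1ccccc1CCN", "ANT", 7.0)])
        tables = build_tables(records, mols, clustering, "ANT")
        key = bm_skeleton(mols[0])
        assert tables.bm.means[key] == pytest.approx(7.0)
        assert tables.bm.counts[key] == 1

    def test_inactive_dilutes_shared_skeleton(self):
        records, mols, clustering = _library([
            ("a", "c1ccccc1CCN", "ANT", 8.0),
            ("i", "c1ccccc1CCO", "IN", 0.0),
        ])
        tables = build_tables(records, mols, clustering, "ANT")
        key = bm_skeleton(mols[0])
        assert tables.bm.means[key] == pytest.approx(4.0)

    def test_brute_force_groupby_oracle(self):
        spec = [
            ("a", "c1ccccc1CCN", "ANT", 7.0),
            ("b", "c1ccccc1CCCO", "ANT", 6.0),
            ("g", "CC(C)Cc1ccncc1", "AG", 5.5),
            ("i", "c1ccncc1CCO", "IN", 0.0),
        ]
        records, mols, clustering = _library(spec)
        for target in ("ANT", "AG"):
            tables = build_tables(records, mols, clustering, target)
            # oracle: exhaustive group-by over every scaffold key
            px = {r.compound_id: (r.pX if r.activity_class == target else 0.0)
                  for r in records}
            groups = {}
            for r, m in zip(records, mols):
                k = bm_skeleton(m)
                if k is not None:
                    groups.setdefault(("BM", k), []).append(px[r.compound_id])
                for ring in plain_rings(m):
                    groups.setdefault(("PR", ring), []).append(px[r.compound_id])
                groups.setdefault(
                    ("CL", clustering.cluster_of[r.compound_id]), []).append(px[r.compound_id])
            for (kind, key), vals in groups.items():
                table = {"BM": tables.bm, "PR": tables.pr, "CL": tables.cluster}[kind]
                assert table.means[key] == pytest.approx(np.mean(vals))
                assert table.counts[key] == len(vals)

    def test_empty_dataset_rejected(self):
        clustering = ClusterAssignment({}, [], [], SimilarityConfig())
        with pytest.raises(ValueError):
            build_tables([], [], clustering, "ANT")


class TestScoreCompound:
    def _tables(self, bm=None, pr=None, cl=None):
        clustering = ClusterAssignment({}, [], [], SimilarityConfig())
        return ScoreTables(
            "ANT",
            ScoreTable("BM", "ANT", bm or {}),
            ScoreTable("PR", "ANT", pr or {}),
            ScoreTable("CLUSTER", "ANT", cl or {}),
            clustering)

    def test_equal_components_identity(self):
        m = mol("c1ccccc1C")
        key = bm_skeleton(m)
        (ring,) = plain_rings(m)
        t = self._tables(bm={key: 6.0}, pr={ring: 6.0}, cl={0: 6.0})
        cs = score_compound("x", m, t, cluster_id=0)
        assert cs.Score == pytest.approx(6.0)

    def test_component_arithmetic(self):
        m = mol("c1ccccc1C")
        key = bm_skeleton(m)
        (ring,) = plain_rings(m)
        t = self._tables(bm={key: 6.0}, pr={ring: 3.0})
        cs = score_compound("x", m, t, cluster_id=None)
        assert (cs.BMS, cs.PRS, cs.SCS) == (6.0, 3.0, 0.0)
        assert cs.Score == pytest.approx(3.0)

    def test_multi_ring_inner_mean(self):
        m = mol("c1ccccc1Cc1ccncc1")  # benzene + pyridine
        rings = sorted(plain_rings(m))
        t = self._tables(pr={rings[0]: 8.0, rings[1]: 4.0})
        cs = score_compound("x", m, t, cluster_id=None)
        assert cs.PRS == pytest.approx(6.0)

    def test_acyclic_compound_all_zero_tables(self):
        cs = score_compound("x", mol("CCCCCC"), self._tables(), cluster_id=None)
        assert cs.BMS == cs.PRS == cs.SCS == 0.0


class TestLibraryScoring:
    SPEC = [
        ("a", "c1ccccc1CCN", "ANT", 7.0),
        ("b", "c1ccccc1CCCO", "ANT", 6.0),
        ("g", "CC(C)Cc1ccncc1", "AG", 5.5),
        ("i", "c1ccncc1CCO", "IN", 0.0),
    ]

    def test_frozen_table_self_consistency(self):
        records, mols, clustering = _library(self.SPEC)
        tables = build_tables(records, mols, clustering, "ANT")
        built = score_library(records, mols, tables)
        for r, m in zip(records, mols):
            frozen = score_compound(
                r.compound_id, m, tables,
                cluster_id=clustering.cluster_of[r.compound_id])
            assert built.loc[r.compound_id, "Score"] == pytest.approx(frozen.Score)

    def test_score_bounded_by_max_px(self):
        records, mols, clustering = _library(self.SPEC)
        for target in ("ANT", "AG"):
            tables = build_tables(records, mols, clustering, target)
            scores = score_library(records, mols, tables)["Score"]
            assert (scores >= 0).all()
            assert (scores <= max(r.pX for r in records)).all()

    def test_no_antagonists_means_zero_ant_scores(self):
        spec = [("g", "CC(C)Cc1ccncc1", "AG", 5.5), ("i", "c1ccncc1CCO", "IN", 0.0)]
        records, mols, clustering = _library(spec)
        tables = build_tables(records, mols, clustering, "ANT")
        assert (score_library(records, mols, tables)["Score"] == 0).all()

    def test_adding_inactive_lowers_key_mean(self):
        records, mols, clustering = _library(self.SPEC)
        base = build_tables(records, mols, clustering, "ANT")
        extra = self.SPEC + [("i2", "c1ccccc1CCCN", "IN", 0.0)]  # shares benzene PR
        records2, mols2, clustering2 = _library(extra)
        more = build_tables(records2, mols2, clustering2, "ANT")
        benzene = Chem.CanonSmiles("c1ccccc1")
        assert more.pr.means[benzene] <= base.pr.means[benzene]


class TestExternalScoring:
    def test_unseen_molecule_scores_zero(self):
        records, mols, clustering = _library(TestLibraryScoring.SPEC)
        t_ant = build_tables(records, mols, clustering, "ANT")
        t_ag = build_tables(records, mols, clustering, "AG")
        out = score_external_library(["u"], [mol("C1CC1C1CC1C#N")], t_ant, t_ag)
        assert out.loc["u", "Score-ANT"] == 0.0
        assert out.loc["u", "Score-AG"] == 0.0

    def test_training_singleton_reproduced(self):
        spec = [("a", "Clc1ccc(CN2CCN(C)CC2)cc1", "ANT", 7.0)]
        records, mols, clustering = _library(spec)
        t_ant = build_tables(records, mols, clustering, "ANT")
        t_ag = build_tables(records, mols, clustering, "AG")
        out = score_external_library(["copy"], [Chem.MolFromSmiles(records[0].smiles)],
                                     t_ant, t_ag)
        assert out.loc["copy", "Score-ANT"] == pytest.approx(7.0)
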