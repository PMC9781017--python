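import math

import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from trpv1screen import chemio
from trpv1screen.chemio import (
    ActivityRecord,
    DecoyWindow,
    RawActivityEntry,
    curate,
    read_library,
    resolve_ant_ag_overlap,
    select_decoys,
    to_pX,
)


class TestToPX:
    @pytest.mark.parametrize("nm, expected", [
        (1000.0, 6.0),
        (1.0, 9.0),
        (15850.0, 4.8),       # 15.85 uM agonist potency
    ])
    def test_known_conversions(self, nm, expected):
        assert to_pX(nm) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            to_pX(bad)

    @given(st.floats(min_value=0.0, max_value=12.0))
    @settings(deadline=None)
    def test_inverse_identity(self, p):
        # to_pX(10^(9-p)) = p and strict monotonicity around it
        assert to_pX(10 ** (9 - p)) == pytest.approx(p, abs=1e-9)

    def test_strictly_decreasing(self):
        values = [0.5, 1, 10, 500, 1e6]
        px = [to_pX(v) for v in values]
        assert all(a > b for a, b in zip(px, px[1:]))


class TestCurate:
    def test_duplicates_merged_on_nM_scale(self):
        entries = [
            RawActivityEntry("c1", "c1ccccc1O", "IC50", 100.0),
            RawActivityEntry("c2", "Oc1ccccc1", "IC50", 1000.0),
        ]
        out = curate(entries, "antagonist_assay")
        assert len(out) == 1
        assert out[0].activity_class == "ANT"
        assert out[0].pX == pytest.approx(-math.log10(550e-9), abs=1e-9)

    def test_px_scale_merge_switch(self):
        entries = [
            RawActivityEntry("c1", "c1ccccc1O", "IC50", 100.0),
            RawActivityEntry("c2", "Oc1ccccc1", "IC50", 1000.0),
        ]
        out = curate(entries, "antagonist_assay", duplicate_mean="pX")
        assert out[0].pX == pytest.approx((to_pX(100) + to_pX(1000)) / 2)

    def test_weak_actives_demoted_to_inactive(self):
        entries = [RawActivityEntry("w", "CCO", "EC50", 50000.0)]
        out = curate(entries, "agonist_assay")
        assert out[0].activity_class == "IN"
        assert out[0].pX == 0.0

    def test_declared_inactive_ki_entries(self):
        entries = [RawActivityEntry("k", "CCN", "Ki", None, declared_inactive=True)]
        out = curate(entries, "inactivity_assay")
        assert [(r.activity_class, r.pX) for r in out] == [("IN", 0.0)]

    def test_idempotent_at_record_level(self):
        entries = [
            RawActivityEntry("a", "c1ccccc1CCN", "IC50", 10.0),
            RawActivityEntry("b", "CCO", "IC50", 90000.0),
        ]
        once = curate(entries, "antagonist_assay")
        again = curate(
            [RawActivityEntry(r.compound_id, r.smiles, "IC50",
                              10 ** (9 - r.pX) if r.pX else None,
                              declared_inactive=r.pX == 0)
             for r in once], "antagonist_assay")
        assert {(r.smiles, r.activity_class) for r in once} == \
               {(r.smiles, r.activity_class) for r in again}

    def test_desalting_merges_salt_forms(self):
        entries = [
            RawActivityEntry("free", "c1ccccc1CCN", "IC50", 100.0),
            RawActivityEntry("hcl", "c1ccccc1CCN.Cl", "IC50", 100.0),
        ]
        assert len(curate(entries, "antagonist_assay")) == 1


class TestOverlapResolution:
    def _rec(self, cid, smi, cls, px):
        return ActivityRecord(cid, Chem.CanonSmiles(smi), cls, px)

    def test_disjoint_unchanged(self):
        ant = [self._rec("a", "c1ccccc1CN", "ANT", 7.0)]
        ag = [self._rec("g", "CCOC(=O)C", "AG", 6.0)]
        ant2, ag2 = resolve_ant_ag_overlap(ant, ag)
        assert ant2 == ant and ag2 == ag

    def test_desensitizer_kept_as_agonist(self):
        shared = "c1ccccc1CCO"
        ant = [self._rec("x", shared, "ANT", 7.5), self._rec("a", "CCCCN", "ANT", 6.0)]
        ag = [self._rec("x", shared, "AG", 5.5)]
        ant2, ag2 = resolve_ant_ag_overlap(ant, ag)
        assert len(ant2) == len(ant) - 1
        kept = [r for r in ag2 if r.smiles == Chem.CanonSmiles(shared)]
        assert kept[0].pX == 5.5  # agonist potency retained, not the IC50

    def test_no_structure_in_two_classes(self):
        ant = [self._rec("x", "c1ccccc1CCO", "ANT", 7.5)]
        ag = [self._rec("x", "c1ccccc1CCO", "AG", 5.5)]
        ant2, ag2 = resolve_ant_ag_overlap(ant, ag)
        assert not ({r.smiles for r in ant2} & {r.smiles for r in ag2})


class TestReadLibrary:
    def test_csv_counts_and_bad_smiles_reported(self, tmp_path):
        p = tmp_path / "lib.csv"
        p.write_text("compound_id,smiles,assay_kind,value_nM\n"
                     "a,CCO,IC50,100\nb,c1ccccc1,IC50,200\n"
                     "bad,not_a_smiles,IC50,1\n"
                     "c,CCN,IC50,300\nd,CCC,IC50,400\n")
        entries, rep = read_library(p, "smiles_csv")
        assert len(entries) == 4
        assert rep.n_failed == 1 and rep.failures == ["bad"]

    def test_missing_file_is_hard_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_library(tmp_path / "nope.csv")

    def test_sdf_roundtrip(self, tmp_path, capsaicin):
        p = tmp_path / "one.sdf"
        w = Chem.SDWriter(str(p))
        capsaicin.SetProp("_Name", "capsaicin")
        w.write(capsaicin)
        w.close()
        entries, rep = read_library(p, "sdf")
        assert rep.n_failed == 0 and len(entries) == 1
        assert Chem.CanonSmiles(entries[0].smiles) == Chem.MolToSmiles(capsaicin)

    def test_curated_roundtrip_preserves_structures(self, tmp_path):
        records = [ActivityRecord("a", Chem.CanonSmiles("c1ccccc1CCN"), "ANT", 7.0),
                   ActivityRecord("b", Chem.CanonSmiles("CCO"), "IN", 0.0)]
        p = tmp_path / "curated.csv"
        chemio.write_records(records, p)
        back = chemio.read_records(p)
        assert sorted(r.smiles for r in back) == sorted(r.smiles for r in records)


class TestDecoys:
    POOL = [ActivityRecord(f"d{i}", smi, "IN", 0.0) for i, smi in enumerate([
        "c1ccccc1CCCO", "c1ccccc1CCN", "c1ccc2ccccc2c1", "CC(C)Cc1ccccc1",
        "c1ccccc1OCCO", "Clc1ccccc1CCO", "c1ccncc1CCO", "CCCCc1ccccc1O",
    ])]
    WINDOW = DecoyWindow((90.0, 250.0), (-1.0, 5.0), (0, 6), (0, 3))

    def test_out_of_window_pool_gives_empty(self):
        window = DecoyWindow((1000.0, 2000.0), (0.0, 1.0), (0, 1), (0, 1))
        with pytest.warns(UserWarning, match="decoy candidates"):
            assert select_decoys(self.POOL, window, 3, seed=0) == []

    def test_whole_pool_when_n_matches(self):
        with pytest.warns(UserWarning):
            out = select_decoys(self.POOL, self.WINDOW, 50, seed=0)
        assert {r.compound_id for r in out} == {r.compound_id for r in self.POOL}
        assert all(r.activity_class == "DCY" and r.pX == 0.0 for r in out)

    def test_seed_determinism(self):
        a = select_decoys(self.POOL, self.WINDOW, 4, seed=7)
        b = select_decoys(self.POOL, self.WINDOW, 4, seed=7)
        assert [r.compound_id for r in a] == [r.compound_id for r in b]


class TestInvariantValidation:
    def test_active_below_cutoff_rejected(self):
        with pytest.raises(ValueError):
            ActivityRecord("x", "CCO", "ANT", 4.5)

    def test_inactive_with_potency_rejected(self):
        with pytest.raises(ValueError):
            ActivityRecord("x", "CCO", "IN", 6.0)

    def test_unknown_assay_kind_rejected(self):
        with pytest.raises(ValueError):
            RawActivityEntry("x", "CCO", "IC90", 1.0)
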