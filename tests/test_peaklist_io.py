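import warnings

import numpy as np
import pytest

from serpinmr.peaklist_io import (
    MethylPeak,
    MethylSite,
    PeakList,
    PeakListError,
    read_peaklist,
    read_structure,
    write_peaklist,
    write_results_table,
)


class TestMethylSite:
    def test_label_round_trip(self):
        site = MethylSite.from_label("I375d1")
        assert (site.residue_number, site.methyl_id, site.residue_type) == (
            375, "d1", "I",
        )
        assert site.label == "I375d1"

    @pytest.mark.parametrize("label", ["I375d2", "M10d1", "A5g1", "X12d1", "L"])
    def test_invalid_labels_rejected(self, label):
        with pytest.raises(PeakListError):
            MethylSite.from_label(label)

    def test_residue_type_constrains_methyl_id(self):
        with pytest.raises(PeakListError):
            MethylSite(100, "e", "V")


class TestSparkyIO:
    def test_parse_row(self, tmp_path):
        p = tmp_path / "a.list"
        p.write_text("Assignment w1 w2 Height\nI375d1 0.71 12.8 1.2e6\n")
        pl = read_peaklist(p, dialect="sparky")
        (peak,) = pl.peaks
        assert peak.site == MethylSite(375, "d1", "I")
        assert peak.delta_H == 0.71
        assert peak.delta_C == 12.8
        assert peak.intensity == 1.2e6

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.list"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            pl = read_peaklist(p)
        assert pl.peaks == []

    def test_unknown_assignment_kept_unassigned(self, tmp_path):
        p = tmp_path / "a.list"
        p.write_text("Q99x1 0.5 20.0 1.0\n")
        with pytest.warns(UserWarning, match="unparseable"):
            pl = read_peaklist(p)
        assert pl.peaks[0].site is None

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "a.list"
        p.write_text("I375d1 0.71 12.8 1.0\nL288d1 bad 22.0 1.0\n")
        with pytest.raises(PeakListError, match=":2"):
            read_peaklist(p)

    def test_round_trip_bit_exact(self, tmp_path, peaklists):
        src = peaklists["M"]
        path = tmp_path / "m.list"
        write_peaklist(src, path, dialect="sparky")
        back = read_peaklist(path, dialect="sparky", state_label="M")
        assert len(back.peaks) == len(src.peaks)
        for a, b in zip(src.peaks, back.peaks):
            assert a.site == b.site
            assert a.delta_H == b.delta_H  # repr round-trip is exact
            assert a.delta_C == b.delta_C
            assert a.intensity == b.intensity

    def test_order_independence(self, tmp_path, peaklists):
        src = peaklists["Z"]
        p1, p2 = tmp_path / "a.list", tmp_path / "b.list"
        write_peaklist(src, p1)
        shuffled = PeakList(
            state_label="Z",
            peaks=list(reversed(src.peaks)),
        )
        write_peaklist(shuffled, p2)
        a = read_peaklist(p1).assigned
        b = read_peaklist(p2).assigned
        assert set(a) == set(b)
        for site in a:
            assert a[site].delta_H == b[site].delta_H


class TestCsvDialect:
    def test_round_trip(self, tmp_path, peaklists):
        src = peaklists["S"]
        path = tmp_path / "s.csv"
        write_peaklist(src, path, dialect="csv")
        back = read_peaklist(path, dialect="csv")
        assert {p.site for p in back.peaks} == {p.site for p in src.peaks}
        got = back.assigned
        for site, p in src.assigned.items():
            assert got[site].delta_H == pytest.approx(p.delta_H, abs=0)


class TestNmrStar:
    STAR = """\
data_synthetic_shifts
save_assigned_chemical_shifts
   loop_
      _Atom_chem_shift.ID
      _Atom_chem_shift.Seq_ID
      _Atom_chem_shift.Comp_ID
      _Atom_chem_shift.Atom_ID
      _Atom_chem_shift.Val
      1 375 ILE CD1 12.8
      2 375 ILE HD1 0.71
      3 288 LEU CD1 24.1
      4 288 LEU HD1 0.85
      5 288 LEU CD2 23.0
   stop_
save_
"""

    def test_pairs_assembled(self, tmp_path):
        p = tmp_path / "shifts.str"
        p.write_text(self.STAR)
        with pytest.warns(UserWarning, match="incomplete"):
            pl = read_peaklist(p, dialect="nmrstar")
        assigned = pl.assigned
        assert assigned[MethylSite(375, "d1", "I")].delta_H == 0.71
        assert assigned[MethylSite(375, "d1", "I")].delta_C == 12.8
        assert assigned[MethylSite(288, "d1", "L")].delta_C == 24.1
        # L288d2 has a 13C shift but no 1H partner -> skipped
        assert MethylSite(288, "d2", "L") not in assigned


class TestStructure:
    def test_toy_ile_pdb(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        pdb.write_text(
            "ATOM      1  CA  ILE A  10      0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CD1 ILE A  10      1.500   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CA  GLY A  11      5.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        model = read_structure(pdb, mutation_residues=[11])
        site = MethylSite(10, "d1", "I")
        assert np.allclose(model.methyl_coords[site], [1.5, 0, 0])
        assert model.min_distance(site, "mutation") == pytest.approx(3.5)

    def test_absent_ligand_warns(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        pdb.write_text(
            "ATOM      1  CD1 ILE A  10      1.500   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        with pytest.warns(UserWarning, match="ligand"):
            model = read_structure(pdb, ligand_resname="LIG")
        assert model.ligand_atoms == []

    def test_missing_mutation_residue_errors(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        pdb.write_text(
            "ATOM      1  CD1 ILE A  10      1.500   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        with pytest.raises(PeakListError, match="mutation residue"):
            read_structure(pdb, mutation_residues=[342])

    def test_distances_match_brute_force(self, tmp_path, scenario):
        from serpinmr.synthetic_data import _write_toy_pdb

        pdb = tmp_path / "synth.pdb"
        _write_toy_pdb(scenario, pdb)
        model = read_structure(pdb, mutation_residues=[999], ligand_resname="LIG")
        # brute-force pairwise distances agree with the original coordinates
        # to PDB format precision (3 decimals)
        for site, xyz in list(scenario.structure.methyl_coords.items())[:25]:
            assert np.allclose(model.methyl_coords[site], xyz, atol=1e-3)


class TestResultsTable:
    def test_round_trip_to_formatting_precision(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({"site": ["I375d1"], "dCH": [0.03905124837]})
        out = tmp_path / "t.tsv"
        write_results_table(df, out)
        back = pd.read_csv(out, sep="\t")
        assert back["dCH"][0] == pytest.approx(0.03905124837, rel=1e-5)

    def test_empty_errors(self, tmp_path):
        import pandas as pd

        with pytest.raises(PeakListError):
            write_results_table(pd.DataFrame(), tmp_path / "t.tsv")
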