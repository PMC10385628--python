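"""Structure reading/writing, interaction typing, residue contacts, pI."""

import numpy as np
import pytest

from contactzones import synthetic as syn
from contactzones.structure_io import (
    AtomRecord,
    TypingError,
    UnknownElementError,
    assign_interaction_types,
    covalent_bonds,
    dedupe_altlocs,
    isoelectric_point,
    net_charge,
    place_riding_hydrogens,
    read_ensemble,
    read_structure,
    residue_contacts,
    write_pdb,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       1.234   2.345   3.456  1.00 10.00           N
ATOM      2  CA  ALA A   1       2.468   3.141   3.456  0.80 12.50           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60 10.00           C
ATOM      2  CA BALA A   1       0.500   0.000   0.000  0.40 11.00           C
END
"""


class TestReading:
    def test_minimal_pdb_roundtrips_positions(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(MINIMAL_PDB)
        model = read_structure(p)
        atoms = model.atoms
        assert len(atoms) == 2
        assert atoms[0].position == pytest.approx((1.234, 2.345, 3.456))
        assert atoms[1].occupancy == pytest.approx(0.80)
        assert atoms[1].b_factor == pytest.approx(12.50)
        assert atoms[0].chain == "A" and atoms[0].residue_number == 1

    def test_both_altlocs_retained_and_dedupe_keeps_highest_occ(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        atoms = read_structure(p).atoms
        assert len(atoms) == 2
        assert sorted(a.altloc for a in atoms) == ["A", "B"]
        kept = dedupe_altlocs(atoms)
        assert len(kept) == 1 and kept[0].altloc == "A"

    def test_write_then_read_preserves_coordinates(self, tmp_path, glycine_atoms):
        # five-residue protonated peptide built from shifted glycines
        atoms = []
        for r in range(5):
            for a in glycine_atoms:
                atoms.append(
                    AtomRecord(
                        id=len(atoms) + 1, element=a.element, name=a.name,
                        residue_name="GLY", residue_number=r + 1, chain="A",
                        position=tuple(np.asarray(a.position) + [3.5 * r, 0, 0]),
                    )
                )
        p = tmp_path / "pep.pdb"
        write_pdb(atoms, p)
        back = read_structure(p).atoms
        assert len(back) == len(atoms)
        np.testing.assert_allclose(
            [b.position for b in back], [a.position for a in atoms], atol=1.5e-3
        )

    def test_mmcif_and_autodetect(self, tmp_path, glycine_atoms):
        import gemmi

        p = tmp_path / "g.pdb"
        write_pdb(glycine_atoms, p)
        st = gemmi.read_structure(str(p))
        st.setup_entities()
        cif = tmp_path / "g.cif"
        st.make_mmcif_document().write_file(str(cif))
        for fmt in ("mmcif", "auto"):
            model = read_structure(cif, format=fmt)
            assert len(model.atoms) == len(glycine_atoms)

    def test_multimodel_returns_ordered_ensemble(self, tmp_path, glycine_atoms):
        shifted = [
            AtomRecord(
                id=a.id, element=a.element, name=a.name, residue_name="GLY",
                residue_number=1, chain="A",
                position=tuple(np.asarray(a.position) + 1.0),
            )
            for a in glycine_atoms
        ]
        p = tmp_path / "ens.pdb"
        write_pdb([glycine_atoms, shifted], p)
        models = read_ensemble(p)
        assert len(models) == 2
        d = np.array(models[1].atoms[0].position) - np.array(
            models[0].atoms[0].position
        )
        np.testing.assert_allclose(d, [1.0, 1.0, 1.0], atol=1e-3)

    def test_unreadable_file_raises_parse_error(self, tmp_path):
        from contactzones.structure_io import StructureParseError

        p = tmp_path / "bad.cif"
        p.write_text("this is not a structure\n")
        with pytest.raises(StructureParseError):
            read_structure(p, format="mmcif")

    def test_unknown_element_rejected(self):
        with pytest.raises(UnknownElementError):
            AtomRecord(
                id=1, element="Qq", name="QQ", residue_name="UNK",
                residue_number=1, chain="A", position=(0, 0, 0),
            )


class TestInteractionTyping:
    def test_glycine_typing(self, glycine_atoms):
        tm = assign_interaction_types(glycine_atoms, side="a")
        by_name = dict(zip([a.name for a in tm.atoms], tm.types))
        assert by_name["HA2"] == "Hc" and by_name["HA3"] == "Hc"
        assert by_name["H"] == "Ho/n"
        assert by_name["O"] == "O"
        assert by_name["N"] == "N"
        assert by_name["CA"] == "C" and by_name["C"] == "C"

    def test_bare_water_oxygen_typed_w(self, water_atom):
        tm = assign_interaction_types(water_atom)
        assert tm.types == ["W"]

    def test_guanidinium_h_polar_n_hydrophobic(self, guanidinium_atoms):
        tm = assign_interaction_types(guanidinium_atoms)
        by_name = dict(zip([a.name for a in tm.atoms], tm.types))
        for h in ("HE", "HH11", "HH12", "HH21", "HH22"):
            assert by_name[h] == "Ho/n"
        for n in ("NE", "NH1", "NH2"):
            assert by_name[n] == "N"
        assert by_name["CZ"] == "C" and by_name["CD"] == "C"

    def test_type_partition_covers_all_atoms(self, glycine_atoms, water_atom,
                                             guanidinium_atoms):
        atoms = glycine_atoms + water_atom + guanidinium_atoms
        tm = assign_interaction_types(atoms)
        assert sum(tm.type_counts().values()) == len(atoms)

    def test_orphan_hydrogen_raises(self):
        orphan = AtomRecord(
            id=1, element="H", name="HX", residue_name="GLY",
            residue_number=1, chain="A", position=(99.0, 99.0, 99.0),
        )
        with pytest.raises(TypingError, match="HX"):
            assign_interaction_types([orphan])


def _glygly_heavy():
    """Gly-Gly dipeptide heavy atoms at idealized geometry (with OXT)."""
    coords = {
        ("N", 1): (0.00, 0.00, 0.00),
        ("CA", 1): (1.46, 0.00, 0.00),
        ("C", 1): (2.01, 1.42, 0.00),
        ("O", 1): (1.25, 2.39, 0.00),
        ("N", 2): (3.19, 2.02, 0.00),
        ("CA", 2): (4.61, 1.64, 0.00),
        ("C", 2): (5.16, 3.06, 0.00),
        ("O", 2): (4.40, 4.03, 0.00),
        ("OXT", 2): (6.40, 3.51, 0.00),
    }
    return [
        AtomRecord(id=i + 1, element=name.rstrip("XTA12") or name[0],
                   name=name, residue_name="GLY", residue_number=resnum,
                   chain="A", position=pos)
        for i, ((name, resnum), pos) in enumerate(coords.items())
    ]


class TestRidingHydrogens:
    def test_dipeptide_gets_standard_h_counts(self):
        heavy = _glygly_heavy()
        completed = place_riding_hydrogens(heavy)
        by_parent = {}
        bonds = covalent_bonds(completed)
        keys = [(a.name, a.residue_number) for a in completed]
        for i, j in bonds:
            for h, p in ((i, j), (j, i)):
                if completed[h].element == "H":
                    by_parent.setdefault(keys[p], []).append(keys[h])
        # terminal amine 2, alpha carbons 2 each, amide N 1, acid OH 1,
        # carbonyl C and O none
        assert len(by_parent.get(("N", 1), [])) == 2
        assert len(by_parent.get(("CA", 1), [])) == 2
        assert len(by_parent.get(("N", 2), [])) == 1
        assert len(by_parent.get(("CA", 2), [])) == 2
        assert len(by_parent.get(("OXT", 2), [])) == 1
        for untouched in (("C", 1), ("O", 1), ("C", 2), ("O", 2)):
            assert untouched not in by_parent
        # neutron-normalized bond lengths
        pos = {(a.name, a.residue_number): np.array(a.position)
               for a in completed}
        for hk in by_parent[("CA", 1)]:
            assert np.linalg.norm(pos[hk] - pos[("CA", 1)]) == pytest.approx(
                1.083, abs=1e-6
            )
        for hk in by_parent[("N", 2)]:
            assert np.linalg.norm(pos[hk] - pos[("N", 2)]) == pytest.approx(
                1.009, abs=1e-6
            )
        for hk in by_parent[("OXT", 2)]:
            assert np.linalg.norm(pos[hk] - pos[("OXT", 2)]) == pytest.approx(
                0.967, abs=1e-6
            )

    def test_placed_hydrogens_type_correctly(self):
        tm = assign_interaction_types(place_riding_hydrogens(_glygly_heavy()))
        counts = tm.type_counts()
        assert counts["Hc"] == 4 and counts["Ho/n"] == 4


class TestResidueContacts:
    def _one(self, pos, i=1, resnum=1, chain="A", el="C"):
        return [AtomRecord(id=i, element=el, name=el, residue_name="UNK",
                           residue_number=resnum, chain=chain, position=pos)]

    def test_single_pair_below_cutoff(self):
        got = residue_contacts(self._one((0, 0, 0)), self._one((3, 0, 0), chain="B"))
        assert len(got) == 1
        assert got[0].min_distance == pytest.approx(3.0)

    def test_single_pair_above_cutoff_empty(self):
        got = residue_contacts(
            self._one((0, 0, 0)), self._one((3, 0, 0), chain="B"), cutoff=2.5
        )
        assert got == []

    def test_grid_matches_bruteforce_and_symmetry(self, rng):
        def grid_model(chain, origin):
            atoms = []
            for k in range(9):
                pos = np.array(origin) + [2.1 * (k % 3), 2.1 * (k // 3), 0]
                atoms.append(
                    AtomRecord(id=k + 1, element="C", name="C",
                               residue_name="UNK", residue_number=k + 1,
                               chain=chain, position=tuple(pos))
                )
            return atoms

        a = grid_model("A", (0, 0, 0))
        b = grid_model("B", (1.3, 0.7, 2.2))
        got = residue_contacts(a, b, cutoff=4.0)
        # brute force over all residue pairs
        expected = set()
        for x in a:
            for y in b:
                d = np.linalg.norm(np.array(x.position) - np.array(y.position))
                if d < 4.0:
                    expected.add((x.residue_key, y.residue_key))
        assert {(c.residue_a, c.residue_b) for c in got} == expected
        swapped = residue_contacts(b, a, cutoff=4.0)
        assert {(c.residue_b, c.residue_a) for c in swapped} == expected

    def test_bad_cutoff(self):
        with pytest.raises(ValueError):
            residue_contacts(self._one((0, 0, 0)), self._one((1, 0, 0)), cutoff=0)

    def test_hbond_flag_uses_donor_acceptor_distance(self):
        a = self._one((0, 0, 0), el="O")
        b = self._one((2.8, 0, 0), chain="B", el="N")
        assert residue_contacts(a, b)[0].is_hbond
        c = self._one((2.8, 0, 0), chain="B", el="C")
        assert not residue_contacts(a, c)[0].is_hbond


class TestIsoelectricPoint:
    def test_termini_only_closed_form(self):
        # two-group system: pI is the pKa midpoint
        got = isoelectric_point("GG", pka_set={"Nterm": 9.6, "Cterm": 2.34})
        assert got == pytest.approx((9.6 + 2.34) / 2, abs=0.01)

    def test_composition_only(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        assert isoelectric_point(seq) == pytest.approx(
            isoelectric_point(seq[::-1]), abs=1e-6
        )

    def test_basic_vs_acidic_residue(self):
        assert isoelectric_point("K") > isoelectric_point("D")

    @pytest.mark.parametrize("seq", ["G", "KDKPPR", "ACDEFGHIKLMNPQRSTVWY"])
    def test_bisection_converges_and_monotone_edits(self, seq):
        pi = isoelectric_point(seq)
        assert abs(net_charge(seq, pi)) < 1e-4
        assert isoelectric_point(seq + "K") >= pi - 1e-6
        assert isoelectric_point(seq + "D") <= pi + 1e-6

    def test_unknown_letter(self):
        with pytest.raises(ValueError):
            isoelectric_point("GXG")
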