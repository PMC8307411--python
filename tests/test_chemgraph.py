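"""Connection-table parsing and 2D stereo perception."""

import math
import random

import pytest
from hypothesis import given, strategies as st

from molharmony.chemgraph import (Atom, Bond, CT_CIS, CT_NONE, CT_TRANS,
                                  Molecule, MolfileParseError, PARITY_CCW,
                                  PARITY_CW, PARITY_NONE, PARITY_UNKNOWN,
                                  StructureError, WEDGE_UP,
                                  assign_atom_parity, classify_double_bond,
                                  parse_kcf, parse_molfile, write_molfile)
from molharmony.fixtures import gen_molecule
from molharmony.substructure import graph_isomorphism

METHANE_BLOCK = """methane


  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
"""

ETHANOL_BLOCK = """ethanol


  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.8660    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
  2  3  1  0  0  0  0
M  END
"""

RGROUP_BLOCK = """generic


  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    0.0000    0.0000 R#  0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
M  END
"""

KCF_BLOCK = """ENTRY       CTEST  Compound
ATOM        3
            1   C1a C    0.0  0.0
            2   C1b C    1.0  0.0
            3   O1a O    1.5  0.87
BOND        2
            1     1   2 1
            2     2   3 1
///
"""


class TestParseMolfile:
    def test_minimal_single_atom(self):
        mol = parse_molfile(METHANE_BLOCK)
        assert len(mol.atoms) == 1
        assert mol.formula() == {"C": 1}

    def test_ethanol_adjacency(self):
        mol = parse_molfile(ETHANOL_BLOCK)
        assert [a.element for a in mol.atoms] == ["C", "C", "O"]
        assert sorted(mol.neighbors(2)) == [1, 3]
        assert mol.neighbors(3) == [2]

    def test_r_group_symbol_normalized(self):
        mol = parse_molfile(RGROUP_BLOCK)
        assert mol.atom(2).is_r and mol.atom(2).element == "R"
        assert mol.formula() == {"C": 1, "R": 1}

    def test_malformed_counts_line_names_it(self):
        bad = METHANE_BLOCK.replace("  1  0", "  X  0")
        with pytest.raises(MolfileParseError, match="counts line"):
            parse_molfile(bad)

    def test_bond_to_missing_atom(self):
        bad = ETHANOL_BLOCK.replace("  2  3  1", "  2  9  1")
        with pytest.raises((StructureError, MolfileParseError)):
            parse_molfile(bad)

    def test_m_chg_overrides_atom_line(self):
        block = ETHANOL_BLOCK.replace("M  END", "M  CHG  1   3  -1\nM  END")
        mol = parse_molfile(block)
        assert mol.atom(3).charge == -1
        assert mol.atom(1).charge == 0

    @given(st.integers(0, 500))
    def test_roundtrip_preserves_graph(self, seed):
        mol = gen_molecule(random.Random(seed), 3 + seed % 8, id=f"m{seed}")
        back = parse_molfile(write_molfile(mol))
        assert back.formula() == mol.formula()
        match = graph_isomorphism(mol, back)
        assert match is not None

    def test_roundtrip_preserves_charge_and_order(self):
        mol = Molecule("chg", [Atom(1, "N", charge=1), Atom(2, "O", charge=-1)],
                       [Bond(1, 2, 2)])
        back = parse_molfile(write_molfile(mol))
        assert back.atom(1).charge == 1
        assert back.atom(2).charge == -1
        assert back.bonds[0].order == 2


class TestParseKCF:
    def test_atom_types_and_elements(self):
        mol = parse_kcf(KCF_BLOCK)
        assert mol.id == "CTEST"
        assert mol.atom(1).kegg_type == "C1a"
        assert mol.atom(3).element == "O"

    def test_matches_equivalent_molfile(self):
        kcf = parse_kcf(KCF_BLOCK)
        mdl = parse_molfile(ETHANOL_BLOCK)
        assert graph_isomorphism(kcf, mdl) is not None

    def test_unknown_type_kept_verbatim(self, caplog):
        block = KCF_BLOCK.replace("O1a O", "Qq9 O")
        mol = parse_kcf(block)
        assert mol.atom(3).kegg_type == "Qq9"

    def test_missing_atom_section(self):
        with pytest.raises(MolfileParseError, match="ATOM"):
            parse_kcf("ENTRY  X\nBOND  0\n///\n")


def _chiral(wedge, mirror=False):
    """Bromochlorofluoromethane-like center drawn with one wedge."""
    sx = -1.0 if mirror else 1.0
    atoms = [Atom(1, "C", x=0, y=0), Atom(2, "F", x=sx * 1.0, y=0.0),
             Atom(3, "Cl", x=sx * -0.5, y=0.87),
             Atom(4, "Br", x=sx * -0.5, y=-0.87)]
    bonds = [Bond(1, 2, 1, wedge=wedge), Bond(1, 3, 1), Bond(1, 4, 1)]
    return Molecule("chiral", atoms, bonds)


class TestAtomParity:
    def test_no_wedges_gives_none_or_unknown(self):
        mol = assign_atom_parity(_chiral("none"))
        assert mol.atom(1).parity == PARITY_UNKNOWN       # candidate, no wedge
        assert mol.atom(2).parity == PARITY_NONE          # not a candidate

    def test_wedge_direction_sets_parity(self):
        up = assign_atom_parity(_chiral(WEDGE_UP))
        down = assign_atom_parity(_chiral("down"))
        assert up.atom(1).parity in (PARITY_CW, PARITY_CCW)
        assert down.atom(1).parity != up.atom(1).parity

    def test_reflection_flips_parity(self):
        plain = assign_atom_parity(_chiral(WEDGE_UP))
        mirrored = assign_atom_parity(_chiral(WEDGE_UP, mirror=True))
        assert {plain.atom(1).parity, mirrored.atom(1).parity} == \
            {PARITY_CW, PARITY_CCW}

    def test_misplaced_wedge_warns_and_unknown(self, caplog):
        mol = _chiral("none")
        bonds = [Bond(1, 2, 1), Bond(3, 1, 1, wedge=WEDGE_UP),  # narrow at Cl
                 Bond(1, 4, 1)]
        mol = Molecule("chiral", mol.atoms, bonds)
        with caplog.at_level("WARNING"):
            assign_atom_parity(mol)
        assert mol.atom(1).parity == PARITY_UNKNOWN
        assert "narrow end" in caplog.text


def _butene(same_side=True, rotate=0.0, mirror=False):
    """2-butene: CH3-CH=CH-CH3 with the methyls drawn cis or trans."""
    y4 = 1.0 if same_side else -1.0
    pts = [(-1.0, 1.0), (0.0, 0.0), (1.0, 0.0), (2.0, y4)]
    c, s = math.cos(rotate), math.sin(rotate)
    sx = -1.0 if mirror else 1.0
    atoms = []
    for i, (x, y) in enumerate(pts, 1):
        rx, ry = c * x - s * y, s * x + c * y
        atoms.append(Atom(i, "C", x=sx * rx, y=ry))
    bonds = [Bond(1, 2, 1), Bond(2, 3, 2), Bond(3, 4, 1)]
    return Molecule("butene", atoms, bonds)


class TestDoubleBondStereo:
    def test_terminal_alkene_is_none(self):
        mol = Molecule("ethene", [Atom(1, "C", x=0, y=0), Atom(2, "C", x=1, y=0),
                                  Atom(3, "C", x=2, y=1)],
                       [Bond(1, 2, 2), Bond(2, 3, 1)])
        assert classify_double_bond(mol, mol.bonds[0]) == CT_NONE

    def test_cis_and_trans_butene(self):
        cis = _butene(same_side=True)
        trans = _butene(same_side=False)
        assert classify_double_bond(cis, cis.bonds[1]) == CT_CIS
        assert classify_double_bond(trans, trans.bonds[1]) == CT_TRANS

    @pytest.mark.parametrize("angle", [0.3, 1.1, 2.5, 4.0])
    def test_rigid_rotation_invariance(self, angle):
        mol = _butene(same_side=True, rotate=angle)
        assert classify_double_bond(mol, mol.bonds[1]) == CT_CIS

    def test_reflection_preserves_label(self):
        # cis/trans is not chiral: mirroring the drawing keeps the label
        mol = _butene(same_side=True, mirror=True)
        assert classify_double_bond(mol, mol.bonds[1]) == CT_CIS
        tr = _butene(same_side=False, mirror=True)
        assert classify_double_bond(tr, tr.bonds[1]) == CT_TRANS

    def test_hetero_double_bond_is_labeled(self):
        # C=N with one substituent on each heavy atom: not skipped
        mol = Molecule("imine", [Atom(1, "C", x=-1, y=1), Atom(2, "C", x=0, y=0),
                                 Atom(3, "N", x=1, y=0), Atom(4, "C", x=2, y=1)],
                       [Bond(1, 2, 1), Bond(2, 3, 2), Bond(3, 4, 1)])
        assert classify_double_bond(mol, mol.bonds[1]) in (CT_CIS, CT_TRANS)
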