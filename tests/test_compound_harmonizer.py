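"""Compound pair detection, classification, and structural validators."""

import random

import pytest

from helpers import butane, ethanol, isobutane, r_ch2_oh
from molharmony.chemgraph import (Atom, Bond, Molecule, PARITY_CCW, PARITY_CW)
from molharmony.compound_harmonizer import (DIR_A_TO_B, DIR_B_TO_A,
                                            EQUIVALENCE, GENERIC_SPECIFIC,
                                            LOOSE_REL, RelationshipType,
                                            classify_chemical_details,
                                            detect_pairs_by_identifier,
                                            validate_generic_pair,
                                            validate_ring_chain_pair,
                                            validate_tautomer_pair)
from molharmony.fixtures import gen_molecule, gen_nonpair, gen_pair
from molharmony.substructure import AtomMatch, graph_isomorphism


def _chiral(id, parity1=None, parity4=None):
    m = Molecule(id, [Atom(1, "C"), Atom(2, "N"), Atom(3, "O"), Atom(4, "C"),
                      Atom(5, "S")],
                 [Bond(1, 2, 1), Bond(1, 3, 1), Bond(1, 4, 1), Bond(4, 5, 1)])
    if parity1:
        m.atom(1).parity = parity1
    if parity4:
        m.atom(4).parity = parity4
    return m


def _identity_match(mol):
    return AtomMatch.from_dict({i: i for i in mol.heavy_indices()})


class TestClassifyChemicalDetails:
    def test_self_pair_is_equivalence(self):
        for builder_seed in range(5):
            m = gen_molecule(random.Random(builder_seed), 6)
            rel = classify_chemical_details(m, m, _identity_match(m))
            assert rel == RelationshipType(EQUIVALENCE)

    def test_subset_gives_directed_generic_specific(self):
        bare = _chiral("bare")
        rich = _chiral("rich", parity1=PARITY_CW)
        rel = classify_chemical_details(bare, rich, _identity_match(bare))
        assert rel == RelationshipType(GENERIC_SPECIFIC, DIR_A_TO_B)

    def test_direction_reverses_on_swap(self):
        bare = _chiral("bare")
        rich = _chiral("rich", parity1=PARITY_CW)
        fwd = classify_chemical_details(bare, rich, _identity_match(bare))
        rev = classify_chemical_details(rich, bare, _identity_match(bare))
        assert fwd.direction == DIR_A_TO_B
        assert rev.direction == DIR_B_TO_A
        assert rev == fwd.swapped()

    def test_conflicting_parity_is_loose(self):
        # mirrors the case of the same compound annotated with opposite
        # stereo descriptors in the two databases
        d = _chiral("d", parity1=PARITY_CW)
        l = _chiral("l", parity1=PARITY_CCW)
        rel = classify_chemical_details(d, l, _identity_match(d))
        assert rel == RelationshipType(LOOSE_REL)

    def test_incomparable_detail_sets_are_loose(self):
        a = _chiral("a", parity1=PARITY_CW)
        b = _chiral("b", parity4=PARITY_CW)
        rel = classify_chemical_details(a, b, _identity_match(a))
        assert rel.kind == LOOSE_REL

    def test_partial_mapping_rejected(self):
        m = ethanol()
        with pytest.raises(ValueError, match="bijection"):
            classify_chemical_details(m, m, AtomMatch.from_dict({1: 1}))


class TestDetectPairsByIdentifier:
    def test_shared_structure_gives_equivalence(self):
        pairs = detect_pairs_by_identifier([ethanol("a1")], [ethanol("b1")])
        assert len(pairs) == 1
        assert pairs[0].relationship.kind == EQUIVALENCE
        assert pairs[0].origin == "identifier"

    def test_stereo_differing_pair_classified_by_details(self):
        a = _chiral("a", parity1=PARITY_CW)
        b = _chiral("b", parity1=PARITY_CCW)
        pairs = detect_pairs_by_identifier([a], [b])
        assert len(pairs) == 1
        assert pairs[0].relationship.kind in (GENERIC_SPECIFIC, LOOSE_REL)

    def test_disjoint_databases_empty(self):
        assert detect_pairs_by_identifier([ethanol()], [butane()]) == []

    def test_one_compound_may_pair_multiply(self):
        a = [ethanol("a1")]
        b = [ethanol("b1"), ethanol("b2")]
        assert len(detect_pairs_by_identifier(a, b)) == 2


class TestValidateGenericPair:
    def test_methyl_instantiates_r(self):
        # R-CH2-OH vs CH3-CH2-OH: the methyl specifies the R group
        b = Molecule("etoh", [Atom(1, "C"), Atom(2, "C"), Atom(3, "O")],
                     [Bond(1, 2, 1), Bond(2, 3, 1)])
        pair = validate_generic_pair(r_ch2_oh(), b)
        assert pair is not None
        assert pair.relationship == RelationshipType(GENERIC_SPECIFIC, DIR_A_TO_B)
        assert pair.origin == "generic_validation"

    def test_branch_without_r_position_rejected(self):
        # dimethyl ether: the extra methyl hangs off the oxygen, which
        # carries no R in the pattern
        b = Molecule("dme", [Atom(1, "C"), Atom(2, "O"), Atom(3, "C")],
                     [Bond(1, 2, 1), Bond(2, 3, 1)])
        assert validate_generic_pair(r_ch2_oh(), b) is None

    def test_both_generic_with_r_terminated_branch(self):
        # the more specific side's branch may itself end in an R group
        a = r_ch2_oh("a")
        batoms = [Atom(1, "C"), Atom(2, "C"), Atom(3, "O"), Atom(4, "R", is_r=True)]
        b = Molecule("b", batoms, [Bond(1, 2, 1), Bond(2, 3, 1), Bond(1, 4, 1)])
        pair = validate_generic_pair(a, b)
        assert pair is not None
        assert pair.relationship.kind == GENERIC_SPECIFIC

    def test_unconsumed_r_rejected(self):
        # same heavy skeleton, nothing to absorb the R: R=H is disallowed
        b = Molecule("co", [Atom(1, "C"), Atom(2, "O")], [Bond(1, 2, 1)])
        assert validate_generic_pair(r_ch2_oh(), b) is None

    def test_requires_r_in_first_argument(self):
        with pytest.raises(ValueError, match="R group"):
            validate_generic_pair(ethanol(), butane())

    def test_generated_pairs_validate_with_direction(self, rng):
        for seed in range(25):
            a, b, exp = gen_pair(random.Random(seed), "generic_specific")
            pair = validate_generic_pair(a, b)
            assert pair is not None
            assert pair.relationship == exp.relationship
            # fewer concrete atoms on the generic side
            assert len(a.heavy_indices(include_r=False)) <= len(b.heavy_indices())


class TestValidateTautomerPair:
    def test_keto_enol_accepted(self):
        keto = Molecule("keto", [Atom(1, "C"), Atom(2, "C"), Atom(3, "O")],
                        [Bond(1, 2, 1), Bond(2, 3, 2)])
        enol = Molecule("enol", [Atom(1, "C"), Atom(2, "C"), Atom(3, "O")],
                        [Bond(1, 2, 2), Bond(2, 3, 1)])
        pair = validate_tautomer_pair(keto, enol)
        assert pair is not None
        assert pair.origin == "tautomer"

    def test_identical_molecules_equivalent(self):
        pair = validate_tautomer_pair(ethanol("a"), ethanol("b"))
        assert pair is not None
        assert pair.relationship.kind == EQUIVALENCE

    def test_different_skeleton_rejected(self):
        assert validate_tautomer_pair(butane(), isobutane()) is None

    def test_formula_mismatch_raises(self):
        with pytest.raises(ValueError, match="formula"):
            validate_tautomer_pair(ethanol(), butane())

    def test_generated_pairs_accepted_nonpairs_rejected(self):
        for seed in range(25):
            a, b, exp = gen_pair(random.Random(seed), "tautomer")
            pair = validate_tautomer_pair(a, b)
            assert pair is not None and pair.relationship == exp.relationship
        for seed in range(25):
            for kind in ("skeleton", "illegal_shift"):
                a, b = gen_nonpair(random.Random(seed), kind)
                assert validate_tautomer_pair(a, b) is None


class TestValidateRingChainPair:
    def test_aldose_ring_accepted(self):
        for seed in range(20):
            circ, lin, exp = gen_pair(random.Random(seed), "ring_chain")
            pair = validate_ring_chain_pair(circ, lin)
            assert pair is not None
            assert pair.relationship == exp.relationship
            assert pair.origin == "ring_chain"

    def test_acyclic_pair_has_no_candidate(self):
        assert validate_ring_chain_pair(butane("a"), butane("b")) is None

    def test_ring_without_anomeric_hydroxyl_rejected(self):
        for seed in range(10):
            ring, chain = gen_nonpair(random.Random(seed), "missing_hemiacetal")
            assert validate_ring_chain_pair(ring, chain) is None

    def test_transform_conserves_atoms(self):
        circ, lin, _ = gen_pair(random.Random(3), "ring_chain")
        assert circ.formula() == lin.formula()


class TestRelationshipInvariants:
    def test_trichotomy_on_generated_pairs(self):
        seen = set()
        for seed in range(20):
            for cat in ("equivalence", "loose", "generic_specific",
                        "tautomer", "ring_chain"):
                _, _, exp = gen_pair(random.Random(seed), cat)
                assert exp.relationship.kind in (EQUIVALENCE,
                                                 GENERIC_SPECIFIC, LOOSE_REL)
                seen.add(exp.relationship.kind)
        assert seen == {EQUIVALENCE, GENERIC_SPECIFIC, LOOSE_REL}

    def test_equivalence_carries_no_direction(self):
        with pytest.raises(ValueError):
            RelationshipType(EQUIVALENCE, DIR_A_TO_B)
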