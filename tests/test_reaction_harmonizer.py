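"""EC parsing, reaction pairing, the iterative loop, and quality checks."""

import random

import pytest

from helpers import ethanol
from molharmony.chemgraph import Atom, Bond, Molecule
from molharmony.compound_harmonizer import (CompoundPair, DIR_A_TO_B,
                                            DIR_B_TO_A, EQUIVALENCE,
                                            GENERIC_SPECIFIC, LOOSE_REL,
                                            RelationshipType)
from molharmony.fixtures import FixtureSpec, gen_databases
from molharmony.reaction_harmonizer import (EC_FULL, EC_THREE_LEVEL,
                                            ECParseError, Reaction,
                                            classify_reaction_pair,
                                            harmonization_loop,
                                            pair_reactions, parse_ec,
                                            quality_check_reaction)


def _pair(ida, idb, kind, direction="none"):
    return CompoundPair(ida, idb, RelationshipType(kind, direction))


class TestParseEC:
    def test_four_level(self):
        ec = parse_ec("1.1.1.168")
        assert ec.levels == (1, 1, 1, 168) and ec.specified_depth == 4

    def test_dash_lowers_depth(self):
        assert parse_ec("2.7.1.-").specified_depth == 3

    @pytest.mark.parametrize("bad", ["abc", "1.2", "1.-.3.4", "1.2.-.-", "x.y.z.w"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ECParseError):
            parse_ec(bad)


def _rx(rid, ec, subs, prods):
    return Reaction(rid, [parse_ec(ec)], [(c, 1) for c in subs],
                    [(c, 1) for c in prods])


BASE_PAIRS = [_pair("a1", "b1", EQUIVALENCE), _pair("a2", "b2", EQUIVALENCE)]


class TestPairReactions:
    def test_equivalently_paired_single_step(self):
        ra = _rx("RA", "1.1.1.1", ["a1"], ["a2"])
        rb = _rx("RB", "1.1.1.1", ["b1"], ["b2"])
        out = pair_reactions([ra], [rb], BASE_PAIRS)
        assert len(out) == 1
        assert out[0].relationship.kind == EQUIVALENCE
        assert out[0].ec_tier == EC_FULL

    def test_extra_proton_still_pairs(self):
        ra = _rx("RA", "1.1.1.1", ["a1"], ["a2", "H+"])
        rb = _rx("RB", "1.1.1.1", ["b1"], ["b2"])
        assert len(pair_reactions([ra], [rb], BASE_PAIRS)) == 1

    def test_orientation_flip_tried(self):
        ra = _rx("RA", "1.1.1.1", ["a1"], ["a2"])
        rb = _rx("RB", "1.1.1.1", ["b2"], ["b1"])
        assert len(pair_reactions([ra], [rb], BASE_PAIRS)) == 1

    def test_three_level_tier_only_when_requested(self):
        ra = _rx("RA", "1.1.1.5", ["a1"], ["a2"])
        rb = _rx("RB", "1.1.1.9", ["b1"], ["b2"])
        assert pair_reactions([ra], [rb], BASE_PAIRS, ec_mode=EC_FULL) == []
        out = pair_reactions([ra], [rb], BASE_PAIRS, ec_mode=EC_THREE_LEVEL)
        assert len(out) == 1 and out[0].ec_tier == EC_THREE_LEVEL

    def test_unpaired_compound_blocks(self):
        ra = _rx("RA", "1.1.1.1", ["a1"], ["aX"])
        rb = _rx("RB", "1.1.1.1", ["b1"], ["b2"])
        assert pair_reactions([ra], [rb], BASE_PAIRS) == []

    def test_symmetric_under_database_swap(self):
        ra = _rx("RA", "1.1.1.1", ["a1"], ["a2"])
        rb = _rx("RB", "1.1.1.1", ["b1"], ["b2"])
        fwd = pair_reactions([ra], [rb], BASE_PAIRS)
        swapped = [CompoundPair(p.id_b, p.id_a, p.relationship.swapped())
                   for p in BASE_PAIRS]
        rev = pair_reactions([rb], [ra], swapped)
        assert len(fwd) == len(rev) == 1
        assert fwd[0].relationship.kind == rev[0].relationship.kind


class TestClassifyReactionPair:
    def test_all_equivalence(self):
        rel = classify_reaction_pair([_pair("a", "b", EQUIVALENCE),
                                      _pair("c", "d", EQUIVALENCE)])
        assert rel.kind == EQUIVALENCE

    def test_consistent_generic_specific(self):
        rel = classify_reaction_pair([
            _pair("a", "b", EQUIVALENCE),
            _pair("c", "d", GENERIC_SPECIFIC, DIR_A_TO_B)])
        assert rel == RelationshipType(GENERIC_SPECIFIC, DIR_A_TO_B)

    def test_inconsistent_directions_loose(self):
        rel = classify_reaction_pair([
            _pair("a", "b", GENERIC_SPECIFIC, DIR_A_TO_B),
            _pair("c", "d", GENERIC_SPECIFIC, DIR_B_TO_A)])
        assert rel.kind == LOOSE_REL

    def test_loose_pair_dominates(self):
        for extra in ([], [_pair("e", "f", GENERIC_SPECIFIC, DIR_A_TO_B)]):
            rel = classify_reaction_pair(
                [_pair("a", "b", EQUIVALENCE), _pair("c", "d", LOOSE_REL)] + extra)
            assert rel.kind == LOOSE_REL


@pytest.fixture(scope="module")
def result_and_dbs():
    dbs = gen_databases(FixtureSpec(seed=11))
    res = harmonization_loop(dbs.compounds_a, dbs.compounds_b,
                             dbs.reactions_a, dbs.reactions_b)
    return res, dbs


class TestHarmonizationLoop:

    def test_recovers_exactly_planted_compound_pairs(self, result_and_dbs):
        res, dbs = result_and_dbs
        got = {(p.id_a, p.id_b): (p.relationship.kind, p.relationship.direction,
                                  p.origin) for p in res.compound_pairs}
        exp = {(p.id_a, p.id_b): (p.relationship.kind, p.relationship.direction,
                                  p.origin) for p in dbs.expected_compound_pairs}
        assert got == exp

    def test_recovers_planted_reaction_relationships(self, result_and_dbs):
        res, dbs = result_and_dbs
        got = {(p.id_a, p.id_b): p.relationship.kind for p in res.reaction_pairs}
        exp = {(a, b): k for a, b, k in dbs.expected_reaction_pairs}
        assert got == exp

    def test_ring_chain_found_after_first_round(self, result_and_dbs):
        res, dbs = result_and_dbs
        assert len(res.rounds) >= 2
        assert not set(dbs.ring_chain_keys) & set(res.rounds[0])
        assert set(dbs.ring_chain_keys) <= set(res.rounds[1])

    def test_empty_databases(self):
        res = harmonization_loop({}, {}, [], [])
        assert res.compound_pairs == [] and res.reaction_pairs == []

    def test_no_shared_ecs_gives_identifier_pairs_only(self):
        dbs = gen_databases(FixtureSpec(seed=5))
        rx_a = [Reaction(r.id, [parse_ec("6.6.1.1")], r.substrates, r.products)
                for r in dbs.reactions_a]
        rx_b = [Reaction(r.id, [parse_ec("6.6.2.1")], r.substrates, r.products)
                for r in dbs.reactions_b]
        res = harmonization_loop(dbs.compounds_a, dbs.compounds_b, rx_a, rx_b)
        assert res.reaction_pairs == []
        assert all(p.origin == "identifier" for p in res.compound_pairs)

    def test_pair_list_monotone_over_rounds(self, result_and_dbs):
        res, _ = result_and_dbs
        keys = [set(r) for r in res.rounds]
        for i, j in zip(keys, keys[1:]):
            assert not i & j          # rounds add strictly new pairs


def _mol(id, elements, bonds):
    return Molecule(id, [Atom(i + 1, el) for i, el in enumerate(elements)],
                    [Bond(a, b, o) for a, b, o in bonds])


class TestQualityCheck:
    @pytest.fixture
    def compounds(self):
        return {"S": _mol("S", ["C", "C", "O"], [(1, 2, 1), (2, 3, 1)]),
                "P": _mol("P", ["C", "C", "O"], [(1, 2, 1), (2, 3, 2)]),
                "P2": _mol("P2", ["C", "C"], [(1, 2, 1)])}

    def test_balanced_fully_mapped_complete(self, compounds):
        r = Reaction("R1", [parse_ec("1.1.1.1")], [("S", 1)], [("P", 1)],
                     mapping=[(("S", i), ("P", i)) for i in (1, 2, 3)])
        assert quality_check_reaction(r, compounds) == "complete"

    def test_atom_imbalance_flagged(self, compounds):
        r = Reaction("R2", [parse_ec("1.1.1.1")], [("S", 1)], [("P2", 1)],
                     mapping=[(("S", 1), ("P2", 1))])
        assert quality_check_reaction(r, compounds) == "incomplete_reaction"

    def test_element_mismatch_flagged(self, compounds):
        r = Reaction("R3", [parse_ec("1.1.1.1")], [("S", 1)], [("P", 1)],
                     mapping=[(("S", 1), ("P", 1)), (("S", 2), ("P", 3)),
                              (("S", 3), ("P", 2))])
        assert quality_check_reaction(r, compounds) == "incorrect_mapping"

    def test_partial_mapping_flagged(self, compounds):
        r = Reaction("R4", [parse_ec("1.1.1.1")], [("S", 1)], [("P", 1)],
                     mapping=[(("S", 1), ("P", 1))])
        assert quality_check_reaction(r, compounds) == "incomplete_mapping"

    def test_stoichiometry_weighting(self, compounds):
        two_to_one = Reaction("R5", [parse_ec("1.1.1.1")],
                              [("P2", 1)], [("P2", 2)], mapping=None)
        assert quality_check_reaction(two_to_one, compounds) == \
            "incomplete_reaction"
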