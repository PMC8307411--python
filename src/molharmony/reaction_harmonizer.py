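"""Reaction pairing across databases and the iterative harmonization loop.

Two reactions pair when they share an EC number (exactly, or on the first
three levels in the relaxed tier) and their participant multisets admit a
perfect matching under the compound-pair relation, ignoring designated
extra entities such as H+.  Reaction pairs inherit a hierarchical
relationship from the compound pairs they use: all-equivalence pairs are
equivalent; equivalences plus generic-specific pairs pointing consistently
the same way are generic-specific; anything looser, or mixed directions,
is loose.

The harmonization loop alternates compound and reaction pairing: near-miss
reaction pairs (shared EC, at least one matched compound, some unmatched)
propose new compound candidates — R-group compounds against every partner
participant, and same-formula leftovers for tautomer and ring/chain
validation — until no new compound pair appears.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .chemgraph import Molecule
from .compound_harmonizer import (CompoundPair, DIR_A_TO_B, DIR_B_TO_A,
                                  DIR_NONE, EQUIVALENCE, GENERIC_SPECIFIC,
                                  LOOSE_REL, RelationshipType,
                                  detect_pairs_by_identifier,
                                  relationship_rank, validate_generic_pair,
                                  validate_ring_chain_pair,
                                  validate_tautomer_pair)

logger = logging.getLogger(__name__)

EC_FULL = "full"
EC_THREE_LEVEL = "three_level"

QC_COMPLETE = "complete"
QC_INCOMPLETE_REACTION = "incomplete_reaction"
QC_INCORRECT_MAPPING = "incorrect_mapping"
QC_INCOMPLETE_MAPPING = "incomplete_mapping"

#: compound ids treated as ignorable extra entities during pairing
DEFAULT_IGNORABLE = frozenset({"H+", "h+", "PROTON", "Hplus"})


class ECParseError(ValueError):
    pass


@dataclass(frozen=True)
class ECNumber:
    levels: tuple[int, ...]
    specified_depth: int

    def __str__(self) -> str:
        parts = [str(v) for v in self.levels[:self.specified_depth]]
        parts += ["-"] * (4 - self.specified_depth)
        return ".".join(parts)


def parse_ec(text: str) -> ECNumber:
    """Parse ``"1.1.1.168"`` (depth 4) or ``"2.7.1.-"`` (depth 3)."""
    parts = text.strip().split(".")
    if len(parts) not in (3, 4):
        raise ECParseError(f"not an EC number: {text!r}")
    levels = []
    depth = 0
    seen_dash = False
    for p in parts:
        if p == "-":
            seen_dash = True
            continue
        if seen_dash or not re.fullmatch(r"\d+", p):
            raise ECParseError(f"not an EC number: {text!r}")
        levels.append(int(p))
        depth += 1
    if depth < 3:
        raise ECParseError(
            f"EC number must specify at least three levels: {text!r}")
    return ECNumber(tuple(levels), depth)


def ec_match(e1: ECNumber, e2: ECNumber, mode: str) -> bool:
    if mode == EC_FULL:
        return (e1.specified_depth == 4 and e2.specified_depth == 4
                and e1.levels == e2.levels)
    return e1.levels[:3] == e2.levels[:3]


@dataclass
class Reaction:
    id: str
    ecs: list[ECNumber]
    substrates: list[tuple[str, int]]      # (compound id, stoichiometry)
    products: list[tuple[str, int]]
    mapping: list[tuple[tuple[str, int], tuple[str, int]]] | None = None
    is_generic: bool = False

    def participants(self) -> list[str]:
        return [cid for cid, _ in self.substrates + self.products]

    def has_complete_ec(self) -> bool:
        return any(ec.specified_depth >= 3 for ec in self.ecs)


def mark_generic(reactions: list[Reaction], compounds: dict[str, Molecule]) -> None:
    """Set ``is_generic`` from the participant structures."""
    for r in reactions:
        r.is_generic = any(
            cid in compounds and any(a.is_r for a in compounds[cid].atoms)
            for cid in r.participants())


@dataclass(frozen=True)
class ReactionPair:
    id_a: str
    id_b: str
    relationship: RelationshipType
    ec_tier: str
    compound_pairs_used: tuple[CompoundPair, ...]


class PairIndex:
    """Best-known compound pair per cross-database id pair."""

    def __init__(self, pairs=()):
        self._pairs: dict[tuple[str, str], CompoundPair] = {}
        for p in pairs:
            self.add(p)

    def add(self, pair: CompoundPair) -> bool:
        key = (pair.id_a, pair.id_b)
        cur = self._pairs.get(key)
        if cur is None or (relationship_rank(pair.relationship)
                           < relationship_rank(cur.relationship)):
            self._pairs[key] = pair
            return cur is None
        return False

    def get(self, id_a: str, id_b: str) -> CompoundPair | None:
        return self._pairs.get((id_a, id_b))

    def pairs(self) -> list[CompoundPair]:
        return [self._pairs[k] for k in sorted(self._pairs)]

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, key) -> bool:
        return key in self._pairs


def _expand(side: list[tuple[str, int]], ignorable) -> list[str]:
    out = []
    for cid, stoich in side:
        if cid in ignorable:
            continue
        out.extend([cid] * int(stoich))
    return out


_WEIGHT = {EQUIVALENCE: 3, GENERIC_SPECIFIC: 2, LOOSE_REL: 1}


def _match_side(ids_a: list[str], ids_b: list[str], index: PairIndex,
                require_perfect: bool):
    """Match two participant multisets through the compound-pair relation.

    Returns ``(used_pairs, unmatched_a, unmatched_b)`` of the maximum
    matching that prefers stronger relationships, or ``None`` when a
    perfect matching is required but impossible.
    """
    if not ids_a and not ids_b:
        return [], [], []
    if require_perfect and len(ids_a) != len(ids_b):
        return None
    n, m = len(ids_a), len(ids_b)
    size = max(n, m)
    NEG = -1000.0
    w = np.full((size, size), NEG)
    for i, ca in enumerate(ids_a):
        for j, cb in enumerate(ids_b):
            p = index.get(ca, cb)
            if p is not None:
                w[i, j] = _WEIGHT[p.relationship.kind]
    rows, cols = linear_sum_assignment(-w)
    used, matched_a, matched_b = [], set(), set()
    for i, j in zip(rows, cols):
        if i < n and j < m and w[i, j] > NEG:
            used.append(index.get(ids_a[i], ids_b[j]))
            matched_a.add(i)
            matched_b.add(j)
    unmatched_a = [ids_a[i] for i in range(n) if i not in matched_a]
    unmatched_b = [ids_b[j] for j in range(m) if j not in matched_b]
    if require_perfect and (unmatched_a or unmatched_b):
        return None
    return used, unmatched_a, unmatched_b


def classify_reaction_pair(used: list[CompoundPair]) -> RelationshipType:
    """Hierarchical relationship of a reaction pair from its compound pairs."""
    if not used:
        raise ValueError("classify_reaction_pair requires at least one pair")
    kinds = {p.relationship.kind for p in used}
    if LOOSE_REL in kinds:
        return RelationshipType(LOOSE_REL)
    if kinds == {EQUIVALENCE}:
        return RelationshipType(EQUIVALENCE)
    dirs = {p.relationship.direction for p in used
            if p.relationship.kind == GENERIC_SPECIFIC}
    if len(dirs) == 1:
        return RelationshipType(GENERIC_SPECIFIC, next(iter(dirs)))
    return RelationshipType(LOOSE_REL)


def _ec_tier(ra: Reaction, rb: Reaction, ec_mode: str) -> str | None:
    if any(ec_match(ea, eb, EC_FULL) for ea in ra.ecs for eb in rb.ecs):
        return EC_FULL
    if ec_mode == EC_THREE_LEVEL and any(
            ec_match(ea, eb, EC_THREE_LEVEL) for ea in ra.ecs for eb in rb.ecs):
        return EC_THREE_LEVEL
    return None


def _try_pair(ra: Reaction, rb: Reaction, index: PairIndex, tier: str,
              ignorable) -> ReactionPair | None:
    best = None
    subs_a = _expand(ra.substrates, ignorable)
    prods_a = _expand(ra.products, ignorable)
    for side1, side2 in ((rb.substrates, rb.products),
                         (rb.products, rb.substrates)):
        res1 = _match_side(subs_a, _expand(side1, ignorable), index, True)
        res2 = _match_side(prods_a, _expand(side2, ignorable), index, True)
        if res1 is None or res2 is None:
            continue
        used = res1[0] + res2[0]
        if not used:
            continue
        rel = classify_reaction_pair(used)
        key = {p for p in used}
        pair = ReactionPair(ra.id, rb.id, rel, tier,
                            tuple(sorted(key, key=lambda p: (p.id_a, p.id_b))))
        if best is None or (relationship_rank(rel)
                            < relationship_rank(best.relationship)):
            best = pair
    return best


def pair_reactions(db_a: list[Reaction], db_b: list[Reaction],
                   pairs, ec_mode: str = EC_FULL,
                   ignorable=DEFAULT_IGNORABLE) -> list[ReactionPair]:
    """All valid reaction pairs given a compound-pair list.

    Reactions lacking any EC specified to at least three levels are
    excluded.  Both substrate/product orientations are tried; the one
    yielding the stronger relationship wins.
    """
    index = pairs if isinstance(pairs, PairIndex) else PairIndex(pairs)
    out: list[ReactionPair] = []
    for ra in db_a:
        if not ra.has_complete_ec():
            continue
        for rb in db_b:
            if not rb.has_complete_ec():
                continue
            tier = _ec_tier(ra, rb, ec_mode)
            if tier is None:
                continue
            if ec_mode == EC_FULL and tier != EC_FULL:
                continue
            pair = _try_pair(ra, rb, index, tier, ignorable)
            if pair is not None:
                out.append(pair)
    return out


def _near_miss_candidates(ra: Reaction, rb: Reaction, index: PairIndex,
                          ignorable) -> tuple[list[str], list[str]] | None:
    """Unmatched participants of a near-miss reaction pair.

    Near miss: shared EC (checked by the caller), at least one matched
    compound pair, and some unmatched compounds in the best orientation.
    """
    best = None
    subs_a = _expand(ra.substrates, ignorable)
    prods_a = _expand(ra.products, ignorable)
    for side1, side2 in ((rb.substrates, rb.products),
                         (rb.products, rb.substrates)):
        u1, ua1, ub1 = _match_side(subs_a, _expand(side1, ignorable), index, False)
        u2, ua2, ub2 = _match_side(prods_a, _expand(side2, ignorable), index, False)
        n_matched = len(u1) + len(u2)
        unmatched_a = ua1 + ua2
        unmatched_b = ub1 + ub2
        if n_matched >= 1 and (unmatched_a or unmatched_b):
            if best is None or n_matched > best[0]:
                best = (n_matched, sorted(set(unmatched_a)), sorted(set(unmatched_b)))
    return (best[1], best[2]) if best else None


def _is_generic(mol: Molecule) -> bool:
    return any(a.is_r for a in mol.atoms)


def _validate_candidates(unmatched_a, unmatched_b,
                         compounds_a, compounds_b, index: PairIndex):
    """Run the structural validators over near-miss leftovers."""
    new: list[CompoundPair] = []

    def consider(pair):
        if pair is not None and (pair.id_a, pair.id_b) not in index:
            new.append(pair)

    for ca in unmatched_a:
        mol_a = compounds_a.get(ca)
        if mol_a is None:
            continue
        for cb in unmatched_b:
            mol_b = compounds_b.get(cb)
            if mol_b is None or (ca, cb) in index:
                continue
            same_formula = mol_a.formula() == mol_b.formula()
            if _is_generic(mol_a) and not same_formula:
                consider(validate_generic_pair(mol_a, mol_b))
            if _is_generic(mol_b) and not same_formula:
                p = validate_generic_pair(mol_b, mol_a)
                if p is not None:
                    consider(CompoundPair(ca, cb, p.relationship.swapped(),
                                          p.mapping, p.origin))
            if same_formula and not _is_generic(mol_a) and not _is_generic(mol_b):
                try:
                    consider(validate_tautomer_pair(mol_a, mol_b))
                except ValueError:
                    pass
                p = validate_ring_chain_pair(mol_a, mol_b)
                consider(p)
                if p is None:
                    q = validate_ring_chain_pair(mol_b, mol_a)
                    if q is not None:
                        consider(CompoundPair(ca, cb,
                                              q.relationship.swapped(),
                                              q.mapping, q.origin))
    return new


@dataclass
class HarmonizationResult:
    compound_pairs: list[CompoundPair]
    reaction_pairs: list[ReactionPair]
    rounds: list[list[tuple[str, str]]]    # new pair keys discovered per round

    def __iter__(self):
        return iter((self.compound_pairs, self.reaction_pairs))


def harmonization_loop(compounds_a: dict[str, Molecule],
                       compounds_b: dict[str, Molecule],
                       reactions_a: list[Reaction],
                       reactions_b: list[Reaction],
                       ec_mode: str = EC_FULL,
                       ignorable=DEFAULT_IGNORABLE) -> HarmonizationResult:
    """Iterate compound and reaction pairing to a fixpoint.

    Round 0 seeds the pair list from loose coloring identifiers; each
    subsequent round pairs reactions, mines near-miss pairs for new
    compound candidates, and validates them.  The pair list grows
    monotonically in a finite universe, so termination is guaranteed.
    """
    index = PairIndex(detect_pairs_by_identifier(
        list(compounds_a.values()), list(compounds_b.values())))
    rounds: list[list[tuple[str, str]]] = []
    while True:
        new_pairs: list[CompoundPair] = []
        for ra in reactions_a:
            if not ra.has_complete_ec():
                continue
            for rb in reactions_b:
                if not rb.has_complete_ec() or _ec_tier(ra, rb, ec_mode) is None:
                    continue
                cand = _near_miss_candidates(ra, rb, index, ignorable)
                if cand is None:
                    continue
                new_pairs.extend(_validate_candidates(
                    cand[0], cand[1], compounds_a, compounds_b, index))
        added = []
        for p in new_pairs:
            if index.add(p):
                added.append((p.id_a, p.id_b))
        if not added:
            break
        rounds.append(sorted(set(added)))
        logger.info("harmonization round %d: %d new compound pairs",
                    len(rounds), len(set(added)))
    reaction_pairs = pair_reactions(reactions_a, reactions_b, index,
                                    ec_mode, ignorable)
    return HarmonizationResult(index.pairs(), reaction_pairs, rounds)


# -- quality checks -----------------------------------------------------------

def quality_check_reaction(r: Reaction, compounds: dict[str, Molecule],
                           include_h: bool = False) -> str:
    """Classify an atom-resolved reaction into the defect taxonomy.

    ``incomplete_reaction`` — stoichiometry-weighted element counts differ
    between the two sides (H excluded unless ``include_h``);
    ``incorrect_mapping`` — some mapping entry joins atoms of different
    elements; ``incomplete_mapping`` — the mapping covers less than all
    balanceable atoms; ``complete`` otherwise.
    """
    def side_formula(side):
        total: dict[str, int] = {}
        for cid, stoich in side:
            mol = compounds[cid]
            for el, n in mol.formula(include_h=include_h).items():
                total[el] = total.get(el, 0) + n * int(stoich)
        return total

    fs, fp = side_formula(r.substrates), side_formula(r.products)
    if not include_h:
        fs.pop("H", None)
        fp.pop("H", None)
    if fs != fp:
        return QC_INCOMPLETE_REACTION

    mapping = r.mapping or []
    for (cid1, i1), (cid2, i2) in mapping:
        e1 = compounds[cid1].atom(i1).element
        e2 = compounds[cid2].atom(i2).element
        if e1 != e2:
            return QC_INCORRECT_MAPPING

    def countable(side):
        n = 0
        for cid, stoich in side:
            mol = compounds[cid]
            k = len(mol.heavy_indices()) if not include_h else len(mol.atoms)
            n += k * int(stoich)
        return n

    mapped_s = len({(c, i) for (c, i), _ in mapping})
    mapped_p = len({(c, i) for _, (c, i) in mapping})
    if mapped_s < countable(r.substrates) or mapped_p < countable(r.products):
        return QC_INCOMPLETE_MAPPING
    return QC_COMPLETE


# -- I/O ----------------------------------------------------------------------

def reaction_from_record(rec: dict) -> Reaction:
    mapping = None
    if rec.get("mapping"):
        mapping = [((m[0][0], int(m[0][1])), (m[1][0], int(m[1][1])))
                   for m in rec["mapping"]]
    return Reaction(
        id=rec["id"],
        ecs=[parse_ec(e) for e in rec.get("ecs", [])],
        substrates=[(c, int(s)) for c, s in rec["substrates"]],
        products=[(c, int(s)) for c, s in rec["products"]],
        mapping=mapping)


def load_reactions_json(path) -> list[Reaction]:
    with open(path) as fh:
        return [reaction_from_record(rec) for rec in json.load(fh)]


def write_reaction_pairs_tsv(pairs: list[ReactionPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\trelationship\tdirection\tec_tier\tcompound_pairs\n")
        for p in pairs:
            cps = ";".join(f"{c.id_a}~{c.id_b}" for c in p.compound_pairs_used)
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.relationship.kind}\t"
                     f"{p.relationship.direction}\t{p.ec_tier}\t{cps}\n")
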