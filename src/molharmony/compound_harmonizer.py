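"""Compound pairing and validation across two databases.

Candidate pairs are found by equal *loose* coloring identifiers (stereo
ignored) and then ranked by how well their chemical details — atom parity
and double-bond cis/trans labels — agree across an atom mapping:

* **equivalence**       — identical detail sets;
* **generic_specific**  — one detail set strictly contains the other; the
  relationship is directed from the less specified (general) compound to
  the more specified one.  Unknown stereo counts as absent, never as a
  conflict;
* **loose**             — conflicting details that cannot be reconciled.

Pairs the identifiers cannot see are validated structurally: generic
compounds (R groups) by R-aware subgraph containment, tautomers by
collapsing double bonds and checking that every mismatch is an adjacent
hydrogen/double-bond shift, and ring/chain (hemiacetal) representations by
reversing the ring closure and comparing identifiers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import networkx as nx

from .chemgraph import (CT_CIS, CT_TRANS, Molecule, PARITY_CCW, PARITY_CW,
                        PARITY_NONE)
from .coloring import LOOSE, compound_identifier
from .substructure import (AtomMatch, MatchOptions, all_isomorphisms,
                           graph_isomorphism, subgraph_search)

logger = logging.getLogger(__name__)

EQUIVALENCE = "equivalence"
GENERIC_SPECIFIC = "generic_specific"
LOOSE_REL = "loose"

DIR_NONE = "none"
DIR_A_TO_B = "a_to_b"
DIR_B_TO_A = "b_to_a"


@dataclass(frozen=True)
class RelationshipType:
    kind: str
    direction: str = DIR_NONE

    def __post_init__(self):
        if self.kind in (EQUIVALENCE, LOOSE_REL) and self.direction != DIR_NONE:
            raise ValueError(f"{self.kind} relationship cannot carry a direction")

    def swapped(self) -> "RelationshipType":
        """The same relationship seen with the two compounds swapped."""
        if self.kind != GENERIC_SPECIFIC:
            return self
        flip = {DIR_A_TO_B: DIR_B_TO_A, DIR_B_TO_A: DIR_A_TO_B, DIR_NONE: DIR_NONE}
        return RelationshipType(self.kind, flip[self.direction])


#: classification strength; smaller rank = stronger agreement
_RANK = {EQUIVALENCE: 0, GENERIC_SPECIFIC: 1, LOOSE_REL: 2}


def relationship_rank(rel: RelationshipType) -> int:
    return _RANK[rel.kind]


@dataclass(frozen=True)
class CompoundPair:
    id_a: str
    id_b: str
    relationship: RelationshipType
    mapping: AtomMatch | None = None
    origin: str = "identifier"   # identifier | generic_validation | tautomer | ring_chain


# -- chemical details ---------------------------------------------------------

def chemical_details(mol: Molecule, atoms: set[int] | None = None) -> set:
    """Stereo descriptors of ``mol`` as a comparable set.

    Entries are ``("parity", atom, value)`` for determined atom parities and
    ``("ct", (i, j), value)`` for labeled double bonds.  ``unknown`` stereo
    yields no entry (absent, subset-compatible).  ``atoms`` restricts the
    set to descriptors fully inside the given atom subset.
    """
    keep = atoms if atoms is not None else {a.index for a in mol.atoms}
    out = set()
    for a in mol.atoms:
        if a.index in keep and a.parity in (PARITY_CW, PARITY_CCW):
            out.add(("parity", a.index, a.parity))
    for bd in mol.bonds:
        if bd.cis_trans in (CT_CIS, CT_TRANS) and bd.a in keep and bd.b in keep:
            key = (bd.a, bd.b) if bd.a < bd.b else (bd.b, bd.a)
            out.add(("ct", key, bd.cis_trans))
    return out


def _translate_details(details: set, mapping: dict[int, int]) -> set:
    out = set()
    for d in details:
        if d[0] == "parity":
            out.add(("parity", mapping[d[1]], d[2]))
        else:
            i, j = mapping[d[1][0]], mapping[d[1][1]]
            out.add(("ct", (i, j) if i < j else (j, i), d[2]))
    return out


def _relationship_from_details(da_in_b: set, db: set) -> RelationshipType:
    if da_in_b == db:
        return RelationshipType(EQUIVALENCE)
    if da_in_b < db:
        return RelationshipType(GENERIC_SPECIFIC, DIR_A_TO_B)
    if db < da_in_b:
        return RelationshipType(GENERIC_SPECIFIC, DIR_B_TO_A)
    return RelationshipType(LOOSE_REL)


def classify_chemical_details(a: Molecule, b: Molecule,
                              mapping: AtomMatch) -> RelationshipType:
    """Classify a same-formula pair through a full heavy-atom bijection."""
    m = mapping.as_dict()
    heavy_a = set(a.heavy_indices())
    heavy_b = set(b.heavy_indices())
    if set(m) != heavy_a or set(m.values()) != heavy_b:
        raise ValueError("classification requires a full heavy-atom bijection")
    da = _translate_details(chemical_details(a, heavy_a), m)
    db = chemical_details(b, heavy_b)
    return _relationship_from_details(da, db)


# -- identifier-based detection ----------------------------------------------

def detect_pairs_by_identifier(db_a, db_b) -> list[CompoundPair]:
    """All cross-database pairs with equal loose coloring identifiers.

    ``db_a``/``db_b`` are iterables of molecules.  Each detected pair is
    classified by detail comparison over the best available isomorphism
    (equivalence preferred over generic-specific over loose, since distinct
    isomorphisms of a symmetric molecule may align the details differently).
    """
    by_ident: dict[str, list[Molecule]] = {}
    for mol in db_b:
        by_ident.setdefault(compound_identifier(mol, LOOSE).value, []).append(mol)
    pairs: list[CompoundPair] = []
    for mol_a in db_a:
        ident = compound_identifier(mol_a, LOOSE).value
        for mol_b in by_ident.get(ident, []):
            best: tuple[RelationshipType, AtomMatch] | None = None
            for iso in all_isomorphisms(mol_a, mol_b):
                rel = classify_chemical_details(mol_a, mol_b, iso)
                if best is None or relationship_rank(rel) < relationship_rank(best[0]):
                    best = (rel, iso)
                if relationship_rank(rel) == 0:
                    break
            if best is None:
                logger.warning("identifier collision without isomorphism: %s / %s",
                               mol_a.id, mol_b.id)
                pairs.append(CompoundPair(mol_a.id, mol_b.id,
                                          RelationshipType(LOOSE_REL),
                                          None, "identifier"))
            else:
                pairs.append(CompoundPair(mol_a.id, mol_b.id, best[0],
                                          best[1], "identifier"))
    return pairs


# -- generic (R group) validation --------------------------------------------

def validate_generic_pair(a: Molecule, b: Molecule) -> CompoundPair | None:
    """Validate a generic compound ``a`` (contains R) against ``b``.

    The R/H-stripped graph of ``a`` must embed in ``b``; every connected
    unmatched branch of ``b`` must hang off exactly one matched atom whose
    preimage in ``a`` carries an R group, one branch per R.  On success the
    pair is generic_specific from ``a`` (general) to ``b`` when the details
    of ``a`` are contained in those of ``b``, loose otherwise; ``None``
    marks an invalid pair.
    """
    r_atoms = [at.index for at in a.atoms if at.is_r]
    if not r_atoms:
        raise ValueError("validate_generic_pair requires an R group in the "
                         "first compound")
    r_attach: dict[int, int] = {}   # core atom -> number of R substituents
    for r in r_atoms:
        hosts = a.heavy_neighbors(r, include_r=False)
        if len(hosts) != 1:
            return None              # dangling or R-R bonded wildcard
        r_attach[hosts[0]] = r_attach.get(hosts[0], 0) + 1

    matches = subgraph_search(a, b, MatchOptions(ignore_r_h=True))
    heavy_b = set(b.heavy_indices())
    gb = nx.Graph()
    gb.add_nodes_from(heavy_b)
    for bd in b.bonds:
        if bd.a in heavy_b and bd.b in heavy_b:
            gb.add_edge(bd.a, bd.b)

    best: CompoundPair | None = None
    for match in matches:
        m = match.as_dict()              # a-core -> b
        image = set(m.values())
        unmatched = heavy_b - image
        branch_counts: dict[int, int] = {}
        ok = True
        components = nx.connected_components(gb.subgraph(unmatched)) if unmatched else []
        for comp in components:
            attach = {t for u in comp for t in gb.neighbors(u) if t in image}
            if len(attach) != 1:
                ok = False
                break
            host = next(iter(attach))
            branch_counts[host] = branch_counts.get(host, 0) + 1
        if not ok:
            continue
        inv = {t: p for p, t in m.items()}
        # every branch must instantiate an R; every R must absorb one branch
        need = {t: r_attach.get(inv[t], 0) for t in image}
        got = {t: branch_counts.get(t, 0) for t in image}
        if need != got:
            continue
        da = _translate_details(chemical_details(a, set(m)), m)
        db_details = chemical_details(b)
        rel = (RelationshipType(GENERIC_SPECIFIC, DIR_A_TO_B)
               if da <= db_details else RelationshipType(LOOSE_REL))
        pair = CompoundPair(a.id, b.id, rel, match, "generic_validation")
        if best is None or relationship_rank(rel) < relationship_rank(best.relationship):
            best = pair
        if relationship_rank(rel) == 1:
            break
    return best


# -- tautomer validation ------------------------------------------------------

def _collapsed(mol: Molecule) -> Molecule:
    out = mol.copy()
    for bd in out.bonds:
        if bd.order == 2:
            bd.order = 1
    return out


def _double_bond_keys(mol: Molecule) -> set[tuple[int, int]]:
    return {bd.key() for bd in mol.bonds if bd.order == 2}


def validate_tautomer_pair(a: Molecule, b: Molecule) -> CompoundPair | None:
    """Validate two same-formula compounds as tautomers.

    Both skeletons are rebuilt with every double bond as single and must be
    isomorphic; double bonds at unmatched positions must pair up as
    adjacent-bond hydrogen shifts (the double bond moves to a neighboring
    bond; when explicit hydrogens are present on both inputs, the far atoms
    must gain/lose one H accordingly).  Remaining chemical details away
    from the changeable positions set the relationship.
    """
    if a.formula() != b.formula():
        raise ValueError("tautomer validation requires identical formulas")
    ca, cb = _collapsed(a), _collapsed(b)
    check_h = any(at.element == "H" for at in a.atoms) and \
        any(at.element == "H" for at in b.atoms)

    best: CompoundPair | None = None
    for iso in all_isomorphisms(ca, cb):
        m = iso.as_dict()
        da = {tuple(sorted((m[i], m[j]))) for i, j in _double_bond_keys(a)}
        db_keys = _double_bond_keys(b)
        mism_a = da - db_keys            # double in a, single in b (b coords)
        mism_b = db_keys - da            # double in b, single in a
        if not mism_a and not mism_b:
            changeable: set[int] = set()
        else:
            if len(mism_a) != len(mism_b):
                continue
            pairing = _match_shifts(a, b, m, mism_a, mism_b, check_h)
            if pairing is None:
                continue
            changeable = {i for e in (mism_a | mism_b) for i in e}
        inv = {t: p for p, t in m.items()}
        keep_b = {i for i in b.heavy_indices() if i not in changeable}
        keep_a = {inv[i] for i in keep_b}
        da_det = _translate_details(chemical_details(a, keep_a), m)
        db_det = chemical_details(b, keep_b)
        rel = _relationship_from_details(da_det, db_det)
        pair = CompoundPair(a.id, b.id, rel, iso, "tautomer")
        if best is None or relationship_rank(rel) < relationship_rank(best.relationship):
            best = pair
        if relationship_rank(rel) == 0:
            break
    return best


def _match_shifts(a, b, m, mism_a, mism_b, check_h) -> dict | None:
    """Perfect pairing of mismatched double bonds by adjacent H shifts."""
    inv = {t: p for p, t in m.items()}
    edges: dict[tuple, list[tuple]] = {}
    for ea in mism_a:
        for eb in mism_b:
            shared = set(ea) & set(eb)
            if len(shared) != 1:
                continue
            if check_h:
                s = next(iter(shared))
                far_a = next(i for i in ea if i != s)   # lost the double bond
                far_b = next(i for i in eb if i != s)   # gained it
                if b.h_count(far_a) != a.h_count(inv[far_a]) + 1:
                    continue
                if b.h_count(far_b) != a.h_count(inv[far_b]) - 1:
                    continue
            edges.setdefault(ea, []).append(eb)
    used: set[tuple] = set()
    assign: dict[tuple, tuple] = {}

    def bt(items):
        if not items:
            return True
        ea, rest = items[0], items[1:]
        for eb in edges.get(ea, []):
            if eb not in used:
                used.add(eb)
                assign[ea] = eb
                if bt(rest):
                    return True
                used.discard(eb)
                del assign[ea]
        return False

    return assign if bt(sorted(mism_a)) else None


# -- ring/chain (hemiacetal) validation ---------------------------------------

def _ring_bonds(mol: Molecule) -> set[tuple[int, int]]:
    g = nx.Graph()
    heavy = mol.heavy_indices()
    g.add_nodes_from(heavy)
    keep = set(heavy)
    for bd in mol.bonds:
        if bd.a in keep and bd.b in keep:
            g.add_edge(bd.a, bd.b)
    bridges = {tuple(sorted(e)) for e in nx.bridges(g)}
    return {tuple(sorted(e)) for e in g.edges} - bridges


def validate_ring_chain_pair(circular: Molecule,
                             linear: Molecule) -> CompoundPair | None:
    """Validate a ring-form/open-form (hemiacetal) compound pair.

    Each ring C-O bond whose carbon also bears a hydroxyl group (the
    hemiacetal/hemiketal motif) is tried in turn: the ring bond is broken,
    the carbonyl C=O restored on that carbon, and any explicit H moved from
    the hydroxyl oxygen back to the former ring oxygen.  The pair is valid
    iff some modification reproduces the open form's loose identifier.
    """
    if circular.formula() != linear.formula():
        raise ValueError("ring/chain validation requires identical formulas")
    ring = _ring_bonds(circular)
    target = compound_identifier(linear, LOOSE).value
    candidates = []
    for i, j in ring:
        for c, o_ring in ((i, j), (j, i)):
            if circular.atom(c).element != "C" or circular.atom(o_ring).element != "O":
                continue
            for o_h in circular.heavy_neighbors(c):
                if o_h == o_ring:
                    continue
                oa = circular.atom(o_h)
                if oa.element != "O":
                    continue
                bd = circular.bond_between(c, o_h)
                if bd.order != 1 or len(circular.heavy_neighbors(o_h)) != 1:
                    continue
                candidates.append((c, o_ring, o_h))
    if not candidates:
        logger.info("%s/%s: no hemiacetal bond", circular.id, linear.id)
        return None

    best: CompoundPair | None = None
    for c, o_ring, o_h in sorted(candidates):
        mod = circular.copy()
        mod.bonds = [bd for bd in mod.bonds
                     if bd.key() != tuple(sorted((c, o_ring)))]
        h_on_oh = [j for j in mod.neighbors(o_h)
                   if mod.atom(j).element == "H"]
        for bd in mod.bonds:
            if bd.key() == tuple(sorted((c, o_h))):
                bd.order = 2
            elif h_on_oh and bd.key() == tuple(sorted((o_h, h_on_oh[0]))):
                bd.a, bd.b = o_ring, h_on_oh[0]
        mod.atom(c).parity = PARITY_NONE     # anomeric center becomes sp2
        mod.atom(o_h).parity = PARITY_NONE
        mod = Molecule(mod.id, mod.atoms, mod.bonds, mod.source)
        if compound_identifier(mod, LOOSE).value != target:
            continue
        iso = graph_isomorphism(mod, linear)
        if iso is None:
            continue
        rel = classify_chemical_details(mod, linear, iso)
        pair = CompoundPair(circular.id, linear.id, rel, iso, "ring_chain")
        if best is None or relationship_rank(rel) < relationship_rank(best.relationship):
            best = pair
        if relationship_rank(rel) == 0:
            break
    return best


# -- export -------------------------------------------------------------------

def pairs_to_records(pairs: list[CompoundPair]) -> list[dict]:
    out = []
    for p in pairs:
        out.append({
            "id_a": p.id_a, "id_b": p.id_b,
            "relationship": p.relationship.kind,
            "direction": p.relationship.direction,
            "origin": p.origin,
            "mapping": list(p.mapping.mapping) if p.mapping else None,
        })
    return out


def write_pairs_tsv(pairs: list[CompoundPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\trelationship\tdirection\torigin\tmapping\n")
        for r in pairs_to_records(pairs):
            mp = ";".join(f"{i}-{j}" for i, j in r["mapping"]) if r["mapping"] else ""
            fh.write(f"{r['id_a']}\t{r['id_b']}\t{r['relationship']}\t"
                     f"{r['direction']}\t{r['origin']}\t{mp}\n")


def write_pairs_json(pairs: list[CompoundPair], path) -> None:
    with open(path, "w") as fh:
        json.dump(pairs_to_records(pairs), fh, indent=1)
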