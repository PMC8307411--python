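"""Synthetic compound/reaction generators with known ground truth.

Random molecules are valence-respecting connected heavy-atom graphs drawn
from the C/N/O/S alphabet, with 2D coordinates from a deterministic
breadth-first layout.  On top of them the module plants every pair
category the harmonizer must recover — equivalence (relabeled copies),
loose (conflicting wedge stereo), generic-specific (a branch replaced by
an R group), tautomer (an adjacent hydrogen/double-bond shift), and
ring/chain (a hemiacetal ring closure applied in reverse) — as well as
matched non-pairs that the validators must reject, reactions with planted
bond edits and the RDM descriptions consistent with them, and two mini
databases wired so that the iterative harmonization loop discovers
reaction-mediated pairs round by round.

All generation is driven by :class:`random.Random` seeded explicitly, so
identical seeds give identical molfile text on any platform.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .chemgraph import (Atom, Bond, Molecule, WEDGE_DOWN, WEDGE_UP,
                        perceive_stereo)
from .coloring import LOOSE, compound_identifier, symmetry_classes
from .compound_harmonizer import (CompoundPair, DIR_A_TO_B, EQUIVALENCE,
                                  GENERIC_SPECIFIC, LOOSE_REL,
                                  RelationshipType)
from .rdm_mapping import PairAtomMapping, RDMDescription
from .reaction_harmonizer import Reaction, parse_ec
from .substructure import MatchOptions, subgraph_search

#: minimal valence table used for plausible random graph growth
VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 5, "H": 1, "R": 1}

_ELEMENT_POOL = ["C", "C", "C", "C", "C", "N", "O", "S"]

PAIR_CATEGORIES = ("equivalence", "loose", "generic_specific",
                   "tautomer", "ring_chain")
NONPAIR_KINDS = ("skeleton", "illegal_shift", "missing_hemiacetal")


# -- random molecules ---------------------------------------------------------

def _free_valence(mol: Molecule) -> dict[int, int]:
    free = {}
    for a in mol.atoms:
        used = sum(bd.order if bd.order != 4 else 1 for bd in mol.bonds_of(a.index))
        free[a.index] = VALENCE.get(a.element, 4) - used
    return free


def _layout(mol: Molecule) -> None:
    """Deterministic BFS coordinates: unit bonds, fanned child angles."""
    if not mol.atoms:
        return
    start = mol.atoms[0].index
    pos = {start: (0.0, 0.0)}
    angle = {start: 0.0}
    queue = [start]
    offsets = [2 * math.pi / 3, -2 * math.pi / 3, math.pi / 3,
               -math.pi / 3, math.pi, 0.5]
    while queue:
        u = queue.pop(0)
        k = 0
        for v in sorted(mol.neighbors(u)):
            if v in pos:
                continue
            th = angle[u] + offsets[k % len(offsets)] + 0.07 * (k // len(offsets) + 1)
            k += 1
            ux, uy = pos[u]
            pos[v] = (ux + math.cos(th), uy + math.sin(th))
            angle[v] = th
            queue.append(v)
    for a in mol.atoms:
        a.x, a.y = pos.get(a.index, (0.0, 0.0))


def gen_molecule(rng: random.Random, size: int, id: str = "mol",
                 double_prob: float = 0.15, ring_prob: float = 0.15) -> Molecule:
    """Random connected valence-respecting heavy-atom graph."""
    if size < 1:
        raise ValueError("size must be >= 1")
    atoms = [Atom(1, "C")]
    bonds: list[Bond] = []
    free = [VALENCE["C"]]
    for i in range(2, size + 1):
        hosts = [j for j in range(len(atoms)) if free[j] >= 1]
        if not hosts:
            el = "C"
            host = None
        else:
            host = rng.choice(hosts)
            el = rng.choice(_ELEMENT_POOL)
        order = 1
        if host is not None and rng.random() < double_prob \
                and free[host] >= 2 and VALENCE[el] >= 2:
            order = 2
        atoms.append(Atom(i, el))
        free.append(VALENCE[el])
        if host is not None:
            bonds.append(Bond(host + 1, i, order))
            free[host] -= order
            free[-1] -= order
    if size >= 5 and rng.random() < ring_prob:
        closable = [(i, j) for i in range(size) for j in range(i + 3, size)
                    if free[i] >= 1 and free[j] >= 1]
        existing = {bd.key() for bd in bonds}
        closable = [(i, j) for i, j in closable
                    if (i + 1, j + 1) not in existing]
        if closable:
            i, j = rng.choice(closable)
            bonds.append(Bond(i + 1, j + 1, 1))
    mol = Molecule(id, atoms, bonds)
    _layout(mol)
    return mol


def permuted_copy(mol: Molecule, rng: random.Random,
                  new_id: str | None = None) -> Molecule:
    """Same structure with atoms renumbered by a random permutation."""
    old = [a.index for a in mol.atoms]
    shuffled = old[:]
    rng.shuffle(shuffled)
    remap = {o: n for o, n in zip(old, shuffled)}
    atoms = sorted((Atom(remap[a.index], a.element, a.charge, a.x, a.y,
                         a.parity, a.kegg_type, a.is_r) for a in mol.atoms),
                   key=lambda a: a.index)
    bonds = [Bond(remap[bd.a], remap[bd.b], bd.order, bd.wedge, bd.cis_trans)
             for bd in mol.bonds]
    return Molecule(new_id or mol.id, atoms, bonds, mol.source)


def annotate_kegg_types(mol: Molecule) -> Molecule:
    """Attach synthetic KEGG-style atom types (element+degree+environment).

    The letter suffix hashes the neighbor-element composition, so the
    labels are coarser than full atom colors — several atoms may share a
    type, exactly like real KEGG atom types — yet fully deterministic.
    """
    from .chemgraph import ATOMIC_NUMBERS
    for a in mol.atoms:
        if a.element == "H":
            a.kegg_type = None
            continue
        nbrs = mol.heavy_neighbors(a.index)
        s = sum(ATOMIC_NUMBERS.get(mol.atom(j).element, 0) for j in nbrs)
        letter = "abcdefghijklmnopqrstuvwxyz"[s % 26]
        a.kegg_type = f"{a.element}{len(nbrs)}{letter}"
    return mol


# -- planted compound pairs ---------------------------------------------------

def _stereo_core(id: str, wedge: str, rng: random.Random | None = None,
                 tail: int = 0) -> Molecule:
    """Asymmetric stereocenter (C bonded to N, O, S) with one wedge bond."""
    atoms = [Atom(1, "C", x=0.0, y=0.0), Atom(2, "N", x=1.0, y=0.0),
             Atom(3, "O", x=-0.5, y=0.87), Atom(4, "S", x=-0.5, y=-0.87)]
    bonds = [Bond(1, 2, 1, wedge=wedge), Bond(1, 3, 1), Bond(1, 4, 1)]
    n = 4
    host = 2
    for k in range(tail):
        n += 1
        atoms.append(Atom(n, "C", x=1.0 + k + 1, y=0.0))
        bonds.append(Bond(host, n, 1))
        host = n
    mol = Molecule(id, atoms, bonds)
    return perceive_stereo(mol)


def gen_pair(rng: random.Random, category: str,
             id_a: str = "a", id_b: str = "b"):
    """A planted compound pair: ``(mol_a, mol_b, expected CompoundPair)``."""
    if category == "equivalence":
        m = gen_molecule(rng, rng.randint(5, 9), id=id_a)
        b = permuted_copy(m, rng, new_id=id_b)
        return m, b, CompoundPair(id_a, id_b, RelationshipType(EQUIVALENCE),
                                  None, "identifier")
    if category == "loose":
        tail = rng.randint(0, 3)
        a = _stereo_core(id_a, WEDGE_UP, tail=tail)
        b = _stereo_core(id_b, WEDGE_DOWN, tail=tail)
        return a, b, CompoundPair(id_a, id_b, RelationshipType(LOOSE_REL),
                                  None, "identifier")
    if category == "generic_specific":
        b = gen_molecule(rng, rng.randint(6, 9), id=id_b, double_prob=0.0,
                         ring_prob=0.0)          # a tree always has leaves
        leaves = [i for i in b.heavy_indices()
                  if len(b.heavy_neighbors(i)) == 1]
        leaf = rng.choice(leaves)
        a = b.copy(new_id=id_a)
        at = a.atom(leaf)
        at.element, at.is_r, at.charge = "R", True, 0
        for bd in a.bonds_of(leaf):
            bd.order = 1
        return a, b, CompoundPair(
            id_a, id_b, RelationshipType(GENERIC_SPECIFIC, DIR_A_TO_B),
            None, "generic_validation")
    if category == "tautomer":
        return _tautomer_pair(rng, id_a, id_b)
    if category == "ring_chain":
        return _ring_chain_pair(rng, id_a, id_b)
    raise ValueError(f"unknown pair category {category!r}")


def _tautomer_pair(rng, id_a, id_b):
    """Keto form vs enol-like form: O= moved to an adjacent C-C bond."""
    while True:
        base = gen_molecule(rng, rng.randint(4, 7), id=id_a,
                            double_prob=0.0, ring_prob=0.0)
        free = _free_valence(base)
        options = []
        for y in base.heavy_indices():
            if base.atom(y).element != "C" or free[y] < 2:
                continue
            for z in base.heavy_neighbors(y):
                if base.atom(z).element == "C" and free[z] >= 1:
                    options.append((y, z))
        if not options:
            continue
        y, z = rng.choice(options)
        n = len(base.atoms) + 1
        keto = base.copy(new_id=id_a)
        keto.atoms.append(Atom(n, "O", x=keto.atom(y).x + 0.3,
                               y=keto.atom(y).y + 1.0))
        keto.bonds.append(Bond(y, n, 2))
        keto = Molecule(id_a, keto.atoms, keto.bonds)
        enol = base.copy(new_id=id_b)
        enol.atoms.append(Atom(n, "O", x=enol.atom(y).x + 0.3,
                               y=enol.atom(y).y + 1.0))
        enol.bonds.append(Bond(y, n, 1))
        for bd in enol.bonds:
            if bd.key() == tuple(sorted((y, z))):
                bd.order = 2
        enol = Molecule(id_b, enol.atoms, enol.bonds)
        if compound_identifier(keto, LOOSE).value == \
                compound_identifier(enol, LOOSE).value:
            continue   # symmetric skeleton: shift is invisible, re-draw
        return keto, enol, CompoundPair(id_a, id_b,
                                        RelationshipType(EQUIVALENCE),
                                        None, "tautomer")


def _ring_chain_pair(rng, id_a, id_b):
    """Furanose/pyranose-like ring closure of an open-chain aldehyde."""
    m = rng.randint(4, 6)                     # carbons in the chain
    atoms = [Atom(i, "C", x=float(i), y=0.0) for i in range(1, m + 1)]
    bonds = [Bond(i, i + 1, 1) for i in range(1, m)]
    o_d = m + 1                               # carbonyl oxygen on C1
    o_h = m + 2                               # hydroxyl oxygen on Cm
    atoms.append(Atom(o_d, "O", x=1.0, y=1.0))
    atoms.append(Atom(o_h, "O", x=float(m), y=1.0))
    bonds.append(Bond(1, o_d, 2))
    bonds.append(Bond(m, o_h, 1))
    extra = rng.randint(0, 2)                 # decorate mid-chain hydroxyls
    nxt = m + 3
    for c in rng.sample(range(2, m), min(extra, m - 2)):
        atoms.append(Atom(nxt, "O", x=float(c), y=-1.0))
        bonds.append(Bond(c, nxt, 1))
        nxt += 1
    linear = Molecule(id_b, atoms, bonds)

    ring_atoms = [Atom(a.index, a.element, a.charge, a.x, a.y) for a in atoms]
    ring_bonds = []
    for bd in bonds:
        order = 1 if bd.key() == (1, o_d) else bd.order
        ring_bonds.append(Bond(bd.a, bd.b, order))
    ring_bonds.append(Bond(1, o_h, 1))        # the hemiacetal ring bond
    circular = Molecule(id_a, ring_atoms, ring_bonds)
    return circular, linear, CompoundPair(id_a, id_b,
                                          RelationshipType(EQUIVALENCE),
                                          None, "ring_chain")


def gen_nonpair(rng: random.Random, kind: str, id_a: str = "a",
                id_b: str = "b"):
    """Same-formula decoys every validator must reject."""
    n = rng.randint(4, 6)
    if kind == "skeleton":
        atoms = [Atom(i, "C", x=float(i)) for i in range(1, n + 1)]
        atoms.append(Atom(n + 1, "O", x=0.0, y=1.0))
        path = [Bond(i, i + 1, 1) for i in range(1, n)] + [Bond(1, n + 1, 2)]
        a = Molecule(id_a, atoms, path)
        branched = [Bond(i, i + 1, 1) for i in range(1, n - 1)]
        branched.append(Bond(n - 2, n, 1))          # reattach the last C
        branched.append(Bond(1, n + 1, 2))
        b = Molecule(id_b, [Atom(i, at.element, x=at.x, y=at.y)
                            for i, at in zip(range(1, n + 2), atoms)], branched)
        return a, b
    if kind == "illegal_shift":
        atoms = [Atom(i, "C", x=float(i)) for i in range(1, n + 1)]
        atoms.append(Atom(n + 1, "O", x=float(n), y=1.0))
        base = [Bond(i, i + 1, 1) for i in range(1, n)] + [Bond(n, n + 1, 1)]
        a_bonds = [Bond(bd.a, bd.b, 2 if bd.key() == (n, n + 1) else 1)
                   for bd in base]
        b_bonds = [Bond(bd.a, bd.b, 2 if bd.key() == (1, 2) else 1)
                   for bd in base]
        return (Molecule(id_a, atoms, a_bonds),
                Molecule(id_b, [Atom(a.index, a.element, x=a.x, y=a.y)
                                for a in atoms], b_bonds))
    if kind == "missing_hemiacetal":
        ring_atoms = [Atom(i, "C", x=float(i)) for i in range(1, n + 1)]
        ring_atoms.append(Atom(n + 1, "O", y=1.0))
        ring_bonds = [Bond(i, i + 1, 1) for i in range(1, n)]
        ring_bonds += [Bond(n, n + 1, 1), Bond(n + 1, 1, 1)]
        chain_atoms = [Atom(i, "C", x=float(i)) for i in range(1, n + 1)]
        chain_atoms.append(Atom(n + 1, "O", y=1.0))
        chain_bonds = [Bond(i, i + 1, 1) for i in range(1, n + 1)]
        return (Molecule(id_a, ring_atoms, ring_bonds),
                Molecule(id_b, chain_atoms, chain_bonds))
    raise ValueError(f"unknown non-pair kind {kind!r}")


# -- reactions with planted atom mappings -------------------------------------

@dataclass
class ReactionFixture:
    reaction: Reaction
    compounds: dict[str, Molecule]
    truth: PairAtomMapping                  # ground-truth substrate->product
    rdms: list[RDMDescription]
    centers: tuple[int, ...]                # substrate center atoms


def gen_reaction_with_mapping(seed: int, n_center_edits: int) -> ReactionFixture:
    """Substrate/product pair with planted branch-loss edits and RDMs.

    Each edit removes one terminal branch atom at a distinct center; the
    emitted RDM descriptions are consistent with the edits and the true
    atom mapping (identity on retained atoms) is recorded.  Generation
    retries until the molecule is asymmetric enough that the planted
    mapping is the unique optimum.
    """
    if n_center_edits < 1:
        raise ValueError("n_center_edits must be >= 1")
    for attempt in range(200):
        rng = random.Random(f"rxnfix:{seed}:{attempt}")
        core = gen_molecule(rng, rng.randint(6, 9), id=f"S{seed}",
                            double_prob=0.1, ring_prob=0.1)
        free = _free_valence(core)
        hosts = [i for i in core.heavy_indices() if free[i] >= 1]
        if len(hosts) < n_center_edits:
            continue
        hosts = sorted(rng.sample(hosts, n_center_edits))
        sub = core.copy(new_id=f"S{seed}")
        nxt = len(sub.atoms) + 1
        leaves = []
        for h in hosts:
            sub.atoms.append(Atom(nxt, "C", x=sub.atom(h).x + 0.17,
                                  y=sub.atom(h).y - 1.0))
            sub.bonds.append(Bond(h, nxt, 1))
            leaves.append(nxt)
            nxt += 1
        sub = Molecule(sub.id, sub.atoms, sub.bonds)
        prod = core.copy(new_id=f"P{seed}")
        annotate_kegg_types(sub)
        annotate_kegg_types(prod)
        if any(len(c) > 1 for c in symmetry_classes(sub)):
            continue
        if any(len(c) > 1 for c in symmetry_classes(prod)):
            continue
        # planted optimum must be structurally unique
        mod = sub.copy()
        drop = {tuple(sorted((h, l))) for h, l in zip(hosts, leaves)}
        mod.bonds = [bd for bd in mod.bonds if bd.key() not in drop]
        mod = Molecule(mod.id, mod.atoms, mod.bonds)
        if len(subgraph_search(prod, mod, MatchOptions())) != 1:
            continue
        rdms = []
        for h, l in zip(hosts, leaves):
            nb_s = sorted(sub.atom(j).kegg_type
                          for j in sub.heavy_neighbors(h) if j != l)
            nb_p = sorted(prod.atom(j).kegg_type
                          for j in prod.heavy_neighbors(h))
            rdms.append(RDMDescription(
                center=(sub.atom(h).kegg_type, prod.atom(h).kegg_type),
                diff_s=(sub.atom(l).kegg_type,), diff_p=(),
                matched_s=tuple(nb_s), matched_p=tuple(nb_p)))
        truth = PairAtomMapping(
            sub.id, prod.id,
            tuple((i, i) for i in sorted(core.heavy_indices())),
            frozenset((h, h) for h in hosts))
        ec = parse_ec(f"1.1.1.{1 + seed % 200}")
        reaction = Reaction(
            id=f"R{seed}", ecs=[ec],
            substrates=[(sub.id, 1)], products=[(prod.id, 1)],
            mapping=[((sub.id, i), (prod.id, j)) for i, j in truth.pairs])
        return ReactionFixture(reaction, {sub.id: sub, prod.id: prod},
                               truth, rdms, tuple(hosts))
    raise RuntimeError("could not generate an asymmetric reaction fixture")


def gen_combinatorial_case(k: int = 6):
    """Symmetric multi-center case whose assignments explode combinatorially.

    A ``k``-ring whose every atom bears an identical leaving branch, with
    one identical RDM per branch: every center has ``k`` candidates on both
    sides, giving ``(k*k)**k`` assignments.
    """
    atoms = [Atom(i, "C", x=math.cos(2 * math.pi * i / k),
                  y=math.sin(2 * math.pi * i / k)) for i in range(1, k + 1)]
    bonds = [Bond(i, i % k + 1, 1) for i in range(1, k + 1)]
    for i in range(1, k + 1):
        atoms.append(Atom(k + i, "C", x=2 * math.cos(2 * math.pi * i / k),
                          y=2 * math.sin(2 * math.pi * i / k)))
        bonds.append(Bond(i, k + i, 1))
    sub = annotate_kegg_types(Molecule("Scomb", atoms, bonds))
    p_atoms = [Atom(i, "C", x=a.x, y=a.y) for i, a in enumerate(atoms[:k], 1)]
    p_bonds = [Bond(i, i % k + 1, 1) for i in range(1, k + 1)]
    prod = annotate_kegg_types(Molecule("Pcomb", p_atoms, p_bonds))
    ring_s = sub.atom(1).kegg_type
    ring_p = prod.atom(1).kegg_type
    leaf_s = sub.atom(k + 1).kegg_type
    rdm = RDMDescription(center=(ring_s, ring_p), diff_s=(leaf_s,), diff_p=(),
                         matched_s=(ring_s, ring_s), matched_p=(ring_p, ring_p))
    return sub, prod, [rdm] * k


# -- mini databases for the harmonization loop --------------------------------

@dataclass
class FixtureSpec:
    """Study conditions for the planted mini databases."""
    seed: int = 0
    n_compounds: int = 30                   # compounds per database side
    n_reactions: int = 12                   # reactions per side
    planted: dict = field(default_factory=lambda: {
        "equivalence": 5, "loose": 2, "generic_specific": 2,
        "tautomer": 2, "ring_chain": 1})


@dataclass
class MiniDatabases:
    compounds_a: dict[str, Molecule]
    compounds_b: dict[str, Molecule]
    reactions_a: list[Reaction]
    reactions_b: list[Reaction]
    expected_compound_pairs: list[CompoundPair]
    expected_reaction_pairs: list[tuple[str, str, str]]   # (id_a, id_b, kind)
    ring_chain_keys: list[tuple[str, str]]


def gen_databases(spec: FixtureSpec) -> MiniDatabases:
    """Two planted mini databases exercising the full harmonization loop.

    The wiring guarantees: equivalence/loose pairs are identifier-visible
    from round 0; generic and tautomer pairs become visible through
    near-miss reaction pairs in the first loop round; the ring/chain pair
    sits in a reaction whose only cross-matches are themselves round-1
    discoveries, so it cannot be found before round 2.
    """
    rng = random.Random(spec.seed)
    compounds_a: dict[str, Molecule] = {}
    compounds_b: dict[str, Molecule] = {}
    expected: list[CompoundPair] = []
    idents: set[str] = set()

    def unique(mol: Molecule) -> bool:
        return compound_identifier(mol, LOOSE).value not in idents

    def register(mol: Molecule) -> None:
        idents.add(compound_identifier(mol, LOOSE).value)

    def plant(category: str, tag: str):
        for _ in range(100):
            a, b, exp = gen_pair(rng, category, id_a=f"A_{tag}",
                                 id_b=f"B_{tag}")
            ia = compound_identifier(a, LOOSE).value
            ib = compound_identifier(b, LOOSE).value
            shared = category in ("equivalence", "loose")
            if shared and ia in idents:
                continue
            if not shared and (ia in idents or ib in idents or ia == ib):
                continue
            idents.add(ia)
            idents.add(ib)
            compounds_a[a.id] = a
            compounds_b[b.id] = b
            expected.append(exp)
            return exp
        raise RuntimeError(f"could not plant a unique {category} pair")

    counts = spec.planted
    eq = [plant("equivalence", f"eq{i+1}") for i in range(counts["equivalence"])]
    lo = [plant("loose", f"lo{i+1}") for i in range(counts["loose"])]
    ge = [plant("generic_specific", f"ge{i+1}")
          for i in range(counts["generic_specific"])]
    ta = [plant("tautomer", f"ta{i+1}") for i in range(counts["tautomer"])]
    rc = [plant("ring_chain", f"rc{i+1}") for i in range(counts["ring_chain"])]
    if len(eq) < 5 or len(ge) < 2:
        raise ValueError("the reaction wiring needs >=5 equivalence and "
                         ">=2 generic pairs planted")

    proton = Molecule("H+", [Atom(1, "H", charge=1)], [])
    compounds_a["H+"] = proton

    def filler(db, side):
        i = 0
        while len(db) < spec.n_compounds:
            i += 1
            for _ in range(100):
                m = gen_molecule(rng, rng.randint(4, 10), id=f"{side}_f{i}")
                if unique(m):
                    register(m)
                    db[m.id] = m
                    break
            else:
                raise RuntimeError("could not generate a unique filler")

    filler(compounds_a, "A")
    filler(compounds_b, "B")

    def rx(rid, ec, subs, prods):
        return Reaction(id=rid, ecs=[parse_ec(ec)],
                        substrates=[(c, 1) for c in subs],
                        products=[(c, 1) for c in prods])

    def ids(pair, side):
        return pair.id_a if side == "a" else pair.id_b

    reactions_a, reactions_b = [], []
    expected_rx: list[tuple[str, str, str]] = []

    def both(n, ec, parts_a, parts_b, prods_a, prods_b, kind):
        ra = rx(f"RA{n}", ec, parts_a, prods_a)
        rb = rx(f"RB{n}", ec, parts_b, prods_b)
        reactions_a.append(ra)
        reactions_b.append(rb)
        if kind:
            expected_rx.append((ra.id, rb.id, kind))

    # round-1 discoveries: generic and tautomer pairs via near misses
    both(1, "1.1.1.1", [ids(ge[0], "a"), ids(eq[0], "a")],
         [ids(ge[0], "b"), ids(eq[0], "b")],
         [ids(eq[1], "a")], [ids(eq[1], "b")], GENERIC_SPECIFIC)
    both(2, "1.1.1.2", [ids(ge[1], "a"), ids(eq[2], "a")],
         [ids(ge[1], "b"), ids(eq[2], "b")],
         [ids(eq[3], "a")], [ids(eq[3], "b")], GENERIC_SPECIFIC)
    both(3, "2.3.1.5", [ids(ta[0], "a"), ids(eq[4], "a")],
         [ids(ta[0], "b"), ids(eq[4], "b")],
         [ids(eq[0], "a")], [ids(eq[0], "b")], EQUIVALENCE)
    both(4, "2.3.1.9", [ids(ta[1], "a"), ids(eq[1], "a")],
         [ids(ta[1], "b"), ids(eq[1], "b")],
         [ids(eq[2], "a")], [ids(eq[2], "b")], EQUIVALENCE)
    # round-2 discovery: the ring/chain pair hides behind round-1 pairs
    both(5, "3.2.1.7", [ids(rc[0], "a"), ids(ge[0], "a")],
         [ids(rc[0], "b"), ids(ge[0], "b")],
         [ids(ge[1], "a")], [ids(ge[1], "b")], GENERIC_SPECIFIC)
    # plain reaction pairs
    both(6, "4.1.1.3", [ids(eq[0], "a"), ids(eq[1], "a")],
         [ids(eq[0], "b"), ids(eq[1], "b")],
         [ids(eq[2], "a")], [ids(eq[2], "b")], EQUIVALENCE)
    both(7, "4.1.2.4", [ids(lo[0], "a"), ids(eq[3], "a")],
         [ids(lo[0], "b"), ids(eq[3], "b")],
         [ids(eq[4], "a")], [ids(eq[4], "b")], LOOSE_REL)
    both(8, "5.3.1.1", [ids(eq[0], "a"), ids(eq[4], "a")],
         [ids(eq[0], "b"), ids(eq[4], "b")],
         [ids(eq[3], "a"), "H+"], [ids(eq[3], "b")], EQUIVALENCE)

    # per-side fillers with non-shared EC numbers: no cross pairs
    fillers_a = [cid for cid in compounds_a if cid.startswith("A_f")]
    fillers_b = [cid for cid in compounds_b if cid.startswith("B_f")]
    n_fill = spec.n_reactions - len(reactions_a)
    for k in range(n_fill):
        fa = fillers_a[2 * k % len(fillers_a)], fillers_a[(2 * k + 1) % len(fillers_a)]
        fb = fillers_b[2 * k % len(fillers_b)], fillers_b[(2 * k + 1) % len(fillers_b)]
        reactions_a.append(rx(f"RA{9 + k}", f"6.1.1.{k + 1}", [fa[0]], [fa[1]]))
        reactions_b.append(rx(f"RB{9 + k}", f"6.2.1.{k + 1}", [fb[0]], [fb[1]]))

    return MiniDatabases(compounds_a, compounds_b, reactions_a, reactions_b,
                         expected, expected_rx,
                         [(p.id_a, p.id_b) for p in rc])
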