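"""Chemically-aware subgraph isomorphism and maximum common subgraph.

Backtracking (VF2-style) matchers over the hydrogen-suppressed molecular
graph.  Atom compatibility is element + formal charge, with the wildcard
element ``R`` in a pattern matching any heavy target atom; bond
compatibility is exact order equality unless ``order_strict`` is disabled,
in which case orders inter-match (used by tautomer validation, where single
and double bonds are interchangeable).

All searches are deterministic: candidates are visited in sorted order and
results are returned canonically sorted, so repeated runs and permuted
inputs give identical answers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chemgraph import Molecule


@dataclass(frozen=True)
class MatchOptions:
    ignore_r_h: bool = False   # strip R atoms from the pattern before matching
    order_strict: bool = True  # exact bond-order equality


@dataclass(frozen=True)
class AtomMatch:
    """Injective, label- and bond-preserving embedding."""
    mapping: tuple[tuple[int, int], ...]          # (pattern atom, target atom)
    matched_bonds: frozenset[tuple[int, int]] = frozenset()

    @classmethod
    def from_dict(cls, mapping: dict[int, int], bonds=()) -> "AtomMatch":
        return cls(tuple(sorted(mapping.items())),
                   frozenset(tuple(sorted(b)) for b in bonds))

    def as_dict(self) -> dict[int, int]:
        return dict(self.mapping)

    def __len__(self) -> int:
        return len(self.mapping)


class _Graph:
    """Hydrogen-suppressed adjacency view of a molecule."""

    def __init__(self, mol: Molecule, drop_r: bool = False):
        self.mol = mol
        self.nodes = sorted(mol.heavy_indices(include_r=not drop_r))
        keep = set(self.nodes)
        self.adj: dict[int, dict[int, int]] = {i: {} for i in self.nodes}
        for bd in mol.bonds:
            if bd.a in keep and bd.b in keep:
                self.adj[bd.a][bd.b] = bd.order
                self.adj[bd.b][bd.a] = bd.order

    def label(self, i: int):
        a = self.mol.atom(i)
        return (a.element, a.charge)

    def degree(self, i: int) -> int:
        return len(self.adj[i])


def _atom_compat(pg: _Graph, tg: _Graph, p: int, t: int) -> bool:
    pe, pc = pg.label(p)
    te, tc = tg.label(t)
    if pe == "R":
        return True                      # wildcard: any heavy atom
    return pe == te and pc == tc


def _bond_compat(po: int, to: int, order_strict: bool) -> bool:
    return po == to if order_strict else True


def _search(pg: _Graph, tg: _Graph, options: MatchOptions,
            first_only: bool = False,
            require_full: bool = False) -> list[AtomMatch]:
    if not pg.nodes or not tg.nodes:
        return []
    if require_full and len(pg.nodes) != len(tg.nodes):
        return []

    # candidate sets with degree pruning (valid for monomorphisms)
    cand = {}
    for p in pg.nodes:
        cs = [t for t in tg.nodes
              if _atom_compat(pg, tg, p, t) and pg.degree(p) <= tg.degree(t)]
        if not cs:
            return []
        cand[p] = cs

    # fail-first ordering: fewest candidates first, then keep the pattern
    # connected so mapped-neighbor constraints apply as early as possible
    order: list[int] = []
    placed: set[int] = set()
    remaining = set(pg.nodes)
    while remaining:
        adjacent = [p for p in remaining if any(q in placed for q in pg.adj[p])]
        pool = adjacent or sorted(remaining)
        nxt = min(pool, key=lambda p: (len(cand[p]), -pg.degree(p), p))
        order.append(nxt)
        placed.add(nxt)
        remaining.discard(nxt)

    results: list[AtomMatch] = []
    mapping: dict[int, int] = {}
    used: set[int] = set()

    def backtrack(pos: int) -> bool:
        if pos == len(order):
            bonds = [(a, b) for a in mapping for b, _ in pg.adj[a].items()
                     if a < b and b in mapping]
            results.append(AtomMatch.from_dict(mapping, bonds))
            return first_only
        p = order[pos]
        for t in cand[p]:
            if t in used:
                continue
            ok = True
            for q, po in pg.adj[p].items():
                if q in mapping:
                    to = tg.adj[t].get(mapping[q])
                    if to is None or not _bond_compat(po, to, options.order_strict):
                        ok = False
                        break
            if ok:
                mapping[p] = t
                used.add(t)
                if backtrack(pos + 1):
                    return True
                del mapping[p]
                used.discard(t)
        return False

    backtrack(0)
    return sorted(results, key=lambda m: m.mapping)


def subgraph_search(pattern: Molecule, target: Molecule,
                    options: MatchOptions = MatchOptions()) -> list[AtomMatch]:
    """All distinct embeddings of ``pattern`` into ``target``.

    Embeddings are injective on atoms; every pattern bond must map onto a
    target bond of compatible order (monomorphism — the target may hold
    extra bonds between matched atoms).  With ``ignore_r_h`` the pattern is
    stripped of R atoms (explicit H is always excluded on both sides); the
    returned indices still refer to the original pattern numbering.
    """
    pg = _Graph(pattern, drop_r=options.ignore_r_h)
    tg = _Graph(target)
    return _search(pg, tg, options)


def graph_isomorphism(a: Molecule, b: Molecule,
                      options: MatchOptions = MatchOptions()) -> AtomMatch | None:
    """Full bijection between the heavy graphs of ``a`` and ``b``, if any."""
    ga, gb = _Graph(a), _Graph(b)
    if len(ga.nodes) != len(gb.nodes):
        return None
    if sorted(ga.label(i) for i in ga.nodes) != sorted(gb.label(i) for i in gb.nodes):
        return None
    na = sum(len(v) for v in ga.adj.values())
    nb = sum(len(v) for v in gb.adj.values())
    if na != nb:
        return None
    res = _search(ga, gb, options, first_only=True, require_full=True)
    return res[0] if res else None


def all_isomorphisms(a: Molecule, b: Molecule,
                     options: MatchOptions = MatchOptions(),
                     limit: int = 1000) -> list[AtomMatch]:
    """Every heavy-graph bijection between ``a`` and ``b`` (capped)."""
    ga, gb = _Graph(a), _Graph(b)
    if len(ga.nodes) != len(gb.nodes):
        return []
    res = _search(ga, gb, options, require_full=True)
    return res[:limit]


def maximum_common_subgraph(a: Molecule, b: Molecule,
                            anchors: dict[int, int] | None = None,
                            options: MatchOptions = MatchOptions()) -> AtomMatch:
    """Maximum connected-extension common subgraph of ``a`` and ``b``.

    Grows an atom mapping outward from ``anchors`` (or from every
    label-compatible seed pair when no anchors are given); each added pair
    must be bond-consistent with everything already mapped, i.e. a bond
    between mapped ``a``-atoms exists iff a compatible bond exists between
    their images.  Returns the mapping with the most atoms; ties broken by
    (1) more matched bonds, (2) lexicographically smallest mapping.
    """
    ga, gb = _Graph(a), _Graph(b)
    anchors = dict(anchors or {})
    for p, t in anchors.items():
        if p not in ga.adj or t not in gb.adj or not _atom_compat(ga, gb, p, t):
            raise ValueError(f"anchor {p}->{t} violates atom labels")
    if len(set(anchors.values())) != len(anchors):
        raise ValueError("anchor mapping is not injective")
    for p, t in anchors.items():
        for q, u in anchors.items():
            if p < q:
                po, to = ga.adj[p].get(q), gb.adj[t].get(u)
                if (po is None) != (to is None):
                    raise ValueError(f"anchors {p},{q} violate bond structure")
                if po is not None and not _bond_compat(po, to, options.order_strict):
                    raise ValueError(f"anchors {p},{q} violate bond orders")

    best: dict = {"map": dict(anchors), "bonds": -1, "key": None}

    def consistent(mapping, p, t) -> bool:
        if not _atom_compat(ga, gb, p, t):
            return False
        for q, u in mapping.items():
            po, to = ga.adj[p].get(q), gb.adj[t].get(u)
            if (po is None) != (to is None):
                return False
            if po is not None and not _bond_compat(po, to, options.order_strict):
                return False
        return True

    def matched_bond_count(mapping) -> int:
        return sum(1 for p in mapping for q in ga.adj[p] if p < q and q in mapping)

    def record(mapping) -> None:
        n, nb = len(mapping), matched_bond_count(mapping)
        key = tuple(sorted(mapping.items()))
        cur = (len(best["map"]), best["bonds"])
        if (n, nb) > cur or ((n, nb) == cur and
                             (best["key"] is None or key < best["key"])):
            best["map"] = dict(mapping)
            best["bonds"] = nb
            best["key"] = key

    def candidates(mapping, used_t, excluded):
        if not mapping:
            pool = ((p, t) for p in ga.nodes for t in gb.nodes)
        else:
            fp = sorted({q for p in mapping for q in ga.adj[p] if q not in mapping})
            ft = {u for t in mapping.values() for u in gb.adj[t] if u not in used_t}
            pool = ((p, t) for p in fp for t in sorted(ft))
        return [(p, t) for p, t in pool
                if (p, t) not in excluded and t not in used_t
                and p not in mapping and consistent(mapping, p, t)]

    def extend(mapping, used_t, excluded) -> None:
        bound = len(mapping) + min(len(ga.nodes) - len(mapping),
                                   len(gb.nodes) - len(used_t))
        if bound < len(best["map"]):
            return
        cands = candidates(mapping, used_t, excluded)
        if not cands:
            record(mapping)
            return
        p, t = cands[0]
        mapping[p] = t
        used_t.add(t)
        extend(mapping, used_t, excluded)
        del mapping[p]
        used_t.discard(t)
        extend(mapping, used_t, excluded | {(p, t)})

    if best["map"]:
        best["bonds"] = matched_bond_count(best["map"])
        best["key"] = tuple(sorted(best["map"].items()))
    extend(dict(anchors), set(anchors.values()), frozenset())
    m = best["map"]
    bonds = [(p, q) for p in m for q in ga.adj[p] if p < q and q in m]
    return AtomMatch.from_dict(m, bonds)
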