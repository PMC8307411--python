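"""Hand-built molecules and independent brute-force oracles for the tests.

The oracles deliberately share no code with the package's matchers: they
enumerate injections/permutations directly, so agreement is meaningful.
"""

from __future__ import annotations

import itertools

from molharmony.chemgraph import Atom, Bond, Molecule


# -- tiny named molecules -----------------------------------------------------

def ethanol(id="ethanol"):
    return Molecule(id, [Atom(1, "C"), Atom(2, "C"), Atom(3, "O")],
                    [Bond(1, 2, 1), Bond(2, 3, 1)])


def ethylamine(id="ethylamine"):
    return Molecule(id, [Atom(1, "C"), Atom(2, "C"), Atom(3, "N")],
                    [Bond(1, 2, 1), Bond(2, 3, 1)])


def propane(id="propane"):
    return Molecule(id, [Atom(i, "C") for i in (1, 2, 3)],
                    [Bond(1, 2, 1), Bond(2, 3, 1)])


def butane(id="butane"):
    return Molecule(id, [Atom(i, "C") for i in range(1, 5)],
                    [Bond(i, i + 1, 1) for i in range(1, 4)])


def isobutane(id="isobutane"):
    return Molecule(id, [Atom(i, "C") for i in range(1, 5)],
                    [Bond(1, 2, 1), Bond(1, 3, 1), Bond(1, 4, 1)])


def ring6(id="ring6"):
    return Molecule(id, [Atom(i, "C") for i in range(1, 7)],
                    [Bond(i, i % 6 + 1, 1) for i in range(1, 7)])


def carboxylate(id="carboxylate"):
    """C-C(=O)(-O^-): the two terminal oxygens are resonance partners."""
    return Molecule(id, [Atom(1, "C"), Atom(2, "C"), Atom(3, "O"),
                         Atom(4, "O", charge=-1)],
                    [Bond(1, 2, 1), Bond(2, 3, 2), Bond(2, 4, 1)])


def r_ch2_oh(id="r_ch2_oh"):
    """Generic fragment R-CH2-OH."""
    return Molecule(id, [Atom(1, "R", is_r=True), Atom(2, "C"), Atom(3, "O")],
                    [Bond(1, 2, 1), Bond(2, 3, 1)])


# -- brute-force oracles ------------------------------------------------------

def _heavy(mol: Molecule, drop_r=False):
    return sorted(mol.heavy_indices(include_r=not drop_r))


def _label(mol, i):
    a = mol.atom(i)
    return (a.element, a.charge)


def _order(mol, i, j):
    bd = mol.bond_between(i, j)
    if bd is None:
        return None
    return bd.order


def _compat(pm, tm, p, t):
    pe, pc = _label(pm, p)
    te, _ = _label(tm, t)
    if te == "H":
        return False
    if pe == "R":
        return True
    return _label(pm, p) == _label(tm, t)


def brute_embeddings(pattern: Molecule, target: Molecule,
                     order_strict=True, drop_r=False):
    """All monomorphic embeddings, by exhaustive enumeration."""
    pn = _heavy(pattern, drop_r=drop_r)
    tn = _heavy(target)
    out = []
    for perm in itertools.permutations(tn, len(pn)):
        m = dict(zip(pn, perm))
        ok = all(_compat(pattern, target, p, t) for p, t in m.items())
        if ok:
            for i, j in itertools.combinations(pn, 2):
                po = _order(pattern, i, j)
                if po is None:
                    continue
                to = _order(target, m[i], m[j])
                if to is None or (order_strict and po != to):
                    ok = False
                    break
        if ok:
            out.append(tuple(sorted(m.items())))
    return sorted(set(out))


def brute_isomorphism(a: Molecule, b: Molecule, order_strict=True):
    """Any full heavy-atom bijection preserving labels and bonds."""
    an, bn = _heavy(a), _heavy(b)
    if len(an) != len(bn):
        return None
    for perm in itertools.permutations(bn):
        m = dict(zip(an, perm))
        if not all(_compat(a, b, p, t) and _compat(b, a, t, p)
                   for p, t in m.items()):
            continue
        good = True
        for i, j in itertools.combinations(an, 2):
            po, to = _order(a, i, j), _order(b, m[i], m[j])
            if (po is None) != (to is None):
                good = False
                break
            if po is not None and order_strict and po != to:
                good = False
                break
        if good:
            return m
    return None


def _connected_subsets(mol: Molecule, nodes):
    """All connected subsets of the heavy graph, by BFS growth."""
    adj = {i: set(mol.heavy_neighbors(i)) for i in nodes}
    found = set()
    for seed in nodes:
        frontier = [frozenset([seed])]
        while frontier:
            s = frontier.pop()
            if s in found:
                continue
            found.add(s)
            reach = {j for i in s for j in adj[i]} - set(s)
            for j in reach:
                found.add(s)  # no-op clarity
                frontier.append(s | {j})
    return found


def brute_mcs_size(a: Molecule, b: Molecule, order_strict=True):
    """(atoms, bonds) of the maximum connected common induced subgraph."""
    an, bn = _heavy(a), _heavy(b)
    best = (0, 0)
    for subset in _connected_subsets(a, an):
        sub = sorted(subset)
        if len(sub) < best[0]:
            continue
        for perm in itertools.permutations(bn, len(sub)):
            m = dict(zip(sub, perm))
            if not all(_compat(a, b, p, t) and _compat(b, a, t, p)
                       for p, t in m.items()):
                continue
            good = True
            nb = 0
            for i, j in itertools.combinations(sub, 2):
                po, to = _order(a, i, j), _order(b, m[i], m[j])
                if (po is None) != (to is None):
                    good = False
                    break
                if po is not None:
                    if order_strict and po != to:
                        good = False
                        break
                    nb += 1
            if good and (len(sub), nb) > best:
                best = (len(sub), nb)
    return best


def brute_orbits(mol: Molecule):
    """Automorphism orbits of the heavy graph, by permutation enumeration."""
    nodes = _heavy(mol)
    orbit_of = {i: {i} for i in nodes}
    for perm in itertools.permutations(nodes):
        m = dict(zip(nodes, perm))
        if not all(_label(mol, i) == _label(mol, m[i]) for i in nodes):
            continue
        good = True
        for i, j in itertools.combinations(nodes, 2):
            if _order(mol, i, j) != _order(mol, m[i], m[j]):
                good = False
                break
        if good:
            for i in nodes:
                orbit_of[i].add(m[i])
    # merge into disjoint orbits
    orbits = []
    seen = set()
    for i in nodes:
        if i in seen:
            continue
        stack, group = [i], set()
        while stack:
            x = stack.pop()
            if x in group:
                continue
            group.add(x)
            stack.extend(orbit_of[x] - group)
        seen |= group
        orbits.append(sorted(group))
    return sorted(orbits)
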