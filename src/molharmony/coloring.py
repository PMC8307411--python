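"""Neighborhood-specific graph coloring.

Every atom receives a canonical color string built by iterative refinement
of its bonded neighborhood (Morgan-style): the base invariant is the
element plus charge (plus stereo descriptors in *detailed* mode), and each
round appends the sorted list of (bond label, neighbor color) pairs.
Automorphic atoms end with identical colors, and the sorted multiset of
final colors — prefixed with the molecular formula — is the *compound
coloring identifier* used for cross-database compound detection.

Two resolutions are exposed:

* ``loose``   — stereo descriptors excluded; the working identifier for
  pair detection, robust to the stereo annotation gaps that are common
  across databases.
* ``detailed`` — atom parity and double-bond cis/trans included; used to
  rank how specifically two paired compounds agree.

To keep color strings bounded, neighbor colors are referenced through their
rank in the sorted set of the previous round's colors.  Ranks are derived
from sorted strings only, so the construction is invariant to input atom
order and identical across isomorphic molecules.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chemgraph import (AROMATIC, CT_CIS, CT_TRANS, Molecule, PARITY_CCW,
                        PARITY_CW)

LOOSE = "loose"
DETAILED = "detailed"

_BOND_LABEL = {1: "1", 2: "2", 3: "3", AROMATIC: "a"}


@dataclass(frozen=True)
class AtomColor:
    atom_index: int
    color: str
    depth: int


@dataclass(frozen=True)
class CompoundIdentifier:
    value: str
    mode: str


def _bond_label(bond, mode: str) -> str:
    lab = _BOND_LABEL.get(bond.order, str(bond.order))
    if mode == DETAILED and bond.order == 2 and bond.cis_trans in (CT_CIS, CT_TRANS):
        lab += bond.cis_trans[0]
    return lab


def _base_invariant(mol: Molecule, i: int, mode: str) -> str:
    a = mol.atom(i)
    s = a.element
    if a.charge:
        s += f"{a.charge:+d}"
    s += f"H{mol.h_count(i)}"
    if mode == DETAILED and a.parity in (PARITY_CW, PARITY_CCW):
        s += "@1" if a.parity == PARITY_CW else "@2"
    return s


def color_atoms(mol: Molecule, mode: str = LOOSE) -> list[AtomColor]:
    """Iteratively refined atom colors on the hydrogen-suppressed graph.

    Refinement stops once the partition into color classes is stable across
    a round (capped at the atom count).  Equal color strings imply equal
    rooted neighborhoods up to the refinement depth.
    """
    if mode not in (LOOSE, DETAILED):
        raise ValueError(f"unknown coloring mode {mode!r}")
    nodes = mol.heavy_indices()
    if not nodes:                       # e.g. a lone explicit-H "molecule"
        nodes = [a.index for a in mol.atoms]
    if not nodes:
        raise ValueError("cannot color an empty molecule")
    node_set = set(nodes)

    base = {i: _base_invariant(mol, i, mode) for i in nodes}
    colors = dict(base)
    n_classes = len(set(colors.values()))
    depth = 0
    for _ in range(len(nodes)):
        ranks = {c: r for r, c in enumerate(sorted(set(colors.values())))}
        new = {}
        for i in nodes:
            nbr = sorted(
                f"{_bond_label(bd, mode)}:{ranks[colors[bd.other(i)]]}"
                for bd in mol.bonds_of(i) if bd.other(i) in node_set)
            new[i] = base[i] + "[" + "|".join(nbr) + "]"
        depth += 1
        colors = new
        n_new = len(set(colors.values()))
        if n_new == n_classes:
            break
        n_classes = n_new
    return [AtomColor(i, f"d{depth}:{colors[i]}", depth) for i in sorted(nodes)]


def compound_identifier(mol: Molecule, mode: str = LOOSE) -> CompoundIdentifier:
    """Canonical whole-compound identifier.

    Formula header (H excluded, elements sorted, R counted separately)
    followed by the sorted multiset of final atom colors.  Deterministic and
    invariant to input atom order; identical for isomorphic molecules.
    """
    formula = mol.formula(include_h=False)
    header = "".join(f"{el}{n}" for el, n in sorted(formula.items()))
    cols = sorted(ac.color for ac in color_atoms(mol, mode))
    return CompoundIdentifier(value=header + "//" + "|".join(cols), mode=mode)


def one_bond_color(mol: Molecule, atom_index: int) -> str:
    """Color from exactly one refinement round, H counts excluded.

    ``element(+charge)`` followed by the sorted ``(bond order, neighbor
    element)`` list, e.g. the central carbon of propane is ``C(1:C)(1:C)``.
    This is the locality probe behind the mapping-consistency metric: the
    one-bond color of an atom changes exactly when a bond incident to it is
    made, broken, or changes order.
    """
    a = mol.atom(atom_index)
    s = a.element
    if a.charge:
        s += f"{a.charge:+d}"
    nbr = sorted(
        f"({_bond_label(bd, LOOSE)}:{mol.atom(bd.other(atom_index)).element})"
        for bd in mol.bonds_of(atom_index)
        if mol.atom(bd.other(atom_index)).element != "H")
    return s + "".join(nbr)


def symmetry_classes(mol: Molecule, mode: str = LOOSE) -> list[list[int]]:
    """Partition of heavy-atom indices by final refined color.

    Refinement-equivalent atoms share a class; on small graphs the partition
    is no finer than the true automorphism orbits (refinement never splits
    an orbit), though it may merge non-automorphic atoms in pathological
    regular graphs.
    """
    groups: dict[str, list[int]] = {}
    for ac in color_atoms(mol, mode):
        groups.setdefault(ac.color, []).append(ac.atom_index)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def write_identifier_tsv(rows, path) -> None:
    """Export ``(compound_id, mode, identifier)`` rows as TSV."""
    with open(path, "w") as fh:
        fh.write("compound_id\tmode\tidentifier\n")
        for cid, mode, ident in rows:
            fh.write(f"{cid}\t{mode}\t{ident}\n")
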