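"""Molecular graphs, molfile/KCF readers, and 2D stereo perception.

Compounds from metabolic databases arrive as MDL molfile V2000 connection
tables or as KEGG KCF blocks (a molfile-like table that additionally carries
KEGG atom types).  Both are parsed into the same :class:`Molecule` container:
a labeled graph of :class:`Atom` and :class:`Bond` records keeping the
1-based atom numbering of the source file, which every downstream atom
mapping refers to.

Stereochemistry is perceived from the 2D drawing itself: atom parity from
wedge/hash bond annotations, and cis/trans labels for double bonds from the
geometric split of the plane along the bond axis.  The cis/trans procedure
handles hetero double bonds (e.g. C=N) as well as C=C.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace

logger = logging.getLogger(__name__)

# -- label vocabularies -------------------------------------------------------

PARITY_NONE = "none"
PARITY_CW = "clockwise"
PARITY_CCW = "counterclockwise"
PARITY_UNKNOWN = "unknown"

WEDGE_NONE = "none"
WEDGE_UP = "up"
WEDGE_DOWN = "down"

CT_NONE = "none"
CT_CIS = "cis"
CT_TRANS = "trans"
CT_UNRESOLVED = "unresolved"

AROMATIC = 4  # molfile bond order code 4; taken from input, never perceived

#: molfile symbols normalized to the wildcard element "R"
R_SYMBOLS = {"R", "R#", "*", "A", "X", "Q"}

#: atomic numbers for substituent priority ranking; R ranks below everything
ATOMIC_NUMBERS = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16,
    "Cl": 17, "Br": 35, "I": 53, "Se": 34, "Si": 14, "As": 33, "R": 0,
}

GEOM_TOL = 1e-6  # coordinate-space tolerance for colinearity decisions

_CHARGE_CODES = {0: 0, 1: 3, 2: 2, 3: 1, 4: 0, 5: -1, 6: -2, 7: -3}
_WEDGE_CODES = {0: WEDGE_NONE, 1: WEDGE_UP, 6: WEDGE_DOWN}


class MolfileParseError(ValueError):
    """Raised when a connection-table block cannot be parsed."""


class StructureError(ValueError):
    """Raised when a parsed table is internally inconsistent."""


@dataclass
class Atom:
    index: int                      # 1-based, molfile order
    element: str                    # "C", "N", ... or "R" for any wildcard
    charge: int = 0
    x: float = 0.0
    y: float = 0.0
    parity: str = PARITY_NONE
    kegg_type: str | None = None    # opaque KEGG atom-type label, e.g. "C1a"
    is_r: bool = False


@dataclass
class Bond:
    a: int
    b: int
    order: int = 1                  # 1, 2, 3 or AROMATIC (4)
    wedge: str = WEDGE_NONE         # narrow end at atom ``a``
    cis_trans: str = CT_NONE

    def key(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)

    def other(self, i: int) -> int:
        return self.b if i == self.a else self.a


class Molecule:
    """Labeled molecular graph with 1-based atom indices.

    Explicit hydrogens are parsed and kept, but matching and coloring work
    on the hydrogen-suppressed view (``heavy_indices`` / ``h_count``).
    """

    def __init__(self, id: str, atoms: list[Atom], bonds: list[Bond],
                 source: str = "molfile"):
        self.id = id
        self.atoms = list(atoms)
        self.bonds = list(bonds)
        self.source = source
        seen = set()
        for a in self.atoms:
            if a.index in seen:
                raise StructureError(f"{id}: duplicate atom index {a.index}")
            seen.add(a.index)
        self._atom = {a.index: a for a in self.atoms}
        pairs = set()
        for bd in self.bonds:
            if bd.a == bd.b:
                raise StructureError(f"{id}: self-bond on atom {bd.a}")
            if bd.a not in self._atom or bd.b not in self._atom:
                raise StructureError(
                    f"{id}: bond {bd.a}-{bd.b} references a missing atom")
            if bd.key() in pairs:
                raise StructureError(f"{id}: duplicate bond {bd.key()}")
            pairs.add(bd.key())
        self._adj: dict[int, list[Bond]] = {a.index: [] for a in self.atoms}
        for bd in self.bonds:
            self._adj[bd.a].append(bd)
            self._adj[bd.b].append(bd)

    # -- accessors ------------------------------------------------------------

    def atom(self, i: int) -> Atom:
        return self._atom[i]

    def has_atom(self, i: int) -> bool:
        return i in self._atom

    def bonds_of(self, i: int) -> list[Bond]:
        return self._adj[i]

    def neighbors(self, i: int) -> list[int]:
        return [bd.other(i) for bd in self._adj[i]]

    def bond_between(self, i: int, j: int) -> Bond | None:
        for bd in self._adj[i]:
            if bd.other(i) == j:
                return bd
        return None

    def heavy_indices(self, include_r: bool = True) -> list[int]:
        out = []
        for a in self.atoms:
            if a.element == "H":
                continue
            if a.element == "R" and not include_r:
                continue
            out.append(a.index)
        return out

    def heavy_neighbors(self, i: int, include_r: bool = True) -> list[int]:
        out = []
        for j in self.neighbors(i):
            e = self._atom[j].element
            if e == "H" or (e == "R" and not include_r):
                continue
            out.append(j)
        return out

    def h_count(self, i: int) -> int:
        """Number of explicit hydrogen neighbors of atom ``i``."""
        return sum(1 for j in self.neighbors(i) if self._atom[j].element == "H")

    def formula(self, include_h: bool = True) -> dict[str, int]:
        """Element counts; R wildcards counted as their own pseudo-element."""
        out: dict[str, int] = {}
        for a in self.atoms:
            if a.element == "H" and not include_h:
                continue
            out[a.element] = out.get(a.element, 0) + 1
        return out

    def copy(self, new_id: str | None = None) -> "Molecule":
        return Molecule(new_id or self.id,
                        [replace(a) for a in self.atoms],
                        [replace(b) for b in self.bonds],
                        self.source)

    def subgraph(self, indices, new_id: str | None = None):
        """Reindexed sub-molecule on ``indices``.

        Returns ``(molecule, old_to_new)`` where atoms are renumbered 1..k in
        ascending original order.
        """
        keep = sorted(set(indices))
        old_to_new = {old: new for new, old in enumerate(keep, start=1)}
        atoms = [replace(self._atom[old], index=old_to_new[old]) for old in keep]
        bonds = [replace(bd, a=old_to_new[bd.a], b=old_to_new[bd.b])
                 for bd in self.bonds
                 if bd.a in old_to_new and bd.b in old_to_new]
        return Molecule(new_id or self.id, atoms, bonds, self.source), old_to_new

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (f"Molecule({self.id!r}, {len(self.atoms)} atoms, "
                f"{len(self.bonds)} bonds)")


# -- molfile V2000 ------------------------------------------------------------

def parse_molfile(text: str, id: str | None = None) -> Molecule:
    """Parse an MDL molfile V2000 block into a :class:`Molecule`.

    Atom order and 1-based numbering follow the atom block.  R-group symbols
    (:data:`R_SYMBOLS`) are normalized to element ``"R"`` with ``is_r`` set.
    ``M  CHG`` property lines override atom-line charge codes, resetting all
    atom-line charges first, per the V2000 convention.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileParseError("molfile too short: no counts line (line 4)")
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise MolfileParseError(f"malformed counts line: {counts!r}") from None
    if len(lines) < 4 + n_atoms + n_bonds:
        raise MolfileParseError(
            f"counts line declares {n_atoms} atoms / {n_bonds} bonds "
            "but the block is shorter")

    atoms: list[Atom] = []
    for i in range(n_atoms):
        line = lines[4 + i]
        try:
            x = float(line[0:10])
            y = float(line[10:20])
            symbol = line[31:34].strip()
            if not symbol:
                raise ValueError
        except (ValueError, IndexError):
            # tolerant fallback for loosely formatted (hand-written) blocks
            parts = line.split()
            if len(parts) < 4:
                raise MolfileParseError(
                    f"malformed atom line {4 + i + 1}: {line!r}") from None
            x, y, symbol = float(parts[0]), float(parts[1]), parts[3]
        code = 0
        if len(line) >= 39:
            try:
                code = int(line[36:39])
            except ValueError:
                code = 0
        is_r = symbol in R_SYMBOLS
        atoms.append(Atom(index=i + 1,
                          element="R" if is_r else symbol,
                          charge=_CHARGE_CODES.get(code, 0),
                          x=x, y=y, is_r=is_r))

    bonds: list[Bond] = []
    for i in range(n_bonds):
        line = lines[4 + n_atoms + i]
        try:
            a = int(line[0:3])
            b = int(line[3:6])
            order = int(line[6:9])
            stereo = int(line[9:12]) if len(line) >= 12 and line[9:12].strip() else 0
        except (ValueError, IndexError):
            parts = line.split()
            if len(parts) < 3:
                raise MolfileParseError(
                    f"malformed bond line {4 + n_atoms + i + 1}: {line!r}") from None
            a, b, order = int(parts[0]), int(parts[1]), int(parts[2])
            stereo = int(parts[3]) if len(parts) > 3 else 0
        if not (1 <= a <= n_atoms) or not (1 <= b <= n_atoms):
            raise StructureError(
                f"bond line {4 + n_atoms + i + 1} references missing atom "
                f"index ({a}, {b})")
        bonds.append(Bond(a=a, b=b, order=order,
                          wedge=_WEDGE_CODES.get(stereo, WEDGE_NONE)))

    chg: dict[int, int] = {}
    saw_chg = False
    for line in lines[4 + n_atoms + n_bonds:]:
        if line.startswith("M  END"):
            break
        if line.startswith("M  CHG"):
            saw_chg = True
            parts = line.split()
            n = int(parts[2])
            for k in range(n):
                chg[int(parts[3 + 2 * k])] = int(parts[4 + 2 * k])
    if saw_chg:
        for a in atoms:
            a.charge = chg.get(a.index, 0)

    mol_id = id if id is not None else (lines[0].strip() or "unnamed")
    return Molecule(mol_id, atoms, bonds, source="molfile")


_REV_CHARGE = {0: 0, 3: 1, 2: 2, 1: 3, -1: 5, -2: 6, -3: 7}
_REV_WEDGE = {WEDGE_NONE: 0, WEDGE_UP: 1, WEDGE_DOWN: 6}


def write_molfile(mol: Molecule) -> str:
    """Serialize to a V2000 block with deterministic field widths."""
    out = [mol.id, "  molharmony", ""]
    out.append(f"{len(mol.atoms):3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    charged = []
    for a in mol.atoms:
        symbol = "R#" if a.is_r else a.element
        out.append(f"{a.x:10.4f}{a.y:10.4f}{0.0:10.4f} {symbol:<3s} 0{_REV_CHARGE.get(a.charge, 0):3d}  0  0  0  0  0  0  0  0  0  0")
        if a.charge != 0:
            charged.append(a)
    for bd in mol.bonds:
        out.append(f"{bd.a:3d}{bd.b:3d}{bd.order:3d}{_REV_WEDGE[bd.wedge]:3d}  0  0  0")
    for a in charged:
        out.append(f"M  CHG  1 {a.index:3d} {a.charge:3d}")
    out.append("M  END")
    return "\n".join(out) + "\n"


# -- KEGG KCF -----------------------------------------------------------------

_KNOWN_KCF_ELEMENTS = {"C", "N", "O", "S", "P", "H", "F", "R", "X", "Z", "I", "B"}


def parse_kcf(text: str, id: str | None = None) -> Molecule:
    """Parse a KEGG KCF block.

    ``kegg_type`` is taken verbatim from column 2 of the ATOM section; the
    element is inferred from the leading alphabetic prefix of the type
    (``"C1a"`` -> C).  Unknown type tokens are kept verbatim with a warning.
    """
    lines = text.splitlines()
    entry_id = id
    atom_at = bond_at = None
    n_atoms = n_bonds = 0
    for ln, line in enumerate(lines):
        if line.startswith("ENTRY") and entry_id is None:
            parts = line.split()
            if len(parts) > 1:
                entry_id = parts[1]
        elif line.startswith("ATOM"):
            atom_at = ln
            n_atoms = int(line.split()[1])
        elif line.startswith("BOND"):
            bond_at = ln
            n_bonds = int(line.split()[1])
    if atom_at is None:
        raise MolfileParseError("KCF block has no ATOM section")

    atoms: list[Atom] = []
    for i in range(n_atoms):
        parts = lines[atom_at + 1 + i].split()
        if len(parts) < 2:
            raise MolfileParseError(
                f"malformed KCF atom line: {lines[atom_at + 1 + i]!r}")
        idx = int(parts[0])
        ktype = parts[1]
        m = re.match(r"([A-Za-z]+)", ktype)
        prefix = m.group(1) if m else ""
        element = prefix[:1].upper() if prefix else "R"
        if element not in _KNOWN_KCF_ELEMENTS:
            logger.warning("unknown KEGG atom type %r on atom %d; kept verbatim",
                           ktype, idx)
        floats = []
        for tok in parts[2:]:
            try:
                floats.append(float(tok))
            except ValueError:
                continue
        x = floats[0] if len(floats) > 0 else 0.0
        y = floats[1] if len(floats) > 1 else 0.0
        is_r = element == "R"
        atoms.append(Atom(index=idx, element=element, x=x, y=y,
                          kegg_type=ktype, is_r=is_r))

    bonds: list[Bond] = []
    if bond_at is not None:
        for i in range(n_bonds):
            parts = lines[bond_at + 1 + i].split()
            a, b, order = int(parts[1]), int(parts[2]), int(parts[3])
            bonds.append(Bond(a=a, b=b, order=order))

    return Molecule(entry_id or "unnamed", atoms, bonds, source="kcf")


# -- stereo perception --------------------------------------------------------

def assign_atom_parity(mol: Molecule) -> Molecule:
    """Perceive atom parity from wedge/hash annotations, in place.

    A stereocenter candidate is an atom with >= 3 distinct non-H neighbors.
    If a wedge/hash bond has its narrow end at the candidate, the wedged
    neighbor is lifted out of plane (up -> z=+1, down -> z=-1) and parity is
    the sign of the signed volume spanned by the neighbors ordered by index
    (candidates with three neighbors use the candidate's own position as the
    in-plane fourth reference point).  Candidates without usable wedge
    information get ``unknown``, never ``none``.
    """
    for atom in mol.atoms:
        nbrs = mol.heavy_neighbors(atom.index)
        if len(nbrs) < 3:
            atom.parity = PARITY_NONE
            continue
        z = {}
        misplaced = False
        for bd in mol.bonds_of(atom.index):
            if bd.wedge == WEDGE_NONE:
                continue
            if bd.a == atom.index:
                z[bd.b] = 1.0 if bd.wedge == WEDGE_UP else -1.0
            else:
                misplaced = True
        if not z:
            if misplaced:
                logger.warning(
                    "%s: wedge narrow end not at stereocenter candidate %d",
                    mol.id, atom.index)
            atom.parity = PARITY_UNKNOWN
            continue
        pts = []
        for j in sorted(nbrs):
            nb = mol.atom(j)
            pts.append((nb.x, nb.y, z.get(j, 0.0)))
        if len(pts) == 3:
            pts.append((atom.x, atom.y, 0.0))
        v1 = tuple(pts[1][k] - pts[0][k] for k in range(3))
        v2 = tuple(pts[2][k] - pts[0][k] for k in range(3))
        v3 = tuple(pts[3][k] - pts[0][k] for k in range(3))
        det = (v1[0] * (v2[1] * v3[2] - v2[2] * v3[1])
               - v1[1] * (v2[0] * v3[2] - v2[2] * v3[0])
               + v1[2] * (v2[0] * v3[1] - v2[1] * v3[0]))
        if abs(det) < GEOM_TOL:
            atom.parity = PARITY_UNKNOWN
        else:
            atom.parity = PARITY_CCW if det > 0 else PARITY_CW
    return mol


def _priority_key(mol: Molecule, sub: int, exclude: int):
    """Substituent ranking key: element first, then immediate neighborhood."""
    a = mol.atom(sub)
    own = ATOMIC_NUMBERS.get(a.element, 0)
    env = sorted((ATOMIC_NUMBERS.get(mol.atom(j).element, 0)
                  for j in mol.heavy_neighbors(sub) if j != exclude),
                 reverse=True)
    return (own, tuple(env))


def classify_double_bond(mol: Molecule, bond: Bond) -> str:
    """Label a double bond ``cis``/``trans`` from the 2D drawing.

    One prioritized substituent is chosen per end: the only group when there
    is exactly one, otherwise the group ranking highest by element and then
    immediate neighborhood.  The plane is split by the line through the two
    double-bond atoms; prioritized groups on the same side give ``cis``,
    opposite sides ``trans``.  Ends without a substituent or with
    priority-equivalent top groups give ``none``; substituents lying on the
    dividing line within :data:`GEOM_TOL` give ``unresolved``.
    """
    if bond.order != 2:
        raise ValueError("classify_double_bond requires a double bond")
    pa, pb = mol.atom(bond.a), mol.atom(bond.b)
    dx, dy = pb.x - pa.x, pb.y - pa.y
    norm = math.hypot(dx, dy)
    if norm < GEOM_TOL:
        logger.warning("%s: degenerate double-bond geometry %d-%d",
                       mol.id, bond.a, bond.b)
        return CT_UNRESOLVED

    sides = []
    for end, other in ((bond.a, bond.b), (bond.b, bond.a)):
        subs = [j for j in mol.heavy_neighbors(end) if j != other]
        if not subs:
            return CT_NONE
        if len(subs) == 1:
            chosen = subs[0]
        else:
            ranked = sorted(subs,
                            key=lambda j: _priority_key(mol, j, end),
                            reverse=True)
            if _priority_key(mol, ranked[0], end) == _priority_key(mol, ranked[1], end):
                return CT_NONE
            chosen = ranked[0]
        c = mol.atom(chosen)
        cross = dx * (c.y - pa.y) - dy * (c.x - pa.x)
        if abs(cross) / norm < GEOM_TOL:
            logger.warning("%s: substituent %d colinear with double bond %d-%d",
                           mol.id, chosen, bond.a, bond.b)
            return CT_UNRESOLVED
        sides.append(cross > 0)
    return CT_CIS if sides[0] == sides[1] else CT_TRANS


def assign_cis_trans(mol: Molecule) -> Molecule:
    """Set ``cis_trans`` on every double bond of ``mol``, in place."""
    for bd in mol.bonds:
        if bd.order == 2:
            bd.cis_trans = classify_double_bond(mol, bd)
    return mol


def perceive_stereo(mol: Molecule) -> Molecule:
    """Convenience: atom parity + double-bond cis/trans, in place."""
    assign_atom_parity(mol)
    assign_cis_trans(mol)
    return mol
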