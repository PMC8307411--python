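"""KEGG RCLASS RDM parsing and compound-pair atom-mapping derivation.

An RDM description encodes a substrate/product transformation as a
reaction-center atom pair (R), the *different* region (D) — atoms bonded
to the center that change between the two sides — and the *matched*
region (M) of unchanged center neighbors, all expressed as KEGG atom-type
labels (``C1a``, ``S2a``, ...).

Atom mappings are derived by enumerating the candidate atoms each
reaction center can bind to on both sides, deleting the changed bonds
named by the different region, and running an anchored maximum common
subgraph search on what remains.  Among all center assignments the
optimal mapping maximizes the number of mapped atoms and, among ties,
minimizes the fraction of mapped atoms whose one-bond color changes.
Center-candidate combinatorics can explode on symmetric compounds with
many centers; a configurable cap turns that case into an explicit
:class:`CombinatorialLimit` error instead of an open-ended search.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass

from .chemgraph import Molecule, write_molfile
from .coloring import one_bond_color
from .substructure import maximum_common_subgraph

logger = logging.getLogger(__name__)

DEFAULT_COMBINATION_LIMIT = 10 ** 5


class RDMParseError(ValueError):
    pass


class MappingError(ValueError):
    """No consistent atom mapping could be derived."""


class CombinatorialLimit(RuntimeError):
    """Center-assignment combinations exceed the configured cap."""

    def __init__(self, count: int, limit: int):
        super().__init__(
            f"{count} center-assignment combinations exceed the cap {limit}")
        self.count = count
        self.limit = limit


@dataclass(frozen=True)
class RDMDescription:
    center: tuple[str, str]              # (substrate label, product label)
    diff_s: tuple[str, ...]
    diff_p: tuple[str, ...]
    matched_s: tuple[str, ...]
    matched_p: tuple[str, ...]


@dataclass(frozen=True)
class PairAtomMapping:
    compound_a: str
    compound_b: str
    pairs: tuple[tuple[int, int], ...]         # 1-based atom index pairs
    centers: frozenset[tuple[int, int]]

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def _split_side(tok: str) -> tuple[str, ...]:
    if tok == "*" or tok == "":
        return ()
    return tuple(tok.split("+"))


def _parse_triple(tok: str) -> RDMDescription:
    fields = tok.split(":")
    if len(fields) != 3:
        raise RDMParseError(f"malformed RDM triple {tok!r}: expected "
                            "center:difference:matched")
    sides = []
    for f in fields:
        if "-" not in f:
            raise RDMParseError(f"malformed RDM field {f!r} in {tok!r}")
        s, _, p = f.partition("-")
        sides.append((s, p))
    (rs, rp), (ds, dp), (ms, mp) = sides
    if rs in ("", "*") or rp in ("", "*"):
        raise RDMParseError(f"empty reaction center in {tok!r}")
    matched_s, matched_p = _split_side(ms), _split_side(mp)
    if len(matched_s) != len(matched_p):
        raise RDMParseError(
            f"matched regions differ in length in {tok!r}")
    return RDMDescription(center=(rs, rp),
                          diff_s=_split_side(ds), diff_p=_split_side(dp),
                          matched_s=matched_s, matched_p=matched_p)


def parse_rclass(definition: str) -> list[RDMDescription]:
    """Parse an RCLASS DEFINITION string into RDM descriptions.

    Triples are ``r_s-r_p:d_s-d_p:m_s-m_p`` with ``*`` for an empty region
    and ``+`` joining either whole triples or multiple labels within one
    field side; whitespace also separates triples.
    """
    out: list[RDMDescription] = []
    for token in definition.split():
        pieces = token.split("+")
        if len(pieces) > 1 and all(p.count(":") == 2 for p in pieces):
            for p in pieces:
                out.append(_parse_triple(p))
        else:
            out.append(_parse_triple(token))
    if not out:
        raise RDMParseError("empty RCLASS definition")
    return out


def read_rclass_file(path) -> dict[str, list[RDMDescription]]:
    """Read a KEGG-style flat file of ENTRY/DEFINITION blocks."""
    entries: dict[str, list[RDMDescription]] = {}
    entry = None
    buf: list[str] = []

    def flush():
        if entry is not None and buf:
            entries[entry] = parse_rclass(" ".join(buf))

    with open(path) as fh:
        for line in fh:
            if line.startswith("ENTRY"):
                flush()
                entry = line.split()[1]
                buf = []
            elif line.startswith("DEFINITION"):
                buf = [line[len("DEFINITION"):].strip()]
            elif line.startswith(" ") and buf:
                buf.append(line.strip())
            elif line.startswith("///"):
                flush()
                entry = None
                buf = []
    flush()
    return entries


# -- center candidates --------------------------------------------------------

def _label_element(label: str) -> str:
    m = re.match(r"([A-Za-z]+)", label)
    return m.group(1)[:1].upper() if m else "R"


def candidate_centers(mol: Molecule, label: str) -> set[int]:
    """Atoms of ``mol`` that can bind a reaction center of type ``label``.

    Matches by KEGG atom type when the molecule carries annotations;
    otherwise falls back to the element prefix of the label.
    """
    annotated = any(a.kegg_type for a in mol.atoms)
    if annotated:
        return {a.index for a in mol.atoms if a.kegg_type == label}
    logger.warning("%s: no KEGG atom types; falling back to element matching "
                   "for label %r", mol.id, label)
    el = _label_element(label)
    return {a.index for a in mol.atoms if a.element == el}


# -- mapping derivation -------------------------------------------------------

def _remove_diff_bonds(mol: Molecule, center: int, labels) -> list[Molecule]:
    """All copies of ``mol`` with one center bond removed per diff label."""
    if not labels:
        return [mol]
    annotated = any(a.kegg_type for a in mol.atoms)

    def matches(idx: int, label: str) -> bool:
        a = mol.atom(idx)
        return (a.kegg_type == label) if annotated else \
            (a.element == _label_element(label))

    choice_sets = []
    for label in labels:
        nbrs = [j for j in mol.heavy_neighbors(center) if matches(j, label)]
        if not nbrs:
            return []
        choice_sets.append(nbrs)
    results = []
    for combo in itertools.product(*choice_sets):
        if len(set(combo)) != len(combo):
            continue
        out = mol.copy()
        drop = {tuple(sorted((center, j))) for j in combo}
        out.bonds = [bd for bd in out.bonds if bd.key() not in drop]
        results.append(Molecule(out.id, out.atoms, out.bonds, out.source))
    return results


def _changed_ratio(a: Molecule, b: Molecule, mapping: dict[int, int]) -> float:
    if not mapping:
        return 0.0
    changed = sum(1 for i, j in mapping.items()
                  if one_bond_color(a, i) != one_bond_color(b, j))
    return changed / len(mapping)


def derive_pair_mapping(a: Molecule, b: Molecule,
                        rdms: list[RDMDescription],
                        limit: int = DEFAULT_COMBINATION_LIMIT) -> PairAtomMapping:
    """Derive the optimal atom mapping between ``a`` and ``b`` from RDMs.

    Raises :class:`CombinatorialLimit` when the number of center-assignment
    combinations exceeds ``limit`` and :class:`MappingError` when no
    assignment yields a consistent mapping.
    """
    if limit <= 0:
        raise ValueError("limit must be positive")
    if not rdms:
        raise MappingError("no RDM descriptions given")

    cands = []
    count = 1
    for rdm in rdms:
        ca = sorted(candidate_centers(a, rdm.center[0]))
        cb = sorted(candidate_centers(b, rdm.center[1]))
        if not ca or not cb:
            raise MappingError(
                f"no candidate atoms for reaction center {rdm.center}")
        cands.append((ca, cb))
        count *= len(ca) * len(cb)
    if count > limit:
        raise CombinatorialLimit(count, limit)

    best = None   # (size, -ratio monotone via tuple ordering, key, mapping, centers)
    for assignment in itertools.product(
            *[itertools.product(ca, cb) for ca, cb in cands]):
        src = [p for p, _ in assignment]
        dst = [q for _, q in assignment]
        if len(set(src)) != len(src) or len(set(dst)) != len(dst):
            continue
        if any(a.atom(p).element != b.atom(q).element
               for p, q in assignment):
            continue
        mods_a = [a]
        for (p, _), rdm in zip(assignment, rdms):
            mods_a = [m2 for m1 in mods_a
                      for m2 in _remove_diff_bonds(m1, p, rdm.diff_s)]
        mods_b = [b]
        for (_, q), rdm in zip(assignment, rdms):
            mods_b = [m2 for m1 in mods_b
                      for m2 in _remove_diff_bonds(m1, q, rdm.diff_p)]
        anchors = dict(assignment)
        for ma in mods_a:
            for mb in mods_b:
                try:
                    mcs = maximum_common_subgraph(ma, mb, anchors)
                except ValueError:
                    continue
                mapping = mcs.as_dict()
                ratio = _changed_ratio(a, b, mapping)
                score = (len(mapping), -ratio)
                canon = tuple(sorted(mapping.items()))
                if (best is None or score > best[0]
                        or (score == best[0] and canon < best[1])):
                    best = (score, canon, mapping, frozenset(assignment))
    if best is None:
        raise MappingError(
            f"no consistent mapping between {a.id} and {b.id}")
    _, _, mapping, centers = best
    return PairAtomMapping(a.id, b.id, tuple(sorted(mapping.items())), centers)


# -- export -------------------------------------------------------------------

def write_mapping_tsv(mappings: list[PairAtomMapping], path) -> None:
    with open(path, "w") as fh:
        fh.write("compound_a\tatom_a\tcompound_b\tatom_b\tis_center\n")
        for m in mappings:
            for i, j in m.pairs:
                c = int((i, j) in m.centers)
                fh.write(f"{m.compound_a}\t{i}\t{m.compound_b}\t{j}\t{c}\n")


def write_rdm_sdfile(a: Molecule, b: Molecule, mapping: PairAtomMapping,
                     path) -> None:
    """Paired-substructure export: two molfiles plus the index map.

    A single sdfile holding both connection tables and an ``ATOM_MAP`` data
    field of ``atom_a atom_b is_center`` rows — a transferable alternative
    to a list of RDM descriptions.
    """
    with open(path, "w") as fh:
        for mol in (a, b):
            fh.write(write_molfile(mol))
            fh.write("$$$$\n")
        fh.write("> <ATOM_MAP>\n")
        for i, j in mapping.pairs:
            fh.write(f"{i} {j} {int((i, j) in mapping.centers)}\n")
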