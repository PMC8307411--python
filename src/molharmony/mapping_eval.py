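"""Atom-mapping consistency scoring via changed one-bond atom colors.

The one-bond color of an atom captures exactly its immediate bonded
environment, so the fraction of mapped atoms whose one-bond color differs
across a substrate/product mapping estimates the proportion of reaction
center atoms — atoms where a bond is made, broken, or changes order.
Comparing two independent mappings of the same compounds (e.g. two
databases' versions) is done on resonance-normalized mappings:
interchangeable atoms such as the two carboxylate oxygens are permuted
into a canonical representative first, so chemically identical mappings
compare as the same.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chemgraph import Molecule
from .coloring import one_bond_color, symmetry_classes
from .rdm_mapping import PairAtomMapping

VERDICT_SAME = "same"
VERDICT_INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class ReactionLevelMapping:
    """Union of compound-pair mappings at reaction scope.

    ``pairs`` hold ``((compound_id, atom), (compound_id, atom))`` entries;
    ``conflicts`` flags endpoints that take part in more than one pair
    (one atom mapped to multiple targets), which are retained rather than
    silently dropped.
    """
    pairs: tuple[tuple[tuple[str, int], tuple[str, int]], ...]
    conflicts: frozenset[tuple[str, int]] = frozenset()

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ConsistencyReport:
    verdict: str
    fraction_a: float
    fraction_b: float
    mapped_counts: tuple[int, int]
    resonance_corrected: bool


def reaction_level_mapping(pair_mappings) -> ReactionLevelMapping:
    """Combine compound-pair mappings into one reaction-level mapping."""
    pairs = []
    for pm in pair_mappings:
        for i, j in pm.pairs:
            pairs.append(((pm.compound_a, i), (pm.compound_b, j)))
    seen_src: dict[tuple[str, int], set] = {}
    seen_dst: dict[tuple[str, int], set] = {}
    for src, dst in pairs:
        seen_src.setdefault(src, set()).add(dst)
        seen_dst.setdefault(dst, set()).add(src)
    conflicts = {k for k, v in seen_src.items() if len(v) > 1}
    conflicts |= {k for k, v in seen_dst.items() if len(v) > 1}
    return ReactionLevelMapping(tuple(sorted(pairs)), frozenset(conflicts))


def _iter_pairs(mapping, mols: dict[str, Molecule]):
    """Normalize either mapping flavor to ((mol, atom), (mol, atom))."""
    if isinstance(mapping, PairAtomMapping):
        ma, mb = mols[mapping.compound_a], mols[mapping.compound_b]
        for i, j in mapping.pairs:
            yield (ma, i), (mb, j)
    else:
        for (ca, i), (cb, j) in mapping.pairs:
            yield (mols[ca], i), (mols[cb], j)


def changed_color_fraction(mapping, mols: dict[str, Molecule],
                           normalize: bool = True) -> float:
    """Fraction of mapped atoms whose one-bond color differs across the map.

    By default the mapping is resonance-normalized first, so permuting
    interchangeable atoms (e.g. the two carboxylate oxygens) cannot inflate
    the fraction; since normalization is idempotent, the fraction is
    invariant under :func:`resonance_normalize`.  ``normalize=False`` gives
    the raw, uncorrected value.
    """
    if normalize:
        mapping = resonance_normalize(mapping, mols)
    pairs = list(_iter_pairs(mapping, mols))
    if not pairs:
        raise ValueError("changed-color fraction undefined for an empty mapping")
    changed = sum(1 for (ma, i), (mb, j) in pairs
                  if one_bond_color(ma, i) != one_bond_color(mb, j))
    return changed / len(pairs)


# -- resonance normalization --------------------------------------------------

_RESONANCE_ANCHORS = {"C", "P", "S", "N", "As"}


def _resonance_classes(mol: Molecule) -> dict[int, int]:
    """Atom -> class id; interchangeable atoms share a class.

    Classes merge (a) full symmetry classes of the molecule and (b)
    terminal oxygens sharing a carboxylate/phosphate-like anchor atom,
    detected on the bond-order-collapsed local group so that -OH / =O
    pairs count as interchangeable.
    """
    parent = {i: i for i in mol.heavy_indices()}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for group in symmetry_classes(mol):
        for i in group[1:]:
            union(group[0], i)
    for i in mol.heavy_indices():
        a = mol.atom(i)
        if a.element not in _RESONANCE_ANCHORS:
            continue
        terminal_o = [j for j in mol.heavy_neighbors(i)
                      if mol.atom(j).element == "O"
                      and len(mol.heavy_neighbors(j)) == 1]
        for j in terminal_o[1:]:
            union(terminal_o[0], j)
    return {i: find(i) for i in parent}


def resonance_normalize(mapping, mols: dict[str, Molecule]):
    """Canonical representative of a mapping's resonance-equivalence class.

    Within each pair of (source class, target class), the assignment among
    interchangeable atoms is arbitrary; sources and targets are re-paired
    in ascending order, yielding the lexicographically smallest member of
    the orbit.  Mappings differing only by permuting resonant atoms
    normalize to the identical object.
    """
    if isinstance(mapping, PairAtomMapping):
        ma, mb = mols[mapping.compound_a], mols[mapping.compound_b]
        cls_a, cls_b = _resonance_classes(ma), _resonance_classes(mb)
        groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for i, j in mapping.pairs:
            groups.setdefault((cls_a.get(i, -i), cls_b.get(j, -j)), []).append((i, j))
        new_pairs = []
        for members in groups.values():
            srcs = sorted(i for i, _ in members)
            dsts = sorted(j for _, j in members)
            new_pairs.extend(zip(srcs, dsts))
        new_pairs.sort()
        centers_src = {i for i, _ in mapping.centers}
        d = dict(new_pairs)
        centers = frozenset((i, d[i]) for i in centers_src if i in d)
        return PairAtomMapping(mapping.compound_a, mapping.compound_b,
                               tuple(new_pairs), centers)

    # reaction-level: normalize per (compound_a, compound_b) block
    cls_cache: dict[str, dict[int, int]] = {}

    def cls(cid, i):
        if cid not in cls_cache:
            cls_cache[cid] = _resonance_classes(mols[cid])
        return cls_cache[cid].get(i, -i)

    groups = {}
    for (ca, i), (cb, j) in mapping.pairs:
        groups.setdefault((ca, cb, cls(ca, i), cls(cb, j)), []).append((i, j))
    new_pairs = []
    for (ca, cb, _, _), members in groups.items():
        srcs = sorted(i for i, _ in members)
        dsts = sorted(j for _, j in members)
        new_pairs.extend((((ca, i), (cb, j))) for i, j in zip(srcs, dsts))
    return ReactionLevelMapping(tuple(sorted(new_pairs)), mapping.conflicts)


def compare_mappings(m1, m2, mols: dict[str, Molecule],
                     correct_resonance: bool = True) -> ConsistencyReport:
    """Compare two atom mappings of the same molecules.

    Verdict is ``same`` iff the (optionally resonance-normalized) pair sets
    are equal; the report carries both changed-color fractions — the
    scatter-plot coordinates used to judge which mapping is more plausible.
    """
    if isinstance(m1, PairAtomMapping) != isinstance(m2, PairAtomMapping):
        raise ValueError("cannot compare mappings of different scopes")
    if isinstance(m1, PairAtomMapping):
        if (m1.compound_a, m1.compound_b) != (m2.compound_a, m2.compound_b):
            raise ValueError("mappings address different compound pairs")
    if correct_resonance:
        m1 = resonance_normalize(m1, mols)
        m2 = resonance_normalize(m2, mols)
    same = set(m1.pairs) == set(m2.pairs)
    return ConsistencyReport(
        verdict=VERDICT_SAME if same else VERDICT_INCONSISTENT,
        fraction_a=changed_color_fraction(m1, mols, normalize=correct_resonance),
        fraction_b=changed_color_fraction(m2, mols, normalize=correct_resonance),
        mapped_counts=(len(m1), len(m2)),
        resonance_corrected=correct_resonance)


def write_scatter_tsv(reports: list[ConsistencyReport], path) -> None:
    """Emit (fraction_a, fraction_b, verdict) rows for external plotting."""
    with open(path, "w") as fh:
        fh.write("fraction_a\tfraction_b\tverdict\n")
        for r in reports:
            fh.write(f"{r.fraction_a:.6f}\t{r.fraction_b:.6f}\t{r.verdict}\n")
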