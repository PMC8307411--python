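# molharmony

Hierarchical harmonization of atom-resolved compounds and metabolic
reactions across metabolic databases.

## The problem

Building an atom-resolved metabolic network means merging compound and
reaction descriptions from databases (KEGG-style, MetaCyc-style) that
disagree in exactly the ways naive identifier matching cannot absorb:

* **Generic compounds** carry R-group placeholders, so no structure-derived
  identifier (InChI, SMILES, coloring identifiers) can pair them with their
  specific instantiations.
* **Stereo annotations are incomplete and inconsistent** — the same
  metabolite may carry full, partial, or conflicting atom parity and
  cis/trans labels in the two sources.
* **Drawing conventions differ** — sugars appear as open-chain aldehydes in
  one database and hemiacetal rings in the other; tautomers shift a
  hydrogen together with a double bond.
* **Atom mappings** (substrate→product atom correspondences) are encoded
  differently (explicit index pairs vs KEGG RCLASS RDM descriptions) and
  contain errors that only a local chemical-environment metric exposes.

`molharmony` addresses all four.  It is aimed at metabolic-modeling and
cheminformatics researchers who need defensible compound/reaction
correspondence tables, with an audit trail of *how strongly* each pair
agrees.

## The method

**Atom coloring and identifiers.** Every atom gets a canonical color by
Morgan-style iterative refinement on the hydrogen-suppressed graph:
color⁰ = element(+charge, +stereo in *detailed* mode), and
colorᵏ⁺¹ = color⁰ ‖ sorted (bond order, neighbor colorᵏ) list, iterated to
a stable partition.  The sorted multiset of final colors plus the formula
is the compound identifier; the *loose* mode (stereo ignored) detects
candidate pairs, the *detailed* mode ranks them.

**Relationship taxonomy.** A pair's chemical details (atom parities,
cis/trans labels, with *unknown* treated as absent) are compared across an
atom mapping: equal sets → **equivalence**; one a strict subset →
**generic-specific**, directed general→specific; otherwise **loose**.

**Structural validators.** Pairs invisible to identifiers are validated by
a chemically-aware subgraph matcher (VF2-style, with R wildcards and
optional bond-order relaxation): R-group containment with one unmatched
branch per R atom; tautomers by collapsing double bonds, testing
isomorphism, and requiring every double-bond mismatch to be an adjacent
hydrogen shift; ring/chain forms by breaking the hemiacetal C–O ring bond,
restoring C=O, and re-deriving the identifier.

**Reaction harmonization.** Two reactions pair when they share an EC
number (fully, or on three levels in the relaxed tier) and their
participant multisets match perfectly under the compound-pair relation
(extra H⁺ ignored).  The reaction inherits the weakest compound-pair
relationship, with mixed generic-specific directions demoted to loose.
An iterative loop mines *near-miss* reaction pairs (shared EC, ≥1 matched
compound, some unmatched) for new validator candidates until a fixpoint.

**RDM atom mappings and the consistency metric.** KEGG RCLASS RDM triples
(reaction center / difference / matched region) are parsed, candidate
center atoms enumerated on both sides, difference-region bonds deleted,
and an anchored maximum-common-subgraph search returns the mapping with
most mapped atoms and least changed-atom ratio; a configurable cap turns
combinatorial blow-ups on symmetric multi-center compounds into an
explicit error.  Mapping quality is scored by the **changed one-bond
atom-color fraction** — the share of mapped atoms whose immediate bonded
environment differs across the mapping — after canonicalizing resonance
swaps such as the two carboxylate oxygens.

## Worked example

```python
import random
from molharmony import fixtures, harmonization_loop

dbs = fixtures.gen_databases(fixtures.FixtureSpec(seed=11))
res = harmonization_loop(dbs.compounds_a, dbs.compounds_b,
                         dbs.reactions_a, dbs.reactions_b)
print(len(res.compound_pairs), "compound pairs;",
      len(res.reaction_pairs), "reaction pairs")
for i, new in enumerate(res.rounds, 1):
    print("round", i, "discovered", new)
```

prints

```
12 compound pairs; 8 reaction pairs
round 1 discovered [('A_ge1', 'B_ge1'), ('A_ge2', 'B_ge2'), ('A_ta1', 'B_ta1'), ('A_ta2', 'B_ta2')]
round 2 discovered [('A_rc1', 'B_rc1')]
```

The two planted 30-compound databases share 12 true pairs.  Five
equivalence and two loose pairs are found immediately from loose coloring
identifiers (round 0); the first loop round pairs reactions and validates
the generic (`ge*`) and tautomer (`ta*`) compounds left unmatched in
near-miss reaction pairs; the ring/chain sugar pair (`rc1`) sits in a
reaction whose other participants are themselves round-1 discoveries, so
it can only surface in round 2 — the loop then reaches its fixpoint and
classifies all 8 cross-database reaction pairs.

The same pipeline is scriptable from the shell:

```bash
molharmony gen-fixtures --seed 11 --out fix/
molharmony harmonize-reactions --compounds-a fix/compounds_a \
    --compounds-b fix/compounds_b --reactions-a fix/reactions_a.json \
    --reactions-b fix/reactions_b.json --out harmonized/
```

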