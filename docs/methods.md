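# Methods

This note records the models, algorithms, numerical choices, and open
design decisions behind `molharmony`, and what the synthetic study
conditions do and do not establish about behavior on real databases.

## Molecular graphs and stereo perception

Molecules are labeled graphs over 1-based atom indices in connection-table
order; all downstream atom mappings refer to these indices.  Explicit
hydrogens are parsed and retained, but every matching and coloring
operation runs on the hydrogen-suppressed view with a per-heavy-atom
explicit-H count annotation — databases mix implicit and explicit
hydrogen, and suppressing it is the only representation both conventions
share.  R-group symbols (`R`, `R#`, `*`, `A`, `X`, `Q`) are normalized to
the pseudo-element `R`; aromatic bond labels (order code 4) are taken from
the input and never perceived.

Atom parity is perceived from wedge/hash annotations in the 2D drawing: a
stereocenter candidate (≥3 non-H neighbors) with a wedge whose narrow end
sits at the candidate gets the wedged neighbor lifted to z=±1 and parity
from the sign of the signed volume over index-ordered neighbors; three-
neighbor centers use the candidate's own position as the in-plane fourth
point.  Candidates without usable wedges are `unknown`, which downstream
classification treats as *absent*, never as *conflicting* — this is what
lets partially annotated databases form generic-specific rather than loose
pairs.  Mirroring a drawing flips parity (antisymmetry), as it must.

Double-bond cis/trans uses the plane-splitting construction: one
prioritized substituent per end (the only group, else highest by element
then immediate neighborhood; priority ties → `none`), sides taken from the
sign of the cross product against the bond axis.  This handles hetero
double bonds (C=N) that element-restricted methods skip.  Note that
mirroring a drawing flips *both* substituents' sides, so cis/trans labels
are reflection-invariant — only rigid-motion invariance and reflection
invariance are meaningful properties here, and both are tested.

Numerical tolerance: colinearity and degenerate geometry are decided at
1e-6 in coordinate units; anything closer to the dividing line than that
is reported `unresolved` rather than silently classified.

## Coloring and identifiers

Atom colors come from Morgan-style refinement: base invariant =
element + charge + H count (+ parity in detailed mode), then repeated
extension by the sorted list of (bond label, neighbor color) pairs until
the number of color classes stabilizes, capped at the atom count.  To keep
strings bounded, each round references neighbors through their rank in the
sorted set of the previous round's colors; ranks are derived from sorted
strings only, so the construction is invariant to input atom order and
identical across isomorphic molecules.  Equal final colors then imply
equal rooted neighborhoods to the refinement depth by induction over
rounds.

Like any refinement scheme, this can merge non-automorphic atoms in
pathological regular graphs; the test suite bounds the risk by checking
partitions against brute-force automorphism orbits on small molecules, and
identifier soundness (equal identifier ⇔ isomorphic) against brute-force
isomorphism.  Detailed mode only *adds* invariant material, so
detailed-equality implies loose-equality by construction.

The one-bond color (element + charge + sorted one-neighbor list, H
excluded) is deliberately not the refined color: its locality is the
point.  It changes exactly at atoms where an incident bond is made,
broken, or changes order, which is what makes the changed-color fraction a
proxy for the proportion of reaction-center atoms in a mapping.

## Substructure matching

The matcher is a VF2-style backtracking search over candidate lists with
fail-first ordering (fewest candidates first, connectivity maintained);
atom compatibility is (element, charge) with pattern-side `R` matching any
heavy atom, bond compatibility exact order unless `order_strict=False`
(tautomer validation).  Embeddings are monomorphisms — target bonds
between matched atoms may exist beyond the pattern's.  The maximum common
subgraph uses McGregor-style include/exclude branching over frontier
pairs, growing connected extensions from the anchor set, with induced-edge
consistency (a bond between mapped atoms exists on one side iff a
compatible bond exists on the other); ties break on matched-bond count,
then lexicographically smallest mapping, so results are deterministic.
All three operations are verified against independent exhaustive
enumeration on small random instances.

## Pair classification and validators

"Chemical details" are atom parities plus cis/trans labels; charges and H
counts are structural (part of the graph labels), not details.  Details
compared across a full heavy-atom bijection yield equivalence / directed
generic-specific / loose.  Because symmetric molecules admit several
isomorphisms that align details differently, classification searches all
isomorphisms (capped at 1000) and keeps the strongest outcome.

*Generic validation*: the R/H-stripped pattern must embed in the target;
each connected unmatched target branch must hang off exactly one matched
atom, and the number of branches at each such atom must equal the number
of R atoms its preimage carries.  The equality (rather than ≤) encodes the
decision that R may not instantiate to hydrogen — an unconsumed R would be
exactly that.  One R absorbs one branch; a substituent pattern needing two
branches at one position must carry two R atoms there.  A branch may
itself terminate in an R (generic-to-generic pairs).

*Tautomer validation*: formulas must match exactly; both molecules are
rebuilt with double bonds as single and must be isomorphic; the double
bonds present on only one side must admit a perfect pairing in which each
pair shares exactly one atom (the adjacent H-shift pattern).  When both
inputs carry explicit hydrogens the far atoms must also gain/lose one H;
hydrogen-suppressed inputs are checked on the heavy skeleton only.
Longer-range shifts are rejected by construction.  Remaining details away
from the changeable atoms set the relationship.

*Ring/chain validation*: candidate bonds are ring (non-bridge) C–O bonds
whose carbon bears a terminal single-bonded O (the hemiacetal motif); the
transform breaks the ring bond, restores C=O on that carbon, moves any
explicit H from the hydroxyl O to the former ring O, clears the anomeric
parity (the carbon becomes sp2), and compares loose identifiers with the
open form.  Every candidate is tried; validation succeeds if any matches.

## Reaction pairing and the loop

Participant multisets (stoichiometry-expanded, ignorable entities removed
— default H⁺ only, H₂O intentionally not) are matched by maximum-weight
assignment (scipy `linear_sum_assignment`) with weights
equivalence > generic-specific > loose, so ties resolve toward the
strongest classification; both substrate/product orientations are tried
and the stronger result wins.  Reactions without an EC specified to at
least three levels are excluded.  The three-level EC tier is only assigned
when no full match exists.

The loop seeds pairs from loose identifiers, then alternates: pair
reactions; for near-miss pairs (shared EC, ≥1 matched, some unmatched)
propose R-carrying unmatched compounds against all partner participants
and same-formula leftovers to the tautomer and ring/chain validators (both
orientations); append validated pairs keyed by id pair, keeping the
strongest relationship.  The pair list grows monotonically in a finite
universe, so termination is guaranteed; rounds are recorded so discovery
depth is observable.

Quality checking classifies a reaction by precedence: element imbalance
(stoichiometry-weighted, H excluded by default) → `incomplete_reaction`;
any mapping entry joining different elements → `incorrect_mapping`;
mapped coverage below all balanceable atoms → `incomplete_mapping`; else
`complete`.

## RDM mapping derivation

Candidate centers match by KEGG atom type when annotations exist, by the
label's element prefix otherwise (with a logged warning).  The assignment
space is the product over RDM triples of (substrate candidates ×
product candidates); its size is computed *before* enumeration and
compared against the cap (default 10⁵), making intractable symmetric
multi-center cases an explicit, fast `CombinatorialLimit` error rather
than an open-ended search.  For each injective assignment, one
center-incident bond is removed per difference-region label (all choices
enumerated when the label is ambiguous), and an anchored MCS on the
modified graphs yields a candidate mapping.  The optimum maximizes mapped
atoms, then minimizes the changed one-bond-color ratio computed on the
*original* structures, then takes the canonically smallest mapping.
Raising the cap can only convert errors into results, never change a
successful result.

## Consistency metric and resonance correction

The changed-color fraction is (#mapped atoms whose one-bond colors
differ) / (#mapped atoms).  Interchangeable-atom classes are the union of
full symmetry classes and terminal oxygens sharing a C/N/P/S/As anchor
(the carboxylate/phosphate motifs; bond orders intentionally ignored so
-OH/=O pairs count as interchangeable).  Nitro/guanidinium groups fall out
of the same terminal-O rule where applicable; broader tautomer-level
resonance is out of scope.  Normalization re-pairs sources and targets
within each (source class, target class) group in ascending order — the
lexicographically smallest orbit representative — and is idempotent.  The
fraction is computed on the normalized mapping by default, which is the
only reading under which it is invariant to resonance permutation; the
uncorrected value remains available (`normalize=False`) because the
before/after contrast is itself informative: resonance swaps inflate the
raw fraction and the raw disagreement rate between two mapping sources,
and correction removes exactly that component.  Reaction-level mappings
are unions of compound-pair mappings with conflicting endpoints retained
and flagged rather than dropped, since one-atom-to-many mappings are a
real defect class worth surfacing.

## Synthetic study conditions

The generators define the conditions everything is measured under.
Random molecules are valence-respecting connected heavy-atom graphs
(valences C4 N3 O2 S2 P5 H1 R1; element pool 5:1:1:1 C:N:O:S; double-bond
probability 0.15; ring-closure probability 0.15; sizes 4–12 by use),
with deterministic BFS layouts at unit bond length.  Planted pairs:
equivalence = relabeled copies; loose = opposite wedges on an asymmetric
N/O/S-substituted stereocenter; generic-specific = one terminal branch
replaced by R; tautomer = a keto O= moved to an adjacent C–C bond;
ring/chain = a hemiacetal closure applied in reverse to a C4–C6 aldehyde
chain with 0–2 decorating hydroxyls.  The planted mini databases hold 30
compounds and 12 reactions per side with 5/2/2/2/1
equivalence/loose/generic/tautomer/ring-chain pairs, sized so the whole
loop (and the rest of the suite) runs in seconds while every discovery
path — including the two-round ring/chain dependency — is exercised;
identifier uniqueness outside planted collisions is enforced by
regeneration.  Reaction fixtures regenerate until the molecule is
asymmetric (singleton symmetry classes) and the planted embedding is
unique, so "exact recovery" is well defined.

What this does *not* show: robustness to real databases' aromatic
perception differences, charge/protonation disagreements, multi-fragment
entries, malformed tables, or KEGG's actual 68-type atom typing (synthetic
types are element+degree+environment labels with the same
coarser-than-color character).  The wedge-based parity perception replaces
an external curation step whose settings are unknown; agreement with it is
unverified.

## Known limitations

* Refinement colors can merge non-automorphic atoms on regular graphs;
  brute-force oracles bound this only at fixture scale.
* Generic validation requires each branch to attach at a single matched
  atom; R groups bridging two attachment points are rejected.
* Stoichiometric coefficients must match after ignorable-entity removal;
  whether real databases require this is undecided, and the stricter
  reading was chosen.
* The RCLASS grammar accepts both whole-triple `+` joins and within-field
  `+` label joins by structural disambiguation; a token that is ambiguous
  under both readings parses as a single triple.
* MCS search is exact and exponential in the worst case; it is intended
  for metabolite-sized molecules, not polymers.
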