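# Methods

## Data model

A character is `qualitative` (closed, ordered vocabulary of state tokens),
`count` (meristic; values are closed integer ranges `[lo, hi]`, a printed
single value n stored as `[n, n]`), or `caudal_formula` (a pair of count
ranges, upper + lower caudal lobe; the same type carries the two-part
infraorbital pore formula). Species-level cells are ranges or state sets;
specimen observations are point values, with a small observation *set*
allowed for left/right asymmetric counts (an observation set matches when
any member matches). `UNKNOWN` (`?`) is compatible with everything.

Two species values are *incompatible* (distinguishing) when their value
sets are disjoint: non-overlapping ranges, disjoint state sets, or formulae
disjoint in at least one lobe. Overlap — not mere inequality — is the
criterion throughout, which is why partially overlapping meristic ranges
are never treated as diagnostic.

Cell grammar (TSV): `?` | INT | INT-INT | `/RANGE + RANGE/` | token |
token`/`token (polymorphism). En dashes in printed ranges are accepted on
input; the writer emits hyphens. A trailing `?` inside a cell (the
`/9 + 8?/` caudal entry of *S. paucifasciata*) flags the value as uncertain
on the record without altering compatibility; uncertain characters are
excluded from that taxon's diagnostic sets unless explicitly included.

## The canonical matrix

The packaged matrix holds 12 species × 18 characters. Two printed rows are
omitted: the anal-fin ray count (a constant 3/5½ for every species) and the
branched dorsal-fin ray count, both written in half-ray notation that the
cell grammar deliberately does not model. In their place the matrix carries
`body_bars`, the flank bar-pattern character of the morphocode (states:
numerous/broad bars, 2–4 thin black bars, plain brown, mostly fused), with
per-species values taken from the species diagnoses and colour-pattern
accounts. This keeps every morphocode character matrix-sourced and makes
the key's colour-pattern couplet routable from the matrix. The pectoral-ray
column of the typeset table cannot be segmented consistently for the last
three species; the matrix follows the diagnosis texts (10–11 for
*S. paucifasciata*, 9–10 for *S. peninsulae* and *S. tenebrosa*).

Qualitative phrases are normalised to closed vocabularies through an
explicit synonym map shipped with the matrix (e.g. "Variable" →
`present/absent`, "Light, thin" → `light_thin`). "Variable" is stored as
the polymorphic set {present, absent}; the unobservable lower-lip marks of
*S. paucifasciata* stay `?` (their absence is argued to be a preservation
artefact, and the toolkit leaves the interpretation to the user).

A note on one published claim: the comparison table's cephalic pore counts
for *S. robertsi* and *S. peninsulae* are disjoint (supraorbital 6 vs 5,
supratemporal 4 vs 3, infraorbital 4 + 8 vs 4 + 10), so `pairwise_diffs`
lists them alongside the pectoral and caudal ray counts that the prose
singles out as the only external separators of the pair. The toolkit
reports what the matrix implies and does not suppress the pore characters.

## Morphocode derivation

The integer morphocode (characters A–L) is defined by a state legend per
character mapped onto matrix characters. Codes are derived, not stored: a
matrix value equal to a legend state codes silently; a value strictly
inside one state (a point count within a two-value state, or a state set
inside the "bar present" group) takes the smallest containing state; a
value outside every legend state is resolved by the range-overlap rule —
the unique overlapping state with a warning, a `{..}` brace set with a
warning when several overlap, `?` with a warning when none do. UNKNOWN
codes `?` silently. The light, thin caudal bar of *S. aurantiaca* codes as
state 0 (bar present) of character G, the legend defining no separate
state for it.

## Keys

Evaluation semantics: at each couplet every satisfied lead is followed;
species ranges, polymorphic cells, unknown values and unobserved specimen
characters can satisfy both leads, in which case both branches are explored
and all reached terminals are returned (removing an observation can
therefore never shrink a terminal set). A couplet where neither lead is
satisfied contributes a dead end. Soft predicates — live coloration and
geography, which no preserved-specimen matrix can carry — are stored
verbatim but excluded from routing unless explicitly enabled; a lead whose
predicates are all soft is vacuously satisfied, so the printed key's
couplet 10 (live interspace colours) leaves *S. peninsulae* and
*S. crocotula* mutually ambiguous, and the printed key's couplet 8
dead-ends *S. aurantiaca* whose tabulated anus position disagrees with the
key's routing. These are reported, not repaired.

Generation is greedy: at each node, over the taxa still compatible with the
path, every character is offered with every binary split of its value space
(vocabulary subsets for qualitative characters; thresholds for counts and
for each formula lobe). Splits are scored lexicographically: number of
straddling taxa first (a straddler descends both branches, duplicating
leaves and breaking the n − 1 couplet bound), then the objective —
`minimax-branch` minimises the larger side, `min-expected-depth` the total
of both sides — with ties broken by character order and then the split's
lexicographic representation, making generation fully deterministic.
Greedy construction is not provably optimal; correctness (every taxon keys
out to itself) is guaranteed whenever all taxon pairs are distinguishable,
which is checked first.

## Parsimony

Unordered-parsimony reconstruction uses the Fitch downpass generalised to
polytomies by Hartigan's state-count rule: at a node, states attaining the
maximal count k over the children's sets form the downpass set, and
(#children − k) steps are added. Polymorphic tips enter as their full state
sets (equivalent to minimising over all single-state resolutions of each
tip); UNKNOWN expands to the character's vocabulary. The uppass computes
exact MPR sets — the states a node takes in at least one
most-parsimonious reconstruction: conditional on a parent state p, p itself
is the unique optimum when p is in the node's max-count set; otherwise the
max-count states are optimal, joined by p when p reaches count k − 1. Both
step counts and MPR sets are cross-checked in the tests against exhaustive
enumeration over all internal assignments on random trees (≤ 8 tips, ≤ 4
states, polytomies and polymorphic tips included). Tips report their full
coded sets. Branch lengths are ignored.

Synapomorphy screening of a clade against a single outgroup tip compares
the clade-internal reconstruction at the clade MRCA — the downpass set,
which depends only on the clade's own subtree — with the outgroup's states;
a character is reported when the two are disjoint, with the derived
state(s) taken from the MRCA set. MPR ambiguity (an equally parsimonious
mapping that moves the gain inside the clade, which arises on *some*
arbitrary resolutions whenever the polymorphic-tipped cherry attaches at
the clade stem) is reported as a caveat (`ambiguous_mpr`) rather than
disqualifying the character, and polymorphic clade tips are listed. This
convention makes the verdict a property of the documented constraints, not
of the arbitrary resolution: the lower-lip marks reconstruct as a group
synapomorphy with state `present` under every seeded resolution of the
constraint tree.

Homoplasy indices per character: CI = (k−1)/s and RI = (g−s)/(g−m), with k
the number of states across tip sets, m = k−1, s the parsimony steps and
g = #tips − modal-state frequency (a polymorphic tip counts towards a state
it contains). Both are reported absent for constant characters and RI also
when g = m. With polymorphic tips k counts every state appearing in any
tip set, so the indices assume each such state is realised.

## The constraint tree

Only three facts about the species tree are fixed: the 12 species form a
clade, *S. paucifasciata* is sister to *S. balteata*, and the single
outgroup tip (*Cobitis taenia*, the rooting taxon of the molecular
analyses) lies outside the group. Everything else is a uniformly random
seeded bifurcation, and every such node is flagged
`arbitrary_resolution` — no phylogeny is invented, and tree-dependent
results are assessed for stability across ≥ 20 re-seeded resolutions
rather than asserted on any one topology.

## Synthetic data

`SimConfig` defaults mirror the canonical matrix: 12 taxa × 18 characters;
half the characters qualitative with 3 states, most of the rest counts
with range widths 0–2 (meristic-like), a formula character or two
(fractions 0.50/0.39/0.11); polymorphism rate 0.02 and unknown rate 0.03,
the approximate cell fractions of the real table. All randomness flows
from one explicit seed through a single `numpy` generator; regeneration is
bit-identical. The `disjoint` flag makes every character's per-taxon
values pairwise non-overlapping — the regime in which a generated key must
route every noise-free simulated specimen to its source taxon, which the
tests assert at 100%. Specimen noise perturbs an observation to an
adjacent count or an alternative state with the configured probability and
logs every perturbation, so misrouted specimens can be reconciled against
the log exactly.

What the generator does *not* emulate: correlated characters, clade-shaped
character covariance, observer error structure, or continuous
morphometrics. Passing the recovery property therefore demonstrates the
key machinery, not field identifiability of real specimens, where
character overlap (the Phuket panels) is precisely the interesting case.

## Problem sizes

The packaged analyses are small by nature (12 taxa, 18 characters, 29
specimens). Stochastic checks use 200 random trees of ≤ 8 tips for the
parsimony oracle (exhaustive enumeration stays exact at that size), 20
re-seeded resolutions for synapomorphy stability, and 100–200 simulated
specimens for the recovery property; minimal diagnostic sets default to
k_max = 4, where exhaustive subset enumeration over 18 characters is exact
and immediate.

## Known limitations

- Half-ray fin counts (…½) are outside the cell grammar; the two affected
  rows are not modelled.
- Exact key optimality is not attempted (exponential; the greedy key is
  correct but may not minimise depth).
- Crisp matching only: no probabilistic or partial-credit identification.
- Molecular results (tree inference, support values) are out of scope; the
  constraint tree deliberately encodes only documented relationships.
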