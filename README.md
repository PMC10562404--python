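# morphokey

Morphological diagnostics for the *Schistura cincticauda* species group — a
clade of small nemacheilid loaches from streams of eastern Myanmar and
western/southern Thailand, diagnosed externally by a pair of black marks on
the lower lip. The group contains (at least) twelve species, each separable
from every other only by a *combination* of character states: fin-ray counts,
caudal-fin branched-ray formulae (upper + lower lobe), cephalic pore counts,
anus position, presence of an axillary pelvic lobe, and colour-pattern
states.

`morphokey` turns that style of taxonomic evidence into typed, testable
objects:

- **Character matrices** (`datamodel`) — taxa × characters where a cell is a
  qualitative state set (polymorphism = a set of size > 1, `?` = unknown), a
  meristic count range `[lo, hi]`, or a two-part formula `/u + l/`. TSV
  read/write round-trips exactly; a NEXUS `DATA` block writer exports coded
  matrices (with `{01}` polymorphism and `?` missing) for external
  phylogenetic tools.
- **Dichotomous keys** (`key_engine`) — couplets of predicate-guarded leads.
  Evaluation follows *every* satisfied lead (ranges, polymorphic cells and
  unknowns can satisfy both), `verify_key` routes each taxon's own row
  through the key and reports dead ends / ambiguities, and `generate_key`
  builds a correct key greedily from any matrix whose taxa are pairwise
  distinguishable (n taxa ⇒ n − 1 couplets).
- **Diagnosability** (`diagnosis`) — pairwise distinguishing characters
  (disjoint value sets; unknown never distinguishes), the unique-combination
  check, exhaustive minimal diagnostic-set search, specimen classification
  with per-character candidate sets and conflict reporting, and panel
  tallies that reproduce published specimen arithmetic.
- **Ancestral states** (`ancestral`) — unordered (Fitch) parsimony with
  Hartigan's generalisation to polytomies, exact MPR state sets per node,
  synapomorphy screening of a clade against an outgroup, and
  consistency/retention indices (CI = (k−1)/s, RI = (g−s)/(g−m)).
- **Synthetic data** (`synthetic_data`) — seeded generators for matrices
  with controllable polymorphism/unknown rates, specimen panels drawn from a
  taxon's value sets with logged noise, and random bifurcating trees under
  clade constraints.
- **Packaged datasets** (`fixtures`) — the canonical 12 × 18 comparison
  matrix, the integer morphocode scheme (characters A–L with state legends),
  the printed identification key, the Phuket/MCZ specimen panels and the
  re-examined *S. robertsi* holotype, and a constraints-only species tree
  (only the documented relationships are fixed; the rest is a seeded,
  flagged arbitrary resolution).

## Worked example

```python
import morphokey as mk
from morphokey import fixtures as fx

matrix = fx.load_table1()                     # 12 taxa x 18 characters
zrc, mcz, holo = fx.load_specimen_panels()

# The S. robertsi holotype: caudal 7 + 7, pectoral {7, 8} (left/right asymmetry)
result = mk.classify_specimen(matrix, holo.specimens[0])
print(result.status, result.overall)
print(result.per_character)
```

```
unique ('S. robertsi',)
{'caudal_rays': ('S. robertsi',), 'pectoral_rays': ('S. myaekanbawensis', 'S. robertsi')}
```

The caudal formula alone pins the holotype; the pectoral count would also
admit *S. myaekanbawensis*, and the intersection is unique.

```python
report = mk.panel_report(matrix, zrc)         # 20 Phuket specimens
print({t: n for t, n in report["caudal_rays"].items() if n})
```

```
{'S. balteata': 12, 'S. crocotula': 12, 'S. hartli': 12, 'S. ataranensis': 12,
 'S. robertsi': 8, 'S. peninsulae': 12}
```

Of the 20 Phuket specimens, 8 carry caudal formulae inside the
*S. robertsi* ranges and 12 carry 8 + 8 — compatible with *S. peninsulae*
(and with every other 8 + 8 species), while all 20 pectoral counts fit
*S. robertsi*: the mixed signal behind the unresolved identity of the
Phuket population.

```python
key = mk.generate_key(matrix)                 # 11 couplets for 12 species
print(mk.render_key(key).splitlines()[0])
```

```
1 - anus_position = middistance. ..... 2
```

`mk.verify_key(key, matrix).ok` is `True`: every species keys out to
itself. Running `verify_key` on the *printed* key instead flags
*S. aurantiaca* (its matrix row dead-ends at couplet 8) plus the
*S. peninsulae*/*S. crocotula* couplet that the print separates only by
live coloration — the toolkit reports such key-versus-table conflicts
rather than deciding which source is right.

A command-line interface mirrors the library:

```sh
morphokey fixtures --out-dir fx
morphokey key-check --key fx/key.json --matrix fx/table1.tsv   # exit 1: conflicts
morphokey panel --matrix fx/table1.tsv --panel fx/zrc-phuket.tsv
morphokey simulate --taxa 8 --chars 10 --seed 1 --out-dir sim
```

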