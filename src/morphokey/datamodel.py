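"""Core types for morphological character matrices and specimens.

The data model mirrors how ichthyological comparison tables are printed:
characters are either qualitative (a closed vocabulary of state tokens,
possibly polymorphic within a species), meristic counts (small integer
ranges such as fin-ray numbers), or two-part count formulae such as the
branched caudal-fin ray formula "8 + 8" (upper lobe + lower lobe).

Species-level cells are *ranges or state sets*; specimen-level observations
are always point values (a single count, a single state token, or an exact
formula), optionally a small set of point values for left/right asymmetric
counts.  The ``compatible`` relation between a species value and a specimen
observation is the workhorse of both key routing and classification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "MorphokeyError",
    "MatrixFormatError",
    "KindMismatchError",
    "QUALITATIVE",
    "COUNT",
    "CAUDAL_FORMULA",
    "UNKNOWN",
    "Unknown",
    "CharacterDef",
    "CountRange",
    "CaudalFormula",
    "StateSet",
    "TaxonRecord",
    "CharacterMatrix",
    "Specimen",
    "SpecimenPanel",
    "parse_cell",
    "format_cell",
    "parse_matrix",
    "write_matrix",
    "write_nexus",
    "parse_specimens",
    "write_specimens",
    "compatible",
    "values_compatible",
]


class MorphokeyError(Exception):
    """Base class for all morphokey errors."""


class MatrixFormatError(MorphokeyError):
    """A malformed document cell; reports row, column and offending text."""

    def __init__(self, message, row=None, column=None, text=None):
        detail = message
        if row is not None or column is not None:
            detail += f" (row {row!r}, column {column!r}, cell {text!r})"
        super().__init__(detail)
        self.row, self.column, self.text = row, column, text


class KindMismatchError(MorphokeyError):
    """A value or observation does not match the character kind."""


# Character kinds
QUALITATIVE = "qualitative"
COUNT = "count"
CAUDAL_FORMULA = "caudal_formula"
_KINDS = (QUALITATIVE, COUNT, CAUDAL_FORMULA)


class Unknown:
    """Singleton marker for missing data; compatible with everything."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "UNKNOWN"


UNKNOWN = Unknown()


@dataclass(frozen=True)
class CharacterDef:
    """Definition of one character column of a matrix.

    ``vocabulary`` is meaningful only for qualitative characters and is a
    closed, ordered, duplicate-free list of state tokens.
    """

    id: str
    label: str = ""
    kind: str = QUALITATIVE
    vocabulary: tuple = ()
    description: str = ""

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise MorphokeyError(f"unknown character kind {self.kind!r}")
        object.__setattr__(self, "vocabulary", tuple(self.vocabulary))
        if self.kind == QUALITATIVE:
            if not self.vocabulary:
                raise MorphokeyError(
                    f"qualitative character {self.id!r} needs a non-empty vocabulary")
            if len(set(self.vocabulary)) != len(self.vocabulary):
                raise MorphokeyError(
                    f"duplicate state tokens in vocabulary of {self.id!r}")


@dataclass(frozen=True)
class CountRange:
    """Closed integer range [lo, hi]; a printed single value n is [n, n]."""

    lo: int
    hi: int

    def __post_init__(self):
        if not (0 <= self.lo <= self.hi):
            raise MorphokeyError(f"invalid count range [{self.lo}, {self.hi}]")

    def __contains__(self, n):
        return self.lo <= n <= self.hi

    def overlaps(self, other: "CountRange") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi

    def __str__(self):
        return str(self.lo) if self.lo == self.hi else f"{self.lo}-{self.hi}"


@dataclass(frozen=True)
class CaudalFormula:
    """Two-part branched-ray formula: upper lobe + lower lobe count ranges."""

    upper: CountRange
    lower: CountRange

    def matches(self, upper: int, lower: int) -> bool:
        return upper in self.upper and lower in self.lower

    def overlaps(self, other: "CaudalFormula") -> bool:
        return self.upper.overlaps(other.upper) and self.lower.overlaps(other.lower)

    def __str__(self):
        return f"/{self.upper} + {self.lower}/"


@dataclass(frozen=True)
class StateSet:
    """Non-empty subset of a qualitative character's vocabulary.

    Polymorphism ("Variable" cells) is a set of size > 1.
    """

    states: frozenset

    def __post_init__(self):
        object.__setattr__(self, "states", frozenset(self.states))
        if not self.states:
            raise MorphokeyError("state set may not be empty (use UNKNOWN)")

    @property
    def polymorphic(self):
        return len(self.states) > 1

    def __contains__(self, token):
        return token in self.states

    def __str__(self):
        return "/".join(sorted(self.states))


@dataclass
class TaxonRecord:
    """One taxon row: values for every character of the parent matrix.

    ``uncertain`` lists character ids whose printed value carried an explicit
    uncertainty mark (e.g. the "9 + 8?" caudal entry); uncertainty does not
    alter compatibility but is available to downstream consumers.
    """

    name: str
    values: dict = field(default_factory=dict)
    has_molecular_data: bool = True
    newly_described: bool = False
    uncertain: frozenset = frozenset()
    notes: str = ""

    def value(self, char_id):
        return self.values[char_id]


@dataclass
class CharacterMatrix:
    """Ordered characters x ordered taxa, with validation on construction."""

    characters: list
    taxa: list

    def __post_init__(self):
        ids = [c.id for c in self.characters]
        if len(set(ids)) != len(ids):
            raise MorphokeyError("duplicate character ids in matrix")
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise MorphokeyError(f"duplicate taxon name(s): {', '.join(dup)}")
        self._by_id = {c.id: c for c in self.characters}
        for t in self.taxa:
            for c in self.characters:
                if c.id not in t.values:
                    raise MorphokeyError(
                        f"taxon {t.name!r} has no value for character {c.id!r}")
                _check_value_kind(c, t.values[c.id], t.name)
            extra = set(t.values) - set(ids)
            if extra:
                raise MorphokeyError(
                    f"taxon {t.name!r} has values for unknown characters {sorted(extra)}")

    def character(self, char_id) -> CharacterDef:
        try:
            return self._by_id[char_id]
        except KeyError:
            raise MorphokeyError(f"no character {char_id!r} in matrix") from None

    @property
    def character_ids(self):
        return [c.id for c in self.characters]

    @property
    def taxon_names(self):
        return [t.name for t in self.taxa]

    def taxon(self, name) -> TaxonRecord:
        for t in self.taxa:
            if t.name == name:
                return t
        raise MorphokeyError(f"no taxon {name!r} in matrix")

    def value(self, taxon_name, char_id):
        return self.taxon(taxon_name).values[char_id]


def _check_value_kind(char: CharacterDef, value, taxon_name):
    if value is UNKNOWN:
        return
    if char.kind == QUALITATIVE:
        if not isinstance(value, StateSet):
            raise KindMismatchError(
                f"{taxon_name}/{char.id}: expected a state set, got {value!r}")
        bad = value.states - set(char.vocabulary)
        if bad:
            raise MorphokeyError(
                f"{taxon_name}/{char.id}: state(s) {sorted(bad)} outside vocabulary "
                f"{list(char.vocabulary)}")
    elif char.kind == COUNT:
        if not isinstance(value, CountRange):
            raise KindMismatchError(
                f"{taxon_name}/{char.id}: expected a count range, got {value!r}")
    elif char.kind == CAUDAL_FORMULA:
        if not isinstance(value, CaudalFormula):
            raise KindMismatchError(
                f"{taxon_name}/{char.id}: expected a caudal formula, got {value!r}")


@dataclass
class Specimen:
    """Concrete observations of one individual.

    Observations are point values: a state token, a single integer, or an
    exact (upper, lower) formula tuple.  A small *set* of point values is
    allowed for left/right asymmetric counts (the robertsi holotype has
    "8 and 7 pectoral-fin rays"); a set observation matches a species value
    if any member matches.
    """

    id: str
    observations: dict = field(default_factory=dict)
    provenance: str = ""

    def observed(self, char_id):
        return char_id in self.observations


@dataclass
class SpecimenPanel:
    """A named collection of specimens with shared provenance."""

    name: str
    specimens: list
    notes: str = ""
    perturbations: list = field(default_factory=list)

    def __post_init__(self):
        ids = [s.id for s in self.specimens]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise MorphokeyError(f"duplicate specimen id(s): {', '.join(dup)}")

    def __len__(self):
        return len(self.specimens)


# ---------------------------------------------------------------------------
# Cell grammar
#
#   cell       := "?" | "-" | value ["?"]
#   value      := INT | INT "-" INT | "/" formula "/" | token ("/" token)*
#   formula    := range "+" range
#   range      := INT | INT "-" INT
#
# En-dashes in printed ranges are accepted everywhere; the writer emits
# plain hyphens.  A trailing "?" inside a cell marks the value as uncertain
# (kept on the record, does not alter compatibility).
# ---------------------------------------------------------------------------

_DASH = re.compile(r"[–‒—]")  # en dash and friends -> hyphen
_RANGE_RE = re.compile(r"^(\d+)(?:-(\d+))?$")


def _parse_range(text):
    m = _RANGE_RE.match(text.strip())
    if not m:
        return None
    lo = int(m.group(1))
    hi = int(m.group(2)) if m.group(2) else lo
    return CountRange(lo, hi)


def parse_cell(text, kind=None, vocabulary=None):
    """Parse one matrix cell.

    Returns ``(value, uncertain)``.  If *kind* is None, the kind is inferred
    from the cell syntax.  Raises :class:`MatrixFormatError` on malformed
    cells (callers add row/column context).
    """
    raw = _DASH.sub("-", text.strip())
    if raw in ("?", "-", ""):
        return UNKNOWN, False
    uncertain = False
    if raw.startswith("/") :
        if not raw.endswith("/"):
            raise MatrixFormatError(f"unterminated formula {text!r}")
        body = raw[1:-1]
        if body.rstrip().endswith("?"):
            uncertain = True
            body = body.rstrip()[:-1]
        parts = body.split("+")
        if len(parts) != 2:
            raise MatrixFormatError(f"formula must have two lobes: {text!r}")
        upper, lower = (_parse_range(p) for p in parts)
        if upper is None or lower is None:
            raise MatrixFormatError(f"malformed formula range in {text!r}")
        value = CaudalFormula(upper, lower)
        if kind not in (None, CAUDAL_FORMULA):
            raise KindMismatchError(f"formula cell {text!r} for {kind} character")
        return value, uncertain
    if raw.endswith("?"):
        uncertain = True
        raw = raw[:-1].strip()
    rng = _parse_range(raw)
    if rng is not None and kind in (None, COUNT):
        return rng, uncertain
    if kind == COUNT:
        raise MatrixFormatError(f"malformed count cell {text!r}")
    if kind == CAUDAL_FORMULA:
        raise MatrixFormatError(f"malformed formula cell {text!r}")
    tokens = [t.strip() for t in raw.split("/")]
    if any(not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", t) for t in tokens):
        raise MatrixFormatError(f"malformed state cell {text!r}")
    if vocabulary is not None:
        bad = [t for t in tokens if t not in vocabulary]
        if bad:
            raise MatrixFormatError(
                f"unknown state token(s) {bad} (vocabulary {list(vocabulary)})")
    return StateSet(frozenset(tokens)), uncertain


def format_cell(value, uncertain=False):
    """Inverse of :func:`parse_cell` (hyphen-normalised)."""
    if value is UNKNOWN:
        return "?"
    if isinstance(value, CaudalFormula):
        if uncertain:
            return f"/{value.upper} + {value.lower}?/"
        return str(value)
    text = str(value)
    return text + "?" if uncertain else text


def parse_matrix(text, characters=None, synonyms=None) -> CharacterMatrix:
    """Parse a tab-separated matrix document.

    Row 1 holds character ids; column 1 holds taxon names.  Lines starting
    with ``#`` are comments.  If *characters* (a list of
    :class:`CharacterDef`) is given, cells are parsed strictly against the
    declared kinds and vocabularies; otherwise kinds are inferred from cell
    syntax and vocabularies collected from the observed tokens.

    *synonyms* maps character id -> {printed text -> normalised cell text}
    and is applied before parsing (e.g. ``"Variable" -> "present/absent"``).
    """
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not rows:
        raise MatrixFormatError("empty matrix document")
    header = rows[0].split("\t")
    char_ids = [h.strip() for h in header[1:]]
    if characters is not None:
        declared = {c.id: c for c in characters}
        missing = [cid for cid in char_ids if cid not in declared]
        if missing:
            raise MatrixFormatError(f"undeclared character id(s) {missing}")
    taxa_cells = []
    for line in rows[1:]:
        cells = line.split("\t")
        name = cells[0].strip()
        vals = [c for c in cells[1:]]
        if len(vals) != len(char_ids):
            raise MatrixFormatError(
                f"row for {name!r} has {len(vals)} cells, expected {len(char_ids)}",
                row=name)
        taxa_cells.append((name, vals))

    parsed = {}   # (taxon, char) -> (value, uncertain)
    inferred_kind = {}
    observed_tokens = {cid: [] for cid in char_ids}
    for name, vals in taxa_cells:
        for cid, raw in zip(char_ids, vals):
            raw = raw.strip()
            if synonyms and cid in synonyms and raw in synonyms[cid]:
                raw = synonyms[cid][raw]
            kind = declared[cid].kind if characters is not None else None
            vocab = (declared[cid].vocabulary
                     if characters is not None and kind == QUALITATIVE else None)
            try:
                value, unc = parse_cell(raw, kind=kind, vocabulary=vocab)
            except MorphokeyError as exc:
                raise MatrixFormatError(str(exc), row=name, column=cid, text=raw) from exc
            parsed[(name, cid)] = (value, unc)
            if characters is None and value is not UNKNOWN:
                k = (QUALITATIVE if isinstance(value, StateSet)
                     else COUNT if isinstance(value, CountRange) else CAUDAL_FORMULA)
                prev = inferred_kind.setdefault(cid, k)
                if prev != k:
                    raise MatrixFormatError(
                        "mixed cell kinds in column", row=name, column=cid, text=raw)
                if k == QUALITATIVE:
                    for tok in sorted(value.states):
                        if tok not in observed_tokens[cid]:
                            observed_tokens[cid].append(tok)

    if characters is None:
        characters = []
        for cid in char_ids:
            kind = inferred_kind.get(cid, QUALITATIVE)
            vocab = observed_tokens[cid] if kind == QUALITATIVE else ()
            if kind == QUALITATIVE and not vocab:
                vocab = ("?",)  # all-unknown column; placeholder vocabulary
            characters.append(CharacterDef(id=cid, kind=kind, vocabulary=vocab))
    else:
        characters = [declared[cid] for cid in char_ids]

    taxa = []
    for name, _ in taxa_cells:
        values, unc_ids = {}, set()
        for cid in char_ids:
            value, unc = parsed[(name, cid)]
            values[cid] = value
            if unc:
                unc_ids.add(cid)
        taxa.append(TaxonRecord(name=name, values=values, uncertain=frozenset(unc_ids)))
    return CharacterMatrix(characters=characters, taxa=taxa)


def write_matrix(matrix: CharacterMatrix) -> str:
    """Serialise a matrix so that ``parse_matrix`` round-trips it."""
    lines = ["\t".join(["taxon"] + matrix.character_ids)]
    for t in matrix.taxa:
        cells = [format_cell(t.values[cid], uncertain=cid in t.uncertain)
                 for cid in matrix.character_ids]
        lines.append("\t".join([t.name] + cells))
    return "\n".join(lines) + "\n"


def write_nexus(matrix, coded: dict) -> str:
    """Write per-taxon code strings as a NEXUS DATA block.

    *coded* maps taxon name -> code string over the morphocode state digits;
    ``?`` marks missing data and brace sets ``{01}`` polymorphism.  All code
    strings must have the same length (counting a brace set as one symbol).
    *matrix* (optional) fixes the taxon output order.
    """
    if matrix is not None:
        coded = {name: coded[name] for name in matrix.taxon_names if name in coded}
    def nchar(code):
        n, in_brace = 0, False
        for ch in code:
            if ch == "{":
                in_brace = True
                n += 1
            elif ch == "}":
                in_brace = False
            elif not in_brace:
                n += 1
        return n

    lengths = {name: nchar(code) for name, code in coded.items()}
    if len(set(lengths.values())) > 1:
        raise MorphokeyError(f"unequal code lengths: {lengths}")
    n_char = next(iter(lengths.values())) if lengths else 0
    symbols = sorted({ch for code in coded.values() for ch in code if ch.isdigit()})
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(coded)} NCHAR={n_char};",
        f"    FORMAT DATATYPE=STANDARD SYMBOLS=\"{''.join(symbols) or '01'}\" "
        "MISSING=? GAP=-;",
        "    MATRIX",
    ]
    width = max((len(n) for n in coded), default=0) + 2
    for name, code in coded.items():
        safe = name.replace(" ", "_")
        lines.append(f"        {safe:<{width}}{code}")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Specimen tables: column 1 = specimen id; cells are point values or {a,b}
# sets; caudal observations use the /u + l/ formula syntax with point counts.
# ---------------------------------------------------------------------------

_FORMULA_OBS = re.compile(r"^/?\s*(\d+)\s*\+\s*(\d+)\s*/?$")


def _parse_obs_point(text):
    raw = _DASH.sub("-", text.strip())
    m = _FORMULA_OBS.match(raw)
    if m:
        return (int(m.group(1)), int(m.group(2)))
    if raw.isdigit():
        return int(raw)
    if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", raw):
        return raw
    raise MatrixFormatError(f"malformed observation {text!r}")


def _parse_obs(text):
    raw = text.strip()
    if raw in ("", "?", "-"):
        return None
    if raw.startswith("{") and raw.endswith("}"):
        members = [m for m in raw[1:-1].split(",") if m.strip()]
        return frozenset(_parse_obs_point(m) for m in members)
    return _parse_obs_point(raw)


def _format_obs(obs):
    if isinstance(obs, frozenset):
        return "{" + ",".join(sorted(_format_obs(o) for o in obs)) + "}"
    if isinstance(obs, tuple):
        return f"/{obs[0]} + {obs[1]}/"
    return str(obs)


def parse_specimens(text) -> list:
    """Parse a tab-separated specimen table into a list of Specimens."""
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not rows:
        return []
    header = rows[0].split("\t")
    char_ids = [h.strip() for h in header[1:]]
    specimens = []
    seen = set()
    for line in rows[1:]:
        cells = line.split("\t")
        sid = cells[0].strip()
        if sid in seen:
            raise MorphokeyError(f"duplicate specimen id {sid!r}")
        seen.add(sid)
        obs = {}
        for cid, raw in zip(char_ids, cells[1:]):
            try:
                val = _parse_obs(raw)
            except MorphokeyError as exc:
                raise MatrixFormatError(str(exc), row=sid, column=cid, text=raw) from exc
            if val is not None:
                obs[cid] = val
        specimens.append(Specimen(id=sid, observations=obs))
    return specimens


def write_specimens(specimens, char_ids=None) -> str:
    if char_ids is None:
        char_ids = []
        for s in specimens:
            for cid in s.observations:
                if cid not in char_ids:
                    char_ids.append(cid)
    lines = ["\t".join(["specimen"] + list(char_ids))]
    for s in specimens:
        cells = [(_format_obs(s.observations[cid]) if cid in s.observations else "?")
                 for cid in char_ids]
        lines.append("\t".join([s.id] + cells))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Compatibility
# ---------------------------------------------------------------------------

def compatible(value, obs, kind=None) -> bool:
    """Is a specimen observation compatible with a species value?

    count: true iff lo <= obs <= hi; formula: true iff both lobes in range;
    qualitative: true iff obs in the state set; UNKNOWN matches everything.
    A frozenset observation matches if any member matches.
    """
    if value is UNKNOWN:
        return True
    if isinstance(obs, frozenset):
        return any(compatible(value, o, kind) for o in obs)
    if isinstance(value, CountRange):
        if not isinstance(obs, int):
            raise KindMismatchError(f"count value vs observation {obs!r}")
        return obs in value
    if isinstance(value, CaudalFormula):
        if not (isinstance(obs, tuple) and len(obs) == 2):
            raise KindMismatchError(f"formula value vs observation {obs!r}")
        return value.matches(*obs)
    if isinstance(value, StateSet):
        if not isinstance(obs, str):
            raise KindMismatchError(f"state value vs observation {obs!r}")
        return obs in value
    raise KindMismatchError(f"unsupported value {value!r}")


def values_compatible(a, b) -> bool:
    """Overlap test between two species-level values of the same character.

    Two values are compatible when their value sets intersect; UNKNOWN is
    compatible with everything.  Incompatibility (disjoint sets) is what
    makes a character *distinguishing* for a pair of taxa.
    """
    if a is UNKNOWN or b is UNKNOWN:
        return True
    if isinstance(a, CountRange) and isinstance(b, CountRange):
        return a.overlaps(b)
    if isinstance(a, CaudalFormula) and isinstance(b, CaudalFormula):
        return a.overlaps(b)
    if isinstance(a, StateSet) and isinstance(b, StateSet):
        return bool(a.states & b.states)
    raise KindMismatchError(f"cannot compare {a!r} with {b!r}")
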