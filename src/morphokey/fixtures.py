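"""Packaged in-paper datasets for the Schistura cincticauda species group.

Everything ships as plain-text package data with provenance headers: the
canonical 12x18 comparison matrix, the twelve-character integer morphocode
scheme (A-L) with its state legends, the printed dichotomous key, the
Phuket/MCZ specimen panels and the re-examined robertsi holotype, and a
constraints-only species tree (only the relationships the revision actually
asserts are fixed; the rest is a seeded arbitrary resolution and flagged as
such).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .datamodel import (
    UNKNOWN,
    CaudalFormula,
    CharacterDef,
    CharacterMatrix,
    CountRange,
    MorphokeyError,
    SpecimenPanel,
    StateSet,
    parse_matrix,
    parse_specimens,
)
from .key_engine import DichotomousKey, load_key_json
from .synthetic_data import random_resolved_tree

__all__ = [
    "OUTGROUP",
    "MorphocodeScheme",
    "MorphocodeCharacter",
    "load_table1",
    "load_morphocode",
    "derive_morphocode",
    "load_key",
    "load_specimen_panels",
    "load_constraint_tree",
]

OUTGROUP = "Cobitis taenia"

_PANEL_FILES = ("zrc_phuket.tsv", "mcz_paratypes.tsv", "robertsi_holotype.tsv")


def _read(name: str) -> str:
    return (resources.files("morphokey") / "data" / name).read_text(encoding="utf-8")


def load_table1() -> CharacterMatrix:
    """The canonical comparison matrix: 12 species x 18 characters.

    Taxon flags (molecular data available, newly described) and
    literature-derived provenance notes come from the companion character
    definition file.
    """
    meta = json.loads(_read("table1_characters.json"))
    characters = [
        CharacterDef(id=c["id"], label=c.get("label", ""), kind=c["kind"],
                     vocabulary=tuple(c.get("vocabulary", ())),
                     description=c.get("description", ""))
        for c in meta["characters"]
    ]
    matrix = parse_matrix(_read("table1.tsv"), characters=characters,
                          synonyms=meta.get("synonyms"))
    for record in matrix.taxa:
        info = meta["taxa"].get(record.name, {})
        record.has_molecular_data = bool(info.get("molecular", True))
        record.newly_described = bool(info.get("newly_described", False))
        record.notes = info.get("notes", "")
    return matrix


@dataclass(frozen=True)
class MorphocodeCharacter:
    code: str            # letter A..L
    label: str
    source: str          # character id in the matrix
    legend: str          # the state legend, quoted from the scheme
    states: dict         # digit -> value spec: {"counts": [...]}, {"formula": [u,l]}, {"tokens": [...]}


@dataclass(frozen=True)
class MorphocodeScheme:
    characters: tuple
    notes: tuple = ()

    def __post_init__(self):
        for ch in self.characters:
            if not ch.states:
                raise MorphokeyError(f"morphocode character {ch.code} has no states")
            for digit in ch.states:
                if digit not in ch.legend:
                    raise MorphokeyError(
                        f"state {digit} of character {ch.code} missing from legend")

    def character(self, code) -> MorphocodeCharacter:
        for ch in self.characters:
            if ch.code == code:
                return ch
        raise MorphokeyError(f"no morphocode character {code!r}")


def load_morphocode() -> MorphocodeScheme:
    """The integer morphocode scheme: 12 characters A-L with state legends."""
    raw = json.loads(_read("morphocode.json"))
    chars = tuple(
        MorphocodeCharacter(code=c["code"], label=c["label"], source=c["source"],
                            legend=c["legend"], states=c["states"])
        for c in raw["characters"])
    return MorphocodeScheme(characters=chars, notes=tuple(raw.get("notes", ())))


def _match_state(value, spec):
    """(verdict, state size) for one matrix value vs one legend state.

    verdict: 'equal' (value set identical to the state's value set),
    'subset' (value set strictly inside it), 'overlap', or 'none'.
    """
    if "counts" in spec:
        wanted = set(spec["counts"])
        have = set(range(value.lo, value.hi + 1))
        if have == wanted:
            return "equal", len(wanted)
        if have < wanted:
            return "subset", len(wanted)
        return ("overlap" if have & wanted else "none"), len(wanted)
    if "formula" in spec:
        u, l = spec["formula"]
        if (value.upper.lo, value.upper.hi, value.lower.lo, value.lower.hi) == (u, u, l, l):
            return "equal", 1
        return ("overlap" if (u in value.upper and l in value.lower) else "none"), 1
    tokens = set(spec["tokens"])
    if value.states == tokens:
        return "equal", len(tokens)
    if value.states < tokens:
        return "subset", len(tokens)
    return ("overlap" if value.states & tokens else "none"), len(tokens)


def derive_morphocode(matrix: CharacterMatrix, scheme: MorphocodeScheme):
    """Code strings per taxon (one symbol per scheme character) + warnings.

    A matrix value that equals a legend state codes silently; a value
    outside every legend state but *overlapping* exactly one is resolved to
    that state with a warning (the range-overlap rule); overlap with several
    states yields a polymorphic brace set with a warning; no overlap at all
    (or UNKNOWN) yields '?' (UNKNOWN silently, otherwise with a warning).
    """
    codes, warnings = {}, []
    for record in matrix.taxa:
        symbols = []
        for ch in scheme.characters:
            value = record.values.get(ch.source)
            if value is None:
                raise MorphokeyError(
                    f"scheme character {ch.code} sources missing matrix "
                    f"character {ch.source!r}")
            if value is UNKNOWN:
                symbols.append("?")
                continue
            verdicts = {digit: _match_state(value, spec)
                        for digit, spec in ch.states.items()}
            equal = sorted(d for d, (v, _) in verdicts.items() if v == "equal")
            if equal:
                symbols.append(equal[0])
                continue
            # a value strictly inside one legend state (e.g. a point count
            # within a two-value state): take the smallest containing state
            subsets = sorted((size, d) for d, (v, size) in verdicts.items()
                             if v == "subset")
            if subsets and (len(subsets) == 1 or subsets[0][0] < subsets[1][0]):
                symbols.append(subsets[0][1])
                continue
            hits = sorted(d for d, (v, _) in verdicts.items() if v != "none")
            if not hits:
                symbols.append("?")
                warnings.append(
                    f"{record.name}/{ch.code}: value {value} matches no legend "
                    f"state ({ch.legend})")
            elif len(hits) == 1:
                symbols.append(hits[0])
                warnings.append(
                    f"{record.name}/{ch.code}: value {value} not a legend state; "
                    f"resolved to {hits[0]} by range overlap")
            else:
                symbols.append("{" + "".join(hits) + "}")
                warnings.append(
                    f"{record.name}/{ch.code}: value {value} overlaps states "
                    f"{{{''.join(hits)}}}; coded polymorphic")
        codes[record.name] = "".join(symbols)
    return codes, warnings


def load_key() -> DichotomousKey:
    """The printed dichotomous key (couplets 1-11, 12 terminal species)."""
    return load_key_json(_read("key.json"))


def load_specimen_panels() -> list:
    """The three published specimen panels: ZRC-Phuket, MCZ paratypes, holotype."""
    panels = []
    for fname in _PANEL_FILES:
        text = _read(fname)
        name, notes = "", []
        for line in text.splitlines():
            stripped = line.strip()
            if stripped.startswith("# panel:"):
                name = stripped.split(":", 1)[1].strip()
            elif stripped.startswith("#"):
                notes.append(stripped.lstrip("# "))
        specimens = parse_specimens(text)
        panels.append(SpecimenPanel(name=name or fname, specimens=specimens,
                                    notes=" ".join(notes)))
    return panels


def load_constraint_tree(seed: int = 0):
    """A rooted species tree fixing only the documented constraints.

    The 12 species of the group form a clade (monophyly is demonstrated by
    the molecular analyses); S. paucifasciata is sister to S. balteata (the
    shared rare few-thin-bars colour pattern); one outgroup tip lies outside
    the group.  Every other ingroup relationship is an arbitrary seeded
    resolution, flagged ``arbitrary_resolution`` on the nodes.
    """
    matrix = load_table1()
    ingroup = matrix.taxon_names
    constraints = [frozenset(ingroup),
                   frozenset({"S. balteata", "S. paucifasciata"})]
    return random_resolved_tree(ingroup + [OUTGROUP], constraints, seed=seed)
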