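"""Diagnosability analysis over a character matrix.

A character *distinguishes* two taxa when their value sets are disjoint —
non-overlapping count ranges, disjoint state sets, or caudal formulae
disjoint in at least one lobe.  UNKNOWN never distinguishes.  On top of
this relation the module provides pairwise difference tables, the
unique-combination check, exhaustive minimal diagnostic-set search,
specimen classification with conflict reporting, and panel tallies that
reproduce published specimen arithmetic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .datamodel import (
    UNKNOWN,
    CharacterMatrix,
    MorphokeyError,
    Specimen,
    SpecimenPanel,
    compatible,
    values_compatible,
)

__all__ = [
    "PairwiseDiff",
    "DiagnosticSet",
    "ClassificationResult",
    "pairwise_diffs",
    "unique_combination_check",
    "minimal_diagnostic_sets",
    "classify_specimen",
    "panel_report",
]


@dataclass(frozen=True)
class PairwiseDiff:
    taxon_a: str
    taxon_b: str
    distinguishing: tuple   # character ids with disjoint value sets

    def involves(self, name):
        return name in (self.taxon_a, self.taxon_b)


def pairwise_diffs(matrix: CharacterMatrix) -> list:
    """All unordered taxon pairs with their distinguishing characters."""
    if len(matrix.taxa) < 2:
        raise MorphokeyError("pairwise differences need at least two taxa")
    out = []
    for a, b in itertools.combinations(matrix.taxa, 2):
        chars = tuple(
            c.id for c in matrix.characters
            if not values_compatible(a.values[c.id], b.values[c.id]))
        out.append(PairwiseDiff(taxon_a=a.name, taxon_b=b.name,
                                distinguishing=chars))
    return out


def unique_combination_check(matrix: CharacterMatrix):
    """(True, []) iff every pair of taxa is distinguishable by >= 1 character."""
    if len(matrix.taxa) < 2:
        return True, []
    offending = [(d.taxon_a, d.taxon_b) for d in pairwise_diffs(matrix)
                 if not d.distinguishing]
    return (not offending), offending


@dataclass(frozen=True)
class DiagnosticSet:
    taxon: str
    characters: tuple
    minimal: bool = True


def _distinguishes(matrix, focal, other, char_ids) -> bool:
    return any(
        not values_compatible(focal.values[cid], other.values[cid])
        for cid in char_ids)


def minimal_diagnostic_sets(matrix: CharacterMatrix, taxon: str,
                            k_max: int = 4, include_uncertain: bool = False) -> list:
    """All minimal character subsets of size <= k_max diagnostic for *taxon*.

    A subset is diagnostic when no other taxon is compatible with the focal
    taxon on all its members; minimal when no proper subset is diagnostic.
    Enumeration is exhaustive, ordered by size then character order.
    Characters whose focal value is UNKNOWN can never contribute; characters
    flagged uncertain on the focal record are excluded unless
    *include_uncertain* is set.
    """
    focal = matrix.taxon(taxon)
    if not (1 <= k_max <= len(matrix.characters)):
        raise MorphokeyError(f"k_max must be in [1, {len(matrix.characters)}]")
    usable = [c.id for c in matrix.characters
              if focal.values[c.id] is not UNKNOWN
              and (include_uncertain or c.id not in focal.uncertain)]
    others = [t for t in matrix.taxa if t.name != taxon]
    found = []
    found_sets = []
    order = {cid: i for i, cid in enumerate(matrix.character_ids)}
    for size in range(1, k_max + 1):
        for combo in itertools.combinations(usable, size):
            if any(set(prev) <= set(combo) for prev in found_sets):
                continue   # a subset is already diagnostic: not minimal
            if all(_distinguishes(matrix, focal, o, combo) for o in others):
                found_sets.append(combo)
                found.append(DiagnosticSet(taxon=taxon, characters=combo,
                                           minimal=True))
    found.sort(key=lambda d: (len(d.characters),
                              tuple(order[c] for c in d.characters)))
    return found


@dataclass
class ClassificationResult:
    specimen_id: str
    per_character: dict          # char id -> sorted candidate taxon list
    overall: tuple               # intersection over observed characters
    status: str                  # unique | multiple | conflict
    conflicts: list = field(default_factory=list)  # (char a, char b) disjoint pairs

    def to_json(self):
        return {"specimen": self.specimen_id, "status": self.status,
                "overall": list(self.overall),
                "per_character": {k: list(v) for k, v in self.per_character.items()},
                "conflicts": [list(c) for c in self.conflicts]}


def classify_specimen(matrix: CharacterMatrix, specimen: Specimen) -> ClassificationResult:
    """Candidate taxa per observed character and their intersection.

    ``conflict`` status means the intersection is empty; the conflict detail
    names the pairs of observed characters whose candidate sets are
    disjoint (the situation of the Phuket specimens, whose pectoral counts
    point one way and caudal formulae another).
    """
    if not specimen.observations:
        raise MorphokeyError(f"specimen {specimen.id!r} has no observations")
    missing = [c for c in specimen.observations if c not in matrix.character_ids]
    if missing:
        raise MorphokeyError(
            f"specimen {specimen.id!r} observes character(s) absent from the "
            f"matrix: {sorted(missing)}")
    per_char = {}
    for cid, obs in specimen.observations.items():
        per_char[cid] = tuple(
            t.name for t in matrix.taxa if compatible(t.values[cid], obs))
    overall = set(matrix.taxon_names)
    for cands in per_char.values():
        overall &= set(cands)
    overall = tuple(t for t in matrix.taxon_names if t in overall)
    if len(overall) == 1:
        status = "unique"
    elif overall:
        status = "multiple"
    else:
        status = "conflict"
    conflicts = []
    if status == "conflict":
        for a, b in itertools.combinations(sorted(per_char), 2):
            if not (set(per_char[a]) & set(per_char[b])):
                conflicts.append((a, b))
    return ClassificationResult(specimen_id=specimen.id, per_character=per_char,
                                overall=overall, status=status, conflicts=conflicts)


def panel_report(matrix: CharacterMatrix, panel: SpecimenPanel) -> dict:
    """Tally of specimens compatible with each taxon, per observed character.

    Returns {character id: {taxon: count}} over the characters observed in
    the panel, plus a "_panel" entry with name and size.  A specimen counts
    towards a (character, taxon) cell when its observation is compatible
    with the taxon's value for that character — the arithmetic behind
    statements like "12 specimens have 8 + 8 branched caudal-fin rays
    (diagnostic for S. peninsulae)".
    """
    if not panel.specimens:
        raise MorphokeyError(f"panel {panel.name!r} is empty")
    observed = []
    for s in panel.specimens:
        for cid in s.observations:
            if cid not in observed:
                observed.append(cid)
    report = {"_panel": {"name": panel.name, "size": len(panel.specimens)}}
    for cid in observed:
        if cid not in matrix.character_ids:
            raise MorphokeyError(f"panel observes unknown character {cid!r}")
        counts = {}
        for t in matrix.taxa:
            counts[t.name] = sum(
                1 for s in panel.specimens
                if cid in s.observations
                and compatible(t.values[cid], s.observations[cid]))
        report[cid] = counts
    return report
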