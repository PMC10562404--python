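"""Seeded generators for matrices, specimen panels and constrained trees.

The generators emulate the statistical shape of a taxonomic comparison
table: a mix of qualitative characters with small closed vocabularies,
meristic counts stored as narrow integer ranges (width 0-2), and two-part
caudal formulae; a small fraction of polymorphic ("Variable") cells and of
unobserved ("?") cells.  All randomness flows from one explicit seed via a
single numpy Generator; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datamodel import (
    CAUDAL_FORMULA,
    COUNT,
    QUALITATIVE,
    UNKNOWN,
    CaudalFormula,
    CharacterDef,
    CharacterMatrix,
    CountRange,
    MorphokeyError,
    Specimen,
    SpecimenPanel,
    StateSet,
    TaxonRecord,
)
from .ancestral import RootedTree, TreeNode

__all__ = ["SimConfig", "random_matrix", "specimens_from_taxon",
           "random_resolved_tree"]


@dataclass(frozen=True)
class SimConfig:
    """Shape of a simulated character matrix.

    Defaults mirror the canonical 12x18 comparison matrix: half of the
    characters qualitative (2-4 states), most of the rest meristic counts
    with range widths 0-2, a formula character or two, a couple of percent
    of polymorphic cells and of unknown cells.
    """

    n_taxa: int = 12
    n_characters: int = 18
    frac_qualitative: float = 0.5
    frac_count: float = 0.39
    frac_caudal: float = 0.11
    n_states: int = 3
    count_width_min: int = 0
    count_width_max: int = 2
    polymorphism_rate: float = 0.02
    unknown_rate: float = 0.03
    disjoint: bool = False
    seed: int = 0

    def __post_init__(self):
        total = self.frac_qualitative + self.frac_count + self.frac_caudal
        if abs(total - 1.0) > 1e-9:
            raise MorphokeyError(f"kind fractions must sum to 1, got {total}")
        for name in ("polymorphism_rate", "unknown_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise MorphokeyError(f"{name} must be in [0,1], got {r}")
        if self.n_taxa < 1 or self.n_characters < 1:
            raise MorphokeyError("need at least one taxon and one character")
        if not (0 <= self.count_width_min <= self.count_width_max):
            raise MorphokeyError("invalid count width bounds")
        if self.n_states < 2:
            raise MorphokeyError("qualitative characters need >= 2 states")


def _kind_counts(config: SimConfig):
    n = config.n_characters
    n_qual = round(config.frac_qualitative * n)
    n_count = round(config.frac_count * n)
    n_caudal = n - n_qual - n_count
    if n_caudal < 0:
        n_count += n_caudal
        n_caudal = 0
    return n_qual, n_count, n_caudal


def random_matrix(config: SimConfig) -> CharacterMatrix:
    """Generate a matrix satisfying all data-model invariants.

    With ``unknown_rate 0`` and ``polymorphism_rate 0`` every cell is a
    point or narrow-range value; with ``disjoint`` the per-taxon values of
    every character are pairwise non-overlapping (each taxon then carries a
    full unique combination).  Regeneration with the same config is
    bit-identical.
    """
    rng = np.random.default_rng(config.seed)
    n_qual, n_count, n_caudal = _kind_counts(config)
    kinds = ([QUALITATIVE] * n_qual + [COUNT] * n_count + [CAUDAL_FORMULA] * n_caudal)

    n_states = config.n_taxa if config.disjoint else config.n_states
    characters = []
    for i, kind in enumerate(kinds):
        vocab = tuple(f"s{j}" for j in range(n_states)) if kind == QUALITATIVE else ()
        characters.append(CharacterDef(id=f"c{i:02d}", label=f"character {i}",
                                       kind=kind, vocabulary=vocab))

    # per-character generation parameters
    stride = config.count_width_max + 1
    taxa_values = [dict() for _ in range(config.n_taxa)]
    for char in characters:
        if char.kind == QUALITATIVE:
            for j in range(config.n_taxa):
                if config.disjoint:
                    taxa_values[j][char.id] = StateSet(frozenset({f"s{j}"}))
                    continue
                if rng.random() < config.unknown_rate:
                    taxa_values[j][char.id] = UNKNOWN
                    continue
                base = int(rng.integers(0, n_states))
                states = {f"s{base}"}
                if rng.random() < config.polymorphism_rate:
                    other = int(rng.integers(0, n_states - 1))
                    if other >= base:
                        other += 1
                    states.add(f"s{other}")
                taxa_values[j][char.id] = StateSet(frozenset(states))
        elif char.kind == COUNT:
            centre = int(rng.integers(3, 40))
            for j in range(config.n_taxa):
                width = int(rng.integers(config.count_width_min,
                                         config.count_width_max + 1))
                if config.disjoint:
                    lo = centre + j * stride
                else:
                    if rng.random() < config.unknown_rate:
                        taxa_values[j][char.id] = UNKNOWN
                        continue
                    lo = max(0, centre + int(rng.integers(-2, 3)))
                taxa_values[j][char.id] = CountRange(lo, lo + width)
        else:  # caudal formula
            u0 = int(rng.integers(6, 10))
            l0 = int(rng.integers(6, 10))
            for j in range(config.n_taxa):
                wu = int(rng.integers(0, 2))
                wl = int(rng.integers(0, 2))
                if config.disjoint:
                    ulo = u0 + j * 2
                    llo = l0
                else:
                    if rng.random() < config.unknown_rate:
                        taxa_values[j][char.id] = UNKNOWN
                        continue
                    ulo = max(0, u0 + int(rng.integers(-1, 2)))
                    llo = max(0, l0 + int(rng.integers(-1, 2)))
                taxa_values[j][char.id] = CaudalFormula(
                    CountRange(ulo, ulo + wu), CountRange(llo, llo + wl))

    taxa = [TaxonRecord(name=f"taxon{j:02d}", values=taxa_values[j])
            for j in range(config.n_taxa)]
    return CharacterMatrix(characters=characters, taxa=taxa)


def specimens_from_taxon(matrix: CharacterMatrix, taxon: str, n: int,
                         noise_rate: float = 0.0, seed: int = 0) -> SpecimenPanel:
    """Draw *n* specimens from a taxon's value sets.

    Each observation is sampled uniformly from the taxon's value set
    (UNKNOWN characters yield no observation).  With probability
    *noise_rate* an observation is perturbed to an adjacent count or an
    alternative state; every perturbation is appended to the panel's
    ``perturbations`` log as (specimen id, character id, original,
    perturbed).
    """
    record = matrix.taxon(taxon)
    rng = np.random.default_rng(seed)
    specimens, log = [], []
    for i in range(n):
        sid = f"{taxon}-sim-{i:03d}"
        obs = {}
        for char in matrix.characters:
            value = record.values[char.id]
            if value is UNKNOWN:
                continue
            if isinstance(value, StateSet):
                point = str(rng.choice(sorted(value.states)))
            elif isinstance(value, CountRange):
                point = int(rng.integers(value.lo, value.hi + 1))
            else:
                point = (int(rng.integers(value.upper.lo, value.upper.hi + 1)),
                         int(rng.integers(value.lower.lo, value.lower.hi + 1)))
            if noise_rate > 0 and rng.random() < noise_rate:
                perturbed = _perturb(point, char, rng)
                if perturbed is not None and perturbed != point:
                    log.append((sid, char.id, point, perturbed))
                    point = perturbed
            obs[char.id] = point
        specimens.append(Specimen(id=sid, observations=obs,
                                  provenance=f"simulated from {taxon}"))
    return SpecimenPanel(name=f"sim-{taxon}", specimens=specimens,
                         notes=f"{n} specimens simulated from {taxon}",
                         perturbations=log)


def _perturb(point, char: CharacterDef, rng):
    if isinstance(point, str):
        others = [s for s in char.vocabulary if s != point]
        if not others:
            return None
        return str(rng.choice(others))
    if isinstance(point, int):
        step = 1 if rng.random() < 0.5 else -1
        return max(0, point + step)
    upper, lower = point
    step = 1 if rng.random() < 0.5 else -1
    if rng.random() < 0.5:
        return (max(0, upper + step), lower)
    return (upper, max(0, lower + step))


# ---------------------------------------------------------------------------
# Constrained random trees
# ---------------------------------------------------------------------------

def _check_constraints(tips, constraints):
    tipset = set(tips)
    norm = []
    for c in constraints:
        c = frozenset(c)
        if not c <= tipset:
            raise MorphokeyError(f"constraint {sorted(c)} has tips outside the tree")
        if len(c) < 2:
            raise MorphokeyError(f"constraint {sorted(c)} is trivial")
        norm.append(c)
    for a in norm:
        for b in norm:
            if a is b:
                continue
            if a & b and not (a <= b or b <= a):
                raise MorphokeyError(
                    f"incompatible constraints {sorted(a)} / {sorted(b)}")
    return norm


def random_resolved_tree(tips, constraints=(), seed: int = 0) -> RootedTree:
    """Fully bifurcating rooted tree honouring every required clade.

    Nodes forced by a constraint are flagged ``arbitrary_resolution=False``;
    every other internal node is an arbitrary, seeded resolution and is
    flagged as such.  Incompatible (overlapping, non-nested) constraints
    raise an error.
    """
    tips = list(tips)
    if len(set(tips)) != len(tips):
        raise MorphokeyError("duplicate tip labels")
    if not tips:
        raise MorphokeyError("need at least one tip")
    norm = _check_constraints(tips, constraints)
    rng = np.random.default_rng(seed)

    def build(tip_subset, constrained: bool):
        inner = [c for c in norm if c < tip_subset]
        maximal = [c for c in inner
                   if not any(c < d for d in inner)]
        covered = set().union(*maximal) if maximal else set()
        blocks = [build(c, True) for c in sorted(maximal, key=sorted)]
        blocks += [TreeNode(label=t) for t in sorted(tip_subset - covered)]
        while len(blocks) > 1:
            i = int(rng.integers(0, len(blocks)))
            a = blocks.pop(i)
            j = int(rng.integers(0, len(blocks)))
            b = blocks.pop(j)
            joined = TreeNode(children=[a, b], arbitrary_resolution=True)
            blocks.append(joined)
        root = blocks[0]
        if not root.is_leaf:
            root.arbitrary_resolution = not constrained
        return root

    return RootedTree(build(frozenset(tips), constrained=False))
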