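"""Dichotomous identification keys: represent, run, verify, render, generate.

A key is a set of numbered couplets, each with exactly two leads; a lead is a
conjunction of predicates plus a target (another couplet or a terminal
taxon).  Evaluation follows *every* satisfied lead: species-level ranges,
polymorphic cells and unknowns may satisfy both leads of a couplet, in which
case both branches are explored and all reached terminals are reported.
Soft predicates (live coloration, geography) are carried verbatim but are
excluded from routing unless explicitly enabled.
"""

from __future__ import annotations

import itertools
import json
from collections import deque
from dataclasses import dataclass, field

from .datamodel import (
    CAUDAL_FORMULA,
    COUNT,
    QUALITATIVE,
    UNKNOWN,
    CaudalFormula,
    CharacterMatrix,
    CountRange,
    MorphokeyError,
    Specimen,
    StateSet,
    TaxonRecord,
)

__all__ = [
    "KeyStructureError",
    "Predicate",
    "Lead",
    "Couplet",
    "DichotomousKey",
    "KeyTrace",
    "VerificationReport",
    "key_from_json",
    "key_to_json",
    "load_key_json",
    "evaluate_key",
    "verify_key",
    "generate_key",
    "render_key",
    "parse_rendered_key",
]


class KeyStructureError(MorphokeyError):
    """The key violates a structural invariant (cycles, bad targets, ...)."""


@dataclass(frozen=True)
class Predicate:
    """One testable condition of a lead.

    ``test`` is one of
      ("in", frozenset_of_state_tokens)
      ("range", CountRange)
      ("lobe", "upper"|"lower", CountRange)
      ("formula", (upper, lower))          -- exact point formula
    or None for a purely soft (free-text) predicate.
    """

    char: str | None
    test: tuple | None
    soft: bool = False
    text: str = ""

    def matches(self, value) -> bool:
        """Overlap semantics against a species value or specimen observation.

        UNKNOWN / unobserved (None) satisfies every predicate; an observation
        set (frozenset) matches if any member matches.
        """
        if self.test is None:
            return True
        if value is None or value is UNKNOWN:
            return True
        if isinstance(value, frozenset):
            return any(self.matches(v) for v in value)
        op = self.test[0]
        if op == "in":
            tokens = self.test[1]
            if isinstance(value, StateSet):
                return bool(value.states & tokens)
            if isinstance(value, str):
                return value in tokens
        elif op == "range":
            rng = self.test[1]
            if isinstance(value, CountRange):
                return value.overlaps(rng)
            if isinstance(value, int):
                return value in rng
        elif op == "lobe":
            which, rng = self.test[1], self.test[2]
            if isinstance(value, CaudalFormula):
                return getattr(value, which).overlaps(rng)
            if isinstance(value, tuple):
                return (value[0] if which == "upper" else value[1]) in rng
        elif op == "formula":
            u, l = self.test[1]
            if isinstance(value, CaudalFormula):
                return u in value.upper and l in value.lower
            if isinstance(value, tuple):
                return value == (u, l)
        raise MorphokeyError(
            f"predicate on {self.char!r} cannot test value {value!r}")

    def describe(self) -> str:
        if self.text:
            return self.text
        if self.test is None:
            return "(unstated)"
        op = self.test[0]
        if op == "in":
            return f"{self.char} = {'/'.join(sorted(self.test[1]))}"
        if op == "range":
            return f"{self.char} {self.test[1]}"
        if op == "lobe":
            return f"{self.char} {self.test[1]} lobe {self.test[2]}"
        if op == "formula":
            u, l = self.test[1]
            return f"{self.char} {u} + {l}"
        return repr(self.test)


@dataclass(frozen=True)
class Lead:
    predicates: tuple
    target: tuple  # ("couplet", id) or ("taxon", name)

    def __post_init__(self):
        if not self.predicates:
            raise KeyStructureError("a lead needs at least one predicate")

    def satisfied_by(self, get_value, include_soft=False) -> bool:
        for p in self.predicates:
            if p.soft and not include_soft:
                continue
            if not p.matches(get_value(p.char)):
                return False
        return True


@dataclass(frozen=True)
class Couplet:
    id: int
    leads: tuple

    def __post_init__(self):
        if self.id < 1:
            raise KeyStructureError(f"couplet id must be positive, got {self.id}")
        if len(self.leads) != 2:
            raise KeyStructureError(
                f"couplet {self.id} must have exactly two leads, got {len(self.leads)}")


@dataclass
class DichotomousKey:
    couplets: dict
    start: int

    def __post_init__(self):
        self.validate()

    def validate(self, matrix: CharacterMatrix | None = None):
        if self.start not in self.couplets:
            raise KeyStructureError(f"start couplet {self.start} not in key")
        for cid, c in self.couplets.items():
            if cid != c.id:
                raise KeyStructureError(f"couplet indexed {cid} carries id {c.id}")
            for lead in c.leads:
                kind, ref = lead.target
                if kind == "couplet" and ref not in self.couplets:
                    raise KeyStructureError(
                        f"couplet {cid} points to missing couplet {ref}")
        # acyclicity + reachability from start
        colour = {}
        order = []

        def dfs(cid):
            colour[cid] = "grey"
            for lead in self.couplets[cid].leads:
                kind, ref = lead.target
                if kind == "couplet":
                    if colour.get(ref) == "grey":
                        raise KeyStructureError(f"cycle through couplet {ref}")
                    if ref not in colour:
                        dfs(ref)
            colour[cid] = "black"
            order.append(cid)

        dfs(self.start)
        unreachable = set(self.couplets) - set(colour)
        if unreachable:
            raise KeyStructureError(
                f"couplet(s) {sorted(unreachable)} unreachable from start")
        if matrix is not None:
            missing = [t for t in self.terminal_taxa() if t not in matrix.taxon_names]
            if missing:
                raise KeyStructureError(
                    f"terminal taxon/taxa not in matrix: {', '.join(missing)}")

    def terminal_taxa(self):
        """Distinct terminal taxa, in couplet order."""
        seen = []
        for cid in sorted(self.couplets):
            for lead in self.couplets[cid].leads:
                kind, ref = lead.target
                if kind == "taxon" and ref not in seen:
                    seen.append(ref)
        return seen


@dataclass
class KeyTrace:
    path: list
    terminals: frozenset
    status: str                      # unique | ambiguous | dead_end
    dead_ends: list = field(default_factory=list)  # (couplet id, reason)


# ---------------------------------------------------------------------------
# JSON form
# ---------------------------------------------------------------------------

def _predicate_from_json(obj) -> Predicate:
    if not isinstance(obj, dict):
        raise KeyStructureError(f"predicate must be an object, got {obj!r}")
    soft = bool(obj.get("soft", False))
    text = obj.get("text", "")
    char = obj.get("char")
    if "in" in obj:
        test = ("in", frozenset(obj["in"]))
    elif "lobe" in obj:
        lo, hi = obj["range"]
        test = ("lobe", obj["lobe"], CountRange(lo, hi))
    elif "range" in obj:
        lo, hi = obj["range"]
        test = ("range", CountRange(lo, hi))
    elif "formula" in obj:
        u, l = obj["formula"]
        test = ("formula", (u, l))
    elif soft:
        test = None
    else:
        raise KeyStructureError(f"predicate without a test: {obj!r}")
    if test is not None and char is None:
        raise KeyStructureError(f"non-soft predicate needs a character: {obj!r}")
    return Predicate(char=char, test=test, soft=soft, text=text)


def _predicate_to_json(p: Predicate):
    obj = {}
    if p.char is not None:
        obj["char"] = p.char
    if p.test is not None:
        op = p.test[0]
        if op == "in":
            obj["in"] = sorted(p.test[1])
        elif op == "range":
            obj["range"] = [p.test[1].lo, p.test[1].hi]
        elif op == "lobe":
            obj["lobe"] = p.test[1]
            obj["range"] = [p.test[2].lo, p.test[2].hi]
        elif op == "formula":
            obj["formula"] = list(p.test[1])
    if p.soft:
        obj["soft"] = True
    if p.text:
        obj["text"] = p.text
    return obj


def key_from_json(obj) -> DichotomousKey:
    """Build and validate a key from its JSON object form."""
    if not isinstance(obj, dict) or "couplets" not in obj or "start" not in obj:
        raise KeyStructureError("key JSON needs 'start' and 'couplets'")
    couplets = {}
    for cobj in obj["couplets"]:
        leads = []
        for lobj in cobj.get("leads", []):
            tgt = lobj.get("target", {})
            if "couplet" in tgt:
                target = ("couplet", int(tgt["couplet"]))
            elif "taxon" in tgt:
                target = ("taxon", tgt["taxon"])
            else:
                raise KeyStructureError(f"lead without target in couplet {cobj.get('id')}")
            preds = tuple(_predicate_from_json(p) for p in lobj.get("predicates", []))
            leads.append(Lead(predicates=preds, target=target))
        cid = int(cobj["id"])
        if cid in couplets:
            raise KeyStructureError(f"duplicate couplet id {cid}")
        couplets[cid] = Couplet(id=cid, leads=tuple(leads))
    return DichotomousKey(couplets=couplets, start=int(obj["start"]))


def key_to_json(key: DichotomousKey):
    couplets = []
    for cid in sorted(key.couplets):
        c = key.couplets[cid]
        leads = []
        for lead in c.leads:
            kind, ref = lead.target
            leads.append({
                "predicates": [_predicate_to_json(p) for p in lead.predicates],
                "target": {kind: ref},
            })
        couplets.append({"id": cid, "leads": leads})
    return {"start": key.start, "couplets": couplets}


def load_key_json(text: str) -> DichotomousKey:
    return key_from_json(json.loads(text))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _value_getter(subject, matrix: CharacterMatrix | None):
    """Return a char-id -> value function for a specimen or taxon record."""
    if isinstance(subject, TaxonRecord):
        def get(char):
            if char is None:
                return None
            try:
                return subject.values[char]
            except KeyError:
                raise MorphokeyError(
                    f"predicate references character {char!r} absent from "
                    f"taxon record {subject.name!r}") from None
        return get
    if isinstance(subject, Specimen):
        def get(char):
            if char is None:
                return None
            if char in subject.observations:
                return subject.observations[char]
            if matrix is not None and char not in matrix.character_ids:
                raise MorphokeyError(
                    f"predicate references character {char!r} absent from the "
                    f"specimen and from the matrix")
            return None   # unobserved: treated like UNKNOWN
        return get
    raise MorphokeyError(f"cannot key out subject {subject!r}")


def evaluate_key(key: DichotomousKey, subject, matrix=None,
                 include_soft=False) -> KeyTrace:
    """Run a subject through the key, following every satisfied lead.

    UNKNOWN and unobserved characters satisfy both leads of a couplet; a
    couplet where neither lead is satisfied contributes a dead end.  The
    returned trace lists visited couplets in breadth-first order, the set of
    terminal taxa reached, and a status (unique / ambiguous / dead_end).
    """
    get = _value_getter(subject, matrix)
    path, seen = [], set()
    terminals = set()
    dead_ends = []
    queue = deque([key.start])
    while queue:
        cid = queue.popleft()
        if cid in seen:
            continue
        seen.add(cid)
        path.append(cid)
        couplet = key.couplets[cid]
        followed = 0
        for lead in couplet.leads:
            if lead.satisfied_by(get, include_soft=include_soft):
                followed += 1
                kind, ref = lead.target
                if kind == "taxon":
                    terminals.add(ref)
                else:
                    queue.append(ref)
        if followed == 0:
            reason = " | ".join(
                " AND ".join(p.describe() for p in lead.predicates if not p.soft)
                for lead in couplet.leads)
            dead_ends.append((cid, reason))
    status = ("dead_end" if not terminals
              else "unique" if len(terminals) == 1 else "ambiguous")
    return KeyTrace(path=path, terminals=frozenset(terminals), status=status,
                    dead_ends=dead_ends)


@dataclass
class VerificationReport:
    """Per-taxon key traces, with the taxa that fail to key out to themselves."""

    traces: dict        # taxon -> KeyTrace
    failures: dict      # taxon -> human-readable reason

    @property
    def ok(self):
        return not self.failures

    def to_json(self):
        return {
            "ok": self.ok,
            "failures": dict(self.failures),
            "traces": {t: {"path": tr.path, "terminals": sorted(tr.terminals),
                           "status": tr.status, "dead_ends": tr.dead_ends}
                       for t, tr in self.traces.items()},
        }


def verify_key(key: DichotomousKey, matrix: CharacterMatrix,
               include_soft=False) -> VerificationReport:
    """Route every taxon's own record through the key and report misfits.

    A taxon fails when its trace terminals differ from {itself}: misrouted
    (wrong taxon), ambiguous (extra taxa) or dead end (no taxon).  The
    failure message names the first offending couplet where determinable.
    """
    key.validate(matrix=matrix)
    traces, failures = {}, {}
    for record in matrix.taxa:
        trace = evaluate_key(key, record, matrix=matrix, include_soft=include_soft)
        traces[record.name] = trace
        if trace.terminals == frozenset({record.name}):
            continue
        if trace.status == "dead_end":
            cid, reason = trace.dead_ends[0]
            failures[record.name] = (
                f"dead end at couplet {cid}: no lead satisfied ({reason})")
        elif record.name not in trace.terminals:
            failures[record.name] = (
                f"misrouted: reached {sorted(trace.terminals)}"
                + (f"; dead end at couplet {trace.dead_ends[0][0]}"
                   if trace.dead_ends else ""))
        else:
            extra = sorted(trace.terminals - {record.name})
            failures[record.name] = f"ambiguous: also reached {extra}"
    return VerificationReport(traces=traces, failures=failures)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _qual_splits(char, records):
    vocab = list(char.vocabulary)
    seen = set()
    for r in range(1, len(vocab)):
        for combo in itertools.combinations(vocab, r):
            left = frozenset(combo)
            right = frozenset(vocab) - left
            if right in seen:
                continue
            seen.add(left)
            yield (Predicate(char.id, ("in", left)),
                   Predicate(char.id, ("in", right)),
                   f"in:{'|'.join(sorted(left))}")


def _count_bounds(values):
    los = [v.lo for v in values]
    his = [v.hi for v in values]
    return (min(los), max(his)) if los else None


def _count_splits(char, records):
    values = [r.values[char.id] for r in records if r.values[char.id] is not UNKNOWN]
    bounds = _count_bounds(values)
    if bounds is None:
        return
    lo, hi = bounds
    for t in range(lo, hi):
        yield (Predicate(char.id, ("range", CountRange(lo, t))),
               Predicate(char.id, ("range", CountRange(t + 1, hi))),
               f"range:<={t}")


def _formula_splits(char, records):
    values = [r.values[char.id] for r in records if r.values[char.id] is not UNKNOWN]
    for which in ("upper", "lower"):
        bounds = _count_bounds([getattr(v, which) for v in values])
        if bounds is None:
            continue
        lo, hi = bounds
        for t in range(lo, hi):
            yield (Predicate(char.id, ("lobe", which, CountRange(lo, t))),
                   Predicate(char.id, ("lobe", which, CountRange(t + 1, hi))),
                   f"lobe:{which}:<={t}")


def generate_key(matrix: CharacterMatrix,
                 objective="minimax-branch") -> DichotomousKey:
    """Greedily build a dichotomous key over all taxa of the matrix.

    At each node the (character, binary split of its value space) is chosen
    that optimises the objective over the taxa still compatible with the
    node; ranges, polymorphic cells and unknowns that straddle a split send
    the taxon down both branches.  Splits are scored to avoid straddling
    first (a duplicated taxon deepens two subtrees and breaks the n-1
    couplet bound), then by the stated objective, with ties broken by
    character order and the lexicographic split representation.

    Requires every taxon pair to be distinguishable by at least one
    character (the unique-combination condition).
    """
    from .diagnosis import unique_combination_check

    if objective not in ("minimax-branch", "min-expected-depth"):
        raise MorphokeyError(f"unknown objective {objective!r}")
    ok, offending = unique_combination_check(matrix)
    if not ok:
        pairs = ", ".join(f"({a}, {b})" for a, b in offending)
        raise MorphokeyError(
            f"indistinguishable taxon pair(s): {pairs}; see pairwise_diffs for "
            "the full report")

    split_makers = {QUALITATIVE: _qual_splits, COUNT: _count_splits,
                    CAUDAL_FORMULA: _formula_splits}

    def build(records):
        if len(records) == 1:
            return ("taxon", records[0].name)
        best = None
        for ci, char in enumerate(matrix.characters):
            for left_p, right_p, split_key in split_makers[char.kind](char, records):
                left, right, both = [], [], 0
                for rec in records:
                    v = rec.values[char.id]
                    inl = left_p.matches(v)
                    inr = right_p.matches(v)
                    if inl:
                        left.append(rec)
                    if inr:
                        right.append(rec)
                    if inl and inr:
                        both += 1
                if len(left) >= len(records) or len(right) >= len(records):
                    continue  # no progress on one side
                if not left or not right:
                    continue
                if objective == "minimax-branch":
                    score = (both, max(len(left), len(right)),
                             len(left) + len(right), ci, split_key)
                else:
                    score = (both, len(left) + len(right),
                             max(len(left), len(right)), ci, split_key)
                if best is None or score < best[0]:
                    best = (score, left_p, right_p, left, right)
        if best is None:
            names = [r.name for r in records]
            raise MorphokeyError(f"cannot separate taxa {names}")
        _, left_p, right_p, left, right = best
        return ("node", left_p, build(left), right_p, build(right))

    root = build(list(matrix.taxa))

    # number couplets breadth-first so the start couplet is 1
    couplets = {}
    counter = itertools.count(1)
    queue = deque()

    def enqueue(node):
        cid = next(counter)
        queue.append((cid, node))
        return cid

    if root[0] == "taxon":
        raise MorphokeyError("a single-taxon matrix does not need a key")
    enqueue(root)
    while queue:
        cid, node = queue.popleft()
        _, left_p, left_c, right_p, right_c = node
        leads = []
        for pred, child in ((left_p, left_c), (right_p, right_c)):
            if child[0] == "taxon":
                leads.append(Lead(predicates=(pred,), target=("taxon", child[1])))
            else:
                child_id = enqueue(child)
                leads.append(Lead(predicates=(pred,), target=("couplet", child_id)))
        couplets[cid] = Couplet(id=cid, leads=tuple(leads))
    return DichotomousKey(couplets=couplets, start=1)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_SIDECAR_MARK = "# --- key-json sidecar ---"


def render_key(key: DichotomousKey) -> str:
    """Couplet-style plain text with an embedded machine-readable sidecar."""
    lines = []
    for cid in sorted(key.couplets):
        c = key.couplets[cid]
        for i, lead in enumerate(c.leads):
            prefix = f"{cid} - " if i == 0 else " " * len(f"{cid} ") + "- "
            desc = "; ".join(p.describe() for p in lead.predicates)
            kind, ref = lead.target
            tgt = f"*{ref}*" if kind == "taxon" else str(ref)
            lines.append(f"{prefix}{desc}. ..... {tgt}")
    lines.append("")
    lines.append(_SIDECAR_MARK)
    payload = json.dumps(key_to_json(key), indent=None, sort_keys=True)
    lines.append("# " + payload)
    return "\n".join(lines) + "\n"


def parse_rendered_key(text: str) -> DichotomousKey:
    """Recover the key from rendered text via its embedded sidecar."""
    lines = text.splitlines()
    for i, ln in enumerate(lines):
        if ln.strip() == _SIDECAR_MARK:
            payload = "\n".join(l[2:] if l.startswith("# ") else l
                                for l in lines[i + 1:])
            return load_key_json(payload)
    raise KeyStructureError("no key-json sidecar found in rendered text")
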