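"""Rooted trees and unordered-parsimony ancestral-state reconstruction.

The reconstruction is classic Fitch parsimony on binary trees, generalised
to polytomies with Hartigan's state-count rule; polymorphic tips enter the
downpass as multi-state sets (the standard ambiguity treatment, equivalent
to minimising over all resolutions of each polymorphic tip to one of its
states).  Branch lengths play no role.

Node state sets are reported keyed by a stable post-order numbering; tips
additionally by label.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

from .datamodel import UNKNOWN, MorphokeyError, StateSet

__all__ = [
    "TreeNode",
    "RootedTree",
    "FitchResult",
    "HomoplasyIndices",
    "SynapomorphyReport",
    "parse_newick",
    "write_newick",
    "fitch",
    "synapomorphies",
    "homoplasy",
]


@dataclass
class TreeNode:
    label: str | None = None
    children: list = field(default_factory=list)
    arbitrary_resolution: bool = False

    @property
    def is_leaf(self):
        return not self.children


class RootedTree:
    """A rooted tree with uniquely labelled tips; polytomies permitted."""

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [n.label for n in self.leaves()]
        if any(lbl is None for lbl in labels):
            raise MorphokeyError("every tip must be labelled")
        dup = sorted({l for l in labels if labels.count(l) > 1})
        if dup:
            raise MorphokeyError(f"duplicate tip label(s): {', '.join(dup)}")

    def postorder(self):
        out = []

        def walk(node):
            for ch in node.children:
                walk(ch)
            out.append(node)

        walk(self.root)
        return out

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def tip_labels(self):
        return [n.label for n in self.leaves()]

    def parents(self):
        par = {id(self.root): None}
        for node in self.postorder():
            for ch in node.children:
                par[id(ch)] = node
        return par

    def mrca(self, labels) -> TreeNode:
        """Most recent common ancestor of a set of tip labels."""
        want = set(labels)
        missing = want - set(self.tip_labels)
        if missing:
            raise MorphokeyError(f"tip(s) not in tree: {sorted(missing)}")
        best = None

        def tipset(node):
            nonlocal best
            if node.is_leaf:
                return {node.label}
            s = set()
            for ch in node.children:
                s |= tipset(ch)
            if want <= s and (best is None or len(s) < len(best[1])):
                best = (node, s)
            return s

        tipset(self.root)
        return best[0]

    def clade_tips(self, node) -> set:
        if node.is_leaf:
            return {node.label}
        out = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.label)
            else:
                stack.extend(n.children)
        return out

    def reroot_at_edge(self, child: TreeNode) -> "RootedTree":
        """New rooting with *child*'s subtree on one side of the root.

        Used to check that parsimony step counts are a property of the
        unrooted tree.
        """
        par = self.parents()
        if par[id(child)] is None:
            return RootedTree(_copy(self.root))
        # path from child up to the old root
        path = [child]
        while par[id(path[-1])] is not None:
            path.append(par[id(path[-1])])
        new_root = TreeNode()
        new_root.children.append(_copy(child))
        # rebuild the remainder hanging off the reversed path
        prev_new = new_root
        for i in range(1, len(path)):
            node = path[i]
            keep = [_copy(ch) for ch in node.children if ch is not path[i - 1]]
            carrier = TreeNode(label=node.label)
            carrier.children = keep
            prev_new.children.append(carrier)
            prev_new = carrier
        # the old root's carrier may be degree-1; splice it out
        _suppress_unifurcations(new_root)
        return RootedTree(new_root)


def _copy(node: TreeNode) -> TreeNode:
    new = TreeNode(label=node.label, arbitrary_resolution=node.arbitrary_resolution)
    new.children = [_copy(ch) for ch in node.children]
    return new


def _suppress_unifurcations(node: TreeNode):
    for i, ch in enumerate(list(node.children)):
        _suppress_unifurcations(ch)
    node.children = [
        (ch.children[0] if (len(ch.children) == 1 and ch.label is None) else ch)
        for ch in node.children
    ]


def parse_newick(text: str) -> RootedTree:
    """Parse a Newick string (labelled tips; polytomies permitted)."""
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True)
    except Exception as exc:
        raise MorphokeyError(f"malformed Newick: {exc}") from exc

    def convert(dnode):
        node = TreeNode(label=dnode.taxon.label if dnode.taxon is not None
                        else (dnode.label or None))
        node.children = [convert(ch) for ch in dnode.child_nodes()]
        return node

    return RootedTree(convert(dtree.seed_node))


def write_newick(tree: RootedTree) -> str:
    def fmt(node):
        label = node.label or ""
        if " " in label:
            label = f"'{label}'"
        if node.is_leaf:
            return label
        inner = ",".join(fmt(ch) for ch in node.children)
        return f"({inner}){label}"

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Fitch / Hartigan parsimony
# ---------------------------------------------------------------------------

@dataclass
class FitchResult:
    character_id: str
    steps: int
    downpass: dict      # node number -> frozenset of states
    final: dict         # node number -> frozenset (uppass / MPR sets)
    node_labels: dict   # node number -> tip label (tips only)
    mrca_number: dict   # kept empty; reserved

    def tip_final(self, label):
        for num, lbl in self.node_labels.items():
            if lbl == label:
                return self.final[num]
        raise MorphokeyError(f"no tip {label!r}")


def _normalise_states(value, vocabulary=None):
    if value is UNKNOWN or value is None:
        if not vocabulary:
            raise MorphokeyError("UNKNOWN tip state needs a vocabulary")
        return frozenset(vocabulary)
    if isinstance(value, StateSet):
        return frozenset(value.states)
    if isinstance(value, (set, frozenset, list, tuple)):
        return frozenset(value)
    return frozenset([value])


def fitch(tree: RootedTree, tip_states: dict, vocabulary=None,
          character_id="character") -> FitchResult:
    """Minimum-change reconstruction of an unordered character.

    *tip_states* maps tip label -> state, set of states (polymorphism), or
    UNKNOWN (expanded to the full *vocabulary*).  Steps equal the minimum
    number of state changes over all internal assignments; on binary trees
    this is classic Fitch, on polytomies the Hartigan generalisation.  The
    ``final`` sets are the MPR sets: states a node takes in at least one
    most-parsimonious reconstruction (polymorphic tips keep their full set).
    """
    nodes = tree.postorder()
    numbers = {id(n): i for i, n in enumerate(nodes)}
    tipsets = {}
    for node in nodes:
        if node.is_leaf:
            if node.label not in tip_states:
                raise MorphokeyError(f"tip {node.label!r} has no state")
            tipsets[id(node)] = _normalise_states(tip_states[node.label], vocabulary)
    alphabet = frozenset().union(*tipsets.values())

    down = {}
    near = {}   # Hartigan's secondary set: states with count == k-1
    steps = 0
    for node in nodes:
        i = numbers[id(node)]
        if node.is_leaf:
            down[i] = tipsets[id(node)]
            near[i] = frozenset()
            continue
        counts = dict.fromkeys(alphabet, 0)
        for ch in node.children:
            for s in down[numbers[id(ch)]]:
                counts[s] += 1
        k = max(counts.values())
        down[i] = frozenset(s for s, c in counts.items() if c == k)
        near[i] = frozenset(s for s, c in counts.items() if c == k - 1)
        steps += len(node.children) - k

    # Uppass (MPR sets).  Conditional on a parent MPR state p: if p is in
    # the node's max-count set it is the unique optimum; otherwise the
    # max-count states are optimal, joined by p itself when p reaches count
    # k-1.  The final set unions this over all parent MPR states.
    final = {}
    parents = tree.parents()
    for node in reversed(nodes):   # preorder
        i = numbers[id(node)]
        parent = parents[id(node)]
        if parent is None:
            final[i] = down[i]
        elif node.is_leaf:
            final[i] = down[i]     # polymorphic tips keep their full set
        else:
            fp = final[numbers[id(parent)]]
            out = fp & (down[i] | near[i])
            if fp - down[i]:
                out |= down[i]
            final[i] = frozenset(out)

    labels = {numbers[id(n)]: n.label for n in nodes if n.is_leaf}
    return FitchResult(character_id=character_id, steps=steps, downpass=down,
                       final=final, node_labels=labels, mrca_number={})


# ---------------------------------------------------------------------------
# Synapomorphies
# ---------------------------------------------------------------------------

@dataclass
class SynapomorphyReport:
    character_id: str
    states: frozenset        # derived state(s) reconstructed on the clade stem
    steps: int
    polymorphic_tips: list   # clade tips with more than one state
    ambiguous_mpr: bool      # an equally parsimonious non-synapomorphy mapping exists


def synapomorphies(tree: RootedTree, tip_states_by_char: dict, clade,
                   outgroup: str, vocabularies=None) -> list:
    """Characters whose state on the clade stem is derived vs the outgroup.

    *tip_states_by_char* maps character id -> {tip label -> state(s)}.
    The clade must be monophyletic in the tree and the outgroup outside it.
    A character is reported when the clade-internal reconstruction at the
    clade MRCA (the parsimony downpass set, which does not depend on how
    the rest of the tree is resolved) is disjoint from the outgroup's
    states.  MPR ambiguity — an equally parsimonious mapping that moves the
    gain inside the clade — is reported via ``ambiguous_mpr`` rather than
    disqualifying the character, and polymorphic clade tips are listed as a
    caveat.
    """
    clade = set(clade)
    mrca = tree.mrca(clade)
    clade_in_tree = tree.clade_tips(mrca)
    if clade_in_tree != clade:
        raise MorphokeyError(
            f"clade is not monophyletic: MRCA also spans "
            f"{sorted(clade_in_tree - clade)}")
    if outgroup in clade:
        raise MorphokeyError(f"outgroup {outgroup!r} lies inside the clade")

    reports = []
    nodes = tree.postorder()
    numbers = {id(n): i for i, n in enumerate(nodes)}
    for char_id, tip_states in sorted(tip_states_by_char.items()):
        vocab = (vocabularies or {}).get(char_id)
        result = fitch(tree, tip_states, vocabulary=vocab, character_id=char_id)
        mnum = numbers[id(mrca)]
        clade_states = result.downpass[mnum]
        out_states = _normalise_states(tip_states[outgroup], vocab)
        if clade_states & out_states:
            continue   # not derived relative to the outgroup (incl. constant)
        poly = sorted(t for t in clade
                      if len(_normalise_states(tip_states[t], vocab)) > 1)
        ambiguous = not (result.final[mnum] <= clade_states)
        reports.append(SynapomorphyReport(
            character_id=char_id, states=frozenset(clade_states),
            steps=result.steps, polymorphic_tips=poly, ambiguous_mpr=ambiguous))
    return reports


# ---------------------------------------------------------------------------
# Homoplasy indices
# ---------------------------------------------------------------------------

@dataclass
class HomoplasyIndices:
    character_id: str
    steps: int
    ci: float | None     # consistency index (k-1)/steps
    ri: float | None     # retention index (g-s)/(g-m)


def homoplasy(tree: RootedTree, tip_states_by_char: dict,
              vocabularies=None) -> list:
    """Consistency and retention indices per character.

    ci = (k-1)/steps for k observed states; ri = (g-s)/(g-m) with m = k-1
    and g = number of tips minus the modal-state frequency (a polymorphic
    tip counts towards a state if the state is in its set).  Both are
    reported absent (None) when undefined: constant characters (steps = 0)
    and, for ri, characters whose maximum conceivable steps equal the
    minimum (g = m).
    """
    out = []
    n_tips = len(tree.tip_labels)
    for char_id, tip_states in sorted(tip_states_by_char.items()):
        vocab = (vocabularies or {}).get(char_id)
        result = fitch(tree, tip_states, vocabulary=vocab, character_id=char_id)
        sets = [_normalise_states(tip_states[t], vocab) for t in tree.tip_labels]
        observed = set().union(*sets)
        k = len(observed)
        m = k - 1
        modal = max(sum(1 for s in sets if state in s) for state in observed)
        g = n_tips - modal
        s = result.steps
        if s == 0 or m == 0:
            out.append(HomoplasyIndices(char_id, s, None, None))
            continue
        ci = m / s
        ri = (g - s) / (g - m) if g > m else None
        out.append(HomoplasyIndices(char_id, s, ci, ri))
    return out
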