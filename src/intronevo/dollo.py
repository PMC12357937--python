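"""Dollo parsimony reconstruction of intron gain/loss on a rooted species tree.

Under Dollo parsimony each character (an intron position) arises exactly
once and may subsequently be lost any number of times.  For a character
with possessor leaf set S the reconstruction is closed-form:

* the gain lies on the branch above MRCA(S);
* state 1 occupies the minimal connected subtree spanning S from MRCA(S)
  (a node below the MRCA is 1 iff its clade contains a member of S);
* one loss is charged per maximal subtree hanging off that spanning
  structure that contains no member of S.

This minimises total events among all single-origin scenarios, which is
the criterion the biology of intron insertion sites justifies: exact
re-insertion at the same codon position and phase is vanishingly unlikely
compared to loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy

from .errors import TreeError
from .homology import PresenceMatrix


class SpeciesTree:
    """A rooted species tree with uniquely labelled nodes.

    Wraps a dendropy tree.  Unnamed internal nodes are auto-labelled by the
    sorted tuple of their descendant leaf names so that event reports are
    stable across runs and across equivalent Newick serialisations.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._index()

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse types
            raise TreeError(f"cannot parse Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesTree":
        return cls.from_newick(Path(path).read_text(encoding="utf-8"))

    def _index(self) -> None:
        self.nodes: dict[str, dendropy.Node] = {}
        self.leaf_sets: dict[int, frozenset[str]] = {}
        leaves = [n for n in self.tree.leaf_node_iter()]
        if len(leaves) < 2:
            raise TreeError("tree must have at least 2 leaves")
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                name = node.taxon.label if node.taxon else node.label
                if not name:
                    raise TreeError("unnamed leaf")
                self.leaf_sets[id(node)] = frozenset([name])
            else:
                ls: set[str] = set()
                for ch in node.child_nodes():
                    ls |= self.leaf_sets[id(ch)]
                self.leaf_sets[id(node)] = frozenset(ls)
                if not node.label:
                    node.label = "+".join(sorted(ls))
            name = self.label_of(node)
            if name in self.nodes:
                raise TreeError(f"duplicate node label {name!r}")
            self.nodes[name] = node

    @staticmethod
    def label_of(node: dendropy.Node) -> str:
        if node.is_leaf() and node.taxon is not None:
            return node.taxon.label
        return node.label

    @property
    def leaf_labels(self) -> set[str]:
        return self.leaf_sets[id(self.tree.seed_node)]

    @property
    def root_label(self) -> str:
        return self.label_of(self.tree.seed_node)

    def node(self, label: str) -> dendropy.Node:
        try:
            return self.nodes[label]
        except KeyError:
            raise TreeError(f"no node labelled {label!r}") from None

    def leaves_under(self, label: str) -> frozenset[str]:
        return self.leaf_sets[id(self.node(label))]

    def mrca(self, leaf_names: Sequence[str]) -> dendropy.Node:
        want = set(leaf_names)
        best = None
        for node in self.tree.postorder_node_iter():
            ls = self.leaf_sets[id(node)]
            if want <= ls and (best is None or len(ls) < len(self.leaf_sets[id(best)])):
                best = node
        if best is None:
            raise TreeError(f"leaves {sorted(want)} not all in tree")
        return best

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        node = self.node(descendant)
        target = self.node(ancestor)
        while node is not None:
            if node is target:
                return True
            node = node.parent_node
        return False


def read_tree(newick: str) -> SpeciesTree:
    """Parse a rooted Newick string (file contents) into a SpeciesTree."""
    return SpeciesTree.from_newick(newick)


@dataclass
class AncestralStates:
    """node label x character -> {0,1} presence states."""

    states: dict[str, dict[str, int]]

    def state(self, node_label: str, character: str) -> int:
        return self.states[node_label][character]

    def to_tsv(self, path: str | Path, characters: Sequence[str]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("node\t" + "\t".join(characters) + "\n")
            for node in sorted(self.states):
                row = "\t".join(str(self.states[node][c]) for c in characters)
                fh.write(f"{node}\t{row}\n")


@dataclass
class EventMap:
    """Per-branch gains and losses, keyed by the branch's child node label."""

    gains: dict[str, list[str]] = field(default_factory=dict)
    losses: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_gains(self) -> int:
        return sum(len(v) for v in self.gains.values())

    @property
    def n_losses(self) -> int:
        return sum(len(v) for v in self.losses.values())

    @property
    def total_events(self) -> int:
        return self.n_gains + self.n_losses

    def gain_branch(self, character: str) -> str:
        for child, chars in self.gains.items():
            if character in chars:
                return child
        raise KeyError(character)

    def loss_branches(self, character: str) -> list[str]:
        return sorted(
            child for child, chars in self.losses.items() if character in chars
        )

    def as_records(self) -> list[tuple[str, str, str]]:
        recs = [
            (child, char, "gain")
            for child, chars in sorted(self.gains.items())
            for char in chars
        ]
        recs += [
            (child, char, "loss")
            for child, chars in sorted(self.losses.items())
            for char in chars
        ]
        return recs

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("branch_child\tcharacter\tevent\n")
            for child, char, ev in self.as_records():
                fh.write(f"{child}\t{char}\t{ev}\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gains": {k: sorted(v) for k, v in self.gains.items()},
            "losses": {k: sorted(v) for k, v in self.losses.items()},
            "totals": {
                "gains": self.n_gains,
                "losses": self.n_losses,
                "events": self.total_events,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def dollo_reconstruct(
    tree: SpeciesTree, matrix: PresenceMatrix
) -> tuple[AncestralStates, EventMap]:
    """Minimum-event single-origin reconstruction of every character."""
    taxa = set(matrix.taxa)
    if taxa != tree.leaf_labels:
        raise TreeError(
            "matrix taxa and tree leaves differ: "
            f"matrix-only={sorted(taxa - tree.leaf_labels)}, "
            f"tree-only={sorted(tree.leaf_labels - taxa)}"
        )
    states: dict[str, dict[str, int]] = {
        label: {} for label in tree.nodes
    }
    events = EventMap()
    for char in matrix.characters:
        possessors = set(matrix.possessors(char))
        mrca = tree.mrca(sorted(possessors))
        in_clade: set[str] = set()
        for node in mrca.preorder_iter():
            label = tree.label_of(node)
            in_clade.add(label)
            has_member = bool(tree.leaf_sets[id(node)] & possessors)
            states[label][char] = 1 if has_member else 0
        for label in tree.nodes:
            if label not in in_clade:
                states[label][char] = 0
        events.gains.setdefault(tree.label_of(mrca), []).append(char)
        for node in mrca.preorder_iter():
            if node is mrca:
                continue
            label = tree.label_of(node)
            parent_label = tree.label_of(node.parent_node)
            if states[parent_label][char] == 1 and states[label][char] == 0:
                events.losses.setdefault(label, []).append(char)
    return AncestralStates(states), events


def gains_between(
    tree: SpeciesTree, states: AncestralStates, ancestor: str, descendant: str
) -> int:
    """Number of characters absent at ``ancestor`` and present at ``descendant``.

    The two node labels must stand in an ancestor-descendant relation
    (equality allowed, giving 0).
    """
    if not tree.is_ancestor(ancestor, descendant):
        raise TreeError(
            f"{ancestor!r} is not an ancestor of {descendant!r}"
        )
    anc = states.states[ancestor]
    dec = states.states[descendant]
    return sum(1 for c in anc if anc[c] == 0 and dec[c] == 1)


def exon_count_at(
    states: AncestralStates,
    node: str,
    characters: Sequence[str] | None = None,
) -> int:
    """Reconstructed exon count at a node: present characters + 1.

    ``characters`` restricts the count to one gene family's characters
    (default: all characters in the reconstruction).
    """
    node_states = states.states[node]
    chars = characters if characters is not None else list(node_states)
    return sum(node_states[c] for c in chars) + 1


def compare_topologies(
    trees: Sequence[SpeciesTree],
    matrix: PresenceMatrix,
    names: Sequence[str] | None = None,
) -> dict:
    """Total Dollo events for each candidate topology over one matrix.

    Returns per-tree totals, per-branch event records, and the name of the
    topology minimising total events (ties broken by input order).
    """
    if len(trees) < 2:
        raise TreeError("need at least two topologies to compare")
    leafsets = {frozenset(t.leaf_labels) for t in trees}
    if len(leafsets) != 1:
        raise TreeError("topologies do not share a leaf set")
    if names is None:
        names = [f"tree{i + 1}" for i in range(len(trees))]
    report: dict = {"trees": {}}
    best_name, best_total = None, None
    for name, tree in zip(names, trees):
        _, events = dollo_reconstruct(tree, matrix)
        report["trees"][name] = {
            "gains": events.n_gains,
            "losses": events.n_losses,
            "total_events": events.total_events,
            "events": events.as_records(),
        }
        if best_total is None or events.total_events < best_total:
            best_name, best_total = name, events.total_events
    report["minimal"] = best_name
    report["minimal_total"] = best_total
    return report
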