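"""Dollo reconstruction: closed form vs exhaustive single-gain minimisation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from intronevo.dollo import (
    SpeciesTree,
    compare_topologies,
    dollo_reconstruct,
    exon_count_at,
    gains_between,
    read_tree,
)
from intronevo.errors import TreeError
from intronevo.homology import PresenceMatrix

from conftest import random_rooted_newick


def _matrix(possessors, all_taxa):
    df = pd.DataFrame(
        {"c1": [1 if t in possessors else 0 for t in all_taxa]},
        index=pd.Index(all_taxa, name="taxon"),
    )
    return PresenceMatrix(df)


def brute_force_min_events(tree: SpeciesTree, possessors: set[str]) -> int:
    """Exhaustive minimum of gains+losses over all single-gain assignments.

    Enumerates every 0/1 assignment to internal nodes (leaves fixed by the
    character); a gain is a 0->1 edge, with presence at the root counting
    as a gain on the root branch.  Valid Dollo scenarios have exactly one
    gain; the minimum total event count over them is returned.
    """
    internal = [n for n in tree.tree.preorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in tree.tree.leaf_node_iter()]
    best = None
    for bits in itertools.product([0, 1], repeat=len(internal)):
        state = {id(n): b for n, b in zip(internal, bits)}
        for leaf in leaves:
            state[id(leaf)] = 1 if tree.label_of(leaf) in possessors else 0
        gains = state[id(tree.tree.seed_node)]
        losses = 0
        for node in tree.tree.preorder_node_iter():
            for child in node.child_nodes():
                a, b = state[id(node)], state[id(child)]
                gains += (a, b) == (0, 1)
                losses += (a, b) == (1, 0)
        if gains == 1:
            total = gains + losses
            if best is None or total < best:
                best = total
    return best


class TestReadTree:
    def test_basic_shapes(self):
        t = read_tree("((A,B),C);")
        assert t.leaf_labels == {"A", "B", "C"}
        assert len(t.tree.seed_node.child_nodes()) == 2
        assert read_tree("((A,B),(C,D));").leaf_labels == {"A", "B", "C", "D"}

    def test_internal_autolabels_are_deterministic(self):
        t = read_tree("((B,A),C);")
        assert "A+B" in t.nodes

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(TreeError):
            read_tree("((A,A),C);")

    def test_fixture_tree_matches_matrix_taxa(self, fixture):
        for tree in fixture["trees"].values():
            assert tree.leaf_labels == set(
                fixture["matrices"]["slc26a1"].taxa
            )


class TestDolloReconstruct:
    def test_character_in_all_leaves_gains_at_root(self):
        tree = read_tree("((A,B),(C,D));")
        states, events = dollo_reconstruct(
            tree, _matrix({"A", "B", "C", "D"}, ["A", "B", "C", "D"])
        )
        assert events.gain_branch("c1") == tree.root_label
        assert events.n_losses == 0

    def test_clade_and_split_characters(self):
        tree = read_tree("((A,B),(C,D));")
        states, events = dollo_reconstruct(
            tree, _matrix({"A", "B"}, ["A", "B", "C", "D"])
        )
        assert events.gain_branch("c1") == "A+B"
        assert events.n_losses == 0
        states, events = dollo_reconstruct(
            tree, _matrix({"A", "C"}, ["A", "B", "C", "D"])
        )
        assert events.gain_branch("c1") == tree.root_label
        assert set(events.loss_branches("c1")) == {"B", "D"}

    def test_singleton_character_on_terminal_branch(self):
        tree = read_tree("((A,B),C);")
        _, events = dollo_reconstruct(tree, _matrix({"C"}, ["A", "B", "C"]))
        assert events.gain_branch("c1") == "C"
        assert events.total_events == 1

    def test_leafset_mismatch_rejected(self):
        tree = read_tree("((A,B),C);")
        with pytest.raises(TreeError, match="differ"):
            dollo_reconstruct(tree, _matrix({"A"}, ["A", "B", "X"]))

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_matches_exhaustive_minimisation(self, n_leaves):
        rng = np.random.default_rng(n_leaves * 101)
        for rep in range(8):
            tree = read_tree(random_rooted_newick(rng, n_leaves))
            taxa = sorted(tree.leaf_labels)
            k = int(rng.integers(1, n_leaves + 1))
            possessors = set(
                rng.choice(taxa, size=k, replace=False).tolist()
            )
            _, events = dollo_reconstruct(tree, _matrix(possessors, taxa))
            assert events.total_events == brute_force_min_events(
                tree, possessors
            ), (tree.tree.as_string(schema="newick"), possessors)

    def test_gain_node_never_moves_leafward_when_possessors_added(self):
        rng = np.random.default_rng(77)
        for rep in range(10):
            tree = read_tree(random_rooted_newick(rng, 7))
            taxa = sorted(tree.leaf_labels)
            k = int(rng.integers(1, 6))
            possessors = set(rng.choice(taxa, size=k, replace=False).tolist())
            extra = [t for t in taxa if t not in possessors]
            if not extra:
                continue
            _, ev_before = dollo_reconstruct(tree, _matrix(possessors, taxa))
            bigger = possessors | {extra[0]}
            _, ev_after = dollo_reconstruct(tree, _matrix(bigger, taxa))
            assert tree.is_ancestor(
                ev_after.gain_branch("c1"), ev_before.gain_branch("c1")
            )

    def test_every_state_transition_is_logged_once(self):
        rng = np.random.default_rng(3)
        tree = read_tree(random_rooted_newick(rng, 8))
        taxa = sorted(tree.leaf_labels)
        possessors = set(taxa[::2])
        states, events = dollo_reconstruct(tree, _matrix(possessors, taxa))
        assert events.n_gains == 1
        # every parent=1/child=0 edge appears exactly once as a loss
        n_transitions = 0
        for node in tree.tree.preorder_node_iter():
            for child in node.child_nodes():
                a = states.state(tree.label_of(node), "c1")
                b = states.state(tree.label_of(child), "c1")
                n_transitions += (a, b) == (1, 0)
        assert n_transitions == events.n_losses

    def test_states_form_connected_subtree(self, fixture):
        tree = fixture["trees"]["lavoue_near"]
        pm = fixture["matrices"]["slc26a2"]
        states, _ = dollo_reconstruct(tree, pm)
        for char in pm.characters:
            ones = {
                lbl for lbl in tree.nodes if states.state(lbl, char) == 1
            }
            # each 1-node other than the gain node has a 1-parent
            tops = {
                lbl for lbl in ones
                if tree.node(lbl).parent_node is None
                or tree.label_of(tree.node(lbl).parent_node) not in ones
            }
            assert len(tops) == 1


class TestNodeQueries:
    def test_gains_between_same_node_is_zero(self, fixture):
        tree = fixture["trees"]["lavoue_near"]
        states, _ = dollo_reconstruct(tree, fixture["matrices"]["slc26a1"])
        assert gains_between(tree, states, "Teleostei", "Teleostei") == 0

    def test_unrelated_nodes_rejected(self, fixture):
        tree = fixture["trees"]["lavoue_near"]
        states, _ = dollo_reconstruct(tree, fixture["matrices"]["slc26a1"])
        with pytest.raises(TreeError, match="ancestor"):
            gains_between(tree, states, "Eurypterygii", "OsmStom")

    def test_exon_count_without_introns(self):
        tree = read_tree("((A,B),C);")
        states, _ = dollo_reconstruct(tree, _matrix({"A"}, ["A", "B", "C"]))
        assert exon_count_at(states, "B") == 1
        assert exon_count_at(states, "A") == 2


class TestCompareTopologies:
    def test_identical_trees_identical_totals(self):
        a = read_tree("((A,B),(C,D));")
        b = read_tree("((A,B),(C,D));")
        rep = compare_topologies([a, b], _matrix({"A", "C"}, list("ABCD")))
        totals = [v["total_events"] for v in rep["trees"].values()]
        assert totals[0] == totals[1] == 3

    def test_four_leaf_toy_matches_brute_force(self):
        trees = [read_tree("((A,B),(C,D));"), read_tree("((A,C),(B,D));")]
        pm = _matrix({"A", "C"}, list("ABCD"))
        rep = compare_topologies(trees, pm, names=["mismatch", "match"])
        assert rep["trees"]["match"]["total_events"] == brute_force_min_events(
            trees[1], {"A", "C"}
        ) == 1
        assert rep["minimal"] == "match"

    def test_leafset_mismatch_rejected(self):
        with pytest.raises(TreeError, match="leaf"):
            compare_topologies(
                [read_tree("((A,B),C);"), read_tree("((A,B),D);")],
                _matrix({"A"}, ["A", "B", "C"]),
            )
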