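"""Fitch/Sankoff reconstruction, event extraction and the event map."""

import numpy as np
import pandas as pd
import pytest

from evotrek.parsimony import (
    build_event_map,
    extract_events,
    fitch,
    replay_events,
    sankoff,
)
from evotrek.phylo import parse_newick

from conftest import random_column, random_tree
from oracles import enumerate_parsimony


class TestFitch:
    def test_constant_column_no_changes(self, quartet_tree):
        changes, lab = fitch(quartet_tree, {"A": 1, "B": 1, "C": 1, "D": 1})
        assert changes == 0
        assert set(lab.values()) == {1}

    def test_clade_split_one_change(self, quartet_tree):
        # exhaustively verified: one 0->1 (or 1->0) transition suffices
        changes, _ = fitch(quartet_tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        best, _ = enumerate_parsimony(quartet_tree, {"A": 1, "B": 1, "C": 0, "D": 0}, 1, 1)
        assert changes == best == 1

    def test_incongruent_column_two_changes(self, quartet_tree):
        col = {"A": 1, "C": 1, "B": 0, "D": 0}
        changes, _ = fitch(quartet_tree, col)
        best, _ = enumerate_parsimony(quartet_tree, col, 1, 1)
        assert changes == best == 2

    def test_missing_leaf_raises(self, quartet_tree):
        with pytest.raises(ValueError, match="missing"):
            fitch(quartet_tree, {"A": 1, "B": 0, "C": 1})

    def test_labeling_cost_consistent(self, quartet_tree):
        col = {"A": 1, "B": 0, "C": 1, "D": 0}
        changes, lab = fitch(quartet_tree, col)
        assert len(extract_events(lab, quartet_tree)) == changes


class TestSankoff:
    def test_unit_costs_equal_fitch(self):
        rng = np.random.default_rng(11)
        for i in range(25):
            tree = random_tree(int(rng.integers(4, 9)), i)
            col = random_column(tree, rng)
            cost, labs, _ = sankoff(tree, col, 1, 1)
            assert cost == fitch(tree, col)[0]
            assert labs

    def test_moderate_gain_cost_forces_single_gain(self):
        # presence nested inside absence: explaining it without a gain takes
        # two losses (cost 2), so a gain at cost 1.5 is the unique optimum
        tree = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        col = {"A": 1, "B": 1, "C": 0, "D": 0, "E": 0}
        cost, labs, _ = sankoff(tree, col, cost_gain=1.5, cost_loss=1)
        assert cost == pytest.approx(1.5)
        for lab in labs:
            events = extract_events(lab, tree)
            assert sum(1 for _, k in events if k == "gain") == 1

    def test_prohibitive_gain_cost_yields_gain_free_optima(self):
        # Dollo-style large gain cost means *at most* one gain — with a free
        # root state the optimum explains nested presence by ancestral
        # presence plus losses, paying no gain at all
        tree = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        col = {"A": 1, "B": 1, "C": 0, "D": 0, "E": 0}
        cost, labs, _ = sankoff(tree, col, cost_gain=1000, cost_loss=1)
        assert cost == pytest.approx(2.0)
        for lab in labs:
            assert all(k == "loss" for _, k in extract_events(lab, tree))

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for i in range(40):
            tree = random_tree(int(rng.integers(4, 9)), 1000 + i)
            col = random_column(tree, rng)
            cg, cl = float(rng.uniform(0.2, 3)), float(rng.uniform(0.2, 3))
            cost, labs, overflow = sankoff(tree, col, cg, cl, cap=4096)
            best, optimal = enumerate_parsimony(tree, col, cg, cl)
            assert not overflow
            assert cost == pytest.approx(best)
            assert {frozenset(l.items()) for l in labs} == optimal

    def test_polytomy_supported(self):
        tree = parse_newick("(A:1,B:1,C:1,OUT:1);")
        cost, labs, _ = sankoff(tree, {"A": 1, "B": 1, "C": 1, "OUT": 0}, 1, 1)
        assert cost == 1

    def test_negative_costs_rejected(self, quartet_tree):
        with pytest.raises(ValueError):
            sankoff(quartet_tree, {"A": 1, "B": 1, "C": 0, "D": 0}, -1, 1)


class TestExtractAndReplay:
    def test_constant_labeling_no_events(self, quartet_tree):
        lab = {n.id: 1 for n in quartet_tree.preorder()}
        assert extract_events(lab, quartet_tree) == []

    def test_single_transition_single_gain(self, quartet_tree):
        lab = {n.id: 0 for n in quartet_tree.preorder()}
        leaf_a = quartet_tree.find("A")
        lab[leaf_a.id] = 1
        events = extract_events(lab, quartet_tree)
        assert events == [(leaf_a.id, "gain")]

    def test_replay_inverts_extraction(self):
        rng = np.random.default_rng(7)
        for i in range(20):
            tree = random_tree(int(rng.integers(4, 9)), 2000 + i)
            col = random_column(tree, rng)
            cost, labs, _ = sankoff(tree, col, 2, 1)
            for lab in labs:
                events = extract_events(lab, tree)
                assert replay_events(tree, lab[tree.root.id], events) == col


class TestEventMap:
    def test_everywhere_present_family_has_no_events(self, kch_tree):
        matrix = pd.DataFrame([[1, 1, 1]], index=["f1"], columns=["A", "B", "OUT"])
        em = build_event_map(matrix, kch_tree)
        fe = em.families["f1"]
        assert fe.root_state == 1 and fe.events == [] and fe.n_scenarios == 1

    def test_single_leaf_family_gains_on_terminal_branch(self, kch_tree):
        matrix = pd.DataFrame([[1, 0, 0]], index=["f1"], columns=["A", "B", "OUT"])
        em = build_event_map(matrix, kch_tree, cost_gain=1, cost_loss=1)
        fe = em.families["f1"]
        leaf_a = kch_tree.find("A")
        assert fe.events == [(leaf_a.id, "gain")]

    def test_ingroup_only_family_is_ambiguous(self, kch_tree):
        """Present in the whole ingroup, absent in the outgroup: gain on the
        ingroup stem or ancestral presence plus outgroup loss are co-optimal
        under equal costs — the classic polarization ambiguity."""
        matrix = pd.DataFrame([[1, 1, 0]], index=["kch"], columns=["A", "B", "OUT"])
        em = build_event_map(matrix, kch_tree, cost_gain=1, cost_loss=1)
        fe = em.families["kch"]
        assert fe.n_scenarios == 2
        stem = kch_tree.find("ST")
        out = kch_tree.find("OUT")
        scen = {(rs, tuple(ev)) for rs, ev in fe.scenarios}
        assert scen == {
            (0, ((stem.id, "gain"),)),
            (1, ((out.id, "loss"),)),
        }

    def test_gain_count_monotone_in_gain_cost(self):
        rng = np.random.default_rng(3)
        tree = random_tree(8, 99)
        matrix = pd.DataFrame(
            [[int(rng.integers(2)) for _ in tree.leaf_names()] for _ in range(20)],
            index=[f"f{i}" for i in range(20)],
            columns=tree.leaf_names(),
        )
        prev = None
        for cg in (0.5, 1.0, 2.0, 4.0):
            em = build_event_map(matrix, tree, cost_gain=cg, cost_loss=1)
            gains = sum(
                sum(1 for _, k in fe.events if k == "gain")
                for fe in em.families.values()
            )
            if prev is not None:
                assert gains <= prev
            prev = gains

    def test_taxa_mismatch_raises(self, kch_tree):
        matrix = pd.DataFrame([[1, 1]], index=["f1"], columns=["A", "X"])
        with pytest.raises(ValueError, match="match"):
            build_event_map(matrix, kch_tree)

    def test_duplication_annotation_carried(self, kch_tree):
        matrix = pd.DataFrame([[1, 1, 1]], index=["f1"], columns=["A", "B", "OUT"])
        cn = pd.DataFrame([[2, 1, 1]], index=["f1"], columns=["A", "B", "OUT"])
        em = build_event_map(matrix, kch_tree, copy_number=cn)
        assert em.families["f1"].annotations["duplication"] == ["A"]
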