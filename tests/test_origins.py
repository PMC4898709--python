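import numpy as np
import pytest

import glowtree as gt
from glowtree.mk_asr import ChainSettings, mcmc_asr
from glowtree.origins import (
    classify_mechanism,
    events_from_asr,
    expected_gains_stochastic_map,
    threshold_sweep,
)

from conftest import random_ultrametric_tree
from oracles import edge_scan_transitions


class TestBinarize:
    def test_threshold_and_tie_rule(self):
        out = gt.binarize([0.93, 0.5, 0.51, 0.0], threshold=0.5)
        np.testing.assert_array_equal(out, [1, 0, 1, 0])

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            gt.binarize([0.5], threshold=1.0)


class TestCountTransitions:
    def test_all_absent_empty(self, five_tip_tree):
        flat = five_tip_tree.flat
        assert gt.count_transitions(flat, np.zeros(flat.n_nodes, dtype=int)) == []

    def test_two_painted_clades(self):
        t = gt.TimeTree.from_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,(E:2,F:2):1);"
        )
        flat = t.flat
        states = np.zeros(flat.n_nodes, dtype=int)
        for pair in ({"A", "B"}, {"E", "F"}):
            v = flat.mrca(pair)
            for u in flat.subtree_nodes(v):
                states[u] = 1
        ev = gt.count_transitions(flat, states)
        assert sum(e.direction == "gain" for e in ev) == 2
        assert sum(e.direction == "loss" for e in ev) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_edge_scan_oracle_and_telescoping(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_ultrametric_tree(rng, 50)
        flat = tree.flat
        for _ in range(25):
            states = rng.integers(0, 2, flat.n_nodes)
            ev = gt.count_transitions(flat, states)
            gains = sum(e.direction == "gain" for e in ev)
            losses = sum(e.direction == "loss" for e in ev)
            assert (gains, losses) == edge_scan_transitions(flat, states)
            # telescoping identity along every root-to-tip path
            for tip in range(flat.n_tips):
                g = l = 0
                v = tip
                while v != flat.root:
                    p = int(flat.parent[v])
                    g += states[p] == 0 and states[v] == 1
                    l += states[p] == 1 and states[v] == 0
                    v = p
                assert g - l == states[tip] - states[flat.root]

    def test_disjoint_clade_adds_one_gain(self, five_tip_tree):
        flat = five_tip_tree.flat
        states = np.zeros(flat.n_nodes, dtype=int)
        states[flat.tip_index["A"]] = 1
        base = sum(e.direction == "gain" for e in gt.count_transitions(flat, states))
        v = flat.mrca({"D", "E"})
        for u in flat.subtree_nodes(v):
            states[u] = 1
        more = sum(e.direction == "gain" for e in gt.count_transitions(flat, states))
        assert more == base + 1

    def test_child_order_invariance(self):
        a = gt.TimeTree.from_newick("((A:1,B:1):1,C:2);")
        b = gt.TimeTree.from_newick("(C:2,(B:1,A:1):1);")
        sa = np.array([1, 0, 0, 1, 0])  # tips sorted A,B,C then postorder internals
        ev_a = gt.count_transitions(a.flat, sa)
        ev_b = gt.count_transitions(b.flat, sa)
        assert len(ev_a) == len(ev_b)

    def test_state_length_mismatch(self, five_tip_tree):
        with pytest.raises(ValueError):
            gt.count_transitions(five_tip_tree.flat, [0, 1])


class TestClassifyMechanism:
    def test_pure_and_mixed(self, five_tip_tree, five_tip_traits):
        flat = five_tip_tree.flat
        gain_a = gt.OriginEvent(0, int(flat.parent[flat.tip_index["A"]]), flat.tip_index["A"], "gain")
        assert classify_mechanism(gain_a, flat, five_tip_traits) == "intrinsic"
        root_gain = gt.OriginEvent(0, flat.root, flat.mrca({"A", "B", "C"}), "gain")
        assert classify_mechanism(root_gain, flat, five_tip_traits) == "mixed"

    def test_no_present_descendants_warns_unknown(self, five_tip_tree, five_tip_traits, caplog):
        flat = five_tip_tree.flat
        gain_d = gt.OriginEvent(0, int(flat.parent[flat.tip_index["D"]]), flat.tip_index["D"], "gain")
        with caplog.at_level("WARNING"):
            assert classify_mechanism(gain_d, flat, five_tip_traits) == "unknown"
        assert "no state-1" in caplog.text

    def test_loss_rejected(self, five_tip_tree, five_tip_traits):
        ev = gt.OriginEvent(0, 4, 0, "loss")
        with pytest.raises(ValueError):
            classify_mechanism(ev, five_tip_tree.flat, five_tip_traits)

    def test_planted_fixture_truth(self, small_fixture):
        """Every non-overlapping planted gain classifies to its painted mechanism."""
        flat = small_fixture.tree.flat
        keys = flat.node_keys()
        states = np.array(
            [small_fixture.truth["node_states"][keys[v]] for v in range(flat.n_nodes)]
        )
        ev = gt.count_transitions(flat, states)
        tallies = {}
        for e in ev:
            if e.direction == "gain":
                mech = classify_mechanism(e, flat, small_fixture.traits)
                tallies[mech] = tallies.get(mech, 0) + 1
        assert tallies == small_fixture.truth["mechanism_tallies"]


class TestSummarize:
    def _fake_events(self, flat, counts):
        per_tree = []
        gain_targets = [v for v in range(flat.n_nodes - 1)]
        for ti, c in enumerate(counts):
            evs = [
                gt.OriginEvent(ti, int(flat.parent[gain_targets[k]]), gain_targets[k], "gain", "unknown")
                for k in range(c)
            ]
            per_tree.append(evs)
        return per_tree

    def test_identical_trees_min_mode_median_equal(self, five_tip_tree):
        sample = gt.TreeSample([five_tip_tree] * 3)
        per_tree = self._fake_events(five_tip_tree.flat, [2, 2, 2])
        traits = gt.TraitTable({lab: 0 for lab in five_tip_tree.tip_labels})
        s = gt.summarize(per_tree, sample, traits)
        assert s.minimum == s.mode == s.median == 2

    def test_two_tree_arithmetic(self, yule_tree_50):
        sample = gt.TreeSample([yule_tree_50] * 2)
        per_tree = self._fake_events(yule_tree_50.flat, [27, 29])
        traits = gt.TraitTable({lab: 0 for lab in yule_tree_50.tip_labels})
        s = gt.summarize(per_tree, sample, traits)
        assert s.minimum == 27 and s.median == 28

    def test_tallies_sum_to_reference_gains(self, small_fixture):
        res = mcmc_asr(
            small_fixture.sample, small_fixture.traits,
            chain=ChainSettings(iterations=2000, burnin_frac=0.25, thin=5), seed=1,
        )
        per_tree = events_from_asr(res, small_fixture.traits)
        s = gt.summarize(per_tree, small_fixture.sample, small_fixture.traits, small_fixture.richness)
        assert sum(s.mechanism_tallies.values()) == s.per_tree_gains[s.reference_tree]
        assert s.events_table.shape[0] == sum(len(e) for e in per_tree)

    def test_missing_richness_marks_incomplete(self, five_tip_tree):
        sample = gt.TreeSample([five_tip_tree])
        per_tree = self._fake_events(five_tip_tree.flat, [1])
        traits = gt.TraitTable({lab: 0 for lab in five_tip_tree.tip_labels})
        s = gt.summarize(per_tree, sample, traits, richness=None)
        assert not s.species_tally_complete


class TestSweepAndMapping:
    def test_higher_threshold_never_gains_more(self, small_fixture):
        res = mcmc_asr(
            small_fixture.sample, small_fixture.traits,
            chain=ChainSettings(iterations=2000, burnin_frac=0.25, thin=5), seed=2,
        )
        df = threshold_sweep(res, small_fixture.traits, thresholds=(0.5, 0.9))
        lo = df.loc[df.threshold == 0.5, "modal_gains"].item()
        hi = df.loc[df.threshold == 0.9, "modal_gains"].item()
        assert hi <= lo

    def test_stochastic_map_agrees_with_edge_counts(self, small_fixture):
        """Expected gains from sampled histories track the planted count."""
        truth = small_fixture.truth
        est = expected_gains_stochastic_map(
            small_fixture.tree, small_fixture.traits,
            gt.MkParams(truth["q01"], truth["q10"]), n_maps=150, seed=9,
        )
        assert est == pytest.approx(truth["n_gains"], rel=0.25)
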