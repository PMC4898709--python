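import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

import glowtree as gt
from glowtree.mk_asr import ChainSettings, RatePriors, mcmc_asr

from conftest import random_traits, random_ultrametric_tree
from oracles import enumeration_loglik_and_marginals


class TestTransitionMatrix:
    def test_zero_time_identity(self):
        np.testing.assert_allclose(
            gt.transition_matrix(gt.MkParams(0.3, 0.7), 0.0), np.eye(2)
        )

    def test_zero_rates_identity(self):
        np.testing.assert_allclose(
            gt.transition_matrix(gt.MkParams(0.0, 0.0), 100.0), np.eye(2)
        )

    def test_symmetric_stationary_limit(self):
        P = gt.transition_matrix(gt.MkParams(1.0, 1.0), 1000.0)
        np.testing.assert_allclose(P, np.full((2, 2), 0.5), atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            gt.transition_matrix(gt.MkParams(0.1, 0.1), -1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_matrix_exponential(self, seed):
        rng = np.random.default_rng(seed)
        q01, q10 = rng.uniform(0.01, 2.0, 2)
        t = rng.uniform(0.0, 20.0)
        Q = np.array([[-q01, q01], [q10, -q10]])
        np.testing.assert_allclose(
            gt.transition_matrix(gt.MkParams(q01, q10), t), expm(Q * t), atol=1e-10
        )
        assert gt.transition_matrix(gt.MkParams(q01, q10), t).sum(axis=1) == pytest.approx([1, 1], abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        q01=st.floats(0.0, 5.0),
        q10=st.floats(0.0, 5.0),
        t1=st.floats(0.0, 50.0),
        t2=st.floats(0.0, 50.0),
    )
    def test_semigroup_and_stochasticity_properties(self, q01, q10, t1, t2):
        """Rows sum to one, entries stay in [0, 1], and P(t1)P(t2) = P(t1+t2)
        for arbitrary non-negative rates and durations."""
        p = gt.MkParams(q01, q10)
        P1 = gt.transition_matrix(p, t1)
        assert np.all((P1 >= 0) & (P1 <= 1))
        np.testing.assert_allclose(P1.sum(axis=1), [1, 1], atol=1e-12)
        np.testing.assert_allclose(
            P1 @ gt.transition_matrix(p, t2),
            gt.transition_matrix(p, t1 + t2),
            atol=1e-10,
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_chapman_kolmogorov(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = gt.MkParams(*rng.uniform(0.01, 1.5, 2))
        t1, t2 = rng.uniform(0.0, 10.0, 2)
        np.testing.assert_allclose(
            gt.transition_matrix(p, t1) @ gt.transition_matrix(p, t2),
            gt.transition_matrix(p, t1 + t2),
            atol=1e-10,
        )


class TestPruning:
    def test_single_tip_uniform_root(self):
        t = gt.TimeTree.from_newick("(A:0,B:0);", require_ultrametric=False)
        traits = gt.TraitTable({"A": 0, "B": None})
        ll = gt.tree_loglik(t, traits, gt.MkParams(0.3, 0.2))
        assert ll == pytest.approx(math.log(0.5), abs=1e-12)

    def test_all_missing_is_loglik_zero(self, five_tip_tree):
        traits = gt.TraitTable({lab: None for lab in five_tip_tree.tip_labels})
        for p in (gt.MkParams(0.1, 0.9), gt.MkParams(2.0, 0.1)):
            assert gt.tree_loglik(five_tip_tree, traits, p) == pytest.approx(0.0, abs=1e-12)

    def test_missing_trait_row_rejected(self, five_tip_tree):
        with pytest.raises(ValueError, match="lacks"):
            gt.tree_loglik(five_tip_tree, gt.TraitTable({"A": 0}), gt.MkParams(0.1, 0.1))

    @pytest.mark.parametrize("n_tips,polytomy,seed", [
        (4, False, 0), (5, False, 1), (6, True, 2), (7, True, 3), (8, False, 4),
    ])
    def test_matches_enumeration(self, n_tips, polytomy, seed):
        rng = np.random.default_rng(seed)
        tree = random_ultrametric_tree(rng, n_tips, allow_polytomy=polytomy)
        traits = random_traits(rng, tree, p_present=0.4, p_missing=0.2)
        params = gt.MkParams(*rng.uniform(0.05, 0.8, 2))
        want_ll, want_marg = enumeration_loglik_and_marginals(tree, traits, params)
        got_ll = gt.tree_loglik(tree, traits, params)
        got_marg = gt.marginal_asr(tree, traits, params)
        assert got_ll == pytest.approx(want_ll, abs=1e-12)
        np.testing.assert_allclose(got_marg, want_marg, atol=1e-12)

    def test_tip_order_invariance(self):
        params = gt.MkParams(0.4, 0.2)
        traits = gt.TraitTable({"A": 1, "B": 0, "C": 1}, {"A": "unknown", "C": "unknown"})
        a = gt.tree_loglik(gt.TimeTree.from_newick("((A:1,B:1):1,C:2);"), traits, params)
        b = gt.tree_loglik(gt.TimeTree.from_newick("(C:2,(B:1,A:1):1);"), traits, params)
        assert a == pytest.approx(b, abs=1e-14)

    def test_reroot_invariance_under_stationary_prior(self):
        import dendropy

        params = gt.MkParams(0.3, 0.6)
        traits = gt.TraitTable(
            {"A": 1, "B": 0, "C": 1, "D": 0}, {"A": "unknown", "C": "unknown"}
        )
        t = gt.TimeTree.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        base = gt.tree_loglik(t, traits, params, root="stationary")
        t2 = gt.TimeTree.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        edge = next(
            nd.edge for nd in t2.tree.preorder_node_iter()
            if nd.taxon is not None and nd.taxon.label == "C"
        )
        t2.tree.reroot_at_edge(edge, length1=1.0, length2=1.0)
        rerooted = gt.TimeTree(t2.tree)
        assert gt.tree_loglik(rerooted, traits, params, root="stationary") == pytest.approx(
            base, abs=1e-10
        )


class TestMarginals:
    def test_unanimous_tips_no_change_limit(self, yule_tree_50):
        traits = gt.TraitTable(
            {lab: 1 for lab in yule_tree_50.tip_labels},
            {lab: "unknown" for lab in yule_tree_50.tip_labels},
        )
        m = gt.marginal_asr(yule_tree_50, traits, gt.MkParams(1e-9, 1e-9))
        assert np.all(m > 1 - 1e-6)

    def test_cherry_symmetry_gives_half_at_root(self):
        t = gt.TimeTree.from_newick("(A:1,B:1);")
        traits = gt.TraitTable({"A": 0, "B": 1}, {"B": "unknown"})
        m = gt.marginal_asr(t, traits, gt.MkParams(0.4, 0.4))
        assert m[t.flat.root] == pytest.approx(0.5, abs=1e-12)

    def test_probabilities_in_unit_interval(self, five_tip_tree, five_tip_traits):
        m = gt.marginal_asr(five_tip_tree, five_tip_traits, gt.MkParams(0.2, 0.05))
        assert np.all(m >= 0) and np.all(m <= 1)


class TestMCMC:
    def test_same_seed_identical_chain(self, small_fixture):
        sample = gt.subsample_trees(small_fixture.sample, 3, mode="even")
        kw = dict(
            sample=sample, traits=small_fixture.traits,
            chain=ChainSettings(iterations=500, burnin_frac=0.2, thin=5), seed=42,
        )
        a, b = mcmc_asr(**kw), mcmc_asr(**kw)
        assert a.trace.equals(b.trace)
        for x, y in zip(a.node_prob1, b.node_prob1):
            np.testing.assert_array_equal(x, y)

    def test_iterations_must_exceed_burnin(self):
        with pytest.raises(ValueError):
            ChainSettings(iterations=100, burnin_frac=1.0)

    def test_prior_recovered_without_data(self, yule_tree_50):
        """With fully missing data the rate posterior is the prior."""
        traits = gt.TraitTable({lab: None for lab in yule_tree_50.tip_labels})
        res = mcmc_asr(
            gt.TreeSample([yule_tree_50]), traits,
            chain=ChainSettings(iterations=22_000, burnin_frac=0.1, thin=10),
            seed=5,
        )
        prior_mean = 1.0 / yule_tree_50.height()
        assert res.rate_summary["q01"]["mean"] == pytest.approx(prior_mean, rel=0.2)
        assert res.rate_summary["q10"]["mean"] == pytest.approx(prior_mean, rel=0.2)

    def test_trees_all_reconstructed(self, small_fixture):
        res = mcmc_asr(
            small_fixture.sample, small_fixture.traits,
            chain=ChainSettings(iterations=400, burnin_frac=0.25, thin=10), seed=3,
        )
        assert len(res.node_prob1) == len(small_fixture.sample)
        for probs, tree in zip(res.node_prob1, small_fixture.sample):
            assert len(probs) == tree.flat.n_nodes
            assert np.all((probs >= 0) & (probs <= 1))
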