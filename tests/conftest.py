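import numpy as np
import pytest

import glowtree as gt
from glowtree.synthetic_data import make_fish_fixture, simulate_bd_tree


@pytest.fixture(scope="session")
def five_tip_tree():
    return gt.TimeTree.from_newick("(((A:1,B:1):1,C:2):1,(D:2.5,E:2.5):0.5);")


@pytest.fixture(scope="session")
def five_tip_traits():
    return gt.TraitTable(
        {"A": 1, "B": 0, "C": 1, "D": 0, "E": None},
        {"A": "intrinsic", "C": "bacterial"},
    )


@pytest.fixture(scope="session")
def small_fixture():
    """A reduced fish-like dataset for module tests (fast to generate)."""
    return make_fish_fixture(
        seed=7, n_tips=80, target_gains=8, tree_sample_size=10,
        mechanism_counts=(3, 4, 1), n_exceptional=2,
    )


@pytest.fixture(scope="session")
def yule_tree_50():
    return simulate_bd_tree(lam=0.2, mu=0.0, seed=17, n_tips=50)


def random_ultrametric_tree(rng, n_tips, allow_polytomy=False):
    """Independent small-tree generator for oracle tests (coalescent-style
    merging, not the package's birth-death simulator)."""
    labels = [f"x{i}" for i in range(n_tips)]
    nodes = {lab: (lab, 0.0) for lab in labels}  # name -> (newick, age)
    items = list(labels)
    age = 0.0
    while len(items) > 1:
        age += float(rng.exponential(1.0))
        k = 3 if (allow_polytomy and len(items) >= 3 and rng.random() < 0.3) else 2
        picked = rng.choice(len(items), size=k, replace=False)
        kids = [items[i] for i in sorted(picked, reverse=True)]
        for i in sorted(picked, reverse=True):
            items.pop(i)
        parts = []
        for kd in kids:
            s, a = nodes[kd]
            parts.append(f"{s}:{age - a:.10f}")
        name = f"({','.join(parts)})"
        nodes[name] = (name, age)
        items.append(name)
    s, a = nodes[items[0]]
    return gt.TimeTree.from_newick(s + ";")


def random_traits(rng, tree, p_present=0.4, p_missing=0.0):
    states = {}
    mechs = {}
    for lab in tree.tip_labels:
        u = rng.random()
        if u < p_missing:
            states[lab] = None
        elif u < p_missing + p_present:
            states[lab] = 1
            mechs[lab] = ["intrinsic", "bacterial", "unknown"][int(rng.integers(3))]
        else:
            states[lab] = 0
    return gt.TraitTable(states, mechs)
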