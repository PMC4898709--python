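"""Simulated trees, traits and richness tables with known ground truth.

The generator emulates the shape of a fish-scale comparative dataset: a
~300-tip ultrametric time tree about 150 Ma deep, a posterior-like sample of
branch-length-jittered trees over the same topology, a rare binary trait with
a known number of clustered gains (27 by default, painted with 8 intrinsic /
17 bacterial / 2 unknown mechanisms), and per-clade described-species counts
spanning orders of magnitude, with a few clades planted at elevated
diversification rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import dendropy
import numpy as np
import yaml

from ._flat import FlatTree
from .diversification import BDParams, crown_size_pmf
from .mk_asr import MkParams, _edge_probs
from .origins import count_transitions
from .treeio import (
    CladeRichness,
    RichnessTable,
    TimeTree,
    TraitTable,
    TreeSample,
    write_trees,
)

_RETRY_CAP = 5000


# ------------------------------------------------------------- tree building
def _flat_to_dendropy(flat: FlatTree, blen: Optional[np.ndarray] = None) -> dendropy.Tree:
    """Construct a dendropy tree from a FlatTree (optionally with new branch
    lengths), without any string round trip."""
    if blen is None:
        blen = flat.blen
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: List[dendropy.Node] = [dendropy.Node() for _ in range(flat.n_nodes)]
    for i, lab in enumerate(flat.labels):
        nodes[i].taxon = tns.new_taxon(label=lab)
    for v in range(flat.n_nodes - 1):
        nodes[int(flat.parent[v])].add_child(nodes[v])
        nodes[v].edge.length = float(blen[v])
    tree.seed_node = nodes[flat.root]
    return tree


def simulate_bd_tree(
    lam: float,
    mu: float,
    seed: int,
    n_tips: Optional[int] = None,
    age: Optional[float] = None,
    condition_on_survival: bool = True,
) -> TimeTree:
    """Gillespie forward birth-death simulation, extinct lineages pruned.

    Stop either at ``n_tips`` extant lineages (the present is then set just
    before the next event, so terminal branches have positive length) or at
    ``age`` Ma.  Complete extinction triggers a resample up to a retry cap.
    """
    if lam <= 0 or mu < 0:
        raise ValueError("need lam > 0 and mu >= 0")
    if (n_tips is None) == (age is None):
        raise ValueError("exactly one of n_tips / age must be given")
    rng = np.random.default_rng(seed)
    for _ in range(_RETRY_CAP):
        out = _simulate_once(lam, mu, rng, n_tips, age)
        if out is not None:
            return out
        if age is not None and not condition_on_survival:
            raise RuntimeError("clade went extinct and conditioning is disabled")
    raise RuntimeError("retry cap exhausted in birth-death simulation")


def _simulate_once(lam, mu, rng, n_stop, age_stop) -> Optional[TimeTree]:
    # node records: (parent, birth_time); alive holds indices
    parent = [-1, 0, 0]
    btime = [0.0, 0.0, 0.0]
    children: List[List[int]] = [[1, 2], [], []]
    alive = [1, 2]
    t = 0.0
    while True:
        n = len(alive)
        if n == 0:
            return None
        if n_stop is not None and n == n_stop:
            t += float(rng.exponential(1.0 / ((lam + mu) * n)))
            break
        dt = float(rng.exponential(1.0 / ((lam + mu) * n)))
        if age_stop is not None and t + dt > age_stop:
            t = age_stop
            break
        t += dt
        i = alive[int(rng.integers(n))]
        if rng.random() < lam / (lam + mu):
            for _ in range(2):
                parent.append(i)
                btime.append(t)
                children[i].append(len(parent) - 1)
                children.append([])
            alive.remove(i)
            alive.extend([len(parent) - 2, len(parent) - 1])
        else:
            alive.remove(i)
    if len(alive) < 2:
        return None
    alive_set = set(alive)

    # prune extinct lineages, suppressing unifurcations by merging branch spans
    import sys

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10 * len(parent) + 1000))

    def nwk(i: int) -> Optional[Tuple[str, float]]:
        """(subtree string without root branch, pendant length) or None."""
        if not children[i]:
            if i not in alive_set:
                return None
            return f"L{i}", t - btime[i]
        kids = [nwk(c) for c in children[i]]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        span = btime[children[i][0]] - btime[i]
        if len(kids) == 1:
            s1, l1 = kids[0]
            return s1, l1 + span
        inner = ",".join(f"{s1}:{l1:.12g}" for s1, l1 in kids)
        return f"({inner})", span

    res = nwk(0)
    if res is None:
        return None
    tt = TimeTree.from_newick(f"{res[0]}:{res[1]:.12g};", require_ultrametric=False)
    if tt.n_tips < 2:
        return None
    # relabel deterministically: t0001.. by current sorted order
    relab = {lab: f"t{k + 1:04d}" for k, lab in enumerate(tt.flat.labels)}
    for lf in tt.tree.leaf_node_iter():
        lf.taxon.label = relab[lf.taxon.label]
    return TimeTree(tt.tree).validate(require_ultrametric=False)


def rescale_tree_depth(tree: TimeTree, depth: float) -> TimeTree:
    """Uniformly rescale branch lengths so the crown age equals ``depth`` Ma."""
    h = tree.flat.height()
    if h <= 0:
        raise ValueError("tree has zero height")
    f = depth / h
    flat = tree.flat
    return TimeTree(_flat_to_dendropy(flat, flat.blen * f)).validate()


# ------------------------------------------------------------------- traits
def simulate_traits(
    tree: "TimeTree | FlatTree",
    params: MkParams,
    root_state: int = 0,
    seed: int = 0,
) -> Tuple[np.ndarray, Dict[str, int]]:
    """Evolve a binary state down every branch by exact endpoint sampling.

    Returns (true node states over the FlatTree, tip-state dict).
    """
    flat = tree.flat if isinstance(tree, TimeTree) else tree
    rng = np.random.default_rng(seed)
    P00, P01, P10, P11 = _edge_probs(flat, params)
    p1_from = [P01, P11]  # P(child=1 | parent state)
    states = np.zeros(flat.n_nodes, dtype=np.int8)
    states[flat.root] = root_state
    for v in range(flat.n_nodes - 2, -1, -1):
        ps = states[flat.parent[v]]
        states[v] = 1 if rng.random() < p1_from[ps][v] else 0
    tips = {flat.labels[i]: int(states[i]) for i in range(flat.n_tips)}
    return states, tips


# -------------------------------------------------------------------- jitter
def jitter_tree_sample(
    tree: TimeTree, n: int, sigma: float = 0.1, seed: int = 0
) -> TreeSample:
    """Branch-length-only posterior stand-in: node ages are jittered by
    lognormal multiplicative noise applied to parent/child age ratios, so every
    tree stays ultrametric with the same topology."""
    flat = tree.flat
    rng = np.random.default_rng(seed)
    trees = []
    ages0 = flat.ages
    parent = flat.parent
    for _ in range(n):
        ages = ages0.copy()
        root = flat.root
        ages[root] = ages0[root] * math.exp(sigma * rng.standard_normal())
        for v in reversed(flat.internal_postorder):
            if v == root:
                continue
            p = parent[v]
            ratio = ages0[v] / ages0[p]
            ages[v] = ages[p] * ratio ** math.exp(sigma * rng.standard_normal())
        blen = np.zeros(flat.n_nodes)
        for v in range(flat.n_nodes - 1):
            blen[v] = ages[parent[v]] - ages[v]
        trees.append(TimeTree(_flat_to_dendropy(flat, blen)).validate())
    return TreeSample(trees)


def plant_rate_shift_tree(
    seed: int,
    n_background: int = 90,
    n_clade: int = 30,
    lam_bg: float = 0.1,
    rate_factor: float = 10.0,
) -> Tuple[TimeTree, int]:
    """A pure-birth background tree with one grafted fast clade.

    Simulates the background at ``lam_bg``, then replaces the tip with the
    longest pendant edge by an ``n_clade``-tip clade simulated at
    ``rate_factor * lam_bg`` (resampled until it fits under the pendant edge,
    so no rescaling distorts the true rates).  Returns the tree and the flat
    index of the planted crown node.
    """
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(_RETRY_CAP + 1)
    s_bg = int(kids[0].generate_state(1)[0] % (2**31))
    bg = simulate_bd_tree(lam_bg, 0.0, seed=s_bg, n_tips=n_background)
    flat = bg.flat
    host = int(np.argmax(flat.blen[: flat.n_tips]))
    stem_age = float(flat.blen[host])
    clade = None
    for child_ss in kids[1:]:
        sd = int(child_ss.generate_state(1)[0] % (2**31))
        cand = simulate_bd_tree(lam_bg * rate_factor, 0.0, seed=sd, n_tips=n_clade)
        if cand.height() < 0.9 * stem_age:
            clade = cand
            break
    if clade is None:
        raise RuntimeError("could not fit a fast clade under the host pendant edge")

    host_label = flat.labels[host]
    tns = bg.tree.taxon_namespace
    host_leaf = next(
        lf for lf in bg.tree.leaf_node_iter() if lf.taxon.label == host_label
    )
    sub = clade.tree
    for lf in sub.leaf_node_iter():
        lf.taxon = tns.new_taxon(label=f"c_{lf.taxon.label}")
    graft = sub.seed_node
    graft.edge.length = stem_age - clade.height()
    parent = host_leaf.parent_node
    parent.remove_child(host_leaf)
    parent.add_child(graft)
    tns.remove_taxon(host_leaf.taxon)
    out = TimeTree(bg.tree).validate()
    crown = out.flat.mrca([f"c_{lab}" for lab in clade.flat.labels])
    return out, crown


# ------------------------------------------------- crown-size simulation oracle
def simulate_crown_sizes(
    bd: BDParams, t: float, n_samples: int, seed: int = 0
) -> np.ndarray:
    """Sizes of ``n_samples`` birth-death crown clades at age ``t`` conditioned
    on survival of both crown lineages.

    Brute-force Gillespie on population counts, vectorised across replicates:
    each round advances every still-running replicate by one event.  This is a
    direct simulation of the process and shares no machinery with the
    closed-form crown-size distribution.
    """
    lam, mu = bd.lam, bd.mu
    rng = np.random.default_rng(seed)
    out: List[np.ndarray] = []
    got = 0
    p_birth = lam / (lam + mu)
    while got < n_samples:
        batch = max(2 * (n_samples - got), 10_000)
        # two independent single-lineage populations per crown clade
        n = np.ones(2 * batch, dtype=np.int64)
        clock = np.zeros(2 * batch)
        active = np.arange(2 * batch)
        while active.size:
            na = n[active].astype(float)
            clock[active] += rng.exponential(1.0, active.size) / ((lam + mu) * na)
            done = clock[active] >= t
            act = active[~done]
            if act.size == 0:
                break
            birth = rng.random(act.size) < p_birth
            n[act] += np.where(birth, 1, -1)
            active = act[n[act] > 0]
        n[clock < t] = 0  # extinct before reaching t
        n1, n2 = n[:batch], n[batch:]
        ok = (n1 > 0) & (n2 > 0)
        out.append((n1 + n2)[ok])
        got += int(ok.sum())
    return np.concatenate(out)[:n_samples]


# ------------------------------------------------------------------- fixture
@dataclass
class SyntheticDataset:
    tree: TimeTree
    sample: TreeSample
    traits: TraitTable
    richness: RichnessTable
    truth: Dict = field(default_factory=dict)

    def write(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
            fh.write(self.tree.as_newick() + "\n")
        write_trees(self.sample, os.path.join(outdir, "trees.nex"), format="nexus")
        self.traits.to_tsv(os.path.join(outdir, "traits.tsv"))
        self.richness.to_tsv(os.path.join(outdir, "richness.tsv"))
        with open(os.path.join(outdir, "truth.yaml"), "w") as fh:
            yaml.safe_dump(self.truth, fh, sort_keys=True)

    @classmethod
    def read(cls, outdir: str) -> "SyntheticDataset":
        import os

        from .treeio import read_trees

        tree = read_trees(os.path.join(outdir, "tree.nwk"), "newick")[0]
        sample = read_trees(os.path.join(outdir, "trees.nex"), "nexus")
        traits = TraitTable.from_tsv(os.path.join(outdir, "traits.tsv"))
        richness = RichnessTable.from_tsv(os.path.join(outdir, "richness.tsv"))
        with open(os.path.join(outdir, "truth.yaml")) as fh:
            truth = yaml.safe_load(fh)
        return cls(tree, sample, traits, richness, truth)


def _gain_clades_ok(flat: FlatTree, states: np.ndarray, target: int) -> Optional[List[int]]:
    """Return gain child nodes iff the painting has exactly ``target`` disjoint
    gains, no losses, every gain subtends at least one present tip, and no two
    gains sit on sibling edges (sister gains cannot be distinguished from a
    single parental gain by any reconstruction, so they would make the truth
    ambiguous)."""
    events = count_transitions(flat, states)
    gains = [e for e in events if e.direction == "gain"]
    losses = [e for e in events if e.direction == "loss"]
    if len(gains) != target or losses:
        return None
    gain_nodes = [e.child for e in gains]
    clades = flat.clades()
    seen: set = set()
    for g in gain_nodes:
        tipset = clades[g]
        present = [lab for lab in tipset if states[flat.tip_index[lab]] == 1]
        if not present:
            return None
        if seen & tipset:
            return None
        seen |= tipset

    # Separation: repainting the region spanning any two gains as present must
    # require at least two loss events on purely-absent side branches,
    # otherwise a reconstruction can merge the pair (or a chain) into a single
    # deeper origin and the truth count is not identifiable.
    gain_set = set(gain_nodes)
    parent = flat.parent

    def path_to_root(v: int) -> List[int]:
        out = []
        while v != flat.root:
            out.append(v)
            v = int(parent[v])
        out.append(flat.root)
        return out

    paths = {g: path_to_root(int(parent[g])) for g in gain_nodes}
    for i, g1 in enumerate(gain_nodes):
        for g2 in gain_nodes[i + 1 :]:
            p1, p2 = paths[g1], paths[g2]
            anc2 = set(p2)
            mrca = next(v for v in p1 if v in anc2)
            spine = set(
                p1[: p1.index(mrca) + 1] + p2[: p2.index(mrca) + 1]
            )
            hang = [
                c
                for v in spine
                for c in flat.children[v]
                if c not in spine and c != g1 and c != g2
            ]
            if not hang:
                return None  # sister gains
            if len(hang) == 1 and any(
                states[flat.tip_index[lab]] == 1 for lab in clades[hang[0]]
            ):
                return None  # chain: a third gain inside the only side branch
    return gain_nodes


def make_fish_fixture(
    seed: int = 0,
    n_tips: int = 301,
    target_gains: int = 27,
    tree_sample_size: int = 500,
    depth_ma: float = 150.0,
    mechanism_counts: Optional[Tuple[int, int, int]] = None,
    jitter_sigma: float = 0.1,
    n_exceptional: int = 6,
    exceptional_rate_factor: float = 3.0,
    loss_rate_fraction: float = 0.2,
) -> SyntheticDataset:
    """Build the default fish-like dataset with a fully known truth block.

    A pure-birth topology rescaled to ``depth_ma`` crown age; a binary trait
    rejection-sampled until exactly ``target_gains`` disjoint, loss-free gains
    are realised; mechanisms painted largest-first (intrinsic to the largest
    clades, unknown to the smallest); richness drawn from the crown-size
    distribution at each clade's age, with ``n_exceptional`` clades planted at
    ``exceptional_rate_factor`` times the background net diversification.
    """
    if target_gains >= n_tips / 4:
        raise ValueError("target_gains must be < n_tips / 4")
    if mechanism_counts is None:
        # the default 8 intrinsic / 17 bacterial / 2 unknown split, scaled
        # proportionally when a different total is requested
        n_int = round(target_gains * 8 / 27)
        n_unk = round(target_gains * 2 / 27)
        mechanism_counts = (n_int, target_gains - n_int - n_unk, n_unk)
    if sum(mechanism_counts) != target_gains:
        raise ValueError("mechanism counts must sum to target_gains")
    ss = np.random.SeedSequence(seed)
    s_tree, s_trait, s_jit, s_rich = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]

    base = simulate_bd_tree(lam=1.0, mu=0.0, seed=s_tree, n_tips=n_tips)
    tree = rescale_tree_depth(base, depth_ma)
    flat = tree.flat
    L = flat.tree_length()
    q01 = target_gains / L
    q10 = loss_rate_fraction * q01
    params = MkParams(q01, q10)

    gain_nodes: Optional[List[int]] = None
    states = None
    trait_rng = np.random.SeedSequence(s_trait)
    for child_ss in trait_rng.spawn(_RETRY_CAP):
        sd = int(child_ss.generate_state(1)[0] % (2**31))
        cand_states, _tips = simulate_traits(flat, params, root_state=0, seed=sd)
        gain_nodes = _gain_clades_ok(flat, cand_states, target_gains)
        if gain_nodes is not None:
            states = cand_states
            break
    if gain_nodes is None:
        raise RuntimeError("retry cap exhausted before hitting target gain count")

    # --- mechanisms: largest gain clades intrinsic, smallest unknown
    clades = flat.clades()
    n_int, n_bact, n_unk = mechanism_counts
    order = sorted(
        gain_nodes, key=lambda g: (-len(clades[g]), min(clades[g]))
    )
    mech_of_gain: Dict[int, str] = {}
    for k, g in enumerate(order):
        if k < n_int:
            mech_of_gain[g] = "intrinsic"
        elif k < n_int + n_bact:
            mech_of_gain[g] = "bacterial"
        else:
            mech_of_gain[g] = "unknown"

    mech_tips: Dict[str, str] = {}
    for g, mech in mech_of_gain.items():
        for lab in clades[g]:
            if states[flat.tip_index[lab]] == 1:
                mech_tips[lab] = mech
    traits = TraitTable(
        {flat.labels[i]: int(states[i]) for i in range(flat.n_tips)}, mech_tips
    )

    sample = jitter_tree_sample(tree, tree_sample_size, sigma=jitter_sigma, seed=s_jit)

    # --- richness table: one named clade per gain
    rich_rng = np.random.default_rng(s_rich)
    r_bg = math.log(n_tips / 2.0) / depth_ma
    bg = BDParams(r_bg, 0.0)
    # plant the elevated-rate clades on the largest gain clades with >=3 tips,
    # split two-thirds intrinsic / one-third bacterial to mirror exceptional
    # richness concentrating in intrinsically luminous lineages
    n_exc_int = int(math.ceil(2 * n_exceptional / 3))
    elig_int = [g for g in order if len(clades[g]) >= 3 and mech_of_gain[g] == "intrinsic"]
    elig_bact = [g for g in order if len(clades[g]) >= 3 and mech_of_gain[g] == "bacterial"]
    planted = set(elig_int[:n_exc_int]) | set(elig_bact[: n_exceptional - n_exc_int])
    clade_rows: List[CladeRichness] = []
    truth_rates: Dict[str, float] = {}
    planted_names: List[str] = []
    keys = flat.node_keys()
    for k, g in enumerate(order):
        node = g
        # singleton gains: name the smallest ancestral clade with >=2 tips
        while len(clades[node]) < 2:
            node = int(flat.parent[node])
        tipset = clades[node]
        age = float(flat.ages[node]) if node >= flat.n_tips else float(
            flat.ages[flat.parent[node]]
        )
        rate = BDParams(bg.r * exceptional_rate_factor, bg.eps) if g in planted else bg
        n_vals, pmf = crown_size_pmf(rate, max(age, 1.0))
        draw = int(rich_rng.choice(n_vals, p=pmf / pmf.sum()))
        species = max(draw, len(tipset), 2)
        name = f"clade_{k + 1:02d}_{keys[g]}"
        clade_rows.append(
            CladeRichness(name=name, tips=tipset, species=species, crown_age_ma=None)
        )
        truth_rates[name] = rate.r
        if g in planted:
            planted_names.append(name)
    richness = RichnessTable(clade_rows)

    events = count_transitions(flat, states)
    truth = {
        "seed": seed,
        "q01": float(q01),
        "q10": float(q10),
        "root_state": 0,
        "n_gains": int(sum(e.direction == "gain" for e in events)),
        "n_losses": int(sum(e.direction == "loss" for e in events)),
        "gain_nodes": [keys[g] for g in gain_nodes],
        "mechanism_tallies": {
            "intrinsic": n_int,
            "bacterial": n_bact,
            "unknown": n_unk,
        },
        "node_states": {keys[v]: int(states[v]) for v in range(flat.n_nodes)},
        "background_r": float(bg.r),
        "background_eps": float(bg.eps),
        "clade_rates": truth_rates,
        "planted_exceptional": planted_names,
    }
    return SyntheticDataset(tree, sample, traits, richness, truth)
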