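"""Reading, validation, summarising and subsampling of time-calibrated trees
and their companion trait / clade-richness tables.

All trees are rooted with branch lengths in millions of years (Ma).  Posterior
samples (e.g. from a Bayesian dating run) are held as a :class:`TreeSample`
over an identical taxon set.  Trait tables give each tip a binary state
(0 absent, 1 present) plus, for present tips, a mechanism annotation
(``intrinsic`` | ``bacterial`` | ``unknown``).  Richness tables attach described
species counts and crown ages to named clades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from ._flat import FlatTree

ULTRAMETRIC_RTOL = 1e-6
MECHANISMS = ("intrinsic", "bacterial", "unknown")


class TreeParseError(ValueError):
    """Raised when a tree file violates the dialect or the time-tree contract."""


# ---------------------------------------------------------------------- trees
@dataclass
class TimeTree:
    """A rooted ultrametric tree with branch lengths in Ma."""

    tree: dendropy.Tree
    _flat: Optional[FlatTree] = field(default=None, repr=False, compare=False)

    @property
    def flat(self) -> FlatTree:
        if self._flat is None:
            self._flat = FlatTree.from_dendropy(self.tree)
        return self._flat

    @property
    def tip_labels(self) -> List[str]:
        return self.flat.labels

    @property
    def n_tips(self) -> int:
        return self.flat.n_tips

    def height(self) -> float:
        return self.flat.height()

    def root_to_tip_depths(self) -> np.ndarray:
        flat = self.flat
        depth = np.zeros(flat.n_nodes)
        for v in range(flat.n_nodes - 2, -1, -1):
            depth[v] = depth[flat.parent[v]] + flat.blen[v]
        return depth[: flat.n_tips]

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.root_to_tip_depths()
        m = float(np.mean(d))
        if m == 0:
            return True
        return bool(np.max(np.abs(d - m)) / m <= rtol)

    def validate(self, require_ultrametric: bool = True) -> "TimeTree":
        flat = self.flat  # triggers duplicate-label and layout checks
        if not np.all(np.isfinite(flat.blen)):
            raise TreeParseError("non-finite branch length")
        if np.any(flat.blen < 0):
            raise TreeParseError("negative branch length")
        if require_ultrametric and not self.is_ultrametric():
            raise TreeParseError(
                "tree is not ultrametric within relative tolerance "
                f"{ULTRAMETRIC_RTOL:g}; pass require_ultrametric=False to accept"
            )
        return self

    def as_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    @classmethod
    def from_newick(cls, s: str, require_ultrametric: bool = True) -> "TimeTree":
        try:
            tree = dendropy.Tree.get(
                data=s, schema="newick", preserve_underscores=True,
                rooting="force-rooted",
            )
        except Exception as exc:
            raise TreeParseError(f"could not parse newick string: {exc}") from exc
        return cls(tree).validate(require_ultrametric=require_ultrametric)


@dataclass
class TreeSample:
    """An ordered list of :class:`TimeTree` over one taxon set."""

    trees: List[TimeTree]
    weights: Optional[np.ndarray] = None

    def __post_init__(self):
        if not self.trees:
            raise ValueError("empty tree sample")
        ref = set(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees[1:], start=1):
            if set(t.tip_labels) != ref:
                raise TreeParseError(f"tree {i} has a different taxon set than tree 0")

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i: int) -> TimeTree:
        return self.trees[i]

    def __iter__(self):
        return iter(self.trees)

    @property
    def taxon_set(self) -> frozenset:
        return frozenset(self.trees[0].tip_labels)


def read_trees(
    path: str,
    format: str = "newick",
    require_ultrametric: bool = True,
) -> TreeSample:
    """Read one or more trees from a Newick or NEXUS file into a TreeSample.

    Each tree is validated (unique tips, finite non-negative branch lengths,
    ultrametric within tolerance unless disabled).  Parse failures name the
    offending tree index.
    """
    if format not in ("newick", "nexus"):
        raise TreeParseError(f"unknown tree format {format!r}")
    try:
        tl = dendropy.TreeList.get(
            path=path,
            schema=format,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several unrelated types
        raise TreeParseError(f"could not parse {path!r} as {format}: {exc}") from exc
    if len(tl) == 0:
        raise TreeParseError(f"no trees found in {path!r}")
    trees = []
    for i, t in enumerate(tl):
        for nd in t.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length is None:
                raise TreeParseError(f"tree {i}: missing branch length")
        try:
            trees.append(TimeTree(t).validate(require_ultrametric=require_ultrametric))
        except (TreeParseError, ValueError) as exc:
            raise TreeParseError(f"tree {i}: {exc}") from exc
    return TreeSample(trees)


def write_trees(sample: TreeSample, path: str, format: str = "newick") -> None:
    tl = dendropy.TreeList()
    for t in sample:
        tl.append(t.tree)
    tl.write(path=path, schema=format, suppress_rooting=True)


def subsample_trees(
    sample: TreeSample, n: int, seed: int = 0, mode: str = "even"
) -> TreeSample:
    """Take ``n`` trees: ``even`` mode every floor(len/n)-th tree from index 0;
    ``random`` mode without replacement under ``seed`` (original order kept)."""
    if n > len(sample):
        raise ValueError(f"cannot subsample {n} from {len(sample)} trees")
    if n == len(sample):
        return TreeSample(list(sample.trees))
    if mode == "even":
        step = len(sample) // n
        idx = [i * step for i in range(n)]
    elif mode == "random":
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(sample), size=n, replace=False).tolist())
    else:
        raise ValueError(f"unknown subsample mode {mode!r}")
    return TreeSample([sample.trees[i] for i in idx])


def mcc_tree(sample: TreeSample, height_summary: str = "mean") -> TimeTree:
    """Maximum clade credibility tree with summarised node heights.

    Returns the member tree maximising the product of clade posterior
    frequencies over the sample (ties broken by lowest index), with each node
    height replaced by the mean (or median) height of the matching clade across
    the trees that contain it.
    """
    if height_summary not in ("mean", "median"):
        raise ValueError("height_summary must be 'mean' or 'median'")
    ntree = len(sample)
    freq: Dict[frozenset, int] = {}
    heights: Dict[frozenset, list] = {}
    for t in sample:
        flat = t.flat
        clades = flat.clades()
        for v in flat.internal_postorder:
            key = clades[v]
            freq[key] = freq.get(key, 0) + 1
            heights.setdefault(key, []).append(float(flat.ages[v]))

    best_i, best_score = 0, -math.inf
    for i, t in enumerate(sample):
        flat = t.flat
        clades = flat.clades()
        score = sum(
            math.log(freq[clades[v]] / ntree) for v in flat.internal_postorder
        )
        if score > best_score:
            best_i, best_score = i, score

    summ = np.mean if height_summary == "mean" else np.median
    chosen = sample[best_i]
    out = dendropy.Tree(chosen.tree)  # deep clone via taxon-sharing copy
    # summarised age per node, then rebuild branch lengths from ages
    age: Dict[dendropy.Node, float] = {}
    for nd in out.postorder_node_iter():
        if nd.is_leaf():
            age[nd] = 0.0
        else:
            key = frozenset(
                lf.taxon.label for lf in nd.leaf_iter()
            )
            age[nd] = float(summ(heights[key]))
    for nd in out.preorder_node_iter():
        if nd.parent_node is not None:
            # mean heights over different conditioning sets can invert very
            # short parent/child pairs; clamp at zero as summary trees do
            nd.edge.length = max(age[nd.parent_node] - age[nd], 0.0)
    return TimeTree(out).validate(require_ultrametric=False)


# --------------------------------------------------------------------- traits
@dataclass
class TraitTable:
    """Tip -> binary state (0/1/None=missing) with mechanism for state-1 tips."""

    states: Dict[str, Optional[int]]
    mechanisms: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for tip, st in self.states.items():
            if st not in (0, 1, None):
                raise ValueError(f"tip {tip!r}: state must be 0, 1 or missing")
            if st == 1:
                mech = self.mechanisms.get(tip)
                if mech not in MECHANISMS:
                    raise ValueError(
                        f"tip {tip!r}: state-1 tips need a mechanism in {MECHANISMS}"
                    )
            elif tip in self.mechanisms:
                raise ValueError(f"tip {tip!r}: mechanism given for a state-0 tip")

    def check_covers(self, tips: Sequence[str]) -> None:
        missing = [t for t in tips if t not in self.states]
        if missing:
            raise ValueError(f"trait table lacks entries for tips: {missing[:5]}...")

    @classmethod
    def from_tsv(cls, path: str) -> "TraitTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        need = {"tip", "state"}
        if not need <= set(df.columns):
            raise ValueError(f"trait table needs columns {need}")
        states: Dict[str, Optional[int]] = {}
        mechs: Dict[str, str] = {}
        for _, row in df.iterrows():
            tip = str(row["tip"])
            raw = row["state"]
            if pd.isna(raw) or raw in ("", "?", "NA", "-"):
                states[tip] = None
            else:
                states[tip] = int(raw)
            if states[tip] == 1:
                mech = row.get("mechanism")
                mechs[tip] = str(mech) if not pd.isna(mech) else "unknown"
        return cls(states, mechs)

    def to_tsv(self, path: str) -> None:
        rows = []
        for tip in sorted(self.states):
            st = self.states[tip]
            rows.append(
                {
                    "tip": tip,
                    "state": "" if st is None else st,
                    "mechanism": self.mechanisms.get(tip, ""),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- richness
@dataclass
class CladeRichness:
    name: str
    tips: frozenset
    species: int
    crown_age_ma: Optional[float] = None  # None -> take from tree

    def __post_init__(self):
        if len(self.tips) < 2:
            raise ValueError(f"clade {self.name!r}: needs >= 2 defining tips")
        if self.species < len(self.tips):
            raise ValueError(
                f"clade {self.name!r}: described species ({self.species}) fewer "
                f"than sampled tips ({len(self.tips)})"
            )


@dataclass
class RichnessTable:
    clades: List[CladeRichness]

    def __iter__(self):
        return iter(self.clades)

    def __len__(self):
        return len(self.clades)

    def by_name(self, name: str) -> CladeRichness:
        for c in self.clades:
            if c.name == name:
                return c
        raise KeyError(name)

    @classmethod
    def from_tsv(cls, path: str) -> "RichnessTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        need = {"clade", "tips", "species"}
        if not need <= set(df.columns):
            raise ValueError(f"richness table needs columns {need}")
        clades = []
        for _, row in df.iterrows():
            age = row.get("crown_age_ma")
            clades.append(
                CladeRichness(
                    name=str(row["clade"]),
                    tips=frozenset(str(row["tips"]).split(";")),
                    species=int(row["species"]),
                    crown_age_ma=None
                    if (pd.isna(age) or age in ("", "from_tree"))
                    else float(age),
                )
            )
        return cls(clades)

    def to_tsv(self, path: str) -> None:
        rows = [
            {
                "clade": c.name,
                "tips": ";".join(sorted(c.tips)),
                "species": c.species,
                "crown_age_ma": "" if c.crown_age_ma is None else c.crown_age_ma,
            }
            for c in self.clades
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
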