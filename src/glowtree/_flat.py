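"""Array-backed rooted tree used by the likelihood and counting machinery.

Tips occupy indices ``0 .. n_tips-1`` in sorted-label order; internal nodes
follow in postorder, so the root is always the last index.  Conversion from a
:class:`dendropy.Tree` is deterministic, which keeps every seeded computation
reproducible bit-for-bit.
"""

from __future__ import annotations

from typing import Iterable, List, Optional

import numpy as np
import dendropy


class FlatTree:
    """Immutable indexed view of a rooted (possibly multifurcating) time tree."""

    __slots__ = (
        "labels",
        "tip_index",
        "parent",
        "children",
        "blen",
        "ages",
        "n_tips",
        "n_nodes",
        "internal_postorder",
        "_clades",
        "_node_keys",
    )

    def __init__(
        self,
        labels: List[str],
        parent: np.ndarray,
        children: List[List[int]],
        blen: np.ndarray,
    ):
        self.labels = list(labels)
        self.tip_index = {lab: i for i, lab in enumerate(self.labels)}
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = [list(c) for c in children]
        self.blen = np.asarray(blen, dtype=float)
        self.n_tips = len(labels)
        self.n_nodes = len(children)
        # layout contract: children always precede parents
        for v in range(self.n_tips, self.n_nodes):
            if any(c >= v for c in self.children[v]):
                raise ValueError("FlatTree requires postorder node layout")
        self.internal_postorder = list(range(self.n_tips, self.n_nodes))
        self.ages = self._compute_ages()
        self._clades: Optional[List[frozenset]] = None
        self._node_keys: Optional[List[str]] = None

    # ------------------------------------------------------------------ build
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "FlatTree":
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = sorted(
            (lf.taxon.label if lf.taxon is not None else str(lf.label)) for lf in leaves
        )
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels in tree")
        index = {lab: i for i, lab in enumerate(labels)}
        n_tips = len(labels)

        order = []  # internal nodes in postorder
        for nd in tree.postorder_node_iter():
            if not nd.is_leaf():
                order.append(nd)
        n_nodes = n_tips + len(order)

        node_id = {}
        for nd in tree.leaf_node_iter():
            lab = nd.taxon.label if nd.taxon is not None else str(nd.label)
            node_id[nd] = index[lab]
        for k, nd in enumerate(order):
            node_id[nd] = n_tips + k

        parent = np.full(n_nodes, -1, dtype=np.int64)
        children: List[List[int]] = [[] for _ in range(n_nodes)]
        blen = np.zeros(n_nodes, dtype=float)
        for nd in tree.preorder_node_iter():
            v = node_id[nd]
            if nd.parent_node is not None:
                parent[v] = node_id[nd.parent_node]
                blen[v] = float(nd.edge.length) if nd.edge.length is not None else 0.0
            children[v] = [node_id[c] for c in nd.child_nodes()]
        return cls(labels, parent, children, blen)

    def _compute_ages(self) -> np.ndarray:
        ages = np.zeros(self.n_nodes, dtype=float)
        for v in self.internal_postorder:
            ch = self.children[v]
            ages[v] = float(np.mean([ages[c] + self.blen[c] for c in ch]))
        return ages

    # ------------------------------------------------------------- properties
    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def edges(self) -> Iterable[int]:
        """Child indices of all edges (every node except the root)."""
        return range(self.n_nodes - 1)

    def clades(self) -> List[frozenset]:
        """Per node, the frozenset of descendant tip labels."""
        if self._clades is None:
            out: List[frozenset] = [frozenset()] * self.n_nodes
            for i in range(self.n_tips):
                out[i] = frozenset((self.labels[i],))
            for v in self.internal_postorder:
                acc = frozenset()
                for c in self.children[v]:
                    acc = acc | out[c]
                out[v] = acc
            self._clades = out
        return self._clades

    def subtree_nodes(self, v: int) -> List[int]:
        """All nodes of the subtree rooted at ``v`` (including ``v``), preorder."""
        out = [v]
        stack = list(self.children[v])
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(self.children[u])
        return out

    def mrca(self, tips: Iterable[str]) -> int:
        idx = [self.tip_index[t] for t in tips]
        if not idx:
            raise ValueError("empty tip set")
        clades = self.clades()
        target = frozenset(self.labels[i] for i in idx)
        # walk up from one member until the clade covers all of them
        v = idx[0]
        while not target <= clades[v]:
            v = int(self.parent[v])
        return v

    def node_keys(self) -> List[str]:
        """Stable human-readable node ids: smallest tip labels of the first two
        child subtrees joined by '|' (tips are their own label)."""
        if self._node_keys is None:
            mins: List[str] = [""] * self.n_nodes
            for i in range(self.n_tips):
                mins[i] = self.labels[i]
            keys: List[str] = [""] * self.n_nodes
            for i in range(self.n_tips):
                keys[i] = self.labels[i]
            for v in self.internal_postorder:
                ch = self.children[v]
                cmins = sorted(mins[c] for c in ch)
                mins[v] = cmins[0]
                keys[v] = "|".join(cmins[:2])
            self._node_keys = keys
        return self._node_keys

    def tree_length(self) -> float:
        return float(np.sum(self.blen[: self.n_nodes - 1]))

    def height(self) -> float:
        return float(self.ages[self.root])
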