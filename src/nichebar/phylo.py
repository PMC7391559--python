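"""Rooted phylogeny container used throughout the package.

Nodes are stored in postorder (children before parents, root last) and are
identified by their postorder index; unlabeled internal nodes get the
deterministic label ``n<postorder index>``.  Newick parsing is delegated to
dendropy; only topology, branch lengths and labels are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy


@dataclass
class Phylogeny:
    children: list[list[int]]           # postorder-indexed adjacency
    lengths: list[float]                # branch length above each node (root: 0)
    labels: list[str]                   # tip labels given, internal auto "n<i>"

    parent: list[int] = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.children)
        if not (len(self.lengths) == len(self.labels) == n):
            raise ValueError("children/lengths/labels must have equal length")
        self.parent = [-1] * n
        for v in range(n):
            for c in self.children[v]:
                if c >= v:
                    raise ValueError("nodes must be in postorder (children first)")
                self.parent[c] = v
        for v, bl in enumerate(self.lengths):
            if not math.isfinite(bl) or bl < 0:
                raise ValueError(f"branch length above node {self.labels[v]} invalid: {bl}")
        tips = self.tip_labels
        if len(set(tips)) != len(tips):
            raise ValueError("duplicate tip labels")

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    @property
    def tip_indices(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.is_tip(v)]

    @property
    def internal_indices(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.is_tip(v)]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[v] for v in self.tip_indices]

    def postorder(self) -> range:
        return range(self.n_nodes)

    def preorder(self) -> Iterable[int]:
        return reversed(range(self.n_nodes))

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(label) from None

    # -- derived quantities ----------------------------------------------
    def depths(self) -> list[float]:
        """Distance from the root to every node."""
        d = [0.0] * self.n_nodes
        for v in self.preorder():
            if v != self.root:
                d[v] = d[self.parent[v]] + self.lengths[v]
        return d

    def tipsets(self) -> list[frozenset[str]]:
        """Descendant tip-label set of every node."""
        out: list[frozenset[str]] = [frozenset()] * self.n_nodes
        for v in self.postorder():
            if self.is_tip(v):
                out[v] = frozenset([self.labels[v]])
            else:
                s: set[str] = set()
                for c in self.children[v]:
                    s |= out[c]
                out[v] = frozenset(s)
        return out

    def mrca(self, tip_labels: Sequence[str]) -> int:
        """Index of the most recent common ancestor of the given tips."""
        want = frozenset(tip_labels)
        missing = want - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        for v, s in enumerate(self.tipsets()):
            if want <= s:
                return v
        raise AssertionError("unreachable: root contains all tips")

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.depths()
        tip_d = [d[v] for v in self.tip_indices]
        return max(tip_d) - min(tip_d) <= tol * max(1.0, max(tip_d))

    # -- newick -----------------------------------------------------------
    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if self.is_tip(v):
                core = self.labels[v]
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return core
            return f"{core}:{self.lengths[v]:.12g}"

        return rec(self.root) + ";"


def from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    order = list(dtree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(order)}
    children, lengths, labels = [], [], []
    for i, nd in enumerate(order):
        kids = [index[id(c)] for c in nd.child_nodes()]
        children.append(kids)
        bl = nd.edge.length
        is_root = nd.parent_node is None
        if bl is None:
            if not is_root:
                name = nd.taxon.label if nd.taxon else (nd.label or f"n{i}")
                raise ValueError(f"missing branch length on edge above '{name}'")
            bl = 0.0
        lengths.append(float(bl))
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise ValueError("unlabeled tip in tree")
            labels.append(nd.taxon.label)
        else:
            labels.append(nd.label if nd.label else f"n{i}")
    return Phylogeny(children=children, lengths=lengths, labels=labels)


def parse_newick(newick: str) -> Phylogeny:
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    return from_dendropy(dtree)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
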