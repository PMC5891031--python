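"""Rooted species trees for post-WGD loss modeling.

The tree root represents the polyploidy event itself: every locus is in state
U there.  A tree may carry a *stem* branch (a length attached to the outermost
clade in newick, ``((A,B),C):0.5;``) running from the WGD down to the first
speciation; losses on the stem are shared by all genomes.  Branch lengths are
in alpha*t units (base loss rate times time).

Newick parsing/writing is delegated to dendropy; internally the tree is
flattened to postorder arrays for fast pruning.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np


class LossTree:
    """A rooted binary tree flattened to arrays.

    Nodes are indexed in postorder (children before parents); the seed node
    (first speciation, or the single tip) is last.  Every node has an edge to
    its parent; the seed node's edge is the WGD stem branch (length 0 when the
    newick does not specify one).
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self._dendropy = tree
        self.n_nodes = n
        self.parent = np.full(n, -1, dtype=np.int64)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.edge_lengths = np.zeros(n, dtype=float)
        self.is_tip = np.zeros(n, dtype=bool)
        labels: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
            if nd.edge.length is not None:
                self.edge_lengths[i] = float(nd.edge.length)
            if nd.is_leaf():
                self.is_tip[i] = True
                labels[i] = nd.taxon.label if nd.taxon is not None else str(nd.label)
        if any(self.is_tip[i] and labels[i] is None for i in range(n)):
            raise ValueError("every tip must be labeled")
        if (self.edge_lengths < 0).any():
            raise ValueError("negative branch length in tree")
        self.tip_labels = labels
        self.taxa: tuple[str, ...] = tuple(sorted(labels[i] for i in range(n) if self.is_tip[i]))
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate tip labels")
        #: genome index (position in self.taxa) per tip node, -1 for internals
        self.tip_genome = np.full(n, -1, dtype=np.int64)
        for i in range(n):
            if self.is_tip[i]:
                self.tip_genome[i] = self.taxa.index(labels[i])
        self.seed = n - 1

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, newick: str) -> "LossTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     rooting="force-rooted",
                                     suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises schema-specific errors
            raise ValueError(f"could not parse newick ({exc})") from exc
        return cls(tree)

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if self.is_tip[i]:
                core = self.tip_labels[i]
            else:
                core = "(" + ",".join(render(c) for c in self.children[i]) + ")"
            return f"{core}:{self.edge_lengths[i]:.10g}"

        return render(self.seed) + ";"

    # -------------------------------------------------------------- queries
    @property
    def n_edges(self) -> int:
        """Number of branches, counting the WGD stem above the seed node."""
        return self.n_nodes

    def edge_label(self, i: int) -> str:
        """Human-readable branch id: the sorted tips below the branch (the
        branch above the seed node is the WGD "stem")."""
        if i == self.seed:
            return "stem"
        return "+".join(sorted(self.tips_below(i)))

    def tips_below(self, i: int) -> list[str]:
        out: list[str] = []
        stack = [i]
        while stack:
            j = stack.pop()
            if self.is_tip[j]:
                out.append(self.tip_labels[j])
            else:
                stack.extend(self.children[j])
        return out

    def early_edge_mask(self, early: Sequence[str] | None = None) -> np.ndarray:
        """Boolean mask of branches in the "early" class (root-proximal).

        By default this is every branch incident to the WGD root: the stem
        when it has positive length, otherwise the seed node's child edges.
        ``early`` may name branches explicitly by :meth:`edge_label`.
        """
        mask = np.zeros(self.n_edges, dtype=bool)
        if early is not None:
            labels = {self.edge_label(i): i for i in range(self.n_edges)}
            for name in early:
                if name not in labels:
                    raise ValueError(f"unknown branch label {name!r}; known: {sorted(labels)}")
                mask[labels[name]] = True
            return mask
        if self.edge_lengths[self.seed] > 0:
            mask[self.seed] = True
        else:
            for c in self.children[self.seed]:
                mask[c] = True
        return mask

    def with_lengths(self, lengths: np.ndarray) -> "LossTree":
        out = LossTree(self._dendropy)
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != (self.n_edges,):
            raise ValueError("length vector does not match edge count")
        out.edge_lengths = lengths.copy()
        return out


# ---------------------------------------------------------------- topologies

def _insertions(shape, tip):
    """All ways of attaching ``tip`` onto an edge of ``shape`` or above its root."""
    out = [(shape, tip)]
    if isinstance(shape, tuple):
        left, right = shape
        out.extend((x, right) for x in _insertions(left, tip))
        out.extend((left, x) for x in _insertions(right, tip))
    return out


def _shape_to_newick(shape, branch_length: float, stem_length: float) -> str:
    def render(s) -> str:
        if isinstance(s, tuple):
            return "(" + ",".join(render(x) for x in s) + f"):{branch_length:g}"
        return f"{s}:{branch_length:g}"

    if isinstance(shape, tuple):
        inner = "(" + ",".join(render(x) for x in shape) + f"):{stem_length:g};"
    else:  # single taxon
        inner = f"({shape}):{stem_length:g};"
    return inner


def enumerate_rooted_topologies(taxa: Iterable[str], branch_length: float = 0.3,
                                stem_length: float = 0.3) -> list[str]:
    """All rooted binary topologies on ``taxa`` as newick strings.

    There are (2k-3)!! topologies for k taxa (3 for three taxa, 15 for four).
    Branch lengths are placeholders for subsequent optimization.
    """
    taxa = list(taxa)
    if len(set(taxa)) != len(taxa):
        raise ValueError("taxa must be unique")
    if not taxa:
        return []
    shapes = [taxa[0]]
    for tip in taxa[1:]:
        shapes = [s2 for s in shapes for s2 in _insertions(s, tip)]
    return [_shape_to_newick(s, branch_length, stem_length) for s in shapes]
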