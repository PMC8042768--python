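"""Rooted phylogeny container backed by index arrays.

Trees are parsed from Newick with dendropy and converted to a flat postorder
representation that the likelihood engine and simulator iterate over.  The
substitution model is non-reversible, so the root placement is meaningful:
trees must be rooted and binary (an unrooted trifurcation at the base is
rejected with advice to root, ideally on an outgroup).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

DEFAULT_BRANCH_LENGTH = 0.05


class TreeStructureError(ValueError):
    """Raised for polytomies, unrooted inputs, or malformed Newick."""


@dataclass
class RootedTree:
    """Rooted binary tree over ``taxa`` in flat postorder arrays.

    Nodes are indexed 0..n_nodes-1 with leaves first, in the order of
    ``taxa``.  ``parent[i]`` is -1 for the root; ``lengths[i]`` is the length
    of the branch above node i (NaN for the root).  ``postorder`` visits
    children before parents; the root is last.
    """

    taxa: tuple[str, ...]
    parent: np.ndarray
    lengths: np.ndarray
    children: tuple[tuple[int, ...], ...]
    postorder: np.ndarray

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    @property
    def branch_nodes(self) -> np.ndarray:
        """Indices of non-root nodes, i.e. one per branch (postorder)."""
        return self.postorder[:-1]

    def copy(self) -> "RootedTree":
        return RootedTree(
            taxa=self.taxa,
            parent=self.parent.copy(),
            lengths=self.lengths.copy(),
            children=self.children,
            postorder=self.postorder.copy(),
        )

    def is_leaf(self, node: int) -> bool:
        return len(self.children[node]) == 0

    def total_length(self) -> float:
        return float(np.nansum(self.lengths))

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, default_length: float | None = None) -> "RootedTree":
        """Parse a rooted binary Newick string.

        Branches without lengths get ``DEFAULT_BRANCH_LENGTH`` with a
        warning.  A basal trifurcation (the usual signature of an unrooted
        tree) raises :class:`TreeStructureError`.
        """
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeStructureError(f"could not parse Newick tree: {exc}") from exc
        return cls._from_dendropy(dt, default_length)

    @classmethod
    def from_file(cls, path, default_length: float | None = None) -> "RootedTree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), default_length)

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree, default_length=None) -> "RootedTree":
        if default_length is None:
            default_length = DEFAULT_BRANCH_LENGTH
        seed = dt.seed_node
        if len(seed.child_nodes()) != 2:
            raise TreeStructureError(
                "tree must be rooted and binary; found a basal polytomy — "
                "root the tree first (including an outgroup is recommended)"
            )
        leaves = [lf for lf in dt.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
        if any(lb is None for lb in labels) or len(set(labels)) != len(labels):
            raise TreeStructureError("leaf labels must be present and unique")
        taxa = tuple(labels)
        index = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        nxt = len(leaves)
        order = []
        for nd in dt.postorder_node_iter():
            kids = nd.child_nodes()
            if kids:
                if len(kids) != 2:
                    raise TreeStructureError(
                        "internal polytomy found; only binary trees are supported"
                    )
                index[id(nd)] = nxt
                nxt += 1
            order.append(index[id(nd)])
        n = nxt
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.full(n, np.nan)
        children: list[tuple[int, ...]] = [() for _ in range(n)]
        warned = False
        for nd in dt.postorder_node_iter():
            i = index[id(nd)]
            kids = nd.child_nodes()
            children[i] = tuple(index[id(k)] for k in kids)
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    if not warned:
                        warnings.warn(
                            f"branch lengths missing; defaulting to {default_length}",
                            stacklevel=3,
                        )
                        warned = True
                    lengths[i] = default_length
                else:
                    lengths[i] = float(nd.edge.length)
                    if lengths[i] < 0:
                        raise TreeStructureError("negative branch length")
        return cls(
            taxa=taxa,
            parent=parent,
            lengths=lengths,
            children=tuple(children),
            postorder=np.asarray(order, dtype=np.int64),
        )

    # -- serialization ----------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            if self.is_leaf(node):
                label = self.taxa[node]
                if any(ch in label for ch in " (),:;"):
                    label = f"'{label}'"
                body = label
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[node]) + ")"
            if self.parent[node] >= 0:
                body += f":{self.lengths[node]:.12g}"
            return body

        return fmt(self.root) + ";"

    # -- queries -----------------------------------------------------------

    def branch_generations(self) -> np.ndarray:
        """Generation of each branch: 0 for pendant edges, then 1 + max of
        the child-edge generations, so tips are optimized before the edges
        that subtend them."""
        gen = np.zeros(self.n_nodes, dtype=np.int64)
        for node in self.postorder:
            if not self.is_leaf(node):
                gen[node] = 1 + max(gen[c] for c in self.children[node])
        return gen

    def mrca(self, labels) -> int:
        want = {self.taxa.index(lb) for lb in labels}
        below: list[set] = [set() for _ in range(self.n_nodes)]
        for node in self.postorder:
            if self.is_leaf(node):
                below[node] = {node}
            else:
                for c in self.children[node]:
                    below[node] |= below[c]
            if want <= below[node]:
                return int(node)
        raise ValueError("labels not all present in tree")

    def clade_length(self, labels) -> float:
        """Sum of branch lengths strictly inside the clade spanned by
        ``labels`` (the stem branch of the clade's MRCA is excluded)."""
        top = self.mrca(labels)
        total = 0.0
        stack = list(self.children[top])
        while stack:
            node = stack.pop()
            total += float(self.lengths[node])
            stack.extend(self.children[node])
        return total

    def drop_leaf(self, label: str) -> "RootedTree":
        """Return a new tree without ``label``, suppressing the resulting
        degree-two node by summing the two adjoining branch lengths."""
        if label not in self.taxa:
            raise ValueError(f"taxon {label!r} not in tree")
        dt = dendropy.Tree.get(data=self.to_newick(), schema="newick")
        tx = dt.taxon_namespace.get_taxon(label)
        dt.prune_taxa([tx], suppress_unifurcations=True)
        # pruning a child of the root can leave a root with a single child
        seed = dt.seed_node
        while len(seed.child_nodes()) == 1:
            child = seed.child_nodes()[0]
            child.parent_node = None
            dt.seed_node = child
            child.edge.length = None
            seed = child
        return RootedTree._from_dendropy(dt)
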