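"""Rooted phylogenetic trees with branch lengths.

A :class:`PhyloTree` is the backbone of every covariance computation in the
package: the Brownian-motion covariance of a set of tips is the matrix of
shared root-to-tip path lengths, and the stationary Ornstein-Uhlenbeck
covariance is a function of the patristic distance matrix.  Trees are parsed
from newick via dendropy and held in a small node structure so traversals
(Felsenstein pruning, independent contrasts) stay simple and fast.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["PhyloTree", "TreeNode", "read_newick_tree", "prune_to_species"]


@dataclass
class TreeNode:
    """One node of a rooted tree; ``length`` is the edge to the parent."""

    label: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted tree with unique tip labels and non-negative branch lengths.

    The root's own ``length`` is ignored (taken as 0).  Polytomies are
    allowed; :meth:`resolve_polytomies` produces the strictly binary version
    needed by the contrasts recursion (extra edges get length 0).
    """

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [n.label for n in self.postorder() if n.is_tip]
        if any(lab is None for lab in labels):
            raise ValueError("every tip must carry a label")
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        for node in self.postorder():
            if node is self.root:
                continue
            bl = node.length
            if bl is None or not np.isfinite(bl):
                raise ValueError(f"missing or non-finite branch length above {node.label or 'internal node'}")
            if bl < 0:
                raise ValueError("branch lengths must be >= 0")
        self._labels = labels

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(data=text, schema="newick")
        except Exception as err:  # dendropy raises schema-specific errors
            raise ValueError(f"invalid newick ({err.__class__.__name__}): tip labels must be unique and syntax valid") from err
        seen_missing = []

        def convert(dnode) -> TreeNode:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            length = dnode.edge.length
            node = TreeNode(label=label, length=0.0 if length is None else float(length))
            if length is None and dnode.parent_node is not None:
                seen_missing.append(label or "internal node")
            for child in dnode.child_nodes():
                node.children.append(convert(child))
            return node

        root = convert(dtree.seed_node)
        if seen_missing:
            raise ValueError(f"newick is missing branch lengths (first at {seen_missing[0]})")
        return cls(root)

    def copy(self) -> "PhyloTree":
        def cp(n: TreeNode) -> TreeNode:
            return TreeNode(n.label, n.length, [cp(c) for c in n.children])

        return PhyloTree(cp(self.root))

    # -- basic accessors ---------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in postorder (stable for a given tree)."""
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    def postorder(self):
        out = []

        def walk(node: TreeNode):
            for child in node.children:
                walk(child)
            out.append(node)

        walk(self.root)
        return out

    def total_length(self) -> float:
        return float(sum(n.length for n in self.postorder() if n is not self.root))

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_tip:
                core = node.label
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node is self.root:
                return core
            return f"{core}:{node.length:.10g}"

        return fmt(self.root) + ";"

    # -- covariance / distance machinery ----------------------------------

    def _depths_and_parents(self):
        parent: dict[int, TreeNode | None] = {id(self.root): None}
        depth: dict[int, float] = {id(self.root): 0.0}
        for node in self.postorder():
            for child in node.children:
                parent[id(child)] = node
        # second pass top-down for depths
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child in node.children:
                depth[id(child)] = depth[id(node)] + child.length
                stack.append(child)
        return depth, parent

    def _tip_nodes(self) -> dict[str, TreeNode]:
        return {n.label: n for n in self.postorder() if n.is_tip}

    def cov_matrix(self, order: list[str] | None = None) -> np.ndarray:
        """Brownian-motion covariance at unit rate: shared path lengths.

        ``C[i, j]`` is the root-to-MRCA path length of tips ``i`` and ``j``;
        the diagonal is the root-to-tip depth.
        """
        order = list(order) if order is not None else self.tip_labels
        depth, parent = self._depths_and_parents()
        tips = self._tip_nodes()
        missing = [lab for lab in order if lab not in tips]
        if missing:
            raise KeyError(f"labels not in tree: {missing}")

        def ancestors(node: TreeNode) -> list[TreeNode]:
            chain = []
            cur: TreeNode | None = node
            while cur is not None:
                chain.append(cur)
                cur = parent[id(cur)]
            return chain

        chains = {lab: ancestors(tips[lab]) for lab in order}
        chain_sets = {lab: {id(n) for n in chains[lab]} for lab in order}
        n = len(order)
        C = np.zeros((n, n))
        for i, a in enumerate(order):
            C[i, i] = depth[id(tips[a])]
            for j in range(i + 1, n):
                b = order[j]
                mrca = next(node for node in chains[a] if id(node) in chain_sets[b])
                C[i, j] = C[j, i] = depth[id(mrca)]
        return C

    def dist_matrix(self, order: list[str] | None = None) -> np.ndarray:
        """Patristic (path-length) distances between tips."""
        order = list(order) if order is not None else self.tip_labels
        C = self.cov_matrix(order)
        d = np.diag(C)
        return d[:, None] + d[None, :] - 2.0 * C

    # -- editing -----------------------------------------------------------

    def scaled_to_depth(self, depth: float) -> "PhyloTree":
        """Copy with branch lengths rescaled so the mean root-to-tip depth
        equals ``depth`` (phylogram-style normalization)."""
        cur = float(np.mean(np.diag(self.cov_matrix())))
        if cur <= 0:
            raise ValueError("tree has zero depth")
        out = self.copy()
        f = depth / cur
        for node in out.postorder():
            node.length *= f
        return out

    def resolve_polytomies(self) -> "PhyloTree":
        """Return a binary tree; multifurcations become zero-length ladders."""

        def fix(node: TreeNode) -> TreeNode:
            children = [fix(c) for c in node.children]
            while len(children) > 2:
                a = children.pop()
                b = children.pop()
                children.append(TreeNode(None, 0.0, [b, a]))
            return TreeNode(node.label, node.length, children)

        return PhyloTree(fix(self.root))


def read_newick_tree(path) -> PhyloTree:
    """Read a rooted newick tree with branch lengths.

    A trifurcating (unrooted-style) top-level node is accepted and treated as
    a root polytomy.  Missing branch lengths are an error.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"empty newick file: {path}")
    return PhyloTree.from_newick(text)


def prune_to_species(tree: PhyloTree, keep) -> PhyloTree:
    """Restrict ``tree`` to the tips in ``keep``.

    Unary internal nodes are collapsed with branch lengths summed, so all
    pairwise path lengths between kept tips are preserved.  If the old root
    ends up with a single child, that child becomes the new root (its edge is
    absorbed); path lengths between tips are unaffected.
    """
    keep = set(keep)
    unknown = keep - set(tree.tip_labels)
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("pruning requires at least 2 tips to keep")

    def rebuild(node: TreeNode) -> TreeNode | None:
        if node.is_tip:
            if node.label in keep:
                return TreeNode(node.label, node.length, [])
            return None
        children = [c for c in (rebuild(ch) for ch in node.children) if c is not None]
        if not children:
            return None
        if len(children) == 1:
            child = children[0]
            child.length += node.length
            return child
        return TreeNode(node.label, node.length, children)

    new_root = rebuild(tree.root)
    assert new_root is not None
    new_root.length = 0.0
    return PhyloTree(new_root)
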