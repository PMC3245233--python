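"""Phylogenetic trees: Newick I/O, rerooting, random trees, Robinson-Foulds.

Trees are stored rooted (an arbitrary root is fine: the pruning
likelihood is root-invariant for reversible models) with branch lengths
in expected substitutions per site.  Unrooted trees round-trip through a
trifurcating root.  Polytomies are allowed everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

__all__ = ["TreeNode", "PhyloTree", "read_newick", "robinson_foulds", "random_tree"]

#: Lower bound kept on optimised branch lengths (substitutions/site).
MIN_BRANCH_LENGTH = 1e-8


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0          # branch above this node; ignored at the root
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted tree over uniquely labelled leaves."""

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [n.name for n in self.leaves()]
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        if any(lbl is None for lbl in labels):
            raise ValueError("all leaves must be labelled")
        for node in self.postorder():
            if node is not self.root and node.length < 0:
                raise ValueError("branch lengths must be non-negative")

    # -- traversal ---------------------------------------------------------
    def postorder(self):
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out[::-1]

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[TreeNode]:
        """Non-root nodes; each carries the branch above it."""
        return [n for n in self.postorder() if n is not self.root]

    def copy(self) -> "PhyloTree":
        def clone(n: TreeNode) -> TreeNode:
            return TreeNode(n.name, n.length, [clone(c) for c in n.children])
        return PhyloTree(clone(self.root))

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def total_length(self) -> float:
        return sum(n.length for n in self.edges())

    # -- rerooting ---------------------------------------------------------
    def rerooted_at_edge(self, edge_index: int, fraction: float = 0.5) -> "PhyloTree":
        """New tree rooted on the branch above ``self.edges()[edge_index]``.

        Likelihood under a reversible model is invariant to this move
        (the pulley principle), which tests exploit.  The original root,
        if left with degree 2 in the unrooted graph, is suppressed.
        """
        nodes = self.postorder()
        adj: dict[int, list[tuple[int, float]]] = {id(n): [] for n in nodes}
        by_id = {id(n): n for n in nodes}
        for parent in nodes:
            for child in parent.children:
                adj[id(parent)].append((id(child), child.length))
                adj[id(child)].append((id(parent), child.length))
        child = self.edges()[edge_index]
        parent = next(n for n in nodes if child in n.children)
        t = child.length
        adj[id(parent)] = [(k, w) for k, w in adj[id(parent)] if k != id(child)]
        adj[id(child)] = [(k, w) for k, w in adj[id(child)] if k != id(parent)]
        root_key = "new_root"
        adj[root_key] = [(id(child), fraction * t), (id(parent), (1.0 - fraction) * t)]
        adj[id(child)].append((root_key, fraction * t))
        adj[id(parent)].append((root_key, (1.0 - fraction) * t))

        def build(key, parent_key, length) -> TreeNode:
            old = by_id.get(key)
            name = old.name if old is not None and old.is_leaf else None
            kids = [build(k, key, w) for k, w in adj[key] if k != parent_key]
            if len(kids) == 1 and name is None:  # suppress degree-2 node
                kid = kids[0]
                kid.length += length
                return kid
            return TreeNode(name, length, kids)

        new_root = TreeNode()
        new_root.children = [build(k, root_key, w) for k, w in adj[root_key]]
        return PhyloTree(new_root)

    # -- newick ------------------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node: TreeNode, top: bool) -> str:
            label = node.name or ""
            if any(c in (label or "") for c in " ()[]:;,"):
                label = f"'{label}'"
            if node.is_leaf:
                body = label
            else:
                body = "(" + ",".join(fmt(c, False) for c in node.children) + ")" + label
            return body if top else f"{body}:{node.length:.10g}"
        return fmt(self.root, True) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
        def convert(dnode) -> TreeNode:
            name = dnode.taxon.label if dnode.taxon else (dnode.label or None)
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            return TreeNode(name, float(length), [convert(c) for c in dnode.child_nodes()])
        return cls(convert(dtree.seed_node))


def read_newick(path: str | Path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())


# -- Robinson-Foulds -------------------------------------------------------

def _bipartitions(tree: PhyloTree) -> set[frozenset]:
    """Non-trivial splits of the unrooted tree, each as its smaller-side set
    canonicalised against the full leaf set."""
    all_leaves = frozenset(tree.leaf_names())
    below: dict[int, frozenset] = {}
    splits = set()
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node is tree.root:
            continue
        side = below[id(node)]
        if 1 < len(side) < len(all_leaves) - 1:
            other = all_leaves - side
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def robinson_foulds(tree_a: PhyloTree, tree_b: PhyloTree) -> int:
    """Symmetric-difference count of non-trivial bipartitions.

    Topology-only and unrooted: branch lengths and root placement are
    ignored.  Polytomies contribute whatever splits they actually induce.
    """
    if set(tree_a.leaf_names()) != set(tree_b.leaf_names()):
        raise ValueError("trees must share an identical leaf set")
    return len(_bipartitions(tree_a) ^ _bipartitions(tree_b))


# -- random trees ----------------------------------------------------------

def random_tree(n_taxa: int, rng: np.random.Generator,
                mean_branch_length: float = 0.1,
                names: list[str] | None = None) -> PhyloTree:
    """Random coalescent-style topology with exponential branch lengths.

    Pairs of lineages are joined uniformly at random until one remains;
    every branch length is an independent exponential draw with the given
    mean, giving moderate divergence comparable to curated protein-family
    trees at small scale.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    names = names or [f"t{i}" for i in range(n_taxa)]
    if len(names) != n_taxa:
        raise ValueError("names length mismatch")
    nodes = [TreeNode(name, float(rng.exponential(mean_branch_length))) for name in names]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = int(i), int(j)
        merged = TreeNode(None, float(rng.exponential(mean_branch_length)),
                          [nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = nodes[0]
    root.length = 0.0
    return PhyloTree(root)
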