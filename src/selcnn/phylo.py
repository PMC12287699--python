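"""Phylogenies for the simulator: balanced trees with uniform branch lengths.

The simulation design deliberately constrains the tree space: sequences evolve
along a fully balanced binary topology (8 taxa by default) rooted at its
midpoint, with every edge set to the same divergence ``d`` in expected
substitutions per codon site.  Leaf order is a fixed preorder traversal and
defines the row order of every emitted alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TreeNode:
    name: str
    branch_length: float  # length of the edge above this node; 0 at the root
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """A rooted tree with named leaves in deterministic traversal order."""

    root: TreeNode

    @property
    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def n_nodes(self) -> int:
        count = 0

        def walk(node: TreeNode) -> None:
            nonlocal count
            count += 1
            for child in node.children:
                walk(child)

        walk(self.root)
        return count

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.branch_length:g}"
            inner = ",".join(fmt(c) for c in node.children)
            if node.branch_length > 0:
                return f"({inner}){node.name}:{node.branch_length:g}"
            return f"({inner}){node.name}"

        return fmt(self.root) + ";"


def build_symmetric_tree(n_leaves: int, divergence: float) -> PhyloTree:
    """Build the balanced binary simulation tree.

    Parameters
    ----------
    n_leaves
        Number of taxa; must be a power of two in {2, 4, 8, 16}.
    divergence
        Length of every edge, in expected substitutions per codon site per
        branch (``d > 0``).  The default study condition uses 8 leaves and
        ``d = 0.2``.

    Returns
    -------
    PhyloTree
        Balanced tree rooted at its midpoint, leaves labelled ``t1..tn`` in
        traversal order.
    """
    if n_leaves not in (2, 4, 8, 16):
        raise ValueError(
            f"n_leaves must be a power of two in {{2,4,8,16}}, got {n_leaves}"
        )
    if not divergence > 0:
        raise ValueError(f"divergence must be positive, got {divergence}")

    counter = iter(range(1, n_leaves + 1))
    internal = iter(range(1, n_leaves))  # internal node labels, root excluded

    def grow(n: int, length: float, is_root: bool = False) -> TreeNode:
        if n == 1:
            return TreeNode(name=f"t{next(counter)}", branch_length=length)
        name = "root" if is_root else f"n{next(internal)}"
        node = TreeNode(name=name, branch_length=0.0 if is_root else length)
        node.children = [grow(n // 2, divergence), grow(n // 2, divergence)]
        return node

    return PhyloTree(root=grow(n_leaves, 0.0, is_root=True))


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string (e.g. a user-supplied tree) into a PhyloTree."""
    import dendropy

    tree = dendropy.Tree.get(data=text, schema="newick")

    def convert(node: "dendropy.Node") -> TreeNode:
        name = node.taxon.label if node.taxon is not None else (node.label or "")
        out = TreeNode(
            name=name.replace(" ", "_"),
            branch_length=float(node.edge.length or 0.0),
        )
        out.children = [convert(c) for c in node.child_nodes()]
        return out

    return PhyloTree(root=convert(tree.seed_node))
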