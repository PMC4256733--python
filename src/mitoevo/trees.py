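"""Rooted phylogenetic trees.

A deliberately small tree class: the reconstruction algorithms in
:mod:`mitoevo.ancestral_content` need parent links, stable node ids and
cheap post-/pre-order traversal, nothing more.  Newick parsing is
delegated to dendropy; the parsed tree is converted into this structure
so the numerical code does not depend on a third-party node API.
"""

from __future__ import annotations

from typing import Iterator

import dendropy


class TreeNode:
    """A node of a rooted tree.

    Attributes
    ----------
    name : str or None
        Leaf label, or internal label when one was present in the input.
    length : float or None
        Length of the branch above this node (``None`` for the root or
        when the input tree carries no lengths).
    children : list of TreeNode
    parent : TreeNode or None
    id : str
        Unique, stable identifier: the leaf name for leaves, the internal
        label when present, otherwise a generated ``N<k>`` token.
    """

    __slots__ = ("name", "length", "children", "parent", "id")

    def __init__(self, name=None, length=None):
        self.name = name
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.id: str = ""

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"TreeNode({self.id!r})"


class RootedTree:
    """A rooted, possibly multifurcating tree with unique leaf labels."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._assign_ids()
        names = [leaf.name for leaf in self.leaves()]
        if any(n is None or n == "" for n in names):
            raise ValueError("every leaf must be labelled")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
        for node in self.nodes():
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length at node {node.id!r}")

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        """Parse a single Newick tree from a string."""
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            msg = str(exc)
            if "Multiple occurrences" in msg or "Duplicate" in type(exc).__name__:
                raise ValueError(f"duplicate leaf labels in newick input: {msg}")
            raise ValueError(f"newick parse error: {msg}") from exc
        return cls(_convert(dtree.seed_node))

    def _assign_ids(self) -> None:
        counter = 0
        seen: set[str] = set()
        for node in self.postorder():
            if node.is_leaf:
                node.id = node.name or ""
            elif node.name:
                node.id = node.name
            else:
                node.id = f"N{counter}"
                counter += 1
            while node.id in seen:  # internal label colliding with a leaf
                node.id = f"N{counter}"
                counter += 1
            seen.add(node.id)

    # -- traversal -----------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def nodes(self) -> list[TreeNode]:
        return list(self.preorder())

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def node_by_id(self, node_id: str) -> TreeNode:
        for node in self.preorder():
            if node.id == node_id:
                return node
        raise KeyError(node_id)

    def mrca(self, leaf_names) -> TreeNode:
        """Most recent common ancestor of a non-empty set of leaves."""
        wanted = set(leaf_names)
        if not wanted:
            raise ValueError("mrca of an empty leaf set")
        below: dict[TreeNode, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.name} & wanted
            else:
                below[node] = set().union(*(below[c] for c in node.children))
            if below[node] == wanted:
                return node
        raise ValueError(f"leaves not in tree: {sorted(wanted)}")

    # -- output --------------------------------------------------------

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(render(c) for c in node.children)
                body = f"({inner})" + (node.name or "")
            if node.length is not None:
                body += f":{node.length:.12g}"
            return body

        return render(self.root) + ";"

    def copy(self) -> "RootedTree":
        return RootedTree.from_newick(self.to_newick())

    def __repr__(self):  # pragma: no cover
        return f"RootedTree(<{len(self.leaves())} leaves>)"


def _convert(dnode) -> TreeNode:
    name = None
    if dnode.taxon is not None:
        name = dnode.taxon.label
    elif dnode.label:
        name = dnode.label
    node = TreeNode(name=name, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_convert(child))
    return node
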