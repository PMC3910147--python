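"""Rooted reference trees: the vertical backbone of all lateral-transfer inference.

A :class:`ReferenceTree` is a rooted, node-labelled tree whose leaves are the
taxa (languages/doculects or genomes) of an analysis.  Polytomies are allowed:
classification trees such as the Ethnologue language trees are rarely binary,
and the parsimony machinery downstream never assumes bifurcation.  Internal
nodes without a label in the input receive deterministic labels ``N<i>`` where
``i`` is the node's preorder index, so gain/loss events and lateral edges are
reproducibly addressable across runs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator

import dendropy

__all__ = ["Node", "ReferenceTree", "NewickError", "read_newick", "write_newick"]


class NewickError(ValueError):
    """Raised for malformed Newick input (unbalanced parentheses, missing
    semicolon, duplicate or empty leaf labels, empty tree)."""


@dataclass(eq=False)
class Node:
    """A single tree node.  ``length`` is the branch length to the parent
    (``None`` when the input carries no lengths); the root has no parent."""

    label: str
    parent: "Node | None" = None
    children: list["Node"] = field(default_factory=list)
    length: float | None = None
    index: int = -1  # preorder index, assigned by ReferenceTree

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal/{len(self.children)}ch"
        return f"<Node {self.label!r} ({kind})>"


class ReferenceTree:
    """Rooted tree with unique node labels and preorder node indexing.

    Parameters
    ----------
    root:
        Root :class:`Node` of an already linked node structure.  Unlabeled
        internal nodes are auto-labelled ``N<preorder index>``.
    """

    def __init__(self, root: Node):
        self.root = root
        self.nodes: list[Node] = []
        self._assign_indices_and_labels()
        self._by_label = {n.label: n for n in self.nodes}
        self._validate()
        self._clades: dict[int, frozenset[str]] | None = None

    # -- construction helpers -------------------------------------------------

    def _assign_indices_and_labels(self) -> None:
        stack = [self.root]
        i = 0
        while stack:
            node = stack.pop()
            node.index = i
            self.nodes.append(node)
            i += 1
            # reversed so children come off the stack in original order
            stack.extend(reversed(node.children))
        for node in self.nodes:
            if not node.label:
                if node.is_leaf:
                    raise NewickError("empty leaf label in tree")
                node.label = f"N{node.index}"

    def _validate(self) -> None:
        if len(self._by_label) != len(self.nodes):
            seen: set[str] = set()
            for n in self.nodes:
                if n.label in seen:
                    raise NewickError(f"duplicate node label: {n.label!r}")
                seen.add(n.label)
        if not self.leaves:
            raise NewickError("tree has no leaves")
        for n in self.nodes:
            if n.length is not None and n.length < 0:
                raise NewickError(f"negative branch length on {n.label!r}")

    # -- basic accessors ------------------------------------------------------

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def taxa(self) -> list[str]:
        """Leaf labels in preorder (left-to-right) order."""
        return [n.label for n in self.leaves]

    @property
    def internal_nodes(self) -> list[Node]:
        return [n for n in self.nodes if not n.is_leaf]

    def __len__(self) -> int:
        return len(self.nodes)

    def __getitem__(self, label: str) -> Node:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r} in tree") from None

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def preorder(self) -> Iterator[Node]:
        return iter(self.nodes)

    def postorder(self) -> Iterator[Node]:
        return reversed(self.nodes)

    # -- derived quantities ---------------------------------------------------

    def clade(self, node: Node | str) -> frozenset[str]:
        """Leaf-label set of the clade rooted at ``node``."""
        if self._clades is None:
            clades: dict[int, frozenset[str]] = {}
            for n in self.postorder():
                if n.is_leaf:
                    clades[n.index] = frozenset((n.label,))
                else:
                    clades[n.index] = frozenset().union(
                        *(clades[c.index] for c in n.children)
                    )
            self._clades = clades
        if isinstance(node, str):
            node = self[node]
        return self._clades[node.index]

    def depths(self, unit_lengths: bool = False) -> dict[str, float]:
        """Root-to-node distance for every node.  Missing branch lengths count
        as 1 (``unit_lengths`` forces 1 everywhere)."""
        out: dict[str, float] = {}
        for n in self.preorder():
            if n.parent is None:
                out[n.label] = 0.0
            else:
                step = 1.0 if (unit_lengths or n.length is None) else n.length
                out[n.label] = out[n.parent.label] + step
        return out

    def patristic(self, a: Node | str, b: Node | str, unit_lengths: bool = False) -> float:
        """Path length between two nodes (sum of branch lengths; missing
        lengths count as 1)."""
        if isinstance(a, str):
            a = self[a]
        if isinstance(b, str):
            b = self[b]
        depths = self.depths(unit_lengths=unit_lengths)

        ancestors_a: dict[int, Node] = {}
        n: Node | None = a
        while n is not None:
            ancestors_a[n.index] = n
            n = n.parent
        n = b
        while n is not None and n.index not in ancestors_a:
            n = n.parent
        assert n is not None  # both paths reach the root
        return depths[a.label] + depths[b.label] - 2.0 * depths[n.label]

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        """True when all root-to-leaf depths agree within a relative tolerance."""
        d = self.depths()
        leaf_depths = [d[t] for t in self.taxa]
        span = max(leaf_depths) - min(leaf_depths)
        scale = max(max(leaf_depths), 1e-12)
        return span / scale <= rel_tol

    # -- serialization --------------------------------------------------------

    def write_newick(self, include_lengths: bool = True) -> str:
        return write_newick(self, include_lengths=include_lengths)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<ReferenceTree {len(self.taxa)} taxa, {len(self.nodes)} nodes>"


def read_newick(text: str) -> ReferenceTree:
    """Parse a Newick string into a :class:`ReferenceTree`.

    The string must end with a semicolon.  Leaf labels must be unique and
    non-empty; unlabeled internal nodes are auto-labelled by preorder index.
    Raises :class:`NewickError` on malformed input, naming the offence.
    """
    stripped = text.strip()
    if not stripped:
        raise NewickError("empty Newick input")
    if not stripped.endswith(";"):
        raise NewickError(
            f"Newick string must end with ';' (got trailing {stripped[-10:]!r})"
        )
    if stripped.count("(") != stripped.count(")"):
        raise NewickError(
            "unbalanced parentheses: "
            f"{stripped.count('(')} '(' vs {stripped.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"Newick parse error: {exc}") from exc

    def convert(dnode: dendropy.Node, parent: Node | None) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
        else:
            label = dnode.label or ""
        node = Node(label=label, parent=parent, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.children.append(convert(child, node))
        return node

    root = convert(dtree.seed_node, None)
    tree = ReferenceTree(root)
    if len(tree.taxa) != len(set(tree.taxa)):
        seen: set[str] = set()
        for t in tree.taxa:
            if t in seen:
                raise NewickError(f"duplicate leaf label: {t!r}")
            seen.add(t)
    return tree


def write_newick(tree: ReferenceTree, include_lengths: bool = True) -> str:
    """Serialize a :class:`ReferenceTree` to Newick, keeping all node labels
    (including auto-assigned internal labels) so the output round-trips."""
    buf = io.StringIO()

    def emit(node: Node) -> None:
        if node.children:
            buf.write("(")
            for i, child in enumerate(node.children):
                if i:
                    buf.write(",")
                emit(child)
            buf.write(")")
        buf.write(node.label)
        if include_lengths and node.length is not None:
            buf.write(f":{node.length!r}")  # repr: shortest exact round-trip

    emit(tree.root)
    buf.write(";")
    return buf.getvalue()
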