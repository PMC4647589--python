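"""Rooted phylogenies: Newick I/O, MRCA queries, grafting, unit branch lengths.

The analysis downstream is conditional on a fixed rooted tree, so this module
deliberately offers no inference or rearrangement — only reading, writing,
building (grafting published subtrees onto a backbone) and querying.

Trees may be multifurcating; branch lengths may be missing on input because
the reconstruction overwrites them with 1 ("punctuational" lengths, one unit
of expected change per cladogenetic event).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import dendropy

__all__ = [
    "PhyloNode",
    "PhyloTree",
    "CladeDefinition",
    "TreeError",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "set_unit_branch_lengths",
    "mrca",
    "graft",
]


class TreeError(ValueError):
    """Structural problem with a tree (duplicate tips, bad reference, ...)."""


class NewickParseError(TreeError):
    """Malformed Newick input; carries the character offset when known."""

    def __init__(self, message: str, offset: Optional[int] = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (near character {offset})"
        super().__init__(message)


@dataclass
class PhyloNode:
    """One node of a rooted tree.

    ``length`` is the edge length to the parent (``None`` = missing, legal on
    input; the root's length is ignored). ``label`` is the tip name for
    leaves; internal labels are preserved but unused by the model.
    """

    id: int
    label: Optional[str] = None
    parent: Optional["PhyloNode"] = field(default=None, repr=False)
    children: list["PhyloNode"] = field(default_factory=list, repr=False)
    length: Optional[float] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None


class PhyloTree:
    """A rooted, possibly multifurcating phylogeny with labelled tips.

    Invariants (checked on construction): exactly one root, unique non-empty
    tip labels, >= 2 tips, edge lengths >= 0 where present.
    """

    def __init__(self, root: PhyloNode):
        self.root = root
        self._reindex()
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _reindex(self) -> None:
        self._nodes: list[PhyloNode] = []
        for i, node in enumerate(self._walk_preorder(self.root)):
            node.id = i
            self._nodes.append(node)
        self._tip_index = {n.label: n for n in self._nodes if n.is_tip}

    @staticmethod
    def _walk_preorder(node: PhyloNode) -> Iterator[PhyloNode]:
        stack = [node]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def _validate(self) -> None:
        tips = self.tips()
        if len(tips) < 2:
            raise TreeError("tree must have at least 2 tips")
        labels = [t.label for t in tips]
        if any(not lb for lb in labels):
            raise TreeError("every tip must carry a non-empty label")
        dupes = {lb for lb in labels if labels.count(lb) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        for n in self._nodes:
            if n.length is not None and n.length < 0:
                raise TreeError(f"negative edge length on node {n.id}")
            for c in n.children:
                if c.parent is not n:
                    raise TreeError("inconsistent parent pointers")

    # -- queries --------------------------------------------------------------

    @property
    def nodes(self) -> Sequence[PhyloNode]:
        return tuple(self._nodes)

    def tips(self) -> list[PhyloNode]:
        return [n for n in self._nodes if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self._tip_index)

    def find_tip(self, label: str) -> PhyloNode:
        try:
            return self._tip_index[label]
        except KeyError:
            raise TreeError(f"no tip labelled {label!r}") from None

    def postorder(self) -> list[PhyloNode]:
        order: list[PhyloNode] = []

        def visit(n: PhyloNode) -> None:
            for c in n.children:
                visit(c)
            order.append(n)

        visit(self.root)
        return order

    def preorder(self) -> list[PhyloNode]:
        return list(self._walk_preorder(self.root))

    def copy(self) -> "PhyloTree":
        def clone(n: PhyloNode, parent: Optional[PhyloNode]) -> PhyloNode:
            new = PhyloNode(id=n.id, label=n.label, parent=parent, length=n.length)
            new.children = [clone(c, new) for c in n.children]
            return new

        return PhyloTree(clone(self.root, None))

    def path_to_root(self, node: PhyloNode) -> list[PhyloNode]:
        path = [node]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        return path

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_tips} tips, {len(self._nodes)} nodes>"


@dataclass(frozen=True)
class CladeDefinition:
    """A named clade, identified by the MRCA of a set of member tips."""

    name: str
    tip_labels: frozenset[str]

    def __init__(self, name: str, tip_labels):
        if not name:
            raise ValueError("clade name must be non-empty")
        labels = frozenset(tip_labels)
        if not labels:
            raise ValueError(f"clade {name!r} has no member tips")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "tip_labels", labels)


# -- Newick I/O ---------------------------------------------------------------

_UNROOTED_FLAG = re.compile(r"\[\s*&\s*U\s*\]", re.IGNORECASE)


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted, semicolon-terminated Newick string.

    Labels are taken literally (no underscore-to-space translation); quoted
    labels are supported. Missing branch lengths are stored as ``None``.
    An explicit unrooted flag (``[&U]``) is rejected: ancestral nodes are
    meaningless without a root.
    """
    if _UNROOTED_FLAG.search(text):
        raise TreeError("unrooted trees are rejected; supply a rooted Newick")
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("Newick string must be semicolon-terminated",
                               offset=len(text))
    depth = 0
    for i, ch in enumerate(stripped):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset=i)
    if depth != 0:
        raise NewickParseError("unbalanced '('", offset=len(stripped) - 1)
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode, parent: Optional[PhyloNode]) -> PhyloNode:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = PhyloNode(id=-1, label=label, parent=parent,
                         length=dnode.edge.length)
        node.children = [convert(c, node) for c in dnode.child_nodes()]
        return node

    return PhyloTree(convert(dtree.seed_node, None))


_NEEDS_QUOTES = re.compile(r"[\s()\[\]{}:;,']")


def _format_label(label: str) -> str:
    if _NEEDS_QUOTES.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(length: Optional[float]) -> str:
    if length is None:
        return ""
    if length == int(length):
        return f":{int(length)}"
    return f":{length!r}"


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to strict, semicolon-terminated Newick."""

    def fmt(node: PhyloNode) -> str:
        if node.is_tip:
            body = _format_label(node.label)
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                body += _format_label(node.label)
        if not node.is_root:
            body += _format_length(node.length)
        return body

    return fmt(tree.root) + ";"


# -- operations ---------------------------------------------------------------


def set_unit_branch_lengths(tree: PhyloTree) -> PhyloTree:
    """Return a copy with every edge length set to exactly 1.

    Equal unit lengths model change per cladogenetic event rather than per
    unit of time, which sidesteps missing branch-length data. Idempotent;
    topology untouched.
    """
    out = tree.copy()
    for node in out.nodes:
        if not node.is_root:
            node.length = 1.0
    return out


def mrca(tree: PhyloTree, tips) -> PhyloNode:
    """Most recent common ancestor of a set of tip labels."""
    labels = list(tips)
    if not labels:
        raise TreeError("mrca of an empty tip set is undefined")
    paths = []
    for lb in labels:
        node = tree.find_tip(lb)
        paths.append(list(reversed(tree.path_to_root(node))))  # root ... tip
    ancestor = None
    for level in zip(*paths):
        if all(n is level[0] for n in level):
            ancestor = level[0]
        else:
            break
    assert ancestor is not None  # root is always shared
    return ancestor


def graft(backbone: PhyloTree, subtree, attach_at: int) -> PhyloTree:
    """Attach ``subtree``'s root as a new child of node ``attach_at``.

    Used to assemble composite supertrees from separately published clade
    topologies. ``subtree`` is a :class:`PhyloTree`, or a bare string to
    graft a single new tip. Tip label sets must be disjoint.
    """
    if isinstance(subtree, str):
        sub_root = PhyloNode(id=-1, label=subtree)
        sub_labels = {subtree}
    else:
        sub = subtree.copy()
        sub_root = sub.root
        sub_labels = set(subtree.tip_labels)
    collision = set(backbone.tip_labels) & sub_labels
    if collision:
        raise TreeError(f"tip labels present in both trees: {sorted(collision)}")
    new = backbone.copy()
    target = None
    for node in new.nodes:
        if node.id == attach_at:
            target = node
            break
    if target is None:
        raise TreeError(f"no node with id {attach_at} in backbone")
    sub_root.parent = target
    target.children.append(sub_root)
    return PhyloTree(new.root)
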