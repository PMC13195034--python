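"""Rooted, labelled phylogenies.

A :class:`TaxonTree` is the substrate for every mapping stage: species trees
carrying named internal clades (e.g. ``Tylenchina``, ``Rhabditina``), gene
trees carrying bootstrap supports, and the small major-taxon tree used for
ancestral orthogroup content. Newick text is parsed through dendropy and
converted into a minimal in-package node structure so that downstream code
owns traversal, clade lookup and MRCA logic.

Conventions
-----------
* Internal newick labels that parse as numbers are bootstrap supports
  (required to lie in [0, 100]); any other internal label is a clade name.
* Leaf labels must be unique; named internal labels must not collide with
  leaf labels.
* ``tags`` optionally attaches grouping metadata to leaves, keyed first by
  leaf label and then by level name (e.g. ``{"Caenorhabditis_elegans":
  {"genus": "Caenorhabditis", "major_taxon": "Rhabditina"}}``).
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence

import dendropy


class NewickParseError(ValueError):
    """Malformed newick text (offset reported when determinable)."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (duplicate labels, bad supports, ...)."""


class Node:
    __slots__ = ("label", "support", "children", "parent", "nid")

    def __init__(self, label: Optional[str] = None, support: Optional[float] = None):
        self.label = label
        self.support = support
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None
        self.nid: int = -1

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def name(self) -> str:
        """Stable human-readable identifier: the label, or ``node<nid>``."""
        return self.label if self.label is not None else f"node{self.nid}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.name}>"


class TaxonTree:
    """Rooted tree with unique leaf labels and optional per-leaf tags."""

    def __init__(self, root: Node, tags: Optional[Mapping[str, Mapping[str, str]]] = None):
        self.root = root
        self.tags: Dict[str, Dict[str, str]] = {
            k: dict(v) for k, v in (tags or {}).items()
        }
        self._index_nodes()
        self._validate()

    # -- construction -----------------------------------------------------

    def _index_nodes(self) -> None:
        self._by_label: Dict[str, Node] = {}
        for i, node in enumerate(self.preorder()):
            node.nid = i
            if node.label is not None:
                if node.label in self._by_label:
                    raise TreeValidationError(f"duplicate node label {node.label!r}")
                self._by_label[node.label] = node

    def _validate(self) -> None:
        for node in self.preorder():
            if node is self.root:
                if node.parent is not None:
                    raise TreeValidationError("root must not have a parent")
            elif node.parent is None:
                raise TreeValidationError(f"non-root node {node.name} has no parent")
            if node.support is not None and not (0.0 <= node.support <= 100.0):
                raise TreeValidationError(
                    f"support {node.support} at {node.name} outside [0, 100]"
                )
            if node.is_leaf and node.label is None:
                raise TreeValidationError("leaf without a label")

    # -- traversal --------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> List[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> List[str]:
        return [n.label for n in self.leaves()]  # type: ignore[misc]

    def find(self, label: str) -> Node:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r} in tree") from None

    def subtree_leaves(self, node: Node) -> List[Node]:
        stack, out = [node], []
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            stack.extend(n.children)
        return out

    def subtree_leaf_labels(self, node: Node) -> List[str]:
        return [n.label for n in self.subtree_leaves(node)]  # type: ignore[misc]

    def is_ancestor(self, ancestor: Node, node: Node, strict: bool = False) -> bool:
        if ancestor is node:
            return not strict
        cur = node.parent
        while cur is not None:
            if cur is ancestor:
                return True
            cur = cur.parent
        return False

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the named leaves (or named nodes)."""
        targets = [self.find(lbl) for lbl in labels]
        if not targets:
            raise ValueError("mrca of an empty label set is undefined")
        # Walk up from the first target; the MRCA is the first ancestor that
        # dominates every other target.
        cur: Optional[Node] = targets[0]
        while cur is not None:
            if all(self.is_ancestor(cur, t) for t in targets):
                return cur
            cur = cur.parent
        raise TreeValidationError("disconnected tree")  # pragma: no cover

    def tag_of(self, leaf_label: str, level: str) -> Optional[str]:
        return self.tags.get(leaf_label, {}).get(level)

    def __len__(self) -> int:
        return sum(1 for _ in self.preorder())


# -- newick ---------------------------------------------------------------


def _check_balanced(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at character offset {offset}"
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced '(': {depth} unclosed at end of string"
        )


def _convert(dnode: "dendropy.Node") -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return Node(label=label)
    raw = dnode.label
    support: Optional[float] = None
    label: Optional[str] = None
    if raw is not None:
        try:
            support = float(raw)
        except ValueError:
            label = raw
    node = Node(label=label, support=support)
    for child in dnode.child_nodes():
        node.add_child(_convert(child))
    return node


def parse_newick(text: str, tags: Optional[Mapping[str, Mapping[str, str]]] = None) -> TaxonTree:
    """Parse one newick tree into a :class:`TaxonTree`.

    Numeric internal labels become bootstrap supports; non-numeric internal
    labels become clade names. Raises :class:`NewickParseError` on malformed
    text (naming the character offset for unbalanced parentheses) and
    :class:`TreeValidationError` on duplicate leaf labels.
    """
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty newick string")
    if not stripped.endswith(";"):
        raise NewickParseError("newick string must end with ';'")
    _check_balanced(stripped)
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "duplicate" in str(exc).lower():
            raise TreeValidationError(f"duplicate leaf labels: {exc}") from exc
        raise NewickParseError(f"newick parse failed: {exc}") from exc
    root = _convert(dtree.seed_node)
    tree = TaxonTree(root, tags=tags)
    labels = tree.leaf_labels
    if len(labels) != len(set(labels)):  # pragma: no cover - caught by index
        raise TreeValidationError("duplicate leaf labels")
    return tree


def _needs_quoting(label: str) -> bool:
    return any(ch in label for ch in "(),:;'[] \t\n")


def _fmt_label(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_support(support: float) -> str:
    return f"{int(support)}" if float(support).is_integer() else f"{support}"


def _write_node(node: Node) -> str:
    if node.is_leaf:
        return _fmt_label(node.label or "")
    inner = ",".join(_write_node(c) for c in node.children)
    suffix = ""
    if node.support is not None:
        suffix = _fmt_support(node.support)
    elif node.label is not None:
        suffix = _fmt_label(node.label)
    return f"({inner}){suffix}"


def write_newick(tree: TaxonTree) -> str:
    """Serialize in canonical form (child order preserved, no branch lengths)."""
    return _write_node(tree.root) + ";"
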