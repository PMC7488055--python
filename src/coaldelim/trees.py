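"""Rooted ultrametric trees with node ages.

The unit of analysis throughout the package is a rooted binary tree whose
nodes carry *ages*: time before the present, with every tip at age 0 and
branch lengths measured in expected substitutions per site.  GMYC consumes
one such tree per locus; the multispecies-coalescent layer consumes one per
locus plus a guide tree over candidate species.

Newick parsing and writing go through dendropy; all numerical work happens
on the lightweight :class:`Node`/:class:`UltrametricTree` structures defined
here.
"""

from __future__ import annotations

import io
import math
from typing import Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "Node",
    "UltrametricTree",
    "TreeError",
    "NonUltrametricError",
    "PolytomyError",
    "read_ultrametric_tree",
    "resolve_polytomies",
]

DEFAULT_TOLERANCE = 1e-6


class TreeError(ValueError):
    """Malformed tree input."""


class NonUltrametricError(TreeError):
    """Root-to-tip path lengths spread exceeds the stated tolerance."""


class PolytomyError(TreeError):
    """Tree contains a node with more than two children."""


class Node:
    """Tree node; ``age`` is time before present (tips have age 0)."""

    __slots__ = ("label", "age", "children", "parent", "index")

    def __init__(self, label: str | None = None, age: float = 0.0):
        self.label = label
        self.age = age
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.index: int = -1

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def tips(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_tip]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, age={self.age:.6g}, deg={len(self.children)})"


class UltrametricTree:
    """Rooted binary tree with node ages; tips at age 0.

    Parameters
    ----------
    root
        Root node of an age-annotated tree.  Branch lengths are implied:
        the branch above node ``v`` has length ``v.parent.age - v.age``.
    require_binary
        Reject polytomies (GMYC and the MSC layer both need strictly
        bifurcating trees).  Unifurcations are always collapsed.
    """

    def __init__(self, root: Node, require_binary: bool = True):
        _collapse_unifurcations(root)
        self.root = root
        self._index()
        if require_binary:
            for node in self.nodes:
                if node.children and len(node.children) != 2:
                    raise PolytomyError(
                        f"node {node.label or node.index} has {len(node.children)} "
                        "children; resolve polytomies first (see resolve_polytomies)"
                    )
        labels = [t.label for t in self.tips]
        if any(lab is None for lab in labels):
            raise TreeError("every tip must carry a label")
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")

    def _index(self) -> None:
        self.nodes: list[Node] = list(self.root.postorder())
        for i, node in enumerate(self.nodes):
            node.index = i
        self.tips: list[Node] = [n for n in self.nodes if n.is_tip]
        self.internal_nodes: list[Node] = [n for n in self.nodes if n.children]

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(
        cls,
        source: str,
        tolerance: float = DEFAULT_TOLERANCE,
        require_binary: bool = True,
    ) -> "UltrametricTree":
        """Parse a Newick string with branch lengths into an age-annotated tree.

        Root-to-tip path lengths must agree to within ``tolerance``
        (relative to the mean depth); ages are then snapped so that every
        tip sits at exactly age 0, by measuring each node's age as the mean
        depth minus its own depth.
        """
        try:
            dtree = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            if "uplicate" in str(exc):
                raise TreeError(f"duplicate tip labels in Newick input: {exc}") from exc
            raise TreeError(f"could not parse Newick input: {exc}") from exc
        root = _from_dendropy(dtree)
        _ages_from_branch_lengths(root, tolerance)
        return cls(root, require_binary=require_binary)

    @classmethod
    def from_newick_file(
        cls,
        path,
        tolerance: float = DEFAULT_TOLERANCE,
        require_binary: bool = True,
    ) -> "UltrametricTree":
        with open(path) as fh:
            return cls.from_newick(
                fh.read(), tolerance=tolerance, require_binary=require_binary
            )

    # ------------------------------------------------------------------
    # views
    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips]

    @property
    def root_age(self) -> float:
        return self.root.age

    def internal_ages(self) -> np.ndarray:
        return np.array([n.age for n in self.internal_nodes], dtype=float)

    def mrca(self, labels: Sequence[str]) -> Node:
        want = set(labels)
        tipsets: dict[int, set[str]] = {}
        for node in self.nodes:
            if node.is_tip:
                tipsets[node.index] = {node.label}
            else:
                tipsets[node.index] = set().union(
                    *(tipsets[c.index] for c in node.children)
                )
            if want <= tipsets[node.index]:
                return node
        raise TreeError(f"labels {sorted(want)} not all present in tree")

    # ------------------------------------------------------------------
    # output
    # ------------------------------------------------------------------
    def to_newick(self, precision: int = 12) -> str:
        out = io.StringIO()
        _write_newick(self.root, out, precision)
        out.write(";")
        return out.getvalue()

    def write(self, path, precision: int = 12) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(precision=precision) + "\n")

    def copy(self) -> "UltrametricTree":
        return UltrametricTree(_copy_subtree(self.root), require_binary=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"UltrametricTree(n_tips={self.n_tips}, root_age={self.root_age:.6g})"


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Node:
    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label=label)
        node.age = dnode.edge.length if dnode.edge.length is not None else 0.0
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    return root


def _ages_from_branch_lengths(root: Node, tolerance: float) -> None:
    # On entry each node's ``age`` field temporarily holds its branch length.
    depths: dict[int, float] = {}
    order = list(root.postorder())
    for i, node in enumerate(order):
        node.index = i
    # root-to-node depth, preorder
    for node in reversed(order):
        if node.parent is None:
            depths[node.index] = 0.0
        else:
            depths[node.index] = depths[node.parent.index] + node.age
    tip_depths = np.array([depths[n.index] for n in order if n.is_tip])
    height = float(tip_depths.mean())
    if height > 0:
        spread = float(tip_depths.max() - tip_depths.min()) / height
        if spread > tolerance:
            raise NonUltrametricError(
                f"root-to-tip path lengths spread {spread:.3g} exceeds "
                f"tolerance {tolerance:.3g}; the tree is not ultrametric"
            )
    for node in order:
        node.age = 0.0 if node.is_tip else max(height - depths[node.index], 0.0)
        if node.parent is not None and not node.is_tip:
            # numerical guard: parent at least as old as child
            pass
    # enforce parent age >= child age after snapping
    for node in order:
        if node.parent is not None and node.age > node.parent.age:
            node.parent.age = node.age


def _collapse_unifurcations(root: Node) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        while len(node.children) == 1:
            only = node.children[0]
            node.label = only.label if only.is_tip else node.label
            node.age = only.age
            node.children = only.children
            for c in node.children:
                c.parent = node
        stack.extend(node.children)


def _write_newick(node: Node, out: io.StringIO, precision: int) -> None:
    if node.children:
        out.write("(")
        for i, child in enumerate(node.children):
            if i:
                out.write(",")
            _write_newick(child, out, precision)
        out.write(")")
    if node.label:
        out.write(_quote_label(node.label))
    if node.parent is not None:
        bl = node.parent.age - node.age
        out.write(f":{bl:.{precision}g}")


def _quote_label(label: str) -> str:
    if any(c in label for c in "(),:;[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _copy_subtree(node: Node) -> Node:
    new = Node(label=node.label, age=node.age)
    for child in node.children:
        new.add_child(_copy_subtree(child))
    return new


def read_ultrametric_tree(
    path, tolerance: float = DEFAULT_TOLERANCE
) -> UltrametricTree:
    """Read a Newick file and validate it as a binary ultrametric tree.

    ``tolerance`` bounds the allowed relative spread of root-to-tip path
    lengths; within tolerance, node ages are snapped so tips sit exactly at
    age 0.  Polytomies raise :class:`PolytomyError` directing the caller to
    :func:`resolve_polytomies`.
    """
    return UltrametricTree.from_newick_file(path, tolerance=tolerance)


def resolve_polytomies(
    tree_or_newick, eps: float = 1e-9, seed: int = 0
) -> UltrametricTree:
    """Arbitrarily resolve polytomies with short (``eps``-aged) extra nodes.

    Children of each polytomy are paired off left-to-right after a seeded
    deterministic shuffle, inserting internal nodes a hair older than the
    oldest member of each pair.  The output is binary and deterministic for
    a given seed.
    """
    if isinstance(tree_or_newick, str):
        dtree = dendropy.Tree.get(
            data=tree_or_newick, schema="newick", preserve_underscores=True
        )
        root = _from_dendropy(dtree)
        _ages_from_branch_lengths(root, tolerance=math.inf)
    else:
        root = _copy_subtree(tree_or_newick.root)
    rng = np.random.default_rng(seed)
    for node in list(root.postorder()):
        while len(node.children) > 2:
            kids = node.children
            order = rng.permutation(len(kids))
            a, b = kids[order[0]], kids[order[1]]
            joint = Node(age=max(a.age, b.age) + eps * max(node.age, 1.0))
            joint.age = min(joint.age, node.age)
            joint.add_child(a)
            joint.add_child(b)
            node.children = [kids[i] for i in range(len(kids)) if i not in
                             (order[0], order[1])]
            node.add_child(joint)
    return UltrametricTree(root)
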