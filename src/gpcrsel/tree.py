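"""Rooted gene-tree container for ortholog/paralog decisions.

A :class:`GeneTree` couples a plain rooted tree of :class:`TreeNode` objects
with per-leaf metadata (species, human flag, taxonomic lineage).  Newick
parsing is delegated to dendropy in :mod:`gpcrsel.io`; the tree structure
itself is kept in-package because outgroup rerooting, deterministic polytomy
resolution and the clade-walking rules downstream are the substance of the
analysis and need full control over node identity and child order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence


class TreeNode:
    """A node of a rooted tree; leaves carry a ``name``."""

    __slots__ = ("name", "children", "parent")

    def __init__(self, name: str | None = None,
                 children: Sequence["TreeNode"] = ()) -> None:
        self.name = name
        self.children: list[TreeNode] = list(children)
        self.parent: TreeNode | None = None
        for child in self.children:
            child.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def clade_id(self) -> str:
        """Stable, rotation-invariant identifier: sorted leaf names."""
        return "{" + ",".join(sorted(self.leaf_names())) + "}"

    def copy(self) -> "TreeNode":
        node = TreeNode(self.name)
        for child in self.children:
            node.add(child.copy())
        return node

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"TreeNode({self.name!r})"
        return f"TreeNode(n_leaves={len(self.leaf_names())})"


@dataclass(frozen=True)
class LeafInfo:
    """Metadata attached to one tree leaf."""

    seq_id: str
    species: str
    is_human: bool
    lineage: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.lineage:
            raise ValueError(f"leaf {self.seq_id!r}: lineage must be non-empty")


class GeneTree:
    """A rooted (possibly multifurcating at load time) gene tree.

    Parameters
    ----------
    root:
        Root node; leaf names must be unique and each must have an entry in
        ``leaf_info``.
    leaf_info:
        Mapping from leaf name (= seq_id) to :class:`LeafInfo`.
    target:
        Optional seq_id of the human target leaf.
    """

    def __init__(self, root: TreeNode, leaf_info: Mapping[str, LeafInfo],
                 target: str | None = None) -> None:
        names = root.leaf_names()
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf names: {dupes}")
        missing = [n for n in names if n not in leaf_info]
        if missing:
            raise ValueError(f"leaves without metadata: {missing}")
        if target is not None and target not in set(names):
            raise ValueError(f"target leaf {target!r} not in tree")
        self.root = root
        self.leaf_info = dict(leaf_info)
        self.target = target

    # -- access ---------------------------------------------------------
    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def find_leaf(self, name: str) -> TreeNode:
        for leaf in self.root.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(f"leaf {name!r} not in tree")

    def species_of(self, leaf_name: str) -> str:
        return self.leaf_info[leaf_name].species

    def copy(self) -> "GeneTree":
        return GeneTree(self.root.copy(), self.leaf_info, target=self.target)

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.root.postorder())

    def __len__(self) -> int:
        return len(self.leaf_names())


def _min_leaf_name(node: TreeNode) -> str:
    return min(node.leaf_names())


def resolve_polytomies(root: TreeNode) -> None:
    """Resolve every polytomy in place, deterministically.

    Children of a multifurcating node are ordered by their smallest leaf
    name and folded left-to-right into a ladder, so the result depends only
    on leaf names, never on input child order.
    """
    for child in list(root.children):
        resolve_polytomies(child)
    if len(root.children) > 2:
        ordered = sorted(root.children, key=_min_leaf_name)
        rest = ordered[1:]
        while len(rest) > 1:
            right = TreeNode(children=rest[-2:])
            rest = rest[:-2] + [right]
        root.children = []
        root.add(ordered[0])
        root.add(rest[0])
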