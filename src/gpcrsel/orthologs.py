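"""Ortholog-clade extraction from a rooted gene tree.

The gene tree is rooted on a designated outgroup leaf (by convention a
distant human paralog).  Starting from the human target leaf, the tree is
walked parent by parent toward the root; at each step the newly joined
sibling subtree is either absorbed into the ortholog set or excluded:

* a sibling containing a human leaf other than the target marks the gene
  duplication boundary — the walk stops before absorbing it;
* a sibling whose species set intersects the species already collected is
  excluded (re-seeing a species below the current level signals
  differential gene loss);
* otherwise all its leaves are included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .tree import GeneTree, TreeNode, resolve_polytomies


@dataclass
class OrthologSet:
    """Result of the clade walk from the human target."""

    kept_leaves: set[str]
    excluded_clades: list[tuple[str, str]] = field(default_factory=list)
    stop_node: str | None = None


def root_by_outgroup(tree: GeneTree, outgroup_leaf: str) -> GeneTree:
    """Root (a copy of) the tree so the outgroup leaf sits beside the root.

    The input may be arbitrarily rooted or effectively unrooted; polytomies
    are resolved deterministically by leaf-name order.  Rooting an already
    outgroup-rooted binary tree is the identity.
    """
    tree = tree.copy()
    try:
        leaf = tree.find_leaf(outgroup_leaf)
    except KeyError:
        raise ValueError(f"outgroup leaf {outgroup_leaf!r} not in tree") \
            from None
    root = tree.root
    already = (len(root.children) == 2
               and any(c is leaf for c in root.children))
    if not already:
        root = _reroot_above_leaf(leaf)
    resolve_polytomies(root)
    return GeneTree(root, tree.leaf_info, target=tree.target)


def _reroot_above_leaf(leaf: TreeNode) -> TreeNode:
    """Re-orient the tree around the edge above ``leaf``."""

    def flipped(node: TreeNode, coming_from: TreeNode) -> TreeNode:
        """Subtree seen from ``node`` when arriving via ``coming_from``."""
        parts = [c for c in node.children if c is not coming_from]
        if node.parent is not None:
            parts.append(flipped(node.parent, node))
        if len(parts) == 1:
            parts[0].parent = None
            return parts[0]
        return TreeNode(children=parts)

    parent = leaf.parent
    if parent is None:  # single-leaf tree
        return leaf
    leaf.parent = None
    return TreeNode(children=[leaf, flipped(parent, leaf)])


def extract_ortholog_clade(tree: GeneTree, target_leaf: str) -> OrthologSet:
    """Walk from the target leaf to the root collecting orthologs.

    The result is invariant to child-order rotations of the tree: decisions
    depend only on leaf names, species and the parent chain.
    """
    try:
        node = tree.find_leaf(target_leaf)
    except KeyError:
        raise ValueError(f"target leaf {target_leaf!r} not in tree") from None
    info = tree.leaf_info
    kept = {target_leaf}
    seen_species = {info[target_leaf].species}
    excluded: list[tuple[str, str]] = []
    stop_node: str | None = None
    while node.parent is not None:
        parent = node.parent
        siblings = [c for c in parent.children if c is not node]
        # With a binary tree there is one sibling; polytomies are handled
        # by treating each co-child as its own candidate subtree.
        stop = False
        for sib in sorted(siblings, key=lambda s: min(s.leaf_names())):
            names = sib.leaf_names()
            if any(info[n].is_human and n != target_leaf for n in names):
                stop_node = parent.clade_id()
                stop = True
                break
            species = {info[n].species for n in names}
            if species & seen_species:
                excluded.append((sib.clade_id(), "reseen_species"))
            else:
                kept.update(names)
                seen_species.update(species)
        if stop:
            break
        node = parent
    return OrthologSet(kept, excluded, stop_node)
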