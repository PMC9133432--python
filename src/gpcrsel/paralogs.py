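"""Detection and removal of diverged paralogous clades from a gene tree.

After gene duplication one paralogous clade tends to diverge more than its
sibling.  Each internal node whose two child clades share at least one
species is assessed: when both clades have at least three leaves, the
clades must first be evolutionarily comparable (two-sample t-test on
per-leaf counts of lineage ranks shared with the human lineage, p > 0.1),
and then a two-sample t-test on global alignment scores against the human
target decides removal of the significantly lower-scoring clade (p ≤ 0.1).
When both clades have fewer than three leaves, the lower-average clade is
removed outright; mixed sizes remove nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import ttest_ind

from .io import AlignedFamily
from .tree import GeneTree, TreeNode

DEFAULT_ALPHA = 0.1
GAP_OPEN = -11
GAP_EXTEND = -1


class TargetCladeRemovalError(RuntimeError):
    """The clade containing the human target scored lower — refusing to
    remove it silently; the input tree or scores need inspection."""


def _aligner(matrix_name: str = "BLOSUM62",
             gap_open: float = GAP_OPEN,
             gap_extend: float = GAP_EXTEND) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_alignment_score(seq_a: str, seq_b: str,
                           matrix_name: str = "BLOSUM62",
                           gap_open: float = GAP_OPEN,
                           gap_extend: float = GAP_EXTEND) -> int:
    """Needleman–Wunsch optimal global score with affine gaps.

    Sequences must be ungapped amino-acid strings.  A gap of length k costs
    ``|gap_open| + (k-1)·|gap_extend|``.  The score is symmetric in its
    arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    score = _aligner(matrix_name, gap_open, gap_extend).score(seq_a, seq_b)
    return int(score)


def alignment_score_table(family: AlignedFamily,
                          matrix_name: str = "BLOSUM62",
                          gap_open: float = GAP_OPEN,
                          gap_extend: float = GAP_EXTEND) -> dict[str, int]:
    """Global alignment score of every family member against the target.

    MSA gaps are stripped before alignment.
    """
    aligner = _aligner(matrix_name, gap_open, gap_extend)
    target = family.target.residues.replace("-", "")
    scores = {}
    for rec in family.sequences:
        seq = rec.residues.replace("-", "")
        if not seq:
            raise ValueError(f"sequence {rec.seq_id!r} is all gaps")
        scores[rec.seq_id] = int(aligner.score(target, seq))
    return scores


@dataclass
class InternodeVerdict:
    """Outcome of assessing one internal node's two child clades."""

    node_id: str
    species_overlap: bool
    comparable: bool
    p_score: float | None
    p_lineage: float | None
    removed_clade: str  # "left" | "right" | "none"
    rule_used: str      # "ttest" | "small_clade_average" | "none"
    removed_leaves: tuple[str, ...] = ()


def _safe_ttest(a: Sequence[float], b: Sequence[float],
                equal_var: bool) -> float:
    """Two-sided two-sample t-test p-value; NaN (zero variance in both
    samples) is read as no evidence of a difference (p = 1)."""
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = ttest_ind(np.asarray(a, float), np.asarray(b, float),
                      equal_var=equal_var).pvalue
    return 1.0 if np.isnan(p) else float(p)


def _shared_rank_counts(leaves: Sequence[str], tree: GeneTree,
                        human_lineage: frozenset[str]) -> list[int]:
    return [len(set(tree.leaf_info[name].lineage) & human_lineage)
            for name in leaves]


def assess_internode(node: TreeNode, tree: GeneTree,
                     scores: Mapping[str, float],
                     alpha: float = DEFAULT_ALPHA,
                     equal_var: bool = True,
                     active: set[str] | None = None) -> InternodeVerdict:
    """Assess one internal node with two child clades.

    ``active`` restricts the assessment to leaves not yet removed by an
    earlier verdict.  Missing scores or lineages raise an error naming the
    offending leaf.
    """
    if len(node.children) != 2:
        raise ValueError("internode must have exactly two child clades")
    node_id = node.clade_id()
    sides = []
    for child in node.children:
        names = child.leaf_names()
        if active is not None:
            names = [n for n in names if n in active]
        for name in names:
            if name not in scores:
                raise KeyError(f"no alignment score for leaf {name!r}")
            if name not in tree.leaf_info:
                raise KeyError(f"no lineage for leaf {name!r}")
        sides.append(names)
    left, right = sides
    none_verdict = InternodeVerdict(node_id, False, False, None, None,
                                    "none", "none")
    if not left or not right:
        return none_verdict
    sp_left = {tree.leaf_info[n].species for n in left}
    sp_right = {tree.leaf_info[n].species for n in right}
    if not sp_left & sp_right:
        return none_verdict
    score_l = [scores[n] for n in left]
    score_r = [scores[n] for n in right]
    if len(left) >= 3 and len(right) >= 3:
        human_lineage = frozenset(
            tree.leaf_info[tree.target].lineage if tree.target
            else max((tree.leaf_info[n].lineage for n in tree.leaf_info
                      if tree.leaf_info[n].is_human), default=(), key=len))
        p_lineage = _safe_ttest(
            _shared_rank_counts(left, tree, human_lineage),
            _shared_rank_counts(right, tree, human_lineage), equal_var)
        comparable = p_lineage > alpha
        if not comparable:
            return InternodeVerdict(node_id, True, False, None, p_lineage,
                                    "none", "none")
        p_score = _safe_ttest(score_l, score_r, equal_var)
        if p_score <= alpha:
            removed = "left" if np.mean(score_l) < np.mean(score_r) \
                else "right"
            leaves = tuple(left if removed == "left" else right)
            return InternodeVerdict(node_id, True, True, p_score, p_lineage,
                                    removed, "ttest", leaves)
        return InternodeVerdict(node_id, True, True, p_score, p_lineage,
                                "none", "none")
    if len(left) < 3 and len(right) < 3:
        mean_l, mean_r = np.mean(score_l), np.mean(score_r)
        if mean_l == mean_r:  # exact tie: nothing to prefer
            return InternodeVerdict(node_id, True, False, None, None,
                                    "none", "none")
        removed = "left" if mean_l < mean_r else "right"
        leaves = tuple(left if removed == "left" else right)
        return InternodeVerdict(node_id, True, False, None, None,
                                removed, "small_clade_average", leaves)
    # mixed sizes (one clade < 3, the other >= 3): no removal
    return InternodeVerdict(node_id, True, False, None, None, "none", "none")


def trim_paralogs(tree: GeneTree, msa: AlignedFamily | None = None,
                  scores: Mapping[str, float] | None = None,
                  alpha: float = DEFAULT_ALPHA,
                  equal_var: bool = True,
                  ) -> tuple[set[str], list[InternodeVerdict]]:
    """Remove diverged paralogous clades from the tree's leaf set.

    Internodes are assessed leaves-up (post-order); leaves of a removed
    clade are excluded from every later assessment.  Scores come from
    ``scores`` or are computed from ``msa`` (gap-stripped global alignment
    against the target).  Raises :class:`TargetCladeRemovalError` if a
    removal would take out the clade containing the human target.
    """
    if scores is None:
        if msa is None:
            raise ValueError("need either msa or a precomputed score table")
        scores = alignment_score_table(msa)
    leaf_names = set(tree.leaf_names())
    missing = sorted(leaf_names - set(scores))
    if missing:
        raise KeyError(f"no alignment score for leaves {missing}")
    target = tree.target
    active = set(leaf_names)
    verdicts: list[InternodeVerdict] = []
    for node in tree.root.postorder():
        if node.is_leaf or len(node.children) != 2:
            continue
        verdict = assess_internode(node, tree, scores, alpha=alpha,
                                   equal_var=equal_var, active=active)
        verdicts.append(verdict)
        if verdict.removed_clade != "none":
            if target is not None and target in verdict.removed_leaves:
                raise TargetCladeRemovalError(
                    f"internode {verdict.node_id}: the clade containing the "
                    f"target {target!r} scored lower; refusing to remove it")
            active -= set(verdict.removed_leaves)
    return active, verdicts
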