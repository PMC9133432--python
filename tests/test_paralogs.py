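"""Global alignment scoring and diverged-paralog clade removal."""

import numpy as np
import pytest

from gpcrsel import (TargetCladeRemovalError, alignment_score_table,
                     assess_internode, global_alignment_score, trim_paralogs)
from gpcrsel.conservation import blosum
from gpcrsel.io import AMINO_ACIDS
from gpcrsel.synthetic import simulate_paralog_tree

from conftest import family_from_rows, gene_tree_from_nested

B62 = blosum("BLOSUM62")


class TestGlobalAlignmentScore:
    def test_single_residue_matrix_lookup(self):
        assert global_alignment_score("A", "A") == int(B62["A", "A"]) == 4

    def test_self_alignment_sums_diagonal(self):
        seq = "ACDEFGHIKL"
        expected = sum(int(B62[a, a]) for a in seq)
        assert global_alignment_score(seq, seq) == expected

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = "".join(np.random.default_rng(rng.integers(2**31))
                        .choice(list(AMINO_ACIDS), 30))
            b = "".join(np.random.default_rng(rng.integers(2**31))
                        .choice(list(AMINO_ACIDS), 25))
            assert global_alignment_score(a, b) == \
                global_alignment_score(b, a)

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            global_alignment_score("", "ACD")

    def test_score_table_strips_msa_gaps(self):
        fam = family_from_rows([("T_HUMAN", "HUMAN", "AC-DE"),
                                ("O_MOUSE", "MOUSE", "ACFDE")])
        table = alignment_score_table(fam)
        assert set(table) == {"T_HUMAN", "O_MOUSE"}
        assert table["T_HUMAN"] == global_alignment_score("ACDE", "ACDE")


def two_clade_tree(left, right, species, lineages=None, target=None):
    return gene_tree_from_nested((tuple(left), tuple(right)), species,
                                 lineages=lineages, target=target)


SHARED_LINEAGE = {"MOUSE": ("EUK", "MAM", "MOUSE"),
                  "RAT": ("EUK", "MAM", "RAT"),
                  "FROG": ("EUK", "AMPH", "FROG"),
                  "HUMAN": ("EUK", "MAM", "HOMO")}


class TestAssessInternode:
    def make(self, left_scores, right_scores, shared_species=True):
        left = [f"L{i}_{'MOUSE' if shared_species else 'PIG'}"
                if i == 0 else f"L{i}_SP{i:03d}"
                for i in range(len(left_scores))]
        right = [f"R{i}_MOUSE" if i == 0 else f"R{i}_SQ{i:03d}"
                 for i in range(len(right_scores))]
        species = {n: n.split("_", 1)[1] for n in left + right}
        lineages = {sp: ("EUK", "MAM", sp) for sp in species.values()}
        lineages["HOMO"] = ("EUK", "MAM", "HOMO")
        tree = two_clade_tree(left, right, species, lineages=lineages)
        scores = {n: s for n, s in zip(left, left_scores)}
        scores.update({n: s for n, s in zip(right, right_scores)})
        return tree, scores

    def test_disjoint_species_no_action(self):
        tree, scores = self.make([100, 101, 102], [60, 61, 62],
                                 shared_species=False)
        verdict = assess_internode(tree.root, tree, scores)
        assert not verdict.species_overlap
        assert verdict.removed_clade == "none"

    def test_clearly_lower_clade_removed_by_ttest(self):
        tree, scores = self.make([100, 101, 102], [60, 61, 62])
        verdict = assess_internode(tree.root, tree, scores)
        assert verdict.species_overlap and verdict.comparable
        assert verdict.rule_used == "ttest"
        assert verdict.p_score <= 0.1
        assert verdict.removed_clade == "right"
        assert set(verdict.removed_leaves) == \
            {n for n in scores if n.startswith("R")}

    def test_small_clades_use_average_rule(self):
        tree, scores = self.make([80, 80], [70, 70])
        verdict = assess_internode(tree.root, tree, scores)
        assert verdict.rule_used == "small_clade_average"
        assert verdict.removed_clade == "right"

    def test_mixed_sizes_no_removal(self):
        tree, scores = self.make([100, 101, 102], [60, 61])
        verdict = assess_internode(tree.root, tree, scores)
        assert verdict.removed_clade == "none"
        assert verdict.rule_used == "none"

    def test_incomparable_lineages_block_removal(self):
        # the right clade shares far fewer taxonomic ranks with the human
        # lineage, so the comparability test fires and blocks removal even
        # though its alignment scores are clearly lower
        left = ["T_HUMAN", "L1_MOUSE", "L2_SP001"]
        right = ["R0_MOUSE", "R1_SQ001", "R2_SQ002"]
        species = {n: n.split("_", 1)[1] for n in left + right}
        lineages = {"HUMAN": ("EUK", "MAM", "VERT", "HOMO"),
                    "MOUSE": ("EUK", "MAM", "VERT", "MOUSE"),
                    "SP001": ("EUK", "MAM", "SP001"),
                    "SQ001": ("OTHER",),
                    "SQ002": ("EUK", "SQ002")}
        tree = gene_tree_from_nested((tuple(left), tuple(right)), species,
                                     lineages=lineages, target="T_HUMAN")
        from gpcrsel.tree import LeafInfo
        # the shared-species mouse on the right also carries an alien lineage
        old = tree.leaf_info["R0_MOUSE"]
        tree.leaf_info["R0_MOUSE"] = LeafInfo(old.seq_id, old.species,
                                              old.is_human, ("OTHER",))
        scores = {n: 100 + i for i, n in enumerate(left)}
        scores.update({n: 60 + i for i, n in enumerate(right)})
        verdict = assess_internode(tree.root, tree, scores)
        assert verdict.species_overlap
        assert not verdict.comparable
        assert verdict.p_lineage <= 0.1
        assert verdict.removed_clade == "none"

    def test_missing_score_names_leaf(self):
        tree, scores = self.make([100, 101, 102], [60, 61, 62])
        del scores["L1_SP001"]
        with pytest.raises(KeyError, match="L1_SP001"):
            assess_internode(tree.root, tree, scores)


class TestTrimParalogs:
    def test_planted_diverged_clade_removed(self):
        tree, fam, truth = simulate_paralog_tree(
            n_ortho=6, n_paralog=6, divergence=1.0, seed=3)
        kept, verdicts = trim_paralogs(tree, msa=fam)
        assert kept == set(truth["ortholog_leaves"])
        assert any(v.removed_clade != "none" for v in verdicts)

    def test_no_species_overlap_keeps_everything(self):
        tree, fam, _ = simulate_paralog_tree(
            n_ortho=4, n_paralog=4, divergence=1.0, shared_species=0, seed=1)
        kept, verdicts = trim_paralogs(tree, msa=fam)
        assert kept == set(tree.leaf_names())
        assert all(v.removed_clade == "none" for v in verdicts)

    def test_target_clade_removal_raises_diagnostic(self):
        left = ["T_HUMAN", "L1_MOUSE", "L2_SP001"]
        right = ["R0_MOUSE", "R1_SQ001", "R2_SQ002"]
        species = {n: n.split("_", 1)[1] for n in left + right}
        lineages = {sp: ("EUK", "MAM", sp) for sp in species.values()}
        tree = gene_tree_from_nested((tuple(left), tuple(right)), species,
                                     lineages=lineages, target="T_HUMAN")
        scores = {"T_HUMAN": 60, "L1_MOUSE": 61, "L2_SP001": 62,
                  "R0_MOUSE": 100, "R1_SQ001": 101, "R2_SQ002": 102}
        with pytest.raises(TargetCladeRemovalError):
            trim_paralogs(tree, scores=scores)

    def test_verdicts_stable_under_leaf_relabeling(self):
        tree, fam, _ = simulate_paralog_tree(
            n_ortho=5, n_paralog=5, divergence=0.8, seed=11)
        kept_a, verdicts_a = trim_paralogs(tree, msa=fam)
        # relabel leaves preserving scores/species/lineages
        scores = alignment_score_table(fam)
        mapping = {n: f"Z{i}_{tree.leaf_info[n].species}" if n != "FAM_HUMAN"
                   else n for i, n in enumerate(sorted(tree.leaf_names()))}
        from gpcrsel.tree import GeneTree, LeafInfo

        def relabel(node):
            if node.is_leaf:
                node.name = mapping[node.name]
            for c in node.children:
                relabel(c)

        root = tree.root.copy()
        relabel(root)
        info = {mapping[n]: LeafInfo(mapping[n], li.species, li.is_human,
                                     li.lineage)
                for n, li in tree.leaf_info.items()}
        tree2 = GeneTree(root, info, target="FAM_HUMAN")
        scores2 = {mapping[n]: s for n, s in scores.items()}
        kept_b, verdicts_b = trim_paralogs(tree2, scores=scores2)
        assert {mapping[n] for n in kept_a} == kept_b
        assert [v.removed_clade for v in verdicts_a] == \
            [v.removed_clade for v in verdicts_b]
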