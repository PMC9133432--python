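"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from gpcrsel.io import AlignedFamily, Residue, SequenceRecord, StructureModel
from gpcrsel.tree import GeneTree, LeafInfo, TreeNode


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive and separate from the package)
# ---------------------------------------------------------------------------

def brute_force_conservation(column, matrix, gap_max=Fraction(1, 2)):
    """Conservation of one column by direct recounting, exact arithmetic.

    Returns None for gap-flagged columns; mirrors the scoring rules with an
    independent double loop over residues and the substitution matrix.
    """
    n = len(column)
    gaps = sum(1 for r in column if r == "-")
    if Fraction(gaps, n) > gap_max:
        return None
    nongap = [r for r in column if r != "-"]
    standard = [r for r in nongap if r != "X"]
    if not standard:
        return Fraction(0)
    best = None
    for r in sorted(set(standard)):
        c = standard.count(r)
        if best is None or c > standard.count(best):
            best = r
    total = 0
    for r in standard:
        if r == best or int(matrix[best, r]) > 2:
            total += 1
    return Fraction(total, len(nongap))


def brute_force_rrcs(structure, d_min=3.23, d_max=4.63, near=5):
    """RRCS by an explicit quadruple loop over residues and atoms."""
    backbone = {"N", "CA", "C", "O"}
    scores = {}
    res = structure.residues
    for i in range(len(res)):
        for j in range(i + 1, len(res)):
            ri, rj = res[i], res[j]
            adjacent = ri.chain == rj.chain and abs(ri.index - rj.index) < near
            total = 0.0
            for ai, (na, xa) in enumerate(zip(ri.atom_names, ri.coords)):
                if adjacent and na in backbone:
                    continue
                for nb, xb in zip(rj.atom_names, rj.coords):
                    if adjacent and nb in backbone:
                        continue
                    d = float(np.sqrt(((xa - xb) ** 2).sum()))
                    if d <= d_min:
                        total += 1.0
                    elif d < d_max:
                        total += (d_max - d) / (d_max - d_min)
            if total > 0.0:
                key = tuple(sorted((ri.label, rj.label)))
                scores[key] = total
    return scores


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def family_from_rows(rows, family_id="FAM", target_index=0):
    """AlignedFamily from (seq_id, species, residues) triples."""
    return AlignedFamily(family_id,
                         [SequenceRecord(*row) for row in rows],
                         target_index)


def single_atom_structure(positions, indices=None, structure_id="TOY",
                          state="active", atom_name="CA"):
    """Structure with one carbon pseudo-atom per residue at given positions."""
    residues = []
    for k, xyz in enumerate(positions):
        idx = indices[k] if indices is not None else k + 1
        residues.append(Residue("A", idx, "ALA", f"{(idx - 1) % 7 + 1}x{idx:02d}",
                                [atom_name], ["C"],
                                np.array([xyz], dtype=float)))
    return StructureModel(structure_id, residues, state)


def gene_tree_from_nested(nested, species_of, human=("HUMAN",), target=None,
                          lineages=None):
    """GeneTree from nested tuples of leaf names, e.g. (("a","b"),("c","d"))."""

    def build(x):
        if isinstance(x, str):
            return TreeNode(x)
        return TreeNode(children=[build(c) for c in x])

    root = build(nested)
    info = {}
    for name in root.leaf_names():
        sp = species_of[name]
        lineage = tuple(lineages[sp]) if lineages and sp in lineages else (sp,)
        info[name] = LeafInfo(name, sp, sp in human, lineage)
    return GeneTree(root, info, target=target)


@pytest.fixture
def toy_family():
    """4-row, 6-column family with a conserved, a split and a gappy column."""
    return family_from_rows([
        ("FAM_HUMAN", "HUMAN", "LLDAG-"),
        ("FAM_MOUSE", "MOUSE", "LLDAG-"),
        ("FAM_RAT", "RAT", "LIDSG-"),
        ("FAM_FROG", "FROG", "LIKS--"),
    ])
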