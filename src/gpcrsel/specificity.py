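"""Classification of shared alignment columns between two receptor families.

Each column is labeled by comparing the conservation profiles of the two
families:

* ``gap`` — either side is gap-flagged (> 50% gaps);
* ``consensus`` — both sides conserved above the consensus threshold (90%)
  with similar modal residues (BLOSUM80 > 1);
* ``specific_A`` / ``specific_B`` / ``specific_both`` — a side is conserved
  above the specificity threshold (90%) and the modal residues are
  dissimilar (BLOSUM80 < 2), or, when the modals are similar, the other
  side's conservation falls below the lower threshold (70%);
* ``none`` — everything else.

All threshold comparisons are strict.  On the integer matrix the consensus
similarity cutoff (> 1) and the specificity dissimilarity cutoff (< 2)
partition cleanly: a score of exactly 2 is "similar" in both rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .conservation import ColumnProfile, blosum
from .io import AlignedFamily

SPEC_THR = 0.9
CONS_THR = 0.9
LOWER_THR = 0.7

LABELS = ("specific_A", "specific_B", "specific_both",
          "consensus", "none", "gap")


@dataclass(frozen=True)
class PositionLabel:
    column: int
    label: str
    conservation_A: float | None
    conservation_B: float | None
    modal_A: str | None
    modal_B: str | None
    modal_similarity_score: int | None

    def mirrored(self) -> "PositionLabel":
        """The same verdict with the roles of A and B swapped."""
        swap = {"specific_A": "specific_B", "specific_B": "specific_A"}
        return PositionLabel(self.column, swap.get(self.label, self.label),
                             self.conservation_B, self.conservation_A,
                             self.modal_B, self.modal_A,
                             self.modal_similarity_score)


def classify_position(col_a: ColumnProfile, col_b: ColumnProfile,
                      spec_thr: float = SPEC_THR,
                      cons_thr: float = CONS_THR,
                      lower_thr: float = LOWER_THR,
                      matrix_name: str = "BLOSUM80",
                      column: int | None = None) -> PositionLabel:
    """Label one shared column from the two families' profiles."""
    col = column if column is not None else col_a.column
    if col_a.is_gap or col_b.is_gap:
        return PositionLabel(col, "gap", col_a.conservation,
                             col_b.conservation, col_a.most_frequent,
                             col_b.most_frequent, None)
    ca, cb = col_a.conservation, col_b.conservation
    ma, mb = col_a.most_frequent, col_b.most_frequent
    if ma is None or mb is None:
        return PositionLabel(col, "none", ca, cb, ma, mb, None)
    sim = int(blosum(matrix_name)[ma, mb])
    if ca > cons_thr and cb > cons_thr and sim > 1:
        label = "consensus"
    elif sim < 2:
        a_spec = ca > spec_thr
        b_spec = cb > spec_thr
        label = {(True, True): "specific_both", (True, False): "specific_A",
                 (False, True): "specific_B", (False, False): "none"}[
                     (a_spec, b_spec)]
    else:
        a_spec = ca > spec_thr and cb < lower_thr
        b_spec = cb > spec_thr and ca < lower_thr
        label = "specific_A" if a_spec else (
            "specific_B" if b_spec else "none")
    return PositionLabel(col, label, ca, cb, ma, mb, sim)


def compare_families(family_a: AlignedFamily, family_b: AlignedFamily,
                     shared_column_map: Sequence[tuple[int, int]] | None = None,
                     spec_thr: float = SPEC_THR,
                     cons_thr: float = CONS_THR,
                     lower_thr: float = LOWER_THR,
                     matrix_name: str = "BLOSUM80",
                     allowed_min_exclusive: int = 2,
                     gap_max: float = 0.5) -> list[PositionLabel]:
    """Label every shared column between two families.

    ``shared_column_map`` pairs 1-based columns of A with columns of B; by
    default the identity map is used, which requires equal alignment
    lengths (the "one combined MSA split in two" case).  The reported
    ``column`` of each label is the A-side column.
    """
    from .conservation import column_conservation

    if shared_column_map is None:
        if family_a.length != family_b.length:
            raise ValueError(
                "families have different lengths "
                f"({family_a.length} vs {family_b.length}); supply an "
                "explicit shared_column_map")
        shared_column_map = [(c, c) for c in range(1, family_a.length + 1)]
    labels = []
    for col_a, col_b in shared_column_map:
        if not 1 <= col_a <= family_a.length:
            raise ValueError(f"column {col_a} unmapped in family A")
        if not 1 <= col_b <= family_b.length:
            raise ValueError(f"column {col_b} unmapped in family B")
        pa = column_conservation(family_a.column(col_a), column=col_a,
                                 matrix_name=matrix_name,
                                 allowed_min_exclusive=allowed_min_exclusive,
                                 gap_max=gap_max)
        pb = column_conservation(family_b.column(col_b), column=col_b,
                                 matrix_name=matrix_name,
                                 allowed_min_exclusive=allowed_min_exclusive,
                                 gap_max=gap_max)
        labels.append(classify_position(pa, pb, spec_thr=spec_thr,
                                        cons_thr=cons_thr,
                                        lower_thr=lower_thr,
                                        matrix_name=matrix_name,
                                        column=col_a))
    return labels
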