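"""Per-column conservation scoring with BLOSUM80 substitution tolerance.

The conservation of an alignment column is the fraction of non-gap rows
carrying either the most frequent residue or an "allowed" substitute — a
residue whose BLOSUM80 score against the modal residue is strictly greater
than 2 (half-bit integer matrix).  Columns that are more than 50% gaps are
flagged as gap positions and receive no score.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Sequence

from Bio.Align import substitution_matrices

from .io import AMINO_ACIDS, GAP, AlignedFamily

#: Strict lower bound for an allowed substitution ("higher than 2").
ALLOWED_MIN_EXCLUSIVE = 2
#: Columns with gap fraction above this are gap positions.
GAP_MAX = 0.5


@functools.lru_cache(maxsize=4)
def blosum(name: str = "BLOSUM80"):
    """Standard half-bit integer substitution matrix (cached)."""
    return substitution_matrices.load(name)


def similarity(a: str, b: str, matrix_name: str = "BLOSUM80") -> int:
    return int(blosum(matrix_name)[a, b])


@dataclass(frozen=True)
class ColumnProfile:
    """Residue composition and conservation of one alignment column.

    ``conservation`` is ``None`` for gap-flagged columns; ``most_frequent``
    is ``None`` when no standard residue is present among the non-gap rows.
    """

    column: int
    counts: dict[str, int]
    gap_fraction: float
    most_frequent: str | None
    conservation: float | None

    @property
    def is_gap(self) -> bool:
        return self.conservation is None


def column_conservation(column_residues: Sequence[str],
                        column: int = 1,
                        matrix_name: str = "BLOSUM80",
                        allowed_min_exclusive: int = ALLOWED_MIN_EXCLUSIVE,
                        gap_max: float = GAP_MAX) -> ColumnProfile:
    """Score one column of residues (gaps as ``-``, unknowns as ``X``).

    The modal residue is the most frequent standard amino acid; ties break
    alphabetically.  ``X`` counts in the non-gap denominator but can never
    be modal nor allowed.
    """
    if not column_residues:
        raise ValueError("empty column")
    counts: dict[str, int] = {}
    n_gaps = 0
    for res in column_residues:
        if res == GAP:
            n_gaps += 1
            continue
        if res != "X" and res not in AMINO_ACIDS:
            raise ValueError(f"unknown residue symbol {res!r}")
        counts[res] = counts.get(res, 0) + 1
    n = len(column_residues)
    gap_fraction = n_gaps / n
    if gap_fraction > gap_max:
        return ColumnProfile(column, counts, gap_fraction, None, None)
    nongap = n - n_gaps
    standard = {r: c for r, c in counts.items() if r != "X"}
    if not standard:
        return ColumnProfile(column, counts, gap_fraction, None, 0.0)
    modal = min(standard, key=lambda r: (-standard[r], r))
    matrix = blosum(matrix_name)
    allowed = sum(c for r, c in standard.items()
                  if r != modal
                  and int(matrix[modal, r]) > allowed_min_exclusive)
    conservation = (standard[modal] + allowed) / nongap
    return ColumnProfile(column, counts, gap_fraction, modal, conservation)


def msa_conservation_profile(family: AlignedFamily,
                             matrix_name: str = "BLOSUM80",
                             allowed_min_exclusive: int = ALLOWED_MIN_EXCLUSIVE,
                             gap_max: float = GAP_MAX) -> list[ColumnProfile]:
    """One :class:`ColumnProfile` per column, in column order."""
    return [column_conservation(family.column(col), column=col,
                                matrix_name=matrix_name,
                                allowed_min_exclusive=allowed_min_exclusive,
                                gap_max=gap_max)
            for col in range(1, family.length + 1)]
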