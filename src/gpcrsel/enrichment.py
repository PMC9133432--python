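"""Two-step identification of specifically conserved residues per Gα subtype.

Receptors are split into couplers and non-couplers for a Gα subtype.  The
*specific* approach counts, for every column, how often the column is
specific for the coupler side across all n·m coupler-vs-non-coupler family
comparisons, and rejects any column that is ever specific in the
n·(n−1) within-coupler comparisons (no inside variation allowed).  The
*sensitive* approach instead compares a single pooled alignment of all
couplers and their orthologs against each non-coupler family, tolerating
minor variation within the coupler group.  The pooled residue set merges
both approaches with the consensus positions shared by all families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import AlignedFamily
from .specificity import compare_families

_COUPLER_SPECIFIC = ("specific_A", "specific_both")


@dataclass(frozen=True)
class PositionHit:
    column: int
    coupler_frequency: float
    within_coupler_frequency: float
    label_source: str
    generic_number: str | None = None


@dataclass
class EnrichmentResult:
    g_protein: str
    approach: str  # specific | sensitive | merged
    positions: list[PositionHit] = field(default_factory=list)

    def columns(self) -> list[int]:
        return sorted(hit.column for hit in self.positions)


def _specific_counts(family_a: AlignedFamily, others: Sequence[AlignedFamily],
                     **kwargs) -> dict[int, int]:
    """Per-column count of 'specific for A' labels of A against each other."""
    counts: dict[int, int] = {}
    for other in others:
        for lab in compare_families(family_a, other, **kwargs):
            if lab.label in _COUPLER_SPECIFIC:
                counts[lab.column] = counts.get(lab.column, 0) + 1
    return counts


def specific_approach(couplers: Sequence[AlignedFamily],
                      noncouplers: Sequence[AlignedFamily],
                      g_protein: str = "",
                      columns: Iterable[int] | None = None,
                      **compare_kwargs) -> EnrichmentResult:
    """Strict enrichment: cross-group specificity with zero inside variation.

    A column is reported iff it is specific for at least one coupler in the
    coupler-vs-non-coupler comparisons (frequency over n·m ordered pairs)
    and never specific in the within-coupler comparisons (frequency over
    n·(n−1) ordered pairs must be exactly zero).
    """
    n, m = len(couplers), len(noncouplers)
    if n < 2:
        raise ValueError("specific approach needs at least 2 coupler "
                         "receptors (within-coupler frequency undefined)")
    if m < 1:
        raise ValueError("specific approach needs at least 1 non-coupler")
    if columns is not None:
        cols = sorted(set(columns))
        compare_kwargs = dict(compare_kwargs,
                              shared_column_map=[(c, c) for c in cols])
    cross: dict[int, int] = {}
    within: dict[int, int] = {}
    for i, coupler in enumerate(couplers):
        for col, c in _specific_counts(coupler, noncouplers,
                                       **compare_kwargs).items():
            cross[col] = cross.get(col, 0) + c
        other_couplers = [c for k, c in enumerate(couplers) if k != i]
        for col, c in _specific_counts(coupler, other_couplers,
                                       **compare_kwargs).items():
            within[col] = within.get(col, 0) + c
    positions = []
    for col in sorted(cross):
        freq = cross[col] / (n * m)
        wfreq = within.get(col, 0) / (n * (n - 1))
        if freq > 0 and wfreq == 0:
            positions.append(PositionHit(col, freq, wfreq, "specific"))
    return EnrichmentResult(g_protein, "specific", positions)


def pool_families(families: Sequence[AlignedFamily],
                  family_id: str = "pooled") -> AlignedFamily:
    """Stack equal-length families into one comprehensive alignment."""
    if not families:
        raise ValueError("no families to pool")
    sequences = [rec for fam in families for rec in fam.sequences]
    # target of the first family anchors the pooled alignment
    target_id = families[0].target.seq_id
    index = [rec.seq_id for rec in sequences].index(target_id)
    return AlignedFamily(family_id, sequences, index)


def sensitive_approach(combined: AlignedFamily,
                       noncouplers: Sequence[AlignedFamily],
                       g_protein: str = "",
                       min_frequency: float = 0.0,
                       columns: Iterable[int] | None = None,
                       **compare_kwargs) -> EnrichmentResult:
    """Pooled-alignment enrichment tolerating variation within couplers.

    ``combined`` is one alignment of every coupler receptor with its
    orthologs; it is compared against each non-coupler family and a column
    is reported when its specific-for-couplers frequency over the m
    comparisons is strictly greater than ``min_frequency``.
    """
    if combined.n_sequences == 0:
        raise ValueError("empty combined coupler family")
    if not noncouplers:
        raise ValueError("sensitive approach needs at least 1 non-coupler")
    if columns is not None:
        cols = sorted(set(columns))
        compare_kwargs = dict(compare_kwargs,
                              shared_column_map=[(c, c) for c in cols])
    m = len(noncouplers)
    counts = _specific_counts(combined, noncouplers, **compare_kwargs)
    positions = [PositionHit(col, counts[col] / m, 0.0, "sensitive")
                 for col in sorted(counts)
                 if counts[col] / m > min_frequency]
    return EnrichmentResult(g_protein, "sensitive", positions)


@dataclass(frozen=True)
class PooledPosition:
    column: int
    sources: tuple[str, ...]
    generic_number: str | None = None


def merge_residue_sets(specific: EnrichmentResult | None,
                       sensitive: EnrichmentResult | None,
                       consensus_positions: Iterable[int] = (),
                       generic_map=None) -> list[PooledPosition]:
    """Union of specific, sensitive and consensus positions with provenance.

    ``generic_map`` (column → generic number) optionally annotates the
    pooled positions; a conflicting annotation between inputs is an error.
    """
    tags: dict[int, set[str]] = {}
    gnums: dict[int, str] = {}

    def absorb(result: EnrichmentResult | None) -> None:
        if result is None:
            return
        for hit in result.positions:
            tags.setdefault(hit.column, set()).add(result.approach)
            if hit.generic_number is not None:
                prev = gnums.setdefault(hit.column, hit.generic_number)
                if prev != hit.generic_number:
                    raise ValueError(
                        f"column {hit.column}: conflicting generic numbers "
                        f"{prev!r} vs {hit.generic_number!r}")

    absorb(specific)
    absorb(sensitive)
    for col in consensus_positions:
        tags.setdefault(col, set()).add("consensus")
    pooled = []
    for col in sorted(tags):
        gn = gnums.get(col)
        if gn is None and generic_map is not None:
            gn = generic_map.get(col)
        pooled.append(PooledPosition(col, tuple(sorted(tags[col])), gn))
    return pooled


def consensus_positions(families: Sequence[AlignedFamily],
                        min_fraction: float = 1.0,
                        **compare_kwargs) -> set[int]:
    """Columns labeled consensus in (a fraction of) all pairwise comparisons.

    With the default ``min_fraction=1.0`` a column must be consensus in
    every unordered family pair, mirroring positions conserved across all
    compared receptor families.
    """
    if len(families) < 2:
        raise ValueError("need at least two families")
    n_pairs = 0
    counts: dict[int, int] = {}
    for i in range(len(families)):
        for j in range(i + 1, len(families)):
            n_pairs += 1
            for lab in compare_families(families[i], families[j],
                                        **compare_kwargs):
                if lab.label == "consensus":
                    counts[lab.column] = counts.get(lab.column, 0) + 1
    return {col for col, c in counts.items() if c / n_pairs >= min_fraction}
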