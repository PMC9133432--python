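"""Residue–residue contact scores (RRCS) and activation networks.

RRCS quantifies the contact strength between two residues as a sum over
their heavy-atom pairs of a piecewise-linear function of interatomic
distance: 1 below ``d_min``, 0 above ``d_max`` and a linear ramp between.
ΔRRCS (active − inactive) measures the contact change upon receptor
activation; edges shared by most active/inactive structure pairs form the
common activation network, and group-wise t-tests on ΔRRCS yield
Gα-specific (ΔΔRRCS) networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import ttest_ind

from .io import StructureModel

#: Contact distance bounds (Angstrom) and sequence-adjacency cutoff of the
#: RRCS method; backbone atoms are excluded for sequence-adjacent pairs.
D_MIN = 3.23
D_MAX = 4.63
NEAR_SEQ_CUTOFF = 5
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

Pair = tuple[str, str]


def _label_sort_key(label: str):
    """Numeric-aware key so '2x41' < '10x50' and fallback labels sort last."""
    if "x" in label:
        left, _, right = label.partition("x")
        if left.isdigit() and right.isdigit():
            return (0, int(left), int(right), label)
    return (1, 0, 0, label)


def canonical_pair(a: str, b: str) -> Pair:
    if a == b:
        raise ValueError(f"self-edge {a!r}")
    return (a, b) if _label_sort_key(a) <= _label_sort_key(b) else (b, a)


@dataclass
class ContactNetwork:
    """Residue-pair → value map keyed by canonical label pairs.

    ``edges`` values are RRCS, ΔRRCS or effect sizes depending on ``kind``;
    ``pvalues`` is populated by the statistical network builders.
    """

    edges: dict[Pair, float] = field(default_factory=dict)
    pvalues: dict[Pair, float] | None = None
    provenance: str = ""
    kind: str = "rrcs"

    def __post_init__(self) -> None:
        canon = {}
        for (a, b), v in self.edges.items():
            key = canonical_pair(a, b)
            if not np.isfinite(v):
                raise ValueError(f"non-finite value on edge {key}")
            canon[key] = float(v)
        self.edges = canon
        if self.pvalues is not None:
            self.pvalues = {canonical_pair(a, b): float(p)
                            for (a, b), p in self.pvalues.items()}

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: Pair) -> bool:
        return canonical_pair(*pair) in self.edges

    def get(self, pair: Pair, default: float = 0.0) -> float:
        return self.edges.get(canonical_pair(*pair), default)

    def sorted_edges(self) -> list[tuple[Pair, float]]:
        return sorted(self.edges.items())


# ---------------------------------------------------------------------------
# RRCS
# ---------------------------------------------------------------------------

def _atom_mask(residue, exclude_backbone: bool) -> np.ndarray:
    if not exclude_backbone:
        return np.ones(len(residue.atom_names), dtype=bool)
    return np.array([name not in BACKBONE_ATOMS
                     for name in residue.atom_names], dtype=bool)


def compute_rrcs(structure: StructureModel,
                 d_min: float = D_MIN, d_max: float = D_MAX,
                 near_seq_cutoff: int = NEAR_SEQ_CUTOFF) -> ContactNetwork:
    """RRCS for every residue pair of a heavy-atom structure.

    For residue pairs on the same chain with sequence separation below
    ``near_seq_cutoff``, backbone atoms (N, CA, C, O) are excluded so that
    trivially adjacent backbone contacts do not register.  Pairs with zero
    score are omitted.
    """
    residues = [r for r in structure.residues if len(r.atom_names) > 0]
    skipped = [r for r in structure.residues if len(r.atom_names) == 0]
    for r in skipped:  # pragma: no cover - guarded earlier in practice
        warnings.warn(f"{structure.structure_id}: residue {r.chain}:{r.index} "
                      "has no heavy atoms; skipped")
    ramp = d_max - d_min
    edges: dict[Pair, float] = {}
    for i in range(len(residues)):
        ri = residues[i]
        for j in range(i + 1, len(residues)):
            rj = residues[j]
            adjacent = (ri.chain == rj.chain
                        and abs(ri.index - rj.index) < near_seq_cutoff)
            mi = _atom_mask(ri, adjacent)
            mj = _atom_mask(rj, adjacent)
            if not mi.any() or not mj.any():
                continue
            d = cdist(ri.coords[mi], rj.coords[mj])
            score = float(np.clip((d_max - d) / ramp, 0.0, 1.0).sum())
            if score > 0.0:
                edges[canonical_pair(ri.label, rj.label)] = score
    return ContactNetwork(edges, provenance=structure.structure_id,
                          kind="rrcs")


def delta_rrcs(active: ContactNetwork, inactive: ContactNetwork,
               pool: Iterable[str] | None = None,
               delta_min: float = 0.2,
               pool_mode: str = "both") -> ContactNetwork:
    """ΔRRCS = RRCS(active) − RRCS(inactive), filtered.

    A pair absent from one side contributes score 0 there.  Edges with
    ``|Δ| <= delta_min`` are dropped, as are edges whose endpoints fall
    outside ``pool`` (``pool_mode``: ``"both"`` requires both endpoints in
    the pool, ``"either"`` at least one).  ``pool=None`` disables the pool
    restriction; an explicitly empty pool is an error.
    """
    if pool is not None:
        pool = set(pool)
        if not pool:
            raise ValueError("empty residue pool")
    if pool_mode not in ("both", "either"):
        raise ValueError(f"unknown pool_mode {pool_mode!r}")
    edges: dict[Pair, float] = {}
    for pair in set(active.edges) | set(inactive.edges):
        delta = active.edges.get(pair, 0.0) - inactive.edges.get(pair, 0.0)
        if abs(delta) <= delta_min:
            continue
        if pool is not None:
            inside = [p in pool for p in pair]
            if pool_mode == "both" and not all(inside):
                continue
            if pool_mode == "either" and not any(inside):
                continue
        edges[pair] = delta
    prov = f"{active.provenance}|{inactive.provenance}"
    return ContactNetwork(edges, provenance=prov, kind="delta")


def common_network(networks: Sequence[ContactNetwork],
                   min_count: int = 36) -> ContactNetwork:
    """Edges present (post-filter) in at least ``min_count`` networks.

    Edge values are occurrence counts; the sign of the underlying ΔRRCS is
    deliberately ignored, so gains and losses both count as "observed".
    """
    if not networks:
        raise ValueError("need at least one network")
    if min_count > len(networks):
        warnings.warn(f"min_count={min_count} exceeds the number of networks "
                      f"({len(networks)}); result is empty")
    counts: dict[Pair, int] = {}
    for net in networks:
        for pair in net.edges:
            counts[pair] = counts.get(pair, 0) + 1
    edges = {pair: float(c) for pair, c in counts.items() if c >= min_count}
    return ContactNetwork(edges, kind="common",
                          provenance=f"{len(networks)} networks")


# ---------------------------------------------------------------------------
# Pairing plans and group-specific networks
# ---------------------------------------------------------------------------

@dataclass
class PairingPlan:
    """Per-receptor active/inactive structure ids and their pairings.

    ``explicit_pairs`` overrides the per-receptor Cartesian product with a
    hand-specified list of (receptor, active_id, inactive_id) triples, for
    datasets whose published pair count does not match the enumeration.
    """

    assignments: dict[str, tuple[list[str], list[str]]] = field(
        default_factory=dict)
    explicit_pairs: list[tuple[str, str, str]] | None = None

    def pairs(self) -> list[tuple[str, str, str]]:
        if self.explicit_pairs is not None:
            return list(self.explicit_pairs)
        out = []
        for receptor in sorted(self.assignments):
            actives, inactives = self.assignments[receptor]
            for a in actives:
                for i in inactives:
                    out.append((receptor, a, i))
        return out

    @property
    def receptors(self) -> list[str]:
        if self.explicit_pairs is not None:
            return sorted({r for r, _, _ in self.explicit_pairs})
        return sorted(self.assignments)


def _network_structure_ids(net: ContactNetwork) -> set[str]:
    return {tok for tok in net.provenance.split("|") if tok}


def gprotein_specific_network(
        networks_by_receptor: Mapping[str, Sequence[ContactNetwork]],
        group: Iterable[str],
        alpha: float = 0.01,
        exclude: Iterable[str] = (),
        equal_var: bool = True) -> ContactNetwork:
    """ΔΔRRCS network: edges whose ΔRRCS differs between coupler group and rest.

    For every edge seen in any ΔRRCS network, the group sample collects the
    per-pair ΔRRCS values of the receptors in ``group`` and the rest sample
    those of all other receptors; a network lacking the edge contributes 0.
    Edges with a two-sample t-test p ≤ alpha are retained, valued by the
    group-minus-rest mean ΔRRCS (sign = direction of the specific change).
    ``exclude`` removes receptors or individual structure ids from both
    samples (supports leave-one-receptor-out re-tests).
    """
    group = set(group)
    exclude = set(exclude)
    unknown = group - set(networks_by_receptor)
    if unknown:
        raise ValueError(f"group receptors without networks: {sorted(unknown)}")
    group_nets: list[ContactNetwork] = []
    rest_nets: list[ContactNetwork] = []
    for receptor in sorted(networks_by_receptor):
        if receptor in exclude:
            continue
        for net in networks_by_receptor[receptor]:
            if _network_structure_ids(net) & exclude:
                continue
            (group_nets if receptor in group else rest_nets).append(net)
    universe: set[Pair] = set()
    for net in group_nets + rest_nets:
        universe.update(net.edges)
    edges: dict[Pair, float] = {}
    pvalues: dict[Pair, float] = {}
    for pair in sorted(universe):
        a = np.array([net.edges.get(pair, 0.0) for net in group_nets])
        b = np.array([net.edges.get(pair, 0.0) for net in rest_nets])
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"edge {pair}: sample too small, skipped")
            continue
        with np.errstate(invalid="ignore", divide="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = ttest_ind(a, b, equal_var=equal_var).pvalue
        if np.isnan(p):
            # both samples constant: equal means are no evidence, distinct
            # means are an infinitely sharp separation
            if a.mean() == b.mean():
                continue
            p = 0.0
        if p <= alpha:
            edges[pair] = float(a.mean() - b.mean())
            pvalues[pair] = float(p)
    return ContactNetwork(edges, pvalues=pvalues, kind="ddrrcs",
                          provenance=f"group={','.join(sorted(group))}")
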