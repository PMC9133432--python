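"""MD-trajectory contact statistics and activation-state classification.

Frames are subsampled on a fixed time grid (0–500 ns every 50 ns by
default, 11 frames per replicate), per-frame RRCS values feed a two-sided
two-sample t-test between wild-type and mutant trajectories, and the
significant contact changes of several mutants are intersected to obtain
the changes common to all of them.  Conformations are classified with the
GPCRdb activation distance d(2x41–6x38) − d(3x44–7x52) on Cα atoms:
active above 7.15 Å, inactive below 2 Å, intermediate between (strict
inequalities, so the exact boundary values are intermediate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import ttest_ind

from .io import StructureModel
from .rrcs import ContactNetwork, Pair, compute_rrcs

ACTIVE_MIN_ANGSTROM = 7.15
INACTIVE_MAX_ANGSTROM = 2.0
DEFAULT_MARKERS = ("2x41", "6x38", "3x44", "7x52")


@dataclass(frozen=True)
class Frame:
    time_ns: float
    model: StructureModel


@dataclass
class TrajectorySample:
    """Ordered frames per replicate for one (genotype, state) condition."""

    genotype: str
    state: str
    replicates: list[list[Frame]] = field(default_factory=list)

    def __post_init__(self) -> None:
        roster = None
        for rep in self.replicates:
            times = [f.time_ns for f in rep]
            if times != sorted(times):
                raise ValueError("frames must be time-ordered within a "
                                 "replicate")
            for frame in rep:
                r = frame.model.roster()
                if roster is None:
                    roster = r
                elif r != roster:
                    raise ValueError("frame rosters differ across frames")

    @property
    def n_frames(self) -> int:
        return sum(len(rep) for rep in self.replicates)

    def all_frames(self) -> list[Frame]:
        return [f for rep in self.replicates for f in rep]


def sample_frames(frames: Sequence[Frame], start_ns: float = 0.0,
                  end_ns: float = 500.0,
                  step_ns: float = 50.0) -> list[Frame]:
    """Nearest frame to each grid time start, start+step, …, end (inclusive).

    With ``step`` dividing ``end − start`` the result has
    ``(end − start)/step + 1`` frames.  A trajectory not reaching ``end_ns``
    is an error.
    """
    if not frames:
        raise ValueError("no frames")
    if step_ns <= 0:
        raise ValueError("step_ns must be positive")
    times = np.array([f.time_ns for f in frames])
    if times.max() < end_ns:
        raise ValueError(f"trajectory ends at {times.max()} ns, before "
                         f"end_ns={end_ns} ns")
    n_steps = int(round((end_ns - start_ns) / step_ns))
    targets = [start_ns + k * step_ns for k in range(n_steps + 1)]
    if targets[-1] > end_ns + 1e-9:
        targets = [t for t in targets if t <= end_ns + 1e-9]
    picked = []
    for t in targets:
        picked.append(frames[int(np.argmin(np.abs(times - t)))])
    return picked


def per_frame_rrcs(frames: Sequence[Frame | StructureModel],
                   **rrcs_kwargs) -> list[ContactNetwork]:
    models = [f.model if isinstance(f, Frame) else f for f in frames]
    return [compute_rrcs(m, **rrcs_kwargs) for m in models]


def contact_change_test(wt_frames: Sequence[Frame | StructureModel],
                        mut_frames: Sequence[Frame | StructureModel],
                        alpha: float = 0.05,
                        equal_var: bool = True,
                        **rrcs_kwargs) -> ContactNetwork:
    """Two-sided t-test per residue pair on per-frame RRCS values.

    Edges with p below ``alpha`` are retained, valued by the mutant-minus-WT
    mean RRCS (positive = contact gained in the mutant).  Pairs that are
    constant zero on both sides are skipped.
    """
    if len(wt_frames) < 2 or len(mut_frames) < 2:
        raise ValueError("need at least 2 frames per side")
    wt_nets = per_frame_rrcs(wt_frames, **rrcs_kwargs)
    mut_nets = per_frame_rrcs(mut_frames, **rrcs_kwargs)
    universe: set[Pair] = set()
    for net in wt_nets + mut_nets:
        universe.update(net.edges)
    edges: dict[Pair, float] = {}
    pvalues: dict[Pair, float] = {}
    for pair in sorted(universe):
        a = np.array([net.edges.get(pair, 0.0) for net in mut_nets])
        b = np.array([net.edges.get(pair, 0.0) for net in wt_nets])
        if not a.any() and not b.any():
            continue
        with np.errstate(invalid="ignore", divide="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = ttest_ind(a, b, equal_var=equal_var).pvalue
        if np.isnan(p):
            # both sides constant: a persistent all-or-nothing contact
            # difference is maximally significant, identical constants are
            # no evidence at all
            if a.mean() == b.mean():
                continue
            p = 0.0
        if p < alpha:
            edges[pair] = float(a.mean() - b.mean())
            pvalues[pair] = float(p)
    return ContactNetwork(edges, pvalues=pvalues, kind="contact-change")


def intersect_common_changes(
        per_mutant_networks: Sequence[ContactNetwork]) -> ContactNetwork:
    """Edges significant in every mutant's contact-change network.

    The retained value is the mean effect across mutants; the per-mutant
    effect signs are preserved in ``pvalues``-style metadata only through
    the individual input networks.
    """
    if len(per_mutant_networks) < 2:
        raise ValueError("need at least two networks to intersect")
    shared = set(per_mutant_networks[0].edges)
    for net in per_mutant_networks[1:]:
        shared &= set(net.edges)
    edges = {pair: float(np.mean([net.edges[pair]
                                  for net in per_mutant_networks]))
             for pair in shared}
    return ContactNetwork(edges, kind="common-change",
                          provenance=f"{len(per_mutant_networks)} mutants")


@dataclass(frozen=True)
class StateCall:
    """GPCRdb activation-distance verdict for one frame."""

    frame_id: str
    gpcrdb_distance: float
    call: str  # active | inactive | intermediate


def classify_state(model: StructureModel,
                   markers: Sequence[str] = DEFAULT_MARKERS,
                   active_min: float = ACTIVE_MIN_ANGSTROM,
                   inactive_max: float = INACTIVE_MAX_ANGSTROM) -> StateCall:
    """Classify a conformation by the GPCRdb two-distance metric.

    ``markers`` are four generic numbers (m1, m2, m3, m4); the metric is
    d(m1, m2) − d(m3, m4) on Cα coordinates.
    """
    if len(markers) != 4:
        raise ValueError("need exactly four marker generic numbers")
    coords = []
    for gn in markers:
        res = model.residue_by_generic(gn)  # raises KeyError when missing
        coords.append(res.atom_coord("CA"))
    d_outer = float(np.linalg.norm(coords[0] - coords[1]))
    d_inner = float(np.linalg.norm(coords[2] - coords[3]))
    metric = d_outer - d_inner
    if metric > active_min:
        call = "active"
    elif metric < inactive_max:
        call = "inactive"
    else:
        call = "intermediate"
    return StateCall(model.structure_id, metric, call)
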