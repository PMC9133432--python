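"""Synthetic fixtures with known ground truth for every pipeline stage.

These generators replace the sequence-database and structure-bank inputs
of a real analysis with small, fully controlled objects:

* ortholog families with planted conserved / specifically-conserved /
  variable columns (i.i.d. per-column substitution noise — no phylogenetic
  correlation, which is sufficient to exercise the scoring arithmetic);
* coupler/non-coupler cohorts with planted determinant columns;
* gene trees containing one extra-diverged paralogous clade with
  overlapping species content;
* toy structure pairs with planted residue-contact gains and losses
  (one Cα pseudo-atom per residue plus side-chain pseudo-atoms carrying
  the planted contacts);
* multi-replicate trajectories as noisy convex combinations of two
  coordinate templates.

Every generator is a pure function of its spec and seed, and returns the
planted ground truth alongside the data; the ``save_*`` helpers write a
``truth.json`` sidecar next to each fixture so recovery can be scored
without re-deriving it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import (AMINO_ACIDS, AlignedFamily, Residue, SequenceRecord,
                 StructureModel, write_fasta_msa, write_multimodel_pdb,
                 write_pdb)
from .tree import GeneTree, LeafInfo, TreeNode
from .trajectory import Frame, TrajectorySample

HUMAN_LINEAGE = ("EUKARYOTA", "METAZOA", "CHORDATA", "MAMMALIA",
                 "PRIMATES", "HOMO")


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _species_name(i: int) -> str:
    return f"SP{i:03d}"


# ---------------------------------------------------------------------------
# Families and cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one synthetic ortholog family."""

    n_orthologs: int = 20
    length: int = 60
    conserved_columns: frozenset[int] = frozenset()
    specific_columns: frozenset[int] = frozenset()
    variable_columns: frozenset[int] = frozenset()
    substitution_noise: float = 0.0
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        sets = (self.conserved_columns, self.specific_columns,
                self.variable_columns)
        union = set().union(*sets)
        if sum(len(s) for s in sets) != len(union):
            raise ValueError("column sets must be disjoint")
        if union and (min(union) < 1 or max(union) > self.length):
            raise ValueError(f"column indices must lie in 1..{self.length}")
        for name in ("substitution_noise", "gap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_orthologs < 1 or self.length < 1:
            raise ValueError("n_orthologs and length must be positive")


def _mutate(residue: str, rng: np.random.Generator) -> str:
    alternatives = [a for a in AMINO_ACIDS if a != residue]
    return alternatives[rng.integers(len(alternatives))]


def simulate_family(spec: FamilySpec, family_id: str = "FAM",
                    residue_overrides: Mapping[int, str] | None = None,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[AlignedFamily, dict]:
    """Generate one aligned ortholog family from a spec.

    Columns not listed in any planted set behave like conserved background.
    ``residue_overrides`` pins the planted residue of given columns (used
    by the cohort generator to share coordinates across families).
    """
    rng = rng if rng is not None else _rng(spec.seed)
    planted: dict[int, str] = {}
    for col in range(1, spec.length + 1):
        if residue_overrides and col in residue_overrides:
            planted[col] = residue_overrides[col]
        else:
            planted[col] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    rows = []
    species = ["HUMAN"] + [_species_name(i)
                           for i in range(1, spec.n_orthologs)]
    for row, sp in enumerate(species):
        chars = []
        for col in range(1, spec.length + 1):
            if col in spec.variable_columns:
                res = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
            else:
                res = planted[col]
                if spec.substitution_noise > 0 and \
                        rng.random() < spec.substitution_noise:
                    res = _mutate(res, rng)
            if spec.gap_rate > 0 and rng.random() < spec.gap_rate:
                res = "-"
            chars.append(res)
        rows.append(SequenceRecord(f"{family_id}_{sp}", sp, "".join(chars)))
    family = AlignedFamily(family_id, rows, target_index=0)
    truth = {
        "family_id": family_id,
        "conserved_columns": sorted(spec.conserved_columns),
        "specific_columns": sorted(spec.specific_columns),
        "variable_columns": sorted(spec.variable_columns),
        "column_residues": {str(c): planted[c] for c in sorted(planted)
                            if c not in spec.variable_columns},
    }
    return family, truth


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a coupler/non-coupler cohort sharing one coordinate system.

    At every planted determinant column the coupler families carry one
    shared residue while each non-coupler family carries a residue that is
    BLOSUM80-dissimilar to it (score ≤ 1); all other non-variable columns
    share a common background residue across the whole cohort, so they can
    only come out consensus, never specific.
    """

    n_couplers: int = 3
    n_noncouplers: int = 3
    n_orthologs: int = 12
    length: int = 60
    planted_determinants: frozenset[int] = frozenset({10, 25, 40})
    variable_fraction: float = 0.2
    substitution_noise: float = 0.0
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_determinants and (
                min(self.planted_determinants) < 1
                or max(self.planted_determinants) > self.length):
            raise ValueError("planted determinants must lie within the "
                             "alignment coordinates")
        if self.n_couplers < 2:
            raise ValueError("need at least two couplers")
        if self.n_noncouplers < 1:
            raise ValueError("need at least one non-coupler")


def _dissimilar_residue(reference: str, rng: np.random.Generator) -> str:
    """A residue with BLOSUM80 score ≤ 1 against ``reference``."""
    from .conservation import similarity
    candidates = [a for a in AMINO_ACIDS
                  if a != reference and similarity(reference, a) <= 1]
    return candidates[rng.integers(len(candidates))]


def simulate_cohort(spec: CohortSpec) -> tuple[
        list[AlignedFamily], list[AlignedFamily], dict]:
    """Generate coupler and non-coupler families with planted determinants."""
    rng = _rng(spec.seed)
    background = {col: AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
                  for col in range(1, spec.length + 1)}
    n_var = int(round(spec.variable_fraction
                      * (spec.length - len(spec.planted_determinants))))
    candidates = [c for c in range(1, spec.length + 1)
                  if c not in spec.planted_determinants]
    variable = frozenset(
        rng.choice(candidates, size=min(n_var, len(candidates)),
                   replace=False).tolist()) if n_var else frozenset()
    coupler_residue = {col: background[col]
                       for col in spec.planted_determinants}
    noncoupler_residue = {col: _dissimilar_residue(coupler_residue[col], rng)
                          for col in spec.planted_determinants}

    def build(name: str, determinant_residues: Mapping[int, str]
              ) -> AlignedFamily:
        fam_spec = FamilySpec(
            n_orthologs=spec.n_orthologs, length=spec.length,
            variable_columns=variable,
            substitution_noise=spec.substitution_noise,
            gap_rate=spec.gap_rate, seed=0)
        overrides = dict(background)
        overrides.update(determinant_residues)
        family, _ = simulate_family(fam_spec, family_id=name,
                                    residue_overrides=overrides, rng=rng)
        return family

    couplers = [build(f"CPL{i}", coupler_residue)
                for i in range(1, spec.n_couplers + 1)]
    noncouplers = [build(f"NCP{i}", noncoupler_residue)
                   for i in range(1, spec.n_noncouplers + 1)]
    truth = {
        "determinant_columns": sorted(spec.planted_determinants),
        "coupler_residues": {str(c): r for c, r in coupler_residue.items()},
        "noncoupler_residues": {str(c): r
                                for c, r in noncoupler_residue.items()},
        "variable_columns": sorted(variable),
    }
    return couplers, noncouplers, truth


def sensitive_recovery_fixture(length: int = 30, determinant: int = 15,
                               ) -> tuple[list[AlignedFamily],
                                          list[AlignedFamily], dict]:
    """Deterministic cohort whose determinant the specific approach misses.

    Two large coupler families carry L at the determinant; a third, small
    coupler family (2 orthologs) carries V — similar enough that the pooled
    coupler alignment stays above 90% L-conserved, yet dissimilar under the
    pairwise BLOSUM80 rule (score L/V = 1 < 2), so the within-coupler
    comparison labels the column specific and the specific approach rejects
    it.  The sensitive approach, working on the pooled alignment, recovers
    it against the non-couplers (which carry D).
    """
    rng = _rng(0)
    background = {col: AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
                  for col in range(1, length + 1)}

    def build(name: str, n: int, det_res: str) -> AlignedFamily:
        overrides = dict(background)
        overrides[determinant] = det_res
        fam_spec = FamilySpec(n_orthologs=n, length=length, seed=0)
        family, _ = simulate_family(fam_spec, family_id=name,
                                    residue_overrides=overrides, rng=rng)
        return family

    couplers = [build("CPL1", 12, "L"), build("CPL2", 12, "L"),
                build("CPL3", 2, "V")]
    noncouplers = [build("NCP1", 12, "D"), build("NCP2", 12, "D")]
    truth = {"determinant_columns": [determinant],
             "coupler_residues": {str(determinant): "L"},
             "minority_coupler": "CPL3", "minority_residue": "V",
             "noncoupler_residues": {str(determinant): "D"}}
    return couplers, noncouplers, truth


# ---------------------------------------------------------------------------
# Paralog trees
# ---------------------------------------------------------------------------

def _ladder(leaves: Sequence[TreeNode]) -> TreeNode:
    node = leaves[0]
    for leaf in leaves[1:]:
        node = TreeNode(children=[node, leaf])
    return node


def simulate_paralog_tree(n_ortho: int = 6, n_paralog: int = 6,
                          divergence: float = 0.0,
                          shared_species: int | None = None,
                          seed: int = 0,
                          length: int = 120,
                          base_rate: float = 0.05,
                          lineage_shared_ranks: int = 4,
                          ) -> tuple[GeneTree, AlignedFamily, dict]:
    """A gene tree with two sibling clades, one evolved with extra divergence.

    The ortholog clade holds the human target plus ``n_ortho − 1`` species;
    the paralog clade holds ``n_paralog`` sequences whose species overlap
    the ortholog clade in ``shared_species`` organisms (default: all of
    them) and whose sequences carry an extra per-site substitution
    probability ``1 − exp(−divergence)`` on top of the shared base rate, so
    their global alignment scores to the target are stochastically lower.
    All species share ``lineage_shared_ranks`` taxonomic ranks with the
    human lineage, keeping the clades evolutionarily comparable.
    """
    if n_ortho < 3 or n_paralog < 3:
        raise ValueError("need at least 3 leaves per clade")
    if not 0.0 <= base_rate < 1.0 or divergence < 0.0:
        raise ValueError("invalid base_rate or divergence")
    rng = _rng(seed)
    ancestor = [AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
                for _ in range(length)]

    def evolve(p: float) -> str:
        return "".join(_mutate(res, rng) if rng.random() < p else res
                       for res in ancestor)

    ortho_species = ["HUMAN"] + [_species_name(i) for i in range(1, n_ortho)]
    if shared_species is None:
        shared_species = n_paralog
    pool = [s for s in ortho_species if s != "HUMAN"]
    n_shared = min(shared_species, len(pool), n_paralog)
    para_species = pool[:n_shared] + [
        _species_name(100 + i) for i in range(n_paralog - n_shared)]
    p_extra = 1.0 - float(np.exp(-divergence))
    p_para = 1.0 - (1.0 - base_rate) * (1.0 - p_extra)

    records, leaf_info = [], {}
    ortho_leaves, para_leaves = [], []
    for i, sp in enumerate(ortho_species):
        seq_id = "FAM_HUMAN" if sp == "HUMAN" else f"FAMO{i}_{sp}"
        records.append(SequenceRecord(seq_id, sp, evolve(base_rate)))
        lineage = HUMAN_LINEAGE if sp == "HUMAN" else \
            HUMAN_LINEAGE[:lineage_shared_ranks] + (f"CLADE_{sp}", sp)
        leaf_info[seq_id] = LeafInfo(seq_id, sp, sp == "HUMAN", lineage)
        ortho_leaves.append(seq_id)
    for i, sp in enumerate(para_species):
        seq_id = f"FAMP{i}_{sp}"
        records.append(SequenceRecord(seq_id, sp, evolve(p_para)))
        lineage = HUMAN_LINEAGE[:lineage_shared_ranks] + (f"CLADE_{sp}", sp)
        leaf_info[seq_id] = LeafInfo(seq_id, sp, False, lineage)
        para_leaves.append(seq_id)

    root = TreeNode(children=[
        _ladder([TreeNode(n) for n in ortho_leaves]),
        _ladder([TreeNode(n) for n in para_leaves])])
    tree = GeneTree(root, leaf_info, target="FAM_HUMAN")
    family = AlignedFamily("FAM", records, target_index=0)
    truth = {"ortholog_leaves": ortho_leaves, "paralog_leaves": para_leaves,
             "divergence": divergence, "shared_species": n_shared}
    return tree, family, truth


# ---------------------------------------------------------------------------
# Structure pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructurePairSpec:
    """Recipe for a toy active/inactive structure pair.

    Planted gain pairs are in contact (side-chain pseudo-atoms 3.0 Å apart,
    inside the RRCS saturation distance) in the active state and far apart
    in the inactive state; loss pairs are reversed; every other residue
    pair is kept beyond contact range on an 8 Å grid, up to Gaussian
    ``jitter_sd``.  ``displacement`` is the side-chain travel between the
    two states and must stay positive.

    Contact sites of distinct pairs are offset sideways from each other,
    but when two planted pairs geometrically cross on the grid their
    side-chain atoms can still register additional (real) contacts; with a
    single planted pair the realised contact set equals the planted one
    exactly.
    """

    n_residues: int = 20
    planted_gain_pairs: tuple[tuple[int, int], ...] = ()
    planted_loss_pairs: tuple[tuple[int, int], ...] = ()
    displacement: float = 4.0
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.displacement <= 0:
            raise ValueError("displacement must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        pairs = list(self.planted_gain_pairs) + list(self.planted_loss_pairs)
        seen = set()
        for i, j in pairs:
            if i == j:
                raise ValueError(f"self-pair ({i}, {j})")
            if not (1 <= i <= self.n_residues and 1 <= j <= self.n_residues):
                raise ValueError(f"pair ({i}, {j}) outside 1.."
                                 f"{self.n_residues}")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"pair ({i}, {j}) planted twice")
            seen.add(key)


_SIDECHAIN_NAMES = ("CB", "CG", "CD", "CE", "CZ")


def generic_number_for(index: int) -> str:
    """Deterministic GPCRdb-style label for toy residue ``index``."""
    return f"{(index - 1) % 7 + 1}x{index:02d}"


def simulate_structure_pair(spec: StructurePairSpec) -> tuple[
        StructureModel, StructureModel, dict]:
    """Build an (active, inactive) toy structure pair with planted contacts."""
    rng = _rng(spec.seed)
    m = int(np.ceil(spec.n_residues ** (1 / 3)))
    grid = 8.0
    ca = np.array([[8.0 * (k % m), 8.0 * ((k // m) % m), 8.0 * (k // m ** 2)]
                   for k in range(spec.n_residues)])

    per_residue_pairs: dict[int, int] = {}
    contacts: dict[str, list[tuple[tuple[int, int], bool]]] = {
        "active": [], "inactive": []}
    for pair in spec.planted_gain_pairs:
        contacts["active"].append((pair, True))
        contacts["inactive"].append((pair, False))
    for pair in spec.planted_loss_pairs:
        contacts["active"].append((pair, False))
        contacts["inactive"].append((pair, True))
    for i, j in list(spec.planted_gain_pairs) + list(spec.planted_loss_pairs):
        for r in (i, j):
            per_residue_pairs[r] = per_residue_pairs.get(r, 0) + 1
            if per_residue_pairs[r] > len(_SIDECHAIN_NAMES):
                raise ValueError(
                    f"residue {r} participates in more than "
                    f"{len(_SIDECHAIN_NAMES)} planted pairs; use smaller "
                    "pair sets")

    def build(state: str) -> StructureModel:
        atom_names = {k: ["CA"] for k in range(1, spec.n_residues + 1)}
        atom_xyz = {k: [ca[k - 1]] for k in range(1, spec.n_residues + 1)}
        used = {k: 0 for k in range(1, spec.n_residues + 1)}
        for pair_rank, ((i, j), in_contact) in enumerate(contacts[state]):
            pi, pj = ca[i - 1], ca[j - 1]
            axis = (pj - pi) / np.linalg.norm(pj - pi)
            perp = np.cross(axis, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(axis, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            # offset each pair's contact site sideways so two planted pairs
            # whose residue midpoints coincide on the grid cannot touch
            mid = (pi + pj) / 2 + 1.4 * pair_rank * perp
            for r, p, sign in ((i, pi, 1.0), (j, pj, -1.0)):
                if in_contact:
                    pos = mid - sign * 1.5 * axis
                else:
                    pos = p + 1.0 * perp
                atom_names[r].append(_SIDECHAIN_NAMES[used[r]])
                atom_xyz[r].append(pos)
                used[r] += 1
        residues = []
        for k in range(1, spec.n_residues + 1):
            coords = np.array(atom_xyz[k], dtype=float)
            if spec.jitter_sd > 0:
                coords = coords + rng.normal(0.0, spec.jitter_sd,
                                             coords.shape)
            residues.append(Residue("A", k, "ALA", generic_number_for(k),
                                    list(atom_names[k]),
                                    ["C"] * len(atom_names[k]), coords))
        return StructureModel(f"TOY_{state}", residues, state)

    active = build("active")
    inactive = build("inactive")
    truth = {
        "gain_pairs": [[generic_number_for(i), generic_number_for(j)]
                       for i, j in spec.planted_gain_pairs],
        "loss_pairs": [[generic_number_for(i), generic_number_for(j)]
                       for i, j in spec.planted_loss_pairs],
    }
    return active, inactive, truth


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def activation_state_templates(n_filler: int = 4) -> tuple[
        StructureModel, StructureModel]:
    """Marker-bearing templates with GPCRdb metric 10.0 Å / 0.5 Å.

    The four activation markers (2x41, 6x38, 3x44, 7x52) are placed so the
    two-distance metric is far above the 7.15 Å active cutoff in the active
    template and far below the 2 Å inactive cutoff in the inactive one.
    """
    markers = {  # generic number -> (index, active xyz, inactive xyz)
        "2x41": (41, (0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
        "6x38": (138, (20.0, 0.0, 0.0), (10.5, 0.0, 0.0)),
        "3x44": (64, (0.0, 20.0, 0.0), (0.0, 20.0, 0.0)),
        "7x52": (152, (10.0, 20.0, 0.0), (10.0, 20.0, 0.0)),
    }

    def build(state: str, which: int) -> StructureModel:
        residues = []
        for gn, (idx, a_xyz, i_xyz) in sorted(markers.items(),
                                              key=lambda kv: kv[1][0]):
            xyz = a_xyz if which == 0 else i_xyz
            residues.append(Residue("A", idx, "ALA", gn, ["CA"], ["C"],
                                    np.array([xyz], dtype=float)))
        for k in range(n_filler):
            residues.append(Residue("A", 200 + 10 * k, "GLY", None,
                                    ["CA"], ["C"],
                                    np.array([[50.0 + 10.0 * k, 50.0, 0.0]])))
        return StructureModel(f"TEMPLATE_{state}", residues, state)

    return build("active", 0), build("inactive", 1)


def simulate_trajectory(template_active: StructureModel,
                        template_inactive: StructureModel,
                        n_replicates: int = 7, n_frames: int = 11,
                        mixing: float | Sequence[float] = 1.0,
                        noise_sd: float = 0.0, seed: int = 0,
                        total_ns: float = 500.0,
                        genotype: str = "WT",
                        state: str = "active") -> TrajectorySample:
    """Frames as convex template combinations plus Gaussian coordinate noise.

    ``mixing`` is the per-frame weight of the active template (scalar or a
    length-``n_frames`` path); frame timestamps are uniform over
    ``[0, total_ns]``.  Templates must share their residue/atom roster.
    """
    if template_active.roster() != template_inactive.roster():
        raise ValueError("templates do not share a residue/atom roster")
    if n_replicates < 1 or n_frames < 1:
        raise ValueError("need at least one replicate and one frame")
    weights = np.full(n_frames, float(mixing)) if np.isscalar(mixing) \
        else np.asarray(mixing, dtype=float)
    if weights.shape != (n_frames,):
        raise ValueError(f"mixing path must have length {n_frames}")
    if np.any((weights < 0) | (weights > 1)):
        raise ValueError("mixing weights must lie in [0, 1]")
    rng = _rng(seed)
    act = template_active.stacked_coords()
    inact = template_inactive.stacked_coords()
    times = np.linspace(0.0, total_ns, n_frames) if n_frames > 1 \
        else np.array([0.0])
    replicates = []
    for rep in range(n_replicates):
        frames = []
        for k in range(n_frames):
            coords = weights[k] * act + (1.0 - weights[k]) * inact
            if noise_sd > 0:
                coords = coords + rng.normal(0.0, noise_sd, coords.shape)
            model = template_active.with_coords(
                coords, structure_id=f"{genotype}_{state}_r{rep}_f{k}",
                state=state)
            frames.append(Frame(float(times[k]), model))
        replicates.append(frames)
    return TrajectorySample(genotype, state, replicates)


# ---------------------------------------------------------------------------
# Sidecar writers
# ---------------------------------------------------------------------------

def _write_truth(truth: dict, out_dir: Path) -> None:
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2,
                                                   sort_keys=True) + "\n")


def save_family(family: AlignedFamily, truth: dict,
                out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta_msa(family, out_dir / f"{family.family_id}.fasta")
    _write_truth(truth, out_dir)


def save_structure_pair(active: StructureModel, inactive: StructureModel,
                        truth: dict, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_pdb(active, out_dir / "active.pdb")
    write_pdb(inactive, out_dir / "inactive.pdb")
    _write_truth(truth, out_dir)


def save_trajectory(sample: TrajectorySample, truth: dict,
                    out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, rep in enumerate(sample.replicates):
        write_multimodel_pdb([f.model for f in rep],
                             out_dir / f"{sample.genotype}_{sample.state}_"
                                       f"rep{i}.pdb")
    _write_truth(truth, out_dir)
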