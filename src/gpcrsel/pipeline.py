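"""End-to-end orchestration of the evolution and structure stages.

:class:`PipelineConfig` aggregates every tunable threshold of the pipeline
with the published defaults; :func:`run_evolution_stage` chains ortholog
selection → paralog trimming → conservation → enrichment for a cohort of
receptor families, and :func:`run_structure_stage` chains per-pair ΔRRCS →
common activation network → Gα-specific networks.  Both are deterministic
for a fixed config and inputs, and attach machine-readable provenance
reports per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .enrichment import (EnrichmentResult, PooledPosition, consensus_positions,
                         merge_residue_sets, pool_families, sensitive_approach,
                         specific_approach)
from .io import AlignedFamily, CouplingTable, StructureModel, write_edge_table
from .orthologs import extract_ortholog_clade, root_by_outgroup
from .paralogs import trim_paralogs
from .rrcs import (ContactNetwork, PairingPlan, common_network, compute_rrcs,
                   delta_rrcs, gprotein_specific_network)
from .tree import GeneTree

logger = logging.getLogger("gpcrsel")


@dataclass
class PipelineConfig:
    """All pipeline thresholds, with the published values as defaults."""

    spec_thr: float = 0.9
    cons_thr: float = 0.9
    lower_thr: float = 0.7
    allowed_min_exclusive: int = 2
    gap_max: float = 0.5
    paralog_alpha: float = 0.1
    delta_min: float = 0.2
    common_min_count: int = 36
    galpha_alpha: dict[str, float] = field(
        default_factory=lambda: {"Gs": 0.01, "Gq": 0.01, "Go": 0.01,
                                 "Gi1": 0.1})
    md_alpha: float = 0.05
    coupling_source: str = "union"  # datasetA | datasetB | union | intersection
    sensitive_excluded: tuple[str, ...] = ("G12", "G13")
    consensus_fraction: float = 1.0
    pool_mode: str = "both"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spec_thr", "cons_thr", "lower_thr", "gap_max",
                     "paralog_alpha", "md_alpha", "consensus_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.delta_min < 0 or self.common_min_count < 1:
            raise ValueError("invalid delta_min or common_min_count")
        for g, a in self.galpha_alpha.items():
            if not 0.0 < a <= 1.0:
                raise ValueError(f"galpha_alpha[{g!r}] out of range: {a}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "galpha_alpha" in data:
            data["galpha_alpha"] = dict(data["galpha_alpha"])
        if "sensitive_excluded" in data:
            data["sensitive_excluded"] = tuple(data["sensitive_excluded"])
        return cls(**data)

    def digest(self) -> str:
        """Short config hash for output-file provenance headers."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def alpha_for(self, g_protein: str, default: float = 0.01) -> float:
        return self.galpha_alpha.get(g_protein, default)


class StageError(RuntimeError):
    """An error in one pipeline stage, carrying the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Evolution stage
# ---------------------------------------------------------------------------

@dataclass
class EvolutionStageResult:
    per_g_protein: dict[str, dict[str, EnrichmentResult]]
    consensus: set[int]
    pooled: dict[str, list[PooledPosition]]
    kept_orthologs: dict[str, set[str]]
    report: dict


def run_evolution_stage(
        families: Mapping[str, AlignedFamily],
        coupling: CouplingTable,
        config: PipelineConfig | None = None,
        trees: Mapping[str, GeneTree] | None = None,
        outgroups: Mapping[str, str] | None = None,
        g_proteins: Sequence[str] | None = None) -> EvolutionStageResult:
    """Ortholog selection → paralog trimming → conservation → enrichment.

    ``families`` maps receptor name to its ortholog MSA (all families in a
    shared coordinate system).  When ``trees`` (and optionally
    ``outgroups``) are given, each family is first restricted to the
    ortholog clade of its target and trimmed of diverged paralog clades.
    Enrichment then runs per requested Gα subtype on coupler/non-coupler
    groups from the coupling table.
    """
    config = config or PipelineConfig()
    stage = "evolution"
    compare_kwargs = dict(spec_thr=config.spec_thr, cons_thr=config.cons_thr,
                          lower_thr=config.lower_thr,
                          allowed_min_exclusive=config.allowed_min_exclusive,
                          gap_max=config.gap_max)
    report: dict = {"config": config.digest(), "receptors": {}}
    kept: dict[str, set[str]] = {}
    prepared: dict[str, AlignedFamily] = {}
    for receptor in sorted(families):
        family = families[receptor]
        entry: dict = {"n_input": family.n_sequences}
        if trees is not None and receptor in trees:
            tree = trees[receptor]
            try:
                if outgroups and receptor in outgroups:
                    tree = root_by_outgroup(tree, outgroups[receptor])
                target = tree.target or family.target.seq_id
                ortho = extract_ortholog_clade(tree, target)
                trimmed, verdicts = trim_paralogs(
                    tree, msa=family, alpha=config.paralog_alpha)
                keep_ids = (ortho.kept_leaves & trimmed
                            & set(family.seq_ids())) | {target}
                subset = family.subset(keep_ids)
                entry["excluded_clades"] = len(ortho.excluded_clades)
                entry["n_trim_verdicts"] = sum(
                    v.removed_clade != "none" for v in verdicts)
                entry["n_kept"] = subset.n_sequences
                family = subset
            except (ValueError, KeyError) as exc:
                raise StageError(stage, f"{receptor}: {exc}") from exc
        prepared[receptor] = family
        kept[receptor] = set(family.seq_ids())
        report["receptors"][receptor] = entry

    all_families = [prepared[r] for r in sorted(prepared)]
    try:
        consensus = consensus_positions(
            all_families, min_fraction=config.consensus_fraction,
            **compare_kwargs)
    except ValueError as exc:
        raise StageError(stage, str(exc)) from exc

    requested = list(g_proteins) if g_proteins is not None \
        else coupling.g_proteins
    per_g: dict[str, dict[str, EnrichmentResult]] = {}
    pooled: dict[str, list[PooledPosition]] = {}
    for g in requested:
        couplers = sorted(coupling.couplers(g, config.coupling_source)
                          & set(prepared))
        noncouplers = sorted(coupling.noncouplers(g, config.coupling_source)
                             & set(prepared))
        coupler_fams = [prepared[r] for r in couplers]
        noncoupler_fams = [prepared[r] for r in noncouplers]
        try:
            spec_res = specific_approach(coupler_fams, noncoupler_fams,
                                         g_protein=g, **compare_kwargs)
        except ValueError as exc:
            raise StageError(stage, f"{g}: {exc}") from exc
        sens_res = None
        if g not in config.sensitive_excluded:
            combined = pool_families(coupler_fams, family_id=f"{g}_couplers")
            sens_res = sensitive_approach(combined, noncoupler_fams,
                                          g_protein=g, **compare_kwargs)
        per_g[g] = {"specific": spec_res}
        if sens_res is not None:
            per_g[g]["sensitive"] = sens_res
        pooled[g] = merge_residue_sets(spec_res, sens_res, consensus)
        logger.info("%s: %d specific, %d sensitive, %d pooled positions",
                    g, len(spec_res.positions),
                    len(sens_res.positions) if sens_res else 0,
                    len(pooled[g]))
    return EvolutionStageResult(per_g, consensus, pooled, kept, report)


# ---------------------------------------------------------------------------
# Structure stage
# ---------------------------------------------------------------------------

@dataclass
class StructureStageResult:
    delta_networks: dict[str, list[ContactNetwork]]
    common: ContactNetwork
    specific: dict[str, ContactNetwork]
    report: dict


def run_structure_stage(
        structures: Mapping[str, StructureModel],
        plan: PairingPlan,
        pool: set[str],
        groups: Mapping[str, set[str]],
        config: PipelineConfig | None = None,
        exclude: Mapping[str, set[str]] | None = None,
        ) -> StructureStageResult:
    """Per-pair ΔRRCS → common network → Gα-specific networks.

    ``groups`` maps each Gα subtype to its coupler receptor set; ``pool``
    is the conserved-residue pool restricting ΔRRCS edges; ``exclude``
    optionally lists receptors/structures to drop from a subtype's group
    test.
    """
    config = config or PipelineConfig()
    stage = "structure"
    pairs = plan.pairs()
    if not pairs:
        raise StageError(stage, "empty pairing plan")
    if not pool:
        raise StageError(stage, "empty residue pool")
    rrcs_cache: dict[str, ContactNetwork] = {}

    def rrcs_of(sid: str) -> ContactNetwork:
        if sid not in rrcs_cache:
            if sid not in structures:
                raise StageError(stage, f"structure {sid!r} missing")
            rrcs_cache[sid] = compute_rrcs(structures[sid])
        return rrcs_cache[sid]

    delta_networks: dict[str, list[ContactNetwork]] = {}
    for receptor, active_id, inactive_id in pairs:
        net = delta_rrcs(rrcs_of(active_id), rrcs_of(inactive_id),
                         pool=pool, delta_min=config.delta_min,
                         pool_mode=config.pool_mode)
        delta_networks.setdefault(receptor, []).append(net)
    all_nets = [n for nets in delta_networks.values() for n in nets]
    common = common_network(all_nets, min_count=config.common_min_count)
    specific: dict[str, ContactNetwork] = {}
    for g in sorted(groups):
        group = set(groups[g]) & set(delta_networks)
        if not group or group == set(delta_networks):
            logger.warning("%s: degenerate group, skipped", g)
            continue
        specific[g] = gprotein_specific_network(
            delta_networks, group, alpha=config.alpha_for(g),
            exclude=(exclude or {}).get(g, set()))
    report = {"config": config.digest(), "n_pairs": len(pairs),
              "n_common_edges": len(common),
              "n_specific_edges": {g: len(n) for g, n in specific.items()}}
    return StructureStageResult(delta_networks, common, specific, report)


def export_networks(result: StructureStageResult, out_dir: str | Path,
                    config: PipelineConfig | None = None) -> None:
    """Write every network as a TSV edge table with a config-hash header."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = f"config={config.digest()}"
    write_edge_table(result.common, out_dir / "common_network.tsv",
                     header_comment=header)
    for g, net in result.specific.items():
        write_edge_table(net, out_dir / f"specific_{g}.tsv",
                         header_comment=header)
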