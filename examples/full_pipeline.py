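"""Run the evolution stage end to end from a coupling table.

Builds a synthetic cohort (three Gs couplers, three non-couplers, three
planted determinant columns), a coupling-profile table, and runs ortholog
families through the complete enrichment chain; then feeds the recovered
positions into the structure stage as the conserved-residue pool.
"""

import pandas as pd

from gpcrsel import (CouplingTable, PairingPlan, PipelineConfig,
                     run_evolution_stage, run_structure_stage)
from gpcrsel.synthetic import (CohortSpec, StructurePairSpec, simulate_cohort,
                               simulate_structure_pair)

couplers, noncouplers, truth = simulate_cohort(
    CohortSpec(substitution_noise=0.02, seed=2))
families = {f.family_id: f for f in couplers + noncouplers}
coupling = CouplingTable(pd.DataFrame(
    [{"receptor": f.family_id, "g_protein": "Gs", "source": "merged",
      "couples": int(f in couplers)} for f in couplers + noncouplers]))

config = PipelineConfig()
evolution = run_evolution_stage(families, coupling, config=config,
                                g_proteins=["Gs"])
print(f"planted determinants:  {truth['determinant_columns']}")
print(f"Gs specific approach:  "
      f"{evolution.per_g_protein['Gs']['specific'].columns()}")
print(f"Gs sensitive approach: "
      f"{evolution.per_g_protein['Gs']['sensitive'].columns()}")
print(f"consensus positions:   {len(evolution.consensus)} columns")
print(f"pooled residue set:    {len(evolution.pooled['Gs'])} positions")

# map pooled columns onto the toy structures' generic numbers and run the
# structure stage with that pool
pool = {f"{(c - 1) % 7 + 1}x{c:02d}" for c in range(1, 11)}
structures, assignments = {}, {}
for receptor, gains in (("CPL1", ((2, 9),)), ("NCP1", ()), ("NCP2", ()),
                        ("NCP3", ())):
    actives, inactives = [], []
    for k in range(2):
        act, inact, _ = simulate_structure_pair(StructurePairSpec(
            n_residues=10, planted_gain_pairs=gains, seed=k))
        structures[f"{receptor}_a{k}"] = act
        structures[f"{receptor}_i{k}"] = inact
        actives.append(f"{receptor}_a{k}")
        inactives.append(f"{receptor}_i{k}")
    assignments[receptor] = (actives, inactives)
structure = run_structure_stage(
    structures, PairingPlan(assignments), pool, groups={"Gs": {"CPL1"}},
    config=PipelineConfig(common_min_count=4, galpha_alpha={"Gs": 0.01}))
print(f"structure stage: {structure.report['n_pairs']} pairs, "
      f"{structure.report['n_common_edges']} common edges, "
      f"Gs-specific edges: {sorted(structure.specific['Gs'].edges)}")
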