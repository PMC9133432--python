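"""Generators: determinism, planted structure, sidecar ground truth."""

import json

import numpy as np
import pytest

from gpcrsel import compute_rrcs, delta_rrcs, read_structure, read_fasta_msa
from gpcrsel.synthetic import (CohortSpec, FamilySpec, StructurePairSpec,
                               activation_state_templates, save_family,
                               save_structure_pair, simulate_cohort,
                               simulate_family, simulate_paralog_tree,
                               simulate_structure_pair, simulate_trajectory)


class TestSimulateFamily:
    def test_noiseless_conserved_columns_are_uniform(self):
        spec = FamilySpec(n_orthologs=10, length=8,
                          conserved_columns=frozenset(range(1, 6)), seed=5)
        fam, truth = simulate_family(spec)
        for col in range(1, 6):
            assert len(set(fam.column(col))) == 1
        assert truth["conserved_columns"] == [1, 2, 3, 4, 5]

    def test_same_seed_reproduces_output(self):
        spec = FamilySpec(n_orthologs=12, length=20, substitution_noise=0.1,
                          gap_rate=0.05, seed=9)
        fam1, _ = simulate_family(spec)
        fam2, _ = simulate_family(spec)
        assert [r.residues for r in fam1.sequences] == \
            [r.residues for r in fam2.sequences]

    def test_overlapping_column_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            FamilySpec(length=10, conserved_columns=frozenset({1, 2}),
                       variable_columns=frozenset({2, 3}))

    def test_noise_rate_matches_binomial_expectation(self):
        # empirical planted-residue retention vs the 1-noise expectation
        hits = total = 0
        for seed in range(60):
            spec = FamilySpec(n_orthologs=20, length=5,
                              conserved_columns=frozenset({1}),
                              substitution_noise=0.5, seed=seed)
            fam, truth = simulate_family(spec)
            planted = truth["column_residues"]["1"]
            col = fam.column(1)
            hits += sum(1 for r in col if r == planted)
            total += len(col)
        rate = hits / total
        se = np.sqrt(0.25 / total)
        assert abs(rate - 0.5) < 4 * se

    def test_sidecar_round_trip(self, tmp_path):
        spec = FamilySpec(n_orthologs=5, length=10, seed=2)
        fam, truth = simulate_family(spec)
        save_family(fam, truth, tmp_path)
        back = read_fasta_msa(tmp_path / "FAM.fasta")
        assert back.n_sequences == 5
        sidecar = json.loads((tmp_path / "truth.json").read_text())
        assert sidecar == truth


class TestSimulateParalogTree:
    def test_clades_share_species(self):
        tree, fam, truth = simulate_paralog_tree(n_ortho=5, n_paralog=5,
                                                 shared_species=3, seed=0)
        ortho_sp = {tree.species_of(n) for n in truth["ortholog_leaves"]}
        para_sp = {tree.species_of(n) for n in truth["paralog_leaves"]}
        assert len(ortho_sp & para_sp) == 3
        assert set(fam.seq_ids()) == set(tree.leaf_names())
        assert tree.target == "FAM_HUMAN"

    def test_zero_shared_species_disjoint(self):
        tree, _, truth = simulate_paralog_tree(shared_species=0, seed=0)
        ortho_sp = {tree.species_of(n) for n in truth["ortholog_leaves"]}
        para_sp = {tree.species_of(n) for n in truth["paralog_leaves"]}
        assert not ortho_sp & para_sp


class TestSimulateStructurePair:
    def test_gain_pair_is_only_delta_edge(self):
        spec = StructurePairSpec(n_residues=15,
                                 planted_gain_pairs=((2, 12),))
        active, inactive, truth = simulate_structure_pair(spec)
        net = delta_rrcs(compute_rrcs(active), compute_rrcs(inactive),
                         pool=None)
        assert len(net) == 1
        ((pair, value),) = net.sorted_edges()
        assert set(pair) == set(truth["gain_pairs"][0])
        assert value > 0

    def test_loss_pair_has_negative_delta(self):
        spec = StructurePairSpec(n_residues=15,
                                 planted_loss_pairs=((3, 13),))
        active, inactive, _ = simulate_structure_pair(spec)
        net = delta_rrcs(compute_rrcs(active), compute_rrcs(inactive),
                         pool=None)
        assert len(net) == 1
        ((_, value),) = net.sorted_edges()
        assert value < 0

    def test_no_planted_pairs_no_delta(self):
        active, inactive, _ = simulate_structure_pair(
            StructurePairSpec(n_residues=15))
        net = delta_rrcs(compute_rrcs(active), compute_rrcs(inactive),
                         pool=None, delta_min=0.0)
        assert len(net) == 0

    def test_infeasible_pair_load_rejected(self):
        pairs = tuple((1, j) for j in range(2, 9))  # residue 1 in 7 pairs
        with pytest.raises(ValueError, match="smaller"):
            simulate_structure_pair(
                StructurePairSpec(n_residues=10, planted_gain_pairs=pairs))

    def test_pdb_round_trip_preserves_contacts(self, tmp_path):
        spec = StructurePairSpec(n_residues=10,
                                 planted_gain_pairs=((1, 8),), seed=4)
        active, inactive, truth = simulate_structure_pair(spec)
        save_structure_pair(active, inactive, truth, tmp_path)
        from gpcrsel.io import GenericNumberMap
        gmap = GenericNumberMap({k: f"{(k - 1) % 7 + 1}x{k:02d}"
                                 for k in range(1, 11)})
        a = read_structure(tmp_path / "active.pdb", generic_map=gmap,
                           state="active")
        i = read_structure(tmp_path / "inactive.pdb", generic_map=gmap,
                           state="inactive")
        net = delta_rrcs(compute_rrcs(a), compute_rrcs(i), pool=None)
        assert len(net) == 1


class TestSimulateTrajectory:
    def test_frame_counts_and_determinism(self):
        act, inact = activation_state_templates()
        t1 = simulate_trajectory(act, inact, n_replicates=3, n_frames=5,
                                 noise_sd=0.1, seed=8)
        t2 = simulate_trajectory(act, inact, n_replicates=3, n_frames=5,
                                 noise_sd=0.1, seed=8)
        assert t1.n_frames == 15
        c1 = t1.replicates[2][4].model.stacked_coords()
        c2 = t2.replicates[2][4].model.stacked_coords()
        assert np.array_equal(c1, c2)

    def test_roster_mismatch_rejected(self):
        act, inact = activation_state_templates()
        smaller, _ = activation_state_templates(n_filler=1)
        with pytest.raises(ValueError, match="roster"):
            simulate_trajectory(act, smaller, n_replicates=1, n_frames=2)

    def test_timestamps_span_total_ns(self):
        act, inact = activation_state_templates()
        traj = simulate_trajectory(act, inact, n_replicates=1, n_frames=11,
                                   total_ns=500.0)
        times = [f.time_ns for f in traj.replicates[0]]
        assert times[0] == 0.0 and times[-1] == 500.0
        assert np.allclose(np.diff(times), 50.0)


class TestSimulateCohort:
    def test_planted_determinants_dissimilar_across_groups(self):
        couplers, noncouplers, truth = simulate_cohort(CohortSpec(seed=3))
        from gpcrsel.conservation import similarity
        for col in truth["determinant_columns"]:
            r_c = truth["coupler_residues"][str(col)]
            r_n = truth["noncoupler_residues"][str(col)]
            assert similarity(r_c, r_n) <= 1
            for fam in couplers:
                assert set(fam.column(col)) == {r_c}
            for fam in noncouplers:
                assert set(fam.column(col)) == {r_n}
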