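"""RRCS scoring, ΔRRCS filtering, common and group-specific networks."""

import numpy as np
import pytest

from gpcrsel import (ContactNetwork, PairingPlan, canonical_pair,
                     common_network, compute_rrcs, delta_rrcs,
                     gprotein_specific_network)
from gpcrsel.synthetic import StructurePairSpec, simulate_structure_pair

from conftest import brute_force_rrcs, single_atom_structure


def pair_structure(distance, indices=(1, 10)):
    """Two single-atom residues at a given separation (non-adjacent)."""
    return single_atom_structure([(0.0, 0.0, 0.0), (distance, 0.0, 0.0)],
                                 indices=indices)


class TestComputeRrcs:
    def test_saturated_contact_scores_one(self):
        net = compute_rrcs(pair_structure(3.00))
        assert len(net) == 1
        assert list(net.edges.values())[0] == pytest.approx(1.0)

    def test_boundary_distance_yields_no_edge(self):
        net = compute_rrcs(pair_structure(4.63))
        assert len(net) == 0

    def test_ramp_midpoint_scores_half(self):
        net = compute_rrcs(pair_structure(3.93))
        assert list(net.edges.values())[0] == \
            pytest.approx((4.63 - 3.93) / 1.40)

    def test_adjacent_residues_exclude_backbone(self):
        # two residues 3 A apart but sequence-adjacent: their only atoms
        # are backbone CAs, so no score survives the exclusion
        net = compute_rrcs(pair_structure(3.00, indices=(1, 2)))
        assert len(net) == 0

    def test_matches_brute_force_on_random_structures(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            positions = rng.uniform(0, 12, size=(20, 3))
            model = single_atom_structure(positions)
            fast = compute_rrcs(model)
            slow = brute_force_rrcs(model)
            assert set(fast.edges) == set(slow)
            for pair, value in slow.items():
                assert fast.edges[pair] == pytest.approx(value, abs=1e-9)

    def test_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(1)
        model = single_atom_structure(rng.uniform(0, 10, size=(12, 3)))
        net = compute_rrcs(model)
        for (a, b), v in net.edges.items():
            assert v >= 0
            assert canonical_pair(b, a) in net.edges


class TestDeltaRrcs:
    def test_identical_structures_empty(self):
        model = pair_structure(3.5)
        net = compute_rrcs(model)
        assert len(delta_rrcs(net, net, pool=None)) == 0

    def test_boundary_exactly_0p2_dropped(self):
        active = ContactNetwork({("1x01", "3x03"): 0.2})
        inactive = ContactNetwork({})
        assert len(delta_rrcs(active, inactive, pool=None)) == 0

    def test_small_delta_dropped_large_negative_kept(self):
        active = ContactNetwork({("1x01", "3x03"): 0.15,
                                 ("2x02", "4x04"): 0.0})
        inactive = ContactNetwork({("2x02", "4x04"): 0.5})
        net = delta_rrcs(active, inactive, pool=None)
        assert set(net.edges) == {canonical_pair("2x02", "4x04")}
        assert net.edges[canonical_pair("2x02", "4x04")] == pytest.approx(-0.5)

    def test_pool_restriction_modes(self):
        active = ContactNetwork({("1x01", "3x03"): 1.0})
        inactive = ContactNetwork({})
        both = delta_rrcs(active, inactive, pool={"1x01", "3x03"})
        one = delta_rrcs(active, inactive, pool={"1x01"}, pool_mode="both")
        either = delta_rrcs(active, inactive, pool={"1x01"},
                            pool_mode="either")
        assert len(both) == 1 and len(one) == 0 and len(either) == 1

    def test_empty_pool_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            delta_rrcs(ContactNetwork({}), ContactNetwork({}), pool=set())

    def test_planted_gain_recovered_from_fixture(self):
        active, inactive, truth = simulate_structure_pair(
            StructurePairSpec(n_residues=12, planted_gain_pairs=((2, 9),)))
        net = delta_rrcs(compute_rrcs(active), compute_rrcs(inactive),
                         pool={gn for p in truth["gain_pairs"] for gn in p})
        assert len(net) == 1
        assert next(iter(net.edges.values())) > 0


class TestCommonNetwork:
    def build(self, n_with_edge, n_total=41):
        pair = ("3x50", "7x53")
        nets = [ContactNetwork({pair: 1.0 if i % 2 else -1.0})
                for i in range(n_with_edge)]
        nets += [ContactNetwork({}) for _ in range(n_total - n_with_edge)]
        return nets

    def test_edge_in_36_of_41_kept(self):
        net = common_network(self.build(36), min_count=36)
        assert len(net) == 1
        assert net.edges[canonical_pair("3x50", "7x53")] == 36.0

    def test_edge_in_35_of_41_dropped(self):
        net = common_network(self.build(35), min_count=36)
        assert len(net) == 0

    def test_min_count_one_is_union(self):
        nets = [ContactNetwork({("1x01", "2x02"): 1.0}),
                ContactNetwork({("3x03", "4x04"): -0.5})]
        assert len(common_network(nets, min_count=1)) == 2

    def test_min_count_above_inputs_warns_empty(self):
        with pytest.warns(UserWarning, match="exceeds"):
            net = common_network([ContactNetwork({("1x01", "2x02"): 1.0})],
                                 min_count=5)
        assert len(net) == 0


class TestGproteinSpecificNetwork:
    PAIR = ("3x50", "7x53")

    def networks(self, values_by_receptor):
        return {r: [ContactNetwork({self.PAIR: v}, provenance=f"{r}_s{i}")
                    for i, v in enumerate(vals)]
                for r, vals in values_by_receptor.items()}

    def test_clear_group_effect_retained_with_sign(self):
        rng = np.random.default_rng(0)
        nets = self.networks({
            "A": [1.0, 1.01, 0.99], "B": [1.02, 0.98, 1.0],
            "C": list(rng.normal(0, 0.01, 3)),
            "D": list(rng.normal(0, 0.01, 3))})
        result = gprotein_specific_network(nets, group={"A", "B"},
                                           alpha=0.01)
        key = canonical_pair(*self.PAIR)
        assert key in result.edges
        assert result.edges[key] > 0.5
        assert result.pvalues[key] <= 0.01

    def test_identical_distributions_rarely_retained(self):
        retained = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            nets = self.networks({r: list(rng.normal(0, 0.1, 3))
                                  for r in "ABCDEF"})
            result = gprotein_specific_network(nets, group={"A", "B"},
                                               alpha=0.01)
            retained += len(result)
        assert retained <= 100 * (0.01 + 2 * np.sqrt(0.01 * 0.99 / 100))

    def test_exclusion_flips_outlier_masked_edge(self):
        # the group's effect is hidden by one outlier receptor in the rest
        # group; excluding it reveals the edge
        nets = self.networks({
            "A": [1.0, 1.02, 0.98], "B": [0.99, 1.01, 1.0],
            "C": [0.0, 0.01, -0.01], "D": [0.01, -0.01, 0.0],
            "OUT": [2.0, 3.0, 2.5]})
        with_outlier = gprotein_specific_network(nets, group={"A", "B"},
                                                 alpha=0.01)
        without = gprotein_specific_network(nets, group={"A", "B"},
                                            alpha=0.01, exclude={"OUT"})
        key = canonical_pair(*self.PAIR)
        assert key not in with_outlier.edges
        assert key in without.edges

    def test_structure_id_exclusion_via_provenance(self):
        nets = self.networks({
            "A": [1.0, 1.02, 0.98], "B": [0.99, 1.01, 1.0],
            "C": [0.0, 0.01, -0.01], "D": [5.0, 0.0, 0.01]})
        # dropping the single outlier pair network D_s0 by structure id
        res = gprotein_specific_network(nets, group={"A", "B"}, alpha=0.01,
                                        exclude={"D_s0"})
        key = canonical_pair(*self.PAIR)
        assert key in res.edges

    def test_small_sample_skipped_with_warning(self):
        nets = {"A": [ContactNetwork({self.PAIR: 1.0})],
                "B": [ContactNetwork({self.PAIR: 0.0})]}
        with pytest.warns(UserWarning, match="sample too small"):
            result = gprotein_specific_network(nets, group={"A"}, alpha=0.1)
        assert len(result) == 0


class TestPairingPlan:
    def test_cartesian_product_per_receptor(self):
        plan = PairingPlan({"ADRB2": (["a1", "a2"], ["i1"]),
                            "DRD2": (["a3"], ["i2", "i3"])})
        pairs = plan.pairs()
        assert len(pairs) == 4
        assert all(r in ("ADRB2", "DRD2") for r, _, _ in pairs)

    def test_explicit_pairs_override(self):
        plan = PairingPlan({"ADRB2": (["a1"], ["i1", "i2"])},
                           explicit_pairs=[("ADRB2", "a1", "i1")])
        assert plan.pairs() == [("ADRB2", "a1", "i1")]
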