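import dataclasses

import numpy as np
import pytest

from rinnet import (
    GeometricCriteria,
    InteractionType,
    default_chemistry,
    detect_hbond,
    detect_interactions,
    detect_ionic,
    detect_pication,
    detect_pipistack,
    detect_ssbond,
    detect_vdw,
    filter_network,
    network_for_ensemble,
)
from rinnet.fixtures import (
    make_decoy_state,
    make_ideal_helix,
    make_pication_pair,
    make_salt_bridge,
    make_scripted_contact_ensemble,
    make_stacked_rings,
    make_two_basin_ensemble,
)
from rinnet.interactions import edges_frame, nodes_frame
from rinnet.structures import Atom, Residue, State

from .oracles import ORACLES, edge_tuples

DETECTORS = {
    InteractionType.HBOND: detect_hbond,
    InteractionType.IONIC: detect_ionic,
    InteractionType.PIPISTACK: detect_pipistack,
    InteractionType.PICATION: detect_pication,
    InteractionType.VDW: detect_vdw,
    InteractionType.SSBOND: detect_ssbond,
}


def non_vdw(edges):
    return {(str(e.source), str(e.target), e.type) for e in edges
            if e.type != InteractionType.VDW}


class TestHelix:
    def test_i_i4_hbond_ladder(self, helix18, criteria):
        ens, truth = helix18
        net = detect_interactions(ens.states[0], criteria)
        got = {(str(e.source), str(e.target), e.type)
               for e in net.edges_of(InteractionType.HBOND)}
        assert truth.expected_edges[0] <= got
        # every hydrogen bond is backbone N...O
        for e in net.edges_of(InteractionType.HBOND):
            assert {e.source_atom, e.target_atom} == {"N", "O"}

    def test_no_charged_or_pi_edges(self, helix18, criteria):
        ens, _ = helix18
        net = detect_interactions(ens.states[0], criteria)
        for t in (InteractionType.IONIC, InteractionType.PIPISTACK,
                  InteractionType.PICATION, InteractionType.SSBOND):
            assert net.edges_of(t) == []

    def test_hbond_equals_exhaustive_scan(self, helix18, criteria, chemistry):
        ens, _ = helix18
        edges = detect_hbond(ens.states[0], criteria, chemistry)
        assert edge_tuples(edges) == ORACLES[InteractionType.HBOND](
            ens.states[0], criteria, chemistry)


class TestConstructedPairs:
    def test_salt_bridge_on_off(self, criteria):
        on, truth_on = make_salt_bridge(criteria, on=True)
        off, truth_off = make_salt_bridge(criteria, on=False)
        assert non_vdw(detect_interactions(on.states[0], criteria).edges) \
            == truth_on.expected_edges[0]
        assert non_vdw(detect_interactions(off.states[0], criteria).edges) \
            == set()
        edge = detect_ionic(on.states[0], criteria)[0]
        assert edge.distance == pytest.approx(0.85 * criteria.ionic_max_dist,
                                              abs=1e-6)

    def test_stacked_rings_inside_and_outside_cutoff(self, criteria):
        on, truth = make_stacked_rings(criteria, on=True)
        assert non_vdw(detect_interactions(on.states[0], criteria).edges) \
            == truth.expected_edges[0]
        off, _ = make_stacked_rings(criteria, on=False)
        assert detect_pipistack(off.states[0], criteria) == []

    def test_pication_angle_gate(self, criteria):
        axial, truth = make_pication_pair(criteria, axial=True)
        assert non_vdw(detect_interactions(axial.states[0], criteria).edges) \
            == truth.expected_edges[0]
        in_plane, _ = make_pication_pair(criteria, axial=False)
        assert detect_pication(in_plane.states[0], criteria) == []

    def test_hbond_angle_gate(self, criteria, chemistry):
        # N...O at a valid distance but with a 40 degree antecedent angle
        d = 0.85 * criteria.hbond_max_da
        ca = 1.458 * np.array([np.cos(np.radians(40.0)),
                               np.sin(np.radians(40.0)), 0.0])
        donor = Residue("A", 1, "", "ALA", "amino_acid", [
            Atom(1, "N", "N", [0.0, 0.0, 0.0]),
            Atom(2, "CA", "C", ca)])
        acceptor = Residue("B", 1, "", "ALA", "amino_acid", [
            Atom(3, "O", "O", [d, 0.0, 0.0]),
            Atom(4, "C", "C", [d + 1.2, 0.0, 0.0])])
        state = State(0, {"A": [donor], "B": [acceptor]})
        assert detect_hbond(state, criteria, chemistry) == []

    def test_explicit_hydrogen_geometry_used(self, criteria, chemistry):
        # antecedent angle fails (40 deg) but the explicit H is well placed:
        # with an H the D-H-A angle rule must be applied instead
        d = 0.85 * criteria.hbond_max_da
        ca = 1.458 * np.array([np.cos(np.radians(40.0)),
                               np.sin(np.radians(40.0)), 0.0])
        donor = Residue("A", 1, "", "ALA", "amino_acid", [
            Atom(1, "N", "N", [0.0, 0.0, 0.0]),
            Atom(2, "CA", "C", ca),
            Atom(3, "H", "H", [1.0, 0.0, 0.0])])  # straight toward acceptor
        acceptor = Residue("B", 1, "", "ALA", "amino_acid", [
            Atom(4, "O", "O", [d, 0.0, 0.0]),
            Atom(5, "C", "C", [d + 1.2, 0.0, 0.0])])
        state = State(0, {"A": [donor], "B": [acceptor]})
        edges = detect_hbond(state, criteria, chemistry)
        assert len(edges) == 1
        assert edges[0].angle == pytest.approx(180.0, abs=1e-6)

    def test_ssbond_detected_and_seq_exempt(self, criteria, chemistry):
        mk = lambda num, x: Residue("A", num, "", "CYS", "amino_acid", [
            Atom(num, "SG", "S", [x, 0.0, 0.0])])
        state = State(0, {"A": [mk(1, 0.0), mk(2, 2.0)]})  # adjacent in seq
        edges = detect_ssbond(state, criteria, chemistry)
        assert len(edges) == 1
        assert edges[0].distance == pytest.approx(2.0)


class TestDecoyOracleEquivalence:
    @pytest.mark.parametrize("itype", list(InteractionType))
    def test_each_detector_equals_oracle(self, itype, criteria, chemistry):
        for seed in range(6):
            state = make_decoy_state(120, seed=seed)
            got = edge_tuples(DETECTORS[itype](state, criteria, chemistry))
            want = ORACLES[itype](state, criteria, chemistry)
            assert got == want, f"seed {seed}: {itype} detector != oracle"

    def test_union_detector_consistent_with_per_type(self, criteria,
                                                     chemistry):
        state = make_decoy_state(100, seed=42)
        net = detect_interactions(state, criteria, chemistry)
        for itype in InteractionType:
            assert edge_tuples(net.edges_of(itype)) == \
                ORACLES[itype](state, criteria, chemistry)


class TestNetworkInvariants:
    def test_canonical_orientation_and_no_duplicates(self, criteria,
                                                     chemistry):
        state = make_decoy_state(150, seed=7)
        net = detect_interactions(state, criteria, chemistry)
        seen = set()
        for e in net.edges:
            assert e.source <= e.target
            assert e.identity() not in seen
            seen.add(e.identity())
        node_set = set(net.nodes)
        assert all(e.source in node_set and e.target in node_set
                   for e in net.edges)

    def test_distance_cutoff_monotonicity(self, criteria, chemistry):
        state = make_decoy_state(80, seed=11)
        small = detect_interactions(state, criteria, chemistry)
        bigger = dataclasses.replace(
            criteria,
            hbond_max_da=criteria.hbond_max_da + 0.4,
            ionic_max_dist=criteria.ionic_max_dist + 0.4,
            pipi_max_centroid=criteria.pipi_max_centroid + 0.4,
            pication_max_dist=criteria.pication_max_dist + 0.4,
            ssbond_max_ss=criteria.ssbond_max_ss + 0.4,
        )
        big = detect_interactions(state, bigger, chemistry)
        # per-pair, per-type presence never lost when cutoffs grow
        # (HBOND/VDW pairings may shift because best-acceptor and the
        #  vdW exclusion are themselves distance dependent)
        for t in (InteractionType.IONIC, InteractionType.PIPISTACK,
                  InteractionType.PICATION, InteractionType.SSBOND):
            small_pairs = {e.pair() for e in small.edges_of(t)}
            big_pairs = {e.pair() for e in big.edges_of(t)}
            assert small_pairs <= big_pairs

    def test_determinism_under_atom_order(self, criteria, chemistry):
        state = make_decoy_state(60, seed=3)
        shuffled = State(0, {
            ch: [Residue(r.chain_id, r.number, r.insertion, r.name,
                         r.polymer_class, list(reversed(r.atoms)))
                 for r in residues]
            for ch, residues in state.chains.items()
        })
        a = detect_interactions(state, criteria, chemistry)
        b = detect_interactions(shuffled, criteria, chemistry)
        assert edge_tuples(a.edges) == edge_tuples(b.edges)

    def test_min_seq_separation_excludes_neighbors(self, helix18, criteria,
                                                   chemistry):
        ens, _ = helix18
        net = detect_interactions(ens.states[0], criteria, chemistry)
        for e in net.edges:
            if e.type != InteractionType.SSBOND:
                assert abs(e.source.number - e.target.number) \
                    >= criteria.min_seq_separation


class TestFilterNetwork:
    @pytest.fixture()
    def mixed_network(self, criteria):
        script = {"ionic": [True], "hbond": [True]}
        ens, _ = make_scripted_contact_ensemble(script, criteria=criteria)
        return detect_interactions(ens.states[0], criteria)

    def test_scope_partition(self, mixed_network):
        intra = filter_network(mixed_network, scope="intra_chain")
        inter = filter_network(mixed_network, scope="inter_chain")
        both = filter_network(mixed_network, scope="all")
        assert len(intra.edges) + len(inter.edges) == len(both.edges)
        assert set(e.identity() for e in intra.edges).isdisjoint(
            e.identity() for e in inter.edges)

    def test_type_filter(self, mixed_network):
        only_ionic = filter_network(mixed_network,
                                    types={InteractionType.IONIC})
        assert {e.type for e in only_ionic.edges} <= {InteractionType.IONIC}
        empty = filter_network(mixed_network,
                               types={InteractionType.PIPISTACK})
        assert empty.edges == [] and empty.nodes == []

    def test_nodes_pruned_to_endpoints(self, mixed_network):
        inter = filter_network(mixed_network, scope="inter_chain")
        endpoints = {e.source for e in inter.edges} | \
            {e.target for e in inter.edges}
        assert set(inter.nodes) == endpoints


class TestEnsembleDetection:
    def test_identical_states_identical_networks(self, criteria):
        script = {"ionic": [True, True, True]}
        ens, _ = make_scripted_contact_ensemble(script, criteria=criteria)
        nets = network_for_ensemble(ens, criteria)
        ref = edge_tuples(nets[0].edges)
        assert all(edge_tuples(n.edges) == ref for n in nets)
        assert [n.state_index for n in nets] == [0, 1, 2]

    def test_broken_salt_bridge_counted_in_right_states(self, criteria):
        script = {"ionic": [True, False, True]}
        ens, _ = make_scripted_contact_ensemble(script, criteria=criteria)
        nets = network_for_ensemble(ens, criteria)
        present = [bool(n.edges_of(InteractionType.IONIC)) for n in nets]
        assert present == [True, False, True]

    def test_per_state_equals_single_state_calls(self, criteria):
        ens, _ = make_two_basin_ensemble(3, 2.0, 0.1, seed=9, n_res=10)
        nets = network_for_ensemble(ens, criteria)
        for st, net in zip(ens.states, nets):
            solo = detect_interactions(st, criteria)
            assert edge_tuples(solo.edges) == edge_tuples(net.edges)


class TestTables:
    def test_edges_frame_columns_and_rows(self, helix18, criteria):
        ens, _ = helix18
        net = detect_interactions(ens.states[0], criteria)
        df = edges_frame([net])
        assert list(df.columns) == ["NodeId1", "Interaction", "NodeId2",
                                    "Atom1", "Atom2", "Distance", "Angle",
                                    "State"]
        assert len(df) == len(net.edges)

    def test_nodes_frame_degrees_match_handshake(self, helix18, criteria):
        ens, _ = helix18
        net = detect_interactions(ens.states[0], criteria)
        df = nodes_frame([net])
        assert df["Degree_total"].sum() == 2 * len(net.edges)
        assert len(df) == 18
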