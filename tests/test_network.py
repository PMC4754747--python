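import itertools

import networkx as nx
import numpy as np
import pytest

from dimerdyn.core import ResidueSelection, TrajectoryEnsemble, ValidationError
from dimerdyn.network import (
    bootstrap_networks,
    build_network,
    contact_frames,
    contact_occupancy,
    occupancy_from_frames,
    shortest_paths,
    summarize,
    ResidueNetwork,
)
from dimerdyn.synthetic import SyntheticSpec, build_toy_dimer, generate_ensemble

from test_modes import make_modeset
from conftest import make_ca_model


def static_traj(model, n_frames=3):
    frames = np.stack([model.reference_coordinates] * n_frames)
    return TrajectoryEnsemble(model=model, frames=frames)


class TestContactOccupancy:
    def test_permanent_contact(self):
        model = make_ca_model(2, spacing=3.0)
        occ = contact_occupancy(static_traj(model))
        assert occ.occupancy(("A", 1), ("A", 2)) == 1.0

    def test_never_in_contact(self):
        model = make_ca_model(2, spacing=6.0)
        occ = contact_occupancy(static_traj(model))
        assert occ.occupancy(("A", 1), ("A", 2)) == 0.0

    def test_strict_distance_inequality(self):
        model = make_ca_model(2, spacing=4.5)
        occ = contact_occupancy(static_traj(model), distance=4.5)
        assert occ.occupancy(("A", 1), ("A", 2)) == 0.0

    def test_planted_bernoulli_occupancy(self):
        spec = SyntheticSpec(
            n_residues_per_chain=8,
            n_frames=4000,
            planted_modes=[],
            dissociation_amplitude_stddev=0.0,
            noise_stddev=0.05,
            contact_targets=[(("A", 1), ("A", 5), 0.75)],
            seed=21,
        )
        model = build_toy_dimer(spec)
        traj, _ = generate_ensemble(model, spec)
        occ = contact_occupancy(traj)
        # binomial sampling bound at F=4000: +/- 0.02 around 0.75
        assert occ.occupancy(("A", 1), ("A", 5)) == pytest.approx(0.75, abs=0.02)


def uniform_motion_modeset(model):
    vec = np.tile([1.0, 0.0, 0.0], len(model.residues()))
    return make_modeset(model, [vec])


class TestBuildNetwork:
    def test_complete_graph_for_coherent_motion(self):
        model = make_ca_model(4, spacing=3.0)
        occ = contact_occupancy(static_traj(model))
        # put every pair in permanent contact
        for a, b in itertools.combinations(range(1, 5), 2):
            occ.pairs[tuple(sorted([("A", a), ("A", b)]))] = 1.0
        nets = build_network(uniform_motion_modeset(model), 0, occ)
        g = nets[0].graph
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 6  # complete graph K4

    def test_orthogonal_motion_gives_no_edges(self):
        model = make_ca_model(4, spacing=3.0)
        occ = contact_occupancy(static_traj(model))
        vec = np.zeros(12)
        vec[0::6] = 1.0  # odd residues along x
        vec[4::6] = 1.0  # even residues along y (90 degrees apart)
        ms = make_modeset(model, [vec])
        nets = build_network(ms, 0, occ)
        assert nets[0].graph.number_of_edges() == 0

    def test_direction_undefined_fails_motion_criterion(self):
        model = make_ca_model(3, spacing=3.0)
        vec = np.zeros(9)
        vec[0] = 1.0  # only residue 1 moves
        ms = make_modeset(model, [vec])
        occ = contact_occupancy(static_traj(model))
        nets = build_network(ms, 0, occ)
        assert nets[0].graph.number_of_edges() == 0

    def test_edge_monotonicity_in_thresholds(self, small_model, small_ensemble):
        traj, _ = small_ensemble
        rng = np.random.default_rng(0)
        vec = rng.normal(size=3 * len(small_model.residues()))
        ms = make_modeset(small_model, [vec])
        occ = contact_occupancy(traj)
        base = sum(
            n.graph.number_of_edges()
            for n in build_network(ms, 0, occ, angle_threshold=60, occupancy_threshold=0.5)
        )
        stricter_occ = sum(
            n.graph.number_of_edges()
            for n in build_network(ms, 0, occ, angle_threshold=60, occupancy_threshold=0.9)
        )
        stricter_angle = sum(
            n.graph.number_of_edges()
            for n in build_network(ms, 0, occ, angle_threshold=20, occupancy_threshold=0.5)
        )
        assert stricter_occ <= base
        assert stricter_angle <= base


class TestSummarize:
    def test_triangle_clustering(self):
        g = nx.cycle_graph(3)
        net = ResidueNetwork(
            chain_id="A",
            graph=nx.relabel_nodes(g, {i: ("A", i + 1) for i in g.nodes}),
            parameters={},
        )
        s = summarize(net)
        assert s.average_clustering_coefficient == pytest.approx(1.0)
        assert s.average_degree == pytest.approx(2.0)

    def test_path_graph_hand_enumeration(self):
        g = nx.path_graph(4)  # 4 nodes, 3 edges
        net = ResidueNetwork(
            chain_id="A",
            graph=nx.relabel_nodes(g, {i: ("A", i + 1) for i in g.nodes}),
            parameters={},
        )
        s = summarize(net)
        assert s.average_clustering_coefficient == pytest.approx(0.0)
        assert s.average_degree == pytest.approx(1.5)

    def test_average_degree_identity(self, small_model, small_ensemble):
        traj, _ = small_ensemble
        occ = contact_occupancy(traj)
        nets = build_network(uniform_motion_modeset(small_model), 0, occ)
        for net in nets:
            if net.graph.number_of_nodes() == 0:
                continue
            s = summarize(net)
            assert s.average_degree == pytest.approx(
                2.0 * s.n_edges / s.n_nodes, abs=1e-9
            )

    def test_empty_network_rejected(self):
        net = ResidueNetwork(chain_id="A", graph=nx.Graph(), parameters={})
        with pytest.raises(ValidationError):
            summarize(net)


def graph_to_network(g):
    mapping = {n: ("A", n + 1) for n in g.nodes}
    return ResidueNetwork(chain_id="A", graph=nx.relabel_nodes(g, mapping), parameters={})


class TestShortestPaths:
    def test_adjacent_pair(self):
        net = graph_to_network(nx.path_graph(3))
        report = shortest_paths(net, ("A", 1), ResidueSelection([("A", 2)]))
        assert report.lengths[("A", 2)] == 1
        assert report.n_paths[("A", 2)] == 1

    def test_four_cycle_opposite_corners(self):
        net = graph_to_network(nx.cycle_graph(4))
        report = shortest_paths(net, ("A", 1), ResidueSelection([("A", 3)]))
        assert report.lengths[("A", 3)] == 2
        assert report.n_paths[("A", 3)] == 2

    def test_unreachable_flagged(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        g.add_edge(2, 3)
        net = graph_to_network(g)
        report = shortest_paths(net, ("A", 1), ResidueSelection([("A", 3), ("A", 9)]))
        assert report.lengths[("A", 3)] is None
        assert report.n_paths[("A", 3)] == 0
        assert report.lengths[("A", 9)] is None

    def test_counts_match_enumeration_on_random_graphs(self):
        # exhaustive geodesic enumeration via networkx as the oracle
        for seed in range(20):
            g = nx.gnp_random_graph(12, 0.3, seed=seed)
            net = graph_to_network(g)
            connected = sorted(n for n in g.nodes if g.degree(n) > 0)
            if len(connected) < 2:
                continue
            source = ("A", connected[0] + 1)
            targets = ResidueSelection(
                [("A", n + 1) for n in sorted(g.nodes) if n != connected[0]]
            )
            report = shortest_paths(net, source, targets)
            for target in targets:
                raw_t = target[1] - 1
                if target not in net.graph or not nx.has_path(net.graph, source, target):
                    assert report.lengths[target] is None
                    continue
                paths = list(nx.all_shortest_paths(net.graph, source, target))
                assert report.lengths[target] == len(paths[0]) - 1
                assert report.n_paths[target] == len(paths)


class TestBootstrap:
    def _setup(self, small_model, small_ensemble):
        traj, _ = small_ensemble
        rng = np.random.default_rng(5)
        vec = rng.normal(size=3 * len(small_model.residues()))
        return traj, make_modeset(small_model, [vec])

    def test_fraction_one_reproduces_full_network(self, small_model, small_ensemble):
        traj, ms = self._setup(small_model, small_ensemble)
        occ = contact_occupancy(traj)
        full = build_network(ms, 0, occ, angle_threshold=60, occupancy_threshold=0.5)
        full_summaries = {
            n.chain_id: summarize(n) for n in full if n.graph.number_of_nodes()
        }
        boot = bootstrap_networks(
            traj, ms, 0, fraction=1.0, repeats=3, seed=0,
            angle_threshold=60, occupancy_threshold=0.5,
        )
        for chain, s in full_summaries.items():
            assert boot.mean[chain]["n_edges"] == s.n_edges
            assert boot.sd[chain]["n_edges"] == 0.0

    def test_degenerate_occupancies_zero_dispersion(self, small_model):
        traj = static_traj(small_model, n_frames=10)
        ms = uniform_motion_modeset(small_model)
        boot = bootstrap_networks(traj, ms, 0, fraction=0.8, repeats=5, seed=1)
        for chain in boot.sd:
            for prop, sd in boot.sd[chain].items():
                assert sd == 0.0

    def test_high_occupancy_edges_survive_all_repeats(self):
        spec = SyntheticSpec(
            n_residues_per_chain=8,
            n_frames=1000,
            planted_modes=[],
            dissociation_amplitude_stddev=0.0,
            noise_stddev=0.05,
            contact_targets=[(("A", 1), ("A", 5), 0.95)],
            seed=33,
        )
        model = build_toy_dimer(spec)
        traj, _ = generate_ensemble(model, spec)
        vec = np.zeros(3 * len(model.residues()))
        residues = model.residues()
        vec[3 * residues.index(("A", 1))] = 1.0
        vec[3 * residues.index(("A", 5))] = 1.0
        ms = make_modeset(model, [vec])
        cf = contact_frames(traj)
        rng = np.random.default_rng(7)
        n_take = int(0.8 * traj.n_frames)
        for _ in range(10):
            subset = rng.choice(traj.n_frames, size=n_take, replace=False)
            occ = occupancy_from_frames(cf, frame_subset=subset)
            nets = build_network(ms, 0, occ)
            edges = {e for n in nets for e in n.graph.edges}
            assert (("A", 1), ("A", 5)) in edges or (("A", 5), ("A", 1)) in edges

    def test_invalid_fraction_rejected(self, small_model, small_ensemble):
        traj, ms = self._setup(small_model, small_ensemble)
        with pytest.raises(ValidationError):
            bootstrap_networks(traj, ms, 0, fraction=1.2)
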