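"""Contact networks, communities, paths, H-bonds, dihedrals, Welch's test."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selexp.errors import (
    DegenerateStatisticsError,
    DomainError,
    SelectionError,
)
from selexp.structure_annotation import Atom, StructureModel
from selexp.trajectory_network import (
    ContactEdge,
    ContactNetwork,
    TrajectoryEnsemble,
    chi1_distribution,
    communities,
    contact_network,
    cross_correlation,
    dihedral_angle,
    hbond_occupancy,
    network_to_json,
    shortest_paths,
    welch_test,
)


def point_residue_topology(n: int) -> StructureModel:
    return StructureModel(
        tuple(Atom("A", i + 1, "", "ALA", "CA", "C", (20.0 * i, 0, 0))
              for i in range(n)),
        frozenset(),
    )


def ensemble_with_distances(pair_distances: list[float]) -> TrajectoryEnsemble:
    """Three residues; residue 1↔3 distance set per frame (2 is a spacer)."""
    topo = point_residue_topology(3)
    frames = np.zeros((len(pair_distances), 3, 3))
    rng = np.random.default_rng(0)
    for m, d in enumerate(pair_distances):
        frames[m, 0] = (0, 0, 0)
        frames[m, 1] = (50, 0, 0)
        frames[m, 2] = (d, 0, 0)
    frames += rng.normal(0, 1e-6, frames.shape)  # break zero variance
    return TrajectoryEnsemble(topo, frames)


class TestContactNetwork:
    def test_occupancy_eight_of_ten_keeps_edge(self):
        traj = ensemble_with_distances([3.0] * 8 + [10.0] * 2)
        net = contact_network(traj)
        (edge,) = net.edges
        assert {edge.i, edge.j} == {"A:1", "A:3"}
        assert edge.occupancy == pytest.approx(0.8)

    def test_occupancy_seven_of_ten_drops_edge(self):
        traj = ensemble_with_distances([3.0] * 7 + [10.0] * 3)
        assert contact_network(traj).edges == ()

    def test_sequence_adjacent_excluded(self):
        topo = point_residue_topology(2)
        frames = np.zeros((4, 2, 3))
        frames[:, 1] = (3.0, 0, 0)
        frames += np.random.default_rng(1).normal(0, 1e-6, frames.shape)
        traj = TrajectoryEnsemble(topo, frames)
        assert contact_network(traj).edges == ()
        net = contact_network(traj, exclude_adjacent=False)
        assert len(net.edges) == 1

    def test_perfectly_comoving_unit_correlation_zero_weight(self):
        # 10 static 3-D anchors pin the per-frame superposition; residues
        # 20 and 22 are in contact and share their displacement exactly
        rng = np.random.default_rng(2)
        k = np.arange(10)
        anchors = 20.0 * np.column_stack((k % 3, (k // 3) % 3, k // 9))
        base = np.vstack([anchors, [[100.0, 100, 100], [103.0, 100, 100]]])
        atoms = tuple(
            Atom("A", seq, "", "ALA", "CA", "C", tuple(base[i]))
            for i, seq in enumerate(list(range(1, 11)) + [20, 22])
        )
        frames = np.repeat(base[None].astype(float), 200, axis=0)
        shared = rng.normal(0, 0.5, (200, 3))
        frames[:, 10] += shared
        frames[:, 11] += shared
        frames += rng.normal(0, 1e-6, frames.shape)
        traj = TrajectoryEnsemble(StructureModel(atoms, frozenset()), frames)
        net = contact_network(traj)
        (edge,) = net.edges
        assert {edge.i, edge.j} == {"A:20", "A:22"}
        assert abs(edge.correlation) > 0.999
        assert edge.weight == pytest.approx(-math.log(abs(edge.correlation)), abs=1e-9)
        assert edge.weight < 1e-3

    def test_single_frame_degenerate(self):
        traj = ensemble_with_distances([3.0])
        with pytest.raises(DegenerateStatisticsError):
            contact_network(traj)

    def test_edge_set_monotone_in_cutoff_and_occupancy(self):
        traj = ensemble_with_distances([3.0] * 6 + [4.2] * 2 + [10.0] * 2)
        def edge_set(cutoff, occ):
            return {
                frozenset((e.i, e.j))
                for e in contact_network(traj, cutoff=cutoff, occupancy_min=occ).edges
            }
        assert edge_set(3.5, 0.5) <= edge_set(4.5, 0.5)
        assert edge_set(4.5, 0.9) <= edge_set(4.5, 0.5)

    def test_correlation_matrix_properties(self):
        rng = np.random.default_rng(3)
        topo = point_residue_topology(5)
        frames = np.repeat(
            np.array([[20.0 * i, 0, 0] for i in range(5)])[None], 100, axis=0
        )
        frames = frames + rng.normal(0, 0.3, frames.shape)
        traj = TrajectoryEnsemble(topo, frames)
        order = [("A", str(i + 1)) for i in range(5)]
        corr = cross_correlation(traj, list(range(5)))
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        assert (np.abs(corr) <= 1.0 + 1e-12).all()


class TestCommunities:
    @staticmethod
    def _net(graph: nx.Graph) -> ContactNetwork:
        edges = tuple(
            ContactEdge(str(u), str(v), 1.0, 1.0, 1.0) for u, v in graph.edges
        )
        return ContactNetwork(tuple(str(n) for n in graph.nodes), edges)

    def test_two_cliques_with_bridge(self):
        g = nx.Graph()
        for base in (0, 4):
            for i in range(base, base + 4):
                for j in range(i + 1, base + 4):
                    g.add_edge(i, j)
        g.add_edge(0, 4)
        part = communities(self._net(g))
        groups = {frozenset(c) for c in part.communities()}
        assert groups == {
            frozenset({"0", "1", "2", "3"}), frozenset({"4", "5", "6", "7"})
        }
        # brute-force maximum-modularity 2-partition agrees
        import itertools
        nodes = [str(n) for n in g.nodes]
        gs = nx.relabel_nodes(g, str)
        best_q = -1.0
        for r in range(1, len(nodes)):
            for left in itertools.combinations(nodes, r):
                q = nx.community.modularity(
                    gs, [set(left), set(nodes) - set(left)]
                )
                best_q = max(best_q, q)
        assert part.modularity == pytest.approx(best_q, abs=1e-12)

    def test_disconnected_components_are_communities(self):
        g = nx.Graph([(0, 1), (2, 3)])
        part = communities(self._net(g))
        assert {frozenset(c) for c in part.communities()} == {
            frozenset({"0", "1"}), frozenset({"2", "3"})
        }

    def test_single_triangle_one_community(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2)])
        part = communities(self._net(g))
        assert part.communities() == [{"0", "1", "2"}]

    def test_empty_graph_rejected(self):
        net = ContactNetwork(("a", "b"), ())
        with pytest.raises(DomainError):
            communities(net)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_recovers_planted_two_blocks(self, seed):
        """Noiseless planted partition: dense blocks, single inter-block edge."""
        rng = np.random.default_rng(seed)
        sizes = (int(rng.integers(4, 7)), int(rng.integers(4, 7)))
        g = nx.Graph()
        offset = 0
        blocks = []
        for size in sizes:
            nodes = list(range(offset, offset + size))
            blocks.append({str(n) for n in nodes})
            for i in nodes:
                for j in nodes:
                    if i < j:
                        g.add_edge(i, j)
            offset += size
        g.add_edge(0, sizes[0])
        part = communities(self._net(g))
        assert {frozenset(c) for c in part.communities()} == {
            frozenset(b) for b in blocks
        }


class TestShortestPaths:
    @staticmethod
    def _weighted_net(edges) -> ContactNetwork:
        nodes = sorted({str(n) for e in edges for n in e[:2]})
        return ContactNetwork(
            tuple(nodes),
            tuple(ContactEdge(str(u), str(v), 1.0, 1.0, w) for u, v, w in edges),
        )

    def test_path_graph(self):
        net = self._weighted_net([("a", "b", 1.0), ("b", "c", 1.0)])
        (res,) = shortest_paths(net, ["a"], ["c"])
        assert res.path == ("a", "b", "c")
        assert res.total_weight == pytest.approx(2.0)

    def test_two_hop_beats_heavy_direct_edge(self):
        net = self._weighted_net(
            [("a", "c", 5.0), ("a", "b", 1.0), ("b", "c", 1.0)]
        )
        (res,) = shortest_paths(net, ["a"], ["c"])
        assert res.path == ("a", "b", "c")

    def test_unreachable_reported_infinite(self):
        net = self._weighted_net([("a", "b", 1.0), ("c", "d", 1.0)])
        (res,) = shortest_paths(net, ["a"], ["d"])
        assert math.isinf(res.total_weight) and res.path == ()

    def test_unknown_node(self):
        net = self._weighted_net([("a", "b", 1.0)])
        with pytest.raises(SelectionError):
            shortest_paths(net, ["a"], ["zz"])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_single_source_oracle_on_random_graphs(self, seed):
        """Floyd–Warshall distances equal Dijkstra's on random 8-node graphs."""
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(8, 0.4, seed=int(seed % 2**16))
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 5.0))
        net = self._weighted_net(
            [(u, v, g[u][v]["weight"]) for u, v in g.edges]
        )
        nodes = list(net.nodes)
        if not nodes:
            return
        results = shortest_paths(net, nodes, nodes)
        gs = nx.relabel_nodes(g, str)
        for res in results:
            try:
                expected = nx.dijkstra_path_length(gs, res.source, res.sink)
            except nx.NetworkXNoPath:
                expected = math.inf
            except nx.NodeNotFound:
                continue
            assert res.total_weight == pytest.approx(expected, abs=1e-9)

    def test_triangle_inequality_over_returned_pairs(self):
        net = self._weighted_net(
            [("a", "b", 1.0), ("b", "c", 2.0), ("a", "c", 2.5), ("c", "d", 1.0)]
        )
        nodes = list(net.nodes)
        dist = {
            (r.source, r.sink): r.total_weight
            for r in shortest_paths(net, nodes, nodes)
        }
        for i in nodes:
            for j in nodes:
                for k in nodes:
                    assert dist[(i, j)] <= dist[(i, k)] + dist[(k, j)] + 1e-9


def hbond_ensemble(da_distance: float, angle_deg: float) -> TrajectoryEnsemble:
    """Donor N, its hydrogen, and acceptor O at a chosen geometry.

    H sits 1.0 Å from the donor; the acceptor is placed so that the
    D–H–A angle equals ``angle_deg`` and |D–A| = ``da_distance``.
    """
    theta = math.radians(180.0 - angle_deg)  # angle at H between HD and HA
    h = np.array([1.0, 0.0, 0.0])
    # direction from H to A making (180 - angle) with the H->D direction
    hd = -h / np.linalg.norm(h)
    # rotate hd by (180 - angle) in the xy-plane
    c, s = math.cos(math.pi - theta), math.sin(math.pi - theta)
    ha_dir = np.array([c * hd[0] - s * hd[1], s * hd[0] + c * hd[1], 0.0])
    # pick |HA| so that |DA| = da_distance
    # D=origin; A = h + r*ha_dir; solve |A| = da_distance for r > 0
    b = 2 * float(h @ ha_dir)
    cq = float(h @ h) - da_distance**2
    r = (-b + math.sqrt(b * b - 4 * cq)) / 2
    a = h + r * ha_dir
    atoms = (
        Atom("A", 1, "", "ASN", "ND2", "N", (0, 0, 0)),
        Atom("A", 1, "", "ASN", "HD21", "H", tuple(h)),
        Atom("A", 3, "", "SER", "OG", "O", tuple(a)),
    )
    topo = StructureModel(atoms, frozenset())
    frames = np.array([[atom.xyz for atom in atoms]])
    return TrajectoryEnsemble(topo, frames)


class TestHBonds:
    DONOR = ("A", "1", "ND2")
    ACCEPTOR = ("A", "3", "OG")

    @pytest.mark.parametrize(
        "distance,angle,expected",
        [(3.4, 180.0, 1.0), (3.6, 180.0, 0.0), (3.0, 100.0, 0.0),
         (3.4, 120.0, 1.0)],
    )
    def test_geometric_criteria(self, distance, angle, expected):
        traj = hbond_ensemble(distance, angle)
        (res,) = hbond_occupancy(traj, [(self.DONOR, self.ACCEPTOR)])
        assert res.occupancy == expected
        # verify the constructed geometry is what we claim
        d = np.array(traj.topology.atoms[0].xyz)
        h = np.array(traj.topology.atoms[1].xyz)
        a = np.array(traj.topology.atoms[2].xyz)
        assert np.linalg.norm(d - a) == pytest.approx(distance, abs=1e-9)
        v1, v2 = d - h, a - h
        got = math.degrees(
            math.acos(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2))
        )
        assert got == pytest.approx(angle, abs=1e-6)

    def test_occupancy_counts_frames(self):
        hit = hbond_ensemble(3.4, 180.0)
        miss = hbond_ensemble(3.6, 180.0)
        frames = np.concatenate([hit.frames] * 3 + [miss.frames])
        traj = TrajectoryEnsemble(hit.topology, frames)
        (res,) = hbond_occupancy(traj, [(self.DONOR, self.ACCEPTOR)])
        assert res.occupancy == pytest.approx(0.75)

    def test_donor_without_hydrogen_error(self):
        atoms = (
            Atom("A", 1, "", "ASN", "ND2", "N", (0, 0, 0)),
            Atom("A", 3, "", "SER", "OG", "O", (3, 0, 0)),
        )
        traj = TrajectoryEnsemble(
            StructureModel(atoms, frozenset()),
            np.array([[a.xyz for a in atoms]]),
        )
        with pytest.raises(SelectionError, match="hydrogen"):
            hbond_occupancy(traj, [(self.DONOR, self.ACCEPTOR)])


def chi1_topology(gamma_xyz, resname="LEU", gamma_name="CG"):
    atoms = (
        Atom("A", 1, "", resname, "N", "N", (1.0, 0.0, 0.0)),
        Atom("A", 1, "", resname, "CA", "C", (0.0, 0.0, 0.0)),
        Atom("A", 1, "", resname, "CB", "C", (0.0, 0.0, 1.5)),
        Atom("A", 1, "", resname, gamma_name, "C", tuple(gamma_xyz)),
    )
    topo = StructureModel(atoms, frozenset())
    frames = np.array([[a.xyz for a in atoms]])
    return TrajectoryEnsemble(topo, frames)


class TestChi1:
    def _gamma(self, angle_deg):
        a = math.radians(angle_deg)
        return (math.cos(a), math.sin(a), 1.5)

    def test_plus_sixty_analytic(self):
        traj = chi1_topology(self._gamma(60.0))
        (series,) = chi1_distribution(traj, [("A", "1")])
        assert series.chi1[0] == pytest.approx(60.0, abs=1e-6)

    def test_mirror_antisymmetry(self):
        traj = chi1_topology(self._gamma(60.0))
        mirrored = TrajectoryEnsemble(
            traj.topology, traj.frames * np.array([1.0, -1.0, 1.0])
        )
        (series,) = chi1_distribution(mirrored, [("A", "1")])
        assert series.chi1[0] == pytest.approx(-60.0, abs=1e-6)

    def test_180_is_positive(self):
        traj = chi1_topology(self._gamma(180.0))
        (series,) = chi1_distribution(traj, [("A", "1")])
        assert series.chi1[0] == pytest.approx(180.0, abs=1e-6)

    def test_branched_residue_uses_cg1(self):
        traj = chi1_topology(self._gamma(-60.0), resname="VAL", gamma_name="CG1")
        (series,) = chi1_distribution(traj, [("A", "1")])
        assert series.chi1[0] == pytest.approx(-60.0, abs=1e-6)

    def test_missing_atom_named_error(self):
        traj = chi1_topology(self._gamma(60.0), resname="VAL", gamma_name="CG")
        with pytest.raises(SelectionError, match="CG1"):
            chi1_distribution(traj, [("A", "1")])

    def test_matches_mdanalysis_convention(self):
        """Cross-check the dihedral sign against MDAnalysis on random points."""
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.normal(size=(4, 3))
            expected = math.degrees(
                float(calc_dihedrals(p[0], p[1], p[2], p[3]))
            )
            # MDAnalysis works in float32; compare at that precision
            assert dihedral_angle(*p) == pytest.approx(expected, abs=1e-4)


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_textbook_values(self):
        from scipy import stats

        t, df, p = welch_test([1, 2, 3], [2, 3, 4])
        ref = stats.ttest_ind([1, 2, 3], [2, 3, 4], equal_var=False)
        assert t == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))
        assert df == pytest.approx(4.0)  # equal variances, equal n
        # hand value: t = -1/sqrt(2/3)
        assert t == pytest.approx(-1.0 / math.sqrt(2.0 / 3.0), abs=1e-12)

    def test_constant_samples_equal_means(self):
        t, df, p = welch_test([0.5, 0.5], [0.5, 0.5])
        assert (t, p) == (0.0, 1.0)

    def test_planted_effect_reaches_significance(self):
        rng = np.random.default_rng(11)
        a = np.clip(rng.normal(0.9, 0.03, 5), 0, 1)
        b = np.clip(rng.normal(0.3, 0.03, 5), 0, 1)
        _, _, p = welch_test(a, b)
        assert p < 1e-3

    def test_small_samples_rejected(self):
        with pytest.raises(DomainError):
            welch_test([1.0], [1.0, 2.0])


class TestSerialisation:
    def test_network_json_schema(self):
        import json

        net = ContactNetwork(
            ("a", "b"), (ContactEdge("a", "b", 0.9, 0.5, 0.7),)
        )
        doc = json.loads(network_to_json(net))
        assert doc["schema_version"] == 1
        assert doc["nodes"] == ["a", "b"]
        assert doc["edges"][0]["occupancy"] == 0.9
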