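"""Source-state assignment and lineage-graph construction."""

import numpy as np
import pytest

from morphlineage import (
    assign_source_states,
    build_lineage_graph,
    chain_pairs,
    chain_timepoints,
    simulate_timepoint_series,
    TimeSeriesSimSpec,
)

from conftest import brute_force_assignments, brute_force_graph, make_slice


def random_instance(rng, n_clusters, n_cells, d=2):
    centers = rng.uniform(-20, 20, size=(n_clusters, d))
    labels = rng.integers(0, n_clusters, size=n_cells)
    earlier = make_slice(
        0,
        centers[labels] + rng.normal(0, 2.0, size=(n_cells, d)),
        [f"k{c}" for c in labels],
        prefix="e",
    )
    labels2 = rng.integers(0, n_clusters, size=n_cells)
    later = make_slice(
        1,
        centers[labels2] + rng.normal(0, 2.0, size=(n_cells, d)),
        [f"k{c}" for c in labels2],
        prefix="l",
    )
    return earlier, later


class TestAssignSourceStates:
    def test_single_earlier_cell_assigns_its_cluster(self):
        earlier = make_slice(0, [[0.0, 0.0]], ["A"])
        later = make_slice(1, [[5.0, 5.0]], ["X"])
        (a,) = assign_source_states(earlier, later, k=1)
        assert a.assigned_source_cluster == "A"
        assert not a.tie_broken

    def test_modal_cluster_of_ten_neighbors(self):
        # 10 earlier cells, 6xA closer-packed with 4xB; modal cluster wins
        pos = [[i, 0.0] for i in range(10)]
        clusters = ["A"] * 6 + ["B"] * 4
        earlier = make_slice(0, pos, clusters)
        later = make_slice(1, [[4.5, 0.0]], ["X"])
        (a,) = assign_source_states(earlier, later, k=10)
        assert a.assigned_source_cluster == "A"
        assert not a.tie_broken
        assert len(a.neighbor_ids) == 10

    def test_frequency_tie_uses_nearest_spot(self):
        # 5xA and 5xB among the 10 nearest; the single nearest is B
        pos = [[0.1, 0.0]] + [[i + 1.0, 0.0] for i in range(9)]
        clusters = ["B"] + ["A", "B", "A", "B", "A", "B", "A", "A", "B"]
        assert clusters.count("A") == clusters.count("B") == 5
        earlier = make_slice(0, pos, clusters)
        later = make_slice(1, [[0.0, 0.0]], ["X"])
        (a,) = assign_source_states(earlier, later, k=10)
        assert a.assigned_source_cluster == "B"
        assert a.tie_broken

    def test_k_larger_than_earlier_uses_all(self):
        earlier = make_slice(0, [[0, 0], [1, 0], [2, 0]], ["A", "A", "B"])
        later = make_slice(1, [[0, 1]], ["X"])
        (a,) = assign_source_states(earlier, later, k=10)
        assert len(a.neighbor_ids) == 3
        assert a.assigned_source_cluster == "A"

    def test_dimension_mismatch_raises(self):
        earlier = make_slice(0, [[0, 0]], ["A"])
        later = make_slice(1, [[0, 0, 0]], ["X"])
        with pytest.raises(ValueError, match="dimension"):
            assign_source_states(earlier, later)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(5):
            earlier, later = random_instance(rng, 4, 60)
            got = {
                a.later_cell_id: (a.assigned_source_cluster, a.tie_broken)
                for a in assign_source_states(earlier, later, k=10)
            }
            assert got == brute_force_assignments(earlier, later, 10)


class TestBuildLineageGraph:
    def test_strict_threshold_on_exact_fraction(self):
        # later cluster of 10 cells: 3 assigned from A (0.30, retained),
        # 2 from B (0.20, NOT retained: "more than 20%" is strict)
        earlier = make_slice(0, [[0, 0], [10, 0], [20, 0]], ["A", "B", "C"])
        pos = [[0, 0]] * 3 + [[10, 0]] * 2 + [[20, 0]] * 5
        later = make_slice(1, pos, ["X"] * 10)
        asg = assign_source_states(earlier, later, k=1)
        g = build_lineage_graph(asg, earlier, later, threshold=0.20)
        by_src = {e.earlier_cluster: e for e in g.edges}
        assert by_src["A"].fraction == pytest.approx(0.30) and by_src["A"].retained
        assert by_src["B"].fraction == pytest.approx(0.20) and not by_src["B"].retained
        assert by_src["C"].fraction == pytest.approx(0.50) and by_src["C"].retained

    def test_single_source_gives_fraction_one(self):
        earlier = make_slice(0, [[0, 0], [1, 1]], ["A", "A"])
        later = make_slice(1, [[0, 0], [1, 0], [0, 1]], ["X", "X", "Y"])
        asg = assign_source_states(earlier, later, k=2)
        g = build_lineage_graph(asg, earlier, later)
        assert {e.later_cluster: e.fraction for e in g.edges} == {"X": 1.0, "Y": 1.0}
        assert all(e.retained for e in g.edges)

    def test_invalid_threshold_raises(self):
        earlier = make_slice(0, [[0, 0]], ["A"])
        later = make_slice(1, [[0, 0]], ["X"])
        asg = assign_source_states(earlier, later, k=1)
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError, match="threshold"):
                build_lineage_graph(asg, earlier, later, threshold=bad)

    def test_matches_brute_force_graph(self, rng):
        earlier, later = random_instance(rng, 3, 30)
        asg = assign_source_states(earlier, later, k=10)
        g = build_lineage_graph(asg, earlier, later, threshold=0.20)
        oracle = brute_force_graph(
            {a.later_cell_id: (a.assigned_source_cluster, a.tie_broken) for a in asg},
            later,
            0.20,
        )
        got = {
            (e.earlier_cluster, e.later_cluster): (e.fraction, e.retained)
            for e in g.edges
        }
        assert got.keys() == oracle.keys()
        for key in got:
            assert got[key][0] == pytest.approx(oracle[key][0])
            assert got[key][1] == oracle[key][1]

    def test_threshold_monotonicity(self, rng):
        earlier, later = random_instance(rng, 4, 50)
        asg = assign_source_states(earlier, later, k=10)
        edge_sets = []
        for tau in (0.0, 0.1, 0.2, 0.4, 0.8):
            g = build_lineage_graph(asg, earlier, later, threshold=tau)
            edge_sets.append(g.retained_edge_set())
        for smaller, larger in zip(edge_sets[1:], edge_sets[:-1]):
            assert smaller <= larger

    def test_permutation_invariance(self, rng):
        earlier, later = random_instance(rng, 3, 40)
        perm = rng.permutation(later.n_cells)
        shuffled = make_slice(
            1,
            later.embedding[perm],
            [later.cluster_labels[i] for i in perm],
            prefix="l",
        )
        # same geometry, same labels, different cell order
        g1 = build_lineage_graph(
            assign_source_states(earlier, later, k=10), earlier, later
        )
        g2 = build_lineage_graph(
            assign_source_states(earlier, shuffled, k=10), earlier, shuffled
        )
        key = lambda g: {
            (e.earlier_cluster, e.later_cluster): (e.fraction, e.retained)
            for e in g.edges
        }
        assert key(g1) == key(g2)


class TestChaining:
    def test_identity_series_gives_linear_chain(self):
        slices = [
            make_slice(t, [[0, 0], [10, 0]], ["A", "B"], prefix=f"t{t}")
            for t in range(3)
        ]
        g = chain_timepoints(slices, k=1, threshold=0.2)
        assert g.retained_edge_set() == {
            ("A", 0, "A", 1), ("B", 0, "B", 1),
            ("A", 1, "A", 2), ("B", 1, "B", 2),
        }
        assert set(g.nodes) == {(c, t) for c in "AB" for t in range(3)}

    def test_fewer_than_two_slices_raises(self):
        sl = make_slice(0, [[0, 0]], ["A"])
        with pytest.raises(ValueError):
            chain_timepoints([sl])

    def test_reversed_order_gives_reversed_direction_graph(self):
        slices = [
            make_slice(t, [[0, 0], [10, 0]], ["A", "B"], prefix=f"t{t}")
            for t in range(3)
        ]
        fwd = chain_timepoints(slices, k=1)
        rev = chain_timepoints(slices[::-1], k=1)
        assert fwd.retained_edge_set() != rev.retained_edge_set()
        assert ("A", 2, "A", 1) in rev.retained_edge_set()

    def test_chain_pairs_recovers_generator_truth(self):
        tm = np.array([[0.6, 0.4, 0.0], [0.3, 0.4, 0.3], [0.0, 0.5, 0.5]])
        spec = TimeSeriesSimSpec(
            n_timepoints=4,
            clusters_per_timepoint=3,
            cells_per_cluster=50,
            transition_matrix=tm,
            cluster_separation=10.0,
            cluster_sd=1.0,
            seed=11,
        )
        pairs, truth = simulate_timepoint_series(spec)
        g = chain_pairs(pairs, k=10, threshold=0.20)
        expected = {
            (e.earlier_cluster, e.earlier_timepoint, e.later_cluster, e.later_timepoint)
            for e in truth.edges
            if e.fraction > 0.20
        }
        assert g.retained_edge_set() == expected
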