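"""Network container, file formats, planted generator and perturbations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyncomm import (
    Partition,
    QuotientSpec,
    WeightedNetwork,
    is_equitable,
    perturb,
    planted_equitable_network,
    read_network,
    read_partition,
    write_network,
    write_partition,
)
from dyncomm.network import random_quotient


class TestWeightedNetwork:
    def test_rejects_non_square(self):
        with pytest.raises(ValueError, match="square"):
            WeightedNetwork(np.zeros((2, 3)))

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="unique"):
            WeightedNetwork(np.zeros((2, 2)), labels=("a", "a"))

    def test_default_labels(self):
        net = WeightedNetwork(np.zeros((3, 3)))
        assert net.labels == ("0", "1", "2")


class TestPartition:
    def test_canonical_first_appearance(self):
        # labels renumbered by order of first appearance
        p = Partition([2, 2, 0, 1, 0])
        assert list(p.assignment) == [0, 0, 1, 2, 1]
        assert p.k == 3

    def test_equality_up_to_relabeling(self):
        assert Partition([1, 1, 0]) == Partition([0, 0, 2])

    def test_indicator_round_trip(self):
        p = Partition([0, 1, 0, 2])
        E = p.indicator()
        assert np.all(E.sum(axis=1) == 1)
        assert np.all(E.sum(axis=0) >= 1)
        assert Partition.from_indicator(E) == p

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=30))
    @settings(deadline=None)
    def test_canonicalization_idempotent(self, assignment):
        p = Partition(assignment)
        assert Partition(p.assignment) == p
        # cluster indices form a contiguous 0..k-1 range
        assert set(p.assignment) == set(range(p.k))


class TestIO:
    def test_edgelist_transcription(self, tmp_path):
        # receiver convention: entry (row=target, col=source)
        f = tmp_path / "net.tsv"
        f.write_text("a b 2.0\nb c 1.0\nc a 0.5\n")
        net = read_network(f, format="edgelist")
        assert net.n_nodes == 3
        b, a, c = net.index_of("b"), net.index_of("a"), net.index_of("c")
        assert net.weights[b, a] == 2.0
        assert net.weights[c, b] == 1.0
        assert net.weights[a, c] == 0.5
        assert np.count_nonzero(net.weights) == 3

    def test_dense_symmetric_dyad(self, tmp_path):
        f = tmp_path / "net.txt"
        f.write_text("0 1\n1 0\n")
        net = read_network(f, format="dense")
        assert np.array_equal(net.weights, np.array([[0.0, 1.0], [1.0, 0.0]]))

    def test_dense_non_square_raises(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("0 1 2\n1 0 3\n")
        with pytest.raises(ValueError, match="square"):
            read_network(f, format="dense")

    def test_malformed_line_names_lineno(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("a b 1.0\na c oops\n")
        with pytest.raises(ValueError, match="line 2"):
            read_network(f, format="edgelist")

    def test_self_loop_rejected_by_default(self, tmp_path):
        f = tmp_path / "loop.tsv"
        f.write_text("a a 1.0\n")
        with pytest.raises(ValueError, match="self-loop"):
            read_network(f, format="edgelist")
        net = read_network(f, format="edgelist", allow_self_loops=True)
        assert net.weights[0, 0] == 1.0

    def test_duplicate_edges_accumulate(self, tmp_path, caplog):
        f = tmp_path / "dup.tsv"
        f.write_text("a b 1.0\na b 2.5\n")
        with caplog.at_level("WARNING"):
            net = read_network(f, format="edgelist")
        assert net.weights[net.index_of("b"), net.index_of("a")] == 3.5
        assert any("duplicate" in r.message for r in caplog.records)

    def test_matrixmarket_coordinates(self, tmp_path):
        f = tmp_path / "net.mtx"
        f.write_text(
            "%%MatrixMarket matrix coordinate real general\n"
            "3 3 2\n"
            "1 2 4.5\n"
            "3 1 -1.0\n"
        )
        net = read_network(f, format="matrixmarket")
        expected = np.zeros((3, 3))
        expected[0, 1] = 4.5
        expected[2, 0] = -1.0
        assert np.array_equal(net.weights, expected)

    @pytest.mark.parametrize("fmt", ["dense", "edgelist", "matrixmarket"])
    def test_round_trip(self, fmt, tmp_path, rng):
        W = rng.uniform(0, 1, (10, 10)) * (rng.uniform(0, 1, (10, 10)) < 0.4)
        np.fill_diagonal(W, 0.0)
        net = WeightedNetwork(W)
        f = tmp_path / f"net.{fmt}"
        write_network(net, f, format=fmt)
        back = read_network(f, format=fmt)
        assert back.labels == net.labels
        np.testing.assert_allclose(back.weights, net.weights, atol=1e-12, rtol=0)

    def test_empty_network_edgelist(self, tmp_path):
        net = WeightedNetwork(np.zeros((4, 4)))
        f = tmp_path / "empty.tsv"
        write_network(net, f, format="edgelist")
        back = read_network(f, format="edgelist")
        assert back.n_nodes == 4 and not back.weights.any()

    def test_partition_file_round_trip(self, tmp_path):
        net = WeightedNetwork(np.zeros((4, 4)), labels=("n1", "n2", "n3", "n4"))
        part = Partition([0, 1, 0, 2])
        f = tmp_path / "part.tsv"
        write_partition(part, f, labels=net.labels)
        assert read_partition(f, net) == part


class TestPlantedGenerator:
    def test_block_sums_exact(self, planted50):
        net, part = planted50
        spec_Q = random_quotient(5, seed=1)
        for u, rows in enumerate(part.clusters()):
            for v, cols in enumerate(part.clusters()):
                block = net.weights[np.ix_(rows, cols)]
                np.testing.assert_allclose(block.sum(axis=1), spec_Q[u, v],
                                           atol=1e-12, rtol=0)
                # doubly balanced: constant column sums as well
                np.testing.assert_allclose(
                    block.sum(axis=0), spec_Q[u, v] * rows.size / cols.size,
                    atol=1e-12, rtol=0)

    def test_zero_diagonal(self, planted50):
        net, _ = planted50
        assert not np.diag(net.weights).any()

    @pytest.mark.parametrize("seed", range(20))
    def test_equitable_for_random_specs(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        sizes = tuple(int(s) for s in rng.integers(2, 7, size=k))
        spec = QuotientSpec(sizes, random_quotient(k, seed=seed),
                            block_density=float(rng.uniform(0.3, 1.0)))
        net, part = planted_equitable_network(spec, seed=seed)
        assert is_equitable(net, part, tol=1e-9)

    def test_random_weights_variant_still_equitable(self):
        spec = QuotientSpec((4, 3, 5), random_quotient(3, seed=2))
        net, part = planted_equitable_network(spec, seed=2, random_weights=True)
        assert is_equitable(net, part, tol=1e-9)
        # heterogeneous weights: some block has more than one distinct value
        vals = np.unique(net.weights[np.ix_(range(4), range(4, 7))].round(12))
        assert vals.size > 1

    def test_single_cluster_row_sums(self):
        spec = QuotientSpec((6,), np.array([[3.0]]))
        net, part = planted_equitable_network(spec, seed=0)
        np.testing.assert_allclose(net.weights.sum(axis=1), 3.0, atol=1e-12)
        assert part.k == 1

    def test_singleton_clusters_reproduce_quotient(self):
        Q = np.array([[0.0, 2.0], [0.7, 0.0]])
        spec = QuotientSpec((1, 1), Q)
        net, _ = planted_equitable_network(spec, seed=0)
        np.testing.assert_allclose(net.weights, Q, atol=1e-12)

    def test_infeasible_self_loop_spec(self):
        spec = QuotientSpec((1, 2), np.array([[1.0, 1.0], [1.0, 1.0]]))
        with pytest.raises(ValueError, match="infeasible"):
            planted_equitable_network(spec, seed=0)


class TestPerturb:
    def test_epsilon_zero_is_identity(self, planted50):
        net, _ = planted50
        for kind in ("type1", "type2"):
            out = perturb(net, 0.0, kind, seed=3)
            np.testing.assert_array_equal(out.weights, net.weights)

    def test_type1_preserves_zero_pattern(self, planted50):
        net, _ = planted50
        out = perturb(net, 5.0, "type1", seed=3)
        assert np.array_equal(out.weights == 0, net.weights == 0)

    def test_type2_touches_zeros(self, planted50):
        net, _ = planted50
        out = perturb(net, 1.0, "type2", seed=3)
        assert np.all(out.weights[net.weights == 0] != 0)

    def test_deterministic_given_seed(self, planted50):
        net, _ = planted50
        a = perturb(net, 0.5, "type2", seed=9)
        b = perturb(net, 0.5, "type2", seed=9)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_unknown_kind(self, planted50):
        with pytest.raises(ValueError, match="kind"):
            perturb(planted50[0], 0.1, "type3", seed=0)
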