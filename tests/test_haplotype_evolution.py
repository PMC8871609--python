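"""Haplogroup partition, distances, neighbor joining, and TMRCA."""

import numpy as np
import pytest

from colsel import (
    estimate_mu,
    fixed_differences,
    is_monophyletic,
    mutations_from_mrca,
    neighbor_joining,
    p_distance_matrix,
    partition_core_haplogroups,
    simulate_two_haplogroup_locus,
    thomson_tmrca,
)
from colsel.haplotypes import DistanceMatrix, Tree, read_newick, write_newick
from colsel.synthetic import TwoHaplogroupParams

from conftest import small_haplotype_matrix


class TestPartition:
    def test_two_distinct_haplotypes_form_two_groups(self):
        hm = small_haplotype_matrix([[1, 1, 0, 0], [1, 1, 0, 0]])
        part = partition_core_haplogroups(hm)
        assert set(part.assignment[:2]) != set(part.assignment[2:]) or (
            part.assignment[:2].tolist() != part.assignment[2:].tolist()
        )
        assert len(set(part.assignment.tolist())) == 2
        assert part.separation > 0.9

    def test_all_identical_is_degenerate(self):
        hm = small_haplotype_matrix([[1, 1, 1, 1]])
        with pytest.raises(ValueError, match="identical"):
            partition_core_haplogroups(hm)

    def test_recovers_simulator_truth_across_seeds(self):
        for seed in range(30):
            hm, truth = simulate_two_haplogroup_locus(
                TwoHaplogroupParams(n_per_group=8, seed=seed)
            )
            part = partition_core_haplogroups(hm)
            same = np.array_equal(part.assignment, truth.group)
            flipped = np.array_equal(1 - part.assignment, truth.group)
            assert same or flipped


class TestFixedDifferences:
    def test_identical_groups_have_none(self):
        # both groups contain the same two haplotypes
        hm = small_haplotype_matrix([[1, 0, 1, 0], [0, 1, 0, 1]])
        assert fixed_differences(hm, [0, 0, 1, 1]).count == 0

    def test_matches_simulator_stem_mutations(self, two_hap):
        hm, truth = two_hap
        fd = fixed_differences(hm, truth.group)
        assert fd.count == len(truth.fixed_diff_positions)
        assert np.array_equal(fd.positions, truth.fixed_diff_positions)

    def test_site_entirely_missing_in_one_group_excluded(self):
        hm = small_haplotype_matrix([[-1, -1, 1, 1], [1, 0, 1, 0]])
        fd = fixed_differences(hm, [0, 0, 1, 1])
        assert fd.count == 0 and fd.n_excluded == 1


class TestPDistance:
    def test_identical_pair_is_zero(self):
        hm = small_haplotype_matrix([[0, 0, 1], [1, 1, 0], [1, 1, 0]])
        dm = p_distance_matrix(hm)
        assert dm.matrix[0, 1] == 0

    def test_two_of_three_variable_sites(self):
        # 000 vs 011 across 3 variable sites -> 2/3
        hm = small_haplotype_matrix(
            [[0, 0, 1, 1], [0, 1, 0, 1], [0, 1, 1, 0]]
        )
        dm = p_distance_matrix(hm)
        assert dm.matrix[0, 1] == pytest.approx(2 / 3)

    def test_symmetric_zero_diagonal_brute_force(self):
        rng = np.random.default_rng(8)
        cols = rng.integers(0, 2, (10, 12))
        cols[0] = [0, 1] * 6  # guarantee variability
        hm = small_haplotype_matrix(cols)
        dm = p_distance_matrix(hm, metric="raw_differences")
        for i in range(12):
            assert dm.matrix[i, i] == 0
            for j in range(12):
                assert dm.matrix[i, j] == dm.matrix[j, i]
                assert dm.matrix[i, j] == np.sum(hm.alleles[i] != hm.alleles[j])


def random_additive_tree(rng, n_taxa):
    """Random binary tree; returns (leaf distance matrix oracle, labels).

    Distances are path sums over the generating branch lengths, computed
    independently of any reconstruction code.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # start from a 3-leaf star, then attach leaves to random edges
    nodes = {0: {}, 1: {}, 2: {}, "root": {}}
    edges = {}

    def add_edge(a, b, w):
        edges[(a, b)] = w
        nodes.setdefault(a, {})
        nodes.setdefault(b, {})

    for i in range(3):
        add_edge("root", i, rng.uniform(0.1, 2.0))
    nxt = ["x0"]
    for i in range(3, n_taxa):
        (a, b) = list(edges)[rng.integers(len(edges))]
        w = edges.pop((a, b))
        mid = nxt.pop()
        nxt.append(f"x{i}")
        split = rng.uniform(0.2, 0.8)
        add_edge(a, mid, w * split)
        add_edge(mid, b, w * (1 - split))
        add_edge(mid, i, rng.uniform(0.1, 2.0))
    # all-pairs path lengths by BFS
    adj = {}
    for (a, b), w in edges.items():
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        dist = {i: 0.0}
        stack = [i]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j in range(n_taxa):
            D[i, j] = dist[j]
    return D, labels


class TestNeighborJoining:
    def test_three_taxa_hand_solved_lengths(self):
        dm = DistanceMatrix(
            matrix=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
            labels=["A", "B", "C"], metric="raw_differences",
        )
        tree = neighbor_joining(dm)
        pl = tree.path_lengths()
        assert pl[frozenset({"A", "B"})] == pytest.approx(2)
        assert pl[frozenset({"A", "C"})] == pytest.approx(4)
        # pendant lengths: A:1, B:1, C:3
        assert "C:3" in tree.newick.replace(".0", "")

    def test_four_taxa_additive_matrix_recovered_exactly(self):
        # generating tree ((A:1,B:2):1,(C:3,D:4))
        M = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        dm = DistanceMatrix(matrix=M, labels=list("ABCD"), metric="raw_differences")
        tree = neighbor_joining(dm)
        pl = tree.path_lengths()
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert pl[frozenset({a, b})] == pytest.approx(M[i, j], abs=1e-9)

    def test_star_distances_give_zero_internal_branch(self):
        M = np.full((4, 4), 2.0)
        np.fill_diagonal(M, 0.0)
        dm = DistanceMatrix(matrix=M, labels=list("ABCD"), metric="raw_differences")
        pl = neighbor_joining(dm).path_lengths()
        for pair, d in pl.items():
            assert d == pytest.approx(2.0, abs=1e-9)

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            D, labels = random_additive_tree(rng, n)
            dm = DistanceMatrix(matrix=D, labels=labels, metric="raw_differences")
            pl = neighbor_joining(dm).path_lengths()
            for i in range(n):
                for j in range(i + 1, n):
                    assert pl[frozenset({labels[i], labels[j]})] == pytest.approx(
                        D[i, j], abs=1e-8
                    )

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(matrix=np.array([[0, 1], [1, 0]], float),
                            labels=["A", "B"], metric="raw_differences")
        with pytest.raises(ValueError):
            neighbor_joining(dm)


class TestMonophyly:
    def test_clade_and_non_clade(self):
        tree = Tree(newick="((A:1,B:1):1,C:2);")
        assert is_monophyletic(tree, {"A", "B"}, "C")
        assert is_monophyletic(tree, {"A"}, "C")
        with pytest.raises(ValueError):
            is_monophyletic(tree, {"A", "C"}, "C")

    def test_non_clade_set_is_false(self):
        tree = Tree(newick="(((A:1,B:1):1,X:1):1,C:2);")
        assert not is_monophyletic(tree, {"A", "X"}, "C")

    def test_unknown_leaf_is_an_error(self):
        tree = Tree(newick="((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError):
            is_monophyletic(tree, {"Z"}, "C")

    def test_simulated_haplogroups_are_monophyletic(self):
        ok = 0
        for seed in range(20):
            hm, truth = simulate_two_haplogroup_locus(
                TwoHaplogroupParams(n_per_group=6, seed=seed, t_outgroup=5e6)
            )
            tree = neighbor_joining(p_distance_matrix(hm))
            a = [s for s, g in zip(hm.sample_ids, hm.group_labels) if g == "A"]
            b = [s for s, g in zip(hm.sample_ids, hm.group_labels) if g == "B"]
            if is_monophyletic(tree, a, "outgroup") and is_monophyletic(
                tree, b, "outgroup"
            ):
                ok += 1
        assert ok >= 19


def test_newick_round_trip_preserves_lengths(tmp_path, two_hap_outgroup):
    hm, _ = two_hap_outgroup
    tree = neighbor_joining(p_distance_matrix(hm.take_haplotypes(range(10))))
    p = tmp_path / "t.nwk"
    write_newick(tree, p)
    back = read_newick(p)
    a, b = tree.path_lengths(), back.path_lengths()
    assert set(a) == set(b)
    for k in a:
        assert b[k] == pytest.approx(a[k], rel=1e-9, abs=1e-12)


class TestMuCalibration:
    def test_per_lineage_reading(self):
        assert estimate_mu(100, 5e6).mu == pytest.approx(1e-5)
        assert estimate_mu(0, 5e6).mu == 0.0

    def test_uncertainty_interval_from_divergence_time(self):
        est = estimate_mu(100, 5e6, time_uncertainty_years=1e6)
        assert est.interval[0] == pytest.approx(100 / (2 * 6e6))
        assert est.interval[1] == pytest.approx(100 / (2 * 4e6))

    def test_doubled_convention_exposed(self):
        assert estimate_mu(100, 5e6, convention="doubled").mu == pytest.approx(4e-5)

    def test_zero_time_rejected(self):
        with pytest.raises(ValueError):
            estimate_mu(10, 0)


class TestMutationsFromMrca:
    def test_simulator_truth_recovered_when_all_sites_polarizable(self, two_hap):
        hm, truth = two_hap
        # without a pre-MRCA branch the ancestral state is the reference
        res = mutations_from_mrca(hm, list(hm.ref))
        assert np.array_equal(res.x, truth.x)
        assert res.n_unpolarizable == 0

    def test_haplotype_identical_to_mrca_counts_zero(self):
        hm = small_haplotype_matrix([[0, 1, 1], [0, 1, 0]])
        res = mutations_from_mrca(hm, ["A", "A"])
        assert res.x[0] == 0

    def test_unpolarizable_site_flagged_and_excluded(self):
        hm = small_haplotype_matrix([[0, 1, 1], [0, 1, 0]])
        res = mutations_from_mrca(hm, ["A", "T"])   # site 2: third state
        assert res.n_unpolarizable == 1
        assert res.x.tolist() == [0, 1, 1]

    def test_no_polarizable_site_is_an_error(self):
        hm = small_haplotype_matrix([[0, 1, 1]])
        with pytest.raises(ValueError):
            mutations_from_mrca(hm, ["T"])


class TestThomsonTmrca:
    def test_plug_in_arithmetic(self):
        est = thomson_tmrca([5, 5], mu=1e-3)
        assert est.t == pytest.approx(5000.0)
        assert est.se == pytest.approx(np.sqrt(10) / (2e-3))

    def test_all_zero_counts_give_zero_age(self):
        assert thomson_tmrca([0, 0, 0], mu=1e-5).t == 0.0

    def test_scale_consistency_and_order_invariance(self):
        x = [3, 7, 2, 9]
        assert thomson_tmrca(x, 2e-4).t == pytest.approx(
            thomson_tmrca(x, 1e-4).t / 2
        )
        assert thomson_tmrca(x[::-1], 1e-4).t == thomson_tmrca(x, 1e-4).t

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            thomson_tmrca([1], 0.0)
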