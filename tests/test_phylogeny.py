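"""Distance models, neighbor-joining correctness on additive matrices,
bootstrap supports, and nearest-reference group transfer."""
import numpy as np
import pytest
import skbio

from famevol.phylogeny import (
    DistanceMatrix,
    assign_groups,
    bootstrap_support,
    kinase_distance_matrix,
    neighbor_joining,
    tree_bipartitions,
)
from famevol.simulate import generate_proteome


def random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths; returns the leaf
    labels and their exact path-length (tip-to-tip) distance matrix —
    the independent oracle NJ must reproduce."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # start from a 3-star, then attach each new leaf to a random edge
    parent = {labels[0]: None}
    children = {}
    root = "root"
    children[root] = list(labels[:3])
    length = {l: rng.uniform(0.1, 1.0) for l in labels[:3]}
    parent.update({l: root for l in labels[:3]})
    edges = list(labels[:3])
    for k, leaf in enumerate(labels[3:], start=3):
        target = edges[rng.integers(len(edges))]
        mid = f"n{k}"
        p = parent[target]
        children[p][children[p].index(target)] = mid
        children[mid] = [target, leaf]
        parent[target] = mid
        parent[mid] = p
        parent[leaf] = mid
        lt = length[target]
        split = rng.uniform(0.2, 0.8)
        length[target] = lt * split
        length[mid] = lt * (1 - split)
        length[leaf] = rng.uniform(0.1, 1.0)
        edges += [mid, leaf]
    # tip-to-tip distances through the explicit tree
    def path_to_root(node):
        out = []
        while parent.get(node) is not None:
            out.append(node)
            node = parent[node]
        return out
    d = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        pa = path_to_root(a)
        for j in range(i + 1, n_taxa):
            pb = path_to_root(labels[j])
            shared = set(pa) & set(pb)
            dist = sum(length[x] for x in pa + pb if x not in shared)
            d[i, j] = d[j, i] = dist
    return labels, d


class TestDistances:
    def test_p_distance_and_poisson(self):
        aligned = {"a": "A" * 97 + "CCC", "b": "A" * 100}
        dm = kinase_distance_matrix(aligned, "p-distance")
        assert dm["a", "b"] == pytest.approx(0.03)
        dm2 = kinase_distance_matrix(aligned, "poisson")
        assert dm2["a", "b"] == pytest.approx(-np.log(0.97))

    def test_identical_rows_are_at_distance_zero(self):
        dm = kinase_distance_matrix({"a": "MKV", "b": "MKV"})
        assert dm["a", "b"] == 0.0

    def test_gapped_columns_ignored_pairwise(self):
        dm = kinase_distance_matrix({"a": "M-KV", "b": "MAKL"})
        assert dm["a", "b"] == pytest.approx(1 / 3)

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(ValueError, match="comparable"):
            kinase_distance_matrix({"a": "M-", "b": "-M"})

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.5, 1.0], [1.0, 0.0]]))


class TestNeighborJoining:
    def test_four_taxon_additive_recovery_with_exact_lengths(self):
        # unrooted tree AB|CD, leaf edges A:1 B:2 C:3 D:4, internal edge 1
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert tree_bipartitions(tree) == {frozenset({"A", "B"})}
        tt = tree.tip_tip_distances()
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert tt[a, b] == pytest.approx(d[i, j], abs=1e-9)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_three_taxon_star_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 0.0, "b": 2.0, "c": 3.0})

    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]])))
        assert {t.name for t in tree.tips()} == {"a", "b"}
        assert sum(t.length for t in tree.tips()) == pytest.approx(0.4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_label_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        labels, d = random_additive_tree(rng, 6)
        t1 = neighbor_joining(DistanceMatrix(labels, d))
        perm = rng.permutation(len(labels))
        t2 = neighbor_joining(
            DistanceMatrix([labels[i] for i in perm], d[np.ix_(perm, perm)]))
        assert tree_bipartitions(t1) == tree_bipartitions(t2)
        tt1, tt2 = t1.tip_tip_distances(), t2.tip_tip_distances()
        for a in labels:
            for b in labels:
                assert tt1[a, b] == pytest.approx(tt2[a, b], abs=1e-9)

    def test_agrees_with_scikit_bio_nj(self):
        rng = np.random.default_rng(7)
        labels, d = random_additive_tree(rng, 7)
        ours = neighbor_joining(DistanceMatrix(labels, d))
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, labels))
        tt_o, tt_r = ours.tip_tip_distances(), ref.tip_tip_distances()
        for a in labels:
            for b in labels:
                assert tt_o[a, b] == pytest.approx(tt_r[a, b], abs=1e-9)


class TestBootstrap:
    def test_clear_separation_gets_full_support(self):
        aligned = {
            "a1": "AAAAAAAAAA", "a2": "AAAAAAAAAA",
            "b1": "CCCCCAAAAA", "b2": "CCCCCAAAAA",
            "c1": "GGGGGGGGGG",
        }
        tree = bootstrap_support(aligned, n_reps=50, seed=1)
        supports = [n.support for n in tree.non_tips(include_self=False)
                    if hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_are_binary(self):
        rng = np.random.default_rng(3)
        aligned = {f"s{i}": "".join(rng.choice(list("ACDEF"), 30)) for i in range(6)}
        tree = bootstrap_support(aligned, n_reps=1, seed=5)
        for n in tree.non_tips(include_self=False):
            if hasattr(n, "support"):
                assert n.support in (0.0, 100.0)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(4)
        aligned = {f"s{i}": "".join(rng.choice(list("ACDEFGH"), 40)) for i in range(7)}
        t1 = bootstrap_support(aligned, 20, seed=9)
        t2 = bootstrap_support(aligned, 20, seed=9)
        assert str(t1) == str(t2)


class TestGroupAssignment:
    def _tree(self, newick):
        return skbio.TreeNode.read([newick])

    def test_nearest_reference_wins(self):
        tree = self._tree("((q:0.01,refA:0.01):0.5,(refB:0.1,x:0.1):0.5);")
        assignment, _ = assign_groups(tree, {"refA": "XII-b", "refB": "I-a"})
        assert assignment["q"] == "XII-b"

    def test_tie_breaks_to_lexicographic_reference(self):
        tree = self._tree("(q:0.1,refA:0.2,refB:0.2);")
        assignment, _ = assign_groups(tree, {"refB": "I-b", "refA": "I-a"})
        assert assignment["q"] == "I-a"

    def test_no_references_is_an_error(self):
        tree = self._tree("(a:1,b:1,c:1);")
        with pytest.raises(ValueError):
            assign_groups(tree, {"zz": "I"})

    def test_generator_groups_recovered(self, sim_config):
        prot = generate_proteome(sim_config)
        aligned = {**prot["kinase_domains"], **prot["references"]}
        tree = neighbor_joining(kinase_distance_matrix(aligned))
        assignment, _ = assign_groups(tree, prot["ref_groups"])
        for gid, group in assignment.items():
            assert group == prot["truth"][gid]["group"]
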