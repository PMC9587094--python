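"""Distances, jackknife resampling, NJ topology recovery, consensus, rooting."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from padckit import phylo


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


class TestProteinDistance:
    def test_identical_rows_have_zero_distance(self):
        aln = {"a": "MKLV", "b": "MKLV", "c": "MKLW"}
        dm = phylo.protein_distance(aln)
        assert dm.d[0, 1] == 0.0

    def test_ten_percent_mismatch_closed_form(self):
        # p = 0.1 -> d = -ln(1 - 0.1 - 0.2*0.01) = -ln(0.898)
        aln = {"a": "A" * 10, "b": "C" + "A" * 9, "c": "A" * 10}
        dm = phylo.protein_distance(aln)
        assert dm.d[0, 1] == pytest.approx(-math.log(0.898))

    def test_gapped_columns_are_pairwise_deleted(self):
        aln = {"a": "MK-V", "b": "MKLV", "c": "M-LV"}
        dm = phylo.protein_distance(aln)  # all comparable columns agree
        assert np.allclose(dm.d, 0.0)

    def test_matrix_symmetric_zero_diagonal(self, diverged_dataset):
        dm = phylo.protein_distance(diverged_dataset.alignment)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)
        assert (dm.d >= 0).all()

    def test_saturated_pairs_clamped(self):
        aln = {"a": "AAAAAAAAAA", "b": "CCCCCCCCCC", "c": "AAAAAAAAAA"}
        dm = phylo.protein_distance(aln, d_max=5.0)
        assert dm.d[0, 1] == 5.0

    def test_no_comparable_columns_names_the_pair(self):
        aln = {"seq1": "MK--", "seq2": "--LV", "seq3": "MKLV"}
        with pytest.raises(ValueError, match="seq1.*seq2"):
            phylo.protein_distance(aln)


class TestJackknife:
    def test_replicates_keep_exactly_half_the_columns(self):
        cfg = phylo.JackknifeConfig(n_replicates=20, seed=1)
        for cols in phylo.jackknife_columns(100, cfg):
            assert len(cols) == 50
            assert len(set(cols.tolist())) == 50
        for cols in phylo.jackknife_columns(101, cfg):
            assert len(cols) == 50  # floor(101/2)

    def test_same_seed_reproduces_replicates(self):
        cfg = phylo.JackknifeConfig(n_replicates=10, seed=9)
        a = phylo.jackknife_columns(60, cfg)
        b = phylo.jackknife_columns(60, cfg)
        assert all((x == y).all() for x, y in zip(a, b))

    def test_column_order_is_preserved(self):
        aln = {"a": "ABCDEFGHIJ", "b": "ABCDEFGHIJ", "c": "ABCDEFGHIJ"}
        reps = phylo.jackknife_resample(
            aln, phylo.JackknifeConfig(n_replicates=5, seed=2))
        for rep in reps:
            row = rep["a"]
            assert list(row) == sorted(row)  # monotone source columns
            assert len(row) == 5

    def test_per_column_sampling_frequency_is_half(self):
        cfg = phylo.JackknifeConfig(n_replicates=1000, seed=3)
        counts = np.zeros(20)
        for cols in phylo.jackknife_columns(20, cfg):
            counts[cols] += 1
        assert (np.abs(counts / 1000 - 0.5) <= 0.05).all()


def _additive_distance_matrix(tree: dendropy.Tree) -> phylo.DistanceMatrix:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(pdm.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return phylo.DistanceMatrix(taxa=tuple(t.label for t in taxa), d=d)


def _ls_best_quartet(dm: phylo.DistanceMatrix) -> frozenset:
    """Brute-force oracle: best of the 3 unrooted 4-taxon topologies by
    ordinary least squares fit of the 5 branch lengths."""
    t = dm.taxa
    best = None
    for pair in (("0", (t[0], t[1])), ("1", (t[0], t[2])), ("2", (t[0], t[3]))):
        a, b = pair[1]
        c, d_ = [x for x in t if x not in pair[1]]
        idx = {lab: k for k, lab in enumerate(t)}
        D = dm.d
        def dist(x, y):
            return D[idx[x], idx[y]]
        # four-point estimate of the internal edge
        internal = 0.5 * (0.5 * (dist(a, c) + dist(a, d_) + dist(b, c) + dist(b, d_))
                          - dist(a, b) - dist(c, d_))
        resid = abs(internal) if internal < 0 else 0
        score = (max(internal, 0), -resid)
        key = frozenset((a, b))
        if best is None or score > best[0]:
            best = (score, key)
    return best[1]


def _five_taxon_topologies():
    taxa = ["t1", "t2", "t3", "t4", "t5"]
    seen = set()
    for s1 in itertools.combinations(taxa, 2):
        rest = [x for x in taxa if x not in s1]
        for s2 in itertools.combinations(rest, 2):
            key = frozenset((frozenset(s1), frozenset(s2)))
            if key in seen:
                continue
            seen.add(key)
            odd = [x for x in rest if x not in s2][0]
            yield s1, s2, odd
    # 15 labelled unrooted binary topologies on 5 taxa


def test_there_are_fifteen_five_taxon_topologies():
    assert len(list(_five_taxon_topologies())) == 15


def test_nj_recovers_all_fifteen_five_taxon_topologies():
    rng = np.random.default_rng(8)
    for s1, s2, odd in _five_taxon_topologies():
        def bl():
            return 0.1 + 0.9 * rng.random()
        newick = (f"(({s1[0]}:{bl()},{s1[1]}:{bl()}):{bl()},{odd}:{bl()},"
                  f"({s2[0]}:{bl()},{s2[1]}:{bl()}):{bl()});")
        source = _tree(newick)
        dm = _additive_distance_matrix(source)
        rebuilt = phylo.build_tree(dm)
        assert phylo.tree_bipartitions(rebuilt) == phylo.tree_bipartitions(source)


def test_nj_four_taxon_topology_matches_least_squares_oracle():
    rng = np.random.default_rng(4)
    for _ in range(10):
        b = 0.1 + rng.random(5)
        newick = (f"((a:{b[0]},b:{b[1]}):{b[4]},c:{b[2]},d:{b[3]});")
        dm = _additive_distance_matrix(_tree(newick))
        rebuilt = phylo.build_tree(dm)
        (split,) = phylo.tree_bipartitions(rebuilt)
        oracle = _ls_best_quartet(dm)
        pivot_free = split if "a" not in split else frozenset(dm.taxa) - split
        oracle_pf = oracle if "a" not in oracle else frozenset(dm.taxa) - oracle
        assert pivot_free == oracle_pf


def test_three_taxa_path_lengths_solve_three_point_equations():
    d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0.]])
    tree = phylo.build_tree(phylo.DistanceMatrix(taxa=("a", "b", "c"), d=d))
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in pdm.taxon_namespace}
    assert pdm.patristic_distance(tx["a"], tx["b"]) == pytest.approx(3)
    assert pdm.patristic_distance(tx["a"], tx["c"]) == pytest.approx(5)
    assert pdm.patristic_distance(tx["b"], tx["c"]) == pytest.approx(6)


def test_taxon_order_permutation_gives_same_tree():
    rng = np.random.default_rng(12)
    n = 6
    base = rng.random((n, n)) + 0.2
    d = (base + base.T) / 2
    np.fill_diagonal(d, 0)
    taxa = tuple(f"s{i}" for i in range(n))
    t1 = phylo.build_tree(phylo.DistanceMatrix(taxa=taxa, d=d))
    perm = rng.permutation(n)
    t2 = phylo.build_tree(phylo.DistanceMatrix(
        taxa=tuple(taxa[i] for i in perm), d=d[np.ix_(perm, perm)]))
    assert phylo.tree_bipartitions(t1) == phylo.tree_bipartitions(t2)


def test_degenerate_all_zero_matrix_warns():
    d = np.zeros((4, 4))
    with pytest.warns(UserWarning, match="all-zero"):
        phylo.build_tree(phylo.DistanceMatrix(taxa=("a", "b", "c", "d"), d=d))


class TestConsensus:
    def test_identical_trees_support_equals_replicate_count(self):
        trees = [_tree("((a,b),(c,d),e);") for _ in range(20)]
        res = phylo.consensus(trees)
        assert res.n_replicates == 20
        assert res.clade_support({"c", "d"}) == 20
        assert phylo.tree_bipartitions(res.tree) == phylo.tree_bipartitions(trees[0])

    def test_two_of_three_majority_is_retained(self):
        trees = [_tree("((a,b),(c,d),e);"), _tree("((a,b),(c,e),d);"),
                 _tree("((a,c),(b,d),e);")]
        res = phylo.consensus(trees)
        assert res.clade_support({"a", "b"}) == 2
        bips = phylo.tree_bipartitions(res.tree)
        # ab|cde pivot-normalises (pivot 'a') to {c,d,e}
        assert frozenset({"c", "d", "e"}) in bips

    def test_supports_never_exceed_replicates(self):
        trees = [_tree("((a,b),(c,d),e);"), _tree("((a,c),(b,d),e);")]
        res = phylo.consensus(trees)
        assert all(c <= 2 for c in res.bipartition_counts.values())

    def test_consensus_invariant_under_replicate_order(self):
        trees = [_tree("((a,b),(c,d),e);"), _tree("((a,c),(b,d),e);"),
                 _tree("((a,b),(c,e),d);")]
        r1 = phylo.consensus(trees)
        r2 = phylo.consensus(list(reversed(trees)))
        assert r1.bipartition_counts == r2.bipartition_counts
        assert phylo.tree_bipartitions(r1.tree) == phylo.tree_bipartitions(r2.tree)

    def test_mismatched_leaf_sets_rejected(self):
        with pytest.raises(ValueError, match="identical leaf set"):
            phylo.consensus([_tree("((a,b),(c,d),e);"), _tree("((a,b),c,d);")])

    def test_singleton_and_absent_clade_conventions(self):
        trees = [_tree("((a,b),(c,d),e);")] * 3
        res = phylo.consensus(trees)
        assert res.clade_support({"a"}) == 3          # trivial bipartition
        assert res.clade_support({"a", "c"}) == 0     # never observed

    def test_extended_majority_fills_compatible_minority_splits(self):
        trees = [_tree("((a,b),(c,d),e);"), _tree("((a,b),(c,e),d);"),
                 _tree("((a,b),(d,e),c);"), _tree("((a,c),(d,e),b);")]
        res = phylo.consensus(trees)
        bips = phylo.tree_bipartitions(res.tree)
        norm = {frozenset(res.labels) - s if res.pivot in s else s for s in bips}
        assert {"d", "e"} in [set(s) for s in norm]  # 2/4, added greedily


class TestRooting:
    def test_single_leaf_outgroup_becomes_sister_to_ingroup(self):
        tree = _tree("((a:1,b:1):1,(c:3,og:7):1);")
        rooted = phylo.root_tree(tree, "og")
        root_children = rooted.seed_node.child_nodes()
        og_sides = [n for n in root_children
                    if {lf.taxon.label for lf in n.leaf_iter()} == {"og"}]
        assert len(og_sides) == 1

    def test_outgroup_clade_rooting(self):
        tree = _tree("((a,b),(c,(o1,o2)));")
        rooted = phylo.root_tree(tree, {"o1", "o2"})
        sides = [{lf.taxon.label for lf in n.leaf_iter()}
                 for n in rooted.seed_node.child_nodes()]
        assert {"o1", "o2"} in sides

    def test_non_monophyletic_outgroup_is_an_error(self):
        tree = _tree("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(ValueError, match="not monophyletic"):
            phylo.root_tree(tree, {"a", "c"})

    def test_rerooting_is_idempotent(self):
        tree = _tree("((a:1,b:1):1,(c:3,og:7):1);")
        r1 = phylo.root_tree(tree, "og")
        r2 = phylo.root_tree(r1, "og")
        assert phylo.tree_bipartitions(r1) == phylo.tree_bipartitions(r2)

    def test_unknown_outgroup_label_rejected(self):
        with pytest.raises(ValueError, match="not all present"):
            phylo.root_tree(_tree("((a,b),(c,d));"), "zz")


def test_jackknife_consensus_recovers_families_with_high_support(diverged_dataset):
    ds = diverged_dataset
    res = phylo.jackknife_consensus(
        ds.alignment, phylo.JackknifeConfig(n_replicates=100, seed=5))
    for fam, sub in ds.truth.groupby("family"):
        support = res.clade_support(set(sub.sequence_id))
        assert support >= 95, fam
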