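import numpy as np
import pytest

from _oracles import all_topologies, random_binary_matrix
from paleosnake.errors import ValidationError
from paleosnake.parsimony.length import encode_matrix, min_steps, tree_length
from paleosnake.parsimony.matrix import CharacterMatrix
from paleosnake.parsimony.search import (
    _copy,
    _length,
    _splits_key,
    ensemble_indices,
    heuristic_search,
    tbr_neighbors,
    wagner_tree,
)
from paleosnake.parsimony.tree import PhyloTree


def perfect_matrix(tree: PhyloTree) -> CharacterMatrix:
    """One binary character per internal split: homoplasy-free by design."""
    n = tree.n_leaves
    cells = [[] for _ in range(n)]
    for mask in sorted(tree.bipartitions()):
        for i in range(n):
            cells[i].append(frozenset({1 if (mask >> i) & 1 else 0}))
    return CharacterMatrix(taxa=list(tree.taxa), cells=cells)


class TestWagnerAndTbr:
    def test_wagner_is_complete_binary_tree(self):
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(8)]
        m = random_binary_matrix(taxa, 20, rng)
        enc = encode_matrix(m)
        adj = wagner_tree(enc, np.random.default_rng(1))
        leaves = [u for u in adj if u < 8]
        assert sorted(leaves) == list(range(8))
        assert all(len(adj[u]) == 1 for u in leaves)
        assert all(len(adj[u]) == 3 for u in adj if u >= 8)

    def test_tbr_neighbors_are_valid_trees(self):
        rng = np.random.default_rng(2)
        taxa = [f"t{i}" for i in range(6)]
        m = random_binary_matrix(taxa, 10, rng)
        adj = wagner_tree(encode_matrix(m), np.random.default_rng(3))
        count = 0
        for nb in tbr_neighbors(adj, 6):
            count += 1
            leaves = [u for u in nb if u < 6]
            assert sorted(leaves) == list(range(6))
            assert all(len(nb[u]) == 3 for u in nb if u >= 6)
        assert count > 20

    def test_tbr_reaches_all_six_taxon_topologies(self):
        # the TBR neighborhood of any tree, iterated twice, must cover a
        # large share of the 105 six-taxon topologies (TBR is known to
        # connect tree space)
        taxa = tuple(f"t{i}" for i in range(6))
        start = all_topologies(taxa)[0]
        seen = {_splits_key(start.adj, 6)}
        frontier = [start.adj]
        for _ in range(2):
            new = []
            for adj in frontier:
                for nb in tbr_neighbors(adj, 6):
                    key = _splits_key(nb, 6)
                    if key not in seen:
                        seen.add(key)
                        new.append(nb)
            frontier = new
        assert len(seen) == 105


class TestHeuristicSearch:
    def test_perfect_data_recovers_generating_tree(self):
        n = 10
        taxa = tuple(f"t{i}" for i in range(n))
        rng = np.random.default_rng(5)
        # random binary shape by sequential leaf insertion
        adj = {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}
        next_id = n + 1
        for leaf in range(3, n):
            edges = [(u, v) for u in adj for v in adj[u] if u < v]
            u, v = edges[rng.integers(len(edges))]
            adj[u].discard(v)
            adj[v].discard(u)
            adj[next_id] = {u, v, leaf}
            adj[u].add(next_id)
            adj[v].add(next_id)
            adj[leaf] = {next_id}
            next_id += 1
        tree = PhyloTree(taxa, adj)
        m = perfect_matrix(tree)
        res = heuristic_search(m, n_replicates=3, trees_per_rep=5, seed=9)
        assert res.best_length == sum(min_steps(m, j) for j in range(m.n_char))
        assert res.ci == pytest.approx(1.0)
        assert any(t.bipartitions() == tree.bipartitions() for t in res.trees)

    def test_matches_exhaustive_oracle_on_small_matrices(self):
        taxa = [f"t{i}" for i in range(6)]
        topos = all_topologies(tuple(taxa))
        hits = 0
        for trial in range(10):
            rng = np.random.default_rng(100 + trial)
            m = random_binary_matrix(taxa, 15, rng)
            opt = min(tree_length(t, m) for t in topos)
            res = heuristic_search(m, n_replicates=3, trees_per_rep=5, seed=trial)
            hits += res.best_length == opt
        assert hits == 10

    def test_bit_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        taxa = [f"t{i}" for i in range(8)]
        m = random_binary_matrix(taxa, 30, rng)
        r1 = heuristic_search(m, n_replicates=4, trees_per_rep=5, seed=77)
        r2 = heuristic_search(m, n_replicates=4, trees_per_rep=5, seed=77)
        assert r1.best_length == r2.best_length
        assert [t.bipartitions() for t in r1.trees] == [
            t.bipartitions() for t in r2.trees
        ]
        r3 = heuristic_search(m, n_replicates=4, trees_per_rep=5, seed=78)
        assert r3.replicate_lengths != r1.replicate_lengths or (
            r3.best_length == r1.best_length
        )

    def test_pool_deduplicated_and_at_best_length(self):
        rng = np.random.default_rng(12)
        taxa = [f"t{i}" for i in range(7)]
        m = random_binary_matrix(taxa, 10, rng)
        res = heuristic_search(m, n_replicates=5, trees_per_rep=10, seed=4)
        keys = [t.bipartitions() for t in res.trees]
        assert len(keys) == len(set(keys))
        assert all(tree_length(t, m) == res.best_length for t in res.trees)

    def test_validation_errors(self, toy_tnt):
        from paleosnake.parsimony.matrix import read_tnt

        m = read_tnt(toy_tnt)
        with pytest.raises(ValidationError):
            heuristic_search(m, maxtrees=0)
        small = m.subset_taxa(["A", "B", "C"])
        with pytest.raises(ValidationError):
            heuristic_search(small)


class TestEnsembleIndices:
    def test_homoplasy_free_gives_ci_one(self):
        tree = all_topologies(tuple(f"t{i}" for i in range(6)))[10]
        m = perfect_matrix(tree)
        res = heuristic_search(m, n_replicates=2, trees_per_rep=3, seed=0)
        assert res.ci == pytest.approx(1.0)
        assert res.ri == pytest.approx(1.0)

    def test_single_incongruent_character(self):
        # one binary character split 2+2 against the tree: L=2, m=1, G=2
        m = CharacterMatrix(
            taxa=["A", "B", "C", "D"],
            cells=[[frozenset({0})], [frozenset({1})], [frozenset({0})],
                   [frozenset({1})]],
        )
        res = heuristic_search(m, n_replicates=1, trees_per_rep=1, seed=0)
        # the optimal tree groups the like states: length 1... so force the
        # anti-tree by computing indices at a stated length instead
        from paleosnake.parsimony.search import SearchResult

        fake = SearchResult(
            best_length=2, trees=res.trees, n_replicates=1, trees_per_rep=1,
            maxtrees=1, seed=0,
        )
        ci, ri = ensemble_indices(fake, m)
        assert ci == pytest.approx(0.5)
        assert ri == pytest.approx(0.0)

    def test_no_variation_ri_undefined(self):
        m = CharacterMatrix(
            taxa=["A", "B", "C", "D"],
            cells=[[frozenset({0})], [frozenset({0})], [frozenset({0})],
                   [frozenset({1})]],
        )
        res = heuristic_search(m, n_replicates=1, trees_per_rep=1, seed=0)
        # single autapomorphy: m == G == 1, so RI has no defined value
        assert res.ri is None
        assert res.ci == pytest.approx(1.0)

    def test_informative_only_flag_drops_autapomorphies(self):
        cells = [
            [frozenset({0}), frozenset({0})],
            [frozenset({0}), frozenset({1})],
            [frozenset({1}), frozenset({0})],
            [frozenset({1}), frozenset({0})],
        ]
        m = CharacterMatrix(taxa=["A", "B", "C", "D"], cells=cells)
        res = heuristic_search(m, n_replicates=1, trees_per_rep=1, seed=0)
        ci_all, _ = ensemble_indices(res, m, informative_only=False)
        ci_inf, _ = ensemble_indices(res, m, informative_only=True)
        # the autapomorphic character contributes 1 step and m=1 to both
        # numerator and denominator, so dropping it lowers both sums
        assert ci_all != ci_inf
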