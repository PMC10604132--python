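"""Distances, neighbor joining, bootstrap, bipartition utilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitochar.msa import Alignment
from mitochar.phylogeny import (
    Node,
    Tree,
    bootstrap_support,
    distance_matrix,
    is_monophyletic,
    nj_tree,
    rf_distance,
)


def _random_additive_tree(rng, n):
    """Random binary topology with positive branch lengths; returns
    (tree, leaf names, pairwise path-distance matrix)."""
    nodes = [Node(name=f"t{i}", length=float(rng.uniform(0.1, 2.0)))
             for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = Node(length=float(rng.uniform(0.1, 2.0)), children=[b, a])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = Tree(root=Node(children=nodes))
    names = sorted(tree.leaf_names())
    # path distances by traversal
    dists = {}

    def down(node, acc):
        if node.is_leaf():
            dists[node.name] = acc
            return
        for c in node.children:
            down(c, {k: v + c.length for k, v in acc.items()} | {})

    # distance via lowest common ancestor: accumulate leaf depths per subtree
    D = np.zeros((len(names), len(names)))
    idx = {t: i for i, t in enumerate(names)}

    def collect(node):
        if node.is_leaf():
            return {node.name: node.length}
        out = {}
        subs = [collect(c) for c in node.children]
        for a in range(len(subs)):
            for b in range(a + 1, len(subs)):
                for ta, da in subs[a].items():
                    for tb, db in subs[b].items():
                        D[idx[ta], idx[tb]] = D[idx[tb], idx[ta]] = da + db
        for sub in subs:
            for t, d in sub.items():
                out[t] = d + node.length
        return out

    collect(tree.root)
    return tree, names, D


class TestDistances:
    def test_identical_rows_zero(self):
        a = Alignment(taxa=list("ab"), rows=["ACGTACGT"] * 2)
        for model in ("p", "JC69", "K2P"):
            assert distance_matrix(a, model)[0, 1] == 0

    def test_jc69_closed_form_at_half(self):
        a = Alignment(taxa=list("ab"), rows=["A" * 50 + "C" * 50,
                                             "A" * 50 + "G" * 50])
        d = distance_matrix(a, "JC69")[0, 1]
        assert d == pytest.approx(-0.75 * np.log(1 / 3))

    def test_k2p_transitions_only_closed_form(self):
        # 25% transition differences, zero transversions
        a = Alignment(taxa=list("ab"), rows=["A" * 100, "A" * 75 + "G" * 25])
        d = distance_matrix(a, "K2P")[0, 1]
        P = 0.25
        assert d == pytest.approx(-0.5 * np.log(1 - 2 * P))

    def test_pairwise_deletion(self):
        a = Alignment(taxa=list("ab"), rows=["ACGT-N", "ACGAAC"])
        assert distance_matrix(a, "p")[0, 1] == pytest.approx(1 / 4)

    def test_saturation_errors_with_pair_names(self):
        a = Alignment(taxa=["x", "y"], rows=["A" * 10, "C" * 10])
        with pytest.raises(ValueError, match="x/y"):
            distance_matrix(a, "JC69")


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        D = np.array(
            [[0, 3, 7, 8], [3, 0, 6, 7], [7, 6, 0, 5], [8, 7, 5, 0]], float
        )
        t = nj_tree(D, list("ABCD"))
        assert is_monophyletic(t, ["A", "B"])
        # recovered path lengths reproduce the input exactly
        assert _path_dists(t) == pytest.approx(D)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30)
    def test_recovers_random_additive_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        true, names, D = _random_additive_tree(rng, n)
        est = nj_tree(D, names)
        assert rf_distance(true, est) == 0
        assert _path_dists(est) == pytest.approx(D, abs=1e-9)

    def test_three_taxa_star(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        t = nj_tree(D, list("ABC"))
        assert sorted(t.leaf_names()) == list("ABC")
        assert _path_dists(t) == pytest.approx(D)

    def test_tied_minima_deterministic(self):
        D = np.ones((5, 5)) - np.eye(5)
        taxa = list("ABCDE")
        assert nj_tree(D, taxa).newick() == nj_tree(D, taxa).newick()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1], [2, 0]]), ["a", "b"])

    def test_agrees_with_dendropy_nj(self):
        """Independent cross-check: dendropy's NJ on the same matrix."""
        import dendropy

        rng = np.random.default_rng(5)
        true, names, D = _random_additive_tree(rng, 8)
        noisy = D + rng.uniform(0, 0.01, D.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        mine = nj_tree(noisy, names)
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_csv_of(noisy, names), delimiter=","
        )
        theirs = Tree.from_newick(
            pdm.nj_tree().as_string(schema="newick").replace("[&U] ", "")
        )
        assert rf_distance(mine, theirs) == 0


def _csv_of(D, names):
    import io

    buf = io.StringIO()
    buf.write("," + ",".join(names) + "\n")
    for i, t in enumerate(names):
        buf.write(t + "," + ",".join(str(x) for x in D[i]) + "\n")
    buf.seek(0)
    return buf


def _path_dists(tree):
    names = sorted(tree.leaf_names())
    idx = {t: i for i, t in enumerate(names)}
    D = np.zeros((len(names), len(names)))

    def collect(node):
        if node.is_leaf():
            return {node.name: node.length}
        subs = [collect(c) for c in node.children]
        for a in range(len(subs)):
            for b in range(a + 1, len(subs)):
                for ta, da in subs[a].items():
                    for tb, db in subs[b].items():
                        D[idx[ta], idx[tb]] = D[idx[tb], idx[ta]] = da + db
        return {t: d + node.length for sub in subs for t, d in sub.items()}

    collect(tree.root)
    return D


class TestBipartitions:
    def test_rf_of_identical_trees_is_zero(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1,(E:1,F:1):1);")
        assert rf_distance(t, t) == 0

    def test_four_taxon_alternative_topologies(self):
        t1 = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = Tree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert rf_distance(t1, t2) == 2

    def test_leaf_set_mismatch_errors(self):
        t1 = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = Tree.from_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)

    def test_monophyly(self):
        t = Tree.from_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        assert is_monophyletic(t, ["A", "B"])
        assert is_monophyletic(t, ["A", "B", "C"])
        assert not is_monophyletic(t, ["B", "C"])
        assert not is_monophyletic(t, ["A", "D"])
        assert is_monophyletic(t, ["D"])  # single taxon trivially

    def test_rf_agrees_with_dendropy(self):
        import dendropy

        rng = np.random.default_rng(11)
        t1, names, _ = _random_additive_tree(rng, 9)
        t2, _, _ = _random_additive_tree(np.random.default_rng(12), 9)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.newick(), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2.newick(), schema="newick",
                               taxon_namespace=tns)
        expect = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert rf_distance(t1, t2) == expect


class TestBootstrap:
    def _aln(self, seed=0, ncol=400):
        """Two clearly separated four-taxon groups."""
        rng = np.random.default_rng(seed)
        anc = rng.choice(list("ACGT"), size=ncol)
        g1 = anc.copy()
        flip = rng.random(ncol) < 0.3
        g2 = anc.copy()
        g2[flip] = np.where(g2[flip] == "A", "C", "A")
        rows = []
        taxa = []
        for i, base in enumerate([g1, g1, g2, g2]):
            r = base.copy()
            mut = rng.random(ncol) < 0.02
            r[mut] = rng.choice(list("ACGT"), size=int(mut.sum()))
            rows.append("".join(r))
            taxa.append(f"t{i}")
        return Alignment(taxa=taxa, rows=rows)

    def test_same_seed_reproducible(self):
        a = self._aln()
        t1 = bootstrap_support(a, n_reps=30, seed=7)
        t2 = bootstrap_support(a, n_reps=30, seed=7)
        assert t1.newick() == t2.newick()

    def test_identical_sequences_no_supports(self):
        a = Alignment(taxa=[f"t{i}" for i in range(4)], rows=["ACGT" * 20] * 4)
        t = bootstrap_support(a, n_reps=10, seed=0)
        assert all(n.support is None for n in t.root.walk())

    def test_strong_split_gets_high_support(self):
        t = bootstrap_support(self._aln(), n_reps=50, seed=1)
        assert is_monophyletic(t, ["t0", "t1"])
        supports = [n.support for n in t.root.walk() if n.support is not None]
        assert supports and max(supports) >= 95

    def test_invalid_reps(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._aln(), n_reps=0)
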