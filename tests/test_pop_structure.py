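"""Distance, neighbor joining (vs closed forms and scikit-bio), bootstrap, PCA."""

import dataclasses

import numpy as np
import pytest

from sweeptx import pop_structure as pst
from sweeptx.errors import ValidationError
from sweeptx.pop_structure import DistanceMatrix, allele_sharing_distance, nj_tree, pca

from conftest import make_gm


def random_additive_matrix(rng, n_taxa):
    """Random unrooted binary tree -> (additive distance matrix, bipartitions).

    Built by sequential leaf attachment: start from a 3-leaf star and
    attach each new leaf to a uniformly chosen existing edge with random
    positive branch lengths, accumulating path lengths exactly.
    """
    # adjacency with branch lengths; nodes 0..n_taxa-1 are leaves
    next_node = n_taxa
    edges = {}

    def add_edge(u, v, w):
        edges[(u, v)] = w
        edges[(v, u)] = w

    def drop_edge(u, v):
        del edges[(u, v)], edges[(v, u)]

    b = lambda: float(rng.uniform(0.5, 5.0))
    center = next_node
    next_node += 1
    for leaf in (0, 1, 2):
        add_edge(center, leaf, b())
    for leaf in range(3, n_taxa):
        pairs = [e for e in edges if e[0] < e[1]]
        u, v = pairs[rng.integers(0, len(pairs))]
        w = edges[(u, v)]
        mid = next_node
        next_node += 1
        drop_edge(u, v)
        t = float(rng.uniform(0.25, 0.75))
        add_edge(u, mid, w * t)
        add_edge(mid, v, w * (1 - t))
        add_edge(mid, leaf, b())

    # all-pairs path lengths by BFS over the tree
    import collections
    adj = collections.defaultdict(list)
    for (u, v), w in edges.items():
        adj[u].append((v, w))
    names = [f"t{i}" for i in range(n_taxa)]
    d = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for dst in range(n_taxa):
            d[src, dst] = dist[dst]

    # true bipartitions: leaves on each side of every internal edge
    ref = names[0]
    full = set(names)
    bips = set()
    for (u, v) in [e for e in edges if e[0] < e[1]]:
        if u < n_taxa or v < n_taxa:
            continue   # pendant edge
        seen = {v}
        stack = [v]
        while stack:
            x = stack.pop()
            for y, _ in adj[x]:
                if y != u and y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = {names[x] for x in seen if x < n_taxa}
        if 1 < len(side) < n_taxa - 1:
            bips.add(frozenset(side if ref not in side else full - side))
    return DistanceMatrix(names, d, np.ones((n_taxa, n_taxa), dtype=np.int64)), bips


class TestDistance:
    def test_identical_samples_zero(self):
        gm = make_gm(np.tile([0, 1, 2, 1], (3, 1)).astype(np.int8), pops=["A"] * 3)
        dm = allele_sharing_distance(gm)
        assert np.all(dm.d == 0)

    def test_opposite_homozygotes_distance_one(self):
        gm = make_gm(np.vstack([np.zeros(10), np.full(10, 2)]).astype(np.int8),
                     pops=["A", "B"])
        dm = allele_sharing_distance(gm)
        assert dm.d[0, 1] == pytest.approx(1.0)

    def test_matches_all_pairs_loop_oracle(self, rng):
        dosage = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
        gm = make_gm(dosage, pops=["A"] * 4)
        dm = allele_sharing_distance(gm)
        for i in range(4):
            for j in range(4):
                expected = np.mean([abs(int(dosage[i, k]) - int(dosage[j, k])) / 2
                                    for k in range(30)])
                assert dm.d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_site_and_sample_order_invariance(self, rng, two_pop_gm):
        dm1 = allele_sharing_distance(two_pop_gm)
        perm = rng.permutation(two_pop_gm.n_variants)
        order = np.argsort(two_pop_gm.pos[perm][np.argsort(perm)])  # keep sorted pos
        gm2 = two_pop_gm.take_sites(np.sort(perm))
        dm2 = allele_sharing_distance(gm2)
        np.testing.assert_allclose(dm1.d, dm2.d)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        # d(AB)=3, d(AC)=5, d(BC)=6 -> a=1, b=2, c=4
        d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d, np.ones((3, 3), int)))
        lengths = {c.name: bl for c, bl in tree.root.children}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(4.0)

    def test_additive_four_taxon_round_trip(self):
        """Distances built from a known tree (pendant 1,2,3,4; internal 5)."""
        # tree: (A:1, B:2)-[5]-(C:3, D:4)
        d = np.array([
            [0, 3, 9, 10],
            [3, 0, 10, 11],
            [9, 10, 0, 7],
            [10, 11, 7, 0],
        ], float)
        tree = nj_tree(DistanceMatrix(list("ABCD"), d, np.ones((4, 4), int)))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        # rebuild the path-length matrix from the tree and compare exactly
        got = _tree_distances(tree)
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                assert got[(a, b)] == pytest.approx(d[i, j], abs=1e-10)

    def test_clustered_pairs_become_siblings(self):
        d = np.array([
            [0.0, 0.1, 1.0, 1.1],
            [0.1, 0.0, 1.1, 1.0],
            [1.0, 1.1, 0.0, 0.1],
            [1.1, 1.0, 0.1, 0.0],
        ])
        tree = nj_tree(DistanceMatrix(list("ABCD"), d, np.ones((4, 4), int)))
        assert tree.bipartitions() == {frozenset({"C", "D"})}

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(list("ABC"), d, np.ones((3, 3), int)))

    @pytest.mark.parametrize("trial", range(20))
    def test_recovers_random_additive_topologies(self, trial):
        rng = np.random.default_rng(1000 + trial)
        dm, true_bips = random_additive_matrix(rng, 8)
        assert nj_tree(dm).bipartitions() == true_bips

    def test_agrees_with_skbio_on_noisy_matrix(self, rng):
        """Independent-oracle cross-check on a non-additive matrix."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        n = 7
        base, _ = random_additive_matrix(rng, n)
        noisy = base.d + rng.uniform(0, 0.2, size=(n, n))
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        dm = DistanceMatrix(base.sample_ids, noisy, base.n_sites_used)
        ours = nj_tree(dm).bipartitions()
        sk_tree = skbio_nj(skbio.DistanceMatrix(noisy, ids=base.sample_ids))
        ref = min(base.sample_ids)
        full = set(base.sample_ids)
        theirs = set()
        for node in sk_tree.non_tips():
            side = {t.name for t in node.tips()}
            if 1 < len(side) < n - 1:
                theirs.add(frozenset(side if ref not in side else full - side))
        assert ours == theirs


def _tree_distances(tree):
    """Leaf-to-leaf path lengths of a PhyloTree (LCA on the rooted form)."""
    node_paths = {}

    def walk(node, path):
        path = path + [node]
        if node.is_leaf:
            node_paths[node.name] = path
            return
        for child, _ in node.children:
            walk(child, path)

    walk(tree.root, [])
    branch = {}

    def record(node):
        for child, w in node.children:
            branch[child] = w
            record(child)

    record(tree.root)
    out = {}
    for a, pa in node_paths.items():
        for b, pb in node_paths.items():
            shared = 0
            for x, y in zip(pa, pb):
                if x is y:
                    shared += 1
                else:
                    break
            out[(a, b)] = sum(branch[x] for x in pa[shared:]) \
                + sum(branch[x] for x in pb[shared:])
    return out


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self, two_pop_gm):
        sub = two_pop_gm.take_sites(np.arange(500))
        tree = pst.bootstrap_support(sub, n_boot=1, seed=1)
        sups = _collect_supports(tree)
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_seed_determinism(self, two_pop_gm):
        sub = two_pop_gm.take_sites(np.arange(500))
        t1 = pst.bootstrap_support(sub, n_boot=20, seed=9)
        t2 = pst.bootstrap_support(sub, n_boot=20, seed=9)
        assert t1.newick() == t2.newick()

    def test_population_split_strongly_supported(self, two_pop_gm):
        tree = pst.bootstrap_support(two_pop_gm, n_boot=200, seed=3)
        split = frozenset(s for s in two_pop_gm.sample_ids
                          if two_pop_gm.pop_labels[s] == "pop2")
        ref = min(two_pop_gm.sample_ids)
        assert ref not in split   # canonical orientation
        support = _support_for(tree, split)
        assert support is not None and support >= 95


def _collect_supports(tree):
    out = []

    def visit(node):
        if node.support is not None:
            out.append(node.support)
        for c, _ in node.children:
            visit(c)

    visit(tree.root)
    return out


def _support_for(tree, bipartition):
    # a bipartition may be realized by the node holding either side
    complement = frozenset(tree.leaf_names) - bipartition
    found = []

    def visit(node):
        if not node.is_leaf:
            below = frozenset(node.leaves())
            if below in (bipartition, complement) and node.support is not None:
                found.append(node.support)
            for c, _ in node.children:
                visit(c)

    visit(tree.root)
    return found[0] if found else None


class TestPCA:
    def test_duplicate_samples_identical_scores(self):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 3, size=(1, 40)).astype(np.int8)
        other = rng.integers(0, 3, size=(3, 40)).astype(np.int8)
        gm = make_gm(np.vstack([base, base, other]), pops=["A"] * 5)
        res = pca(gm, k=3)
        np.testing.assert_allclose(res.scores[0], res.scores[1], atol=1e-10)

    def test_eigenvalues_match_svd_oracle(self, rng):
        dosage = rng.integers(0, 3, size=(10, 200)).astype(np.int8)
        gm = make_gm(dosage, pops=["A"] * 10)
        res = pca(gm, k=10)
        # independent route: full SVD of the normalized matrix
        x = dosage.astype(float)
        p = x.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        x = (x[:, keep] - 2 * p[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
        sv = np.linalg.svd(x, compute_uv=False)
        expected = sv ** 2 / (keep.sum() - 1)
        np.testing.assert_allclose(res.eigenvalues, expected[:10], atol=1e-8)

    def test_pc1_separates_diverged_populations(self, two_pop_gm):
        res = pca(two_pop_gm, k=2)
        labels = np.array([two_pop_gm.pop_labels[s] for s in res.sample_ids])
        pc1 = res.scores[:, 0]
        thr = (pc1[labels == "pop1"].mean() + pc1[labels == "pop2"].mean()) / 2
        side = pc1 > thr
        errors = min((side == (labels == "pop2")).sum(),
                     (side == (labels == "pop1")).sum())
        assert errors == 0

    def test_pc1_variance_monotone_in_f(self):
        from sweeptx.synthetic_data import SimConfig, simulate_genotypes

        varexp = []
        for f in (0.02, 0.1, 0.3):
            cfg = SimConfig(seed=44, chrom_lengths={"chr1": 500_000},
                            n_snps=5_000, fst_background=f)
            gm, _ = simulate_genotypes(cfg)
            varexp.append(pca(gm, k=2).variance_explained[0])
        assert varexp[0] < varexp[1] < varexp[2]

    def test_all_monomorphic_rejected(self):
        gm = make_gm(np.zeros((4, 10), dtype=np.int8), pops=["A"] * 4)
        with pytest.raises(Exception):
            pca(gm)
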