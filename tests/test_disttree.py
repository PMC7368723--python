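"""Nei distance, UPGMA (vs a brute-force oracle), bootstrap, tree cut, PCoA."""

import itertools

import numpy as np
import pytest

import heterotic as ht
from heterotic.disttree import DistanceMatrix
from heterotic.qc import MISSING

from conftest import make_matrix


def brute_force_average_linkage(labels, d):
    """Naive average-linkage oracle: cluster-average distances recomputed
    from the original matrix at every step (no Lance-Williams update)."""
    idx = {lab: i for i, lab in enumerate(labels)}
    clusters = {lab: frozenset([lab]) for lab in labels}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            pairs = [(idx[x], idx[y]) for x in clusters[a] for y in clusters[b]]
            avg = np.mean([d[i, j] for i, j in pairs])
            key = (avg, tuple(sorted((a, b))))
            if best is None or key < best[0:2]:
                best = (avg, tuple(sorted((a, b))), a, b)
        avg, _, a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        rep = min(merged)
        clusters[rep] = merged
        merges.append((avg / 2.0, merged))
    return merges


class TestNeiDistance:
    def test_identical_individuals_distance_zero(self):
        g = make_matrix([[0, 2, 1], [0, 2, 1]])
        assert ht.nei_distance(g).values[0, 1] == pytest.approx(0.0)

    def test_opposite_homozygotes_distance_one(self):
        g = make_matrix([[0, 0, 0], [2, 2, 2]])
        assert ht.nei_distance(g).values[0, 1] == pytest.approx(1.0)

    def test_hand_evaluated_het_pair(self):
        # loci (hom-ref, hom-ref) vs (het, hom-ref):
        # D = 1 - (sqrt(0.5) + 1)/2 = 0.146447
        g = make_matrix([[0, 0], [1, 0]])
        assert ht.nei_distance(g).values[0, 1] == pytest.approx(0.1464466, abs=1e-6)

    def test_missing_loci_renormalised_pairwise(self):
        g = make_matrix([[0, 0, MISSING], [2, MISSING, 0]])
        d = ht.nei_distance(g)
        assert d.values[0, 1] == pytest.approx(1.0)  # only locus 0 shared
        assert d.pair_loci[0, 1] == 1

    def test_no_shared_loci_is_an_error(self):
        g = make_matrix([[0, MISSING], [MISSING, 0]])
        with pytest.raises(ValueError, match="share no genotyped loci"):
            ht.nei_distance(g)

    def test_invariant_to_label_swap_and_marker_order(self, panel_and_truth):
        g, _ = panel_and_truth
        d1 = ht.nei_distance(g).values
        flipped = ht.GenotypeMatrix(
            g.individual_ids, g.marker_ids, g.alleles,
            np.where(g.calls == MISSING, MISSING, 2 - g.calls).astype(np.int8),
        )
        np.testing.assert_allclose(ht.nei_distance(flipped).values, d1, atol=1e-12)
        perm = np.random.default_rng(0).permutation(g.n_markers)
        np.testing.assert_allclose(
            ht.nei_distance(g.subset_markers(perm)).values, d1, atol=1e-12
        )

    def test_monotone_in_differing_homozygous_loci(self):
        base = np.zeros((2, 10), dtype=np.int8)
        prev = -1.0
        for k in range(11):
            calls = base.copy()
            calls[1, :k] = 2
            d = ht.nei_distance(make_matrix(calls)).values[0, 1]
            assert d > prev
            prev = d

    def test_nei1972_variant_unbounded_and_zero_for_identical(self):
        g = make_matrix([[0, 2], [0, 2], [2, 0]])
        d = ht.nei_distance(g, variant="nei1972")
        assert d.values[0, 1] == pytest.approx(0.0)
        assert d.values[0, 2] > 1.0  # -ln of a tiny identity


class TestUpgma:
    def test_two_leaves_merge_at_half_distance(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        t = ht.upgma(d)
        assert t.root.height == pytest.approx(0.2)

    def test_block_structure_topology(self):
        labels = ["A", "B", "C", "D"]
        m = np.array(
            [
                [0.0, 0.1, 0.8, 0.9],
                [0.1, 0.0, 0.9, 0.8],
                [0.8, 0.9, 0.0, 0.2],
                [0.9, 0.8, 0.2, 0.0],
            ]
        )
        t = ht.upgma(DistanceMatrix(labels, m))
        assert {frozenset("AB"), frozenset("CD")} <= t.clades()

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        labels = [chr(65 + i) for i in range(n)]
        for _ in range(40):
            pts = rng.normal(size=(n, 3))
            m = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            mine = ht.upgma(DistanceMatrix(labels, m))
            oracle = brute_force_average_linkage(labels, m)
            assert [set(s) for _, s in mine.merges] == [set(s) for _, s in oracle]
            np.testing.assert_allclose(
                [h for h, _ in mine.merges], [h for h, _ in oracle], atol=1e-10
            )

    def test_heights_are_ultrametric(self, panel_and_truth):
        g, _ = panel_and_truth
        t = ht.upgma(ht.nei_distance(g))

        def check(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                check(c)

        check(t.root)

    def test_tie_rule_is_deterministic(self):
        # equilateral: all three distances tie; smallest label pair merges first
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 0.0)
        t = ht.upgma(DistanceMatrix(["c", "a", "b"], m))
        assert frozenset("ab") in t.clades()

    def test_non_finite_rejected(self):
        m = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            ht.upgma(DistanceMatrix(["a", "b"], m))

    def test_newick_parses_with_dendropy(self, separated_panel):
        import dendropy

        g, _ = separated_panel
        t = ht.bootstrap_support(g, n_boot=5, seed=0)
        tree = dendropy.Tree.get(data=t.to_newick(), schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == set(g.individual_ids)


class TestCutTree:
    def test_extreme_cuts(self, panel_and_truth):
        g, _ = panel_and_truth
        t = ht.upgma(ht.nei_distance(g))
        n = g.n_individuals
        assert set(ht.cut_tree(t, 1).values()) == {1}
        assert len(set(ht.cut_tree(t, n).values())) == n

    def test_recovers_separated_groups(self, separated_panel):
        g, truth = separated_panel
        t = ht.upgma(ht.nei_distance(g))
        cut = ht.cut_tree(t, 5)
        # partition must match truth up to label permutation
        from collections import defaultdict

        mapping = defaultdict(set)
        for ind, grp in cut.items():
            i = g.individual_ids.index(ind)
            mapping[grp].add(truth.group_labels[i])
        assert all(len(v) == 1 for v in mapping.values())
        assert len(mapping) == 5


class TestBootstrap:
    def test_deep_divergence_support(self):
        cfg = ht.PanelConfig(
            n_groups=2, n_per_group=5, n_mixed=0, n_markers=150,
            fst=0.9, het_rate=0.0, missing_rate=0.0, seed=4,
        )
        g, truth = ht.simulate_panel(cfg)
        t = ht.bootstrap_support(g, n_boot=100, seed=1)
        group1 = frozenset(
            ind for ind, lab in zip(g.individual_ids, truth.group_labels) if lab == "1"
        )
        supports = {n.leaves(): n.support for n in t.internal_nodes()}
        assert supports.get(group1, 0.0) >= 0.99

    def test_single_replicate_supports_are_binary(self, separated_panel):
        g, _ = separated_panel
        t = ht.bootstrap_support(g, n_boot=1, seed=3)
        all_leaves = frozenset(g.individual_ids)
        for node in t.internal_nodes():
            if node.leaves() != all_leaves:
                assert node.support in (0.0, 1.0)

    def test_same_seed_same_supports(self, separated_panel):
        g, _ = separated_panel
        t1 = ht.bootstrap_support(g, n_boot=20, seed=9)
        t2 = ht.bootstrap_support(g, n_boot=20, seed=9)
        s1 = {n.leaves(): n.support for n in t1.internal_nodes()}
        s2 = {n.leaves(): n.support for n in t2.internal_nodes()}
        assert s1 == s2

    def test_root_support_is_one_and_range_valid(self, separated_panel):
        g, _ = separated_panel
        t = ht.bootstrap_support(g, n_boot=30, seed=2)
        sup = [n.support for n in t.internal_nodes()]
        assert all(0.0 <= s <= 1.0 for s in sup)
        root_leafset = frozenset(g.individual_ids)
        root = [n for n in t.internal_nodes() if n.leaves() == root_leafset]
        assert root[0].support == 1.0

    def test_invalid_n_boot(self, separated_panel):
        g, _ = separated_panel
        with pytest.raises(ValueError, match="n_boot"):
            ht.bootstrap_support(g, n_boot=0)


class TestPcoa:
    def test_euclidean_identity(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(8, 4))
        m = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        o = ht.pcoa(DistanceMatrix([f"p{i}" for i in range(8)], m))
        rec = np.sqrt(((o.coordinates[:, None] - o.coordinates[None]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, m, atol=1e-8)

    def test_equilateral_triangle_geometry(self):
        m = np.full((3, 3), 1.0)
        np.fill_diagonal(m, 0.0)
        o = ht.pcoa(DistanceMatrix(["a", "b", "c"], m))
        assert o.eigenvalues[0] == pytest.approx(o.eigenvalues[1], rel=1e-9)
        assert abs(o.eigenvalues[2]) < 1e-12

    def test_matches_scikit_bio(self, panel_and_truth):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        g, _ = panel_and_truth
        d = ht.nei_distance(g)
        mine = ht.pcoa(d)
        ref = skbio_pcoa(d.values, number_of_dimensions=3)
        for ax in range(3):
            a = mine.coordinates[:, ax]
            b = ref.samples.iloc[:, ax].to_numpy()
            assert abs(abs(np.corrcoef(a, b)[0, 1]) - 1.0) < 1e-6

    def test_axes_ordered_and_percent_bounded(self, panel_and_truth):
        g, _ = panel_and_truth
        o = ht.pcoa(ht.nei_distance(g))
        assert (np.diff(o.eigenvalues) <= 1e-9).all()
        assert o.proportion_explained.sum() <= 100.0 + 1e-9

    def test_truncation_warns(self):
        m = np.full((3, 3), 1.0)
        np.fill_diagonal(m, 0.0)
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            o = ht.pcoa(DistanceMatrix(["a", "b", "c"], m), n_axes=3)
        assert o.coordinates.shape[1] == 2

    def test_groups_separate_on_first_axes(self, separated_panel):
        g, truth = separated_panel
        o = ht.pcoa(ht.nei_distance(g), n_axes=4)
        from scipy.spatial.distance import cdist

        labels = np.array(truth.group_labels)
        # silhouette-flavoured check: within-group spread << between-group
        within, between = [], []
        for lab in np.unique(labels):
            pts = o.coordinates[labels == lab]
            other = o.coordinates[labels != lab]
            within.append(cdist(pts, pts).mean())
            between.append(cdist(pts, other).mean())
        assert np.mean(within) < 0.5 * np.mean(between)
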