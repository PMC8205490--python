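"""Neighbor joining, rooting, bootstrap, clade cutting."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import TreeNode
from skbio.tree import nj as skbio_nj

import aragsl as ag


def aln(seqs, outgroup=None):
    outgroup = outgroup or next(iter(seqs))
    return ag.Alignment(dict(seqs), outgroup)


# ---------------------------------------------------------------- oracles


def enumerate_unrooted_topologies(taxa):
    """All unrooted binary topologies over ``taxa`` as bipartition sets,
    built by sequential taxon insertion on every edge."""

    def edges(tree):
        # tree as nested tuples; collect all subtree positions
        out = []

        def walk(node, path):
            out.append(path)
            if isinstance(node, tuple):
                for i, child in enumerate(node):
                    walk(child, path + (i,))

        for i, child in enumerate(tree):
            walk(child, (i,))
        return out

    def insert(tree, path, leaf):
        if len(path) == 1:
            return tuple(
                (c, leaf) if i == path[0] else c for i, c in enumerate(tree)
            )
        i = path[0]
        return tuple(
            insert_sub(c, path[1:], leaf) if i == j else c
            for j, c in enumerate(tree)
        )

    def insert_sub(node, path, leaf):
        if not path:
            return (node, leaf)
        return tuple(
            insert_sub(c, path[1:], leaf) if i == path[0] else c
            for i, c in enumerate(node)
        )

    trees = [tuple(taxa[:3])]
    for leaf in taxa[3:]:
        nxt = []
        for t in trees:
            for path in edges(t):
                if len(path) == 1:
                    nxt.append(insert(t, path, leaf))
                else:
                    nxt.append(insert(t, path, leaf))
        trees = nxt
    return trees


def topology_bipartitions(tree, all_taxa):
    """Non-trivial bipartitions of a nested-tuple topology."""
    out = set()

    def tips(node):
        if isinstance(node, tuple):
            return frozenset().union(*(tips(c) for c in node))
        return frozenset([node])

    def walk(node):
        if isinstance(node, tuple):
            for c in node:
                side = tips(c)
                if 2 <= len(side) <= len(all_taxa) - 2:
                    out.add(min(side, frozenset(all_taxa) - side, key=sorted))
                walk(c)

    walk(tree)
    return out


def tree_bipartitions(tree):
    all_tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(all_tips) - 2:
            out.add(min(side, all_tips - side, key=sorted))
    return out


def random_additive_matrix(rng, n):
    """Distances realized by a random binary tree with positive lengths."""
    taxa = [f"t{i}" for i in range(n)]
    tree = TreeNode.read([_random_newick(rng, taxa)])
    d = np.zeros((n, n))
    dists = tree.tip_tip_distances()
    ids = list(dists.ids)
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            d[i, j] = dists[ids.index(a), ids.index(b)]
    return DistanceMatrix(d, taxa), tree


def _random_newick(rng, taxa):
    items = [f"{t}:{rng.uniform(0.5, 2.0):.4f}" for t in taxa]
    while len(items) > 3:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        merged = (
            f"({items[i]},{items[j]}):{rng.uniform(0.5, 2.0):.4f}"
        )
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [merged]
    return "(" + ",".join(items) + ");"


# ---------------------------------------------------------------- p-distance


class TestPDistance:
    def test_identical_sequences(self):
        a = aln({"A": "ACGTACGT", "B": "ACGTACGT", "C": "ACGTACGT"})
        dm = ag.p_distance_matrix(a)
        assert dm["A", "B"] == 0.0

    def test_one_mismatch_in_four(self):
        a = aln({"A": "ACGT", "B": "ACGA", "C": "ACGT"})
        assert ag.p_distance_matrix(a)["A", "B"] == pytest.approx(0.25)

    def test_pairwise_deletion_of_gaps(self):
        a = aln({"A": "AC-T", "B": "ACGT", "C": "TTTT"})
        assert ag.p_distance_matrix(a)["A", "B"] == pytest.approx(0.0)

    def test_no_comparable_sites_raises(self):
        a = aln({"A": "AC--", "B": "--GT", "C": "ACGT"})
        with pytest.raises(ValueError, match="no comparable sites"):
            ag.p_distance_matrix(a)


# ---------------------------------------------------------------- NJ


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ["A", "B", "C"])
        tree = ag.neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(1.0, abs=1e-12)
        assert lengths["B"] == pytest.approx(1.0, abs=1e-12)
        assert lengths["C"] == pytest.approx(3.0, abs=1e-12)

    def test_four_taxon_additive_recovers_tree_and_lengths(self):
        # tree ((A:1,B:2):0.5,C:0.7,D:1.3): additive distances
        d = {
            ("A", "B"): 3.0,
            ("A", "C"): 2.2,
            ("A", "D"): 2.8,
            ("B", "C"): 3.2,
            ("B", "D"): 3.8,
            ("C", "D"): 2.0,
        }
        taxa = ["A", "B", "C", "D"]
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = taxa.index(x), taxa.index(y)
            mat[i, j] = mat[j, i] = v
        tree = ag.neighbor_joining(DistanceMatrix(mat, taxa))
        assert tree_bipartitions(tree) == {frozenset({"A", "B"})}
        dists = tree.tip_tip_distances()
        for (x, y), v in d.items():
            assert dists[x, y] == pytest.approx(v, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_matrices_recover_generating_topology(self, n):
        """NJ on additive distances must find the (unique) zero-error
        topology among all exhaustively enumerated unrooted topologies."""
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            dm, true_tree = random_additive_matrix(rng, n)
            nj_tree = ag.neighbor_joining(dm)
            assert tree_bipartitions(nj_tree) == tree_bipartitions(true_tree)
            # oracle: the true bipartition set is realizable by exactly one
            # enumerated topology, and path lengths are reproduced
            taxa = list(dm.ids)
            matches = [
                t
                for t in enumerate_unrooted_topologies(taxa)
                if topology_bipartitions(t, taxa) == tree_bipartitions(nj_tree)
            ]
            assert len(matches) >= 1
            dists = nj_tree.tip_tip_distances()
            for i, a in enumerate(taxa):
                for b in taxa[i + 1 :]:
                    assert dists[a, b] == pytest.approx(dm[a, b], abs=1e-9)

    def test_matches_skbio_reference_topology(self):
        rng = np.random.default_rng(17)
        n = 8
        base = rng.uniform(0.1, 1.0, size=(n, n))
        mat = (base + base.T) / 2
        np.fill_diagonal(mat, 0.0)
        ids = [f"t{i}" for i in range(n)]
        dm = DistanceMatrix(mat, ids)
        ours = ag.neighbor_joining(dm)
        reference = skbio_nj(dm)
        assert tree_bipartitions(ours) == tree_bipartitions(reference)

    def test_asymmetric_matrix_rejected(self):
        class Fake:
            ids = ["a", "b", "c"]
            data = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]])

        with pytest.raises(ValueError, match="symmetric"):
            ag.neighbor_joining(Fake())

    def test_ultrametric_shift_preserves_topology(self):
        rng = np.random.default_rng(4)
        dm, _ = random_additive_matrix(rng, 6)
        shifted = DistanceMatrix(
            dm.data + 2.0 * (1 - np.eye(len(dm.ids))), dm.ids
        )
        assert tree_bipartitions(ag.neighbor_joining(dm)) == tree_bipartitions(
            ag.neighbor_joining(shifted)
        )


# ---------------------------------------------------------------- rooting


class TestRooting:
    def three_taxon_tree(self):
        dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ["A", "B", "C"])
        return ag.neighbor_joining(dm)

    def test_outgroup_forces_ingroup_clade(self):
        rooted = ag.root_by_outgroup(self.three_taxon_tree(), "C")
        assert len(rooted.children) == 2
        ingroup = [c for c in rooted.children if c.name != "C"][0]
        assert {t.name for t in ingroup.tips()} == {"A", "B"}

    def test_idempotent(self):
        once = ag.root_by_outgroup(self.three_taxon_tree(), "C")
        twice = ag.root_by_outgroup(once, "C")
        assert once.compare_rfd(twice) == 0
        d1 = once.tip_tip_distances()
        d2 = twice.tip_tip_distances()
        for a, b in itertools.combinations(["A", "B", "C"], 2):
            assert d1[a, b] == pytest.approx(d2[a, b], abs=1e-12)

    def test_path_lengths_preserved(self):
        rng = np.random.default_rng(8)
        dm, _ = random_additive_matrix(rng, 6)
        unrooted = ag.neighbor_joining(dm)
        rooted = ag.root_by_outgroup(unrooted, "t0")
        before = unrooted.tip_tip_distances()
        after = rooted.tip_tip_distances()
        for a, b in itertools.combinations(list(dm.ids), 2):
            assert after[a, b] == pytest.approx(before[a, b], abs=1e-10)

    def test_missing_outgroup_raises(self):
        with pytest.raises(ValueError, match="not found"):
            ag.root_by_outgroup(self.three_taxon_tree(), "nope")


# ---------------------------------------------------------------- bootstrap


class TestBootstrap:
    def two_clade_alignment(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 4, size=120)
        other = (base + 1) % 4
        bases = np.array(list("ACGT"))
        seqs = {}
        for i in range(3):
            seqs[f"x{i}"] = "".join(bases[base])
            seqs[f"y{i}"] = "".join(bases[other])
        return ag.Alignment(seqs, "x0")

    def test_perfect_signal_gives_full_support(self):
        a = self.two_clade_alignment()
        tree = ag.bootstrap_support(a, n_reps=50, seed=1)
        sups = [
            n.support for n in tree.non_tips(include_self=False) if n.support is not None
        ]
        assert sups and all(s == 1.0 for s in sups)

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ag.bootstrap_support(self.two_clade_alignment(), n_reps=0)

    def test_deterministic_and_bounded(self, small_alignment):
        truth, alignment = small_alignment
        sub_ids = sorted(alignment.ids)[:20]
        sub = ag.Alignment(
            {i: alignment.sequences[i] for i in set(sub_ids) | {alignment.outgroup_id}},
            alignment.outgroup_id,
        )
        t1 = ag.bootstrap_support(sub, n_reps=25, seed=5)
        t2 = ag.bootstrap_support(sub, n_reps=25, seed=5)
        s1 = sorted(
            n.support for n in t1.non_tips(include_self=False) if n.support is not None
        )
        s2 = sorted(
            n.support for n in t2.non_tips(include_self=False) if n.support is not None
        )
        assert s1 == s2
        assert all(0.0 <= s <= 1.0 for s in s1)

    def test_supports_match_independent_bipartition_oracle(self):
        """Recompute supports with dendropy's bipartition machinery on the
        same resampled replicates (same seed, same resampling rule)."""
        import dendropy

        a = self.two_clade_alignment()
        seed, n_reps = 11, 20
        tree = ag.bootstrap_support(a, n_reps=n_reps, seed=seed)

        ids = sorted(a.ids)
        rng = np.random.default_rng(seed)
        seq_mat = np.array([list(a.sequences[i]) for i in ids])
        taxa = dendropy.TaxonNamespace(ids)
        counts = {}
        for _ in range(n_reps):
            cols = rng.integers(0, a.length, size=a.length)
            resampled = ag.Alignment(
                {i: "".join(row) for i, row in zip(ids, seq_mat[:, cols])},
                a.outgroup_id,
            )
            rep = ag.neighbor_joining(ag.p_distance_matrix(resampled))
            dt = dendropy.Tree.get(
                data=str(rep) if str(rep).endswith(";") else str(rep) + ";",
                schema="newick",
                taxon_namespace=taxa,
            )
            dt.encode_bipartitions()
            for edge in dt.preorder_edge_iter():
                bp = edge.bipartition
                if bp.is_trivial():
                    continue
                names = frozenset(
                    t.label
                    for t in bp.leafset_taxa(taxa)
                )
                side = min(names, frozenset(ids) - names, key=sorted)
                counts[side] = counts.get(side, 0) + 1
        all_tips = frozenset(ids)
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            side = min(side, all_tips - side, key=sorted)
            if 2 <= len(side) <= len(all_tips) - 2:
                assert node.support == pytest.approx(
                    counts.get(side, 0) / n_reps, abs=1e-12
                )


# ---------------------------------------------------------------- clades


class TestCladeCutting:
    def rooted_synthetic(self, small_alignment):
        truth, alignment = small_alignment
        dm = ag.p_distance_matrix(alignment)
        return truth, alignment, ag.root_by_outgroup(
            ag.neighbor_joining(dm), alignment.outgroup_id
        )

    def test_k_one_is_single_clade(self, small_alignment):
        truth, alignment, rooted = self.rooted_synthetic(small_alignment)
        clades = ag.cut_clades(rooted, 1, outgroup_id=alignment.outgroup_id)
        assert set(clades.values()) == {1}
        assert len(clades) == len(truth)

    def test_k_n_is_singletons(self, small_alignment):
        truth, alignment, rooted = self.rooted_synthetic(small_alignment)
        n = len(truth)
        clades = ag.cut_clades(rooted, n, outgroup_id=alignment.outgroup_id)
        assert sorted(clades.values()) == list(range(1, n + 1))

    def test_eight_clades_recovered_exactly(self, small_alignment):
        from sklearn.metrics import adjusted_rand_score

        truth, alignment, rooted = self.rooted_synthetic(small_alignment)
        clades = ag.cut_clades(rooted, 8, outgroup_id=alignment.outgroup_id)
        tf = ag.truth_to_frame(truth)
        ari = adjusted_rand_score(
            tf["mam_clade"], [clades[a] for a in tf["accession_id"]]
        )
        assert ari == pytest.approx(1.0)

    def test_out_of_range_k(self, small_alignment):
        truth, alignment, rooted = self.rooted_synthetic(small_alignment)
        with pytest.raises(ValueError, match="out of range"):
            ag.cut_clades(rooted, 0, outgroup_id=alignment.outgroup_id)
        with pytest.raises(ValueError, match="out of range"):
            ag.cut_clades(rooted, len(truth) + 1, outgroup_id=alignment.outgroup_id)


class TestConcordance:
    def test_pure_clades(self):
        clades = {"a": 1, "b": 1, "c": 2}
        labels = {"a": "Allyl", "b": "Allyl", "c": "3MSO"}
        per_clade, overall = ag.clade_chemotype_concordance(clades, labels)
        assert overall == 1.0

    def test_fifty_fifty_clades(self):
        clades = {"a": 1, "b": 1, "c": 2, "d": 2}
        labels = {"a": "X", "b": "Y", "c": "X", "d": "Y"}
        per_clade, overall = ag.clade_chemotype_concordance(clades, labels)
        assert (per_clade["purity"] == 0.5).all()
        assert overall == 0.5

    def test_label_permutation_invariance(self):
        clades = {"a": 1, "b": 1, "c": 2, "d": 2}
        labels = {"a": "X", "b": "X", "c": "X", "d": "Y"}
        swap = {"X": "Y", "Y": "X"}
        _, o1 = ag.clade_chemotype_concordance(clades, labels)
        _, o2 = ag.clade_chemotype_concordance(
            clades, {k: swap[v] for k, v in labels.items()}
        )
        assert o1 == o2

    def test_disjoint_ids_raise(self):
        with pytest.raises(ValueError, match="share no accessions"):
            ag.clade_chemotype_concordance({"a": 1}, {"b": "X"})


class TestNewickRoundTrip:
    def test_topology_lengths_supports_preserved(self, tmp_path, small_alignment):
        truth, alignment = small_alignment
        sub_ids = sorted(alignment.ids)[:15]
        sub = ag.Alignment(
            {i: alignment.sequences[i] for i in set(sub_ids) | {alignment.outgroup_id}},
            alignment.outgroup_id,
        )
        tree = ag.bootstrap_support(sub, n_reps=10, seed=3)
        path = tmp_path / "tree.nwk"
        ag.write_newick(tree, path)
        back = ag.read_newick(path)
        assert tree.compare_rfd(back) == 0
        d1, d2 = tree.tip_tip_distances(), back.tip_tip_distances()
        for a, b in itertools.combinations(sorted(sub.ids)[:6], 2):
            assert d1[a, b] == pytest.approx(d2[a, b], abs=1e-10)
        sup1 = sorted(
            n.support for n in tree.non_tips(include_self=False) if n.support is not None
        )
        sup2 = sorted(
            getattr(n, "support", None)
            for n in back.non_tips(include_self=False)
            if getattr(n, "support", None) is not None
        )
        assert np.allclose(sup1, sup2)
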