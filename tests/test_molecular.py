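"""Haplotypes, K2P distances, NJ/ME trees, bootstrap and newick I/O."""

import math

import numpy as np
import pytest

from fleagm.molecular import (
    AmbiguousReferenceError,
    DistanceMatrixK2P,
    HaplotypeIntegrityError,
    K2PSaturationError,
    SequenceRecord,
    _dendropy_to_utree,
    bootstrap_support,
    collapse_haplotypes,
    k2p_distance,
    k2p_inverse,
    k2p_matrix,
    match_reference,
    max_intragroup_distance,
    me_refine,
    nj_tree,
    read_fasta,
    read_newick,
    tree_length,
    write_fasta,
    write_newick,
)


def _random_seq(rng, n=450):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(seq, positions, rng):
    s = list(seq)
    for p in positions:
        s[p] = rng.choice([c for c in "ACGT" if c != s[p]])
    return "".join(s)


class TestFasta:
    def test_round_trip_with_species_tags(self, tmp_path, rng):
        records = [
            SequenceRecord(f"s{i}", _random_seq(rng, int(rng.integers(100, 700))),
                           species=rng.choice(["canis", "orientis", "unknown"]))
            for i in range(10)
        ]
        f = tmp_path / "seqs.fasta"
        write_fasta(records, f)
        back = read_fasta(f)
        assert back == records

    def test_wrapped_sequences_concatenated(self, tmp_path):
        f = tmp_path / "w.fasta"
        f.write_text(">a\nACGT\nACGT\nAC\n")
        (rec,) = read_fasta(f)
        assert rec.sequence == "ACGTACGTAC"

    def test_empty_file_warns(self, tmp_path, caplog):
        f = tmp_path / "empty.fasta"
        f.write_text("")
        with caplog.at_level("WARNING"):
            assert read_fasta(f) == []
        assert "no sequences" in caplog.text

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError, match="illegal character"):
            SequenceRecord("bad", "ACGTX")


class TestCollapseHaplotypes:
    def test_count_spectrum(self, rng):
        s1, s2 = _random_seq(rng), _random_seq(rng)
        records = [SequenceRecord(f"a{i}", s1) for i in range(3)] + [
            SequenceRecord(f"b{i}", s2) for i in range(2)
        ]
        table = collapse_haplotypes(records)
        assert [h.count for h in table.haplotypes] == [3, 2]
        assert table.haplotypes[0].haplotype_id == "H1"
        assert table.n_sequences == 5

    def test_terminal_truncation_same_haplotype_in_overlap_mode(self, rng):
        s = _random_seq(rng, 600)
        records = [SequenceRecord("full", s), SequenceRecord("trunc", s[:-10])]
        assert len(collapse_haplotypes(records, mode="common_overlap")) == 1
        assert len(collapse_haplotypes(records, mode="full_length")) == 2

    def test_mixed_species_haplotype_rejected(self, rng):
        s = _random_seq(rng)
        records = [
            SequenceRecord("a", s, species="canis"),
            SequenceRecord("b", s, species="orientis"),
        ]
        with pytest.raises(HaplotypeIntegrityError):
            collapse_haplotypes(records)

    def test_idempotent_and_count_conserving(self, rng):
        seqs = [_random_seq(rng, 420) for _ in range(4)]
        records = [
            SequenceRecord(f"r{i}", seqs[int(rng.integers(4))]) for i in range(20)
        ]
        t1 = collapse_haplotypes(records)
        assert t1.n_sequences == 20
        reps = [SequenceRecord(h.haplotype_id, h.sequence) for h in t1.haplotypes]
        t2 = collapse_haplotypes(reps)
        assert len(t2) == len(t1)


class TestMatchReference:
    def test_exact_and_contained_matches(self, rng):
        s = _random_seq(rng, 600)
        table = collapse_haplotypes([SequenceRecord("q", s[5:])])
        panel = [SequenceRecord("h10", s), SequenceRecord("h11", _random_seq(rng, 600))]
        out = match_reference(table, panel)
        assert out.haplotypes[0].matched_reference_id == "h10"

    def test_one_substitution_away_is_novel(self, rng):
        s = _random_seq(rng, 600)
        table = collapse_haplotypes([SequenceRecord("q", _mutate(s, [300], rng))])
        out = match_reference(table, [SequenceRecord("h1", s)])
        assert out.haplotypes[0].matched_reference_id is None

    def test_short_overlap_is_no_call(self, rng, caplog):
        s = _random_seq(rng, 600)
        table = collapse_haplotypes([SequenceRecord("q", s)])
        with caplog.at_level("WARNING"):
            out = match_reference(table, [SequenceRecord("h1", s[:350])])
        assert out.haplotypes[0].matched_reference_id is None
        assert "no call" in caplog.text

    def test_ambiguous_match_rejected(self, rng):
        s = _random_seq(rng, 600)
        table = collapse_haplotypes([SequenceRecord("q", s)])
        with pytest.raises(AmbiguousReferenceError):
            match_reference(table, [SequenceRecord("h1", s), SequenceRecord("h2", s[:500])])


class TestK2P:
    def test_identical_sequences(self, rng):
        s = _random_seq(rng)
        assert k2p_distance(s, s) == 0.0

    def test_spot_values(self):
        # 100 sites, 10 transitions, 0 transversions: -1/2 ln(0.8)
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        assert k2p_distance(a, b) == pytest.approx(0.111572, abs=5e-7)
        # 5 transitions + 5 transversions: -1/2 ln(0.85) - 1/4 ln(0.9)
        c = "G" * 5 + "C" * 5 + "A" * 90
        expected = -0.5 * math.log(0.85) - 0.25 * math.log(0.9)  # 0.1075996
        assert k2p_distance(a, c) == pytest.approx(expected, abs=1e-12)

    def test_pairwise_deletion_of_ambiguous_sites(self):
        a = "AAAN" + "A" * 96
        b = "GAAA" + "A" * 96
        # N site dropped: 99 retained sites, 1 transition
        assert k2p_distance(a, b) == pytest.approx(
            -0.5 * math.log(1 - 2 / 99), abs=1e-12
        )

    def test_saturation_raises(self):
        with pytest.raises(K2PSaturationError):
            k2p_distance("A" * 100, "G" * 100)

    def test_inverse_round_trip(self):
        from fleagm.molecular import k2p_from_counts

        for d in (0.01, 0.05, 0.12, 0.3):
            P, Q = k2p_inverse(d, 2.0)
            assert P / Q == pytest.approx(2.0, rel=1e-9)
            assert k2p_from_counts(P * 1000, Q * 1000, 1000) == pytest.approx(d, rel=1e-9)

    def test_matrix_agrees_with_pairs(self, rng):
        base = _random_seq(rng, 420)
        records = [
            SequenceRecord(f"s{i}", _mutate(base, rng.choice(420, 8, replace=False), rng))
            for i in range(5)
        ]
        M = k2p_matrix(records)
        for i in range(5):
            for j in range(i + 1, 5):
                assert M.matrix[i, j] == k2p_distance(records[i], records[j])
        assert np.allclose(M.matrix, M.matrix.T)

    def test_input_order_permutes_matrix(self, rng):
        records = [SequenceRecord(f"s{i}", _random_seq(rng, 420)) for i in range(4)]
        M1 = k2p_matrix(records)
        perm = [2, 0, 3, 1]
        M2 = k2p_matrix([records[i] for i in perm])
        np.testing.assert_allclose(M2.matrix, M1.matrix[np.ix_(perm, perm)])

    def test_single_sequence_matrix(self, rng):
        M = k2p_matrix([SequenceRecord("s", _random_seq(rng))])
        assert M.matrix.shape == (1, 1) and M.matrix[0, 0] == 0.0

    def test_max_intragroup(self, rng):
        s = _random_seq(rng, 500)
        records = [
            SequenceRecord("a1", s, "canis"),
            SequenceRecord("a2", s, "canis"),
            SequenceRecord("b1", _mutate(s, range(10), rng), "orientis"),
            SequenceRecord("b2", _mutate(s, range(490, 500), rng), "orientis"),
            SequenceRecord("c1", s, "felis"),
        ]
        M = k2p_matrix(records)
        out = max_intragroup_distance(M, [r.species for r in records])
        assert out["canis"] == 0.0
        assert out["orientis"] == pytest.approx(M.matrix[2, 3])
        assert out["felis"] is None


def _matrix(ids, M):
    return DistanceMatrixK2P(ids=ids, matrix=np.asarray(M, float))


class TestTrees:
    def test_three_taxon_closed_form(self):
        M = _matrix(["A", "B", "C"], [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = nj_tree(M)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((0.2 + 0.3 - 0.4) / 2)
        assert lengths["B"] == pytest.approx((0.2 + 0.4 - 0.3) / 2)
        assert lengths["C"] == pytest.approx((0.3 + 0.4 - 0.2) / 2)

    @staticmethod
    def _random_additive(rng, n_taxa):
        """Random binary-tree additive distances, plus the true bipartitions."""
        from fleagm.molecular import _UTree

        tree = _UTree()
        nodes = [tree.new_node(f"t{i}") for i in range(3)]
        center = tree.new_node()
        for u in nodes:
            tree.connect(u, center, float(rng.uniform(0.05, 0.5)))
        for i in range(3, n_taxa):
            u, v = rng.choice(list(tree.edges())[int(rng.integers(len(tree.edges())))], 2, replace=False)
            length = tree.adj[u][v]
            tree.disconnect(u, v)
            mid = tree.new_node()
            split = float(rng.uniform(0.2, 0.8)) * length
            tree.connect(u, mid, split)
            tree.connect(v, mid, length - split)
            leaf = tree.new_node(f"t{i}")
            tree.connect(leaf, mid, float(rng.uniform(0.05, 0.5)))
        leaves = tree.leaves()
        paths = tree.leaf_paths()
        ids = [tree.leaf_label[u] for u in leaves]
        n = len(leaves)
        D = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                d = sum(
                    tree.adj[e[0]][e[1]] for e in paths[leaves[a]] ^ paths[leaves[b]]
                )
                D[a, b] = D[b, a] = d
        return _matrix(ids, D), tree.bipartitions()

    def test_additive_matrix_recovered_exactly(self, rng):
        for _ in range(5):
            M, true_bips = self._random_additive(rng, 7)
            tree = nj_tree(M)
            ut = _dendropy_to_utree(tree)
            assert ut.bipartitions() == true_bips
            # lengths exact: reconstructed path distances match the matrix
            paths = ut.leaf_paths()
            leaves = ut.leaves()
            idx = {ut.leaf_label[u]: u for u in leaves}
            for a in range(len(M.ids)):
                for b in range(a + 1, len(M.ids)):
                    u, v = idx[M.ids[a]], idx[M.ids[b]]
                    d = sum(ut.adj[e[0]][e[1]] for e in paths[u] ^ paths[v])
                    assert d == pytest.approx(M.matrix[a, b], abs=1e-9)

    def test_ultrametric_pairs_joined_first(self):
        M = _matrix(
            ["A", "B", "C", "D"],
            [
                [0, 0.02, 0.5, 0.5],
                [0.02, 0, 0.5, 0.5],
                [0.5, 0.5, 0, 0.02],
                [0.5, 0.5, 0.02, 0],
            ],
        )
        ut = _dendropy_to_utree(nj_tree(M))
        assert ut.bipartitions() == {frozenset({"C", "D"})}

    def test_skbio_crosscheck(self, rng):
        skbio = pytest.importorskip("skbio")
        import io

        M, _ = self._random_additive(rng, 8)
        dm = skbio.DistanceMatrix(M.matrix, ids=M.ids)
        sk_tree = skbio.tree.nj(dm)
        sk_newick = io.StringIO()
        sk_tree.write(sk_newick)
        import dendropy

        sk_dtree = dendropy.Tree.get(data=sk_newick.getvalue(), schema="newick")
        sk_bips = _dendropy_to_utree(sk_dtree).bipartitions()
        our_bips = _dendropy_to_utree(nj_tree(M)).bipartitions()
        assert our_bips == sk_bips

    def test_me_refine_no_move_on_additive(self, rng):
        M, true_bips = self._random_additive(rng, 6)
        tree = nj_tree(M)
        refined = me_refine(tree, M)
        assert _dendropy_to_utree(refined).bipartitions() == true_bips
        assert tree_length(refined) == pytest.approx(tree_length(tree), abs=1e-9)

    def test_me_never_increases_length(self, rng):
        from fleagm.molecular import _me_refine_utree, _ols_lengths

        for _ in range(5):
            M, _ = self._random_additive(rng, 7)
            noisy = M.matrix + rng.uniform(0, 0.05, M.matrix.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            Mn = _matrix(M.ids, noisy)
            ut = _dendropy_to_utree(nj_tree(Mn))
            nj_len = _ols_lengths(ut, Mn)
            final_len = _me_refine_utree(ut, Mn)
            assert final_len <= nj_len + 1e-12

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(_matrix(["A", "B"], [[0, 1], [1, 0]]))


class TestBootstrap:
    @staticmethod
    def _two_clade_alignment(rng, n_within=3, L=500):
        base = _random_seq(rng, L)
        other = _mutate(base, range(0, 60), rng)  # deep split
        records = []
        for k, founder in enumerate([base, other]):
            for i in range(n_within):
                records.append(
                    SequenceRecord(f"c{k}_{i}", _mutate(founder, [100 + 5 * i + 200 * k], rng))
                )
        return records

    def test_deep_split_full_support(self, rng):
        records = self._two_clade_alignment(rng)
        tree = bootstrap_support(records, n_reps=100, seed=4)
        labels = [
            int(node.label)
            for node in tree.preorder_node_iter()
            if node.label is not None
        ]
        assert max(labels) == 100  # the central edge

    def test_reproducible_given_seed(self, rng):
        records = self._two_clade_alignment(rng)
        t1 = bootstrap_support(records, n_reps=50, seed=7)
        t2 = bootstrap_support(records, n_reps=50, seed=7)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_seed_stability_on_clean_alignment(self, rng):
        records = self._two_clade_alignment(rng, n_within=4)
        def supports(seed):
            tree = bootstrap_support(records, n_reps=300, seed=seed)
            return sorted(
                int(n.label) for n in tree.preorder_node_iter() if n.label is not None
            )
        s1, s2 = supports(1), supports(2)
        assert all(abs(a - b) <= 5 for a, b in zip(s1, s2))

    def test_unaligned_input_rejected(self, rng):
        records = [SequenceRecord("a", _random_seq(rng, 400)),
                   SequenceRecord("b", _random_seq(rng, 410)),
                   SequenceRecord("c", _random_seq(rng, 400)),
                   SequenceRecord("d", _random_seq(rng, 400))]
        with pytest.raises(ValueError, match="equal-length"):
            bootstrap_support(records, n_reps=10, seed=0)


class TestNewick:
    def test_three_leaf_round_trip(self, tmp_path):
        M = _matrix(["A", "B", "C"], [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = nj_tree(M)
        f = tmp_path / "t.nwk"
        write_newick(tree, f)
        back = read_newick(f)
        assert {leaf.taxon.label for leaf in back.leaf_node_iter()} == {"A", "B", "C"}

    def test_quoted_labels_with_spaces(self, tmp_path):
        f = tmp_path / "q.nwk"
        f.write_text("('taxon one':0.1,'taxon two':0.2,t3:0.3);\n")
        tree = read_newick(f)
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert "taxon one" in labels

    def test_random_tree_round_trip(self, tmp_path, rng):
        M, _ = TestTrees._random_additive(rng, 8)
        tree = nj_tree(M)
        f = tmp_path / "r.nwk"
        write_newick(tree, f)
        back = read_newick(f)
        assert _dendropy_to_utree(back).bipartitions() == _dendropy_to_utree(tree).bipartitions()
        assert tree_length(back) == pytest.approx(tree_length(tree), abs=1e-9)

    def test_malformed_newick(self, tmp_path):
        f = tmp_path / "bad.nwk"
        f.write_text("((A:0.1,B:0.2;\n")
        with pytest.raises(ValueError, match="malformed"):
            read_newick(f)
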