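import itertools

import networkx as nx
import numpy as np
import pytest

from graphmer.data_prep import PromoterSet
from graphmer.kmer_graph import build_graph
from graphmer.motif_extraction import (
    Pssm,
    agglomerate,
    find_modules,
    merge_pssms,
    promoter_base_frequencies,
    pssm_distance,
    pssm_from_kmer,
    read_meme,
    top_kmers,
    write_meme,
)


class TestTopKmers:
    @pytest.fixture()
    def graph(self):
        return build_graph(["AAAAAA", "AAAAAC", "AAAACC", "CCCCCC"], theta=2)

    def test_n1_is_argmax(self, graph):
        gm = top_kmers(np.array([0.1, 0.9, 0.2, 0.3]), graph, n=1)
        assert gm.kmers == ["AAAAAC"]

    def test_equal_weights_break_lexicographically(self, graph):
        with pytest.warns(UserWarning):
            gm = top_kmers(np.full(4, 0.5), graph, n=10)
        assert gm.kmers == ["AAAAAA", "AAAAAC", "AAAACC", "CCCCCC"]

    def test_matches_sort_oracle(self, rng):
        kmers = sorted({"".join(rng.choice(list("ACGT"), 6)) for _ in range(30)})
        g = build_graph(kmers, theta=2)
        w = rng.normal(size=len(kmers))
        gm = top_kmers(w, g, n=5, include_negative=True)
        expected = [kmers[i] for i in
                    sorted(np.flatnonzero(w != 0), key=lambda i: (-w[i], kmers[i]))[:5]]
        assert gm.kmers == expected

    def test_negative_weights_excluded_by_default(self, graph):
        w = np.array([0.5, -0.9, 0.1, -0.2])
        with pytest.warns(UserWarning):
            gm = top_kmers(w, graph, n=4)
        assert gm.kmers == ["AAAAAA", "AAAACC"]

    def test_induced_subgraph_attached(self, graph):
        gm = top_kmers(np.array([0.5, 0.4, 0.0, 0.3]), graph, n=3)
        assert set(gm.graph.nodes()) == {"AAAAAA", "AAAAAC", "CCCCCC"}
        assert gm.graph.has_edge("AAAAAA", "AAAAAC")


class TestExtractMotifsOrientation:
    def test_auto_orientation_follows_weight_mass(self):
        from graphmer.data_prep import PromoterSet
        from graphmer.motif_extraction import extract_motifs

        g = build_graph(["AAAAAA", "AAAAAC", "CCCCCC", "CCCCCG"], theta=2)
        ps = PromoterSet(["g1"], ["AAAAAACCCCCCG"])
        # motif mass on the negative side: auto must flip
        w = np.array([-0.8, -0.55, 0.1, 0.05])
        gm, _, _ = extract_motifs(w, g, ps, n_top=2)
        assert gm.sign == -1
        assert gm.kmers == ["AAAAAA", "AAAAAC"]
        # positive-dominant weights are analyzed as-is
        gm2, _, _ = extract_motifs(-w, g, ps, n_top=2)
        assert gm2.sign == 1
        assert gm2.kmers == ["AAAAAA", "AAAAAC"]


class TestFindModules:
    def test_clique_plus_isolated_node(self):
        g = nx.Graph()
        g.add_edges_from(itertools.combinations("abcd", 2))  # K4
        g.add_node("x")
        modules = find_modules(g)
        assert modules == [sorted("abcd")]

    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("c", "a")])
        g.add_edges_from([("p", "q"), ("q", "r"), ("r", "p")])
        modules = find_modules(g)
        assert sorted(map(sorted, modules)) == [["a", "b", "c"], ["p", "q", "r"]]

    def test_edgeless_graph_has_no_modules(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        assert find_modules(g) == []

    def test_haircut_trims_pendant_members(self):
        g = nx.Graph()
        g.add_edges_from(itertools.combinations("abcd", 2))
        g.add_edge("a", "tail")  # degree-1 appendage
        modules = find_modules(g, haircut=True)
        assert "tail" not in modules[0]

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            find_modules(nx.Graph())


class TestPssmFromKmer:
    def test_uniform_background_smoothing_value(self):
        p = pssm_from_kmer("ACG", epsilon=0.1)
        # 0.9 + 0.1 * 0.25 at the consensus base
        np.testing.assert_allclose(p.probs[0, 0], 0.925)
        np.testing.assert_allclose(p.probs[1, 1], 0.925)
        np.testing.assert_allclose(p.probs[0, 1], 0.025)

    def test_rows_sum_to_one_and_positive(self):
        q = np.array([0.3, 0.2, 0.2, 0.3])
        p = pssm_from_kmer("ACGTAC", epsilon=0.2, background=q)
        np.testing.assert_allclose(p.probs.sum(axis=1), 1.0, atol=1e-12)
        assert (p.probs > 0).all()

    def test_small_epsilon_approaches_indicator(self):
        p = pssm_from_kmer("AC", epsilon=1e-9)
        assert p.consensus == "AC"
        np.testing.assert_allclose(p.probs[0, 0], 1.0, atol=1e-8)

    def test_target_count_from_promoters(self):
        ps = PromoterSet(["g1", "g2", "g3"], ["AAACGAA", "TTTTTTT", "ACGACG"])
        p = pssm_from_kmer("ACG", promoters=ps)
        assert p.target_count == 2  # promoters containing the k-mer, not occurrences

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            pssm_from_kmer("ACG", epsilon=0.0)


def brute_force_distance(p1, p2, q=None):
    """Exhaustive-offset oracle recomputing the JS distance definition."""
    q = np.full(4, 0.25) if q is None else q
    pi1 = p1.target_count / (p1.target_count + p2.target_count)
    pi2 = 1 - pi1

    def H(mat):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(mat > 0, mat * np.log2(mat), 0.0)
        return -t.sum(axis=1)

    best = (np.inf, None)
    for off in range(-(p2.length - 1), p1.length):
        lo, hi = min(0, off), max(p1.length, off + p2.length)
        a = np.tile(q, (hi - lo, 1))
        b = np.tile(q, (hi - lo, 1))
        a[-lo : -lo + p1.length] = p1.probs
        b[off - lo : off - lo + p2.length] = p2.probs
        d = float((H(pi1 * a + pi2 * b) - pi1 * H(a) - pi2 * H(b)).sum())
        if d < best[0] - 1e-15:
            best = (d, off)
    return best


class TestPssmDistance:
    def test_identical_pssms_at_distance_zero(self):
        p = pssm_from_kmer("ACGTG", epsilon=0.1)
        d, off = pssm_distance(p, p)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert off == 0

    def test_symmetry_with_negated_offset(self):
        p1 = pssm_from_kmer("ACGTG", epsilon=0.1, target_count=3)
        p2 = pssm_from_kmer("CGT", epsilon=0.1, target_count=5)
        d12, o12 = pssm_distance(p1, p2)
        d21, o21 = pssm_distance(p2, p1)
        assert d12 == pytest.approx(d21, abs=1e-12)
        assert o12 == -o21

    def test_matches_exhaustive_oracle_on_toys(self, rng):
        for _ in range(10):
            m1 = rng.dirichlet(np.ones(4), size=2)
            m2 = rng.dirichlet(np.ones(4), size=3)
            p1 = Pssm(m1, target_count=int(rng.integers(1, 9)))
            p2 = Pssm(m2, target_count=int(rng.integers(1, 9)))
            d, off = pssm_distance(p1, p2)
            d_ref, off_ref = brute_force_distance(p1, p2)
            assert d == pytest.approx(d_ref, abs=1e-12)
            assert off == off_ref

    def test_nonnegative(self, rng):
        for _ in range(20):
            p1 = Pssm(rng.dirichlet(np.ones(4), size=3), 2)
            p2 = Pssm(rng.dirichlet(np.ones(4), size=3), 4)
            d, _ = pssm_distance(p1, p2)
            assert d >= -1e-12

    def test_shifted_copy_found_at_nonzero_offset(self):
        p1 = pssm_from_kmer("ACGTGA", epsilon=0.05)
        p2 = pssm_from_kmer("CGTGA", epsilon=0.05)  # p1 shifted by one
        _, off = pssm_distance(p1, p2)
        assert off == 1


class TestAgglomerate:
    def test_singleton_cluster_returns_seed(self):
        p = agglomerate(["ACGTG"])
        seed = pssm_from_kmer("ACGTG", epsilon=0.1)
        np.testing.assert_allclose(p.probs, seed.probs)

    def test_identical_kmers_merge_to_same_table_with_summed_count(self):
        p = agglomerate(["ACGTG", "ACGTG"])
        seed = pssm_from_kmer("ACGTG", epsilon=0.1)
        np.testing.assert_allclose(p.probs, seed.probs, atol=1e-12)
        assert p.target_count == 2

    def test_merge_count_and_provenance(self):
        kmers = ["ACGTGA", "ACGTGC", "ACGTGG"]
        p = agglomerate(kmers)
        assert sorted(p.kmers) == sorted(kmers)  # m seeds -> m - 1 merges
        assert p.target_count == 3

    def test_three_one_mismatch_kmers_weighted_mixture(self):
        # seeds with counts 1 each; consensus column = equal mixture
        p = agglomerate(["ACGTGA", "ACGTGC", "ACGTGG"])
        assert p.length == 6
        assert p.consensus[:5] == "ACGTG"
        # last column: mixture of A/C/G indicators (0.925 consensus prob each)
        last = p.probs[5]
        np.testing.assert_allclose(last[:3], (0.925 + 2 * 0.025) / 3, atol=1e-9)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            agglomerate([])

    def test_mixture_merge_at_best_offset(self):
        p1 = pssm_from_kmer("ACGTG", epsilon=0.1, target_count=3)
        p2 = pssm_from_kmer("ACGTG", epsilon=0.1, target_count=5)
        merged = merge_pssms(p1, p2)
        np.testing.assert_allclose(merged.probs, p1.probs, atol=1e-12)
        assert merged.target_count == 8


class TestMemeIO:
    def test_roundtrip_lossless(self, tmp_path, rng):
        pssms = [
            pssm_from_kmer("ACGTGA", epsilon=0.1, target_count=7),
            Pssm(rng.dirichlet(np.ones(4), size=5), target_count=12, name="toy"),
        ]
        q = np.array([0.3, 0.2, 0.2, 0.3])
        write_meme(pssms, tmp_path / "m.meme", background=q)
        back = read_meme(tmp_path / "m.meme")
        assert len(back) == 2
        for orig, parsed in zip(pssms, back):
            np.testing.assert_allclose(parsed.probs, orig.probs, atol=1e-6)
            assert parsed.target_count == orig.target_count
            np.testing.assert_allclose(parsed.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_header_declares_minimal_format(self, tmp_path):
        write_meme([pssm_from_kmer("ACG")], tmp_path / "m.meme")
        text = (tmp_path / "m.meme").read_text()
        assert text.startswith("MEME version 4")
        assert "letter-probability matrix" in text


class TestPromoterBaseFrequencies:
    def test_counts_normalized(self):
        ps = PromoterSet(["g1", "g2"], ["AACC", "GGTT"])
        q = promoter_base_frequencies(ps)
        np.testing.assert_allclose(q, [0.25, 0.25, 0.25, 0.25])
        assert q.sum() == pytest.approx(1.0)
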