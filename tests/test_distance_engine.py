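"""Distance metrics, half-matrix container, score tables, k-mer embeddings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from funfamkit.core_model import DomainSequence
from funfamkit.distance_engine import (
    DistanceHalfMatrix,
    EmbeddingVector,
    build_half_matrix,
    cosine_distance,
    euclidean_distance,
    kmer_embed,
    manhattan_distance,
    read_embeddings,
    read_half_matrix,
    score_to_distance,
    write_embeddings,
    write_half_matrix,
)

finite_vec = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=2, max_size=6
)


class TestScalarMetrics:
    def test_cosine_examples(self):
        assert cosine_distance([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert cosine_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)
        assert cosine_distance([1.0, 1.0], [1.0, 0.0]) == pytest.approx(1 - 1 / math.sqrt(2))

    def test_cosine_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_distance([0.0, 0.0], [1.0, 0.0])

    def test_euclidean_345(self):
        assert euclidean_distance([0.0, 0.0], [3.0, 4.0]) == pytest.approx(5.0)

    def test_manhattan_example(self):
        assert manhattan_distance([1.0, 2.0], [4.0, 6.0]) == pytest.approx(7.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance([1.0], [1.0, 2.0])

    @given(u=finite_vec, v=finite_vec, w=finite_vec)
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_metric_axioms(self, u, v, w):
        n = min(len(u), len(v), len(w))
        u, v, w = np.array(u[:n]), np.array(v[:n]), np.array(w[:n])
        for metric in (euclidean_distance, manhattan_distance):
            assert metric(u, u) == 0.0
            assert metric(u, v) == pytest.approx(metric(v, u))
            assert metric(u, w) <= metric(u, v) + metric(v, w) + 1e-9
        assert manhattan_distance(u, v) >= euclidean_distance(u, v) - 1e-9


class TestHalfMatrix:
    def test_rank_unrank_bijection(self):
        for n in (2, 3, 5, 9):
            for k in range(n * (n - 1) // 2):
                i, j = DistanceHalfMatrix.unrank(k, n)
                assert i < j
                assert DistanceHalfMatrix.rank(i, j, n) == k

    def test_lookup_symmetry_and_diagonal(self):
        m = DistanceHalfMatrix(ids=["a", "b", "c"], condensed=np.array([1.0, 4.0, 5.0]))
        assert m.lookup("a", "b") == m.lookup("b", "a") == 1.0
        assert m.lookup("a", "c") == 4.0 and m.lookup("b", "c") == 5.0
        assert m.lookup("b", "b") == 0.0

    def test_wrong_condensed_length_rejected(self):
        with pytest.raises(ValueError, match="n\\(n-1\\)/2"):
            DistanceHalfMatrix(ids=["a", "b", "c"], condensed=np.array([1.0]))

    def test_build_agrees_with_scalar_calls(self):
        rng = np.random.default_rng(2)
        vectors = [EmbeddingVector(f"v{i}", rng.normal(size=4)) for i in range(5)]
        scalar = {"cosine": cosine_distance, "euclidean": euclidean_distance, "manhattan": manhattan_distance}
        for metric, fn in scalar.items():
            m = build_half_matrix(vectors, metric=metric)
            for i in range(5):
                for j in range(i + 1, 5):
                    expected = fn(vectors[i].values, vectors[j].values)
                    assert m.lookup(f"v{i}", f"v{j}") == pytest.approx(expected)

    def test_two_identical_vectors(self):
        v = [EmbeddingVector("a", [1.0, 2.0]), EmbeddingVector("b", [1.0, 2.0])]
        m = build_half_matrix(v, metric="euclidean")
        assert list(m.condensed) == [0.0]

    def test_single_vector_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_half_matrix([EmbeddingVector("a", [1.0])])

    def test_disk_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        vectors = [EmbeddingVector(f"v{i}", rng.normal(size=3)) for i in range(4)]
        m = build_half_matrix(vectors, metric="manhattan")
        path = tmp_path / "matrix.tsv"
        write_half_matrix(m, path)
        back = read_half_matrix(path)
        assert back.ids == m.ids
        np.testing.assert_array_equal(back.condensed, m.condensed)


class TestScoreToDistance:
    def test_inverse_bitscore(self):
        m = score_to_distance([("a", "b", 50.0), ("b", "a", 50.0)], kind="inv_bitscore")
        assert m.lookup("a", "b") == pytest.approx(0.02)

    def test_directed_scores_symmetrized_by_mean(self):
        m = score_to_distance([("a", "b", 40.0), ("b", "a", 60.0)], kind="inv_bitscore")
        assert m.lookup("a", "b") == pytest.approx((1 / 40 + 1 / 60) / 2)

    def test_rmsd_passthrough_and_zero(self):
        m = score_to_distance([("a", "b", 0.0), ("a", "c", 2.5)], kind="rmsd")
        assert m.lookup("a", "b") == 0.0
        assert m.lookup("a", "c") == 2.5

    def test_missing_pair_filled_with_ten_times_max(self):
        m = score_to_distance([("a", "b", 0.5), ("a", "c", 1.5)], kind="rmsd")
        assert m.lookup("b", "c") == pytest.approx(15.0)

    def test_nonpositive_bitscore_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            score_to_distance([("a", "b", 0.0)], kind="inv_bitscore")

    def test_unknown_id_rejected_with_explicit_ids(self):
        with pytest.raises(ValueError, match="unknown id"):
            score_to_distance([("a", "zzz", 5.0)], kind="inv_bitscore", ids=["a", "b"])


class TestKmerEmbed:
    def test_monomer_profile(self):
        (vec,) = kmer_embed([DomainSequence("s", "AAAA")], k=1)
        assert vec.values[0] == 1.0 and vec.values[1:].sum() == 0.0

    def test_identical_sequences_zero_cosine(self):
        vecs = kmer_embed([DomainSequence("a", "ACDACD"), DomainSequence("b", "ACDACD")], k=2)
        assert cosine_distance(vecs[0].values, vecs[1].values) == pytest.approx(0.0)

    def test_disjoint_monomers_orthogonal(self):
        vecs = kmer_embed([DomainSequence("a", "AAAA"), DomainSequence("b", "CCCC")], k=1)
        assert cosine_distance(vecs[0].values, vecs[1].values) == pytest.approx(1.0)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            kmer_embed([DomainSequence("a", "AC")], k=3)


def test_embedding_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    vectors = [EmbeddingVector(f"v{i}", rng.normal(size=5)) for i in range(3)]
    path = tmp_path / "emb.tsv"
    write_embeddings(vectors, path)
    back = read_embeddings(path)
    assert [v.seq_id for v in back] == [v.seq_id for v in vectors]
    for x, y in zip(back, vectors):
        np.testing.assert_array_equal(x.values, y.values)
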