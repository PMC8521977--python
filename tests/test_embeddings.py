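"""Embedding loading, tokenization, bag-of-words aggregation and fusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import epivec as ev
from epivec.embeddings import (EmbeddingError, FusedProvider, HashProvider,
                               WordBagProvider, read_entity_tsv,
                               write_entity_tsv, write_word_vectors)


@pytest.mark.parametrize("name,expected", [
    ("HIV/AIDS", ["hiv", "aids"]),
    ("Guinea-Bissau", ["guinea", "bissau"]),
    ("  Malaria ", ["malaria"]),
    ("Chagas disease", ["chagas", "disease"]),
])
def test_tokenize_rules(name, expected):
    assert ev.tokenize(name) == expected


def test_tokenize_rejects_empty():
    with pytest.raises(ValueError):
        ev.tokenize("   ")
    with pytest.raises(ValueError):
        ev.tokenize("...")


class TestBagOfWords:
    def test_min_max_mean_concatenation(self, toy_word_table):
        emb = ev.embed_bag_of_words(toy_word_table, "a b")
        np.testing.assert_allclose(emb.vector, [1, 0, 3, 2, 2, 1])
        assert emb.parts == ("min", "max", "mean")

    def test_single_word_repeats_vector(self, toy_word_table):
        toy_word_table.entries["w"] = np.array([4.0, -1.0])
        emb = ev.embed_bag_of_words(toy_word_table, "w")
        np.testing.assert_allclose(emb.vector, [4, -1, 4, -1, 4, -1])

    def test_permutation_invariance(self, toy_word_table):
        v1 = ev.embed_bag_of_words(toy_word_table, "a b").vector
        v2 = ev.embed_bag_of_words(toy_word_table, "b a").vector
        np.testing.assert_array_equal(v1, v2)

    def test_oov_policies(self, toy_word_table):
        with pytest.raises(EmbeddingError):
            ev.embed_bag_of_words(toy_word_table, "a zzz", oov_policy="error")
        skip = ev.embed_bag_of_words(toy_word_table, "a zzz", oov_policy="skip")
        np.testing.assert_allclose(skip.vector, [1, 2, 1, 2, 1, 2])
        zero = ev.embed_bag_of_words(toy_word_table, "a zzz", oov_policy="zero")
        np.testing.assert_allclose(zero.vector, [0, 0, 1, 2, 0.5, 1])
        # all tokens OOV is an error under every policy
        for policy in ("error", "skip", "zero"):
            with pytest.raises(EmbeddingError):
                ev.embed_bag_of_words(toy_word_table, "zzz qqq", oov_policy=policy)

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.integers(0, 4), min_size=1, max_size=6))
    def test_min_leq_mean_leq_max(self, token_ids):
        rng = np.random.default_rng(0)
        vocab = {f"t{i}": rng.standard_normal(3) for i in range(5)}
        table = ev.EmbeddingTable(vocab, 3, "word", "rand")
        name = " ".join(f"t{i}" for i in token_ids)
        v = ev.embed_bag_of_words(table, name).vector
        lo, hi, mean = v[:3], v[3:6], v[6:]
        assert np.all(lo <= mean + 1e-12) and np.all(mean <= hi + 1e-12)


class TestWordVectorIO:
    def test_round_trip(self, tmp_path, toy_word_table):
        path = tmp_path / "vecs.txt"
        write_word_vectors(toy_word_table, path)
        loaded = ev.load_word_vectors(path)
        assert loaded.dim == 2 and len(loaded) == 2
        for key in toy_word_table.entries:
            np.testing.assert_allclose(loaded.entries[key],
                                       toy_word_table.entries[key], atol=1e-6)

    def test_header_optional_and_duplicates(self, tmp_path, caplog):
        path = tmp_path / "v.txt"
        path.write_text("x 1 2\nX 3 4\n")
        table = ev.load_word_vectors(path)
        np.testing.assert_allclose(table.entries["x"], [3, 4])  # last wins

    def test_inconsistent_dim_names_line(self, tmp_path):
        path = tmp_path / "v.txt"
        path.write_text("a 1 2 3\nb 1 2\n")
        with pytest.raises(EmbeddingError, match="line 2"):
            ev.load_word_vectors(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "v.txt"
        path.write_text("")
        with pytest.raises(EmbeddingError):
            ev.load_word_vectors(path)


def test_entity_lookup_normalizes_and_reports_missing():
    table = ev.EmbeddingTable({"hiv": np.arange(3.0)}, 3, "entity", "toy")
    np.testing.assert_array_equal(ev.embed_entity(table, " HIV ").vector, [0, 1, 2])
    with pytest.raises(EmbeddingError, match="nearest"):
        ev.embed_entity(table, "malaria")


def test_entity_tsv_round_trip(tmp_path):
    table = ev.EmbeddingTable({"hiv aids": np.array([1.0, -2.5])}, 2, "entity", "t")
    path = tmp_path / "e.tsv"
    write_entity_tsv(table, path)
    loaded = read_entity_tsv(path)
    np.testing.assert_allclose(loaded.entries["hiv aids"], [1.0, -2.5])


class TestFusion:
    def test_length_additivity_and_order(self):
        rng = np.random.default_rng(0)
        parts = [ev.SentenceEmbedding(rng.standard_normal(n), "entity-native")
                 for n in (6, 4, 8)]
        fused = ev.fuse(parts)
        assert len(fused) == 18
        swapped = ev.fuse(parts[::-1])
        assert not np.array_equal(fused.vector, swapped.vector)
        np.testing.assert_array_equal(np.sort(fused.vector), np.sort(swapped.vector))

    def test_requires_two_parts(self):
        with pytest.raises(ValueError):
            ev.fuse([ev.SentenceEmbedding(np.zeros(3), "entity-native")])

    def test_associative_on_flattened_result(self):
        rng = np.random.default_rng(1)
        a, b, c = (ev.SentenceEmbedding(rng.standard_normal(3), "entity-native")
                   for _ in range(3))
        left = ev.fuse([ev.fuse([a, b]), c]).vector
        right = ev.fuse([a, ev.fuse([b, c])]).vector
        np.testing.assert_array_equal(left, right)


class TestHashEmbed:
    def test_deterministic_and_name_sensitive(self):
        v1 = ev.hash_embed("x", 8, 1).vector
        v2 = ev.hash_embed("x", 8, 1).vector
        v3 = ev.hash_embed("y", 8, 1).vector
        np.testing.assert_array_equal(v1, v2)
        assert not np.array_equal(v1, v3)

    def test_mean_pairwise_cosine_low(self):
        names = [f"name {i}" for i in range(100)]
        V = np.vstack([ev.hash_embed(n, 64, 1).vector for n in names])
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        iu = np.triu_indices(len(names), 1)
        assert np.abs(V @ V.T)[iu].mean() < 0.25


def test_fused_provider_dims(toy_word_table):
    wb = WordBagProvider(table=toy_word_table)
    h = HashProvider(hash_dim=5, seed=0)
    fp = FusedProvider(providers=[wb, h])
    assert fp.dim == 6 + 5
    assert len(fp.embed("a b")) == 11
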