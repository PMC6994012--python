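import numpy as np
import pytest

from clinsyn.corpus import ConfigurationError, FormatError, MentionAnnotation, Span
from clinsyn.encoders import (
    BiLMConfig,
    CodeVectorTable,
    MentionVector,
    Provenance,
    ReferenceBiLM,
    WordVectorTable,
    admission_icd_vectors,
    bilm_mention_vectors,
    c2v_fuse,
    icd_context_vector,
    output_fuse,
    pool_tokens,
    random_vector_table,
    read_mention_vectors,
    read_vector_table,
    train_reference_bilm,
    type_mention_vector,
    write_mention_vectors,
    write_vector_table,
)


def mention(surface, mid="m1"):
    return MentionAnnotation(mid, "d1", (Span(0, len(surface)),), surface, "C1")


# ---------------------------------------------------------------------------
# vector tables
# ---------------------------------------------------------------------------


class TestVectorTableIO:
    def test_plain_rows(self, tmp_path):
        p = tmp_path / "vecs.txt"
        p.write_text("stroke 1.0 0.0\ncva 0.5 0.5\nsepsis 0.0 1.0\n")
        table = read_vector_table(p)
        assert len(table) == 3 and table.dim == 2
        assert np.allclose(table.get("cva"), [0.5, 0.5])

    def test_header_dialect(self, tmp_path):
        p = tmp_path / "vecs.txt"
        p.write_text("3 2\na 1 0\nb 0 1\nc 1 1\n")
        assert len(read_vector_table(p)) == 3

    def test_ragged_row_reports_line(self, tmp_path):
        p = tmp_path / "vecs.txt"
        p.write_text("a 1 0\nb 1\n")
        with pytest.raises(FormatError, match=":2"):
            read_vector_table(p)

    def test_roundtrip(self, tmp_path):
        table = random_vector_table(["401.9", "250.0"], dim=4, seed=3)
        p = tmp_path / "codes.txt"
        write_vector_table(table, p, header=True)
        back = read_vector_table(p, kind="code")
        for k in table.keys():
            assert np.array_equal(back.get(k), table.get(k))

    def test_missing_key_is_none_not_default(self):
        table = WordVectorTable({"a": np.ones(2)})
        assert table.get("zzz") is None


# ---------------------------------------------------------------------------
# type-level representation
# ---------------------------------------------------------------------------


class TestTypeMentionVector:
    def test_average_of_token_vectors(self):
        table = WordVectorTable({"u": np.array([1.0, 0.0]), "v": np.array([0.0, 2.0])})
        mv = type_mention_vector(mention("u v"), table)
        assert np.allclose(mv.vector, [0.5, 1.0])

    def test_oov_tokens_excluded(self):
        table = WordVectorTable({"u": np.array([2.0, 2.0])})
        mv = type_mention_vector(mention("u mystery"), table)
        assert np.allclose(mv.vector, [2.0, 2.0])

    def test_all_oov_is_absent(self):
        table = WordVectorTable({"u": np.array([1.0])})
        assert type_mention_vector(mention("novel words"), table) is None


# ---------------------------------------------------------------------------
# pooling and fusion
# ---------------------------------------------------------------------------


class TestPooling:
    def test_max_and_avg(self):
        mat = np.array([[1.0, 0.0], [0.0, 2.0]])
        assert np.allclose(pool_tokens(mat, [0, 1], "max"), [1.0, 2.0])
        assert np.allclose(pool_tokens(mat, [0, 1], "avg"), [0.5, 1.0])

    def test_single_token_identity(self):
        mat = np.array([[3.0, -1.0]])
        for mode in ("avg", "max"):
            assert np.allclose(pool_tokens(mat, [0], mode), [3.0, -1.0])

    def test_empty_indices_error(self):
        with pytest.raises(ValueError):
            pool_tokens(np.ones((2, 2)), [], "max")

    def test_max_dominates_avg_elementwise(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            mat = rng.normal(size=(5, 7))
            idx = [0, 2, 4]
            assert np.all(
                pool_tokens(mat, idx, "max") >= pool_tokens(mat, idx, "avg") - 1e-12
            )


class TestIcdContextVector:
    def test_dimensionwise_max(self):
        table = CodeVectorTable({"a": np.array([1.0, 3.0]), "b": np.array([2.0, 0.0])})
        assert np.allclose(icd_context_vector(["a", "b"], table), [2.0, 3.0])

    def test_single_code_identity(self):
        table = CodeVectorTable({"a": np.array([1.0, 3.0])})
        assert np.allclose(icd_context_vector(["a"], table), [1.0, 3.0])

    def test_empty_or_unresolvable_gives_zero_vector(self):
        table = CodeVectorTable({"a": np.array([1.0, 3.0])})
        assert np.allclose(icd_context_vector([], table), [0.0, 0.0])
        assert np.allclose(icd_context_vector(["zz"], table), [0.0, 0.0])

    def test_mean_mode_option(self):
        table = CodeVectorTable({"a": np.array([1.0, 3.0]), "b": np.array([3.0, 1.0])})
        assert np.allclose(icd_context_vector(["a", "b"], table, mode="mean"), [2.0, 2.0])


class TestFusion:
    def test_c2v_fuse_dims_600_600_200(self):
        fused = c2v_fuse(np.ones(600), np.zeros(600), np.ones(200))
        assert fused.shape == (1400,)

    def test_c2v_fuse_order(self):
        left, right, icd = np.full(3, 1.0), np.full(3, 2.0), np.full(2, 3.0)
        fused = c2v_fuse(left, right, icd)
        assert np.allclose(fused[:3], left) and np.allclose(fused[-2:], icd)

    def test_output_fuse_dims_512_512_200(self):
        assert output_fuse(np.ones(512), np.ones(512), np.ones(200)).shape == (1224,)

    def test_output_fuse_without_icd(self):
        assert output_fuse(np.ones(4), np.ones(4)).shape == (8,)

    def test_zero_icd_tail(self):
        fused = c2v_fuse(np.ones(2), np.ones(2), np.zeros(3))
        assert np.allclose(fused[-3:], 0.0)


# ---------------------------------------------------------------------------
# reference BiLM
# ---------------------------------------------------------------------------

TINY = [
    ["the", "cat", "sat", "here"],
    ["the", "dog", "sat", "there"],
    ["a", "cat", "ran", "home"],
    ["the", "dog", "ran", "here"],
    ["a", "bird", "sat", "there"],
    ["the", "cat", "ran", "there"],
]


def tiny_model(**kw):
    defaults = dict(token_dim=12, hidden_dim=10, char_emb_dim=4, epochs=2, seed=0)
    defaults.update(kw)
    return train_reference_bilm(TINY, BiLMConfig(**defaults))


class TestReferenceBiLM:
    def test_shape_contract(self):
        model = tiny_model()
        tvs = model.encode_sentence(["the", "cat", "sat", "here"])
        for layer in (0, 1, 2):
            assert tvs.layers[layer].shape[0] == 4
        assert tvs.layers[0].shape[1] == model.layer_dims[0]
        assert tvs.layers[1].shape[1] == 2 * model.config.hidden_dim

    def test_layer0_context_independent_layer2_contextual(self):
        model = tiny_model()
        a = model.encode_sentence(["the", "cat", "sat", "here"])
        b = model.encode_sentence(["a", "cat", "ran", "there"])
        assert np.array_equal(a.layers[0][1], b.layers[0][1])  # "cat" both times
        assert not np.allclose(a.layers[2][1], b.layers[2][1])

    def test_character_mode_handles_unseen_words(self):
        model = tiny_model()
        tvs = model.encode_sentence(["zyxwv"])
        assert np.all(np.isfinite(tvs.layers[0]))

    def test_word_mode_unseen_words_map_to_unk(self):
        model = tiny_model(token_mode="word")
        a = model.encode_sentence(["zyxwv"])
        b = model.encode_sentence(["qqqqq"])
        assert np.array_equal(a.layers[0], b.layers[0])

    def test_encoding_is_pure(self):
        model = tiny_model()
        a = model.encode_sentence(["the", "cat"])
        b = model.encode_sentence(["the", "cat"])
        for layer in (0, 1, 2):
            assert np.array_equal(a.layers[layer], b.layers[layer])

    def test_training_deterministic_given_seed(self):
        m1 = tiny_model()
        m2 = tiny_model()
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])
        assert m1.perplexity_history == m2.perplexity_history

    def test_training_reduces_heldout_perplexity(self, default_sentences):
        model = train_reference_bilm(
            default_sentences[:200],
            BiLMConfig(token_dim=24, hidden_dim=24, char_emb_dim=8, epochs=2, seed=0),
        )
        assert model.perplexity_history[-1] < model.perplexity_history[0]

    def test_perplexity_nonincreasing_on_average_over_seeds(self):
        # trend check: mean final perplexity below mean initial, over 3 seeds
        firsts, lasts = [], []
        for seed in (0, 1, 2):
            m = tiny_model(seed=seed, epochs=3)
            firsts.append(m.perplexity_history[0])
            lasts.append(m.perplexity_history[-1])
        assert np.mean(lasts) < np.mean(firsts)

    def test_fusion_without_icd_vectors_is_config_error(self):
        with pytest.raises(ConfigurationError):
            train_reference_bilm(TINY, BiLMConfig(fusion="input", epochs=1))

    def test_encode_fusion_mismatch_errors(self):
        model = tiny_model()
        with pytest.raises(ConfigurationError):
            model.encode_sentence(["the"], icd_vector=np.ones(3))

    def test_input_fusion_widens_layer0(self):
        enc = ReferenceBiLM(
            BiLMConfig(fusion="input", token_dim=12, hidden_dim=10, epochs=1),
            vocab=["a", "b"],
            chars=list("ab"),
            d_c=5,
        )
        enc._frozen = True
        tvs = enc.encode_sentence(["a", "b"], icd_vector=np.arange(5.0))
        assert tvs.layers[0].shape == (2, 17)
        # the appended block is the ICD vector itself
        assert np.allclose(tvs.layers[0][:, -5:], np.arange(5.0))

    def test_output_fusion_prediction_dim_but_layers_unchanged(self):
        enc = ReferenceBiLM(
            BiLMConfig(fusion="output", token_dim=12, hidden_dim=10, epochs=1),
            vocab=["a", "b"],
            chars=list("ab"),
            d_c=5,
        )
        assert enc.prediction_input_dim == 2 * 10 + 5
        enc._frozen = True
        tvs = enc.encode_sentence(["a", "b"], icd_vector=np.ones(5))
        assert tvs.layers[0].shape == (2, 12)


class TestMentionVectorStore:
    def test_roundtrip_with_absent_entries(self, tmp_path):
        prov = Provenance(encoder="test", layer=1, pooling="max")
        vecs = {
            "m1": MentionVector("m1", np.array([1.5, -2.25]), prov),
            "m2": None,
        }
        path = tmp_path / "store.txt"
        write_mention_vectors(vecs, path)
        back = read_mention_vectors(path)
        assert back["m2"] is None
        assert np.array_equal(back["m1"].vector, vecs["m1"].vector)
        assert back["m1"].provenance.layer == 1

    def test_store_bytes_reproducible(self, tmp_path):
        prov = Provenance(encoder="test", layer=2, pooling="avg")
        vecs = {"m1": MentionVector("m1", np.array([0.1, 0.2, 0.3]), prov)}
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_mention_vectors(vecs, p1)
        write_mention_vectors(vecs, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestBilmMentionPipeline:
    def test_mention_vectors_cover_all_mentions(self, default_corpus, default_sentences):
        model = train_reference_bilm(
            default_sentences[:150],
            BiLMConfig(token_dim=16, hidden_dim=12, char_emb_dim=4, epochs=1, seed=0),
        )
        docs = {d.doc_id: d for d in default_corpus["documents"]}
        mentions = default_corpus["mentions"][:40]
        vecs = bilm_mention_vectors(model, docs, mentions, layer=1, pooling="max")
        assert set(vecs) == {m.mention_id for m in mentions}
        assert all(v is not None and np.all(np.isfinite(v.vector)) for v in vecs.values())

    def test_provenance_populated(self, default_corpus, default_sentences):
        model = train_reference_bilm(
            default_sentences[:100],
            BiLMConfig(token_dim=16, hidden_dim=12, char_emb_dim=4, epochs=1, seed=0),
        )
        docs = {d.doc_id: d for d in default_corpus["documents"]}
        vecs = bilm_mention_vectors(
            model, docs, default_corpus["mentions"][:5], layer=2, pooling="avg"
        )
        mv = next(iter(vecs.values()))
        assert mv.provenance.layer == 2 and mv.provenance.pooling == "avg"

    def test_admission_icd_vectors_keyed_by_doc(self, default_corpus):
        table = random_vector_table(
            [c.icd_code for c in default_corpus["concepts"]], dim=6, seed=2
        )
        adm = {a.admission_id: a for a in default_corpus["admissions"]}
        out = admission_icd_vectors(default_corpus["documents"], adm, table)
        assert set(out) == {d.doc_id for d in default_corpus["documents"]}
        assert all(v.shape == (6,) for v in out.values())
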