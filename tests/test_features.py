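import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from somnotext import (
    EmbeddingConfig,
    LabeledPost,
    Post,
    WordEmbedding,
    build_tensor,
    parse_ts,
    preprocess,
    sentiment_scores,
    train_embeddings,
)
from somnotext.features import load_stopwords


class TestPreprocess:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("I am the tired one", ["tired", "one"]),
            ("café ☕ @bob", ["café", "@bob"]),
            ("the a", []),
            ("check https://t.co/xyz #finals @prof", ["check", "https://t.co/xyz", "#finals", "@prof"]),
            ("LA biblioteca y el examen", ["biblioteca", "examen"]),
        ],
    )
    def test_examples(self, text, expected):
        assert preprocess(text) == expected

    @settings(max_examples=60, derandomize=True)
    @given(hst.text(max_size=80))
    def test_output_tokens_are_filtered_and_lowercase(self, text):
        stop = load_stopwords()
        for t in preprocess(text):
            assert t == t.lower()
            assert t not in stop
            assert any(c.isascii() and c.isalnum() for c in t)


class TestSentiment:
    LEX = {"alpha": (0.5, 1.0), "beta": (-0.5, 0.0)}

    def test_no_match_is_neutral(self):
        assert sentiment_scores("gamma delta", self.LEX) == (0.0, 0.0)

    def test_single_match(self):
        assert sentiment_scores("alpha gamma", self.LEX) == (0.5, 1.0)

    def test_mean_of_two(self):
        assert sentiment_scores("alpha beta", self.LEX) == (0.0, 0.5)

    @settings(max_examples=40, derandomize=True)
    @given(hst.permutations(["alpha", "beta", "alpha", "gamma"]))
    def test_token_order_invariant(self, words):
        assert sentiment_scores(" ".join(words), self.LEX) == sentiment_scores(
            " ".join(reversed(words)), self.LEX
        )


def toy_embedding(dim=4):
    tokens = [f"tok{i}" for i in range(6)]
    rng = np.random.default_rng(0)
    return WordEmbedding(tokens, rng.normal(size=(6, dim)))


def labeled(pid, ts, text, deprived=False):
    return LabeledPost(
        Post(pid, "s", parse_ts(ts), text),
        400.0 if deprived else 100.0,
        "sleep_deprived" if deprived else "sleep_sufficient",
    )


class TestBuildTensor:
    LEX = {"tok0": (0.5, 1.0)}

    def test_shape_and_trailing_features(self):
        emb = toy_embedding()
        rows = [
            labeled("a", "2015-10-05T14:40", "tok0 tok1 tok2", deprived=True),
            labeled("b", "2015-10-05T09:00", "tok3"),
        ]
        tensor = build_tensor(rows, emb, self.LEX)
        assert tensor.spec.xi == emb.dim + 3
        assert tensor.values.shape == (2, 3, emb.dim + 3)
        assert list(tensor.labels) == [1, 0]
        # hour/polarity/subjectivity replicated at every real token position
        for j in range(3):
            assert tuple(tensor.values[0, j, emb.dim:]) == (0.5, 1.0, 14.0)
        np.testing.assert_allclose(
            tensor.values[0, 0, : emb.dim], emb["tok0"], rtol=1e-6
        )  # stored as float32

    def test_padding_rows_are_all_zero(self):
        emb = toy_embedding()
        rows = [
            labeled("a", "2015-10-05T10:00", "tok0 tok1 tok2 tok3"),
            labeled("b", "2015-10-05T10:00", "tok0"),
        ]
        tensor = build_tensor(rows, emb, self.LEX)
        assert not tensor.values[1, 1:].any()
        # padding is reconstructible: a position is padding iff fully zero
        mask = np.abs(tensor.values).sum(axis=2) > 0
        np.testing.assert_array_equal(mask, [[True] * 4, [True] + [False] * 3])

    def test_out_of_vocabulary_tokens_skipped(self):
        emb = toy_embedding()
        rows = [labeled("a", "2015-10-05T10:00", "tok0 zebra tok1")]
        tensor = build_tensor(rows, emb, self.LEX)
        assert tensor.spec.kappa == 2

    def test_all_oov_row_stays_zero(self):
        emb = toy_embedding()
        rows = [
            labeled("a", "2015-10-05T10:00", "tok0"),
            labeled("b", "2015-10-05T10:00", "zebra quagga"),
        ]
        tensor = build_tensor(rows, emb, self.LEX)
        assert not tensor.values[1].any()

    def test_row_permutation_permutes_tensor(self):
        emb = toy_embedding()
        rows = [
            labeled(f"p{i}", "2015-10-05T10:00", f"tok{i} tok{(i + 1) % 6}")
            for i in range(5)
        ]
        t1 = build_tensor(rows, emb, self.LEX)
        t2 = build_tensor(rows[::-1], emb, self.LEX)
        np.testing.assert_array_equal(t1.values, t2.values[::-1])


class TestEmbeddings:
    def test_min_count_prunes_rare_words(self):
        corpus = [["common", "common", "rare"] for _ in range(4)]
        # "rare" occurs 4 times < 5, "common" 8 times
        emb = train_embeddings(corpus, EmbeddingConfig(dim=8, min_count=5, epochs=1))
        assert "common" in emb and "rare" not in emb

    def test_vector_shapes_and_roundtrip(self, tmp_path):
        corpus = [[f"w{i}", f"w{(i + 1) % 5}"] for i in range(50)]
        emb = train_embeddings(corpus, EmbeddingConfig(dim=8, min_count=1, epochs=2, seed=3))
        assert all(emb[t].shape == (8,) for t in emb.tokens)
        emb.save(tmp_path / "vec.txt")
        back = WordEmbedding.load(tmp_path / "vec.txt")
        assert back.tokens == emb.tokens
        np.testing.assert_allclose(back.vectors, emb.vectors, atol=1e-6)

    def test_deterministic_given_seed(self):
        corpus = [[f"w{i % 7}", f"w{(i + 2) % 7}", f"w{(i + 3) % 7}"] for i in range(60)]
        cfg = EmbeddingConfig(dim=8, min_count=1, epochs=2, seed=11)
        a = train_embeddings(corpus, cfg)
        b = train_embeddings(corpus, cfg)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_embeddings([], EmbeddingConfig(dim=4))

    def test_interchangeable_token_classes_cluster(self):
        """Tokens sharing contexts get more similar vectors: two classes
        of interchangeable words in class-specific frames."""
        rng = np.random.default_rng(5)
        a_words = [f"a{i}" for i in range(8)]
        b_words = [f"b{i}" for i in range(8)]
        corpus = []
        for _ in range(1500):
            if rng.random() < 0.5:
                w = rng.choice(a_words, size=2)
                corpus.append(["ctxa1", w[0], "ctxa2", w[1], "ctxa3"])
            else:
                w = rng.choice(b_words, size=2)
                corpus.append(["ctxb1", w[0], "ctxb2", w[1], "ctxb3"])
        emb = train_embeddings(
            corpus, EmbeddingConfig(dim=16, window=2, min_count=5, epochs=3, seed=5)
        )

        def mean_cos(xs, ys):
            sims = []
            for x in xs:
                for y in ys:
                    if x != y:
                        u, v = emb[x], emb[y]
                        sims.append(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
            return float(np.mean(sims))

        within = (mean_cos(a_words, a_words) + mean_cos(b_words, b_words)) / 2
        between = mean_cos(a_words, b_words)
        assert within > between
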