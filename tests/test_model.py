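import numpy as np
import pytest

from foodsignal.aggregation import GoldExample
from foodsignal.labels import TAG_SET
from foodsignal.model import (
    DualTaskModel,
    DualTaskOutput,
    EncoderConfig,
    PieceVocab,
    TrainConfig,
    joint_loss,
    load_model,
    predict,
    save_model,
    tokenize,
    train,
)
from foodsignal.tokens import word_tokenize

GRILLED = "I got food poisoning from a grilled cheese last night and I've never felt so betrayed in my life"


def _gold(text, relevance, tags):
    tokens = tuple(word_tokenize(text))
    return GoldExample("g1", text, relevance, tokens, tuple(tags))


@pytest.fixture(scope="module")
def tiny_setup():
    texts = [GRILLED, "lovely weather in Boston today", "bad shrimp made me vomit"]
    vocab = PieceVocab.build(texts)
    cfg = EncoderConfig(hidden=16, layers=1, heads=2, max_length=32)
    return texts, vocab, cfg


class TestTokenize:
    def test_cls_first_sep_once_padded(self, tiny_setup):
        texts, vocab, cfg = tiny_setup
        x = tokenize(texts[2], vocab, cfg.max_length)
        assert x.ids[0] == vocab.stoi["[CLS]"]
        assert list(x.ids).count(vocab.stoi["[SEP]"]) == 1
        assert len(x.ids) == cfg.max_length
        n_real = int(x.mask.sum())
        assert all(x.ids[i] == vocab.stoi["[PAD]"] for i in range(n_real, cfg.max_length))
        assert x.n_words == 5

    def test_fixed_total_length(self, tiny_setup):
        texts, vocab, cfg = tiny_setup
        a = tokenize(texts[1], vocab, cfg.max_length)
        b = tokenize(texts[2], vocab, cfg.max_length)
        assert len(a.ids) == len(b.ids) == cfg.max_length

    def test_truncation_drops_whole_words(self, tiny_setup):
        _, vocab, _ = tiny_setup
        x = tokenize(GRILLED, vocab, 8)
        assert x.n_words < len(word_tokenize(GRILLED))
        assert max(x.alignment) < 8

    def test_empty_text_error(self, tiny_setup):
        _, vocab, cfg = tiny_setup
        with pytest.raises(ValueError):
            tokenize("   ", vocab, cfg.max_length)

    def test_unseen_word_falls_back_to_characters(self, tiny_setup):
        _, vocab, cfg = tiny_setup
        x = tokenize("zzgloop vomit", vocab, cfg.max_length)
        assert x.n_words == 2  # representable despite the unknown word


class TestForward:
    def test_deterministic_and_normalized(self, tiny_setup):
        texts, vocab, cfg = tiny_setup
        m = DualTaskModel(cfg, vocab, seed=0)
        out1 = m.output_for(texts[0])
        out2 = m.output_for(texts[0])
        assert out1.relevance == out2.relevance
        np.testing.assert_array_equal(out1.token_scores, out2.token_scores)
        assert 0.0 <= out1.relevance <= 1.0
        np.testing.assert_allclose(out1.token_scores.sum(1), 1.0, atol=1e-6)

    def test_single_word_input(self, tiny_setup):
        _, vocab, cfg = tiny_setup
        m = DualTaskModel(cfg, vocab, seed=0)
        assert m.output_for("vomit").token_scores.shape[0] == 1

    def test_pretrained_kind_needs_optional_stack(self, tiny_setup):
        _, vocab, _ = tiny_setup
        cfg = EncoderConfig(kind="pretrained", identifier="some/encoder")
        with pytest.raises(RuntimeError, match="torch"):
            DualTaskModel(cfg, vocab)


class TestJointLoss:
    def _perfect_output(self, gold):
        scores = np.zeros((len(gold.tags), len(TAG_SET)))
        for i, t in enumerate(gold.tags):
            scores[i, TAG_SET.index(t)] = 1.0
        return DualTaskOutput(1.0 if gold.relevance == "Yes" else 0.0, scores)

    def test_point_mass_on_gold_is_zero(self):
        gold = _gold("bad shrimp made me vomit", "Yes", ["O", "B-FOOD", "O", "O", "B-SYM"])
        assert joint_loss(self._perfect_output(gold), gold, lam=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_lambda_zero_is_sentence_loss_only(self):
        gold = _gold("bad shrimp", "Yes", ["O", "B-FOOD"])
        out = DualTaskOutput(0.25, np.full((2, 9), 1 / 9))
        assert joint_loss(out, gold, lam=0.0) == pytest.approx(-np.log(0.25))

    def test_uniform_token_distribution_ln9(self):
        gold = _gold("bad shrimp", "Yes", ["O", "B-FOOD"])
        out = DualTaskOutput(1.0, np.full((2, 9), 1 / 9))
        assert joint_loss(out, gold, lam=1.0) == pytest.approx(np.log(9.0))

    def test_negative_lambda_error(self):
        gold = _gold("bad shrimp", "Yes", ["O", "B-FOOD"])
        with pytest.raises(ValueError):
            joint_loss(DualTaskOutput(1.0, np.full((2, 9), 1 / 9)), gold, lam=-0.1)

    @pytest.mark.parametrize("lams", [(0.0, 0.5), (0.5, 1.0), (1.0, 2.0)])
    def test_monotone_in_lambda(self, lams):
        gold = _gold("bad shrimp", "Yes", ["O", "B-FOOD"])
        out = DualTaskOutput(0.9, np.full((2, 9), 1 / 9))
        lo, hi = lams
        assert joint_loss(out, gold, lo) <= joint_loss(out, gold, hi)


class TestGradients:
    def test_analytic_matches_numerical(self, tiny_setup):
        texts, vocab, _ = tiny_setup
        cfg = EncoderConfig(hidden=16, layers=1, heads=2, max_length=16)
        m = DualTaskModel(cfg, vocab, seed=3)
        inputs = [tokenize(t, vocab, cfg.max_length) for t in texts[1:]]
        sent = np.array([0, 1])
        tags = [[0] * x.n_words for x in inputs]
        tags[1] = [0, 3, 0, 0, 5]
        lam = 0.7
        _, grads = m.loss_and_grads(inputs, sent, tags, lam)
        # eps small enough that no finite-difference step crosses a ReLU kink
        eps = 1e-6
        rng = np.random.default_rng(0)
        for name, g in grads.items():
            flat = m.params[name].ravel()
            for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp, _ = m.loss_and_grads(inputs, sent, tags, lam)
                flat[i] = old - eps
                lm, _ = m.loss_and_grads(inputs, sent, tags, lam)
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = g.ravel()[i]
                assert abs(num - ana) <= 1e-4 * max(1e-2, abs(num) + abs(ana)), name


class TestTraining:
    def test_overfit_single_example_reproduces_gold(self):
        tags = ["O", "O", "B-KEY", "I-KEY", "O", "O", "B-FOOD", "I-FOOD"] + ["O"] * 11
        gold = _gold(GRILLED, "Yes", tags)
        model, _ = train(
            [gold],
            [gold],
            EncoderConfig(hidden=32, layers=1, heads=2, max_length=32),
            TrainConfig(epochs=60, lr=1e-2, batch_size=1, seed=4),
        )
        label, pred_tags = predict(model, GRILLED)
        assert label == "Yes"
        assert pred_tags == list(gold.tags)

    def test_seeded_epoch0_loss_reproducible(self, small_corpus):
        _, golds = small_corpus
        logs = []
        for _ in range(2):
            _, log = train(
                list(golds[:30]),
                [],
                EncoderConfig(hidden=16, layers=1, heads=2, max_length=32),
                TrainConfig(epochs=1, seed=12),
            )
            logs.append(log[0]["train_loss"])
        assert logs[0] == logs[1]

    def test_training_log_records_validation(self, trained_model):
        _, log, _ = trained_model
        assert all("val_sentence_f1" in e and "val_entity_f1" in e for e in log)
        assert all(np.isfinite(e["train_loss"]) for e in log)


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, trained_model):
        model, _, golds = trained_model
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        for g in golds[:10]:
            assert predict(model, g.text) == predict(back, g.text)
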