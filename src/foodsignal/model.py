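"""The dual-task model: shared encoder, two output heads.

One text encoder produces a vector per input piece.  The vector at the
[CLS] position feeds a linear sentence classifier (is this tweet a
foodborne-illness report?); the vector at each word's first sub-piece
feeds a shared linear token classifier over the 9 IOB2 tags (O plus B-/I-
for FOOD, LOC, SYM, KEY).  The two tasks are trained jointly on a weighted
sum of cross-entropies and share every encoder parameter, so each task
regularizes the other's representation.

The default encoder is a tiny trainable transformer with a word+character
piece vocabulary built from the training corpus; any encoder exposing the
same forward/backward interface (e.g. a full-scale pretrained tweet
encoder) can be plugged in through :class:`EncoderConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .aggregation import YES, NO, GoldExample
from .labels import TAG_SET, repair_iob2
from .nn import Adam, TinyTransformer, TransformerSpec, clip_grads, softmax
from .tokens import word_tokenize

PAD, UNK, CLS, SEP = "[PAD]", "[UNK]", "[CLS]", "[SEP]"
_SPECIALS = (PAD, UNK, CLS, SEP)
N_TAGS = len(TAG_SET)  # 9


class TrainingDiverged(RuntimeError):
    """Raised when the joint loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


@dataclass
class EncoderConfig:
    """Which encoder backs the model.

    ``kind="tiny"`` builds the from-scratch desk-scale transformer
    described by (hidden, layers, heads); ``kind="pretrained"`` names a
    full-scale pretrained tweet encoder by ``identifier`` and requires the
    optional torch/transformers stack to be importable.
    """

    kind: str = "tiny"
    identifier: Optional[str] = None
    hidden: int = 64
    layers: int = 2
    heads: int = 2
    max_length: int = 48

    def __post_init__(self) -> None:
        if self.kind not in ("tiny", "pretrained"):
            raise ValueError(f"unknown encoder kind: {self.kind!r}")
        if self.max_length < 8:
            raise ValueError("max_length must be >= 8")
        if self.kind == "tiny" and self.hidden < 8:
            raise ValueError("tiny encoder hidden size must be >= 8")


@dataclass
class TrainConfig:
    """Optimization settings; ``seed`` fixes initialization and shuffling."""

    lam: float = 1.0  # weight of the token loss in the joint objective
    lr: float = 3e-3
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    max_grad_norm: float = 5.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("loss weight lam must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TokenizedInput:
    """Fixed-length piece ids: [CLS] pieces... [SEP] [PAD]...; ``alignment``
    holds the index of each kept word's first sub-piece."""

    ids: np.ndarray
    mask: np.ndarray
    alignment: list[int]
    n_words: int


@dataclass
class DualTaskOutput:
    """Model prediction: P(Yes) plus one distribution over the 9 tags per
    word token."""

    relevance: float
    token_scores: np.ndarray  # (n_words, 9), rows sum to 1


class PieceVocab:
    """Word-plus-character piece vocabulary.

    Words seen in the training corpus (lowercased) are single pieces; an
    unseen word falls back to its characters, so no input is ever
    unrepresentable.
    """

    def __init__(self, pieces: Sequence[str]):
        self.itos = list(_SPECIALS) + [p for p in pieces if p not in _SPECIALS]
        self.stoi = {p: i for i, p in enumerate(self.itos)}

    def __len__(self) -> int:
        return len(self.itos)

    @classmethod
    def build(cls, texts: Sequence[str], min_freq: int = 1) -> "PieceVocab":
        from collections import Counter

        words: Counter[str] = Counter()
        chars: set[str] = set()
        for text in texts:
            for tok in word_tokenize(text):
                w = tok.text.lower()
                words[w] += 1
                chars.update(w)
        pieces = sorted(c for c in chars) + sorted(
            w for w, c in words.items() if c >= min_freq and len(w) > 1
        )
        return cls(pieces)

    def encode_word(self, word: str) -> list[int]:
        w = word.lower()
        if w in self.stoi:
            return [self.stoi[w]]
        unk = self.stoi[UNK]
        return [self.stoi.get(ch, unk) for ch in w]


def tokenize(text: str, vocab: PieceVocab, max_length: int) -> TokenizedInput:
    """Piece-encode a tweet: [CLS] + word pieces + [SEP], padded to
    ``max_length``.  Words whose pieces do not fit before [SEP] are
    truncated away together with their labels."""
    if not text.strip():
        raise ValueError("cannot tokenize empty text")
    ids = [vocab.stoi[CLS]]
    alignment: list[int] = []
    for tok in word_tokenize(text):
        pieces = vocab.encode_word(tok.text)
        if len(ids) + len(pieces) + 1 > max_length:
            break
        alignment.append(len(ids))
        ids.extend(pieces)
    ids.append(vocab.stoi[SEP])
    mask = [1.0] * len(ids) + [0.0] * (max_length - len(ids))
    ids = ids + [vocab.stoi[PAD]] * (max_length - len(ids))
    return TokenizedInput(
        np.asarray(ids, dtype=np.int64),
        np.asarray(mask, dtype=np.float64),
        alignment,
        len(alignment),
    )


class DualTaskModel:
    """Shared tiny-transformer encoder + sentence head + token head."""

    def __init__(self, encoder_config: EncoderConfig, vocab: PieceVocab, seed: int = 0):
        if encoder_config.kind != "tiny":
            raise RuntimeError(
                "pretrained tweet encoders require the optional torch/transformers "
                "stack; construct the model with kind='tiny' or plug in a custom "
                "encoder object"
            )
        self.config = encoder_config
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        self.encoder = TinyTransformer(
            TransformerSpec(
                vocab_size=len(vocab),
                hidden=encoder_config.hidden,
                layers=encoder_config.layers,
                heads=encoder_config.heads,
                max_length=encoder_config.max_length,
            ),
            rng,
        )
        h = encoder_config.hidden
        self.params = self.encoder.params
        self.params["head_ws"] = rng.normal(0.0, 0.02, (h, 2))
        self.params["head_bs"] = np.zeros(2)
        self.params["head_wt"] = rng.normal(0.0, 0.02, (h, N_TAGS))
        self.params["head_bt"] = np.zeros(N_TAGS)

    # -- forward ----------------------------------------------------------

    def _encode_batch(self, inputs: Sequence[TokenizedInput]):
        ids = np.stack([x.ids for x in inputs])
        mask = np.stack([x.mask for x in inputs])
        return self.encoder.forward(ids, mask)

    def forward(self, inputs: Sequence[TokenizedInput]) -> list[DualTaskOutput]:
        """Deterministic prediction probabilities for a batch."""
        h, _ = self._encode_batch(inputs)
        sent = softmax(h[:, 0, :] @ self.params["head_ws"] + self.params["head_bs"])
        outs = []
        for b, x in enumerate(inputs):
            reps = h[b, x.alignment, :] if x.alignment else np.zeros((0, self.config.hidden))
            tok = softmax(reps @ self.params["head_wt"] + self.params["head_bt"])
            outs.append(DualTaskOutput(float(sent[b, 1]), tok))
        return outs

    def output_for(self, text: str) -> DualTaskOutput:
        return self.forward([tokenize(text, self.vocab, self.config.max_length)])[0]

    # -- loss & gradients -------------------------------------------------

    def loss_and_grads(
        self,
        inputs: Sequence[TokenizedInput],
        sent_gold: np.ndarray,
        tag_gold: Sequence[Sequence[int]],
        lam: float,
    ):
        """Mean joint loss over a batch and gradients for every parameter.

        Per example: cross-entropy of the sentence label plus ``lam`` times
        the mean token cross-entropy over its word tokens ([CLS]/[SEP]/
        [PAD] and continuation pieces excluded).
        """
        B = len(inputs)
        h, cache = self._encode_batch(inputs)
        p = self.params

        sent_logits = h[:, 0, :] @ p["head_ws"] + p["head_bs"]
        sent_p = softmax(sent_logits)
        loss = float(-np.log(sent_p[np.arange(B), sent_gold] + 1e-300).mean())
        dsent = sent_p.copy()
        dsent[np.arange(B), sent_gold] -= 1.0
        dsent /= B

        dh = np.zeros_like(h)
        dh[:, 0, :] = dsent @ p["head_ws"].T
        grads = {
            "head_ws": h[:, 0, :].T @ dsent,
            "head_bs": dsent.sum(0),
            "head_wt": np.zeros_like(p["head_wt"]),
            "head_bt": np.zeros_like(p["head_bt"]),
        }

        if lam > 0:
            for b, x in enumerate(inputs):
                n = min(len(tag_gold[b]), x.n_words)
                if n == 0:
                    continue
                pos = x.alignment[:n]
                labels = np.asarray(tag_gold[b][:n])
                reps = h[b, pos, :]
                logits = reps @ p["head_wt"] + p["head_bt"]
                probs = softmax(logits)
                loss += lam * float(
                    -np.log(probs[np.arange(n), labels] + 1e-300).mean()
                ) / B
                dlog = probs
                dlog[np.arange(n), labels] -= 1.0
                dlog *= lam / (n * B)
                grads["head_wt"] += reps.T @ dlog
                grads["head_bt"] += dlog.sum(0)
                dh[b, pos, :] += dlog @ p["head_wt"].T

        grads.update(self.encoder.backward(dh, cache))
        return loss, grads


def joint_loss(output: DualTaskOutput, gold: GoldExample, lam: float = 1.0) -> float:
    """Joint objective for one example, from prediction probabilities:
    sentence cross-entropy + lam * mean token cross-entropy."""
    if lam < 0:
        raise ValueError("loss weight lam must be >= 0")
    p_correct = output.relevance if gold.relevance == YES else 1.0 - output.relevance
    loss = -np.log(max(p_correct, 1e-300))
    n = min(output.token_scores.shape[0], len(gold.tags))
    if lam > 0 and n > 0:
        idx = [TAG_SET.index(t) for t in gold.tags[:n]]
        tok = output.token_scores[np.arange(n), idx]
        loss += lam * float(-np.log(tok + 1e-300).mean())
    return float(loss)


# ---------------------------------------------------------------------------
# training


def _prepare(examples: Sequence[GoldExample], vocab: PieceVocab, max_length: int):
    inputs = [tokenize(ex.text, vocab, max_length) for ex in examples]
    sent = np.asarray([1 if ex.relevance == YES else 0 for ex in examples])
    tags = [[TAG_SET.index(t) for t in ex.tags] for ex in examples]
    return inputs, sent, tags


def _validation_metrics(model: "DualTaskModel", examples: Sequence[GoldExample]):
    from .evaluation import confusion_from_labels, entity_metrics, evaluate_tag_sequences, sentence_metrics

    pred_rel, pred_tags, gold_tags, toks = [], [], [], []
    bs = 64
    enc = [tokenize(ex.text, model.vocab, model.config.max_length) for ex in examples]
    outs: list[DualTaskOutput] = []
    for i in range(0, len(enc), bs):
        outs.extend(model.forward(enc[i : i + bs]))
    for ex, out, x in zip(examples, outs, enc):
        pred_rel.append(YES if out.relevance >= 0.5 else NO)
        n = min(x.n_words, len(ex.tags))
        tag_idx = out.token_scores[:n].argmax(1)
        pred_tags.append(repair_iob2([TAG_SET[i] for i in tag_idx]))
        gold_tags.append(list(ex.tags[:n]))
        toks.append(list(ex.tokens[:n]))
    sent = sentence_metrics(
        confusion_from_labels(pred_rel, [ex.relevance for ex in examples])
    )
    ent = entity_metrics(evaluate_tag_sequences(pred_tags, gold_tags, toks))
    return sent, ent


def train(
    train_set: Sequence[GoldExample],
    val_set: Sequence[GoldExample],
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
    vocab: PieceVocab | None = None,
) -> tuple[DualTaskModel, list[dict]]:
    """Fit the dual-task model and return (best model, per-epoch log).

    The piece vocabulary is built from the training texts.  After each
    epoch the validation sentence F1 and exact-match entity F1 are logged;
    the returned model carries the weights of the epoch with the highest
    validation sentence F1 (the primary metric).  Fully reproducible given
    ``train_config.seed``.
    """
    if not train_set:
        raise ValueError("training set must be non-empty")
    cfg = encoder_config or EncoderConfig()
    tc = train_config or TrainConfig()
    vocab = vocab or PieceVocab.build([ex.text for ex in train_set])
    model = DualTaskModel(cfg, vocab, seed=tc.seed)
    opt = Adam(model.params, lr=tc.lr)
    rng = np.random.default_rng(tc.seed + 1)

    inputs, sent, tags = _prepare(train_set, vocab, cfg.max_length)
    n = len(train_set)
    log: list[dict] = []
    best_score: tuple[float, float] = (-1.0, -1.0)
    best_params = None

    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, tc.batch_size):
            idx = order[i : i + tc.batch_size]
            loss, grads = model.loss_and_grads(
                [inputs[j] for j in idx], sent[idx], [tags[j] for j in idx], tc.lam
            )
            if not np.isfinite(loss):
                raise TrainingDiverged(epoch)
            clip_grads(grads, tc.max_grad_norm)
            opt.step(grads)
            epoch_loss += loss * len(idx)
        epoch_loss /= n

        entry = {"epoch": epoch, "train_loss": epoch_loss}
        if val_set:
            sent_m, ent_m = _validation_metrics(model, val_set)
            entry["val_sentence_f1"] = sent_m.f1
            entry["val_entity_f1"] = ent_m.f1
            # primary criterion: sentence F1; ties broken by entity F1 so a
            # perfect early sentence head cannot freeze an untrained tagger
            score = (
                sent_m.f1 if sent_m.f1 is not None else -1.0,
                ent_m.f1 if ent_m.f1 is not None else -1.0,
            )
            if score > best_score:
                best_score = score
                best_params = {k: v.copy() for k, v in model.params.items()}
        log.append(entry)

    if best_params is not None:
        for k in model.params:
            model.params[k][...] = best_params[k]
    return model, log


def predict(model: DualTaskModel, text: str) -> tuple[str, list[str]]:
    """Predict (relevance label, IOB2 tag per word token) for one tweet.

    Relevance is Yes iff P(Yes) >= 0.5; token tags are the per-token
    argmax, repaired to valid IOB2 (stray I-X becomes B-X).  Tags are
    produced for the word tokens that fit in the encoder window.
    """
    out = model.output_for(text)
    label = YES if out.relevance >= 0.5 else NO
    tags = repair_iob2([TAG_SET[i] for i in out.token_scores.argmax(1)])
    return label, tags


# ---------------------------------------------------------------------------
# persistence


def save_model(model: DualTaskModel, directory: str | Path) -> None:
    """Save as a directory: config.json + vocab.json + weights.npz."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "config.json").write_text(
        json.dumps(
            {
                "kind": model.config.kind,
                "identifier": model.config.identifier,
                "hidden": model.config.hidden,
                "layers": model.config.layers,
                "heads": model.config.heads,
                "max_length": model.config.max_length,
            },
            indent=2,
        )
    )
    (directory / "vocab.json").write_text(json.dumps(model.vocab.itos))
    np.savez(directory / "weights.npz", **model.params)


def load_model(directory: str | Path) -> DualTaskModel:
    directory = Path(directory)
    cfg = EncoderConfig(**json.loads((directory / "config.json").read_text()))
    vocab = PieceVocab(json.loads((directory / "vocab.json").read_text()))
    model = DualTaskModel(cfg, vocab)
    with np.load(directory / "weights.npz") as data:
        for k in model.params:
            model.params[k][...] = data[k]
    return model
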