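"""Sentence-level and entity-level evaluation.

Sentence classification is scored from a 2x2 confusion table (Yes = the
positive class).  Entity extraction is scored on exact-match entities: a
predicted entity is correct only if a gold entity has the identical type
and the identical token span.  Token accuracy is the fraction of word
tokens whose full BIO tag is predicted exactly.

Undefined metrics (zero denominator) are reported as ``None``, never as 0.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .surveillance import Entity, decode_entities
from .tokens import Token


@dataclass(frozen=True)
class ConfusionCounts:
    """Sentence-task confusion table (positive class = Yes)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class EntityCounts:
    """Entity-task counts: predicted / gold / exactly-matching entities,
    plus token totals for tag accuracy."""

    n_pred: int
    n_gold: int
    n_correct: int
    n_tokens: int = 0
    n_tokens_correct: int = 0

    def __post_init__(self) -> None:
        if self.n_correct > min(self.n_pred, self.n_gold):
            raise ValueError("n_correct cannot exceed n_pred or n_gold")
        if self.n_tokens_correct > self.n_tokens:
            raise ValueError("n_tokens_correct cannot exceed n_tokens")


@dataclass(frozen=True)
class Metrics:
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    accuracy: Optional[float]

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
        }


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def f1_score(precision: Optional[float], recall: Optional[float]) -> Optional[float]:
    """Harmonic mean of precision and recall; None when undefined."""
    if precision is None or recall is None or precision + recall == 0:
        return None
    return 2 * precision * recall / (precision + recall)


def sentence_metrics(counts: ConfusionCounts) -> Metrics:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2TP/(2TP+FP+FN),
    accuracy (TP+TN)/total."""
    tp, fn, fp, tn = counts.tp, counts.fn, counts.fp, counts.tn
    return Metrics(
        precision=_ratio(tp, tp + fp),
        recall=_ratio(tp, tp + fn),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        accuracy=_ratio(tp + tn, tp + fn + fp + tn),
    )


def confusion_from_labels(
    predicted: Sequence[str], gold: Sequence[str], positive: str = "Yes"
) -> ConfusionCounts:
    if len(predicted) != len(gold):
        raise ValueError("predicted and gold label lists differ in length")
    tp = fn = fp = tn = 0
    for p, g in zip(predicted, gold):
        if g == positive:
            tp, fn = tp + (p == positive), fn + (p != positive)
        else:
            fp, tn = fp + (p == positive), tn + (p != positive)
    return ConfusionCounts(tp, fn, fp, tn)


def match_entities(
    predicted: Sequence[Entity], gold: Sequence[Entity]
) -> EntityCounts:
    """Count exact-boundary, exact-type matches between two entity sets.

    Each gold entity matches at most one prediction (multiset
    intersection), so duplicated predictions are not double-credited.
    """
    pred_keys = Counter((e.entity_type, e.start, e.end) for e in predicted)
    gold_keys = Counter((e.entity_type, e.start, e.end) for e in gold)
    n_correct = sum((pred_keys & gold_keys).values())
    return EntityCounts(len(predicted), len(gold), n_correct)


def entity_metrics(counts: EntityCounts, variant: str = "precision_recall") -> Metrics:
    """Entity precision n_correct/n_pred, recall n_correct/n_gold, token
    accuracy, and F1.

    ``variant`` selects the F1 form: ``precision_recall`` (the default
    harmonic mean of precision and recall) or ``accuracy_recall``
    (harmonic mean of token accuracy and recall).
    """
    precision = _ratio(counts.n_correct, counts.n_pred)
    recall = _ratio(counts.n_correct, counts.n_gold)
    accuracy = _ratio(counts.n_tokens_correct, counts.n_tokens)
    if variant == "precision_recall":
        f1 = f1_score(precision, recall)
    elif variant == "accuracy_recall":
        f1 = f1_score(accuracy, recall)
    else:
        raise ValueError(f"unknown entity F1 variant: {variant!r}")
    return Metrics(precision, recall, f1, accuracy)


def evaluate_tag_sequences(
    predicted: Sequence[Sequence[str]],
    gold: Sequence[Sequence[str]],
    tokens: Sequence[Sequence[Token]],
) -> EntityCounts:
    """Aggregate entity counts over a corpus of tag sequences."""
    if not (len(predicted) == len(gold) == len(tokens)):
        raise ValueError("predicted/gold/tokens lists differ in length")
    n_pred = n_gold = n_correct = n_tok = n_tok_ok = 0
    for p_tags, g_tags, toks in zip(predicted, gold, tokens):
        c = match_entities(decode_entities(p_tags, toks), decode_entities(g_tags, toks))
        n_pred += c.n_pred
        n_gold += c.n_gold
        n_correct += c.n_correct
        n_tok += len(toks)
        n_tok_ok += sum(p == g for p, g in zip(p_tags, g_tags))
    return EntityCounts(n_pred, n_gold, n_correct, n_tok, n_tok_ok)


def report_to_json(sentence: Metrics, entity: Metrics) -> str:
    return json.dumps(
        {"sentence": sentence.to_dict(), "entity": entity.to_dict()}, indent=2
    )


def report_to_text(sentence: Metrics, entity: Metrics) -> str:
    def fmt(v: Optional[float]) -> str:
        return f"{v:.4f}" if v is not None else "undef"

    lines = [f"{'task':<22}{'precision':>10}{'recall':>10}{'f1':>10}{'accuracy':>10}"]
    for name, m in (("sentence classification", sentence), ("entity extraction", entity)):
        lines.append(
            f"{name:<22}{fmt(m.precision):>10}{fmt(m.recall):>10}"
            f"{fmt(m.f1):>10}{fmt(m.accuracy):>10}"
        )
    return "\n".join(lines)
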