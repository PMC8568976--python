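"""Majority-vote aggregation of accepted worker annotations into gold labels.

Each tweet's crowd scores (0-5) are binarized (0-2 -> No, 3-5 -> Yes) and
majority-voted into a binary relevance label; each worker's character spans
are projected onto word tokens and voted per token into a consensus IOB2
tag sequence.  Ties break conservatively to No / O.  A deterministic
shuffled split produces train/validation/test subsets.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .crowd_qc import SpanAnnotation, WorkerAnnotation
from .labels import O_TAG, is_valid_iob2, tag_type, types_to_iob2
from .tokens import Token, token_overlaps, word_tokenize

YES = "Yes"
NO = "No"


@dataclass(frozen=True)
class GoldExample:
    """Aggregated consensus label for one tweet: binary relevance plus one
    IOB2 tag per word token."""

    tweet_id: str
    text: str
    relevance: str
    tokens: tuple[Token, ...]
    tags: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.relevance not in (YES, NO):
            raise ValueError(f"relevance must be Yes/No, got {self.relevance!r}")
        if len(self.tags) != len(self.tokens):
            raise ValueError("one tag per token required")
        if not is_valid_iob2(self.tags):
            raise ValueError("tag sequence is not valid IOB2")


def binarize_score(score: int) -> str:
    """Map a 0-5 crowd score to binary relevance: 0-2 -> No, 3-5 -> Yes."""
    if score not in range(6):
        raise ValueError(f"score must be in 0..5, got {score}")
    return YES if score >= 3 else NO


def majority_vote_relevance(scores: Sequence[int]) -> str:
    """Binarize each score, then take the majority label; ties -> No."""
    if not scores:
        raise ValueError("cannot vote on an empty score list")
    votes = Counter(binarize_score(s) for s in scores)
    return YES if votes[YES] > votes[NO] else NO


def spans_to_token_tags(
    spans: Sequence[SpanAnnotation],
    tokens: Sequence[Token],
    related_only: bool = True,
) -> list[str]:
    """Project character spans onto word tokens as IOB2 tags.

    A token overlapping a span of type X (by any amount) is covered: the
    first covered token of the span gets B-X, subsequent ones I-X.  Only
    incident-related spans contribute to gold tags by default; unrelated
    highlights are kept in the raw data but carry no gold label.
    """
    used = sorted(
        (s for s in spans if s.related or not related_only),
        key=lambda s: s.char_start,
    )
    for a, b in zip(used, used[1:]):
        if b.char_start < a.char_end and b.entity_type != a.entity_type:
            raise ValueError("overlapping spans of different types")
    out = [O_TAG] * len(tokens)
    for span in used:
        first = True
        for i, tok in enumerate(tokens):
            if token_overlaps(tok, span.char_start, span.char_end):
                out[i] = f"{'B' if first else 'I'}-{span.entity_type}"
                first = False
    return out


def majority_vote_tags(tag_sequences: Sequence[Sequence[str]]) -> list[str]:
    """Per-token plurality vote over entity-type-or-O (B/I prefixes are
    stripped before voting and reconstructed afterwards); ties -> O."""
    if not tag_sequences:
        raise ValueError("cannot vote on an empty set of tag sequences")
    length = len(tag_sequences[0])
    if any(len(seq) != length for seq in tag_sequences):
        raise ValueError("tag sequences must have equal lengths")
    consensus_types = []
    for i in range(length):
        votes = Counter(tag_type(seq[i]) for seq in tag_sequences)
        top = max(votes.values())
        winners = [lab for lab, c in votes.items() if c == top]
        consensus_types.append(winners[0] if len(winners) == 1 else O_TAG)
    return types_to_iob2(consensus_types)


def aggregate(
    annotations: Sequence[WorkerAnnotation], texts: Mapping[str, str]
) -> list[GoldExample]:
    """Aggregate accepted annotations into one GoldExample per tweet.

    Output order follows first appearance of each tweet in ``annotations``.
    """
    by_tweet: defaultdict[str, list[WorkerAnnotation]] = defaultdict(list)
    for ann in annotations:
        by_tweet[ann.tweet_id].append(ann)
    out = []
    for tweet_id, anns in by_tweet.items():
        text = texts[tweet_id]
        tokens = tuple(word_tokenize(text))
        relevance = majority_vote_relevance([a.score for a in anns])
        tag_seqs = [spans_to_token_tags(a.spans, tokens) for a in anns]
        tags = tuple(majority_vote_tags(tag_seqs))
        out.append(GoldExample(tweet_id, text, relevance, tokens, tags))
    return out


def split_dataset(
    examples: Sequence,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Deterministic shuffled train/validation/test split.

    Shuffles with the given seed and cuts at floor(n * r_train) and
    floor(n * (r_train + r_val)); the three subsets partition the input.
    """
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    n = len(examples)
    if n < 3:
        raise ValueError("need at least 3 examples to split")
    order = np.random.default_rng(seed).permutation(n)
    cut1 = int(n * ratios[0])
    cut2 = int(n * (ratios[0] + ratios[1]))
    shuffled = [examples[i] for i in order]
    return shuffled[:cut1], shuffled[cut1:cut2], shuffled[cut2:]


# ---------------------------------------------------------------------------
# CoNLL-style and JSON-lines I/O


def write_conll(examples: Iterable[GoldExample], path: str | Path) -> None:
    """Two-column token TAB tag blocks separated by blank lines, with
    ``# id:`` / ``# relevance:`` comment lines per tweet."""
    with Path(path).open("w") as fh:
        for ex in examples:
            fh.write(f"# id: {ex.tweet_id}\n")
            fh.write(f"# relevance: {ex.relevance}\n")
            for tok, tag in zip(ex.tokens, ex.tags):
                fh.write(f"{tok.text}\t{tag}\n")
            fh.write("\n")


def read_conll(path: str | Path) -> list[GoldExample]:
    """Read examples written by :func:`write_conll`.

    Character offsets are reconstructed by joining tokens with single
    spaces (the original spacing is not stored in the CoNLL form).
    """
    out: list[GoldExample] = []
    tweet_id, relevance = None, None
    words: list[str] = []
    tags: list[str] = []

    def flush() -> None:
        nonlocal tweet_id, relevance, words, tags
        if words:
            tokens, pos = [], 0
            for w in words:
                tokens.append(Token(w, pos, pos + len(w)))
                pos += len(w) + 1
            out.append(
                GoldExample(
                    tweet_id or f"conll-{len(out)}",
                    " ".join(words),
                    relevance or NO,
                    tuple(tokens),
                    tuple(tags),
                )
            )
        tweet_id, relevance, words, tags = None, None, [], []

    for line in Path(path).read_text().splitlines():
        if not line.strip():
            flush()
        elif line.startswith("# id:"):
            tweet_id = line[5:].strip()
        elif line.startswith("# relevance:"):
            relevance = line[12:].strip()
        else:
            word, _, tag = line.partition("\t")
            words.append(word)
            tags.append(tag.strip())
    flush()
    return out


def write_gold_jsonl(examples: Iterable[GoldExample], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for ex in examples:
            fh.write(
                json.dumps(
                    {
                        "tweet_id": ex.tweet_id,
                        "text": ex.text,
                        "relevance": ex.relevance,
                        "tokens": [[t.text, t.start, t.end] for t in ex.tokens],
                        "tags": list(ex.tags),
                    }
                )
                + "\n"
            )


def read_gold_jsonl(path: str | Path) -> list[GoldExample]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(
                GoldExample(
                    d["tweet_id"],
                    d["text"],
                    d["relevance"],
                    tuple(Token(t, s, e) for t, s, e in d["tokens"]),
                    tuple(d["tags"]),
                )
            )
    return out
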