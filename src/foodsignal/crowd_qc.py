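"""Crowdsourcing quality control.

Implements the annotation-collection protocol used to build the labeled
corpus: tweets are published in batches, each worker may label at most a
fixed number of tweets per batch, every annotation is compared against its
peers on the same tweet with a similarity score, low-similarity annotations
are rejected (and the tweet queued for relabeling), workers whose rejected
fraction is high are blocked from later batches, and overall agreement is
measured with Krippendorff's alpha before and after filtering.
"""

from __future__ import annotations

import csv
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Optional, Sequence

from .labels import O_TAG, normalize_entity_type
from .tokens import Token, token_overlaps, word_tokenize


@dataclass(frozen=True)
class SpanAnnotation:
    """One highlighted phrase: entity type, 0-based half-open character
    offsets into the preprocessed text, and whether the worker judged the
    phrase related to the illness incident."""

    entity_type: str
    char_start: int
    char_end: int
    related: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "entity_type", normalize_entity_type(self.entity_type))
        if not (0 <= self.char_start < self.char_end):
            raise ValueError(
                f"invalid span offsets [{self.char_start}, {self.char_end})"
            )


@dataclass(frozen=True)
class WorkerAnnotation:
    """One worker's labeling of one tweet: a 0-5 relevance score plus
    non-overlapping typed spans."""

    worker_id: str
    tweet_id: str
    score: int
    spans: tuple[SpanAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if self.score not in range(6):
            raise ValueError(f"score must be in 0..5, got {self.score}")
        object.__setattr__(self, "spans", tuple(self.spans))
        ordered = sorted(self.spans, key=lambda s: s.char_start)
        for a, b in zip(ordered, ordered[1:]):
            if b.char_start < a.char_end:
                raise ValueError(
                    f"overlapping spans from worker {self.worker_id} "
                    f"on tweet {self.tweet_id}"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.worker_id, self.tweet_id)


@dataclass
class QcReport:
    """Outcome of the full QC pass over a corpus of annotations."""

    accepted: list[tuple[str, str]] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)
    blocked_workers: list[str] = field(default_factory=list)
    relabel_queue: list[str] = field(default_factory=list)
    unverifiable: list[str] = field(default_factory=list)
    cap_violations: list[tuple[str, str]] = field(default_factory=list)
    alpha_before: Optional[float] = None
    alpha_after: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "accepted": [list(k) for k in self.accepted],
                "rejected": [list(k) for k in self.rejected],
                "blocked_workers": self.blocked_workers,
                "relabel_queue": self.relabel_queue,
                "unverifiable": self.unverifiable,
                "cap_violations": [list(k) for k in self.cap_violations],
                "alpha_before": self.alpha_before,
                "alpha_after": self.alpha_after,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# batching and caps


def make_batches(tweets: Sequence, batch_size: int) -> list[list]:
    """Split a sequence into consecutive batches of ``batch_size`` (the last
    may be shorter), preserving order."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    return [list(tweets[i : i + batch_size]) for i in range(0, len(tweets), batch_size)]


def enforce_worker_cap(
    annotations: Sequence[WorkerAnnotation], cap: int = 10
) -> tuple[list[WorkerAnnotation], list[WorkerAnnotation]]:
    """Within one batch, keep at most ``cap`` annotations per worker
    (earliest submissions first); the excess is returned as violations."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    counts: Counter[str] = Counter()
    accepted, violations = [], []
    for ann in annotations:
        counts[ann.worker_id] += 1
        (accepted if counts[ann.worker_id] <= cap else violations).append(ann)
    return accepted, violations


# ---------------------------------------------------------------------------
# inter-worker agreement

def token_type_labels(
    spans: Iterable[SpanAnnotation],
    tokens: Sequence[Token],
    related_only: bool = False,
) -> list[str]:
    """Project character spans onto word tokens as entity-type-or-O labels.

    A token overlapping a span of type X (by at least one character) gets
    label X.  Spans never overlap within one annotation, so the projection
    is unambiguous.
    """
    out = [O_TAG] * len(tokens)
    for span in spans:
        if related_only and not span.related:
            continue
        for i, tok in enumerate(tokens):
            if token_overlaps(tok, span.char_start, span.char_end):
                out[i] = span.entity_type
    return out


def annotation_similarity(
    a: WorkerAnnotation,
    peers: Sequence[WorkerAnnotation],
    tokens: Sequence[Token],
) -> float:
    """Similarity of one annotation to its peers on the same tweet.

    For each peer p: sim(a, p) = 1/2 * token agreement (fraction of word
    tokens assigned the same entity-type-or-O by both) + 1/2 * score
    agreement (1 - |score_a - score_p| / 5); the result is the mean over
    peers and lies in [0, 1].  A tweet with no word tokens has vacuous
    token agreement 1.
    """
    if not peers:
        raise ValueError("agreement is undefined without peers")
    labels_a = token_type_labels(a.spans, tokens)
    total = 0.0
    for p in peers:
        if p.tweet_id != a.tweet_id:
            raise ValueError("peers must annotate the same tweet")
        labels_p = token_type_labels(p.spans, tokens)
        if tokens:
            tok_agree = sum(x == y for x, y in zip(labels_a, labels_p)) / len(tokens)
        else:
            tok_agree = 1.0
        score_agree = 1.0 - abs(a.score - p.score) / 5.0
        total += 0.5 * tok_agree + 0.5 * score_agree
    return total / len(peers)


def filter_annotations(
    annotations: Sequence[WorkerAnnotation],
    texts: Mapping[str, str],
    threshold: float = 0.6,
) -> tuple[list[WorkerAnnotation], list[WorkerAnnotation], list[str], list[str]]:
    """Reject annotations whose peer similarity falls below ``threshold``.

    Returns (accepted, rejected, relabel_queue, unverifiable): tweets with
    any rejection are queued for republication; tweets with a single
    annotation cannot be verified and are kept but flagged.
    """
    by_tweet: defaultdict[str, list[WorkerAnnotation]] = defaultdict(list)
    for ann in annotations:
        by_tweet[ann.tweet_id].append(ann)

    accepted, rejected, relabel, unverifiable = [], [], [], []
    for tweet_id, anns in by_tweet.items():
        if len(anns) < 2:
            accepted.extend(anns)
            unverifiable.append(tweet_id)
            continue
        tokens = word_tokenize(texts[tweet_id])
        any_rejected = False
        for ann in anns:
            peers = [p for p in anns if p is not ann]
            if annotation_similarity(ann, peers, tokens) < threshold:
                rejected.append(ann)
                any_rejected = True
            else:
                accepted.append(ann)
        if any_rejected:
            relabel.append(tweet_id)
    return accepted, rejected, relabel, unverifiable


def detect_spammers(
    qc_history: Mapping[str, tuple[int, int]],
    min_labeled: int = 3,
    reject_frac: float = 0.5,
) -> list[str]:
    """Workers to block: at least ``min_labeled`` annotations of which at
    least ``reject_frac`` were rejected.

    ``qc_history`` maps worker id to (n_labeled, n_rejected).  The defaults
    block random labelers quickly while tolerating one-off mistakes.
    """
    blocked = []
    for worker, (n_labeled, n_rejected) in qc_history.items():
        if n_labeled >= min_labeled and n_rejected / n_labeled >= reject_frac:
            blocked.append(worker)
    return sorted(blocked)


# ---------------------------------------------------------------------------
# Krippendorff's alpha


def krippendorff_alpha(values_by_unit: Iterable[Iterable[Optional[Hashable]]]) -> float:
    """Krippendorff's alpha for nominal data.

    ``values_by_unit`` gives, per unit (here: one word token of one tweet),
    the labels assigned by the workers who rated it; ``None`` marks a
    missing value.  Units with fewer than two nonmissing values are
    excluded (they contribute no pairable information).

    alpha = 1 - D_o / D_e, with disagreements computed from the coincidence
    matrix: each ordered pair of values within a unit of m pairable values
    contributes 1/(m-1).  The nominal distance is 0 for equal labels and 1
    otherwise.  Perfect observed agreement returns 1.0 exactly.
    """
    pair_counts: Counter[tuple[Hashable, Hashable]] = Counter()
    marginals: Counter[Hashable] = Counter()
    n = 0
    for unit in values_by_unit:
        vals = [v for v in unit if v is not None]
        m = len(vals)
        if m < 2:
            continue
        n += m
        counts = Counter(vals)
        for c, n_c in counts.items():
            marginals[c] += n_c
            for k, n_k in counts.items():
                pair_counts[(c, k)] += n_c * (n_k - (c == k)) / (m - 1)
    if n == 0:
        raise ValueError("need at least one unit with >= 2 nonmissing values")

    d_o = sum(v for (c, k), v in pair_counts.items() if c != k) / n
    if d_o == 0.0:
        return 1.0
    d_e = sum(
        n_c * n_k for c, n_c in marginals.items() for k, n_k in marginals.items() if c != k
    ) / (n * (n - 1))
    if d_e == 0.0:
        raise ValueError("degenerate data: expected disagreement is zero")
    return 1.0 - d_o / d_e


def alpha_from_annotations(
    annotations: Sequence[WorkerAnnotation], texts: Mapping[str, str]
) -> float:
    """Token-level agreement across a set of annotations.

    Units are (tweet, token index); values are the entity-type-or-O label
    each worker's spans induce on that token.  Tweets annotated by a single
    worker contribute no pairable units and drop out.
    """
    by_tweet: defaultdict[str, list[WorkerAnnotation]] = defaultdict(list)
    for ann in annotations:
        by_tweet[ann.tweet_id].append(ann)
    units: list[list[str]] = []
    for tweet_id, anns in by_tweet.items():
        if len(anns) < 2:
            continue
        tokens = word_tokenize(texts[tweet_id])
        per_worker = [token_type_labels(a.spans, tokens) for a in anns]
        for i in range(len(tokens)):
            units.append([labels[i] for labels in per_worker])
    return krippendorff_alpha(units)


# ---------------------------------------------------------------------------
# orchestration


def run_qc(
    tweets: Sequence,
    annotations: Sequence[WorkerAnnotation],
    threshold: float = 0.6,
    cap: int = 10,
    batch_size: int = 500,
    min_labeled: int = 3,
    reject_frac: float = 0.5,
) -> tuple[list[WorkerAnnotation], QcReport]:
    """Run the full batched QC protocol and return accepted annotations.

    Tweets are split into batches in corpus order.  Batches are processed
    sequentially: per-worker caps apply within a batch, the similarity
    filter rejects low-agreement annotations, and workers blocked in
    earlier batches are excluded from later ones.  Agreement (alpha) is
    reported over all annotations before filtering and over the accepted
    set after.
    """
    texts = {t.id: t.text for t in tweets}
    by_tweet: defaultdict[str, list[WorkerAnnotation]] = defaultdict(list)
    for ann in annotations:
        if ann.tweet_id not in texts:
            raise ValueError(f"annotation references unknown tweet {ann.tweet_id}")
        by_tweet[ann.tweet_id].append(ann)

    report = QcReport()
    accepted_all: list[WorkerAnnotation] = []
    history: defaultdict[str, list[int]] = defaultdict(lambda: [0, 0])
    blocked: set[str] = set()

    for batch in make_batches(tweets, batch_size):
        batch_anns = [
            a
            for t in batch
            for a in by_tweet[t.id]
            if a.worker_id not in blocked
        ]
        capped, violations = enforce_worker_cap(batch_anns, cap)
        report.cap_violations.extend(a.key for a in violations)

        acc, rej, relabel, unverifiable = filter_annotations(capped, texts, threshold)
        accepted_all.extend(acc)
        report.accepted.extend(a.key for a in acc)
        report.rejected.extend(a.key for a in rej)
        report.relabel_queue.extend(relabel)
        report.unverifiable.extend(unverifiable)

        for a in acc:
            history[a.worker_id][0] += 1
        for a in rej:
            history[a.worker_id][0] += 1
            history[a.worker_id][1] += 1
        blocked.update(
            detect_spammers(
                {w: (n, r) for w, (n, r) in history.items()}, min_labeled, reject_frac
            )
        )

    report.blocked_workers = sorted(blocked)
    try:
        report.alpha_before = alpha_from_annotations(annotations, texts)
        report.alpha_after = alpha_from_annotations(accepted_all, texts)
    except ValueError:
        pass  # too few pairable units; alphas stay None
    return accepted_all, report


# ---------------------------------------------------------------------------
# I/O (Mechanical Turk-style results export)

_CSV_FIELDS = ("worker_id", "tweet_id", "score", "spans")


def _spans_to_json(spans: Iterable[SpanAnnotation]) -> str:
    return json.dumps(
        [
            {"type": s.entity_type, "start": s.char_start, "end": s.char_end, "related": s.related}
            for s in spans
        ]
    )


def _spans_from_json(blob: str) -> tuple[SpanAnnotation, ...]:
    return tuple(
        SpanAnnotation(d["type"], d["start"], d["end"], d.get("related", True))
        for d in json.loads(blob or "[]")
    )


def write_annotations(
    annotations: Iterable[WorkerAnnotation], path: str | Path, format: str = "csv"
) -> None:
    """Write annotations as CSV (spans serialized as a JSON array) or
    JSON-lines."""
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_FIELDS)
            for a in annotations:
                writer.writerow([a.worker_id, a.tweet_id, a.score, _spans_to_json(a.spans)])
    elif format == "jsonl":
        with path.open("w") as fh:
            for a in annotations:
                fh.write(
                    json.dumps(
                        {
                            "worker_id": a.worker_id,
                            "tweet_id": a.tweet_id,
                            "score": a.score,
                            "spans": json.loads(_spans_to_json(a.spans)),
                        }
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown annotation format: {format!r}")


def read_annotations(path: str | Path, format: str = "csv") -> list[WorkerAnnotation]:
    """Read annotations written by :func:`write_annotations`."""
    path = Path(path)
    out: list[WorkerAnnotation] = []
    if format == "csv":
        with path.open(newline="") as fh:
            for row in csv.DictReader(fh):
                out.append(
                    WorkerAnnotation(
                        row["worker_id"],
                        row["tweet_id"],
                        int(row["score"]),
                        _spans_from_json(row["spans"]),
                    )
                )
    elif format == "jsonl":
        with path.open() as fh:
            for line in fh:
                if not line.strip():
                    continue
                d = json.loads(line)
                out.append(
                    WorkerAnnotation(
                        d["worker_id"],
                        d["tweet_id"],
                        int(d["score"]),
                        tuple(
                            SpanAnnotation(
                                s["type"], s["start"], s["end"], s.get("related", True)
                            )
                            for s in d.get("spans", [])
                        ),
                    )
                )
    else:
        raise ValueError(f"unknown annotation format: {format!r}")
    return out
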