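"""Reading, keyword-filtering, and preprocessing of tweet-like records.

This mirrors the collection stage of a keyword-based surveillance pipeline:
posts are over-collected with a broad symptom/keyword filter and cleaned
(retweets and hyperlinks removed) before any modeling.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

#: The default collection keyword list: foodborne-illness keywords, common
#: symptoms and their variants.  Hashtags are kept verbatim.  Very ambiguous
#: terms ("sick", "fever") are deliberately excluded.
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "#foodpoisoning",
    "#stomachache",
    "food poison",
    "food poisoning",
    "stomach",
    "vomit",
    "puke",
    "diarrhea",
    "the runs",
)

_URL_RE = re.compile(r"https?://\S+")
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class TweetRecord:
    """One social-media post.

    ``created_at`` is timezone-resolved to UTC when parseable; records
    without a timestamp are excluded from time-series operations only.
    ``region`` is an ISO-like code such as ``"US-IL"`` or ``"CA"``, or None
    when location inference failed.
    """

    id: str
    text: str
    created_at: Optional[datetime] = None
    region: Optional[str] = None
    is_retweet: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("tweet id must be non-empty")


@dataclass(frozen=True)
class KeywordList:
    """Ordered, duplicate-free list of lowercase collection phrases."""

    phrases: tuple[str, ...] = DEFAULT_KEYWORDS

    def __post_init__(self) -> None:
        if not self.phrases:
            raise ValueError("keyword list must be non-empty")
        lowered = tuple(p.lower() for p in self.phrases)
        if len(set(lowered)) != len(lowered):
            raise ValueError("keyword list contains duplicate phrases")
        object.__setattr__(self, "phrases", lowered)

    @classmethod
    def from_file(cls, path: str | Path) -> "KeywordList":
        """Read one phrase per line; blank lines and ``#``-comment lines are
        skipped unless the line itself is a hashtag keyword."""
        phrases = []
        for line in Path(path).read_text().splitlines():
            s = line.strip()
            if not s or (s.startswith("#") and " " in s):
                continue
            phrases.append(s)
        return cls(tuple(phrases))


class CorpusError(Exception):
    """Fatal problem reading or validating a corpus file."""


@dataclass
class ReadReport:
    """Bookkeeping from :func:`read_tweets`: malformed lines are counted and
    reported, never silently dropped."""

    n_read: int = 0
    n_malformed: int = 0
    first_bad_line: Optional[int] = None


def _parse_created_at(value: object) -> Optional[datetime]:
    if value is None or value == "":
        return None
    if isinstance(value, datetime):
        dt = value
    else:
        s = str(value).strip()
        if s.endswith("Z"):
            s = s[:-1] + "+00:00"
        dt = datetime.fromisoformat(s)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def _record_from_mapping(obj: dict) -> TweetRecord:
    if "id" not in obj or obj["id"] in (None, "") or "text" not in obj or obj["text"] is None:
        raise ValueError("record requires non-empty id and a text field")
    raw_rt = obj.get("is_retweet", False)
    if isinstance(raw_rt, str):
        is_rt = raw_rt.strip().lower() in ("1", "true", "yes")
    else:
        is_rt = bool(raw_rt)
    region = obj.get("region") or None
    return TweetRecord(
        id=str(obj["id"]),
        text=str(obj["text"]),
        created_at=_parse_created_at(obj.get("created_at")),
        region=str(region) if region else None,
        is_retweet=is_rt,
    )


def read_tweets(
    path: str | Path, format: str = "jsonl"
) -> tuple[list[TweetRecord], ReadReport]:
    """Read tweet records from a JSON-lines or CSV file, in file order.

    Malformed lines (bad JSON, missing id/text, unparseable timestamp) are
    counted in the returned :class:`ReadReport`.  More than 50% malformed
    lines is treated as a broken file and raises :class:`CorpusError`
    naming the first offending line.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"cannot read corpus file: {path}")
    if format not in ("jsonl", "csv"):
        raise CorpusError(f"unknown corpus format: {format!r}")

    records: list[TweetRecord] = []
    report = ReadReport()

    def handle(lineno: int, obj: Optional[dict]) -> None:
        report.n_read += 1
        try:
            if obj is None:
                raise ValueError("unparseable line")
            records.append(_record_from_mapping(obj))
        except (ValueError, TypeError):
            report.n_malformed += 1
            if report.first_bad_line is None:
                report.first_bad_line = lineno

    if format == "jsonl":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError:
                    obj = None
                handle(lineno, obj if isinstance(obj, dict) else None)
    else:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                handle(lineno, row)

    if report.n_read and report.n_malformed * 2 > report.n_read:
        raise CorpusError(
            f"{report.n_malformed}/{report.n_read} malformed records in {path}; "
            f"first offending line: {report.first_bad_line}"
        )
    return records, report


def write_tweets(records: Iterable[TweetRecord], path: str | Path) -> None:
    """Write records as JSON-lines (id, text, created_at ISO-8601, region,
    is_retweet)."""
    with Path(path).open("w") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "id": r.id,
                        "text": r.text,
                        "created_at": r.created_at.isoformat() if r.created_at else None,
                        "region": r.region,
                        "is_retweet": r.is_retweet,
                    }
                )
                + "\n"
            )


def keyword_filter(
    tweets: Sequence[TweetRecord], keywords: KeywordList | None = None
) -> list[TweetRecord]:
    """Retain tweets whose lowercased text contains at least one keyword
    phrase as a contiguous substring, preserving order.

    Matching is deliberately substring-based ("stomach" matches
    "stomachache"): the collection stage over-collects and leaves relevance
    to the classifier.
    """
    kw = keywords or KeywordList()
    out = []
    for t in tweets:
        low = t.text.lower()
        if any(p in low for p in kw.phrases):
            out.append(t)
    return out


def preprocess(tweet: TweetRecord) -> Optional[TweetRecord]:
    """Clean one record; return None when it should be dropped.

    Drops retweets (metadata flag, or text starting with ``"RT @"``),
    removes ``http(s)://`` URL tokens, collapses whitespace runs, strips,
    and drops records whose cleaned text is empty.
    """
    if tweet.is_retweet or tweet.text.startswith("RT @"):
        return None
    cleaned = _URL_RE.sub(" ", tweet.text)
    cleaned = _WS_RE.sub(" ", cleaned).strip()
    if not cleaned:
        return None
    return replace(tweet, text=cleaned)


def preprocess_corpus(tweets: Iterable[TweetRecord]) -> Iterator[TweetRecord]:
    """Apply :func:`preprocess` across a corpus, dropping signalled records."""
    for t in tweets:
        cleaned = preprocess(t)
        if cleaned is not None:
            yield cleaned
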