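"""Outbreak-signal analytics over per-tweet model predictions.

The model emits, per tweet, a Yes/No relevance label and a BIO tag per
word token.  Maximal runs of non-O tags of one type are decoded into
entities; a tweet enters frequency analysis only when it is classified
Yes AND carries at least one FOOD entity.  The surviving incidents are
aggregated into daily count series (UTC calendar days), ranked food-entity
tables, and food-term / region subsets for case studies.
"""

from __future__ import annotations

import re
import string
from collections import Counter
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Callable, Iterable, Optional, Sequence

from .labels import O_TAG, split_tag
from .tokens import Token

_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class Entity:
    """One decoded entity: type, half-open word-token span, surface text."""

    entity_type: str
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("entity token span must be non-empty")
        if not self.surface:
            raise ValueError("entity surface must be non-empty")


@dataclass(frozen=True)
class IncidentRecord:
    """Per-tweet surveillance unit derived from a model prediction."""

    tweet_id: str
    date: Optional[date]
    region: Optional[str]
    relevant: bool
    entities: tuple[Entity, ...] = ()


def decode_entities(
    tags: Sequence[str], tokens: Sequence[Token | str]
) -> list[Entity]:
    """Decode a BIO sequence into entities.

    Each maximal run of non-O tags of one type is one entity; a B- tag
    always starts a new entity even adjacent to a same-type run, and a
    stray I-X with no preceding same-type tag is repaired to B-X.  Token
    type aliases ("other" for KEY, lowercase types) are accepted.
    """
    if len(tags) != len(tokens):
        raise ValueError(f"{len(tags)} tags for {len(tokens)} tokens")
    words = [t.text if isinstance(t, Token) else str(t) for t in tokens]

    entities: list[Entity] = []
    cur_type: Optional[str] = None
    cur_start = 0

    def close(end: int) -> None:
        nonlocal cur_type
        if cur_type is not None:
            entities.append(
                Entity(cur_type, cur_start, end, " ".join(words[cur_start:end]))
            )
            cur_type = None

    for i, tag in enumerate(tags):
        prefix, etype = split_tag(tag)
        if prefix == O_TAG:
            close(i)
        elif prefix == "B" or etype != cur_type:
            close(i)
            cur_type, cur_start = etype, i
    close(len(tags))
    return entities


def incident_filter(record: IncidentRecord) -> bool:
    """The inclusion rule for frequency analysis: classified relevant AND
    at least one FOOD entity predicted."""
    return record.relevant and any(e.entity_type == "FOOD" for e in record.entities)


def daily_series(records: Sequence[IncidentRecord]) -> dict[date, int]:
    """Daily counts of records passing :func:`incident_filter`.

    Returns an ordered date -> count mapping covering every UTC calendar
    day between the first and last passing record, zero-filled for days
    without incidents.  Records without a date are skipped.
    """
    passing = [r for r in records if incident_filter(r) and r.date is not None]
    if not passing:
        return {}
    counts = Counter(r.date for r in passing)
    first, last = min(counts), max(counts)
    series: dict[date, int] = {}
    day = first
    while day <= last:
        series[day] = counts.get(day, 0)
        day += timedelta(days=1)
    return series


def normalize_surface(surface: str) -> str:
    """Canonical surface form: lowercased, surrounding punctuation
    stripped, internal whitespace collapsed."""
    s = _WS_RE.sub(" ", surface.lower()).strip()
    return s.strip(string.punctuation + " ")


def top_food_entities(
    records: Sequence[IncidentRecord], k: int
) -> list[tuple[str, int]]:
    """Top-k FOOD entity surfaces by tweet count over passing records.

    Each tweet contributes at most once per distinct normalized surface
    (tweets are counted, not entity occurrences).  Ties break
    lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    for r in records:
        if not incident_filter(r):
            continue
        surfaces = {
            normalize_surface(e.surface)
            for e in r.entities
            if e.entity_type == "FOOD"
        }
        counts.update(s for s in surfaces if s)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def _whole_word_match(term: str, surface: str) -> bool:
    return re.search(rf"(?<!\w){re.escape(term)}(?!\w)", surface) is not None


def food_term_filter(
    records: Sequence[IncidentRecord],
    terms: Iterable[str],
    whole_word: bool = True,
) -> list[IncidentRecord]:
    """Keep records with at least one FOOD entity whose normalized surface
    contains at least one term (union semantics over terms).

    Whole-word containment by default, so "lettuce" matches "romaine
    lettuce" but not "lettuces"; substring matching is available via
    ``whole_word=False``.
    """
    normalized_terms = [normalize_surface(t) for t in terms]
    if not normalized_terms:
        raise ValueError("term set must be non-empty")

    def hit(record: IncidentRecord) -> bool:
        for e in record.entities:
            if e.entity_type != "FOOD":
                continue
            surf = normalize_surface(e.surface)
            for term in normalized_terms:
                if (_whole_word_match(term, surf) if whole_word else term in surf):
                    return True
        return False

    return [r for r in records if hit(r)]


def region_filter(
    records: Sequence[IncidentRecord],
    predicate: str | Callable[[str], bool] = "US",
) -> list[IncidentRecord]:
    """Keep records whose region code is present and satisfies the
    predicate; records without a region are excluded (location unknown).

    A string predicate matches on country: a code like "US-IL" or "US"
    satisfies predicate "US".
    """
    if callable(predicate):
        test = predicate
    else:
        country = predicate.upper()

        def test(code: str) -> bool:
            return code.upper().split("-")[0] == country

    return [r for r in records if r.region is not None and test(r.region)]


def records_from_predictions(
    predictions: Iterable[dict],
) -> list[IncidentRecord]:
    """Build incident records from prediction dicts (as produced by the
    predict CLI: id, relevance, tokens, tags, plus optional created_at
    date and region carried over from the tweet)."""
    from datetime import datetime

    out = []
    for p in predictions:
        toks = [Token(t, 0, 0) if isinstance(t, str) else Token(*t) for t in p["tokens"]]
        entities = tuple(decode_entities(p["tags"], toks))
        d = p.get("date") or p.get("created_at")
        if isinstance(d, str):
            d = datetime.fromisoformat(d.replace("Z", "+00:00")).date()
        elif isinstance(d, datetime):
            d = d.date()
        out.append(
            IncidentRecord(
                tweet_id=str(p["id"]),
                date=d,
                region=p.get("region"),
                relevant=p["relevance"] == "Yes",
                entities=entities,
            )
        )
    return out


def write_series_csv(series: dict[date, int], path) -> None:
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("date,count\n")
        for day, count in series.items():
            fh.write(f"{day.isoformat()},{count}\n")


def write_ranking_csv(ranking: list[tuple[str, int]], path) -> None:
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("surface,count\n")
        for surface, count in ranking:
            fh.write(f"{surface},{count}\n")
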