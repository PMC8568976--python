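"""Synthetic corpora and simulated crowd workers.

The generator emulates the statistical structure the pipeline assumes:
tweets built from templates that plant FOOD/LOC/SYM/KEY entities at known
character offsets, with three populations — relevant illness reports
(gold Yes), hard negatives that mention an illness keyword in a past,
hypothetical or figurative frame (gold No), and keyword-free small talk
(gold No) — plus noisy workers of configurable reliability, including
spammers who label uniformly at random.  All randomness flows from one
seed through named substreams, so each stage can be regenerated
independently.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np

from .aggregation import YES, NO, GoldExample, spans_to_token_tags
from .corpus_io import TweetRecord
from .crowd_qc import SpanAnnotation, WorkerAnnotation
from .labels import ENTITY_TYPES, O_TAG, tag_type
from .surveillance import decode_entities, normalize_surface
from .tokens import word_tokenize

# ---------------------------------------------------------------------------
# vocabularies and templates

FOODS = (
    "grilled cheese", "lettuce", "romaine lettuce", "salad", "chicken sandwich",
    "pizza", "sushi", "taco", "burger", "ice cream", "potato salad", "oysters",
    "chicken wings", "milkshake", "street hot dog",
)
LOCATIONS = (
    "Chicago", "New York", "Texas", "Ohio", "California", "Boston", "Florida",
    "Seattle",
)
SYMPTOMS = (
    "vomiting", "puking", "diarrhea", "stomach cramps", "throwing up",
    "sick to my stomach",
)
KEYWORD_PHRASES = (
    "food poisoning", "#foodpoisoning", "food poison", "stomach flu",
)

_RELEVANT_TEMPLATES = (
    "I got {KEY} from a {FOOD} last night and I've never felt so betrayed in my life",
    "pretty sure the {FOOD} from that spot in {LOC} gave me {KEY}",
    "been {SYM} all night after eating that {FOOD} , never ordering it again",
    "the {FOOD} I had in {LOC} has me {SYM} , this is definitely {KEY}",
    "my whole family is {SYM} after sharing a {FOOD} , calling the restaurant tomorrow",
    "woke up {SYM} , I blame the {FOOD} from yesterday , classic {KEY}",
)
_CONFOUNDER_TEMPLATES = (
    "it happens too fast to be {KEY} , I just ate way too much",
    "I remember reading an article saying most stomach aches were actually {KEY}",
    "if that {FOOD} ever gives me {KEY} I swear I will never eat there again",
    "years ago I had {KEY} from a {FOOD} , worst week of my life",
    "this deadline is giving me {KEY} lol",
    "watching a documentary about {KEY} outbreaks and how restaurants handle them",
)
_SMALLTALK_TEMPLATES = (
    "had a wonderful brunch with friends today , highly recommend that new place",
    "cannot wait for the weekend honestly , this week dragged forever",
    "the weather in {LOC} is beautiful today , going for a long walk",
    "finally finished the book everyone keeps talking about , loved the ending",
    "my team won again last night , what a season this is turning into",
    "new coffee shop opened around the corner , the playlist alone is worth it",
)

US_REGIONS = ("US-IL", "US-NY", "US-TX", "US-CA", "US-MA", "US-FL", "US-OH", "US-WA")
NON_US_REGIONS = ("CA", "GB", "AU", "IN")

_SLOT_RE = re.compile(r"\{(FOOD|LOC|SYM|KEY)\}")
_SLOT_VOCAB = {"FOOD": FOODS, "LOC": LOCATIONS, "SYM": SYMPTOMS, "KEY": KEYWORD_PHRASES}
#: template slots that carry a gold entity span (SYM included; LOC included).
_SLOT_TYPE = {"FOOD": "FOOD", "LOC": "LOC", "SYM": "SYM", "KEY": "KEY"}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``prevalence`` is the fraction of relevant (gold Yes) tweets;
    irrelevant tweets are hard-negative confounders with probability
    ``confounder_frac``, otherwise keyword-free small talk.  Region codes
    are present on most tweets (the generator emulates the located,
    labeled subset of a stream, not the raw stream).
    """

    n_tweets: int = 1000
    prevalence: float = 0.67
    confounder_frac: float = 0.5
    foods: tuple[str, ...] = FOODS
    locations: tuple[str, ...] = LOCATIONS
    symptoms: tuple[str, ...] = SYMPTOMS
    keywords: tuple[str, ...] = KEYWORD_PHRASES
    start_date: date = date(2018, 1, 1)
    end_date: date = date(2018, 12, 31)
    p_region_us: float = 0.65
    p_region_other: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be in [0, 1]")
        if not (0.0 <= self.confounder_frac <= 1.0):
            raise ValueError("confounder_frac must be in [0, 1]")
        if self.end_date < self.start_date:
            raise ValueError("end_date precedes start_date")
        for name in ("foods", "locations", "symptoms", "keywords"):
            if not getattr(self, name):
                raise ValueError(f"vocabulary {name!r} must be non-empty")


@dataclass(frozen=True)
class WorkerProfile:
    """Reliability profile of one simulated worker.

    ``score_noise``: probability the 0-5 score deviates from the
    gold-consistent band; ``token_flip``: per-token probability of
    flipping the entity-type label to a random wrong one; the span-level
    knobs drop, retype, boundary-jitter, or add whole spans.  A spammer
    ignores gold entirely and labels uniformly at random.
    """

    score_noise: float = 0.1
    span_drop: float = 0.0
    span_add: float = 0.0
    boundary_jitter: float = 0.0
    type_confusion: float = 0.0
    token_flip: float = 0.0
    spammer: bool = False

    def __post_init__(self) -> None:
        for name in ("score_noise", "span_drop", "span_add", "boundary_jitter",
                     "type_confusion", "token_flip"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed % 2**31, zlib.crc32(name.encode()) % 2**31])


def _fill_template(template: str, rng: np.random.Generator,
                   vocab: dict[str, tuple[str, ...]],
                   forced: Optional[dict[str, str]] = None):
    """Instantiate a template; returns (text, spans at exact offsets)."""
    text_parts: list[str] = []
    spans: list[SpanAnnotation] = []
    pos = 0
    last = 0
    for m in _SLOT_RE.finditer(template):
        literal = template[last:m.start()]
        text_parts.append(literal)
        pos += len(literal)
        slot = m.group(1)
        if forced and slot in forced:
            filler = forced[slot]
        else:
            choices = vocab[slot]
            filler = choices[rng.integers(len(choices))]
        text_parts.append(filler)
        spans.append(SpanAnnotation(_SLOT_TYPE[slot], pos, pos + len(filler)))
        pos += len(filler)
        last = m.end()
    tail = template[last:]
    text_parts.append(tail)
    return "".join(text_parts), spans


def _make_example(i: int, kind: str, rng: np.random.Generator,
                  config: GeneratorConfig,
                  forced: Optional[dict[str, str]] = None,
                  day: Optional[date] = None,
                  id_prefix: str = "t") -> tuple[TweetRecord, GoldExample]:
    vocab = {
        "FOOD": config.foods, "LOC": config.locations,
        "SYM": config.symptoms, "KEY": config.keywords,
    }
    templates = {
        "relevant": _RELEVANT_TEMPLATES,
        "confounder": _CONFOUNDER_TEMPLATES,
        "smalltalk": _SMALLTALK_TEMPLATES,
    }[kind]
    template = templates[rng.integers(len(templates))]
    text, spans = _fill_template(template, rng, vocab, forced)

    if day is None:
        n_days = (config.end_date - config.start_date).days + 1
        day = config.start_date + timedelta(days=int(rng.integers(n_days)))
    created = datetime.combine(day, datetime.min.time(), tzinfo=timezone.utc) + timedelta(
        seconds=int(rng.integers(86400))
    )
    u = rng.random()
    if u < config.p_region_us:
        region: Optional[str] = US_REGIONS[rng.integers(len(US_REGIONS))]
    elif u < config.p_region_us + config.p_region_other:
        region = NON_US_REGIONS[rng.integers(len(NON_US_REGIONS))]
    else:
        region = None

    tweet_id = f"{id_prefix}{i:06d}"
    record = TweetRecord(tweet_id, text, created, region, False)
    tokens = tuple(word_tokenize(text))
    tags = tuple(spans_to_token_tags(spans, tokens))
    gold = GoldExample(tweet_id, text, YES if kind == "relevant" else NO, tokens, tags)
    return record, gold


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[TweetRecord], list[GoldExample]]:
    """Generate a corpus with planted gold labels at exact offsets."""
    rng = _substream(config.seed, "corpus")
    tweets, golds = [], []
    for i in range(config.n_tweets):
        if rng.random() < config.prevalence:
            kind = "relevant"
        elif rng.random() < config.confounder_frac:
            kind = "confounder"
        else:
            kind = "smalltalk"
        record, gold = _make_example(i, kind, rng, config)
        tweets.append(record)
        golds.append(gold)
    return tweets, golds


# ---------------------------------------------------------------------------
# worker simulation

_TYPE_LABELS = (O_TAG,) + ENTITY_TYPES


def _types_from_gold(gold: GoldExample) -> list[str]:
    return [tag_type(t) for t in gold.tags]


def _spans_from_types(types: Sequence[str], gold: GoldExample) -> tuple[SpanAnnotation, ...]:
    spans = []
    i, n = 0, len(types)
    while i < n:
        if types[i] == O_TAG:
            i += 1
            continue
        j = i
        while j + 1 < n and types[j + 1] == types[i]:
            j += 1
        spans.append(
            SpanAnnotation(types[i], gold.tokens[i].start, gold.tokens[j].end, True)
        )
        i = j + 1
    return tuple(spans)


def _corrupt_types(types: list[str], profile: WorkerProfile,
                   rng: np.random.Generator) -> list[str]:
    out = list(types)
    n = len(out)
    # span-level noise on the maximal runs of the gold labels
    i = 0
    runs = []
    while i < n:
        if out[i] == O_TAG:
            i += 1
            continue
        j = i
        while j + 1 < n and out[j + 1] == out[i]:
            j += 1
        runs.append((i, j))
        i = j + 1
    for start, end in runs:
        etype = out[start]
        if rng.random() < profile.span_drop:
            for t in range(start, end + 1):
                out[t] = O_TAG
            continue
        if rng.random() < profile.type_confusion:
            etype = ENTITY_TYPES[rng.integers(len(ENTITY_TYPES) - 1)]
            if etype == out[start]:
                etype = ENTITY_TYPES[-1]
            for t in range(start, end + 1):
                out[t] = etype
        if rng.random() < profile.boundary_jitter:
            if end > start and rng.random() < 0.5:
                out[end] = O_TAG  # shrink by one token
            elif end + 1 < n and out[end + 1] == O_TAG:
                out[end + 1] = etype  # extend by one token
    if profile.span_add > 0 and rng.random() < profile.span_add:
        o_positions = [t for t in range(n) if out[t] == O_TAG]
        if o_positions:
            t = o_positions[rng.integers(len(o_positions))]
            out[t] = ENTITY_TYPES[rng.integers(len(ENTITY_TYPES))]
    if profile.token_flip > 0:
        for t in range(n):
            if rng.random() < profile.token_flip:
                wrong = [lab for lab in _TYPE_LABELS if lab != out[t]]
                out[t] = wrong[rng.integers(len(wrong))]
    return out


def simulate_workers(
    golds: Sequence[GoldExample],
    profiles: Sequence[WorkerProfile],
    seed: int = 0,
) -> list[WorkerAnnotation]:
    """Simulate one annotation per (worker, tweet) by corrupting gold.

    Honest workers draw a score uniformly from the gold-consistent band
    (Yes -> 3-5, No -> 0-2), deviating by +/-1..2 with probability
    ``score_noise``, and corrupt the gold token labels per their profile.
    Spammers score and label uniformly at random.  Reproducible by seed.
    """
    if not profiles:
        raise ValueError("need at least one worker profile")
    out: list[WorkerAnnotation] = []
    for w, profile in enumerate(profiles):
        rng = _substream(seed, f"worker-{w}")
        worker_id = f"w{w}"
        for gold in golds:
            if profile.spammer:
                score = int(rng.integers(6))
                types = [
                    _TYPE_LABELS[rng.integers(len(_TYPE_LABELS))]
                    for _ in gold.tokens
                ]
            else:
                band = (3, 4, 5) if gold.relevance == YES else (0, 1, 2)
                score = int(band[rng.integers(3)])
                if rng.random() < profile.score_noise:
                    score = int(np.clip(score + rng.choice([-2, -1, 1, 2]), 0, 5))
                types = _corrupt_types(_types_from_gold(gold), profile, rng)
            out.append(
                WorkerAnnotation(
                    worker_id, gold.tweet_id, score, _spans_from_types(types, gold)
                )
            )
    return out


# ---------------------------------------------------------------------------
# outbreak injection


def inject_outbreak(
    tweets: Sequence[TweetRecord],
    golds: Sequence[GoldExample],
    food_term: str,
    window: tuple[date, date],
    multiplier: float,
    seed: int = 0,
    config: Optional[GeneratorConfig] = None,
) -> tuple[list[TweetRecord], list[GoldExample], tuple[date, date]]:
    """Plant an outbreak: extra relevant tweets naming ``food_term`` inside
    ``window``, scaled to ``multiplier`` times the corpus baseline rate.

    The number of injected tweets is (multiplier - 1) x (baseline daily
    rate of relevant tweets mentioning the term) x (window length), with
    the baseline floored at one mention over the corpus span so a spike
    can be planted even for an otherwise unseen food.  Returns the
    augmented corpus and the planted window for assertion.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    w_start, w_end = window
    if w_end < w_start:
        raise ValueError("empty outbreak window")
    dates = [t.created_at.date() for t in tweets if t.created_at is not None]
    if not dates:
        raise ValueError("corpus has no dated tweets")
    lo, hi = min(dates), max(dates)
    if w_start < lo or w_end > hi:
        raise ValueError(f"window {window} outside corpus date range [{lo}, {hi}]")

    term = normalize_surface(food_term)
    n_baseline = 0
    for g in golds:
        if g.relevance != YES:
            continue
        for e in decode_entities(g.tags, g.tokens):
            if e.entity_type == "FOOD" and term in normalize_surface(e.surface):
                n_baseline += 1
                break
    total_days = (hi - lo).days + 1
    window_days = (w_end - w_start).days + 1
    base_daily = max(n_baseline, 1) / total_days
    n_add = int(round((multiplier - 1) * base_daily * window_days))

    cfg = config or GeneratorConfig(seed=seed)
    rng = _substream(seed, "outbreak")
    new_tweets, new_golds = list(tweets), list(golds)
    templates_with_food = [t for t in _RELEVANT_TEMPLATES if "{FOOD}" in t]
    for i in range(n_add):
        day = w_start + timedelta(days=int(rng.integers(window_days)))
        template = templates_with_food[rng.integers(len(templates_with_food))]
        vocab = {"FOOD": cfg.foods, "LOC": cfg.locations,
                 "SYM": cfg.symptoms, "KEY": cfg.keywords}
        text, spans = _fill_template(template, rng, vocab, forced={"FOOD": food_term})
        created = datetime.combine(
            day, datetime.min.time(), tzinfo=timezone.utc
        ) + timedelta(seconds=int(rng.integers(86400)))
        tweet_id = f"spike{i:05d}"
        region = US_REGIONS[rng.integers(len(US_REGIONS))]
        new_tweets.append(TweetRecord(tweet_id, text, created, region, False))
        tokens = tuple(word_tokenize(text))
        new_golds.append(
            GoldExample(tweet_id, text, YES, tokens,
                        tuple(spans_to_token_tags(spans, tokens)))
        )
    return new_tweets, new_golds, window
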