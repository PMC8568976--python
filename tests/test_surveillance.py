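import itertools
from datetime import date

import pytest

from foodsignal.labels import TAG_SET
from foodsignal.surveillance import (
    Entity,
    IncidentRecord,
    daily_series,
    decode_entities,
    food_term_filter,
    incident_filter,
    normalize_surface,
    region_filter,
    top_food_entities,
)


def decode_oracle(tags, words):
    """Brute-force run scanner: repair stray I-X, then collect maximal
    B-started runs."""
    repaired = []
    prev = None
    for t in tags:
        if t == "O":
            repaired.append(("O", None))
            prev = None
            continue
        p, ty = t.split("-")
        if p == "I" and ty != prev:
            p = "B"
        repaired.append((p, ty))
        prev = ty
    ents, i = [], 0
    while i < len(repaired):
        p, ty = repaired[i]
        if ty is None:
            i += 1
            continue
        j = i + 1
        while j < len(repaired) and repaired[j] == ("I", ty):
            j += 1
        ents.append((ty, i, j, " ".join(words[i:j])))
        i = j
    return ents


def rec(relevant=True, entities=(), day=None, region=None, tid="t"):
    return IncidentRecord(tid, day, region, relevant, tuple(entities))


def food(surface, start=0, end=None):
    end = end if end is not None else start + len(surface.split())
    return Entity("FOOD", start, end, surface)


class TestDecodeEntities:
    def test_all_o_empty(self):
        assert decode_entities(["O"] * 4, list("abcd")) == []

    def test_stray_i_repaired_and_merged(self):
        ents = decode_entities(["I-FOOD", "I-FOOD"], ["grilled", "cheese"])
        assert len(ents) == 1
        assert (ents[0].start, ents[0].end, ents[0].surface) == (0, 2, "grilled cheese")

    def test_b_starts_new_entity_adjacent_to_same_type(self):
        ents = decode_entities(["B-FOOD", "B-FOOD"], ["salad", "taco"])
        assert [(e.start, e.end) for e in ents] == [(0, 1), (1, 2)]

    def test_other_alias_maps_to_key(self):
        ents = decode_entities(["B-other", "I-other"], ["food", "poisoning"])
        assert ents[0].entity_type == "KEY" and ents[0].surface == "food poisoning"

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            decode_entities(["O"], ["a", "b"])

    def test_matches_oracle_exhaustively_length_4(self):
        words = ["w0", "w1", "w2", "w3"]
        for tags in itertools.product(TAG_SET, repeat=4):
            mine = [
                (e.entity_type, e.start, e.end, e.surface)
                for e in decode_entities(list(tags), words)
            ]
            assert mine == decode_oracle(list(tags), words), tags


class TestIncidentFilter:
    def test_yes_with_food_included(self):
        assert incident_filter(rec(True, [food("grilled cheese")]))

    def test_yes_without_food_excluded(self):
        assert not incident_filter(rec(True, [Entity("KEY", 0, 2, "food poisoning")]))

    def test_no_with_food_excluded(self):
        assert not incident_filter(rec(False, [food("salad")]))


class TestDailySeries:
    def test_counts_single_day(self):
        records = [rec(entities=[food("salad")], day=date(2018, 3, 1), tid=str(i)) for i in range(3)]
        assert daily_series(records) == {date(2018, 3, 1): 3}

    def test_empty_input(self):
        assert daily_series([]) == {}

    def test_gap_day_emitted_with_zero(self):
        records = [
            rec(entities=[food("salad")], day=date(2018, 3, 1), tid="a"),
            rec(entities=[food("salad")], day=date(2018, 3, 3), tid="b"),
        ]
        series = daily_series(records)
        assert series[date(2018, 3, 2)] == 0
        assert list(series) == sorted(series)

    def test_conservation(self):
        records = [
            rec(relevant=i % 2 == 0, entities=[food("salad")] if i % 3 else [],
                day=date(2018, 1, 1 + i % 5), tid=str(i))
            for i in range(40)
        ]
        passing = [r for r in records if incident_filter(r)]
        assert sum(daily_series(records).values()) == len(passing)


class TestTopFoods:
    def test_normalization_merges_variants(self):
        records = [
            rec(entities=[food("Lettuce")], tid="a", day=date(2018, 1, 1)),
            rec(entities=[food("lettuce,")], tid="b", day=date(2018, 1, 1)),
        ]
        assert top_food_entities(records, 5) == [("lettuce", 2)]

    def test_k_larger_than_distinct(self):
        records = [rec(entities=[food("salad")], tid="a")]
        assert top_food_entities(records, 20) == [("salad", 1)]

    def test_empty_records(self):
        assert top_food_entities([], 3) == []

    def test_tweet_counted_once_per_surface(self):
        records = [rec(entities=[food("salad", 0), food("salad", 5)], tid="a")]
        assert top_food_entities(records, 5) == [("salad", 1)]

    def test_normalize_surface_rules(self):
        assert normalize_surface("  Romaine   Lettuce, ") == "romaine lettuce"


class TestFoodTermFilter:
    def test_whole_word_containment_kept(self):
        r = rec(entities=[food("romaine lettuce")])
        assert food_term_filter([r], {"lettuce"}) == [r]

    def test_no_term_dropped(self):
        r = rec(entities=[food("grilled cheese")])
        assert food_term_filter([r], {"lettuce", "salad", "sandwich"}) == []

    def test_whole_word_boundary(self):
        r = rec(entities=[food("lettuces")])
        assert food_term_filter([r], {"lettuce"}) == []
        assert food_term_filter([r], {"lettuce"}, whole_word=False) == [r]

    def test_monotone_in_term_set(self):
        records = [
            rec(entities=[food("romaine lettuce")], tid="a"),
            rec(entities=[food("chicken sandwich")], tid="b"),
            rec(entities=[food("taco")], tid="c"),
        ]
        only_a = food_term_filter(records, {"lettuce"})
        both = food_term_filter(records, {"lettuce", "sandwich"})
        assert set(r.tweet_id for r in only_a) <= set(r.tweet_id for r in both)

    def test_empty_terms_error(self):
        with pytest.raises(ValueError):
            food_term_filter([], set())


class TestRegionFilter:
    def test_us_subdivision_kept(self):
        r = rec(region="US-IL")
        assert region_filter([r], "US") == [r]

    def test_missing_region_excluded(self):
        assert region_filter([rec(region=None)], "US") == []

    def test_other_country_excluded(self):
        assert region_filter([rec(region="CA")], "US") == []

    def test_callable_predicate(self):
        r = rec(region="US-IL")
        assert region_filter([r], lambda code: code.endswith("IL")) == [r]
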