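"""Entity types and BIO/IOB2 tag handling shared across the pipeline.

Four entity types are annotated: FOOD (food item), LOC (location), SYM
(symptom), KEY (foodborne-illness keyword phrase such as "food poisoning").
Token tags follow IOB2: ``B-X`` begins an entity of type X, ``I-X``
continues it, ``O`` is outside any entity.
"""

from __future__ import annotations

from typing import Iterable, Sequence

ENTITY_TYPES: tuple[str, ...] = ("FOOD", "LOC", "SYM", "KEY")

O_TAG = "O"

#: All 9 token classes of the tagger, in a fixed order (O first).
TAG_SET: tuple[str, ...] = (O_TAG,) + tuple(
    f"{p}-{t}" for t in ENTITY_TYPES for p in ("B", "I")
)

# Aliases seen in the wild ("B-other" for a keyword entity, lowercase forms).
_TYPE_ALIASES = {
    "FOOD": "FOOD",
    "LOC": "LOC",
    "LOCATION": "LOC",
    "SYM": "SYM",
    "SYMPTOM": "SYM",
    "KEY": "KEY",
    "KEYWORD": "KEY",
    "OTHER": "KEY",
}


def normalize_entity_type(name: str) -> str:
    """Map an entity-type spelling (case-insensitive, aliases allowed) to
    the canonical type name."""
    try:
        return _TYPE_ALIASES[name.strip().upper()]
    except KeyError:
        raise ValueError(f"unknown entity type: {name!r}") from None


def split_tag(tag: str) -> tuple[str, str | None]:
    """Split a BIO tag into (prefix, canonical type); ``O`` -> ("O", None)."""
    if tag == O_TAG or tag.upper() == "O":
        return O_TAG, None
    if len(tag) < 3 or tag[1] != "-" or tag[0].upper() not in ("B", "I"):
        raise ValueError(f"malformed BIO tag: {tag!r}")
    return tag[0].upper(), normalize_entity_type(tag[2:])


def tag_type(tag: str) -> str:
    """The entity-type-or-O carried by a tag (prefix stripped)."""
    _, etype = split_tag(tag)
    return etype if etype is not None else O_TAG


def repair_iob2(tags: Sequence[str]) -> list[str]:
    """Return a valid IOB2 sequence: a stray ``I-X`` (sequence start, or
    preceded by ``O`` or a different type) becomes ``B-X``."""
    out: list[str] = []
    prev_type: str | None = None
    for tag in tags:
        prefix, etype = split_tag(tag)
        if prefix == O_TAG:
            out.append(O_TAG)
        elif prefix == "I" and etype != prev_type:
            out.append(f"B-{etype}")
        else:
            out.append(f"{prefix}-{etype}")
        prev_type = etype
    return out


def types_to_iob2(types: Iterable[str]) -> list[str]:
    """Rebuild IOB2 tags from per-token entity-type-or-O labels: the first
    token of each maximal same-type run gets B, the rest I."""
    out: list[str] = []
    prev: str | None = None
    for t in types:
        if t == O_TAG:
            out.append(O_TAG)
        elif t == prev:
            out.append(f"I-{t}")
        else:
            out.append(f"B-{t}")
        prev = t if t != O_TAG else None
    return out


def is_valid_iob2(tags: Sequence[str]) -> bool:
    """True if no I-X is preceded by neither B-X nor I-X."""
    prev_type: str | None = None
    for tag in tags:
        prefix, etype = split_tag(tag)
        if prefix == "I" and etype != prev_type:
            return False
        prev_type = etype
    return True
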