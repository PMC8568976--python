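"""Word tokenization with character offsets.

Every stage of the pipeline (crowd agreement, gold aggregation, the token
classifier, entity decoding) needs one consistent notion of a "word token"
anchored to character offsets in the preprocessed tweet text, so span
annotations made on characters can be projected onto token labels and back.
"""

from __future__ import annotations

import re
from typing import NamedTuple

# A word is a run of word characters, optionally prefixed by '#' or '@'
# (hashtags/mentions stay single tokens) and allowing internal apostrophes
# ("I've" is one token); any other non-space character is its own token.
_WORD_RE = re.compile(r"[#@]?\w+(?:'\w+)*|[^\w\s]")


class Token(NamedTuple):
    """One word token: surface text plus half-open character offsets."""

    text: str
    start: int
    end: int


def word_tokenize(text: str) -> list[Token]:
    """Split ``text`` into word tokens with recorded character offsets.

    Offsets are 0-based half-open into ``text`` itself, so
    ``text[t.start:t.end] == t.text`` for every token.
    """
    return [Token(m.group(0), m.start(), m.end()) for m in _WORD_RE.finditer(text)]


def token_overlaps(token: Token, start: int, end: int) -> bool:
    """True if the token's character range intersects [start, end)."""
    return token.start < end and token.end > start
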