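"""Shared text primitives: tokenization, phrase matching, sentence splitting, language ID.

Every module that inspects text goes through these helpers so that keyword
rules, country-mention counting, hashing encoders and ROUGE all agree on what
a "token" is: a lowercased maximal run of alphanumerics (internal apostrophes
kept, so "don't" is one token).
"""

from __future__ import annotations

import re
from typing import Callable, Sequence

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)*")

TokenList = list[str]


def tokenize(text: str) -> TokenList:
    """Lowercase alphanumeric tokens of *text*, in order."""
    return _TOKEN_RE.findall(text.lower())


def contains_phrase(tokens: Sequence[str], phrase_tokens: Sequence[str]) -> bool:
    """True if *phrase_tokens* occurs as a contiguous subsequence of *tokens*."""
    return first_phrase_position(tokens, phrase_tokens) is not None


def first_phrase_position(tokens: Sequence[str], phrase_tokens: Sequence[str]) -> int | None:
    """Index of the first contiguous occurrence of *phrase_tokens*, or None."""
    m = len(phrase_tokens)
    if m == 0:
        return None
    phrase = list(phrase_tokens)
    for i in range(len(tokens) - m + 1):
        if list(tokens[i : i + m]) == phrase:
            return i
    return None


def count_phrase_occurrences(tokens: Sequence[str], phrase_tokens: Sequence[str]) -> int:
    """Number of non-overlapping occurrences of the phrase in *tokens*."""
    m = len(phrase_tokens)
    if m == 0:
        return 0
    phrase = list(phrase_tokens)
    count = 0
    i = 0
    n = len(tokens)
    while i <= n - m:
        if list(tokens[i : i + m]) == phrase:
            count += 1
            i += m
        else:
            i += 1
    return count


# ---------------------------------------------------------------------------
# Sentence splitting

#: Tokens (lowercased, dots stripped during scan) that a period does not end a
#: sentence after.  Deliberately short: single capital initials like "A." are
#: treated as real sentence ends.
ABBREVIATIONS = frozenset(
    {
        "dr", "mr", "mrs", "ms", "prof", "gen", "rep", "sen", "st", "jr", "sr",
        "vs", "etc", "inc", "ltd", "co", "corp", "dept", "est", "approx",
        "e.g", "i.e", "u.s", "u.k", "u.n",
        "jan", "feb", "mar", "apr", "jun", "jul", "aug", "sep", "sept", "oct",
        "nov", "dec",
    }
)

_TERMINALS = ".!?"

SentenceSplitter = Callable[[str], list[tuple[int, int]]]


def default_sentence_splitter(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence boundary detection returning character spans.

    A sentence ends at a run of ``.!?`` that is followed by whitespace (or end
    of text), unless the run is a single period attached to a known
    abbreviation.  Spans are 0-based half-open, trimmed of surrounding
    whitespace, non-overlapping and strictly increasing.
    """
    spans: list[tuple[int, int]] = []
    n = len(text)
    start = 0
    i = 0
    while i < n:
        if text[i] in _TERMINALS:
            j = i
            while j + 1 < n and text[j + 1] in _TERMINALS:
                j += 1
            # the word immediately before the terminal run (may contain dots)
            k = i - 1
            while k >= start and (text[k].isalnum() or text[k] == "."):
                k -= 1
            word = text[k + 1 : i].lower()
            is_abbrev = text[i] == "." and j == i and word in ABBREVIATIONS
            next_pos = j + 1
            if not is_abbrev and (next_pos >= n or text[next_pos].isspace()):
                span = _trimmed(text, start, j + 1)
                if span is not None:
                    spans.append(span)
                i = next_pos
                while i < n and text[i].isspace():
                    i += 1
                start = i
                continue
            i = j + 1
        else:
            i += 1
    span = _trimmed(text, start, n)
    if span is not None:
        spans.append(span)
    return spans


def _trimmed(text: str, start: int, end: int) -> tuple[int, int] | None:
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    if start >= end:
        return None
    return (start, end)


# ---------------------------------------------------------------------------
# Language identification

#: Function-word profiles.  Detection scores a text by stopword hits per
#: language and returns the argmax; texts with no hits are "unknown".
_LANGUAGE_PROFILES: dict[str, frozenset[str]] = {
    "en": frozenset(
        "the and of to in a is that for with was on as are be at by this have "
        "from or an it not were has had their they which but all one more no "
        "about new after also its same other been when who will".split()
    ),
    "fr": frozenset(
        "le la les de des du et un une est pour dans que qui au aux avec sur "
        "pas sont ont été cette ces mais plus leur".split()
    ),
    "es": frozenset(
        "el la los las de del y un una es para en que se con por no son como "
        "más pero sus fue este esta".split()
    ),
    "de": frozenset(
        "der die das und von zu den im ein eine ist für mit auf nicht sind "
        "dem des als auch wurde bei nach".split()
    ),
}

LanguageDetector = Callable[[str], str]


def detect_language(text: str) -> str:
    """Stopword-profile language guess over {en, fr, es, de}; "unknown" if no hits.

    Deterministic: ties resolve to the alphabetically first language code.
    """
    tokens = tokenize(text)
    if not tokens:
        return "unknown"
    best_lang = "unknown"
    best_score = 0
    for lang in sorted(_LANGUAGE_PROFILES):
        score = sum(1 for t in tokens if t in _LANGUAGE_PROFILES[lang])
        if score > best_score:
            best_score = score
            best_lang = lang
    return best_lang
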