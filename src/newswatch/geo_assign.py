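"""Single-country assignment for multiply-tagged articles.

Aggregated news feeds tag an article with every country their upstream
matchers saw (about two per article on average); pooling articles per country
requires exactly one.  The resolution cascade:

1. **Mention frequency** — if any candidate country's surface name occurs in
   the title or the first body sentence, take the most frequently mentioned
   one (ties: earliest first occurrence in title-then-first-sentence order).
2. **Embedding similarity** — otherwise collect location/person-like entity
   strings from the body (pluggable NER), encode their concatenation, and take
   the candidate whose encoded canonical name has maximal cosine similarity
   (ties: lexicographically smallest code).
3. **Unresolved** — no entities at all: keep the first candidate tag, flagged.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import Article, SentenceIndex
from .text import count_phrase_occurrences, first_phrase_position, tokenize

NamedEntityExtractor = Callable[[str], list[str]]


class GazetteerError(ValueError):
    pass


@dataclass(frozen=True)
class CountryGazetteer:
    """Canonical country code -> surface names; each surface name maps to one code."""

    names: Mapping[str, tuple[str, ...]]  # code -> (canonical name, aliases...)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for code, surfaces in self.names.items():
            if not surfaces:
                raise GazetteerError(f"country {code}: no surface names")
            for surface in surfaces:
                key = surface.casefold()
                if seen.get(key, code) != code:
                    raise GazetteerError(
                        f"surface name {surface!r} maps to both {seen[key]} and {code}"
                    )
                seen[key] = code

    def canonical_name(self, code: str) -> str:
        return self.names[code][0]

    def surfaces(self, code: str) -> tuple[str, ...]:
        return self.names[code]

    @classmethod
    def from_csv(cls, path: str | Path) -> "CountryGazetteer":
        names: dict[str, tuple[str, ...]] = {}
        with Path(path).open(encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                aliases = tuple(a for a in (row.get("aliases") or "").split("|") if a)
                names[row["code"]] = (row["name"], *aliases)
        return cls(names)

    @classmethod
    def default(cls) -> "CountryGazetteer":
        from importlib.resources import files

        with files("newswatch.data").joinpath("gazetteer.csv").open(encoding="utf-8") as fh:
            names: dict[str, tuple[str, ...]] = {}
            for row in csv.DictReader(fh):
                aliases = tuple(a for a in (row.get("aliases") or "").split("|") if a)
                names[row["code"]] = (row["name"], *aliases)
        return cls(names)


@dataclass(frozen=True)
class CountryAssignment:
    article_id: str
    country: str
    method: str  # mention_frequency | embedding_similarity | unresolved
    score: float


def extract_country_mentions(
    text: str,
    gazetteer: CountryGazetteer,
    candidates: Iterable[str],
) -> dict[str, int]:
    """Occurrence counts of each candidate country's surface names in *text*.

    Token-boundary, case-insensitive; every candidate appears in the result,
    absent countries with count 0.
    """
    candidates = list(candidates)
    if not candidates:
        raise GazetteerError("candidate set must be nonempty")
    tokens = tokenize(text)
    counts: dict[str, int] = {}
    for code in candidates:
        total = 0
        for surface in gazetteer.surfaces(code):
            total += count_phrase_occurrences(tokens, tokenize(surface))
        counts[code] = total
    return counts


def _first_mention_position(tokens: Sequence[str], gazetteer: CountryGazetteer, code: str) -> int:
    positions = [
        pos
        for surface in gazetteer.surfaces(code)
        if (pos := first_phrase_position(tokens, tokenize(surface))) is not None
    ]
    return min(positions) if positions else len(tokens) + 1


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Standard cosine similarity in [-1, 1]; zero vectors are an error."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector (degenerate embedding)")
    return float(np.dot(u, v) / (nu * nv))


_CAP_RUN_RE = re.compile(r"\b[A-Z][\w'.-]*(?:\s+[A-Z][\w'.-]*)*")


def capitalized_run_entity_extractor(text: str) -> list[str]:
    """Heuristic entity extractor: maximal runs of capitalized words, document order.

    A pluggable stand-in for a trained named-entity recognizer; deployments can
    inject any ``text -> list[str]`` callable that returns location/person
    strings in document order.
    """
    entities = []
    for match in _CAP_RUN_RE.finditer(text):
        span_start = match.start()
        # skip sentence-initial single words: crude guard against ordinary
        # sentence capitalization masquerading as a name
        preceding = text[:span_start].rstrip()
        sentence_initial = not preceding or preceding[-1] in ".!?"
        phrase = match.group()
        if sentence_initial and " " not in phrase:
            continue
        entities.append(phrase)
    return entities


def assign_country(
    article: Article,
    sentences: SentenceIndex,
    gazetteer: CountryGazetteer | None = None,
    encoder=None,
    ner: NamedEntityExtractor = capitalized_run_entity_extractor,
) -> CountryAssignment:
    """Resolve the article's candidate tags to a single country (see module doc)."""
    if not article.country_tags:
        raise GazetteerError(f"article {article.article_id}: empty candidate country set")
    if gazetteer is None:
        gazetteer = CountryGazetteer.default()
    candidates = sorted(set(article.country_tags))

    first_sentence = ""
    if len(sentences) > 0:
        s, e = sentences.spans[0]
        first_sentence = article.body[s:e]
    zone = article.title + " " + first_sentence
    counts = extract_country_mentions(zone, gazetteer, candidates)
    if max(counts.values()) > 0:
        zone_tokens = tokenize(zone)
        best = min(
            (code for code in candidates if counts[code] > 0),
            key=lambda c: (-counts[c], _first_mention_position(zone_tokens, gazetteer, c), c),
        )
        return CountryAssignment(article.article_id, best, "mention_frequency", float(counts[best]))

    if encoder is None:
        from .encoders import HashingTextEncoder

        encoder = HashingTextEncoder()
    entities = ner(article.body)
    if not entities:
        return CountryAssignment(article.article_id, article.country_tags[0], "unresolved", 0.0)
    doc_vec = encoder.encode(" ".join(entities))
    if not np.any(doc_vec):
        return CountryAssignment(article.article_id, article.country_tags[0], "unresolved", 0.0)
    best_code = None
    best_sim = -np.inf
    for code in candidates:  # sorted: ties keep lexicographically smallest
        name_vec = encoder.encode(gazetteer.canonical_name(code))
        if not np.any(name_vec):
            continue
        sim = cosine_similarity(doc_vec, name_vec)
        if sim > best_sim:
            best_sim = sim
            best_code = code
    if best_code is None:
        return CountryAssignment(article.article_id, article.country_tags[0], "unresolved", 0.0)
    return CountryAssignment(article.article_id, best_code, "embedding_similarity", float(best_sim))
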