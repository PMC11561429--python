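"""Corpus containers and I/O: read, validate, deduplicate, language-filter, segment.

A corpus is an ordered collection of :class:`Article` records with unique ids.
The on-disk formats are JSONL (one article per line, UTF-8) and CSV with the
same columns (``country_tags`` pipe-delimited).  Deduplication is by
normalized title — the earliest-dated article in each title group survives,
first-seen breaking ties — because syndicated news wires republish the same
story under identical headlines across many outlets.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from .text import (
    LanguageDetector,
    SentenceSplitter,
    default_sentence_splitter,
    detect_language,
)

logger = logging.getLogger(__name__)

_FIELDS = ("article_id", "title", "body", "source", "published_at", "country_tags", "language")


class CorpusValidationError(ValueError):
    """A record failed validation; message names the record number and field."""


@dataclass(frozen=True)
class Article:
    """One news item."""

    article_id: str
    title: str
    body: str = ""
    source: str = ""
    published_at: _dt.date | None = None
    country_tags: tuple[str, ...] = ()
    language: str = "unknown"

    def __post_init__(self) -> None:
        if not self.article_id:
            raise CorpusValidationError("article_id must be nonempty")
        if not self.title.strip():
            raise CorpusValidationError(f"article {self.article_id!r}: title must be nonempty")


@dataclass(frozen=True)
class SentenceIndex:
    """Ordered character spans (0-based, half-open) of the sentences of one body."""

    article_id: str
    spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.spans:
            if not (0 <= start < end):
                raise ValueError(f"empty or negative span ({start}, {end})")
            if start < prev_end:
                raise ValueError("spans must be non-overlapping and strictly increasing")
            prev_end = end

    def __len__(self) -> int:
        return len(self.spans)

    def sentence_texts(self, body: str) -> list[str]:
        return [body[s:e] for s, e in self.spans]


@dataclass
class Corpus:
    """Ordered article collection with provenance metadata."""

    articles: list[Article] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a.article_id for a in self.articles]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusValidationError(f"duplicate article ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.articles)

    def __iter__(self) -> Iterator[Article]:
        return iter(self.articles)

    def __getitem__(self, i: int) -> Article:
        return self.articles[i]

    def ids(self) -> list[str]:
        return [a.article_id for a in self.articles]

    def by_id(self, article_id: str) -> Article:
        for a in self.articles:
            if a.article_id == article_id:
                return a
        raise KeyError(article_id)


# ---------------------------------------------------------------------------
# Reading / writing


def _article_from_record(record: dict, where: str) -> Article:
    for req in ("article_id", "title"):
        if req not in record or record[req] in (None, ""):
            raise CorpusValidationError(f"{where}: missing or empty field {req!r}")
    raw_date = record.get("published_at") or None
    date: _dt.date | None = None
    if raw_date:
        try:
            date = _dt.date.fromisoformat(str(raw_date))
        except ValueError as exc:
            raise CorpusValidationError(f"{where}: field 'published_at': {exc}") from exc
    tags = record.get("country_tags") or ()
    if isinstance(tags, str):
        tags = tuple(t for t in tags.split("|") if t)
    try:
        return Article(
            article_id=str(record["article_id"]),
            title=str(record["title"]),
            body=str(record.get("body", "") or ""),
            source=str(record.get("source", "") or ""),
            published_at=date,
            country_tags=tuple(tags),
            language=str(record.get("language", "unknown") or "unknown"),
        )
    except CorpusValidationError as exc:
        raise CorpusValidationError(f"{where}: {exc}") from exc


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from JSONL or CSV; *format* inferred from suffix when None.

    Malformed records raise :class:`CorpusValidationError` naming the record
    number and offending field.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unsupported format {format!r}")
    articles: list[Article] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusValidationError(f"line {lineno}: invalid JSON: {exc}") from exc
                articles.append(_article_from_record(record, f"line {lineno}"))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            for rowno, record in enumerate(csv.DictReader(fh), start=2):
                articles.append(_article_from_record(record, f"line {rowno}"))
    return Corpus(articles, provenance={"source_path": str(path), "format": format})


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write *corpus* to JSONL or CSV; round-trips through :func:`read_corpus`."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    rows = [
        {
            "article_id": a.article_id,
            "title": a.title,
            "body": a.body,
            "source": a.source,
            "published_at": a.published_at.isoformat() if a.published_at else "",
            "country_tags": list(a.country_tags),
            "language": a.language,
        }
        for a in corpus
    ]
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(_FIELDS))
            writer.writeheader()
            for row in rows:
                row["country_tags"] = "|".join(row["country_tags"])
                writer.writerow(row)
    else:
        raise ValueError(f"unsupported format {format!r}")


# ---------------------------------------------------------------------------
# Filters


def _normalize_title(title: str, normalization: str) -> str:
    if normalization == "exact":
        return title
    if normalization == "casefold_trim":
        return " ".join(title.casefold().split())
    raise ValueError(f"unknown normalization {normalization!r}")


def deduplicate_by_title(corpus: Corpus, normalization: str = "casefold_trim") -> Corpus:
    """Keep one article per normalized title: earliest ``published_at``, then first-seen.

    Articles without a date sort after any dated article.  Output preserves the
    original corpus order of the surviving articles.
    """
    best: dict[str, tuple[tuple, int]] = {}
    for pos, article in enumerate(corpus):
        key = _normalize_title(article.title, normalization)
        date = article.published_at
        rank = ((0, date.toordinal()) if date is not None else (1, 0), pos)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, pos)
    keep_positions = sorted(pos for _, pos in best.values())
    survivors = [corpus[pos] for pos in keep_positions]
    removed = len(corpus) - len(survivors)
    logger.info("deduplicate_by_title: removed %d of %d articles", removed, len(corpus))
    provenance = dict(corpus.provenance)
    provenance.setdefault("filters", []).append(
        {"filter": "deduplicate_by_title", "normalization": normalization, "removed": removed}
    )
    return Corpus(survivors, provenance)


def filter_language(
    corpus: Corpus,
    detector: LanguageDetector = detect_language,
    keep: str = "en",
) -> Corpus:
    """Keep articles whose detected language (title + body) equals *keep*.

    A detector failure flags the article "unknown" and drops it with a warning.
    """
    survivors: list[Article] = []
    for article in corpus:
        try:
            lang = detector(article.title + " " + article.body)
        except Exception:  # noqa: BLE001 - pluggable detector; degrade, don't die
            logger.warning("language detector failed on %s; dropping", article.article_id)
            lang = "unknown"
        if lang == keep:
            survivors.append(replace(article, language=lang))
    fraction = len(survivors) / len(corpus) if len(corpus) else 1.0
    logger.info("filter_language: retained %.1f%% of %d articles", 100 * fraction, len(corpus))
    provenance = dict(corpus.provenance)
    provenance.setdefault("filters", []).append(
        {"filter": "filter_language", "keep": keep, "retained_fraction": fraction}
    )
    return Corpus(survivors, provenance)


def segment_sentences(
    article: Article,
    splitter: SentenceSplitter = default_sentence_splitter,
) -> SentenceIndex:
    """Sentence spans of the article body; empty body gives an empty index."""
    if not article.body.strip():
        return SentenceIndex(article.article_id, ())
    return SentenceIndex(article.article_id, tuple(splitter(article.body)))


def segment_corpus(
    corpus: Corpus | Iterable[Article],
    splitter: SentenceSplitter = default_sentence_splitter,
) -> dict[str, SentenceIndex]:
    return {a.article_id: segment_sentences(a, splitter) for a in corpus}
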