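"""Shared fixtures and independent brute-force oracles used across the suite."""

from __future__ import annotations

import re

import numpy as np
import pytest

from newswatch.corpus_io import Article, Corpus
from newswatch.rules_engine import And, KeywordList, Match, Not, Or, default_rulesets
from newswatch.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def rulesets():
    return default_rulesets()


@pytest.fixture
def tiny_corpus() -> Corpus:
    import datetime as dt

    return Corpus(
        [
            Article("a1", "Kenya doctors end strike", "The strike began. Nurses met in Nairobi.",
                    source="s1", published_at=dt.date(2020, 3, 1), country_tags=("KE", "UG")),
            Article("a2", "Budget meeting update", "The council met. Funding was approved.",
                    source="s2", published_at=dt.date(2020, 4, 2), country_tags=("FR",)),
            Article("a3", "Budget Meeting Update", "Different body, same headline.",
                    source="s3", published_at=dt.date(2020, 4, 1), country_tags=("FR",)),
        ]
    )


@pytest.fixture(scope="session")
def synthetic_bundle():
    """A mid-size seeded corpus shared by read-only tests."""
    config = GeneratorConfig(n_articles=500, prevalence=0.02, seed=42)
    corpus, gt = generate_corpus(config)
    return config, corpus, gt


# ---------------------------------------------------------------------------
# Independent brute-force rule evaluator (regex-based, no shared code paths
# with newswatch.rules_engine beyond the predicate dataclasses themselves).


def _bf_normalize(text: str) -> str:
    return " " + re.sub(r"[^a-z0-9']+", " ", text.lower()) + " "


def _bf_phrase_present(text: str, phrase: str) -> bool:
    normalized_phrase = re.sub(r"[^a-z0-9']+", " ", phrase.lower()).strip()
    return f" {normalized_phrase} " in _bf_normalize(text)


def _bf_distinct(text: str, keywords: KeywordList) -> int:
    return sum(1 for k in keywords.keywords if _bf_phrase_present(text, k))


def brute_force_evaluate(predicate, article, sentence_texts):
    """Reference predicate evaluation: returns (truth, matched sentence indices)."""
    if isinstance(predicate, Match):
        if predicate.scope == "TITLE":
            return _bf_distinct(article.title, predicate.keywords) >= predicate.min_distinct, frozenset()
        if predicate.scope == "BODY":
            return _bf_distinct(article.body, predicate.keywords) >= predicate.min_distinct, frozenset()
        matched = frozenset(
            i
            for i, s in enumerate(sentence_texts)
            if _bf_distinct(s, predicate.keywords) >= predicate.min_distinct
        )
        return len(matched) > 0, matched
    if isinstance(predicate, Not):
        truth, _ = brute_force_evaluate(predicate.child, article, sentence_texts)
        return not truth, frozenset()
    results = [brute_force_evaluate(c, article, sentence_texts) for c in predicate.children]
    if isinstance(predicate, And):
        truth = all(t for t, _ in results)
        return truth, frozenset().union(*(m for _, m in results)) if truth else frozenset()
    if isinstance(predicate, Or):
        truth = any(t for t, _ in results)
        return truth, frozenset().union(*(m for t, m in results if t)) if truth else frozenset()
    raise TypeError(type(predicate))


_VOCAB = [
    "nurse", "doctor", "strike", "walkout", "hospital", "clinic", "vaccine",
    "booster", "burnout", "budget", "council", "report", "protest", "deaths",
    "union", "city", "health", "worker", "pandemic", "meeting",
]
_PHRASES = ["industrial action", "mental health", "health worker"]


def random_predicate(rng: np.random.Generator, depth: int = 0):
    """Random schema-valid predicate tree of depth <= 4."""
    if depth >= 3 or rng.random() < 0.4:
        n_keywords = int(rng.integers(1, 5))
        pool = list(_VOCAB) + _PHRASES
        keywords = tuple(
            str(k) for k in rng.choice(pool, size=n_keywords, replace=False)
        )
        return Match(
            scope=str(rng.choice(["TITLE", "BODY", "SENTENCE"])),
            keywords=KeywordList("kw", keywords),
            min_distinct=int(rng.integers(1, n_keywords + 1)),
        )
    kind = rng.choice(["and", "or", "not"])
    if kind == "not":
        return Not(random_predicate(rng, depth + 1))
    n_children = int(rng.integers(2, 4))
    children = tuple(random_predicate(rng, depth + 1) for _ in range(n_children))
    return And(children) if kind == "and" else Or(children)


def random_article(rng: np.random.Generator, article_id: str = "r0") -> Article:
    def sentence() -> str:
        n = int(rng.integers(3, 9))
        return " ".join(str(w) for w in rng.choice(_VOCAB, size=n)) + "."

    n_sentences = int(rng.integers(1, 6))
    title = " ".join(str(w) for w in rng.choice(_VOCAB, size=4))
    return Article(article_id, title, " ".join(sentence() for _ in range(n_sentences)))
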