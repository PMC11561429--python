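"""Boolean keyword-rule evaluation over titles, bodies, and single sentences.

A topic's rule set is an ordered list of predicate trees; an article is
positive for the topic iff **all** rules pass.  Leaves are MATCH predicates
(scope TITLE / BODY / SENTENCE, a keyword list, and a minimum number of
*distinct* phrases that must occur); internal nodes are AND / OR / NOT.
Exclusion rules are plain NOT-wrapped predicates.

Matching is case-insensitive whole-phrase matching on token boundaries (so
"nurse" never fires on "nursery").  SENTENCE scope passes when at least one
individual sentence satisfies the count, and the indices of every such
sentence are collected — downstream these become topic-focused pseudolabels
for the extractive summarizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
import yaml

from .corpus_io import Article, Corpus, SentenceIndex, segment_sentences
from .text import SentenceSplitter, default_sentence_splitter, tokenize

SCOPES = ("TITLE", "BODY", "SENTENCE")


class RuleConfigError(ValueError):
    """A rule configuration violated the schema; message carries a config path."""


@dataclass(frozen=True)
class KeywordList:
    name: str
    keywords: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.keywords:
            raise RuleConfigError(f"keyword list {self.name!r} is empty")
        lowered = tuple(k.lower() for k in self.keywords)
        if lowered != self.keywords:
            object.__setattr__(self, "keywords", lowered)
        if len(set(self.keywords)) != len(self.keywords):
            raise RuleConfigError(f"keyword list {self.name!r} has duplicate phrases")

    def phrase_tokens(self) -> tuple[tuple[str, ...], ...]:
        return tuple(tuple(tokenize(k)) for k in self.keywords)


@dataclass(frozen=True)
class Match:
    scope: str
    keywords: KeywordList
    min_distinct: int = 1

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise RuleConfigError(f"unknown scope {self.scope!r}")
        if not 1 <= self.min_distinct <= len(self.keywords.keywords):
            raise RuleConfigError(
                f"min_distinct={self.min_distinct} outside [1, {len(self.keywords.keywords)}]"
            )


@dataclass(frozen=True)
class And:
    children: tuple["Predicate", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise RuleConfigError("AND needs at least 2 children")


@dataclass(frozen=True)
class Or:
    children: tuple["Predicate", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise RuleConfigError("OR needs at least 2 children")


@dataclass(frozen=True)
class Not:
    child: "Predicate"


Predicate = Union[Match, And, Or, Not]


@dataclass(frozen=True)
class TopicRuleSet:
    topic_id: int
    topic_name: str
    rules: tuple[Predicate, ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise RuleConfigError(f"topic {self.topic_id}: needs at least one rule")


@dataclass(frozen=True)
class RuleMatch:
    article_id: str
    topic_id: int
    passed: bool
    per_rule: tuple[bool, ...]
    matched_sentence_indices: tuple[int, ...]


# ---------------------------------------------------------------------------
# Evaluation


def _distinct_count(tokens: Sequence[str], keywords: KeywordList) -> int:
    from .text import contains_phrase

    return sum(1 for phrase in keywords.phrase_tokens() if phrase and contains_phrase(tokens, phrase))


def evaluate_predicate(
    predicate: Predicate,
    article: Article,
    sentences: SentenceIndex,
) -> tuple[bool, frozenset[int]]:
    """Evaluate a predicate tree; returns (truth, matched sentence indices).

    Matched sentences are those satisfying a true SENTENCE-scope MATCH that
    contributed to a true outcome; false outcomes (and NOT nodes) contribute
    no sentences.
    """
    if isinstance(predicate, Match):
        if predicate.scope == "TITLE":
            truth = _distinct_count(tokenize(article.title), predicate.keywords) >= predicate.min_distinct
            return truth, frozenset()
        if predicate.scope == "BODY":
            truth = _distinct_count(tokenize(article.body), predicate.keywords) >= predicate.min_distinct
            return truth, frozenset()
        matched = frozenset(
            idx
            for idx, (s, e) in enumerate(sentences.spans)
            if _distinct_count(tokenize(article.body[s:e]), predicate.keywords) >= predicate.min_distinct
        )
        return bool(matched), matched
    if isinstance(predicate, Not):
        truth, _ = evaluate_predicate(predicate.child, article, sentences)
        return not truth, frozenset()
    results = [evaluate_predicate(c, article, sentences) for c in predicate.children]
    if isinstance(predicate, And):
        truth = all(t for t, _ in results)
        matched = frozenset().union(*(m for _, m in results)) if truth else frozenset()
        return truth, matched
    truth = any(t for t, _ in results)
    matched = frozenset().union(*(m for t, m in results if t)) if truth else frozenset()
    return truth, matched


def evaluate_rules(article: Article, sentences: SentenceIndex, ruleset: TopicRuleSet) -> RuleMatch:
    """Conjunction over all rules of the topic; matched sentences are unioned."""
    per_rule: list[bool] = []
    matched: set[int] = set()
    for rule in ruleset.rules:
        truth, sent = evaluate_predicate(rule, article, sentences)
        per_rule.append(truth)
        matched.update(sent)
    passed = all(per_rule)
    return RuleMatch(
        article_id=article.article_id,
        topic_id=ruleset.topic_id,
        passed=passed,
        per_rule=tuple(per_rule),
        matched_sentence_indices=tuple(sorted(matched)),
    )


@dataclass
class RulesReport:
    """Per-topic positive bookkeeping plus pairwise topic overlaps."""

    n_articles: int
    counts: dict[int, int]
    rates_percent: dict[int, float]
    overlap: pd.DataFrame  # topics x topics, NaN diagonal
    mean_rate_percent: float


@dataclass
class ClassificationResult:
    matrix: pd.DataFrame  # articles x topics, boolean
    report: RulesReport
    matches: dict[tuple[str, int], RuleMatch] = field(repr=False)


def classify_corpus(
    corpus: Corpus,
    rulesets: Sequence[TopicRuleSet],
    sentence_index: Mapping[str, SentenceIndex] | None = None,
    splitter: SentenceSplitter = default_sentence_splitter,
) -> ClassificationResult:
    """Apply every topic rule set to every article.

    Returns the boolean label matrix (rows = article ids, columns = topic
    ids), a report with per-topic counts, positive rates (percent of the
    actual corpus size), pairwise overlap counts and the cross-topic mean
    rate, and the full per-(article, topic) match records.
    """
    topic_ids = [rs.topic_id for rs in rulesets]
    if len(set(topic_ids)) != len(topic_ids):
        raise RuleConfigError("topic_ids must be unique across a configuration")
    matches: dict[tuple[str, int], RuleMatch] = {}
    data = {}
    for ruleset in rulesets:
        column = []
        for article in corpus:
            sentences = (
                sentence_index[article.article_id]
                if sentence_index is not None
                else segment_sentences(article, splitter)
            )
            match = evaluate_rules(article, sentences, ruleset)
            matches[(article.article_id, ruleset.topic_id)] = match
            column.append(match.passed)
        data[ruleset.topic_id] = column
    matrix = pd.DataFrame(data, index=corpus.ids(), dtype=bool)
    n = len(corpus)
    counts = {t: int(matrix[t].sum()) for t in topic_ids}
    rates = {t: (100.0 * counts[t] / n if n else 0.0) for t in topic_ids}
    overlap = pd.DataFrame(index=topic_ids, columns=topic_ids, dtype=float)
    for t in topic_ids:
        for u in topic_ids:
            overlap.loc[t, u] = float("nan") if t == u else float((matrix[t] & matrix[u]).sum())
    mean_rate = sum(rates.values()) / len(rates) if rates else 0.0
    report = RulesReport(
        n_articles=n, counts=counts, rates_percent=rates, overlap=overlap, mean_rate_percent=mean_rate
    )
    return ClassificationResult(matrix=matrix, report=report, matches=matches)


# ---------------------------------------------------------------------------
# Config parsing / serialization
#
# Schema (YAML or JSON): a list of
#   {topic_id, topic_name, rules: [<predicate>...]}
# where <predicate> is one of
#   {op: match, scope: title|body|sentence, keywords: [...], min_distinct: int,
#    list_name: str (optional)}
#   {op: and|or, children: [<predicate>...]}
#   {op: not, child: <predicate>}


def _parse_predicate(node: object, path: str) -> Predicate:
    if not isinstance(node, Mapping):
        raise RuleConfigError(f"{path}: expected a mapping, got {type(node).__name__}")
    op = str(node.get("op", "")).lower()
    try:
        if op == "match":
            scope = str(node.get("scope", "")).upper()
            keywords = node.get("keywords")
            if not isinstance(keywords, (list, tuple)):
                raise RuleConfigError(f"{path}.keywords: expected a list")
            kl = KeywordList(
                name=str(node.get("list_name", "keywords")),
                keywords=tuple(str(k) for k in keywords),
            )
            return Match(scope=scope, keywords=kl, min_distinct=int(node.get("min_distinct", 1)))
        if op in ("and", "or"):
            children = node.get("children")
            if not isinstance(children, (list, tuple)):
                raise RuleConfigError(f"{path}.children: expected a list")
            parsed = tuple(
                _parse_predicate(c, f"{path}.children[{i}]") for i, c in enumerate(children)
            )
            return And(parsed) if op == "and" else Or(parsed)
        if op == "not":
            if "child" not in node:
                raise RuleConfigError(f"{path}.child: missing")
            return Not(_parse_predicate(node["child"], f"{path}.child"))
    except RuleConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise RuleConfigError(f"{path}: {exc}") from exc
    raise RuleConfigError(f"{path}.op: unknown variant {op!r}")


def parse_ruleset(config: object, source: str = "config") -> tuple[TopicRuleSet, ...]:
    """Parse rule sets from a loaded config object, a YAML/JSON string, or a path."""
    if isinstance(config, (str, Path)):
        path = Path(config)
        if path.exists():
            text = path.read_text(encoding="utf-8")
            source = str(path)
        else:
            text = str(config)
        config = yaml.safe_load(text)
    if not isinstance(config, (list, tuple)):
        raise RuleConfigError(f"{source}: top level must be a list of topic rule sets")
    rulesets = []
    for i, entry in enumerate(config):
        path = f"{source}[{i}]"
        if not isinstance(entry, Mapping):
            raise RuleConfigError(f"{path}: expected a mapping")
        try:
            topic_id = int(entry["topic_id"])
        except (KeyError, TypeError, ValueError) as exc:
            raise RuleConfigError(f"{path}.topic_id: {exc}") from exc
        rules = entry.get("rules")
        if not isinstance(rules, (list, tuple)) or not rules:
            raise RuleConfigError(f"{path}.rules: expected a nonempty list")
        rulesets.append(
            TopicRuleSet(
                topic_id=topic_id,
                topic_name=str(entry.get("topic_name", f"topic_{topic_id}")),
                rules=tuple(
                    _parse_predicate(r, f"{path}.rules[{j}]") for j, r in enumerate(rules)
                ),
            )
        )
    ids = [rs.topic_id for rs in rulesets]
    if len(set(ids)) != len(ids):
        raise RuleConfigError(f"{source}: duplicate topic_ids {ids}")
    return tuple(rulesets)


def _predicate_to_dict(p: Predicate) -> dict:
    if isinstance(p, Match):
        return {
            "op": "match",
            "scope": p.scope.lower(),
            "list_name": p.keywords.name,
            "keywords": list(p.keywords.keywords),
            "min_distinct": p.min_distinct,
        }
    if isinstance(p, Not):
        return {"op": "not", "child": _predicate_to_dict(p.child)}
    op = "and" if isinstance(p, And) else "or"
    return {"op": op, "children": [_predicate_to_dict(c) for c in p.children]}


def serialize_ruleset(rulesets: Iterable[TopicRuleSet]) -> list[dict]:
    return [
        {
            "topic_id": rs.topic_id,
            "topic_name": rs.topic_name,
            "rules": [_predicate_to_dict(r) for r in rs.rules],
        }
        for rs in rulesets
    ]


def write_ruleset(rulesets: Iterable[TopicRuleSet], path: str | Path) -> None:
    path = Path(path)
    payload = serialize_ruleset(rulesets)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def default_rulesets() -> tuple[TopicRuleSet, ...]:
    """The packaged illustrative rule sets for the six health-workforce topics.

    These are illustrative defaults, not an authoritative expert rule base;
    production deployments supply their own rule files.
    """
    from importlib.resources import files

    return parse_ruleset(
        yaml.safe_load(files("newswatch.data").joinpath("default_rules.yaml").read_text()),
        source="default_rules.yaml",
    )
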