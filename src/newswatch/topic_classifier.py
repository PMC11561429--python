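"""Multilabel topic-relevance classification with negative subsampling and enrichment.

Topic-positive articles are rare (well under a percent of the feed), so
training on the raw corpus would drown the signal in negatives.  The recipe:

* labels start as the rule engine's hard assignments (optionally cleaned and
  enriched by human review, tracked per (article, topic) with provenance);
* a 90/10 train/validation split is drawn once from a seed; the training side
  keeps every positive article and at most ``negative_cap`` sampled
  negatives; the validation side is left untouched so its metrics reflect the
  deployment class balance;
* a fixed document encoder feeds a 2-layer sigmoid head (hidden 768 by
  default) trained with multilabel binary cross-entropy, Adam, a linear
  warmup/decay schedule and early stopping on validation macro ROC-AUC;
* after a first round, the top-scored rule-negative articles per topic are
  exported for human review ("label enrichment"), verdicts re-enter the label
  store, and the classifier is retrained;
* at inference, a topic keeps every article scoring above a probability
  threshold plus the top ``multiplier * N`` ranked articles, ``N`` being the
  topic's rules-positive count.

Default hyperparameters are the production fine-tuning schedule for a
pretrained transformer backbone; desk-scale runs with the hashing encoder
should pass a config with a from-scratch learning rate (~1e-2).
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import Article, Corpus
from .encoders import HashingDocumentEncoder
from .metrics import MetricUndefinedError, roc_auc
from .nn import SigmoidMLP, train_mlp

logger = logging.getLogger(__name__)

LABEL_VALUES = ("positive", "negative", "unknown")
PROVENANCES = ("rule", "human_confirmed", "human_enriched")


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule; defaults are the production fine-tuning recipe."""

    epochs: int = 5
    learning_rate: float = 1e-5
    batch_size: int = 4
    warmup_fraction: float = 0.05
    eval_every_steps: int = 5000
    hidden_size: int = 768
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.eval_every_steps, self.hidden_size) < 0:
            raise ValueError("config values must be positive")
        if self.learning_rate <= 0 or not 0 < self.warmup_fraction < 1:
            raise ValueError("learning_rate > 0 and warmup_fraction in (0,1) required")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.90
    negative_cap: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    @property
    def validation_fraction(self) -> float:
        return 1.0 - self.train_fraction


class LabelStore:
    """Per (article_id, topic_id) relevance label with provenance."""

    def __init__(self) -> None:
        self._labels: dict[tuple[str, int], tuple[str, str]] = {}

    def set_label(self, article_id: str, topic_id: int, label: str, provenance: str) -> None:
        if label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {label!r}")
        if provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        self._labels[(article_id, topic_id)] = (label, provenance)

    def label(self, article_id: str, topic_id: int) -> str:
        return self._labels.get((article_id, topic_id), ("unknown", ""))[0]

    def provenance(self, article_id: str, topic_id: int) -> str | None:
        entry = self._labels.get((article_id, topic_id))
        return entry[1] if entry else None

    def is_positive(self, article_id: str, topic_id: int) -> bool:
        return self.label(article_id, topic_id) == "positive"

    def __len__(self) -> int:
        return len(self._labels)

    @classmethod
    def from_rule_matrix(cls, matrix: pd.DataFrame) -> "LabelStore":
        """Hard rule assignments (articles x topics boolean) as initial labels."""
        store = cls()
        for article_id, row in matrix.iterrows():
            for topic_id, value in row.items():
                store.set_label(article_id, int(topic_id), "positive" if value else "negative", "rule")
        return store

    def apply_review(self, verdicts: Iterable[tuple[str, int, str]], provenance: str = "human_enriched") -> int:
        """Merge human review verdicts (article_id, topic_id, 'positive'|'negative')."""
        n = 0
        for article_id, topic_id, verdict in verdicts:
            self.set_label(article_id, int(topic_id), verdict, provenance)
            n += 1
        return n

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["article_id", "topic_id", "label", "provenance"])
            for (aid, tid), (label, prov) in sorted(self._labels.items()):
                writer.writerow([aid, tid, label, prov])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabelStore":
        store = cls()
        with Path(path).open(encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                store.set_label(row["article_id"], int(row["topic_id"]), row["label"], row["provenance"])
        return store


@dataclass
class Dataset:
    articles: list[Article]
    Y: np.ndarray  # n x n_topics in {0, 1}
    topic_ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.articles)

    @property
    def article_ids(self) -> list[str]:
        return [a.article_id for a in self.articles]


def positive_ratio_percent(n_positive: int, n_negative: int) -> float:
    """Positive share of a training set, in percent."""
    total = n_positive + n_negative
    if total == 0:
        raise ValueError("empty set")
    return 100.0 * n_positive / total


def build_datasets(
    corpus: Corpus,
    labels: LabelStore,
    split: SplitSpec,
    topic_ids: Sequence[int],
) -> tuple[Dataset, Dataset]:
    """Seeded train/validation split with training-side negative subsampling.

    An article is a "positive" if it is labeled positive for at least one
    topic; the training side keeps every positive and at most
    ``split.negative_cap`` negatives sampled uniformly without replacement.
    The validation side is returned as drawn, with no rebalancing.
    """
    topic_ids = tuple(int(t) for t in topic_ids)
    rng = np.random.default_rng(split.seed)
    order = rng.permutation(len(corpus))
    n_train = int(round(split.train_fraction * len(corpus)))
    train_articles = [corpus[i] for i in sorted(order[:n_train])]
    val_articles = [corpus[i] for i in sorted(order[n_train:])]

    def label_matrix(articles: list[Article]) -> np.ndarray:
        return np.array(
            [[1.0 if labels.is_positive(a.article_id, t) else 0.0 for t in topic_ids] for a in articles]
        ).reshape(len(articles), len(topic_ids))

    Y_train = label_matrix(train_articles)
    pos_mask = Y_train.sum(axis=1) > 0
    n_pos = int(pos_mask.sum())
    if n_pos == 0:
        raise ValueError("no positive articles in the training split: untrainable")
    neg_indices = np.flatnonzero(~pos_mask)
    if len(neg_indices) > split.negative_cap:
        neg_indices = rng.choice(neg_indices, size=split.negative_cap, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(pos_mask), neg_indices]).astype(int))
    train = Dataset([train_articles[i] for i in keep], Y_train[keep], topic_ids)
    val = Dataset(val_articles, label_matrix(val_articles), topic_ids)
    logger.info(
        "build_datasets: train %d articles (%d positive, ratio %.2f%%), val %d",
        len(train), n_pos, positive_ratio_percent(n_pos, len(train) - n_pos), len(val),
    )
    return train, val


@dataclass
class TopicClassifier:
    """Document encoder + 2-layer sigmoid head assigning independent topic probabilities."""

    encoder: HashingDocumentEncoder
    head: SigmoidMLP
    topic_ids: tuple[int, ...]

    @classmethod
    def init(
        cls,
        encoder: HashingDocumentEncoder,
        topic_ids: Sequence[int],
        hidden_size: int = 768,
        seed: int = 0,
    ) -> "TopicClassifier":
        head = SigmoidMLP.init(encoder.dim, hidden_size, len(topic_ids), seed=seed)
        return cls(encoder=encoder, head=head, topic_ids=tuple(int(t) for t in topic_ids))

    def encode(self, articles: Sequence[Article]) -> np.ndarray:
        if not articles:
            return np.zeros((0, self.encoder.dim))
        return np.stack([self.encoder.encode_article(a) for a in articles])

    def predict_proba(self, articles: Sequence[Article]) -> pd.DataFrame:
        probs = self.head.forward(self.encode(articles))
        return pd.DataFrame(probs, index=[a.article_id for a in articles], columns=list(self.topic_ids))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.head.params())
        meta = {
            "topic_ids": list(self.topic_ids),
            "encoder": {"dim": self.encoder.dim, "seed": self.encoder.seed, "max_tokens": self.encoder.max_tokens},
        }
        path.with_suffix(".json").write_text(json.dumps(meta), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TopicClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
        arrays = np.load(path.with_suffix(".npz"))
        head = SigmoidMLP(arrays["W1"], arrays["b1"], arrays["W2"], arrays["b2"])
        encoder = HashingDocumentEncoder(**meta["encoder"])
        return cls(encoder=encoder, head=head, topic_ids=tuple(meta["topic_ids"]))


def macro_roc_auc(probs: np.ndarray, Y: np.ndarray) -> float:
    """Macro-average ROC-AUC (x100) over topics; single-class topics are skipped."""
    aucs = []
    for j in range(Y.shape[1]):
        try:
            aucs.append(roc_auc(probs[:, j], Y[:, j].astype(int)))
        except MetricUndefinedError:
            warnings.warn(f"topic column {j}: single-class validation labels, skipped in macro AUC")
    if not aucs:
        raise MetricUndefinedError("no topic has both classes in validation")
    return float(np.mean(aucs))


def train_classifier(
    train: Dataset,
    val: Dataset,
    encoder: HashingDocumentEncoder,
    config: TrainConfig,
) -> tuple[TopicClassifier, list[dict]]:
    """Train the multilabel head; early stopping on validation macro ROC-AUC.

    Returns the classifier holding the best checkpoint and the evaluation
    history (step, epoch, loss, score).
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation sets must be nonempty")
    model = TopicClassifier.init(encoder, train.topic_ids, config.hidden_size, seed=config.seed)
    X_train = model.encode(train.articles)
    X_val = model.encode(val.articles)

    def eval_fn(head: SigmoidMLP) -> float:
        try:
            return macro_roc_auc(head.forward(X_val), val.Y)
        except MetricUndefinedError:
            return -np.inf

    history = train_mlp(
        model.head,
        X_train,
        train.Y,
        None,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        warmup_fraction=config.warmup_fraction,
        seed=config.seed,
        eval_fn=eval_fn,
        eval_every_steps=config.eval_every_steps,
    )
    return model, history


def predict(model: TopicClassifier, articles: Sequence[Article]) -> pd.DataFrame:
    """Per-article, per-topic probabilities in (0, 1); rows are independent."""
    return model.predict_proba(articles)


def select_enrichment_candidates(
    probs: pd.DataFrame,
    labels: LabelStore,
    k: int = 500,
) -> dict[int, list[str]]:
    """Per topic, the k rule-negative articles with highest predicted probability.

    These go out for human review; verdicts return via
    :meth:`LabelStore.apply_review` as ``human_enriched`` labels.  Ties and
    ranking are stabilized by article id.
    """
    candidates: dict[int, list[str]] = {}
    for topic_id in probs.columns:
        negatives = [aid for aid in probs.index if not labels.is_positive(aid, int(topic_id))]
        if len(negatives) < k:
            warnings.warn(f"topic {topic_id}: only {len(negatives)} negatives available (< k={k})")
        ranked = sorted(negatives, key=lambda aid: (-probs.at[aid, topic_id], aid))
        candidates[int(topic_id)] = ranked[:k]
    return candidates


def write_review_csv(candidates: Mapping[int, list[str]], probs: pd.DataFrame, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["article_id", "topic_id", "probability", "verdict"])
        for topic_id, aids in sorted(candidates.items()):
            for aid in aids:
                writer.writerow([aid, topic_id, f"{probs.at[aid, topic_id]:.6f}", ""])


def read_review_csv(path: str | Path) -> list[tuple[str, int, str]]:
    verdicts = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            verdict = (row.get("verdict") or "").strip().lower()
            if verdict in ("positive", "negative"):
                verdicts.append((row["article_id"], int(row["topic_id"]), verdict))
    return verdicts


@dataclass(frozen=True)
class KeptArticle:
    article_id: str
    probability: float
    by_threshold: bool
    by_rank: bool


def apply_inference_filter(
    probs: pd.DataFrame,
    rules_positive_counts: Mapping[int, int],
    threshold: float = 0.95,
    multiplier: int = 3,
) -> dict[int, list[KeptArticle]]:
    """Hybrid keep rule: per topic, {p > threshold} union top multiplier*N by probability.

    N is the topic's rules-positive count.  Each kept article carries reason
    flags (``by_threshold`` / ``by_rank``); output per topic is ordered by
    decreasing probability with article-id tie-breaks.
    """
    kept: dict[int, list[KeptArticle]] = {}
    for topic_id in probs.columns:
        t = int(topic_id)
        n = int(rules_positive_counts.get(t, 0))
        if n < 0:
            raise ValueError(f"topic {t}: negative rules-positive count")
        ranked = sorted(probs.index, key=lambda aid: (-probs.at[aid, topic_id], aid))
        top = set(ranked[: multiplier * n])
        entries = []
        for aid in ranked:
            p = float(probs.at[aid, topic_id])
            by_threshold = p > threshold
            by_rank = aid in top
            if by_threshold or by_rank:
                entries.append(KeptArticle(aid, p, by_threshold, by_rank))
        kept[t] = entries
    return kept
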