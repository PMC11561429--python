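"""Dual-head extractive summarization: oracle labels, masked training, top-3 output.

Extractive (sentence-selection) summarization is used deliberately instead of
abstractive generation: a selected sentence cannot hallucinate.  Two label
sources supervise one sentence scorer with two prediction heads:

* **global** — human annotators mark 1-3 sentences forming a general summary
  of the article;
* **topic** — sentences matched by sentence-scope lexical rules serve as
  topic-focused pseudolabels.

Articles may carry either, both, or (for generic news-highlights pretraining
via greedy ROUGE-1 oracle construction) just oracle labels; the loss for a
missing head is masked out entirely.  At inference each sentence gets
(p_global, p_topic); sentences are ranked by the score sum and the top 3 form
the summary, emitted in document order.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .encoders import HashingSentenceEncoder
from .metrics import rouge_l, rouge_mean, rouge_n
from .nn import SigmoidMLP, train_mlp

logger = logging.getLogger(__name__)


class LabelValidationError(ValueError):
    pass


@dataclass(frozen=True)
class OracleLabels:
    """Per-article extractive labels; either field may be absent (None)."""

    article_id: str
    global_indices: frozenset[int] | None = None
    topic_indices: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.global_indices is not None and not 1 <= len(self.global_indices) <= 3:
            raise LabelValidationError(
                f"article {self.article_id}: global summary must select 1-3 sentences, "
                f"got {len(self.global_indices)}"
            )

    @property
    def has_any(self) -> bool:
        return self.global_indices is not None or self.topic_indices is not None


@dataclass(frozen=True)
class SummarizerTrainConfig:
    """Training schedule; defaults are the production fine-tuning recipe."""

    epochs: int = 10
    learning_rate: float = 1e-5
    batch_size: int = 32
    warmup_fraction: float = 0.10
    hidden_size: int = 768
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.hidden_size) < 0:
            raise ValueError("config values must be positive")
        if self.learning_rate <= 0 or not 0 < self.warmup_fraction < 1:
            raise ValueError("learning_rate > 0 and warmup_fraction in (0,1) required")


# ---------------------------------------------------------------------------
# Oracle label construction


def greedy_oracle_labels(
    source_sentences: Sequence[str],
    highlights: Sequence[str],
    variant: str = "f1",
) -> tuple[int, ...]:
    """Greedy extractive oracle: match each highlight to its best source sentence.

    For each highlight in order, select the not-yet-selected source sentence
    maximizing ROUGE-1 (*variant* "f1" or "recall") with it, earliest index on
    ties.  Returns the selected indices in selection order (at most one per
    highlight).
    """
    if not source_sentences:
        raise ValueError("source sentence list is empty")
    if not highlights:
        raise ValueError("highlight list is empty")
    selected: list[int] = []
    for highlight in highlights:
        best_idx = None
        best_score = -1.0
        for idx, sentence in enumerate(source_sentences):
            if idx in selected:
                continue
            score = rouge_n(sentence, highlight, n=1, variant=variant)
            if score > best_score:
                best_score = score
                best_idx = idx
        if best_idx is not None:
            selected.append(best_idx)
    return tuple(selected)


def build_training_labels(
    rule_matches: Mapping[str, Sequence[int]],
    human_annotations: Mapping[str, Sequence[int]],
    n_sentences: Mapping[str, int],
) -> dict[str, OracleLabels]:
    """Merge rule pseudolabels and human selections into per-article labels.

    Articles present in neither source are excluded.  Out-of-range indices and
    human selections outside 1-3 sentences raise, naming the article.
    """
    labels: dict[str, OracleLabels] = {}
    for article_id in sorted(set(rule_matches) | set(human_annotations)):
        limit = n_sentences.get(article_id)
        if limit is None:
            raise LabelValidationError(f"article {article_id}: unknown sentence count")

        def checked(indices: Sequence[int], source: str) -> frozenset[int]:
            out = frozenset(int(i) for i in indices)
            bad = [i for i in out if not 0 <= i < limit]
            if bad:
                raise LabelValidationError(
                    f"article {article_id}: {source} indices {sorted(bad)} out of range [0, {limit})"
                )
            return out

        global_idx = None
        if article_id in human_annotations:
            global_idx = checked(human_annotations[article_id], "human")
        topic_idx = None
        if article_id in rule_matches and len(rule_matches[article_id]) > 0:
            topic_idx = checked(rule_matches[article_id], "rule")
        if global_idx is None and topic_idx is None:
            continue
        labels[article_id] = OracleLabels(article_id, global_idx, topic_idx)
    return labels


# ---------------------------------------------------------------------------
# Model


@dataclass
class DualHeadSummarizer:
    """Sentence encoder + shared hidden layer + (global, topic) sigmoid heads."""

    encoder: HashingSentenceEncoder
    head: SigmoidMLP  # d_out = 2: column 0 global, column 1 topic

    @classmethod
    def init(
        cls, encoder: HashingSentenceEncoder, hidden_size: int = 768, seed: int = 0
    ) -> "DualHeadSummarizer":
        return cls(encoder=encoder, head=SigmoidMLP.init(encoder.dim, hidden_size, 2, seed=seed))

    def score_sentences(self, sentences: Sequence[str]) -> np.ndarray:
        """(n_sentences, 2) array of (p_global, p_topic)."""
        if not sentences:
            return np.zeros((0, 2))
        return self.head.forward(self.encoder.encode_sentences(list(sentences)))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.head.params())
        meta = {"encoder": {"dim": self.encoder.dim, "seed": self.encoder.seed}}
        path.with_suffix(".json").write_text(json.dumps(meta), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "DualHeadSummarizer":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
        arrays = np.load(path.with_suffix(".npz"))
        head = SigmoidMLP(arrays["W1"], arrays["b1"], arrays["W2"], arrays["b2"])
        return cls(encoder=HashingSentenceEncoder(**meta["encoder"]), head=head)


def train_summarizer(
    articles: Mapping[str, Sequence[str]],
    labels: Mapping[str, OracleLabels],
    sentence_encoder: HashingSentenceEncoder,
    config: SummarizerTrainConfig,
    validation: Mapping[str, tuple[Sequence[str], Sequence[int]]] | None = None,
) -> tuple[DualHeadSummarizer, list[dict]]:
    """Train the dual-head scorer with per-head masked binary cross-entropy.

    *articles* maps article_id -> sentence texts; *labels* supplies the
    per-article :class:`OracleLabels` (articles without any label are
    skipped).  A head's loss contributes only where its label source exists.
    *validation* (article_id -> (sentences, human-selected indices)) drives
    early stopping on the mean ROUGE of the predicted top-3 summary against
    the concatenated human selection.
    """
    model = DualHeadSummarizer.init(sentence_encoder, config.hidden_size, seed=config.seed)
    X_rows, Y_rows, M_rows = [], [], []
    n_labeled = 0
    for article_id in sorted(articles):
        label = labels.get(article_id)
        if label is None or not label.has_any:
            continue
        sentences = list(articles[article_id])
        if not sentences:
            continue
        n_labeled += 1
        X_rows.append(sentence_encoder.encode_sentences(sentences))
        y = np.zeros((len(sentences), 2))
        m = np.zeros((len(sentences), 2))
        if label.global_indices is not None:
            m[:, 0] = 1.0
            y[list(label.global_indices), 0] = 1.0
        if label.topic_indices is not None:
            m[:, 1] = 1.0
            y[list(label.topic_indices), 1] = 1.0
        Y_rows.append(y)
        M_rows.append(m)
    if n_labeled == 0:
        raise ValueError("no labeled articles: nothing to train on")
    X = np.concatenate(X_rows)
    Y = np.concatenate(Y_rows)
    M = np.concatenate(M_rows)

    eval_fn = None
    if validation:
        val_items = sorted(validation.items())

        def eval_fn(head: SigmoidMLP) -> float:
            scores = []
            for _, (sentences, human_idx) in val_items:
                sentences = list(sentences)
                probs = head.forward(sentence_encoder.encode_sentences(sentences))
                summary = _select_top_k(probs, k=3)
                predicted = " ".join(sentences[i] for i in summary)
                reference = " ".join(sentences[i] for i in sorted(human_idx))
                scores.append(rouge_mean(predicted, reference))
            return float(np.mean(scores)) if scores else -np.inf

    history = train_mlp(
        model.head,
        X,
        Y,
        M,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        warmup_fraction=config.warmup_fraction,
        seed=config.seed,
        eval_fn=eval_fn,
        eval_every_steps=None,
    )
    return model, history


def _select_top_k(probs: np.ndarray, k: int) -> list[int]:
    """Indices of the top-k sentences by summed head score, in document order."""
    sums = probs.sum(axis=1)
    ranked = sorted(range(len(sums)), key=lambda i: (-sums[i], i))
    return sorted(ranked[: min(k, len(sums))])


@dataclass(frozen=True)
class Summary:
    article_id: str
    indices: tuple[int, ...]  # document order
    sentences: tuple[str, ...]
    p_global: tuple[float, ...]
    p_topic: tuple[float, ...]

    @property
    def text(self) -> str:
        return " ".join(self.sentences)


def summarize(
    model: DualHeadSummarizer,
    article_id: str,
    sentences: Sequence[str],
    k: int = 3,
) -> Summary:
    """Top-``min(k, n)`` sentences by p_global + p_topic, emitted in document order.

    Ranking ties resolve to the earlier sentence.  Every emitted sentence is
    verbatim from the source.
    """
    sentences = list(sentences)
    if not sentences:
        return Summary(article_id, (), (), (), ())
    probs = model.score_sentences(sentences)
    chosen = _select_top_k(probs, k)
    return Summary(
        article_id=article_id,
        indices=tuple(chosen),
        sentences=tuple(sentences[i] for i in chosen),
        p_global=tuple(float(probs[i, 0]) for i in chosen),
        p_topic=tuple(float(probs[i, 1]) for i in chosen),
    )


def evaluate_summaries(
    predictions: Mapping[str, str],
    references: Mapping[str, str],
) -> tuple[dict[str, dict[str, float]], dict[str, float]]:
    """ROUGE-1/2/L F1 (x100) per article plus their means.

    Articles with an empty reference are skipped with a warning.  Returns
    (per_article, means) where means has keys rouge1/rouge2/rougeL/mean.
    """
    per_article: dict[str, dict[str, float]] = {}
    for article_id in sorted(predictions):
        reference = references.get(article_id, "")
        if not reference.strip():
            warnings.warn(f"article {article_id}: empty reference, skipped")
            continue
        candidate = predictions[article_id]
        r1 = rouge_n(candidate, reference, 1)
        r2 = rouge_n(candidate, reference, 2)
        rl = rouge_l(candidate, reference)
        per_article[article_id] = {
            "rouge1": r1,
            "rouge2": r2,
            "rougeL": rl,
            "mean": (r1 + r2 + rl) / 3.0,
        }
    if not per_article:
        return per_article, {"rouge1": 0.0, "rouge2": 0.0, "rougeL": 0.0, "mean": 0.0}
    keys = ("rouge1", "rouge2", "rougeL", "mean")
    means = {key: float(np.mean([row[key] for row in per_article.values()])) for key in keys}
    return per_article, means
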