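"""Evaluation metrics: ROUGE-1/2/L, Fleiss kappa, Gwet AC1, ROC/PR-AUC, P/R@m.

All metrics are implemented here from their definitions and returned on the
x100 scale used throughout surveillance reporting (a perfect score is 100.0).

ROUGE tokenization is lowercase with splits on non-alphanumerics, no stemming
and no stopword removal.  ROUGE-N uses clipped n-gram counts; ROUGE-L uses the
token-level longest common subsequence.  Fleiss kappa corrects observed
agreement by squared category marginals; Gwet AC1 uses the alternative chance
term ``(1/(K-1)) * sum_q pi_q (1 - pi_q)``, which is far less sensitive to
marginal imbalance (the reason both are reported for skewed sentence-selection
annotations).  ROC-AUC is the midrank statistic (equivalent to the
Mann-Whitney U normalization); PR-AUC is average precision with step
interpolation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .text import tokenize


class MetricUndefinedError(ValueError):
    """The metric is undefined on this input (single class, degenerate marginals)."""


# ---------------------------------------------------------------------------
# ROUGE


def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def rouge_n(candidate: str, reference: str, n: int = 1, variant: str = "f1") -> float:
    """ROUGE-N between two texts, x100.  *variant* in {"f1", "recall", "precision"}."""
    cand = _ngrams(tokenize(candidate), n)
    ref = _ngrams(tokenize(reference), n)
    total_cand = sum(cand.values())
    total_ref = sum(ref.values())
    if total_cand == 0 or total_ref == 0:
        return 0.0
    overlap = sum((cand & ref).values())  # clipped counts
    precision = overlap / total_cand
    recall = overlap / total_ref
    if variant == "recall":
        return 100.0 * recall
    if variant == "precision":
        return 100.0 * precision
    if variant == "f1":
        return 100.0 * _f1(precision, recall)
    raise ValueError(f"unknown variant {variant!r}")


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    # single-row DP, O(len(a) * len(b)) time, O(len(b)) space
    if not a or not b:
        return 0
    row = [0] * (len(b) + 1)
    for x in a:
        prev = 0
        for j, y in enumerate(b, start=1):
            cur = row[j]
            row[j] = prev + 1 if x == y else max(row[j], row[j - 1])
            prev = cur
    return row[-1]


def rouge_l(candidate: str, reference: str, variant: str = "f1") -> float:
    """ROUGE-L (token LCS) between two texts, x100."""
    cand = tokenize(candidate)
    ref = tokenize(reference)
    if not cand or not ref:
        return 0.0
    lcs = _lcs_length(cand, ref)
    precision = lcs / len(cand)
    recall = lcs / len(ref)
    if variant == "recall":
        return 100.0 * recall
    if variant == "precision":
        return 100.0 * precision
    if variant == "f1":
        return 100.0 * _f1(precision, recall)
    raise ValueError(f"unknown variant {variant!r}")


def rouge_mean(candidate: str, reference: str) -> float:
    """Mean of ROUGE-1, ROUGE-2 and ROUGE-L F1, x100 — the summary score."""
    return (
        rouge_n(candidate, reference, 1)
        + rouge_n(candidate, reference, 2)
        + rouge_l(candidate, reference)
    ) / 3.0


# ---------------------------------------------------------------------------
# Inter-annotator agreement


@dataclass(frozen=True)
class RatingsTable:
    """Items x categories matrix of rater counts with a constant rater count per item."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] < 1 or counts.shape[1] < 2:
            raise ValueError("ratings table must be items x categories with >= 2 categories")
        if (counts < 0).any():
            raise ValueError("rater counts must be non-negative")
        row_sums = counts.sum(axis=1)
        if not (row_sums == row_sums[0]).all():
            raise ValueError("every item must have the same number of raters")
        if row_sums[0] < 2:
            raise ValueError("need at least 2 raters per item")
        object.__setattr__(self, "counts", counts)

    @property
    def n_items(self) -> int:
        return self.counts.shape[0]

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]

    @property
    def n_raters(self) -> int:
        return int(self.counts[0].sum())


def _observed_agreement(table: RatingsTable) -> float:
    counts = table.counts
    r = table.n_raters
    per_item = (counts * (counts - 1)).sum(axis=1) / (r * (r - 1))
    return float(per_item.mean())


def fleiss_kappa(table: RatingsTable) -> float:
    """Fleiss kappa x100: (Pbar - Pe) / (1 - Pe), Pe = sum of squared marginals."""
    p_bar = _observed_agreement(table)
    marginals = table.counts.sum(axis=0) / table.counts.sum()
    p_e = float((marginals**2).sum())
    if p_e >= 1.0:
        raise MetricUndefinedError("all ratings in one category: kappa undefined")
    return 100.0 * (p_bar - p_e) / (1.0 - p_e)


def gwet_chance_agreement(table: RatingsTable) -> float:
    """Gwet's chance-agreement term x100: (1/(K-1)) * sum_q pi_q (1 - pi_q)."""
    k = table.n_categories
    pi = (table.counts / table.n_raters).mean(axis=0)
    return 100.0 * float((pi * (1.0 - pi)).sum() / (k - 1))


def gwet_ac1(table: RatingsTable) -> float:
    """Gwet AC1 x100: (Pbar - Pe) / (1 - Pe) with Gwet's chance term."""
    p_bar = _observed_agreement(table)
    p_e = gwet_chance_agreement(table) / 100.0
    if p_e >= 1.0:
        raise MetricUndefinedError("degenerate marginals: AC1 undefined")
    return 100.0 * (p_bar - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# Ranking metrics


def _as_ranked(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1 or len(scores) < 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return scores, labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC-AUC x100 via the midrank statistic; requires both classes present."""
    scores, labels = _as_ranked(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricUndefinedError("ROC-AUC undefined with a single class")
    ranks = rankdata(scores, method="average")
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return 100.0 * float(auc)


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """PR-AUC x100 as average precision (step interpolation), stable-order ties."""
    scores, labels = _as_ranked(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise MetricUndefinedError("PR-AUC undefined with a single class")
    order = np.lexsort((np.arange(len(scores)), -scores))
    sorted_labels = labels[order]
    cum_pos = np.cumsum(sorted_labels)
    precision_at_rank = cum_pos / np.arange(1, len(labels) + 1)
    ap = float(precision_at_rank[sorted_labels == 1].sum() / n_pos)
    return 100.0 * ap


def precision_at(scores: Sequence[float], labels: Sequence[int], m: int) -> float:
    """Precision within the top-m ranked items, x100; ties broken by stable order."""
    scores, labels = _as_ranked(scores, labels)
    if not 1 <= m <= len(scores):
        raise ValueError(f"m={m} outside [1, {len(scores)}]")
    order = np.lexsort((np.arange(len(scores)), -scores))
    return 100.0 * float(labels[order[:m]].sum() / m)


def recall_at(scores: Sequence[float], labels: Sequence[int], m: int) -> float:
    """Recall within the top-m ranked items, x100; requires >= 1 positive."""
    scores, labels = _as_ranked(scores, labels)
    if not 1 <= m <= len(scores):
        raise ValueError(f"m={m} outside [1, {len(scores)}]")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise MetricUndefinedError("recall undefined with no positives")
    order = np.lexsort((np.arange(len(scores)), -scores))
    return 100.0 * float(labels[order[:m]].sum() / n_pos)
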