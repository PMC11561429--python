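"""Metric fixtures (hand-computed), brute-force oracles, and library cross-checks."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from newswatch.metrics import (
    MetricUndefinedError,
    RatingsTable,
    fleiss_kappa,
    gwet_ac1,
    gwet_chance_agreement,
    pr_auc,
    precision_at,
    recall_at,
    roc_auc,
    rouge_l,
    rouge_n,
)
from newswatch.text import tokenize

# ---------------------------------------------------------------------------
# Independent recount oracles


def naive_rouge1_f1(candidate: str, reference: str) -> float:
    c, r = Counter(tokenize(candidate)), Counter(tokenize(reference))
    overlap = sum(min(c[t], r[t]) for t in c)
    tc, tr = sum(c.values()), sum(r.values())
    if tc == 0 or tr == 0 or overlap == 0:
        return 0.0
    p, rec = overlap / tc, overlap / tr
    return 100.0 * 2 * p * rec / (p + rec)


def naive_lcs(a, b) -> int:
    # full-matrix DP, independent of the package's single-row implementation
    table = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            table[i][j] = (
                table[i - 1][j - 1] + 1 if a[i - 1] == b[j - 1]
                else max(table[i - 1][j], table[i][j - 1])
            )
    return table[-1][-1]


def pairwise_roc_auc(scores, labels) -> float:
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return 100.0 * wins / (len(pos) * len(neg))


class TestRouge:
    @pytest.mark.parametrize("cand,ref,n,expected", [
        ("a b c", "a b c", 1, 100.0),
        ("a b c", "a x c", 1, 2 / 3 * 100),
        ("a b", "c d", 2, 0.0),
        ("", "a b", 1, 0.0),
    ])
    def test_rouge_n_fixtures(self, cand, ref, n, expected):
        assert rouge_n(cand, ref, n) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("cand,ref,expected", [
        ("a b c d", "a b c d", 100.0),
        ("a b c d", "a c b d", 75.0),  # LCS = 3 of 4 tokens each side
        ("x y", "a b", 0.0),
    ])
    def test_rouge_l_fixtures(self, cand, ref, expected):
        assert rouge_l(cand, ref) == pytest.approx(expected, abs=1e-4)

    def test_rouge_l_matches_full_matrix_dp_on_random_strings(self):
        rng = np.random.default_rng(3)
        alphabet = list("abcde")
        for _ in range(200):
            a = [str(x) for x in rng.choice(alphabet, size=rng.integers(1, 10))]
            b = [str(x) for x in rng.choice(alphabet, size=rng.integers(1, 10))]
            lcs = naive_lcs(a, b)
            expected = 0.0
            if lcs:
                p, r = lcs / len(a), lcs / len(b)
                expected = 100.0 * 2 * p * r / (p + r)
            assert rouge_l(" ".join(a), " ".join(b)) == pytest.approx(expected, abs=1e-9)

    @given(st.text("abc x", min_size=1, max_size=30), st.text("abc x", min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_f1_symmetry_and_range(self, a, b):
        v1, v2 = rouge_n(a, b, 1), rouge_n(b, a, 1)
        assert v1 == pytest.approx(v2)
        assert 0.0 <= v1 <= 100.0

    def test_matches_independent_recount(self):
        rng = np.random.default_rng(7)
        words = list("abcdefgh")
        for _ in range(100):
            cand = " ".join(rng.choice(words, size=rng.integers(1, 15)))
            ref = " ".join(rng.choice(words, size=rng.integers(1, 15)))
            assert rouge_n(cand, ref, 1) == pytest.approx(naive_rouge1_f1(cand, ref), abs=1e-9)


class TestAgreement:
    def test_perfect_agreement_is_100_for_any_category_count(self):
        for k in (2, 3, 5):
            rows = np.zeros((6, k), dtype=int)
            rows[np.arange(6), np.arange(6) % k] = 4  # 4 raters all agree per item
            table = RatingsTable(rows)
            assert fleiss_kappa(table) == pytest.approx(100.0)
            assert gwet_ac1(table) == pytest.approx(100.0)

    def test_fleiss_hand_fixture(self):
        # 4 items, 3 raters: rows [2,1],[1,2],[3,0],[0,3]
        # P_i = (2 + 2 + 6 + 6)/6 per item -> Pbar = (1/3+1/3+1+1)/4 = 2/3
        # marginals 0.5/0.5 -> Pe = 0.5; kappa = (2/3 - 1/2)/(1/2) = 1/3
        table = RatingsTable(np.array([[2, 1], [1, 2], [3, 0], [0, 3]]))
        assert fleiss_kappa(table) == pytest.approx(100.0 / 3.0, abs=1e-4)

    def test_fleiss_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(2)
        counts = np.zeros((40, 3), dtype=int)
        for i in range(40):
            for _ in range(4):
                counts[i, rng.integers(0, 3)] += 1
        table = RatingsTable(counts)
        assert fleiss_kappa(table) == pytest.approx(100.0 * sm_fleiss(counts), abs=1e-8)

    def test_gwet_chance_term_two_categories(self):
        # pi = mean proportions; K=2 -> Pe = 2 * pi * (1 - pi) summed halves
        table = RatingsTable(np.array([[3, 0], [3, 0], [0, 3], [3, 0]]))
        pi = np.array([3 / 4, 1 / 4])
        expected = 100.0 * float((pi * (1 - pi)).sum())  # /(K-1) with K=2
        assert gwet_chance_agreement(table) == pytest.approx(expected, abs=1e-9)
        assert gwet_ac1(table) == pytest.approx(100.0 * (1 - 0.375) / (1 - 0.375), abs=1e-9)

    def test_hand_fixture_ac1(self):
        # same table as the Fleiss fixture: Pbar=2/3, Gwet Pe = 2*0.5*0.5 = 0.5
        table = RatingsTable(np.array([[2, 1], [1, 2], [3, 0], [0, 3]]))
        assert gwet_ac1(table) == pytest.approx(100.0 / 3.0, abs=1e-4)

    def test_single_category_kappa_undefined(self):
        table = RatingsTable(np.array([[3, 0], [3, 0]]))
        with pytest.raises(MetricUndefinedError):
            fleiss_kappa(table)

    def test_unequal_rater_counts_rejected(self):
        with pytest.raises(ValueError, match="same number of raters"):
            RatingsTable(np.array([[2, 1], [1, 1]]))


class TestRankingMetrics:
    def test_perfect_separation_and_inversion(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(100.0)
        assert roc_auc([0.2, 0.9], [1, 0]) == pytest.approx(0.0)

    def test_single_class_undefined(self):
        with pytest.raises(MetricUndefinedError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_oracle_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        for _ in range(100):
            n = 50
            labels = (rng.random(n) < 0.3).astype(int)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            ours = roc_auc(scores, labels)
            assert ours == pytest.approx(pairwise_roc_auc(scores, labels), abs=1e-9)
            assert ours == pytest.approx(100.0 * roc_auc_score(labels, scores), abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=80)
        labels = (rng.random(80) < 0.4).astype(int)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) == pytest.approx(roc_auc(np.exp(scores), labels))

    def test_average_precision_hand_fixture(self):
        # ranks: pos@1 (P=1), neg@2, pos@3 (P=2/3) -> AP = (1 + 2/3)/2
        assert pr_auc([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(100 * (1 + 2 / 3) / 2, abs=1e-4)

    def test_average_precision_matches_sklearn_without_ties(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(8)
        for _ in range(20):
            n = 40
            scores = rng.permutation(n) / n  # distinct scores
            labels = (rng.random(n) < 0.3).astype(int)
            labels[:2] = [0, 1]
            assert pr_auc(scores, labels) == pytest.approx(
                100.0 * average_precision_score(labels, scores), abs=1e-9
            )

    def test_precision_recall_at_m(self):
        scores = [0.9, 0.8, 0.7, 0.1]
        labels = [1, 1, 0, 0]
        assert precision_at(scores, labels, 2) == pytest.approx(100.0)
        assert recall_at(scores, labels, 2) == pytest.approx(100.0)
        # 1 positive at rank 3
        assert precision_at([0.9, 0.8, 0.7], [0, 0, 1], 2) == pytest.approx(0.0)
        assert recall_at([0.9, 0.8, 0.7], [0, 0, 1], 2) == pytest.approx(0.0)

    def test_precision_recall_identity_and_monotonicity(self):
        rng = np.random.default_rng(9)
        scores = rng.random(30)
        labels = (rng.random(30) < 0.4).astype(int)
        labels[0] = 1
        n_pos = labels.sum()
        prev_recall = 0.0
        for m in range(1, 31):
            p, r = precision_at(scores, labels, m), recall_at(scores, labels, m)
            assert p == pytest.approx(r * n_pos / m)
            assert r >= prev_recall - 1e-12
            prev_recall = r

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            precision_at([0.5], [1], 2)
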