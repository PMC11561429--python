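"""Dataset construction, training head behavior, enrichment ranking, inference filter."""

import numpy as np
import pandas as pd
import pytest

from newswatch.corpus_io import Article, Corpus
from newswatch.encoders import HashingDocumentEncoder
from newswatch.nn import SigmoidMLP, linear_warmup_linear_decay, train_mlp
from newswatch.rules_engine import classify_corpus, default_rulesets
from newswatch.synthetic import GeneratorConfig, generate_corpus
from newswatch.topic_classifier import (
    LabelStore,
    SplitSpec,
    TopicClassifier,
    TrainConfig,
    apply_inference_filter,
    build_datasets,
    positive_ratio_percent,
    select_enrichment_candidates,
    train_classifier,
)

TOPICS = (1, 2, 3, 4, 5, 6)


def _toy_corpus_and_labels(n_pos=50, n_neg=500):
    articles, store = [], LabelStore()
    for i in range(n_pos + n_neg):
        aid = f"t{i:04d}"
        articles.append(Article(aid, f"title {i}", "Body text."))
        for t in TOPICS:
            positive = i < n_pos and t == 1
            store.set_label(aid, t, "positive" if positive else "negative", "rule")
    return Corpus(articles), store


class TestBuildDatasets:
    def test_keeps_all_positives_and_caps_negatives(self):
        corpus, store = _toy_corpus_and_labels(n_pos=50, n_neg=500)
        train, val = build_datasets(corpus, store, SplitSpec(negative_cap=100, seed=0), TOPICS)
        n_pos_train = int((train.Y.sum(axis=1) > 0).sum())
        n_neg_train = len(train) - n_pos_train
        # the 90% training side holds ~45 of the 50 positives; all are kept
        expected_pos = sum(
            1 for a in train.articles if store.is_positive(a.article_id, 1)
        )
        assert n_pos_train == expected_pos
        assert n_neg_train == 100
        assert len(val) == round(0.1 * len(corpus))

    def test_cap_above_negative_count_keeps_all(self):
        corpus, store = _toy_corpus_and_labels(n_pos=10, n_neg=40)
        train, _ = build_datasets(corpus, store, SplitSpec(negative_cap=10_000, seed=0), TOPICS)
        assert len(train) == round(0.9 * 50)

    def test_reproducible_from_seed(self):
        corpus, store = _toy_corpus_and_labels()
        spec = SplitSpec(negative_cap=80, seed=7)
        a_train, a_val = build_datasets(corpus, store, spec, TOPICS)
        b_train, b_val = build_datasets(corpus, store, spec, TOPICS)
        assert a_train.article_ids == b_train.article_ids
        assert a_val.article_ids == b_val.article_ids
        assert np.array_equal(a_train.Y, b_train.Y)

    def test_zero_positives_raise(self):
        corpus, store = _toy_corpus_and_labels(n_pos=0, n_neg=30)
        with pytest.raises(ValueError, match="untrainable"):
            build_datasets(corpus, store, SplitSpec(seed=0), TOPICS)

    def test_reported_positive_ratio_of_production_counts(self):
        # the enriched production-scale bookkeeping: 6512 positives over a
        # 100,000-negative training pool is a 6.11% positive ratio
        assert positive_ratio_percent(6512, 100_000) == pytest.approx(6.11, abs=0.005)


class TestHeadAndSchedule:
    def test_zero_weight_head_outputs_half_everywhere(self):
        head = SigmoidMLP(np.zeros((8, 4)), np.zeros(4), np.zeros((4, 6)), np.zeros(6))
        probs = head.forward(np.random.default_rng(0).normal(size=(5, 8)))
        assert np.allclose(probs, 0.5)

    def test_probabilities_strictly_inside_unit_interval(self):
        head = SigmoidMLP.init(8, 16, 6, seed=1)
        probs = head.forward(np.random.default_rng(1).normal(size=(20, 8)) * 10)
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_bce_loss_nonnegative(self):
        head = SigmoidMLP.init(4, 8, 2, seed=0)
        X = np.random.default_rng(2).normal(size=(10, 4))
        Y = (np.random.default_rng(3).random((10, 2)) < 0.5).astype(float)
        loss, _ = head.loss_and_grads(X, Y)
        assert loss >= 0

    def test_schedule_peaks_at_warmup_boundary_and_ends_at_zero(self):
        total, warmup = 200, 0.05
        values = [linear_warmup_linear_decay(s, total, warmup) for s in range(1, total + 1)]
        boundary = int(np.ceil(warmup * total))
        assert values[boundary - 1] == pytest.approx(1.0)
        assert max(values) == pytest.approx(1.0)
        assert values[-1] == pytest.approx(0.0, abs=1e-12)
        # rises before the boundary, falls after
        assert all(a <= b for a, b in zip(values[: boundary - 1], values[1:boundary]))
        assert all(a >= b for a, b in zip(values[boundary - 1 : -1], values[boundary:]))

    def test_zero_epochs_leaves_model_unchanged_with_empty_history(self):
        head = SigmoidMLP.init(4, 8, 2, seed=0)
        before = {k: v.copy() for k, v in head.params().items()}
        history = train_mlp(
            head, np.zeros((3, 4)), np.zeros((3, 2)), None,
            epochs=0, learning_rate=1e-3, batch_size=2, warmup_fraction=0.1, seed=0,
        )
        assert history == []
        for k, v in head.params().items():
            assert np.array_equal(v, before[k])


class TestTrainingAndPrediction:
    @pytest.fixture(scope="class")
    def trained(self):
        config = GeneratorConfig(
            n_articles=800, prevalence=0.05, duplicate_fraction=0, non_english_fraction=0, seed=31
        )
        corpus, gt = generate_corpus(config)
        result = classify_corpus(corpus, default_rulesets())
        store = LabelStore.from_rule_matrix(result.matrix)
        train, val = build_datasets(corpus, store, SplitSpec(seed=32), TOPICS)
        encoder = HashingDocumentEncoder(dim=512, seed=0)
        model, history = train_classifier(
            train, val, encoder,
            TrainConfig(epochs=25, learning_rate=1e-2, batch_size=32, eval_every_steps=500, seed=0),
        )
        return corpus, gt, model, history

    def test_training_reaches_high_validation_auc(self, trained):
        _, _, _, history = trained
        assert max(h["score"] for h in history) >= 90.0

    def test_history_records_steps_and_losses(self, trained):
        _, _, _, history = trained
        assert all(np.isfinite(h["loss"]) for h in history)
        assert [h["step"] for h in history] == sorted(h["step"] for h in history)

    def test_batching_invariance_of_prediction(self, trained):
        corpus, _, model, _ = trained
        articles = corpus.articles[:16]
        whole = model.predict_proba(articles).to_numpy()
        parts = np.concatenate([model.predict_proba([a]).to_numpy() for a in articles])
        assert np.allclose(whole, parts, atol=1e-10)

    def test_save_load_round_trip(self, trained, tmp_path):
        corpus, _, model, _ = trained
        model.save(tmp_path / "clf")
        loaded = TopicClassifier.load(tmp_path / "clf")
        a = model.predict_proba(corpus.articles[:5]).to_numpy()
        b = loaded.predict_proba(corpus.articles[:5]).to_numpy()
        assert np.allclose(a, b)


class TestEnrichment:
    def test_top_k_rule_negatives_in_probability_order(self):
        probs = pd.DataFrame({1: [0.9, 0.8, 0.7, 0.6, 0.5]}, index=[f"a{i}" for i in range(5)])
        store = LabelStore()
        for i in range(5):
            store.set_label(f"a{i}", 1, "positive" if i == 0 else "negative", "rule")
        with pytest.warns(UserWarning):
            # only 4 negatives exist; asking for 500 warns and returns all
            assert select_enrichment_candidates(probs, store, k=500)[1] == ["a1", "a2", "a3", "a4"]
        candidates = select_enrichment_candidates(probs, store, k=3)
        assert candidates[1] == ["a1", "a2", "a3"]

    def test_equal_probabilities_rank_by_stable_id_order(self):
        probs = pd.DataFrame({1: [0.5] * 4}, index=["a3", "a1", "a2", "a0"])
        store = LabelStore()
        for aid in probs.index:
            store.set_label(aid, 1, "negative", "rule")
        assert select_enrichment_candidates(probs, store, k=2)[1] == ["a0", "a1"]

    def test_k_zero_gives_empty_lists(self):
        probs = pd.DataFrame({1: [0.5]}, index=["a0"])
        store = LabelStore()
        store.set_label("a0", 1, "negative", "rule")
        assert select_enrichment_candidates(probs, store, k=0) == {1: []}


class TestInferenceFilter:
    def test_union_of_threshold_and_rank(self):
        probs = pd.DataFrame({1: [0.99, 0.96, 0.70, 0.20]}, index=["a0", "a1", "a2", "a3"])
        kept = apply_inference_filter(probs, {1: 1}, threshold=0.95, multiplier=3)
        assert [e.article_id for e in kept[1]] == ["a0", "a1", "a2"]

    def test_no_rules_positives_and_low_scores_keeps_nothing(self):
        probs = pd.DataFrame({1: [0.5, 0.3]}, index=["a0", "a1"])
        assert apply_inference_filter(probs, {1: 0})[1] == []

    def test_all_above_threshold_kept_regardless_of_n(self):
        probs = pd.DataFrame({1: [0.99, 0.97, 0.96]}, index=["a0", "a1", "a2"])
        kept = apply_inference_filter(probs, {1: 0})
        assert len(kept[1]) == 3
        assert all(e.by_threshold for e in kept[1])

    def test_lowering_threshold_never_shrinks_kept_set(self):
        rng = np.random.default_rng(5)
        probs = pd.DataFrame({1: rng.random(50)}, index=[f"a{i:02d}" for i in range(50)])
        previous: set = set()
        for threshold in (0.95, 0.8, 0.5, 0.2):
            kept = {e.article_id for e in apply_inference_filter(probs, {1: 3}, threshold)[1]}
            assert previous <= kept
            previous = kept
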