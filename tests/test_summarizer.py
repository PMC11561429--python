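"""Greedy oracle construction, masked dual-head training, summary selection, ROUGE eval."""

import numpy as np
import pytest

from newswatch.encoders import HashingSentenceEncoder
from newswatch.metrics import rouge_n
from newswatch.nn import SigmoidMLP
from newswatch.summarizer import (
    DualHeadSummarizer,
    LabelValidationError,
    OracleLabels,
    SummarizerTrainConfig,
    _select_top_k,
    build_training_labels,
    evaluate_summaries,
    greedy_oracle_labels,
    summarize,
    train_summarizer,
)
from newswatch.synthetic import GeneratorConfig, generate_corpus, generate_highlights


class TestGreedyOracle:
    def test_identical_highlights_self_match(self):
        source = ["the strike began today.", "officials met.", "talks continue tomorrow."]
        assert set(greedy_oracle_labels(source, [source[0], source[2]])) == {0, 2}

    def test_prefers_sentence_sharing_tokens(self):
        source = ["alpha beta gamma delta", "epsilon zeta eta"]
        highlight = ["beta gamma delta"]
        assert greedy_oracle_labels(source, highlight) == (0,)

    def test_already_selected_sentences_are_skipped(self):
        source = ["a b c", "a b d"]
        selected = greedy_oracle_labels(source, ["a b c", "a b c"])
        assert set(selected) == {0, 1}

    def test_tie_resolves_to_earliest_index(self):
        source = ["x y z", "x y z"]
        assert greedy_oracle_labels(source, ["x y"]) == (0,)

    def test_empty_source_is_an_error(self):
        with pytest.raises(ValueError):
            greedy_oracle_labels([], ["h"])

    def test_matches_exhaustive_per_step_search_on_small_instances(self):
        rng = np.random.default_rng(19)
        words = list("abcdefghij")
        for _ in range(200):
            n_src = int(rng.integers(1, 9))
            source = [" ".join(rng.choice(words, size=rng.integers(2, 8))) for _ in range(n_src)]
            highlights = [" ".join(rng.choice(words, size=rng.integers(2, 6)))
                          for _ in range(rng.integers(1, 4))]
            got = greedy_oracle_labels(source, highlights)
            # independent exhaustive per-step argmax
            expected, chosen = [], set()
            for h in highlights:
                scores = [(-rouge_n(s, h, 1), i) for i, s in enumerate(source) if i not in chosen]
                if scores:
                    best = min(scores)[1]
                    expected.append(best)
                    chosen.add(best)
            assert list(got) == expected


class TestBuildTrainingLabels:
    def test_rule_only_article(self):
        labels = build_training_labels({"a": [1, 4]}, {}, {"a": 6})
        assert labels["a"].topic_indices == {1, 4}
        assert labels["a"].global_indices is None

    def test_both_sources_present(self):
        labels = build_training_labels({"a": [1]}, {"a": [0, 2]}, {"a": 5})
        assert labels["a"].topic_indices == {1}
        assert labels["a"].global_indices == {0, 2}

    def test_human_selection_of_four_sentences_rejected(self):
        with pytest.raises(LabelValidationError, match="1-3"):
            build_training_labels({}, {"a": [0, 1, 2, 3]}, {"a": 8})

    def test_out_of_range_index_names_article(self):
        with pytest.raises(LabelValidationError, match="article a"):
            build_training_labels({"a": [9]}, {}, {"a": 3})

    def test_article_with_neither_source_excluded(self):
        assert build_training_labels({"a": []}, {}, {"a": 3}) == {}


class TestMaskedTraining:
    def test_absent_head_receives_exactly_zero_gradient(self):
        head = SigmoidMLP.init(6, 8, 2, seed=0)
        X = np.random.default_rng(0).normal(size=(5, 6))
        Y = np.zeros((5, 2))
        Y[1, 0] = 1.0
        mask = np.zeros((5, 2))
        mask[:, 0] = 1.0  # topic head (column 1) entirely unlabeled
        _, grads = head.loss_and_grads(X, Y, mask)
        assert np.allclose(grads["W2"][:, 1], 0.0)
        assert grads["b2"][1] == 0.0
        assert np.any(grads["W2"][:, 0] != 0.0)

    def test_training_with_only_global_labels_runs(self):
        encoder = HashingSentenceEncoder(dim=32, seed=0)
        articles = {"a": ["one sentence here.", "another sentence text."]}
        labels = {"a": OracleLabels("a", global_indices=frozenset({0}))}
        model, history = train_summarizer(
            articles, labels, encoder,
            SummarizerTrainConfig(epochs=2, learning_rate=1e-2, seed=0),
        )
        assert model.score_sentences(articles["a"]).shape == (2, 2)

    def test_no_labeled_articles_is_an_error(self):
        encoder = HashingSentenceEncoder(dim=16, seed=0)
        with pytest.raises(ValueError, match="nothing to train"):
            train_summarizer({"a": ["s."]}, {}, encoder, SummarizerTrainConfig(epochs=1))

    def test_zero_epochs_leaves_head_unchanged(self):
        encoder = HashingSentenceEncoder(dim=16, seed=0)
        labels = {"a": OracleLabels("a", global_indices=frozenset({0}))}
        model, history = train_summarizer(
            {"a": ["sentence one.", "sentence two."]}, labels, encoder,
            SummarizerTrainConfig(epochs=0, seed=3),
        )
        fresh = DualHeadSummarizer.init(encoder, 768, seed=3)
        for k in ("W1", "b1", "W2", "b2"):
            assert np.array_equal(model.head.params()[k], fresh.head.params()[k])


class TestSummarize:
    def test_selection_by_summed_scores(self):
        # sums: 1.7, 0.2, 1.6, 0.3 -> top-3 = {0, 2, 3}
        probs = np.array([[0.9, 0.8], [0.1, 0.1], [0.7, 0.9], [0.2, 0.1]])
        assert _select_top_k(probs, 3) == [0, 2, 3]

    def test_short_article_returns_all_sentences(self):
        model = DualHeadSummarizer.init(HashingSentenceEncoder(dim=16, seed=0), 8, seed=0)
        summary = summarize(model, "a", ["first.", "second."], k=3)
        assert summary.indices == (0, 1)

    def test_uniform_scores_select_leading_sentences(self):
        probs = np.full((5, 2), 0.5)
        assert _select_top_k(probs, 3) == [0, 1, 2]

    def test_emitted_sentences_verbatim_in_document_order(self):
        model = DualHeadSummarizer.init(HashingSentenceEncoder(dim=32, seed=1), 16, seed=1)
        sentences = [f"sentence number {i} text." for i in range(8)]
        summary = summarize(model, "a", sentences, k=3)
        assert summary.indices == tuple(sorted(summary.indices))
        assert all(s in sentences for s in summary.sentences)
        assert len(summary.indices) == 3

    def test_empty_article_gives_empty_summary(self):
        model = DualHeadSummarizer.init(HashingSentenceEncoder(dim=16, seed=0), 8, seed=0)
        assert summarize(model, "a", []).indices == ()


class TestEvaluateSummaries:
    def test_identical_prediction_scores_100(self):
        _, means = evaluate_summaries({"a": "the strike began"}, {"a": "the strike began"})
        assert means["mean"] == pytest.approx(100.0)

    def test_disjoint_vocabulary_scores_zero(self):
        _, means = evaluate_summaries({"a": "alpha beta"}, {"a": "gamma delta"})
        assert means["mean"] == pytest.approx(0.0)

    def test_empty_reference_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty reference"):
            per_article, _ = evaluate_summaries({"a": "text", "b": "text"}, {"a": "", "b": "text"})
        assert list(per_article) == ["b"]


class TestHighlightsAndRecovery:
    def test_noise_free_highlights_recover_source_indices(self):
        config = GeneratorConfig(n_articles=60, prevalence=0.1, duplicate_fraction=0,
                                 non_english_fraction=0, seed=41)
        _, gt = generate_corpus(config)
        checked = 0
        for aid, truth in gt.articles.items():
            keys = sorted({i for idxs in truth.key_sentences.values() for i in idxs})
            highlights, sources = generate_highlights(list(truth.sentences), keys, dropout=0.0, seed=1)
            oracle = greedy_oracle_labels(list(truth.sentences), highlights)
            assert sorted(oracle) == sources
            checked += 1
        assert checked == len(gt.articles)

    def test_planted_key_sentences_recovered_top1_on_held_out(self):
        config = GeneratorConfig(n_articles=1200, prevalence=0.05, duplicate_fraction=0,
                                 non_english_fraction=0, seed=43)
        _, gt = generate_corpus(config)
        positives = sorted(aid for aid, t in gt.articles.items() if t.topics)
        split = int(0.8 * len(positives))
        train_ids, test_ids = positives[:split], positives[split:]
        sents = {aid: list(gt.articles[aid].sentences) for aid in positives}

        def keys(aid):
            return sorted({i for idxs in gt.articles[aid].key_sentences.values() for i in idxs})

        labels = build_training_labels(
            {aid: keys(aid) for aid in train_ids},
            {aid: keys(aid)[:3] for aid in train_ids},
            {aid: len(sents[aid]) for aid in train_ids},
        )
        model, _ = train_summarizer(
            {aid: sents[aid] for aid in train_ids}, labels,
            HashingSentenceEncoder(dim=512, seed=0),
            SummarizerTrainConfig(epochs=15, learning_rate=1e-2, batch_size=64, seed=0),
        )
        hits = 0
        for aid in test_ids:
            probs = model.score_sentences(sents[aid])
            top1 = int(np.argmax(probs.sum(axis=1)))
            hits += top1 in set(keys(aid))
        assert hits / len(test_ids) >= 0.9
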