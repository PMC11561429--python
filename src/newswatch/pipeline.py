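"""End-to-end orchestration: raw corpus -> per-(topic, country) summary pools.

Stage order is fixed: deduplicate -> language filter -> rule classification ->
(optional) neural classifier with hybrid inference filter -> country
assignment -> (optional) extractive summarization -> grouping.  Every stage
records input/output counts, seeds and wall time in a run manifest; one
global seed deterministically derives per-stage seeds, so a rerun with the
same inputs and config reproduces identical outputs.

Pool membership under the default policy is rules-positives plus articles the
classifier scores above the probability threshold; articles kept only by the
top-``multiplier*N`` rank rule are exported as review candidates (the label
enrichment loop) rather than pooled directly.  Set
``pool_policy="filter_union"`` to pool the raw hybrid filter output instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Corpus, filter_language, deduplicate_by_title, segment_corpus
from .encoders import HashingDocumentEncoder, HashingSentenceEncoder
from .geo_assign import CountryGazetteer, assign_country
from .rules_engine import TopicRuleSet, classify_corpus, default_rulesets, parse_ruleset
from .summarizer import (
    Summary,
    SummarizerTrainConfig,
    build_training_labels,
    summarize,
    train_summarizer,
)
from .topic_classifier import (
    LabelStore,
    SplitSpec,
    TrainConfig,
    apply_inference_filter,
    build_datasets,
    select_enrichment_candidates,
    train_classifier,
)

logger = logging.getLogger(__name__)


@dataclass
class ClassifierStage:
    enabled: bool = True
    train: TrainConfig = field(default_factory=TrainConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    threshold: float = 0.95
    multiplier: int = 3
    pool_policy: str = "threshold_or_rules"  # or "filter_union"
    enrichment_k: int = 500
    encoder_dim: int = 64


@dataclass
class SummarizerStage:
    enabled: bool = True
    train: SummarizerTrainConfig = field(default_factory=SummarizerTrainConfig)
    k: int = 3
    encoder_dim: int = 64


@dataclass
class PipelineConfig:
    rulesets: Sequence[TopicRuleSet] | str | Path | None = None  # None -> packaged defaults
    dedup: bool = True
    dedup_normalization: str = "casefold_trim"
    language_filter: bool = True
    keep_language: str = "en"
    classifier: ClassifierStage = field(default_factory=ClassifierStage)
    summarizer: SummarizerStage = field(default_factory=SummarizerStage)
    seed: int = 0
    output_dir: str | Path | None = None


@dataclass(frozen=True)
class PoolEntry:
    article_id: str
    country: str
    country_method: str
    summary: Summary | None


@dataclass
class PipelineResult:
    #: (topic_id, country_code) -> pool entries
    pools: dict[tuple[int, str], list[PoolEntry]]
    manifest: dict
    review_candidates: dict[int, list[str]]

    def topic_pool(self, topic_id: int) -> list[PoolEntry]:
        return [e for (t, _), entries in self.pools.items() if t == topic_id for e in entries]


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, Path):
            return str(o)
        if hasattr(o, "__dict__"):
            return o.__dict__
        return repr(o)

    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("split", "classifier", "summarizer", "misc")
    return {name: int(child.generate_state(1)[0] % (2**31)) for name, child in zip(names, children)}


def run_pipeline(
    config: PipelineConfig,
    corpus: Corpus,
    human_summary_annotations: Mapping[str, Sequence[int]] | None = None,
) -> PipelineResult:
    """Run the full flow on *corpus* (see module docstring for stage order)."""
    t0 = time.perf_counter()
    if config.rulesets is None:
        rulesets = default_rulesets()
    elif isinstance(config.rulesets, (str, Path)):
        path = Path(config.rulesets)
        if not path.exists():
            raise FileNotFoundError(f"rule file not found before any stage ran: {path}")
        rulesets = parse_ruleset(path)
    else:
        rulesets = tuple(config.rulesets)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": [],
    }

    def record(stage: str, n_in: int, n_out: int, started: float, **extra) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "input_count": n_in,
                "output_count": n_out,
                "wall_seconds": round(time.perf_counter() - started, 4),
                **extra,
            }
        )

    current = corpus
    if config.dedup:
        ts = time.perf_counter()
        n_in = len(current)
        current = deduplicate_by_title(current, config.dedup_normalization)
        record("deduplicate", n_in, len(current), ts)
    if config.language_filter:
        ts = time.perf_counter()
        n_in = len(current)
        current = filter_language(current, keep=config.keep_language)
        record("language_filter", n_in, len(current), ts)

    ts = time.perf_counter()
    sentence_index = segment_corpus(current)
    rules_result = classify_corpus(current, rulesets, sentence_index=sentence_index)
    topic_ids = [rs.topic_id for rs in rulesets]
    rules_positive: dict[int, set[str]] = {
        t: set(rules_result.matrix.index[rules_result.matrix[t]]) for t in topic_ids
    }
    record(
        "rules",
        len(current),
        sum(len(v) for v in rules_positive.values()),
        ts,
        per_topic_counts=rules_result.report.counts,
    )

    review_candidates: dict[int, list[str]] = {t: [] for t in topic_ids}
    kept_by_topic: dict[int, set[str]] = {t: set(rules_positive[t]) for t in topic_ids}
    if config.classifier.enabled and len(current) > 0:
        ts = time.perf_counter()
        labels = LabelStore.from_rule_matrix(rules_result.matrix)
        split = SplitSpec(
            train_fraction=config.classifier.split.train_fraction,
            negative_cap=config.classifier.split.negative_cap,
            seed=seeds["split"],
        )
        train_cfg = TrainConfig(**{**config.classifier.train.__dict__, "seed": seeds["classifier"]})
        train_set, val_set = build_datasets(current, labels, split, topic_ids)
        encoder = HashingDocumentEncoder(dim=config.classifier.encoder_dim, seed=seeds["classifier"])
        model, history = train_classifier(train_set, val_set, encoder, train_cfg)
        probs = model.predict_proba(list(current))
        kept = apply_inference_filter(
            probs,
            {t: len(rules_positive[t]) for t in topic_ids},
            threshold=config.classifier.threshold,
            multiplier=config.classifier.multiplier,
        )
        for t in topic_ids:
            if config.classifier.pool_policy == "filter_union":
                kept_by_topic[t] |= {e.article_id for e in kept[t]}
            else:
                kept_by_topic[t] |= {e.article_id for e in kept[t] if e.by_threshold}
        review_candidates = select_enrichment_candidates(
            probs, labels, k=config.classifier.enrichment_k
        )
        record(
            "classifier",
            len(current),
            sum(len(v) for v in kept_by_topic.values()),
            ts,
            best_val_macro_auc=max((h["score"] for h in history if h.get("score") is not None), default=None),
        )

    pooled_ids = sorted(set().union(*kept_by_topic.values())) if kept_by_topic else []
    articles_by_id = {a.article_id: a for a in current}

    ts = time.perf_counter()
    gazetteer = CountryGazetteer.default()
    assignments = {
        aid: assign_country(articles_by_id[aid], sentence_index[aid], gazetteer)
        for aid in pooled_ids
    }
    record("country_assignment", len(pooled_ids), len(assignments), ts)

    summaries: dict[str, Summary] = {}
    if config.summarizer.enabled and pooled_ids:
        ts = time.perf_counter()
        sentence_encoder = HashingSentenceEncoder(
            dim=config.summarizer.encoder_dim, seed=seeds["summarizer"]
        )
        article_sentences = {
            aid: sentence_index[aid].sentence_texts(articles_by_id[aid].body) for aid in pooled_ids
        }
        rule_pseudo = {}
        for aid in pooled_ids:
            matched: set[int] = set()
            for t in topic_ids:
                match = rules_result.matches.get((aid, t))
                if match is not None and match.passed:
                    matched.update(match.matched_sentence_indices)
            if matched:
                rule_pseudo[aid] = sorted(matched)
        labels_map = build_training_labels(
            rule_pseudo,
            dict(human_summary_annotations or {}),
            {aid: len(article_sentences[aid]) for aid in pooled_ids},
        )
        if labels_map:
            sum_cfg = SummarizerTrainConfig(
                **{**config.summarizer.train.__dict__, "seed": seeds["summarizer"]}
            )
            model, _ = train_summarizer(article_sentences, labels_map, sentence_encoder, sum_cfg)
            for aid in pooled_ids:
                summaries[aid] = summarize(model, aid, article_sentences[aid], k=config.summarizer.k)
        else:
            logger.warning("summarizer stage: no labeled articles, skipping")
        record("summarizer", len(pooled_ids), len(summaries), ts, labeled_articles=len(labels_map))

    pools: dict[tuple[int, str], list[PoolEntry]] = {}
    for t in topic_ids:
        for aid in sorted(kept_by_topic[t]):
            assignment = assignments[aid]
            entry = PoolEntry(
                article_id=aid,
                country=assignment.country,
                country_method=assignment.method,
                summary=summaries.get(aid),
            )
            pools.setdefault((t, assignment.country), []).append(entry)

    manifest["total_wall_seconds"] = round(time.perf_counter() - t0, 4)
    manifest["pool_sizes"] = {f"{t}/{c}": len(v) for (t, c), v in sorted(pools.items())}
    result = PipelineResult(pools=pools, manifest=manifest, review_candidates=review_candidates)
    if config.output_dir is not None:
        _write_outputs(result, Path(config.output_dir))
    return result


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    tmp.replace(path)


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = []
    for (topic_id, country), entries in sorted(result.pools.items()):
        for entry in entries:
            lines.append(
                json.dumps(
                    {
                        "topic_id": topic_id,
                        "country": country,
                        "article_id": entry.article_id,
                        "country_method": entry.country_method,
                        "summary_indices": list(entry.summary.indices) if entry.summary else None,
                        "summary_sentences": list(entry.summary.sentences) if entry.summary else None,
                    },
                    ensure_ascii=False,
                )
            )
    _atomic_write(out_dir / "pools.jsonl", "\n".join(lines) + ("\n" if lines else ""))
    _atomic_write(out_dir / "manifest.json", json.dumps(result.manifest, indent=2, default=str))


# ---------------------------------------------------------------------------
# Report tables


def export_report_tables(
    rules_report,
    out_dir: str | Path,
    classifier_metrics: Mapping[int, Mapping[str, float | None]] | None = None,
    rouge_by_topic: Mapping[int, float] | None = None,
) -> dict[str, Path]:
    """Write the three report tables (rule bookkeeping, ranking metrics, ROUGE).

    Undefined cells (single-class metrics) render as ``NA``.  Mean rows are
    recomputed from the per-topic values.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    topics = sorted(rules_report.counts)
    rows = []
    for t in topics:
        row = {
            "topic": t,
            "n_positive": rules_report.counts[t],
            "positive_rate_percent": round(rules_report.rates_percent[t], 4),
        }
        for u in topics:
            value = rules_report.overlap.loc[t, u]
            row[f"overlap_topic_{u}"] = "NA" if pd.isna(value) else int(value)
        rows.append(row)
    table1 = pd.DataFrame(rows)
    mean_row = {
        "topic": "mean",
        "n_positive": round(float(np.mean([rules_report.counts[t] for t in topics])), 2),
        "positive_rate_percent": round(rules_report.mean_rate_percent, 4),
    }
    table1 = pd.concat([table1, pd.DataFrame([mean_row])], ignore_index=True)
    path1 = out_dir / "rules_report.csv"
    table1.to_csv(path1, index=False)
    written["rules_report"] = path1

    if classifier_metrics is not None:
        rows = []
        metric_keys = ["roc_auc", "pr_auc", "precision_at_2N", "precision_at_10N", "recall_at_2N", "recall_at_10N"]
        for t in sorted(classifier_metrics):
            row = {"topic": t}
            for key in metric_keys:
                value = classifier_metrics[t].get(key)
                row[key] = "NA" if value is None else round(value, 2)
            rows.append(row)
        mean_row = {"topic": "mean"}
        for key in metric_keys:
            values = [
                classifier_metrics[t].get(key)
                for t in classifier_metrics
                if classifier_metrics[t].get(key) is not None
            ]
            mean_row[key] = round(float(np.mean(values)), 2) if values else "NA"
        table2 = pd.DataFrame(rows + [mean_row])
        path2 = out_dir / "classifier_report.csv"
        table2.to_csv(path2, index=False)
        written["classifier_report"] = path2

    if rouge_by_topic is not None:
        rows = [{"topic": t, "rouge_mean": round(v, 2)} for t, v in sorted(rouge_by_topic.items())]
        values = [v for v in rouge_by_topic.values()]
        rows.append({"topic": "mean", "rouge_mean": round(float(np.mean(values)), 2) if values else "NA"})
        table3 = pd.DataFrame(rows)
        path3 = out_dir / "summarization_report.csv"
        table3.to_csv(path3, index=False)
        written["summarization_report"] = path3

    return written
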