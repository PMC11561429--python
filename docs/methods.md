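# Methods

This note documents the models and procedures implemented in `newswatch`, the
choices made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Problem setting

A continuously aggregated news feed (millions of articles, thousands of
outlets) must be narrowed to the articles relevant to a fixed taxonomy of
surveillance topics — here six health-workforce topics: (1) workforce policy
and investment, (2) health-worker education, (3) health-worker vaccination,
(4) strikes and industrial actions, (5) health-worker mental health, (6)
health-worker infections and deaths.  Relevant articles are pooled per
(topic, country) and summarized extractively so human analysts can write
reports.  Positives are rare (well below 1% per topic), human labels are
expensive, and hallucination is unacceptable in the summaries — three
constraints that shape every design decision below.

## Corpus cleaning

Deduplication is keyed on the article **title** because syndicated wire
stories recur under identical headlines.  Default normalization is casefold +
whitespace-collapse (`exact` available); within a duplicate group the
earliest-dated article survives, first-seen breaking ties and undated
articles sorting last.  Both choices are conventions fixed for determinism;
the title-key definition itself does not dictate them.

Language filtering is pluggable (`text -> language code`).  The shipped
detector scores stopword-profile hits for {en, fr, es, de} and takes the
argmax; it is adequate for feed-level screening, not a general language
identifier, and any external detector can be injected.  Sentence
segmentation is likewise pluggable; the default splits on terminal
punctuation runs followed by whitespace, guarded by an abbreviation list, and
returns 0-based half-open character spans (the offset convention used
everywhere in the package).

## Rule engine

A topic's rule set is an ordered list of predicate trees; the article passes
the topic iff **every** rule passes (pure conjunction, order irrelevant).
Leaves are MATCH predicates with a scope (TITLE, BODY, SENTENCE), a keyword
list, and `min_distinct` — the number of **distinct** keyword phrases (not
total occurrences) that must appear.  SENTENCE scope passes when at least one
individual sentence meets the count; every such sentence index is collected
and later reused as a topic-focused summarization pseudolabel.  Exclusion
criteria are expressed uniformly as NOT-wrapped predicates, so one evaluator
covers inclusive and exclusive rules.

Matching is case-insensitive whole-phrase matching on token boundaries:
"nurse" does not fire inside "nursery".  Tokens are maximal alphanumeric runs
(internal apostrophes kept).  The evaluator is verified exactly — truth value
and matched-sentence sets — against an independent regex-based brute-force
evaluator on 1,000 random predicate trees (depth ≤ 4) in the acceptance
suite.

The packaged rule file (`data/default_rules.yaml`) is illustrative: one
inclusion rule per topic (sentence or title scope over the topic's keyword
list) plus one exclusion rule.  Production rule sets are authored by domain
experts and supplied as user configuration; the DSL, not the shipped
keywords, is the deliverable.

## Country assignment

Feed-level tagging yields ~2 candidate countries per article; pooling needs
exactly one.  The cascade: (i) if any candidate's surface name (gazetteer:
ISO-3166 codes, canonical names, common aliases) occurs in the title or first
body sentence, take the most frequently mentioned candidate — ties go to the
earliest first occurrence; (ii) otherwise concatenate location/person-like
entity strings from the body (pluggable NER; default is a capitalized-run
heuristic) and take the candidate whose encoded canonical name maximizes
cosine similarity with the encoded entity string — ties go to the
lexicographically smallest code; (iii) with no entities at all, keep the
first candidate tag flagged `unresolved`.  First-sentence mentions are
restricted to the candidate tag set rather than any country on earth, since
the task is selection among the feed's candidates, not open-world
geolocation.

## Encoders

Every model-facing component accepts an encoder contract: `encode(text)`
returns a fixed-dimension finite vector, deterministically.  The shipped
implementation is a seeded signed-hashing bag-of-tokens projector (keyed
blake2b hashing, so stable across processes), L2-normalized; the document
variant concatenates title, a separator token, and body, truncating the body
tail at 512 tokens to mirror the fixed input window of transformer backbones.
A pretrained contextual encoder drops into the same contract for production
deployments; all shipped tests and examples run on the hashing encoders.

## Multilabel topic classifier

Architecture: encoder vector → affine(d→768) → ReLU → affine(768→6) →
element-wise sigmoid; outputs are independent per-topic probabilities (no
cross-topic normalization).  Loss is multilabel binary cross-entropy.

Training data come from the rule engine's hard assignments, held in a
provenance-tracking label store (`rule`, `human_confirmed`,
`human_enriched`).  A seeded 90/10 train/validation split is drawn once; the
training side keeps **all** positives and at most 100,000 sampled negatives,
while validation is never rebalanced so its metrics reflect deployment class
balance.  Optimization is Adam with linear warmup over the first 5% of steps
then linear decay to zero, evaluating every 5,000 steps with early stopping
on validation macro ROC-AUC (macro over topics; a topic with single-class
validation labels is excluded with a warning).  The dataclass defaults
(5 epochs, learning rate 1e-5, batch 4) are the fine-tuning schedule
appropriate to a pretrained transformer backbone; from-scratch training of
the head over hashing features uses an explicitly passed desk-scale config
(learning rate ~1e-2, batch 32), a standard Adam rate for small MLPs.

The enrichment loop is two-phase and file-based: after a first training
round, the top-500 highest-scored rule-negative articles per topic are
exported to a review CSV; human verdicts re-enter the label store as
`human_enriched` and the classifier is retrained.  At inference a topic
keeps `{p > 0.95} ∪ top-3N by p` (N = rules-positive count), each kept
article carrying reason flags.  The union is monotone in the threshold.

In the end-to-end pipeline the default pool policy admits rules-positives
and threshold-exceeders, routing rank-only keeps to the review export
instead of the pools: the rank component exists to surface candidate false
negatives for human confirmation, and pooling 3N articles unreviewed would
dilute pool precision to ~N/3N by construction.  `pool_policy="filter_union"`
pools the raw union for deployments that want recall over precision.

## Extractive summarizer

One sentence encoder feeds a shared hidden layer with two sigmoid heads:
`p_global` (is this sentence part of a general summary?) supervised by 1–3
human-selected sentences per article, and `p_topic` (is it topic-key?)
supervised by the rule engine's matched-sentence pseudolabels.  An article
may carry either or both label sources; the per-head binary cross-entropy is
masked where a source is missing, so an absent head receives exactly zero
gradient (asserted in tests).  Training runs 10 epochs with Adam at 1e-5
(production default; desk scale ~1e-2 as above), 10% linear warmup then
decay, early stopping on the validation mean of ROUGE-1/2/L between the
predicted top-3 summary and the concatenated human selection.

For generic news-highlights pretraining, extractive oracle labels are built
greedily: each highlight, in order, is matched to the not-yet-selected source
sentence maximizing ROUGE-1 (F1 by default, recall via flag; ties to the
earliest index).  Each source sentence can be selected at most once.  The
greedy step is verified against exhaustive per-step search on all random
instances with ≤ 8 source sentences.

At inference sentences are ranked by `p_global + p_topic` (ties to the
earlier sentence) and the top `min(3, n)` are emitted **in document order** —
the selected set is identical to the ranking prefix; presenting
source-ordered extracts is the usual readability convention.  Every emitted
sentence is verbatim from the source, which is the point of choosing
extraction over abstractive generation.

## Metrics

All metrics are implemented from their definitions and reported ×100.
ROUGE-N uses clipped n-gram counts over lowercased alphanumeric tokens (no
stemming or stopword removal); ROUGE-L is token-LCS F1.  Fleiss κ uses the
squared-marginal chance term; Gwet AC1 uses
`Pe = (1/(K−1)) Σ_q π̂_q (1−π̂_q)` with π̂ the mean category proportions —
the pair is reported together because sentence-selection annotations are
heavily skewed toward "not selected", which depresses κ but not AC1.  The
agreement unit is one (article, sentence) pair with binary
selected/not-selected categories, the only unitization that makes
constant-rater agreement well-defined for free-form sentence selections.
ROC-AUC is the midrank (Mann-Whitney) statistic; PR-AUC is average precision
with step interpolation (the standard unbiased estimator); Precision@m and
Recall@m break score ties by stable input order.  Cross-checks: scikit-learn
for both AUCs, statsmodels for Fleiss κ, full-matrix DP for LCS, and an
O(n²) pairwise oracle for ROC-AUC.

## Synthetic data: what it shows and what it does not

The generator plants, per article: topic membership (independent Bernoulli
per topic at configurable prevalence — 1–2% in tests, 0.05% in the
`realistic()` preset), key sentences carrying topic keywords (so every
planted positive passes the packaged rules by construction — a generator
invariant, not an empirical finding), exact-title duplicate groups, a true
country whose name appears in the first sentence (probability 0.8) or later
in the body, 0–2 extra candidate tags (mean ~2 tags, matching feed
statistics), a ~1% non-English admixture, and simulated annotators who copy
the ground-truth selection with probability α else select 1–3 random
sentences (α=1 gives κ=100, α=0 chance level).  Everything is
bit-reproducible from the config seed.

Topic vocabularies are disjoint from each other and from the background
vocabulary by default (an overlap knob exists to stress cross-topic false
positives).  Sentences are bags of template tokens, not prose.
Consequently the parameter-recovery results (classifier macro ROC-AUC ≥ 95,
summarizer top-1 key-sentence recovery ≥ 90% held-out, pipeline
precision/recall ≥ 0.9) demonstrate that the training loops, losses, masking,
schedules and selection logic are correct — they say nothing about
performance on real journalistic text, where topic signal is distributed,
ambiguous and correlated with confounds.  Real-corpus performance depends on
the pretrained encoder and expert rule sets that production deployments
supply.

## Problem sizes and numerical choices

Shipped tests and the acceptance suite run at desk scale: corpora of
400–2,000 articles, hashing encoders of dimension 256–1,024, 10–30 training
epochs — sizes chosen so the full suite completes in a few minutes on one
CPU while leaving comfortable statistical margins.  Numerical details: BCE
uses an epsilon of 1e-12 inside the logs; sigmoid is computed in the
numerically stable split form; Adam uses (0.9, 0.999, 1e-8); the LR
multiplier is exactly 1 at `ceil(warmup_fraction·total)` steps and exactly 0
at the final step; ranking ties anywhere in the package resolve by stable
article-id or sentence-position order so reruns are identical.

## Known limitations

* The default language detector and capitalized-run NER are heuristics;
  both are pluggable and should be replaced for production use.
* The rule DSL deliberately excludes regular expressions, stemming and fuzzy
  matching; keyword lists must anticipate inflected forms.
* Probabilities are uncalibrated; the 0.95 inference threshold is a ranking
  device, not a calibrated confidence.
* Sub-national geolocation and disambiguation of city/country homonyms are
  out of scope.
* Agreement statistics are point estimates; no confidence intervals are
  provided.
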