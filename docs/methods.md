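# Methods

This note records the modeling assumptions, default parameters, and design
choices behind `foodsignal`, and what the synthetic experiments do and do
not demonstrate.

## Collection and preprocessing

The collection stage deliberately over-collects: a tweet is retained when
its lowercased text contains any of nine keyword phrases as a **plain
substring** ("stomach" matches "stomachache"). Substring matching
maximizes recall; precision is the classifier's job, not the filter's.
Very ambiguous terms ("sick", "fever") are excluded from the default list
because they are dominated by non-foodborne illness. Preprocessing drops
retweets (metadata flag when present, else the `RT @` text prefix — the
flag is not always populated in exports), strips `http(s)://` URL tokens
only (bare-domain detection is noisy and unspecified), collapses
whitespace, and drops records that become empty. Up to 50% malformed lines
in an input file are tolerated and reported; beyond that the file is
treated as broken and reading fails with the first offending line, since a
mostly-unreadable file usually indicates a format mismatch rather than
scattered corruption.

## Crowd quality control

Tweets are published in batches (500 by default) with a per-worker cap of
10 annotations per batch. Each annotation is scored against its peers on
the same tweet:

    sim(a, p) = 1/2 · token agreement + 1/2 · (1 − |score_a − score_p| / 5)

averaged over peers, where token agreement is the fraction of word tokens
assigned the same entity-type-or-O by both workers. Annotations with mean
similarity below 0.6 are rejected and the tweet queued for relabeling.
The equal weighting of the span task and the score task is our
concretization — the agreement algorithm this protocol descends from is
published only as pseudocode — and it is isolated behind a single function
so alternatives can be swapped. Workers with ≥ 3 processed annotations of
which ≥ 50% were rejected are blocked from later batches; these two
thresholds are chosen to block a uniformly random labeler within its first
batch while tolerating one-off mistakes by honest workers.

Agreement is reported as Krippendorff's alpha for nominal data, computed
over token-level units: a unit is one word token of one tweet, its values
are the entity-type-or-O labels induced by each worker's spans. Token
units keep alpha well-defined when span boundaries differ between workers.
The implementation builds the coincidence matrix over all pairable values;
a brute-force pairwise-enumeration oracle in the test suite must agree to
1e-12.

## Aggregation

Relevance: each 0–5 score is binarized first (0–2 → No, 3–5 → Yes), then
majority-voted. Binarize-before-vote makes tie behavior explicit; ties
break to No. Token tags: spans are projected onto word tokens (a token
overlapping a span by ≥ 1 character is covered), votes are taken per token
over entity-type-or-O with B/I prefixes stripped, ties break to O, and
prefixes are rebuilt left-to-right (first token of a maximal same-type run
gets B). Both tie rules are conservative toward precision: a false
incident report costs more downstream than a missed highlight. Only spans
the worker marked incident-related contribute to gold tags; unrelated
highlights are retained in the raw data. Word tokens are maximal runs of
word characters (with `#`/`@` prefixes and internal apostrophes) or single
punctuation marks, with recorded character offsets.

The labeled set is split by seeded shuffle and floor cuts at the 80% and
90% marks, giving 2400/300/300 on a 3000-example corpus.

## Dual-task model

One shared encoder; two linear heads. The input is `[CLS] pieces [SEP]`
padded to `max_length` (48); the sentence head reads the [CLS] vector, the
token head reads each word's **first** sub-piece (continuation pieces are
masked from the token loss — the standard convention for sub-word
encoders). The joint objective per example is

    L = CE(relevance) + λ · mean-over-word-tokens CE(tag),   λ = 1 default.

Equal weighting is the natural default absent evidence that either task
should dominate; λ is exposed in `TrainConfig`. The tag space is IOB2 with
four entity types → 9 token classes.

The bundled encoder is a pre-norm transformer (2 layers, 64 hidden, 2
heads, learned positions) over a word+character piece vocabulary built
from the training corpus; unseen words fall back to character pieces so no
input is unrepresentable. It is implemented directly in numpy with
analytic gradients (verified against central differences to 1e-4 relative
error; note finite differences are only trustworthy at step sizes that do
not cross a ReLU kink) and trained with Adam (lr 3e-3), gradient-norm
clipping at 5, batch size 32, in float64. All initialization and
shuffling derive from `TrainConfig.seed`, so runs are bit-reproducible.
Model selection keeps the epoch with the highest validation sentence F1 —
the primary metric — with validation entity F1 as tie-break; without the
tie-break, a corpus whose sentence task saturates in epoch 0 would freeze
an untrained tagger. Non-finite loss raises an error naming the epoch.

Prediction thresholds P(Yes) at 0.5 (ties → Yes) and takes per-token
argmax tags repaired to valid IOB2 (stray I-X → B-X).

A full-scale pretrained tweet encoder is a configuration
(`EncoderConfig(kind="pretrained", identifier=...)`) that requires the
optional torch/transformers stack; the tiny encoder is the default and the
one exercised by the test suite.

## Evaluation

Sentence metrics are the standard four from the confusion table. Entity
metrics use exact-boundary, exact-type matching (no partial credit):
precision = correct/predicted, recall = correct/gold, token accuracy =
exactly-tagged tokens / tokens, and F1 defaults to the harmonic mean of
precision and recall. An alternative `accuracy_recall` F1 variant
(harmonic mean of token accuracy and recall) is exposed as a config
switch for comparability with reports that define entity F1 that way; the
precision–recall form is the default because it is the form consistent
with the headline scores it accompanies. A metric whose denominator is
zero is reported as `None`, never as 0.

## Surveillance

Entities are maximal runs of non-O tags of one type; a B- tag always
starts a new entity, and `other` is accepted on input as an alias for KEY.
The incident filter keeps a tweet only when it is classified Yes **and**
at least one FOOD entity was predicted. Daily series use UTC calendar
days (no timezone is recoverable from the data) and are zero-filled
between the first and last incident. Food-term subsetting uses whole-word
containment on normalized surfaces ("lettuce" matches "romaine lettuce"
but not "lettuces"); substring matching is available via a flag. Top-food
rankings count tweets, not entity occurrences, and break ties
lexicographically. Region filtering requires a present region code
(absent = location unknown = excluded) and matches on the country part of
ISO-like codes such as `US-IL`.

## Synthetic data: what it emulates, what it does not

The generator's three populations mirror the structure of a
keyword-filtered, crowd-labeled corpus: (a) relevant first-person illness
reports built from templates that plant KEY/FOOD/SYM/LOC entities at known
character offsets; (b) hard negatives that contain an illness keyword in a
past, hypothetical, or figurative frame — the documented failure modes of
n-gram classifiers (negation at a distance, "years ago...", "this
deadline is giving me..."); and (c) keyword-free small talk. Default
prevalence of relevant tweets is 0.67, matching the positive fraction
(203/300) of the labeled test split this pipeline is modeled on. Dates
are uniform over the configured range; region codes are present on 80% of
tweets (65% US, 15% non-US) — the generator emulates the located, labeled
subset of a stream, not the raw stream in which only ~1% of posts carry a
usable location.

Simulated workers corrupt gold: scores are drawn uniformly in the
gold-consistent band (Yes → 3–5, No → 0–2) and deviate by ±1–2 with
probability `score_noise`; token labels flip to a random wrong label with
probability `token_flip`; whole spans can be dropped, retyped,
boundary-jittered, or spuriously added; a spammer ignores gold and labels
uniformly at random (expected agreement with any fixed labeling: 1/5 per
token). All randomness flows from one seed through named substreams
(CRC32 of the stream name), so corpus, workers, and outbreaks regenerate
independently.

Outbreak injection adds relevant tweets naming a chosen food inside a
window, scaled to `multiplier` times the corpus's baseline daily rate for
that food; the experiments use a 10× surge, the order of magnitude of a
large multistate produce outbreak.

**Limits.** Template text is far more separable than real tweets: no
typos, slang, or unseen paraphrases, and entity surfaces come from closed
vocabularies. Passing the learning-sanity checks (validation sentence F1
≥ 0.9, exact-match entity F1 ≥ 0.7 within 30 epochs on 1000 tweets)
demonstrates that the architecture, losses, decoding, and plumbing are
correct and that the two tasks train jointly — it says nothing about
real-Twitter accuracy, which requires a pretrained encoder and a real
labeled corpus. Worker noise is conditionally independent given gold;
real annotator errors correlate (shared misreadings), which majority
voting handles less well.

## Experiment sizes

The bundled experiments (test suite and `scripts/acceptance.py`) use
1000-tweet corpora with 5 workers for QC/aggregation/training, 400-tweet
10-trial corpora for spike localization, and exhaustive oracle checks for
the decoding (all tag sequences to length 6) and alpha (100 random
instances) primitives — sizes chosen so the full study re-runs in minutes
on one CPU while keeping every statistical check at ≥ 3σ separation.

## Known limitations

- The peer-similarity formula and the spammer thresholds are this
  package's choices; the protocol they reconstruct did not publish them.
- Alpha is defined on token units; span- or annotation-level alpha would
  give different absolute values (orderings agreed in our experiments).
- `read_conll` reconstructs offsets by single-space joining; original
  spacing is not preserved by the CoNLL format.
- The tiny encoder caps input at 48 pieces; longer tweets are truncated
  (whole words, labels dropped with them).
- No statistical alarm (CUSUM/EARS) is layered on the daily series; spike
  inspection is visual/by-max, as in the study design this follows.
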