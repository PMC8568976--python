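# foodsignal

Social-media surveillance of foodborne illness. Public posts like

> "I got food poisoning from a grilled cheese last night and I've never
> felt so betrayed in my life."

are early, unreported signals of possible outbreaks (an outbreak: two or
more illnesses from the same food). `foodsignal` implements the full
pipeline that turns a keyword-collected stream of such posts into outbreak
analytics:

1. **corpus_io** — read tweet-like records (JSON-lines/CSV), keyword-filter
   them against a nine-phrase symptom/keyword list (`#foodpoisoning`,
   `stomach`, `vomit`, ...), and clean them (retweets and URLs removed).
2. **crowd_qc** — quality control for crowdsourced labels: batched
   publication, per-worker caps, peer-similarity rejection of low-agreement
   annotations, spammer blocking, and token-level agreement measured as
   Krippendorff's alpha.
3. **aggregation** — majority voting of accepted annotations into gold
   labels: 0–5 relevance scores are binarized (0–2 → No, 3–5 → Yes) and
   voted; character spans are projected to word tokens and voted per token
   into IOB2 tag sequences over four entity types (FOOD, LOC, SYM, KEY);
   deterministic 80/10/10 train/validation/test splitting.
4. **model** — the dual-task model: one shared text encoder whose [CLS]
   vector feeds a sentence relevance classifier and whose per-token vectors
   feed a token tag classifier, trained jointly on
   `L = L_sentence + λ · L_token` (both cross-entropies, λ = 1 by default).
   The bundled encoder is a small trainable transformer written in numpy
   (float64, analytic gradients, gradient-checked); a full-scale pretrained
   tweet encoder can be plugged in via the same interface where the
   optional torch/transformers stack is available.
5. **evaluation** — sentence metrics from the 2×2 confusion table and
   entity metrics under exact-boundary, exact-type matching
   (P = correct/predicted, R = correct/gold, F1 = harmonic mean).
6. **surveillance** — BIO decoding (maximal non-O runs of one type are
   entities), the incident filter (kept only if relevance = Yes **and** a
   FOOD entity is present), zero-filled daily count series, top-k food
   rankings, and food-term / region subsetting for case studies.
7. **synthetic** — a generator that plants gold labels at exact character
   offsets: relevant illness reports, hard negatives (past / hypothetical /
   figurative keyword mentions), keyword-free small talk, simulated workers
   of configurable reliability (including spammers), and injectable
   outbreak spikes.

## Worked example

```python
from foodsignal import decode_entities, incident_filter, IncidentRecord

text = ("I got food poisoning from a grilled cheese last night "
        "and I've never felt so betrayed in my life")
tags = ["O", "O", "B-other", "I-other", "O", "O", "B-food", "I-food"] + ["O"] * 11
for e in decode_entities(tags, text.split()):
    print(e.entity_type, repr(e.surface), (e.start, e.end))
```

prints

```
KEY 'food poisoning' (2, 4)
FOOD 'grilled cheese' (6, 8)
```

— the two maximal non-O runs become one KEY (illness keyword) entity and
one FOOD entity (`other` is accepted as an alias for KEY). Because the
sentence is classified Yes and a FOOD entity is present, the incident
filter admits this tweet into the daily outbreak-frequency series.

End to end on synthetic data:

```python
from foodsignal import (GeneratorConfig, WorkerProfile, generate_corpus,
                        simulate_workers, run_qc, aggregate, split_dataset, train)

tweets, gold = generate_corpus(GeneratorConfig(n_tweets=1000, seed=1))
workers = [WorkerProfile(token_flip=0.2)] * 4 + [WorkerProfile(spammer=True)]
anns = simulate_workers(gold, workers, seed=1)
accepted, report = run_qc(tweets, anns, batch_size=200, cap=200)
print(f"alpha {report.alpha_before:.2f} -> {report.alpha_after:.2f}; "
      f"blocked {report.blocked_workers}")
```

prints

```
alpha 0.19 -> 0.40; blocked ['w4']
```

— peer-similarity filtering rejects the spammer's annotations (raising
token-level agreement) and blocks the spammer from later batches.

The same verbs are available from the shell:
`foodsignal synth | filter | qc | aggregate | split | train | predict |
evaluate | surveil` (see `foodsignal --help`).

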