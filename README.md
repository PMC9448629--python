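# tcmrules

Association-rule mining and rule-based constitution classification for
clinical transaction corpora. The package provides:

- **`tcmrules.records`** — typed items (symptom / constitution / regimen /
  disease / drug), validated medical records, JSONL and CSV readers/writers,
  and projections from records to transactions.
- **`tcmrules.preprocess`** — stop-word removal and a discriminability-based
  filter that deletes symptoms shared evenly across constitutions.
- **`tcmrules.fpgrowth`** — single-machine FP-growth: F-list, FP-tree with
  header chains, conditional pattern bases, recursive mining with the
  single-path shortcut. Support is an absolute count.
- **`tcmrules.parallel`** — the partitioned miner: horizontal sharding,
  per-shard local FP-trees mined without cross-shard communication, balanced
  round-robin grouping of F-list items (default 9 groups), and an exact
  merge-then-threshold step. Results are identical for every shard count and
  executor (`serial` or `process_pool`).
- **`tcmrules.rules`** — association-rule generation with support/confidence
  filtering (lift reported, never filtered on).
- **`tcmrules.pipeline`** — the two-stage procedure: mine symptom ⇒
  constitution and constitution ⇒ regimen rule bases, link them on the shared
  constitution (chain score = product of confidences), classify symptom sets
  by confidence-sum scoring, and recommend regimens.
- **`tcmrules.evaluate`** — precision/recall/F1 from one-vs-rest confusion
  counts (with the AIR/DR/CDR bookkeeping) and stratified k-fold
  cross-validation.
- **`tcmrules.synth`** — a seeded corpus generator with planted
  symptom⇒constitution⇒regimen structure, a shared-symptom pool, stop-word
  contamination and label noise, plus `plant_check` to audit what is
  recoverable at given thresholds.

## CLI

One binary with subcommands; `--config file.yaml` supplies defaults that
flags override, and every run writes a `<out>.manifest.json` for replay.

```sh
# generate a synthetic labeled corpus (presets: uniform, paper_like, noise_free)
tcmrules simulate --n 5000 --seed 1 --preset uniform --out records.jsonl --truth truth.json

# mine global frequent itemsets (partitioned miner)
tcmrules mine --records records.jsonl --min-support 20 --shards 4 --groups 9 \
    --projection symptom_constitution --out itemsets.csv

# train the two-stage rule base, classify, recommend
tcmrules train --records records.jsonl --min-support 20 --min-confidence 0.6 --out rulebase.json
tcmrules predict --rulebase rulebase.json --symptoms "thin white moss|ruddy complexion"
tcmrules recommend --rulebase rulebase.json --constitution PDC --top-k 3

# 10-fold cross-validation, or metric formulas on raw counts
tcmrules evaluate --records records.jsonl --k 10 --seed 0 --out metrics.json
tcmrules evaluate --counts TP=996,FP=176,FN=894
```

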