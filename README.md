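# narrascreen

Screening for childbirth-related post-traumatic stress disorder (CB-PTSD)
from free-text birth narratives.

The pipeline labels each narrative from its PCL-5 questionnaire total
(missing items coded 0; total >= 31 is a provisional case), filters out
narratives under 30 words, balances classes by down-sampling, and splits
train/test per class. Train narratives are embedded (any fixed-dimension
embedding backend; a deterministic offline embedder and a content-addressed
cache are included) and expanded into a pairwise training set: all
within-class pairs of each class are "similar" examples, an equal number of
sampled cross-class pairs are "dissimilar", and each pair's feature is the
Hadamard (elementwise) product of the two embeddings. A small feedforward
network (input → 400 → 50 → 1, ReLU/sigmoid, Adam lr 1e-4, batch 32, ≤ 50
epochs, early stopping on validation loss with patience 3) learns pair
similarity; a test narrative is classified by its mean similarity to each
class's train references. Evaluation re-draws the down-sample and split 10
times and reports F1, sensitivity, specificity, and the label-only
("stepped" ROC) AUC = (sensitivity + specificity) / 2.

Zero-shot and few-shot prompt baselines with strict label parsing run
against an abstract chat backend; deterministic mocks are included, so no
external API is ever required. A synthetic-data module generates corpora
(configurable prevalence, per-class word-count distributions, PCL-5 totals
straddling the cutoff, missing items) and unit-norm embeddings with
controllable class separation, making every stage testable offline.

## CLI

Every subcommand takes `--seed`, writes a reproducibility manifest
(seed + config hash) into `--out`, and exits 0 on success, 2 on validation
errors, 3 on backend errors, 4 on internal errors.

```sh
# generate a synthetic corpus + embedding cache
narrascreen simulate --out runs/sim --seed 0 --n-subjects 400 \
    --prevalence 0.25 --dimension 192 --delta 2.0

# filter / balance / split
narrascreen prepare --corpus runs/sim/corpus.csv --out runs/prep --seed 0

# build the three pair sets
narrascreen augment --corpus runs/sim/corpus.csv \
    --embeddings runs/sim/embeddings.jsonl --out runs/aug --seed 0

# train one pair classifier
narrascreen train --corpus runs/sim/corpus.csv \
    --embeddings runs/sim/embeddings.jsonl --out runs/model --seed 0

# full repeated evaluation (the embedding-classifier workflow)
narrascreen evaluate --corpus runs/sim/corpus.csv \
    --embeddings runs/sim/embeddings.jsonl --out runs/eval --seed 0 \
    --pipeline model3 --n-repeats 10

# prompt baselines against the offline mock backend
narrascreen evaluate --corpus runs/sim/corpus.csv --out runs/eval1 \
    --pipeline model1
narrascreen prompt-run --corpus runs/sim/corpus.csv --out runs/prompts \
    --mode few_shot

# deterministic offline embeddings for an arbitrary corpus
narrascreen embed --corpus runs/sim/corpus.csv --out runs/cache.jsonl \
    --dimension 1536
```

Corpus input is CSV or JSONL with columns/keys `subject_id`, `narrative`,
`pcl5_01` … `pcl5_20` (blank/`NA`/`null` items count as missing). The
embedding cache is versioned JSONL keyed by (model name, sha256 of text).

## Library use

```python
from narrascreen import (
    SynthConfig, generate_corpus, generate_embeddings,
    PipelineConfig, repeat_evaluation,
)

config = SynthConfig(n_subjects=400, prevalence=0.25, dimension=192,
                     delta=2.0, min_words=30, seed=0)
records = generate_corpus(config)
vectors = generate_embeddings(records, config)
report = repeat_evaluation(records, vectors, PipelineConfig(),
                           n_repeats=10, seed=0)
print(report.mean_metrics["f1"], report.mean_auc)
```

Limitations: the case label is a provisional screening signal derived from a
self-report questionnaire, not a clinical diagnosis. No live API client is
shipped; remote backends are interface stubs with injectable transports.
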