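# metaug

Targeted generative data augmentation for metastasis detection from
longitudinal radiology report impressions.

## The problem

A patient accumulates a chronological series of free-text radiology
reports.  For each exam, the task is to decide whether the target organ
(liver, lung, adrenal) harbors metastatic disease at that time, reading
only the impression texts up to that exam.  Positive exams are the
minority class, labels are expensive, and single reports are often
ambiguous ("stable", "unchanged") without the patient's history.

`metaug` implements and evaluates a family of augmentation strategies for
this setting: paraphrase training reports with a generative engine, then
compose the paraphrases into *synthetic patients* — full-length timelines
that preserve positions, dates, and labels.  Paraphrasing everything
(vanilla) is compared against targeted selection:

- **length filter** — only impressions with ≥ 20 words (short texts yield
  near-duplicate paraphrases),
- **KF-MF** — k-fold misclassification filtering: only reports that
  held-out-fold models get wrong,
- **minority** — only reports of majority-positive patients, with
  class-balancing replication.

Targeted strategies train under a *matched computation budget*: a smaller
synthetic set earns proportionally more continuation epochs.

## The model

Reports are embedded one at a time (e_i = M(r_i), d = 768; a deterministic
hashed n-gram encoder by default, or a small from-scratch transformer that
carries the parameter-efficient adaptation regimes — LoRA and deep
prompt-tuning).  A patient-level head projects the embeddings to 128
dimensions, runs a one-directional LSTM, applies multi-head attention
under a causal mask, and emits one metastasis probability per timestep.
Causality is structural: the prediction at time t is bit-identical under
any change to later reports.  Training is BCE over all positions with
Adam, a cosine schedule, and early stopping on validation F1.

Everything runs on a small in-repo numpy autodiff; there are no deep
learning framework dependencies.  See `docs/methods.md` for the full model
description, parameter defaults, and limitations.

## Worked example

```python
from metaug import (
    AggregatorConfig, EncoderConfig, GeneratorConfig, MetastasisModel,
    ParaphraseConfig, SplitSpec, TrainingConfig,
    generate_corpus, split_by_patient, select_by_length,
    train, continue_on_augmented, evaluate_f1,
)
from metaug.pipeline import build_augmented
from metaug.training import budget_matched_epochs

corpus = split_by_patient(
    generate_corpus(GeneratorConfig(n_patients=120, organ="liver", seed=7)),
    SplitSpec(0.6, 0.2, 0.2, seed=0),
)
train_split = corpus.subset("train")
validation = corpus.subset("validation").patients
test = corpus.subset("test").patients

model = MetastasisModel(EncoderConfig(seed=0), AggregatorConfig(seed=0))
config = TrainingConfig(max_epochs=40, patience=15, seed=0)
model, history = train(model, train_split.patients, validation, config)
print(f"baseline:  val F1 {history.best_validation_f1:.3f}, test F1 {evaluate_f1(model, test):.3f}")

selection = select_by_length(train_split.reports(), min_words=20)
augmented = build_augmented(train_split, selection, ParaphraseConfig(n_variants=10, seed=0))
epochs = budget_matched_epochs(
    len(train_split.patients),
    10 * len(train_split.patients),
    len(augmented.synthetic_patients),
)
model, _ = continue_on_augmented(model, augmented, validation, epochs, config)
print(f"augmented: {len(selection)} reports selected, "
      f"{len(augmented.synthetic_patients)} synthetic patients, {epochs} epochs")
print(f"augmented: test F1 {evaluate_f1(model, test):.3f}")
```

Output (deterministic for these seeds):

```
baseline:  val F1 0.863, test F1 0.861
augmented: 401 reports selected, 720 synthetic patients, 10 epochs
augmented: test F1 0.861
```

The same chain is available as a CLI (`metaug generate-corpus`, `select`,
`paraphrase`, `compose`, `train`, `evaluate`, `diversity`, `run`) driven
by YAML configs with strict schema validation.

## Repository layout

```
src/metaug/
  corpus.py      synthetic corpus generator, patient-level splits, JSONL I/O
  paraphrase.py  prompt assembly, rule-based paraphraser, LLM adapter protocol
  augment.py     selection strategies, synthetic-patient composition
  autodiff.py    numpy reverse-mode engine (fused softmax/BCE, Adam)
  encoder.py     hashed n-gram + tiny transformer encoders, LoRA, prefixes
  aggregator.py  projection + LSTM + causal attention head, full classifier
  training.py    early stopping, continuation, budget matching, F1
  evaluation.py  multi-seed sweeps, history windows, self-BLEU, fidelity
  pipeline.py    experiment orchestration and result bundles
  cli.py         `metaug` command-line interface
docs/methods.md  model, assumptions, numerical choices, limitations
scripts/acceptance.py  end-to-end study runner
```
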