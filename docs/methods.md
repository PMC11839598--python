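# Methods

## Problem

Given a patient's chronological sequence of free-text radiology report
impressions r_1..r_l, predict for every timestep t whether the target organ
harbors metastatic disease at exam time, using only reports up to t.  The
positive class is rare and annotation is expensive, so the package studies
*generative data augmentation*: paraphrasing training reports and composing
the paraphrases into synthetic patient timelines, either for every report
(vanilla) or for targeted subsets chosen by length, model confusion, or
class membership.

## Model

The classifier F is a hierarchical sequence model:

1. **Encoder** e_i = M(r_i), a fixed-dimension embedding per report
   (default d = 768).  Two in-repo encoders share the contract:
   - `hashed_ngram` (default): L2-normalized hashed unigram+bigram counts.
     Deterministic, trainable-free, no pretrained checkpoint required.
   - `tiny_transformer`: a 2-layer pre-LN transformer (width 64, 4 heads,
     hashed vocabulary of 2048 buckets) trained from scratch.  It exists to
     carry the three adaptation regimes — full fine-tuning, LoRA on the
     query/value projections, and deep prompt-tuning (trainable per-layer
     key/value prefixes) — with exact parameter-count and identity/merge
     contracts.
   An `external_adapter` kind lets a real pretrained encoder plug in behind
   the same interface.
2. **Aggregator**: linear down-projection to 128 dimensions, a
   one-directional LSTM (128 units), multi-head attention (4 heads) over
   the LSTM outputs under a causal mask (position j attends only to
   positions ≤ j; masked scores receive −1e30 before the softmax, which
   underflows to an exact zero weight), and a per-position linear head with
   logistic squashing.  Causality is structural: the prediction at t is
   bit-identical under any change to later reports.
3. **Single-report baseline**: a flag replaces the LSTM+attention with a
   per-position head on the projected embedding, the architecture used when
   history is withheld.

## Augmentation strategies

- **vanilla** — paraphrase every training report N times (default N = 10).
- **length_filter** — paraphrase only impressions with ≥ 20 whitespace
  tokens (inclusive).  Short impressions admit few rewrites, so their
  variants are near-duplicates; the threshold is read inclusively.
- **kfmf** — k-fold misclassification filtering (k = 5): patients are
  partitioned into seeded patient-level folds, a fresh model is trained for
  20 epochs on the other folds, and every report the held-out model gets
  wrong is selected.
- **minority** — all reports of majority-positive patients (positive
  fraction ≥ ½), replicated `round(n_neg / max(1, n_pos)) − 1` times to
  approximately balance report-level classes.

**Composition**: with l_i,syn variants at position i, m = max_i l_i,syn
synthetic patients are assembled.  Slot i of synthetic patient j takes the
j-th element of a seeded permutation of variant set i while j < l_i,syn, a
seeded draw with replacement when the set is smaller but non-empty, and a
verbatim copy of the original report when the set is empty; every variant
is used at least once, and labels, dates, and positions are inherited from
the source timeline.

**Training protocol**: BCE over all report positions (stable fused
logits-space primitive), Adam with a cosine schedule, early stopping on
validation F1 (full-scale defaults: 1000 epochs, patience 200).  After the
baseline fit, continuation runs exactly E epochs on original + synthetic
patients, with the starting checkpoint kept as a candidate so continuation
can only match or improve validation F1.  Vanilla uses E = 10; targeted
strategies get budget-matched epochs
`round(10 · (n_orig + n_syn_vanilla) / (n_orig + n_syn_targeted))` (at
least 1), equalizing epochs × dataset-size.

## What the corpus generator emulates — and what it does not

The generator produces liver/lung/adrenal-like corpora with the field
structure of de-identified radiology impressions: per-patient exam
timelines with exponential inter-exam gaps (3 exams/year), two-state
Markov labels (stationary positive rate, default 0.31; persistence 0.9),
lognormal impression lengths straddling the 20-word threshold, and
cue-phrase banks (metastasis-affirming vs benign per organ, plus shared
distractor sentences) injected with probability `cue_strength` (default
0.7), so label signal is present but incomplete and history carries
information.  Everything is keyed by blake2b hashes of (seed, patient,
position), making corpora byte-identical across runs.

It does **not** emulate real clinical language: no report grammar beyond
templated sentences, no inter-annotator noise, no site/scanner drift, no
PHI-like structure, and the label process is memoryless given the previous
label.  Absolute F1 values on generated corpora are therefore not
comparable to results on clinical data; only directions and orderings are
meaningful.  Similarly, the rule-based paraphraser (synonym lexicon +
non-cue sentence reordering, cue sentences preserved verbatim, digits
untouched) is a stand-in for an LLM paraphraser behind the same
`LLMAdapter` interface; it guarantees label preservation by construction
but understates lexical diversity.

## Numerical choices

- float64 throughout; a small in-repo reverse-mode autodiff on numpy
  provides exactly the required ops (broadcast arithmetic, matmul/bmm,
  slicing, concat, reductions, fused row-softmax, fused BCE-with-logits
  `max(z,0) − z·t + log1p(exp(−|z|))`).
- Training uses a padded batched forward over patients (tail padding is
  safe because the LSTM and causal attention only flow forward; padded
  outputs are dropped), with length-bucketed minibatches (default batch
  size 32).  The batched path agrees with the per-patient path to ~1e-16.
- Splits are patient-level: patients are ordered by a keyed blake2b hash of
  (seed, patient_id) and counts come from largest-remainder rounding, so a
  450-patient corpus with fractions (4/9, 2/9, 3/9) yields exactly
  200/100/150 patients.
- Self-BLEU: modified n-gram precision with reference clipping, uniform
  weights n = 1..5 (orders where the candidate has no n-grams are
  skipped), brevity penalty against the closest reference length (ties
  favor the shorter), smoothing off by default.
- Pooled positive-class F1; a pool with neither positive gold labels nor
  positive predictions scores 0 with a warning.  Multi-seed summaries
  report mean, population std (ddof = 0), and best.
- History windows use 365.25-day years; the target report is always kept
  and its prediction is read at the truncated sequence's last position.

## Parameter defaults and why

| Parameter | Default | Rationale |
| --- | --- | --- |
| encoder dim d | 768 | hidden size of BERT-scale encoders the hashed encoder stands in for |
| projection / LSTM / heads | 128 / 128 / 4 | full-architecture head dimensions |
| N variants per report | 10 | study condition for vanilla augmentation |
| length threshold | 20 words, inclusive | diversity collapses below it (see `tests/test_paraphrase.py`) |
| KF-MF | k = 5, 20 epochs/fold | enough fit to expose hard reports without convergence cost |
| max_epochs / patience | 1000 / 200 | full-scale protocol; bundled experiments use 40 / 15 |
| continuation epochs | 10 | vanilla budget anchor |
| positive rate / persistence | 0.31 / 0.9 | liver-like class balance with informative history |
| cue_strength | 0.7 | signal present but incomplete, so history and augmentation matter |

The bundled experiments (tests and `scripts/acceptance.py`) run the same
code with scaled sizes — 450 patients, 40-epoch caps — chosen once from
runtime budgets, not tuned against outcomes.

## Limitations

- All quantitative results ship from synthetic corpora; nothing here
  validates clinical performance.
- The rule-based paraphraser cannot produce the lexical variety of an LLM,
  so absolute diversity metrics (self-BLEU, cosine fidelity) are tighter
  than the values a generative model would give.
- The tiny transformer is a contract-carrier for the PEFT regimes, not a
  competitive encoder; full-scale claims about LoRA/prefix quality do not
  transfer.
- Directional comparisons (augmentation helps or ties; longer history
  helps) are stochastic properties of a seeded sweep, not significance
  tests.
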