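"""End-to-end experiment orchestration.

One config drives the whole chain: generate (or load) a corpus, split at
patient level, optionally subset the training patients, fit the baseline,
select reports for augmentation, paraphrase, compose synthetic patients,
continue training under a matched computation budget, and evaluate on the
test split (optionally under history windows), across one or more seeds.

Every run writes a resolved-config snapshot next to its outputs so it can
be re-executed bit-identically.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .aggregator import AggregatorConfig, MetastasisModel
from .augment import (
    AugmentedDataset,
    KFMFConfig,
    SelectionResult,
    assemble_augmented_dataset,
    compose_synthetic_patients,
    generated_sample_count,
    replicate_minority_patient,
    select_by_kfmf,
    select_by_length,
    select_minority,
    select_vanilla,
)
from .autodiff import Adam, bce_with_logits
from .corpus import (
    Corpus,
    GeneratorConfig,
    Patient,
    SplitSpec,
    generate_corpus,
    read_corpus_jsonl,
    split_by_patient,
    _split_hash,
)
from .encoder import EncoderConfig, LoRASpec, PrefixSpec, attach_lora, attach_prefix, init_tiny_transformer
from .errors import ConfigurationError
from .evaluation import (
    HistoryWindowSpec,
    SeedSweepResult,
    truncate_history,
)
from .paraphrase import ParaphraseConfig, generate_variant_sets
from .training import (
    TrainingConfig,
    binary_f1,
    budget_matched_epochs,
    continue_on_augmented,
    evaluate_f1,
    train,
)

STRATEGIES = ("none", "vanilla", "length_filter", "kfmf", "minority")


@dataclass
class ExperimentConfig:
    """Resolved configuration of one experiment grid cell."""

    generator: GeneratorConfig | None = None
    corpus_path: str | None = None
    split: SplitSpec = field(default_factory=SplitSpec)
    train_fraction: float = 1.0
    strategy: str = "none"
    min_words: int = 20
    kfmf: KFMFConfig = field(default_factory=KFMFConfig)
    paraphrase: ParaphraseConfig = field(default_factory=ParaphraseConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    adaptation: str = "full"
    lora: LoRASpec = field(default_factory=LoRASpec)
    prefix: PrefixSpec = field(default_factory=PrefixSpec)
    aggregator: AggregatorConfig = field(default_factory=AggregatorConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    window_years: tuple[float, ...] = ()
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")
        if self.adaptation not in ("full", "lora", "prefix"):
            raise ConfigurationError(f"unknown adaptation {self.adaptation!r}")
        if not 0.0 < self.train_fraction <= 1.0:
            raise ConfigurationError("train_fraction must be in (0, 1]")
        if self.generator is None and self.corpus_path is None:
            raise ConfigurationError("need a generator config or a corpus path")


_NESTED = {
    "generator": GeneratorConfig,
    "split": SplitSpec,
    "kfmf": KFMFConfig,
    "paraphrase": ParaphraseConfig,
    "encoder": EncoderConfig,
    "lora": LoRASpec,
    "prefix": PrefixSpec,
    "aggregator": AggregatorConfig,
    "training": TrainingConfig,
}


def config_from_dict(data: dict) -> ExperimentConfig:
    """Strict construction: unknown keys anywhere are errors."""
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key, value in data.items():
        if key in _NESTED and value is not None:
            cls = _NESTED[key]
            sub_known = {f.name for f in dataclasses.fields(cls)}
            sub_unknown = set(value) - sub_known
            if sub_unknown:
                raise ConfigurationError(
                    f"unknown keys under {key!r}: {sorted(sub_unknown)}"
                )
            kwargs[key] = cls(**value)
        elif key in ("seeds", "window_years") and value is not None:
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return ExperimentConfig(**kwargs)


def config_from_yaml(path) -> ExperimentConfig:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))


def config_to_dict(config: ExperimentConfig) -> dict:
    out = asdict(config)
    out["seeds"] = list(config.seeds)
    out["window_years"] = [
        ("inf" if math.isinf(w) else w) for w in config.window_years
    ]
    return out


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------


def subset_train_patients(
    patients: list[Patient], fraction: float, seed: int
) -> list[Patient]:
    """Seeded patient-level subset; nested across fractions (a 20% subset is
    contained in the 50% subset for the same seed)."""
    if fraction >= 1.0:
        return list(patients)
    ranked = sorted(
        patients, key=lambda p: (_split_hash(p.patient_id, seed), p.patient_id)
    )
    n = max(1, round(fraction * len(patients)))
    keep = {p.patient_id for p in ranked[:n]}
    return [p for p in patients if p.patient_id in keep]


def build_model(config: ExperimentConfig, seed: int) -> MetastasisModel:
    enc = dataclasses.replace(config.encoder, seed=seed)
    agg = dataclasses.replace(
        config.aggregator, seed=seed, input_dim=config.encoder.dim
    )
    enc_params = None
    peft = None
    if enc.kind == "tiny_transformer":
        enc_params = init_tiny_transformer(enc)
        if config.adaptation == "lora":
            peft = attach_lora(enc_params, config.lora, enc, seed=seed)
        elif config.adaptation == "prefix":
            peft = attach_prefix(enc_params, config.prefix, enc, seed=seed)
    return MetastasisModel(enc, agg, enc_params=enc_params, peft_state=peft)


def default_fold_trainer(config: ExperimentConfig, epochs: int):
    """Fold trainer for KF-MF: a fresh model of the main architecture fitted
    for a fixed number of epochs (no early stopping inside a fold)."""

    def trainer(patients: list[Patient], seed: int):
        model = build_model(config, seed)
        rng = np.random.default_rng(seed)
        batch = config.training.batch_size
        n_batches = max(1, int(np.ceil(len(patients) / batch)))
        opt = Adam(
            model.trainable(),
            lr=config.training.learning_rate,
            schedule=config.training.schedule,
            total_steps=epochs * n_batches,
        )
        for _ in range(epochs):
            order = rng.permutation(len(patients))
            for start in range(0, len(order), batch):
                chunk = [patients[int(i)] for i in order[start : start + batch]]
                logits, targets = model.batch_logits(chunk)
                loss = bce_with_logits(logits, targets)
                opt.zero_grad()
                loss.backward()
                opt.step()
        return lambda patient: model.predict(patient).probabilities

    return trainer


def select_reports(
    config: ExperimentConfig, train_corpus: Corpus
) -> SelectionResult:
    reports = train_corpus.reports()
    if config.strategy == "vanilla":
        return select_vanilla(reports)
    if config.strategy == "length_filter":
        return select_by_length(reports, config.min_words)
    if config.strategy == "minority":
        return select_minority(train_corpus)
    if config.strategy == "kfmf":
        trainer = default_fold_trainer(config, config.kfmf.epochs_per_fold)
        return select_by_kfmf(train_corpus, config.kfmf, trainer)
    raise ConfigurationError(f"strategy {config.strategy!r} selects nothing")


def build_augmented(
    train_corpus: Corpus,
    selection: SelectionResult,
    paraphrase_config: ParaphraseConfig,
    engine=None,
) -> AugmentedDataset:
    """Paraphrase the selected reports and assemble synthetic patients."""
    variant_sets = generate_variant_sets(
        train_corpus.reports(), selection, paraphrase_config, engine
    )
    synthetic: list[Patient] = []
    for patient in train_corpus.patients:
        by_pos = {
            i: variant_sets[r.report_id] for i, r in enumerate(patient.reports)
        }
        if selection.strategy == "minority":
            if any(r.report_id in selection.selected_report_ids for r in patient.reports):
                synthetic.extend(
                    replicate_minority_patient(
                        patient, by_pos, selection.replication_factor or 0
                    )
                )
        else:
            synthetic.extend(
                compose_synthetic_patients(
                    patient, by_pos, seed=paraphrase_config.seed
                )
            )
    return assemble_augmented_dataset(train_corpus, synthetic)


def evaluate_with_window(
    model: MetastasisModel,
    patients: list[Patient],
    window_years: float,
    threshold: float = 0.5,
) -> float:
    """Pooled test F1 when only ``window_years`` of history is visible.

    Each report position is predicted from its truncated timeline, reading
    the probability at the truncated sequence's last position.
    """
    if math.isinf(window_years):
        return evaluate_f1(model, patients, threshold)
    spec = HistoryWindowSpec(window_years)
    probs: list[float] = []
    gold: list[int] = []
    for p in patients:
        for t in range(len(p.reports)):
            truncated = truncate_history(p, t, spec)
            probs.append(float(model.predict(truncated).probabilities[-1]))
            gold.append(p.reports[t].label)
    return binary_f1(np.array(probs), np.array(gold), threshold)


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------


@dataclass
class SeedRunResult:
    seed: int
    test_f1: float
    baseline_val_f1: float
    selection_size: int
    generated_samples: int
    continuation_epochs: int
    window_f1: dict[float, float] = field(default_factory=dict)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    per_seed: list[SeedRunResult]
    sweep: SeedSweepResult
    n_train: int
    n_validation: int
    n_test: int


def load_or_generate_corpus(config: ExperimentConfig) -> Corpus:
    if config.generator is not None:
        corpus = generate_corpus(config.generator)
    else:
        corpus = read_corpus_jsonl(config.corpus_path)
    if any(p.split is None for p in corpus.patients):
        corpus = split_by_patient(corpus, config.split)
    return corpus


def run_seed(
    config: ExperimentConfig,
    seed: int,
    train_corpus: Corpus,
    validation: list[Patient],
    test: list[Patient],
    selection: SelectionResult | None = None,
) -> SeedRunResult:
    training = dataclasses.replace(config.training, seed=seed)
    model = build_model(config, seed)
    model, history = train(model, train_corpus.patients, validation, training)
    selection_size = 0
    generated = 0
    continuation_epochs = 0
    if config.strategy != "none":
        para = dataclasses.replace(config.paraphrase, seed=seed)
        if selection is None:
            selection = select_reports(config, train_corpus)
        selection_size = len(selection)
        generated = generated_sample_count(selection, para.n_variants)
        augmented = build_augmented(train_corpus, selection, para)
        n_train = len(train_corpus.patients)
        n_syn = len(augmented.synthetic_patients)
        n_syn_vanilla = para.n_variants * n_train
        continuation_epochs = (
            training.augmented_epochs_base
            if config.strategy == "vanilla"
            else budget_matched_epochs(
                n_train, n_syn_vanilla, n_syn, training.augmented_epochs_base
            )
        )
        model, _ = continue_on_augmented(
            model, augmented, validation, continuation_epochs, training
        )
    test_f1 = evaluate_f1(model, test, training.decision_threshold)
    window_f1 = {
        w: evaluate_with_window(model, test, w, training.decision_threshold)
        for w in config.window_years
    }
    return SeedRunResult(
        seed=seed,
        test_f1=test_f1,
        baseline_val_f1=history.best_validation_f1,
        selection_size=selection_size,
        generated_samples=generated,
        continuation_epochs=continuation_epochs,
        window_f1=window_f1,
    )


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the full grid cell across its seeds and persist results."""
    corpus = load_or_generate_corpus(config)
    train_patients = [p for p in corpus.patients if p.split == "train"]
    validation = [p for p in corpus.patients if p.split == "validation"]
    test = [p for p in corpus.patients if p.split == "test"]
    train_patients = subset_train_patients(
        train_patients, config.train_fraction, config.split.seed
    )
    train_corpus = Corpus(
        train_patients, organ=corpus.organ, generator_config=corpus.generator_config
    )
    # the selection is deterministic given the corpus and the strategy's own
    # seed, so compute it once and share it across the sweep
    selection = (
        select_reports(config, train_corpus) if config.strategy != "none" else None
    )
    per_seed = [
        run_seed(config, seed, train_corpus, validation, test, selection)
        for seed in config.seeds
    ]
    sweep = SeedSweepResult(
        [r.seed for r in per_seed], [r.test_f1 for r in per_seed]
    )
    result = ExperimentResult(
        config, per_seed, sweep, len(train_patients), len(validation), len(test)
    )
    if config.output_dir:
        _write_bundle(result)
    return result


def _write_bundle(result: ExperimentResult) -> None:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(result.config), fh, sort_keys=True)
    with open(out / "results.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["seed", "split", "window_years", "f1", "selection_size",
             "generated_samples", "continuation_epochs"]
        )
        for r in result.per_seed:
            writer.writerow(
                [r.seed, "test", "inf", f"{r.test_f1:.6f}", r.selection_size,
                 r.generated_samples, r.continuation_epochs]
            )
            for w, f1 in r.window_f1.items():
                writer.writerow(
                    [r.seed, "test", w, f"{f1:.6f}", r.selection_size,
                     r.generated_samples, r.continuation_epochs]
                )
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "strategy": result.config.strategy,
                "mean_f1": result.sweep.mean,
                "std_f1": result.sweep.std,
                "best_f1": result.sweep.best,
                "n_train": result.n_train,
                "n_validation": result.n_validation,
                "n_test": result.n_test,
            },
            fh,
            indent=2,
        )
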