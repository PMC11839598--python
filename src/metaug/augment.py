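"""Vanilla and targeted augmentation: which reports to paraphrase, and how
synthetic reports are assembled into synthetic patients.

Selection strategies
--------------------
* vanilla        — every training report.
* length_filter  — reports of at least ``min_words`` whitespace tokens
                   (default 20); short impressions yield near-duplicate
                   paraphrases, so generating from them is wasted effort.
* kfmf           — k-fold misclassification filtering: train k held-out-fold
                   models and select every report a held-out model gets
                   wrong.  The fold trainer is a parameter so the same logic
                   works with the full patient-level model or any stub.
* minority       — all reports of patients whose timelines are majority
                   positive, together with a patient replication factor that
                   approximately balances report-level classes.

Composition matches one paraphrase variant per original report position,
producing ``max_i l_i_syn`` synthetic patients per original patient, so
every generated variant is used at least once.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .corpus import Corpus, Patient, Report
from .errors import ConfigurationError, InputError, IntegrityError
from .paraphrase import SyntheticReportSet

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    """Which training reports an augmentation strategy chose."""

    strategy: str
    selected_report_ids: set[str]
    replication_factor: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.selected_report_ids)


@dataclass
class KFMFConfig:
    """k-fold misclassification filtering parameters (k=5, 20 epochs/fold)."""

    k: int = 5
    epochs_per_fold: int = 20
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")
        if self.epochs_per_fold < 1:
            raise ConfigurationError("epochs_per_fold must be >= 1")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ConfigurationError("decision_threshold must be in (0, 1)")


@dataclass
class AugmentedDataset:
    """Original training patients plus synthetic patients, with provenance."""

    original: Corpus
    synthetic_patients: list[Patient]
    provenance_index: dict[str, str]  # placed report_id -> source report_id

    @property
    def n_patients(self) -> int:
        return len(self.original.patients) + len(self.synthetic_patients)

    def all_patients(self) -> list[Patient]:
        return list(self.original.patients) + list(self.synthetic_patients)


#: Trains a model on a list of patients; returns a per-patient predictor
#: giving one metastasis probability per report position.
FoldTrainer = Callable[[list[Patient], int], Callable[[Patient], np.ndarray]]


# ---------------------------------------------------------------------------
# Selection strategies
# ---------------------------------------------------------------------------


def select_vanilla(train_reports: Sequence[Report]) -> SelectionResult:
    """Select every training report (fixed N variants per report)."""
    return SelectionResult("vanilla", {r.report_id for r in train_reports})


def select_by_length(
    train_reports: Sequence[Report], min_words: int = 20
) -> SelectionResult:
    """Select reports whose impression has at least ``min_words`` tokens.

    Word count is the number of whitespace-delimited tokens after trimming;
    "a minimum of 20 words" is read inclusively, so a 20-token impression is
    selected and a 19-token one is not.
    """
    if min_words < 1:
        raise ConfigurationError("min_words must be >= 1")
    chosen = {r.report_id for r in train_reports if r.word_count >= min_words}
    return SelectionResult(
        "length_filter", chosen, diagnostics={"min_words": min_words}
    )


def kfmf_folds(
    patients: Sequence[Patient], k: int, seed: int
) -> list[list[Patient]]:
    """Seeded patient-level partition into k folds (avoids report leakage)."""
    if k > len(patients):
        raise ConfigurationError(
            f"k={k} exceeds number of patients ({len(patients)})"
        )
    ordered = sorted(patients, key=lambda p: p.patient_id)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ordered))
    chunks = np.array_split(perm, k)
    return [[ordered[int(i)] for i in chunk] for chunk in chunks]


def select_by_kfmf(
    train_corpus: Corpus, config: KFMFConfig, trainer: FoldTrainer
) -> SelectionResult:
    """Select reports misclassified by held-out-fold models.

    Training patients are partitioned into k seeded folds; for each fold a
    fresh model is trained on the other k-1 folds and applied to the held-out
    fold.  A report is selected iff its thresholded prediction differs from
    the gold label.  Each training report is evaluated exactly once, so the
    selection is the union over folds.
    """
    patients = train_corpus.patients
    folds = kfmf_folds(patients, config.k, config.seed)
    selected: set[str] = set()
    per_fold: list[int] = []
    for held_idx in range(config.k):
        held = folds[held_idx]
        rest = [p for i, f in enumerate(folds) if i != held_idx for p in f]
        predictor = trainer(rest, config.seed + held_idx)
        n_miss = 0
        for patient in held:
            probs = np.asarray(predictor(patient), dtype=float)
            if probs.shape[0] != len(patient.reports):
                raise InputError(
                    "predictor returned wrong-length probability series"
                )
            preds = (probs >= config.decision_threshold).astype(int)
            for report, pred in zip(patient.reports, preds):
                if int(pred) != report.label:
                    selected.add(report.report_id)
                    n_miss += 1
        per_fold.append(n_miss)
    return SelectionResult(
        "kfmf",
        selected,
        diagnostics={
            "k": config.k,
            "misclassified_per_fold": per_fold,
            "epochs_per_fold": config.epochs_per_fold,
        },
    )


def select_minority(train_corpus: Corpus) -> SelectionResult:
    """Select all reports of majority-positive patients, with a replication
    factor that approximately balances report-level classes.

    A patient qualifies when at least half of their reports are positive.
    The factor is ``max(0, round(n_neg / max(1, n_pos)) - 1)`` over the whole
    training split: original + factor replicas of the positive-heavy
    patients roughly equalize positive and negative report counts.
    """
    reports = train_corpus.reports()
    n_pos = sum(r.label for r in reports)
    n_neg = len(reports) - n_pos
    factor = max(0, round(n_neg / max(1, n_pos)) - 1)
    chosen = {
        r.report_id
        for p in train_corpus.patients
        if p.reports and p.positive_fraction >= 0.5
        for r in p.reports
    }
    return SelectionResult(
        "minority",
        chosen,
        replication_factor=factor,
        diagnostics={"n_positive": n_pos, "n_negative": n_neg},
    )


def generated_sample_count(
    selection: SelectionResult, n_variants: int
) -> int:
    """Synthetic-sample budget of a strategy: N per selected report, plus the
    replicated copies requested by minority-class augmentation."""
    count = n_variants * len(selection.selected_report_ids)
    if selection.strategy == "minority" and selection.replication_factor:
        count += selection.replication_factor * len(selection.selected_report_ids)
    return count


# ---------------------------------------------------------------------------
# Composition into synthetic patients
# ---------------------------------------------------------------------------


def _slot_rng(seed: int, patient_id: str, position: int) -> np.random.Generator:
    digest = hashlib.blake2b(
        f"{seed}|{patient_id}|{position}".encode(), digest_size=8
    ).digest()
    return np.random.default_rng(int.from_bytes(digest, "big"))


def _place(report: Report, new_pid: str, j: int, tag: str) -> Report:
    return dataclasses.replace(
        report,
        report_id=f"{report.report_id}@{tag}{j}",
        patient_id=new_pid,
    )


def compose_synthetic_patients(
    patient: Patient,
    variant_sets: Mapping[int, SyntheticReportSet],
    seed: int = 0,
) -> list[Patient]:
    """Assemble synthetic patients by randomly matching variants per slot.

    With ``m = max_i l_i_syn``, returns m synthetic patients, each keeping
    the original timeline (positions, dates, labels).  Slot i of synthetic
    patient j holds the j-th element of a seeded permutation of variant set
    i while j < l_i_syn; a seeded draw with replacement from the set when
    the set is smaller but non-empty; and a copy of the original report when
    the set is empty.  Every variant is therefore used at least once, and
    m = 0 yields no synthetic patients.
    """
    l = len(patient.reports)
    missing = [i for i in range(l) if i not in variant_sets]
    if missing:
        raise InputError(f"variant_sets missing positions {missing}")
    m = max((len(variant_sets[i]) for i in range(l)), default=0)
    if m == 0:
        return []
    # per-slot fill orders, keyed by (seed, patient_id, position)
    columns: list[list[Report]] = []
    for i in range(l):
        vs = variant_sets[i].variants
        rng = _slot_rng(seed, patient.patient_id, i)
        if not vs:
            columns.append([patient.reports[i]] * m)
            continue
        perm = [vs[int(t)] for t in rng.permutation(len(vs))]
        col = [perm[j] if j < len(vs) else vs[int(rng.integers(len(vs)))] for j in range(m)]
        columns.append(col)
    out = []
    for j in range(m):
        new_pid = f"{patient.patient_id}::syn{j}"
        reports = []
        for i in range(l):
            src = columns[i][j]
            tag = "p" if src.provenance == "synthetic" else "c"
            reports.append(_place(src, new_pid, j, tag))
        out.append(Patient(new_pid, reports, split=patient.split))
    return out


def replicate_minority_patient(
    patient: Patient,
    variant_sets: Mapping[int, SyntheticReportSet],
    n_replicas: int,
) -> list[Patient]:
    """Replicas for minority-class augmentation.

    Replica t fills slot i with variant ``t mod l_i_syn`` (round-robin over
    distinct paraphrases where available) and falls back to the original
    report for slots without variants.
    """
    out = []
    for t in range(n_replicas):
        new_pid = f"{patient.patient_id}::rep{t}"
        reports = []
        for i, orig in enumerate(patient.reports):
            vs = variant_sets.get(i)
            if vs is not None and len(vs) > 0:
                src = vs.variants[t % len(vs)]
                tag = "p"
            else:
                src, tag = orig, "c"
            reports.append(_place(src, new_pid, t, tag))
        out.append(Patient(new_pid, reports, split=patient.split))
    return out


def assemble_augmented_dataset(
    train_corpus: Corpus, all_synthetic_patients: Sequence[Patient]
) -> AugmentedDataset:
    """Combine original training patients with synthetic ones.

    Every synthetic report must trace back (via ``source_report_id`` or a
    verbatim original copy) to a report of the training corpus; anything
    else is a provenance violation.
    """
    train_report_ids = {r.report_id for r in train_corpus.reports()}
    index: dict[str, str] = {}
    for p in all_synthetic_patients:
        for r in p.reports:
            source = r.source_report_id
            if source is None:
                # original copy placed into a synthetic timeline
                source = r.report_id.split("@")[0]
            if source not in train_report_ids:
                raise IntegrityError(
                    f"synthetic report {r.report_id} traces to {source!r}, "
                    "which is not in the training split"
                )
            index[r.report_id] = source
    return AugmentedDataset(train_corpus, list(all_synthetic_patients), index)
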