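"""Evaluation utilities: multi-seed F1 reporting, history-window truncation,
and diversity/fidelity metrics for synthetic text.

Self-BLEU follows the BLEU recipe — modified n-gram precision with
reference clipping, uniform weights up to n_max = 5, brevity penalty —
applied either against the original source (single-reference) or against
the other variants of the same source (multi-reference).  Lower self-BLEU
means higher lexical diversity.  Semantic fidelity is the cosine similarity
between source and variant under a pluggable text embedder (the hashed
n-gram encoder by default, so no pretrained checkpoint is needed).
"""

from __future__ import annotations

import datetime
import math
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .corpus import Patient, Report
from .encoder import embed_hashed_text
from .errors import InputError
from .paraphrase import SyntheticReportSet

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# Multi-seed reporting
# ---------------------------------------------------------------------------


@dataclass
class SeedSweepResult:
    """Per-seed test F1 with mean ± population std and the best run."""

    seeds: list[int]
    f1_scores: list[float]
    mean: float = field(init=False)
    std: float = field(init=False)
    best: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.seeds) != len(self.f1_scores) or not self.seeds:
            raise InputError("need one F1 per seed, at least one seed")
        arr = np.asarray(self.f1_scores, dtype=float)
        self.mean = float(arr.mean())
        self.std = float(arr.std(ddof=0))
        self.best = float(arr.max())


def evaluate_multi_seed(
    run_fn: Callable[[int], float], seeds: Sequence[int]
) -> SeedSweepResult:
    """Rerun an experiment per seed and aggregate test F1.

    ``run_fn(seed)`` executes the full pipeline for one seed and returns its
    test F1.  A failing seed aborts the sweep with the seed identified.
    """
    if not seeds:
        raise InputError("need at least one seed")
    scores = []
    for seed in seeds:
        try:
            scores.append(float(run_fn(seed)))
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise RuntimeError(f"seed {seed} failed: {exc}") from exc
    return SeedSweepResult(list(seeds), scores)


# ---------------------------------------------------------------------------
# History-window truncation
# ---------------------------------------------------------------------------


@dataclass
class HistoryWindowSpec:
    """How many calendar years of history to keep (inf = unlimited)."""

    window_years: float = math.inf

    def __post_init__(self) -> None:
        if not self.window_years > 0:
            raise InputError("window_years must be > 0")


def truncate_history(
    patient: Patient, target_position: int, spec: HistoryWindowSpec
) -> Patient:
    """Restrict a patient to the history window before the target report.

    Keeps the reports at positions <= target whose date is within
    ``window_years`` (calendar years of 365.25 days) before the target
    report's date; the target itself is always retained, and order is
    preserved.  The prediction for the target is read at the truncated
    sequence's last position.  Applied at evaluation time only.
    """
    if not 0 <= target_position < len(patient.reports):
        raise InputError(
            f"target_position {target_position} out of range for patient "
            f"{patient.patient_id} with {len(patient.reports)} reports"
        )
    target = patient.reports[target_position]
    if math.isinf(spec.window_years):
        kept = patient.reports[: target_position + 1]
    else:
        cutoff = target.date - datetime.timedelta(
            days=spec.window_years * DAYS_PER_YEAR
        )
        kept = [
            r
            for r in patient.reports[: target_position + 1]
            if r.date >= cutoff
        ]
    if target not in kept:
        kept.append(target)
    return Patient(patient.patient_id, list(kept), split=patient.split)


# ---------------------------------------------------------------------------
# Self-BLEU
# ---------------------------------------------------------------------------

_BLEU_TOKEN_RE = re.compile(r"[a-z0-9]+|[^\sa-z0-9]")


def bleu_tokenize(text: str) -> list[str]:
    """Lowercase, punctuation split apart from words (fixed for
    reproducibility)."""
    return _BLEU_TOKEN_RE.findall(text.lower())


def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def self_bleu(
    candidate: str,
    references: Sequence[str],
    n_max: int = 5,
    smoothing: bool = False,
) -> float:
    """BLEU of one candidate against one or more references.

    Modified n-gram precision with per-n-gram clipping at the maximum
    reference count, uniform weights over n = 1..n_max (orders where the
    candidate has no n-grams are skipped), and the standard brevity penalty
    against the closest reference length.  A zero precision yields 0 unless
    ``smoothing`` substitutes a small epsilon.
    """
    if not candidate:
        raise InputError("candidate must be non-empty")
    if not references:
        raise InputError("need at least one reference")
    cand = bleu_tokenize(candidate)
    refs = [bleu_tokenize(r) for r in references]
    log_precisions = []
    for n in range(1, n_max + 1):
        cand_counts = _ngrams(cand, n)
        total = sum(cand_counts.values())
        if total == 0:
            continue
        max_ref: Counter = Counter()
        for ref in refs:
            for gram, count in _ngrams(ref, n).items():
                if count > max_ref[gram]:
                    max_ref[gram] = count
        clipped = sum(min(c, max_ref[g]) for g, c in cand_counts.items())
        if clipped == 0:
            if not smoothing:
                return 0.0
            clipped_frac = 1e-9
        else:
            clipped_frac = clipped / total
        log_precisions.append(math.log(clipped_frac))
    if not log_precisions:
        return 0.0
    c = len(cand)
    r = min((len(ref) for ref in refs), key=lambda rl: (abs(rl - c), rl))
    bp = 1.0 if c >= r else math.exp(1.0 - r / c)
    return bp * math.exp(sum(log_precisions) / len(log_precisions))


# ---------------------------------------------------------------------------
# Semantic fidelity
# ---------------------------------------------------------------------------

Embedder = Callable[[str], np.ndarray]


def _default_embedder(text: str) -> np.ndarray:
    return embed_hashed_text(text, 768)


def semantic_similarity(
    original: str, variant: str, embedder: Embedder | None = None
) -> float:
    """Cosine similarity of the two texts under the given embedder."""
    embedder = embedder or _default_embedder
    a = np.asarray(embedder(original), dtype=float)
    b = np.asarray(embedder(variant), dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("zero-norm embedding; similarity := 0")
        return 0.0
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# Diversity report
# ---------------------------------------------------------------------------


@dataclass
class DiversityReport:
    self_bleu_single: float
    self_bleu_multi: float | None
    cosine_similarity: float
    n_max: int = 5
    n_variants: int = 0
    n_multi_skipped: int = 0


def diversity_report(
    variant_sets: Mapping[str, SyntheticReportSet],
    source_reports: Mapping[str, Report] | Sequence[Report],
    n_max: int = 5,
    embedder: Embedder | None = None,
) -> DiversityReport:
    """Aggregate diversity/fidelity over all (source, variant) pairs.

    single-reference self-BLEU: each variant against its source.
    multi-reference self-BLEU: each variant against the other variants of
    the same source (sets with a single variant are skipped and counted).
    Cosine similarity: mean over all (source, variant) pairs.
    """
    if not isinstance(source_reports, Mapping):
        source_reports = {r.report_id: r for r in source_reports}
    singles: list[float] = []
    multis: list[float] = []
    cosines: list[float] = []
    n_skipped = 0
    for sid, vset in variant_sets.items():
        if not vset.variants:
            continue
        source = source_reports[sid].impression
        texts = [v.impression for v in vset.variants]
        for i, text in enumerate(texts):
            singles.append(self_bleu(text, [source], n_max=n_max))
            cosines.append(semantic_similarity(source, text, embedder))
            others = texts[:i] + texts[i + 1 :]
            if others:
                multis.append(self_bleu(text, others, n_max=n_max))
        if len(texts) == 1:
            n_skipped += 1
    if not singles:
        raise InputError("all variant sets are empty")
    return DiversityReport(
        self_bleu_single=float(np.mean(singles)),
        self_bleu_multi=float(np.mean(multis)) if multis else None,
        cosine_similarity=float(np.mean(cosines)),
        n_max=n_max,
        n_variants=len(singles),
        n_multi_skipped=n_skipped,
    )
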