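"""Longitudinal synthetic radiology-report corpora.

Real metastasis-annotated report collections are held under HIPAA
restrictions, so this module generates corpora with the same statistical
skeleton: one patient per line of JSONL, each patient an ordered timeline of
1-30 impression texts with binary per-report metastasis labels, organ-level
positive rates (liver ~31%, lung ~16%, adrenal ~7%), roughly nine reports per
patient, and impression lengths spanning the 20-word augmentation-filter
threshold.

The lexical signal is controllable: positive reports carry organ-specific
metastasis-affirming cue sentences with probability ``cue_strength``,
negative reports carry benign/negating cues, and the remainder of every
impression is neutral distractor text.  Labels follow a two-state persistence
process so that patient history is genuinely informative.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, InputError

ORGANS = ("lung", "liver", "adrenal")

#: Report-level metastatic occurrence rates by organ.
ORGAN_POSITIVE_RATES = {"lung": 0.16, "liver": 0.31, "adrenal": 0.07}

# ---------------------------------------------------------------------------
# Cue-phrase banks.
#
# Two disjoint banks per organ (metastasis-affirming vs benign/negating) plus
# shared distractor sentences.  The rule-based paraphraser treats any sentence
# containing one of these phrases as immutable, which guarantees label
# preservation by construction; see metaug.paraphrase.
# ---------------------------------------------------------------------------

METASTASIS_CUES = {
    "lung": (
        "new pulmonary metastases are identified",
        "multiple lung nodules consistent with metastatic disease",
        "interval growth of pulmonary metastatic nodules",
        "findings compatible with pulmonary metastatic spread",
    ),
    "liver": (
        "new hepatic metastases are identified",
        "multiple liver lesions consistent with metastatic disease",
        "interval growth of hepatic metastatic lesions",
        "findings compatible with hepatic metastatic spread",
    ),
    "adrenal": (
        "new adrenal metastases are identified",
        "adrenal nodule consistent with metastatic disease",
        "interval growth of adrenal metastatic lesion",
        "findings compatible with adrenal metastatic spread",
    ),
}

BENIGN_CUES = {
    "lung": (
        "no evidence of pulmonary metastatic disease",
        "lungs are clear without suspicious nodules",
        "stable benign appearing pulmonary granuloma",
        "no new or enlarging lung nodules",
    ),
    "liver": (
        "no evidence of hepatic metastatic disease",
        "liver is unremarkable without focal lesion",
        "stable benign appearing hepatic cyst",
        "no new or enlarging liver lesions",
    ),
    "adrenal": (
        "no evidence of adrenal metastatic disease",
        "adrenal glands are unremarkable",
        "stable benign appearing adrenal adenoma",
        "no new or enlarging adrenal nodules",
    ),
}

#: Neutral filler sentences shared across organs; these carry no label signal
#: and are the part of the impression the paraphraser is free to rewrite.
DISTRACTOR_SENTENCES = (
    "the examination was performed with intravenous contrast",
    "comparison is made with the prior study from last visit",
    "mild degenerative changes are seen in the thoracic spine",
    "small hiatal hernia is again demonstrated without change",
    "a tiny 3 mm calcified granuloma is unchanged from prior imaging",
    "scattered diverticula are present without surrounding inflammation",
    "the visualized osseous structures show no aggressive lesion",
    "postsurgical changes are stable in appearance since the previous exam",
    "trace pleural effusion is noted on the right side",
    "the pancreas and spleen are normal in appearance",
    "no pathologically enlarged lymph nodes are identified in the abdomen",
    "a 8 mm simple renal cyst is incidentally noted and unchanged",
    "atherosclerotic calcification of the abdominal aorta is moderate",
    "the gallbladder is surgically absent without ductal dilatation",
    "bibasilar atelectasis is minimal and unchanged from the prior report",
    "clinical correlation is recommended for the incidental findings above",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Report:
    """One radiology exam: date, impression text, binary metastasis label."""

    report_id: str
    patient_id: str
    date: datetime.date
    position: int
    impression: str
    label: int
    organ: str
    findings: str | None = None
    provenance: str = "original"
    source_report_id: str | None = None

    def __post_init__(self) -> None:
        if not self.impression:
            raise InputError("impression must be non-empty")
        if self.label not in (0, 1):
            raise InputError(f"label must be 0 or 1, got {self.label!r}")
        if self.provenance not in ("original", "synthetic"):
            raise InputError(f"invalid provenance {self.provenance!r}")

    @property
    def word_count(self) -> int:
        """Whitespace-delimited token count of the impression (the length-
        filter metric)."""
        return len(self.impression.split())

    def text(self, input_mode: str = "impression_only") -> str:
        """Model input text for the configured mode.

        In ``findings_plus_impression`` mode the findings section (when
        present) precedes the impression, mirroring the structured-report
        setting where the organ subsection is combined with the impression.
        """
        if input_mode == "findings_plus_impression" and self.findings:
            return self.findings + " [SEP] " + self.impression
        return self.impression


@dataclass
class Patient:
    """Ordered report sequence for one patient."""

    patient_id: str
    reports: list[Report]
    split: str | None = None

    def __post_init__(self) -> None:
        for r in self.reports:
            if r.patient_id != self.patient_id:
                raise InputError(
                    f"report {r.report_id} belongs to {r.patient_id}, "
                    f"not {self.patient_id}"
                )

    def __len__(self) -> int:
        return len(self.reports)

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.reports]

    @property
    def positive_fraction(self) -> float:
        return sum(self.labels) / len(self.reports)


@dataclass
class Corpus:
    """A set of patients, optionally remembering the generator that made it."""

    patients: list[Patient]
    organ: str | None = None
    generator_config: "GeneratorConfig | None" = None

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise InputError("patient_ids must be unique within a corpus")

    def __len__(self) -> int:
        return len(self.patients)

    def reports(self) -> list[Report]:
        return [r for p in self.patients for r in p.reports]

    def subset(self, split: str) -> "Corpus":
        return Corpus(
            [p for p in self.patients if p.split == split],
            organ=self.organ,
            generator_config=self.generator_config,
        )


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic corpus generator.

    Defaults mirror the structure of institutional report collections: nine
    reports per patient on average, timelines capped at 30 exams, roughly
    three exams per year over a ten-year accrual window, and impression
    lengths from ~8 to ~120 words (log-normal).  ``label_persistence`` is the
    probability that a metastasis-positive state remains positive at the next
    exam; the first-exam rate is adjusted so that the stationary report-level
    positive rate equals ``positive_rate``.
    """

    n_patients: int
    organ: str = "liver"
    positive_rate: float = 0.31
    mean_reports_per_patient: float = 9.0
    max_reports: int = 30
    reports_per_year: float = 3.0
    label_persistence: float = 0.9
    cue_strength: float = 0.7
    length_distribution: dict = field(
        default_factory=lambda: {"log_mean": math.log(20.0), "log_sd": 0.62}
    )
    with_findings: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.organ not in ORGANS:
            raise ConfigurationError(f"unknown organ {self.organ!r}")
        for name in ("positive_rate", "label_persistence", "cue_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.positive_rate < 1.0:
            raise ConfigurationError("positive_rate must be in (0, 1)")
        if self.mean_reports_per_patient <= 0 or self.reports_per_year <= 0:
            raise ConfigurationError("rates must be positive")
        if self.max_reports < 1:
            raise ConfigurationError("max_reports must be >= 1")


@dataclass
class SplitSpec:
    """Patient-level train/validation/test fractions."""

    train: float = 0.7
    validation: float = 0.15
    test: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.train, self.validation, self.test):
            if f < 0:
                raise ConfigurationError("split fractions must be >= 0")
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_EPOCH_START = datetime.date(2009, 7, 1)
_ACCRUAL_DAYS = 3653  # ten-year accrual window for first exams


def _stationary_entry_rate(rate: float, persistence: float) -> float:
    """P(negative -> positive) making `rate` the stationary positive rate."""
    q = rate * (1.0 - persistence) / (1.0 - rate)
    return min(q, 1.0)


def _sample_labels(rng: np.random.Generator, l: int, cfg: GeneratorConfig) -> list[int]:
    q = _stationary_entry_rate(cfg.positive_rate, cfg.label_persistence)
    labels = [int(rng.random() < cfg.positive_rate)]
    for _ in range(1, l):
        if labels[-1] == 1:
            labels.append(int(rng.random() < cfg.label_persistence))
        else:
            labels.append(int(rng.random() < q))
    return labels


def _sample_impression(
    rng: np.random.Generator, label: int, cfg: GeneratorConfig
) -> str:
    target_words = int(
        round(
            math.exp(
                rng.normal(
                    cfg.length_distribution["log_mean"],
                    cfg.length_distribution["log_sd"],
                )
            )
        )
    )
    target_words = max(5, min(140, target_words))
    sentences: list[str] = []
    if rng.random() < cfg.cue_strength:
        bank = METASTASIS_CUES[cfg.organ] if label == 1 else BENIGN_CUES[cfg.organ]
        sentences.append(bank[int(rng.integers(len(bank)))])
    n_words = sum(len(s.split()) for s in sentences)
    while n_words < target_words:
        s = DISTRACTOR_SENTENCES[int(rng.integers(len(DISTRACTOR_SENTENCES)))]
        sentences.append(s)
        n_words += len(s.split())
    order = rng.permutation(len(sentences))
    return ". ".join(sentences[i].capitalize() for i in order) + "."


def _sample_findings(rng: np.random.Generator, impression: str, organ: str) -> str:
    extra = [
        DISTRACTOR_SENTENCES[int(rng.integers(len(DISTRACTOR_SENTENCES)))]
        for _ in range(2)
    ]
    head = f"{organ.capitalize()} subsection"
    return head + ": " + ". ".join(s.capitalize() for s in extra) + ". " + impression


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Generate a longitudinal corpus; identical config => identical corpus."""
    rng = np.random.default_rng(config.seed)
    gap_mean_days = 365.25 / config.reports_per_year
    patients: list[Patient] = []
    for idx in range(config.n_patients):
        pid = f"{config.organ}-p{idx:05d}"
        l = 1 + int(rng.poisson(max(config.mean_reports_per_patient - 1.0, 0.0)))
        l = min(l, config.max_reports)
        labels = _sample_labels(rng, l, config)
        day = int(rng.integers(_ACCRUAL_DAYS))
        date = _EPOCH_START + datetime.timedelta(days=day)
        reports: list[Report] = []
        for pos in range(l):
            impression = _sample_impression(rng, labels[pos], config)
            findings = (
                _sample_findings(rng, impression, config.organ)
                if config.with_findings
                else None
            )
            reports.append(
                Report(
                    report_id=f"{pid}-r{pos:02d}",
                    patient_id=pid,
                    date=date,
                    position=pos,
                    impression=impression,
                    findings=findings,
                    label=labels[pos],
                    organ=config.organ,
                )
            )
            gap = max(1, int(round(rng.exponential(gap_mean_days))))
            date = date + datetime.timedelta(days=gap)
        patients.append(Patient(pid, reports))
    return Corpus(patients, organ=config.organ, generator_config=config)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def _split_hash(patient_id: str, seed: int) -> int:
    digest = hashlib.blake2b(
        f"{seed}:{patient_id}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big")


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    quotas = [n * f for f in fractions]
    counts = [int(math.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    leftover = n - sum(counts)
    # larger remainder first; ties broken by split order (train, val, test)
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def split_by_patient(corpus: Corpus, spec: SplitSpec) -> Corpus:
    """Assign train/validation/test at patient level.

    Patients are ordered by a keyed hash of (seed, patient_id) and allocated
    by largest-remainder counts, so the assignment depends only on the
    patient ids and the seed — never on report contents — and no patient's
    reports can leak across splits.
    """
    if not corpus.patients:
        return Corpus([], organ=corpus.organ, generator_config=corpus.generator_config)
    ranked = sorted(
        corpus.patients,
        key=lambda p: (_split_hash(p.patient_id, spec.seed), p.patient_id),
    )
    counts = _largest_remainder_counts(
        len(ranked), (spec.train, spec.validation, spec.test)
    )
    names = ("train", "validation", "test")
    assignment: dict[str, str] = {}
    i = 0
    for name, c in zip(names, counts):
        for p in ranked[i : i + c]:
            assignment[p.patient_id] = name
        i += c
    out = [
        dataclasses.replace(p, split=assignment[p.patient_id])
        for p in corpus.patients
    ]
    return Corpus(out, organ=corpus.organ, generator_config=corpus.generator_config)


# ---------------------------------------------------------------------------
# Summaries and serialization
# ---------------------------------------------------------------------------


def corpus_summary(corpus: Corpus) -> dict:
    reports = corpus.reports()
    n_reports = len(reports)
    n_pos = sum(r.label for r in reports)
    words = sorted(r.word_count for r in reports)
    if words:
        qs = np.quantile(words, [0.0, 0.25, 0.5, 0.75, 1.0])
        quantiles = {
            "min": float(qs[0]),
            "q25": float(qs[1]),
            "median": float(qs[2]),
            "q75": float(qs[3]),
            "max": float(qs[4]),
        }
    else:
        quantiles = None
    return {
        "n_patients": len(corpus.patients),
        "n_reports": n_reports,
        "n_positive": n_pos,
        "positive_rate": (n_pos / n_reports) if n_reports else None,
        "words_per_impression": quantiles,
    }


def _report_to_dict(r: Report) -> dict:
    return {
        "report_id": r.report_id,
        "date": r.date.isoformat(),
        "position": r.position,
        "impression": r.impression,
        "findings": r.findings,
        "label": r.label,
        "organ": r.organ,
        "provenance": r.provenance,
        "source_report_id": r.source_report_id,
    }


def _report_from_dict(d: dict, patient_id: str) -> Report:
    return Report(
        report_id=d["report_id"],
        patient_id=patient_id,
        date=datetime.date.fromisoformat(d["date"]),
        position=d["position"],
        impression=d["impression"],
        findings=d.get("findings"),
        label=d["label"],
        organ=d["organ"],
        provenance=d.get("provenance", "original"),
        source_report_id=d.get("source_report_id"),
    )


def patient_to_dict(p: Patient) -> dict:
    return {
        "patient_id": p.patient_id,
        "split": p.split,
        "reports": [_report_to_dict(r) for r in p.reports],
    }


def patient_from_dict(d: dict) -> Patient:
    return Patient(
        patient_id=d["patient_id"],
        reports=[_report_from_dict(r, d["patient_id"]) for r in d["reports"]],
        split=d.get("split"),
    )


def write_corpus_jsonl(corpus: Corpus, path) -> None:
    """One patient per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in corpus.patients:
            fh.write(json.dumps(patient_to_dict(p), sort_keys=True) + "\n")


def read_corpus_jsonl(path, organ: str | None = None) -> Corpus:
    patients = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                patients.append(patient_from_dict(json.loads(line)))
    if organ is None and patients and patients[0].reports:
        organ = patients[0].reports[0].organ
    return Corpus(patients, organ=organ)


def corpus_to_jsonl_bytes(corpus: Corpus) -> bytes:
    """Canonical serialization, used for byte-identity checks."""
    return "".join(
        json.dumps(patient_to_dict(p), sort_keys=True) + "\n" for p in corpus.patients
    ).encode()
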