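"""Paraphrase generation for report impressions.

Two engines share one contract (impression text in, N variant texts out):

* a deterministic rule-based paraphraser used throughout the test suite and
  the bundled experiments — synonym substitution from a fixed lexicon plus
  reordering of non-cue sentences, leaving cue sentences and digits intact so
  the metastasis label is preserved by construction;
* a prompt builder and adapter interface for an external instruction-tuned
  LLM.  No network code ships enabled; the adapter is a pure callable so a
  real generator can be plugged in without touching downstream stages.

The rule engine deliberately collapses on short inputs: impressions under 20
words offer almost no transformation sites, so their variants come out as
near-duplicates — the behaviour that motivates length-based selection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np

from .corpus import BENIGN_CUES, METASTASIS_CUES, Report
from .errors import ConfigurationError, InputError

# All cue phrases, lowercase, across organs; sentences containing any of
# these are never rewritten.
_ALL_CUES = tuple(
    phrase
    for bank in (*METASTASIS_CUES.values(), *BENIGN_CUES.values())
    for phrase in bank
)

#: Versioned synonym lexicon of the rule engine (v1).  Keys are lowercase
#: single tokens; values are replacement strings.  No entry contains or maps
#: to digits, so measurements survive paraphrasing verbatim.
SYNONYM_LEXICON: Mapping[str, tuple[str, ...]] = {
    "examination": ("exam", "imaging study"),
    "performed": ("carried out", "completed", "obtained"),
    "comparison": ("correlation",),
    "prior": ("previous", "earlier"),
    "study": ("exam", "scan"),
    "mild": ("slight", "minimal"),
    "seen": ("noted", "observed", "visualized"),
    "small": ("tiny", "subcentimeter"),
    "demonstrated": ("shown", "redemonstrated"),
    "without": ("with no",),
    "change": ("interval change", "alteration"),
    "unchanged": ("stable", "not significantly changed"),
    "scattered": ("several", "multiple"),
    "present": ("noted", "identified"),
    "inflammation": ("inflammatory change",),
    "visualized": ("imaged", "included"),
    "osseous": ("bony", "skeletal"),
    "aggressive": ("suspicious", "worrisome"),
    "stable": ("unchanged", "steady"),
    "appearance": ("morphology", "aspect"),
    "noted": ("observed", "seen"),
    "normal": ("unremarkable", "within normal limits"),
    "enlarged": ("prominent",),
    "identified": ("detected", "appreciated"),
    "moderate": ("intermediate",),
    "minimal": ("trace", "slight"),
    "recommended": ("advised", "suggested"),
    "incidentally": ("in passing",),
    "calcified": ("calcific",),
    "effusion": ("fluid collection",),
    "trace": ("minimal", "scant"),
    "surgically": ("operatively",),
    "again": ("once more",),
}

_SHORT_SOURCE_WORDS = 20  # below this the transformation space collapses


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ParaphraseConfig:
    """How many variants to produce and with which engine.

    ``temperature`` and ``repetition_penalty`` are decoding metadata recorded
    for the LLM adapter (defaults 0.3 and 1.15); the rule-based engine uses
    only ``seed``.
    """

    n_variants: int = 10
    engine: str = "rule_based"
    temperature: float = 0.3
    repetition_penalty: float = 1.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        if self.engine not in ("rule_based", "llm_adapter"):
            raise ConfigurationError(f"unknown engine {self.engine!r}")


@dataclass
class PromptTemplate:
    """Four-part paraphrasing prompt: background, task, demonstration pair."""

    background: str
    task_description: str
    demonstration_original: str
    demonstration_paraphrase: str

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if not getattr(self, f.name):
                raise InputError(f"prompt template part {f.name!r} is empty")


#: Default template.  The demonstration pair is bundled synthetic fixture
#: text written for this package (no institutional text is reproduced).
DEFAULT_PROMPT_TEMPLATE = PromptTemplate(
    background=(
        "You are assisting with radiology report curation. Radiology "
        "impressions summarize the key observations of an imaging exam in "
        "terse clinical prose."
    ),
    task_description=(
        "Paraphrase the impression below. Preserve every clinical finding, "
        "every measurement and every negation exactly; change only the "
        "wording and sentence structure."
    ),
    demonstration_original=(
        "Stable 6 mm right upper lobe nodule. No new suspicious lesions. "
        "Mild degenerative change of the spine."
    ),
    demonstration_paraphrase=(
        "The 6 mm nodule in the right upper lobe is unchanged. No new "
        "lesions of concern are seen. Slight degenerative spine changes."
    ),
)


@dataclass
class SyntheticReportSet:
    """The paraphrase variants of one original report (possibly none)."""

    source_report_id: str
    variants: list[Report] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variants)


# ---------------------------------------------------------------------------
# Prompt assembly
# ---------------------------------------------------------------------------

_SECTION = "\n<<{name}>>\n"
_SECTION_ORDER = ("BACKGROUND", "TASK", "EXAMPLE_ORIGINAL", "EXAMPLE_PARAPHRASE", "INPUT")


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("<<", "\\<<")


def _unescape(text: str) -> str:
    return text.replace("\\<<", "<<").replace("\\\\", "\\")


def build_prompt(template: PromptTemplate, impression: str) -> str:
    """Assemble the full paraphrasing prompt for one impression.

    Section delimiters inside the impression are backslash-escaped so the
    input can be recovered exactly with :func:`parse_prompt_input`.
    """
    if not impression:
        raise InputError("impression must be non-empty")
    parts = (
        template.background,
        template.task_description,
        template.demonstration_original,
        template.demonstration_paraphrase,
        impression,
    )
    return "".join(
        _SECTION.format(name=name) + _escape(part)
        for name, part in zip(_SECTION_ORDER, parts)
    )


def parse_prompt_input(prompt: str) -> str:
    """Recover the target impression from an assembled prompt."""
    marker = _SECTION.format(name="INPUT")
    if marker not in prompt:
        raise InputError("not a metaug paraphrase prompt")
    return _unescape(prompt.split(marker)[-1])


# ---------------------------------------------------------------------------
# Rule-based engine
# ---------------------------------------------------------------------------


def _split_sentences(text: str) -> list[str]:
    parts = re.split(r"(?<=\.)\s+", text.strip())
    return [p for p in parts if p]


def _is_cue_sentence(sentence: str) -> bool:
    low = sentence.lower()
    return any(cue in low for cue in _ALL_CUES)


def _variant_rng(impression: str, seed: int, k: int, salt: str) -> np.random.Generator:
    digest = hashlib.blake2b(
        f"{seed}|{salt}|{k}|{impression}".encode(), digest_size=8
    ).digest()
    return np.random.default_rng(int.from_bytes(digest, "big"))


def _substitute(sentence: str, rng: np.random.Generator, max_sites: int | None) -> str:
    tokens = sentence.split()
    sites = []
    for i, tok in enumerate(tokens):
        key = tok.lower().strip(".,;:")
        if key in SYNONYM_LEXICON:
            sites.append((i, key))
    if not sites:
        return sentence
    if max_sites is not None and len(sites) > max_sites:
        chosen_idx = rng.choice(len(sites), size=max_sites, replace=False)
        sites = [sites[int(j)] for j in sorted(chosen_idx)]
    out = list(tokens)
    for i, key in sites:
        if max_sites is None and rng.random() >= 0.5:
            continue  # leave this site unchanged in this variant
        options = SYNONYM_LEXICON[key]
        repl = options[int(rng.integers(len(options)))]
        tok = tokens[i]
        trailing = tok[len(tok.rstrip(".,;:")):]
        if tok[0].isupper():
            repl = repl[0].upper() + repl[1:]
        out[i] = repl + trailing
    return " ".join(out)


def rule_paraphrase(
    impression: str, config: ParaphraseConfig, salt: str = ""
) -> list[str]:
    """Produce ``config.n_variants`` deterministic paraphrases.

    Variant ``k`` is a pure function of (impression, seed, salt, k).  Cue
    sentences are copied verbatim; other sentences undergo seeded synonym
    substitution and, for sources of at least 20 words, reordering.  Sources
    under 20 words get at most one substitution site and no reordering, so
    their variants are near-duplicates of each other and of the source.
    """
    if not impression:
        raise InputError("impression must be non-empty")
    n_words = len(impression.split())
    short = n_words < _SHORT_SOURCE_WORDS
    sentences = _split_sentences(impression)
    cue_flags = [_is_cue_sentence(s) for s in sentences]
    variants = []
    for k in range(config.n_variants):
        rng = _variant_rng(impression, config.seed, k, salt)
        rewritten = [
            s if cue else _substitute(s, rng, max_sites=1 if short else None)
            for s, cue in zip(sentences, cue_flags)
        ]
        if not short:
            non_cue_idx = [i for i, cue in enumerate(cue_flags) if not cue]
            if len(non_cue_idx) >= 2:
                perm = rng.permutation(len(non_cue_idx))
                shuffled = [rewritten[non_cue_idx[int(j)]] for j in perm]
                for slot, s in zip(non_cue_idx, shuffled):
                    rewritten[slot] = s
        variants.append(" ".join(rewritten))
    return variants


# ---------------------------------------------------------------------------
# LLM adapter contract
# ---------------------------------------------------------------------------


class LLMAdapter(Protocol):
    """Anything that maps a prompt to ``n`` generated texts."""

    def paraphrase(self, prompt: str, n: int) -> list[str]: ...


def llm_engine(
    adapter: LLMAdapter, template: PromptTemplate = DEFAULT_PROMPT_TEMPLATE
) -> "Engine":
    """Wrap an adapter into the engine contract used by variant generation."""

    def engine(impression: str, config: ParaphraseConfig, salt: str = "") -> list[str]:
        prompt = build_prompt(template, impression)
        texts = adapter.paraphrase(prompt, config.n_variants)
        if len(texts) != config.n_variants:
            raise InputError(
                f"adapter returned {len(texts)} texts, expected {config.n_variants}"
            )
        return texts

    return engine


Engine = Callable[[str, ParaphraseConfig, str], list[str]]


# ---------------------------------------------------------------------------
# Variant-set generation
# ---------------------------------------------------------------------------


def generate_variant_sets(
    reports: Sequence[Report],
    selection,
    config: ParaphraseConfig,
    engine: Engine | None = None,
) -> dict[str, SyntheticReportSet]:
    """N variants for each selected report, empty sets for the rest.

    Variant metadata (patient, label, organ, date, position) is copied from
    the source; provenance is marked synthetic with a back-link to the
    source report.
    """
    by_id = {r.report_id: r for r in reports}
    selected = set(selection.selected_report_ids)
    unknown = selected - set(by_id)
    if unknown:
        raise InputError(f"selection contains unknown report ids: {sorted(unknown)[:5]}")
    if engine is None:
        if config.engine != "rule_based":
            raise ConfigurationError(
                "engine=llm_adapter requires an explicit adapter engine"
            )
        engine = rule_paraphrase
    out: dict[str, SyntheticReportSet] = {}
    for r in reports:
        if r.report_id not in selected:
            out[r.report_id] = SyntheticReportSet(r.report_id, [])
            continue
        texts = engine(r.impression, config, r.report_id)
        variants = [
            dataclasses.replace(
                r,
                report_id=f"{r.report_id}::syn{k}",
                impression=text,
                provenance="synthetic",
                source_report_id=r.report_id,
            )
            for k, text in enumerate(texts)
        ]
        out[r.report_id] = SyntheticReportSet(r.report_id, variants)
    return out


# ---------------------------------------------------------------------------
# Serialization (one SyntheticReportSet per JSONL line)
# ---------------------------------------------------------------------------


def write_variant_sets_jsonl(sets: Mapping[str, SyntheticReportSet], path) -> None:
    import json

    from .corpus import _report_to_dict

    with open(path, "w", encoding="utf-8") as fh:
        for sid in sorted(sets):
            vset = sets[sid]
            fh.write(
                json.dumps(
                    {
                        "source_report_id": vset.source_report_id,
                        "patient_id": (
                            vset.variants[0].patient_id if vset.variants else None
                        ),
                        "variants": [_report_to_dict(v) for v in vset.variants],
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_variant_sets_jsonl(path) -> dict[str, SyntheticReportSet]:
    import json

    from .corpus import _report_from_dict

    out: dict[str, SyntheticReportSet] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            variants = [
                _report_from_dict(v, d["patient_id"]) for v in d["variants"]
            ]
            out[d["source_report_id"]] = SyntheticReportSet(
                d["source_report_id"], variants
            )
    return out
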