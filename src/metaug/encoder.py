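"""Report text encoders: e_i = M(r_i).

Two in-repo encoders share one output contract (a fixed-dimension embedding
per report):

* ``hashed_ngram`` — a trainable-free feature hasher (unigrams + bigrams,
  L2-normalized counts).  Deterministic and fast; the default text backbone
  for the bundled experiments and the semantic-similarity metric.
* ``tiny_transformer`` — a small pre-LN transformer trained from scratch,
  which carries the three adaptation regimes of the full system: full
  fine-tuning, LoRA on the query/value projections (B zero-initialized so
  attachment is an exact identity), and deep prompt-tuning (trainable
  per-layer key/value prefixes, P-tuning-v2 style).

An ``external_adapter`` kind lets a real pretrained encoder be plugged in
behind the same interface without changing any downstream contract.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .autodiff import Tensor, concat, parameter, softmax_rows
from .corpus import Report
from .errors import ConfigurationError, InputError, NumericError, StateError

# ---------------------------------------------------------------------------
# Configuration and domain types
# ---------------------------------------------------------------------------


@dataclass
class EncoderConfig:
    """Encoder family and dimensions.

    ``dim`` is the embedding dimension d handed to the aggregator (default
    768, the hidden size of BERT-scale encoders).  ``width`` is the internal
    width of the tiny transformer; ``heads`` must divide it.
    """

    kind: str = "hashed_ngram"
    dim: int = 768
    layers: int = 2
    heads: int = 4
    width: int = 64
    vocab_hash_size: int = 2048
    max_tokens: int = 64
    input_mode: str = "impression_only"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("hashed_ngram", "tiny_transformer", "external_adapter"):
            raise ConfigurationError(f"unknown encoder kind {self.kind!r}")
        if self.dim < 1:
            raise ConfigurationError("dim must be >= 1")
        if self.width % self.heads != 0:
            raise ConfigurationError("heads must divide width")
        if self.input_mode not in ("impression_only", "findings_plus_impression"):
            raise ConfigurationError(f"unknown input_mode {self.input_mode!r}")


@dataclass
class LoRASpec:
    """Low-rank adaptation of attention projections (default query+value)."""

    rank: int = 4
    scaling: float = 1.0
    target_projections: tuple[str, ...] = ("query", "value")

    def __post_init__(self) -> None:
        self.target_projections = tuple(self.target_projections)
        if self.rank < 1:
            raise ConfigurationError("rank must be >= 1")
        bad = set(self.target_projections) - {"query", "value"}
        if bad:
            raise ConfigurationError(f"unknown LoRA targets {sorted(bad)}")


@dataclass
class PrefixSpec:
    """Deep prompt-tuning: trainable key/value prefixes in every layer."""

    prompt_length: int = 8
    init_token_ids: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.init_token_ids is not None:
            self.init_token_ids = tuple(self.init_token_ids)
        if self.prompt_length < 1:
            raise ConfigurationError("prompt_length must be >= 1")


@dataclass
class ReportEmbedding:
    vector: np.ndarray
    report_id: str

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.all(np.isfinite(self.vector)):
            raise NumericError(f"non-finite embedding for {self.report_id}")


@dataclass
class PeftState:
    """Adaptation state attached to a tiny-transformer parameter set."""

    kind: str  # "lora" | "prefix"
    tensors: dict[str, Tensor]
    spec: object
    merged: bool = False


# ---------------------------------------------------------------------------
# Tokenization and hashing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def hash_token(token: str, buckets: int) -> int:
    """Stable bucket index: blake2b-64 of the token, mod bucket count."""
    digest = hashlib.blake2b(token.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % buckets


# ---------------------------------------------------------------------------
# Hashed n-gram encoder
# ---------------------------------------------------------------------------


def embed_hashed_text(text: str, dim: int) -> np.ndarray:
    """Unigram+bigram hashed counts, L2-normalized (zero vector for empty)."""
    tokens = tokenize(text)
    vec = np.zeros(dim)
    for tok in tokens:
        vec[hash_token(tok, dim)] += 1.0
    for a, b in zip(tokens, tokens[1:]):
        vec[hash_token(a + "_" + b, dim)] += 1.0
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec


def embed_hashed(report: Report, config: EncoderConfig) -> ReportEmbedding:
    """Trainable-free report embedding via feature hashing."""
    text = report.text(config.input_mode)
    return ReportEmbedding(embed_hashed_text(text, config.dim), report.report_id)


# ---------------------------------------------------------------------------
# Tiny transformer
# ---------------------------------------------------------------------------


def init_tiny_transformer(config: EncoderConfig) -> dict[str, Tensor]:
    """Randomly initialized parameter set (seeded, float64)."""
    rng = np.random.default_rng(config.seed)
    w = config.width

    def p(shape, scale=0.02):
        return parameter(rng.normal(0.0, scale, size=shape))

    params: dict[str, Tensor] = {
        "tok_emb": p((config.vocab_hash_size, w)),
        "pos_emb": p((config.max_tokens, w)),
        "out.W": p((w, config.dim)),
        "out.b": parameter(np.zeros(config.dim)),
    }
    for i in range(config.layers):
        for proj in ("Wq", "Wk", "Wv", "Wo"):
            params[f"l{i}.{proj}"] = p((w, w))
        params[f"l{i}.ln1.g"] = parameter(np.ones(w))
        params[f"l{i}.ln1.b"] = parameter(np.zeros(w))
        params[f"l{i}.ln2.g"] = parameter(np.ones(w))
        params[f"l{i}.ln2.b"] = parameter(np.zeros(w))
        params[f"l{i}.ff.W1"] = p((w, 2 * w))
        params[f"l{i}.ff.b1"] = parameter(np.zeros(2 * w))
        params[f"l{i}.ff.W2"] = p((2 * w, w))
        params[f"l{i}.ff.b2"] = parameter(np.zeros(w))
    return params


def _layer_norm(x: Tensor, g: Tensor, b: Tensor) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + 1e-5) ** -0.5 * g + b


def _effective_projection(
    params: Mapping[str, Tensor], peft: PeftState | None, layer: int, proj: str
) -> Tensor:
    W = params[f"l{layer}.W{proj[0]}"]
    if peft is not None and peft.kind == "lora" and proj in peft.spec.target_projections:
        B = peft.tensors[f"l{layer}.{proj}.B"]
        A = peft.tensors[f"l{layer}.{proj}.A"]
        return W + (B @ A) * peft.spec.scaling
    return W


def _attention(
    h: Tensor,
    params: Mapping[str, Tensor],
    config: EncoderConfig,
    peft: PeftState | None,
    layer: int,
) -> Tensor:
    w, n_heads = config.width, config.heads
    dk = w // n_heads
    Q = h @ _effective_projection(params, peft, layer, "query")
    K = h @ params[f"l{layer}.Wk"]
    V = h @ _effective_projection(params, peft, layer, "value")
    if peft is not None and peft.kind == "prefix":
        K = concat([peft.tensors[f"l{layer}.Pk"], K], axis=0)
        V = concat([peft.tensors[f"l{layer}.Pv"], V], axis=0)
    heads = []
    for i in range(n_heads):
        sl = slice(i * dk, (i + 1) * dk)
        scores = (Q[:, sl] @ K[:, sl].T) * (dk**-0.5)
        attn = softmax_rows(scores)
        heads.append(attn @ V[:, sl])
    return concat(heads, axis=1) @ params[f"l{layer}.Wo"]


def tiny_transformer_forward(
    text: str,
    params: Mapping[str, Tensor],
    config: EncoderConfig,
    peft: PeftState | None = None,
) -> Tensor:
    """Full forward pass on one text; returns a (dim,)-shaped Tensor.

    Tokens beyond ``max_tokens`` are head-truncated.  Pipeline: hashed token
    ids -> embedding + learned positions -> `layers` pre-LN blocks of
    multi-head self-attention and feed-forward -> mean pool -> linear map
    to ``dim``.
    """
    ids = [hash_token(t, config.vocab_hash_size) for t in tokenize(text)]
    ids = ids[: config.max_tokens]
    if not ids:
        ids = [0]
    x = params["tok_emb"][np.array(ids)] + params["pos_emb"][: len(ids)]
    for i in range(config.layers):
        h = _layer_norm(x, params[f"l{i}.ln1.g"], params[f"l{i}.ln1.b"])
        x = x + _attention(h, params, config, peft, i)
        h = _layer_norm(x, params[f"l{i}.ln2.g"], params[f"l{i}.ln2.b"])
        ff = (h @ params[f"l{i}.ff.W1"] + params[f"l{i}.ff.b1"]).relu()
        x = x + ff @ params[f"l{i}.ff.W2"] + params[f"l{i}.ff.b2"]
    pooled = x.mean(axis=0)
    return pooled @ params["out.W"] + params["out.b"]


def encode_tiny_transformer(
    report: Report,
    params: Mapping[str, Tensor],
    config: EncoderConfig,
    peft_state: PeftState | None = None,
) -> ReportEmbedding:
    out = tiny_transformer_forward(
        report.text(config.input_mode), params, config, peft_state
    )
    return ReportEmbedding(out.value, report.report_id)


# ---------------------------------------------------------------------------
# PEFT: LoRA
# ---------------------------------------------------------------------------


def attach_lora(
    params: Mapping[str, Tensor], spec: LoRASpec, config: EncoderConfig, seed: int = 0
) -> PeftState:
    """Attach low-rank factors B·A to the target projections.

    A is random-initialized, B zero-initialized, so the adapted encoder is
    bit-identical to the base encoder at attachment.  Base weights are
    frozen (excluded from the trainable set).
    """
    if spec.rank > config.width:
        raise ConfigurationError("LoRA rank exceeds layer width")
    rng = np.random.default_rng(seed)
    tensors: dict[str, Tensor] = {}
    for i in range(config.layers):
        for proj in spec.target_projections:
            tensors[f"l{i}.{proj}.B"] = parameter(
                np.zeros((config.width, spec.rank))
            )
            tensors[f"l{i}.{proj}.A"] = parameter(
                rng.normal(0.0, 0.02, size=(spec.rank, config.width))
            )
    return PeftState("lora", tensors, spec)


def merge_lora(
    params: Mapping[str, Tensor], peft_state: PeftState
) -> dict[str, Tensor]:
    """Fold the LoRA update into the base weights: W' = W + scaling·B·A."""
    if peft_state.kind != "lora":
        raise StateError("merge_lora requires a LoRA state")
    if peft_state.merged:
        raise StateError("LoRA state already merged")
    merged = {k: parameter(v.value.copy()) for k, v in params.items()}
    spec: LoRASpec = peft_state.spec
    n_layers = len({k.split(".")[0] for k in peft_state.tensors})
    for i in range(n_layers):
        for proj in spec.target_projections:
            key = f"l{i}.W{proj[0]}"
            B = peft_state.tensors[f"l{i}.{proj}.B"].value
            A = peft_state.tensors[f"l{i}.{proj}.A"].value
            merged[key] = parameter(params[key].value + spec.scaling * (B @ A))
    peft_state.merged = True
    return merged


# ---------------------------------------------------------------------------
# PEFT: deep prompt-tuning (prefix)
# ---------------------------------------------------------------------------


def attach_prefix(
    params: Mapping[str, Tensor],
    spec: PrefixSpec,
    config: EncoderConfig,
    seed: int = 0,
) -> PeftState:
    """Attach trainable key/value prefixes to every attention layer.

    Optionally initialized from the embeddings of given vocabulary bucket
    ids (cycled over the prompt length), which anchors the prompt in token
    space; otherwise small random initialization.
    """
    rng = np.random.default_rng(seed)
    tensors: dict[str, Tensor] = {}
    for i in range(config.layers):
        if spec.init_token_ids:
            rows = [
                params["tok_emb"].value[spec.init_token_ids[j % len(spec.init_token_ids)]]
                for j in range(spec.prompt_length)
            ]
            init = np.array(rows)
            tensors[f"l{i}.Pk"] = parameter(init.copy())
            tensors[f"l{i}.Pv"] = parameter(init.copy())
        else:
            tensors[f"l{i}.Pk"] = parameter(
                rng.normal(0.0, 0.02, size=(spec.prompt_length, config.width))
            )
            tensors[f"l{i}.Pv"] = parameter(
                rng.normal(0.0, 0.02, size=(spec.prompt_length, config.width))
            )
    return PeftState("prefix", tensors, spec)


# ---------------------------------------------------------------------------
# Parameter accounting
# ---------------------------------------------------------------------------


def trainable_tensors(
    params: Mapping[str, Tensor], peft_state: PeftState | None
) -> list[Tensor]:
    """The tensors optimization may update: all base weights under full
    fine-tuning, only the adapter tensors under a PEFT regime."""
    if peft_state is None:
        return list(params.values())
    return list(peft_state.tensors.values())


def trainable_parameter_count(
    params: Mapping[str, Tensor], peft_state: PeftState | None
) -> int:
    return sum(t.value.size for t in trainable_tensors(params, peft_state))


def total_parameter_count(params: Mapping[str, Tensor]) -> int:
    return sum(t.value.size for t in params.values())
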