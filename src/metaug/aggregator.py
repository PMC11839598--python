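"""Patient-level classification head.

The classifier F maps a patient's report embeddings (e_1..e_l) to one
metastasis probability per timestep in a single pass: linear down-projection
to 128 dimensions, a one-directional LSTM over the timeline, multi-head
attention over the LSTM outputs under a causal mask (position j attends only
to positions <= j), and a per-position linear head with logistic squashing.
Causality is structural, so the prediction at timestep t is bit-identical
under any change to later reports.

A single-report baseline configuration bypasses the LSTM and attention: the
head is applied to each down-projected embedding independently, which is the
architecture used when patient history is withheld.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np

from .autodiff import Tensor, bmm, concat, parameter, softmax_rows
from .corpus import Patient, Report
from .encoder import (
    EncoderConfig,
    PeftState,
    embed_hashed_text,
    tiny_transformer_forward,
    trainable_tensors,
)
from .errors import ConfigurationError, InputError

_MASK_NEG = -1e30


@dataclass
class AggregatorConfig:
    """Head dimensions: 128-d projection, 128-unit LSTM, 4 attention heads."""

    input_dim: int = 768
    projected_dim: int = 128
    recurrent_hidden: int = 128
    attention_heads: int = 4
    single_report: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.projected_dim > self.input_dim:
            raise ConfigurationError("projected_dim must be <= input_dim")
        if self.recurrent_hidden % self.attention_heads != 0:
            raise ConfigurationError("attention_heads must divide recurrent_hidden")


@dataclass
class PredictionSeries:
    """Per-timestep metastasis probabilities for one patient."""

    patient_id: str
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise InputError("probabilities must lie in [0, 1]")


def causal_mask(l: int) -> np.ndarray:
    """Boolean l×l matrix; entry (j, i) is True iff position j may attend
    to position i, i.e. i <= j."""
    if l < 1:
        raise InputError("l must be >= 1")
    return np.tril(np.ones((l, l), dtype=bool))


def init_aggregator_params(config: AggregatorConfig) -> dict[str, Tensor]:
    rng = np.random.default_rng(config.seed)
    d, p, h = config.input_dim, config.projected_dim, config.recurrent_hidden

    def init(shape, scale):
        return parameter(rng.normal(0.0, scale, size=shape))

    params = {
        "proj.W": init((d, p), d**-0.5),
        "proj.b": parameter(np.zeros(p)),
    }
    if config.single_report:
        params["head.W"] = init((p, 1), p**-0.5)
        params["head.b"] = parameter(np.zeros(1))
        return params
    params.update(
        {
            "lstm.Wx": init((p, 4 * h), p**-0.5),
            "lstm.Wh": init((h, 4 * h), h**-0.5),
            "lstm.b": parameter(np.zeros(4 * h)),
            "attn.Wq": init((h, h), h**-0.5),
            "attn.Wk": init((h, h), h**-0.5),
            "attn.Wv": init((h, h), h**-0.5),
            "attn.Wo": init((h, h), h**-0.5),
            "head.W": init((h, 1), h**-0.5),
            "head.b": parameter(np.zeros(1)),
        }
    )
    return params


def _lstm(X: Tensor, params: Mapping[str, Tensor], h_dim: int) -> Tensor:
    l = X.shape[0]
    Wx, Wh, b = params["lstm.Wx"], params["lstm.Wh"], params["lstm.b"]
    h = Tensor(np.zeros((1, h_dim)))
    c = Tensor(np.zeros((1, h_dim)))
    outputs = []
    for t in range(l):
        gates = X[t : t + 1] @ Wx + h @ Wh + b
        i = gates[:, :h_dim].sigmoid()
        f = gates[:, h_dim : 2 * h_dim].sigmoid()
        g = gates[:, 2 * h_dim : 3 * h_dim].tanh()
        o = gates[:, 3 * h_dim :].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        outputs.append(h)
    return concat(outputs, axis=0)


def _causal_attention(
    H: Tensor, params: Mapping[str, Tensor], config: AggregatorConfig
) -> Tensor:
    l = H.shape[0]
    h_dim, n_heads = config.recurrent_hidden, config.attention_heads
    dk = h_dim // n_heads
    mask_add = np.where(causal_mask(l), 0.0, _MASK_NEG)
    Q = H @ params["attn.Wq"]
    K = H @ params["attn.Wk"]
    V = H @ params["attn.Wv"]
    heads = []
    for i in range(n_heads):
        sl = slice(i * dk, (i + 1) * dk)
        scores = (Q[:, sl] @ K[:, sl].T) * (dk**-0.5) + mask_add
        heads.append(softmax_rows(scores) @ V[:, sl])
    return concat(heads, axis=1) @ params["attn.Wo"]


def forward_logits(
    E: Tensor, params: Mapping[str, Tensor], config: AggregatorConfig
) -> Tensor:
    """Logits for all timesteps simultaneously from an (l, d) embedding
    matrix.  Used both for training (gradients flow through E when the
    encoder is trainable) and prediction."""
    if E.shape[0] < 1:
        raise InputError("empty embedding sequence")
    if E.shape[1] != config.input_dim:
        raise InputError(
            f"embedding dim {E.shape[1]} != configured input_dim {config.input_dim}"
        )
    X = E @ params["proj.W"] + params["proj.b"]
    if config.single_report:
        out = X
    else:
        H = _lstm(X, params, config.recurrent_hidden)
        out = _causal_attention(H, params, config)
    logits = out @ params["head.W"] + params["head.b"]
    return logits.reshape(-1)


def forward_logits_batched(
    E_pad: Tensor,
    lengths: list[int],
    params: Mapping[str, Tensor],
    config: AggregatorConfig,
) -> Tensor:
    """Logits for a zero-padded batch of patients: (B, L, d) -> flat logits
    at valid positions, in row-major (patient, timestep) order.

    Padding sits at the tail of each timeline, and both the LSTM and the
    causal attention only let information flow forward, so valid positions
    are unaffected by the padding; padded outputs are simply dropped.
    """
    B, L, d = E_pad.shape
    if d != config.input_dim:
        raise InputError(
            f"embedding dim {d} != configured input_dim {config.input_dim}"
        )
    p_dim = config.projected_dim
    X2 = E_pad.reshape(B * L, d) @ params["proj.W"] + params["proj.b"]
    if config.single_report:
        out2 = X2
    else:
        h_dim = config.recurrent_hidden
        gates_x = (X2 @ params["lstm.Wx"] + params["lstm.b"]).reshape(B, L, 4 * h_dim)
        Wh = params["lstm.Wh"]
        h = Tensor(np.zeros((B, h_dim)))
        c = Tensor(np.zeros((B, h_dim)))
        outputs = []
        for t in range(L):
            gates = gates_x[:, t, :] + h @ Wh
            i = gates[:, :h_dim].sigmoid()
            f = gates[:, h_dim : 2 * h_dim].sigmoid()
            g = gates[:, 2 * h_dim : 3 * h_dim].tanh()
            o = gates[:, 3 * h_dim :].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs.append(h.reshape(B, 1, h_dim))
        H = concat(outputs, axis=1)
        H2 = H.reshape(B * L, h_dim)
        n_heads = config.attention_heads
        dk = h_dim // n_heads
        mask_add = np.where(causal_mask(L), 0.0, _MASK_NEG)
        Q = (H2 @ params["attn.Wq"]).reshape(B, L, h_dim)
        K = (H2 @ params["attn.Wk"]).reshape(B, L, h_dim)
        V = (H2 @ params["attn.Wv"]).reshape(B, L, h_dim)
        heads = []
        for i_h in range(n_heads):
            sl = (slice(None), slice(None), slice(i_h * dk, (i_h + 1) * dk))
            scores = bmm(Q[sl], K[sl], transpose_b=True) * (dk**-0.5) + mask_add
            heads.append(bmm(softmax_rows(scores), V[sl]))
        out2 = concat(heads, axis=2).reshape(B * L, h_dim) @ params["attn.Wo"]
    logits = (out2 @ params["head.W"] + params["head.b"]).reshape(B, L)
    valid = np.zeros((B, L), dtype=bool)
    for b, l in enumerate(lengths):
        valid[b, :l] = True
    return logits[valid]


def forward_patient(
    embeddings: list, params: Mapping[str, Tensor], config: AggregatorConfig
) -> PredictionSeries:
    """Probability series for one patient from precomputed embeddings."""
    if not embeddings:
        raise InputError("empty embedding sequence")
    E = Tensor(np.stack([e.vector for e in embeddings]))
    logits = forward_logits(E, params, config)
    pid = embeddings[0].report_id.rsplit("-r", 1)[0]
    return PredictionSeries(pid, 1.0 / (1.0 + np.exp(-logits.value)))


# ---------------------------------------------------------------------------
# Full classifier: encoder + aggregator
# ---------------------------------------------------------------------------


class MetastasisModel:
    """Classifier F: report texts -> per-timestep metastasis probabilities.

    Couples an encoder (hashed n-gram features by default, or the tiny
    transformer with an optional PEFT regime) with the aggregator head.
    Hashed embeddings are cached per report id since they never change
    during optimization.
    """

    def __init__(
        self,
        encoder_config: EncoderConfig,
        aggregator_config: AggregatorConfig,
        enc_params: dict[str, Tensor] | None = None,
        peft_state: PeftState | None = None,
    ):
        if aggregator_config.input_dim != encoder_config.dim:
            raise ConfigurationError("aggregator input_dim must equal encoder dim")
        self.encoder_config = encoder_config
        self.aggregator_config = aggregator_config
        self.params = init_aggregator_params(aggregator_config)
        self.enc_params = enc_params
        self.peft_state = peft_state
        if encoder_config.kind == "tiny_transformer" and enc_params is None:
            raise ConfigurationError("tiny_transformer encoder requires enc_params")
        self._cache: dict[str, np.ndarray] = {}

    # -- embeddings --------------------------------------------------------

    def _hashed_vector(self, report: Report) -> np.ndarray:
        vec = self._cache.get(report.report_id)
        if vec is None:
            vec = embed_hashed_text(
                report.text(self.encoder_config.input_mode), self.encoder_config.dim
            )
            self._cache[report.report_id] = vec
        return vec

    def _embedding_tensor(self, patient: Patient) -> Tensor:
        if self.encoder_config.kind == "tiny_transformer":
            rows = [
                tiny_transformer_forward(
                    r.text(self.encoder_config.input_mode),
                    self.enc_params,
                    self.encoder_config,
                    self.peft_state,
                ).reshape(1, -1)
                for r in patient.reports
            ]
            return concat(rows, axis=0)
        return Tensor(np.stack([self._hashed_vector(r) for r in patient.reports]))

    # -- training / prediction surface ------------------------------------

    def trainable(self) -> list[Tensor]:
        out = list(self.params.values())
        if self.encoder_config.kind == "tiny_transformer":
            out += trainable_tensors(self.enc_params, self.peft_state)
        return out

    def patient_logits(self, patient: Patient) -> Tensor:
        if not patient.reports:
            raise InputError(f"patient {patient.patient_id} has no reports")
        E = self._embedding_tensor(patient)
        return forward_logits(E, self.params, self.aggregator_config)

    def batch_logits(self, patients: list[Patient]) -> tuple[Tensor, np.ndarray]:
        """Flat logits and aligned labels for a batch, via the padded batched
        forward (hashed encoder) or per-patient passes (trainable encoder)."""
        targets = np.concatenate(
            [np.array(p.labels, dtype=float) for p in patients]
        )
        if self.encoder_config.kind == "tiny_transformer":
            logits = concat([self.patient_logits(p) for p in patients], axis=0)
            return logits, targets
        lengths = [len(p.reports) for p in patients]
        L = max(lengths)
        E_pad = np.zeros((len(patients), L, self.encoder_config.dim))
        for b, p in enumerate(patients):
            for t, r in enumerate(p.reports):
                E_pad[b, t] = self._hashed_vector(r)
        logits = forward_logits_batched(
            Tensor(E_pad), lengths, self.params, self.aggregator_config
        )
        return logits, targets

    def batch_predict(self, patients: list[Patient]) -> list[np.ndarray]:
        """Per-patient probability arrays (no gradient bookkeeping kept).

        Internally chunks by timeline length to keep padding small."""
        order = sorted(range(len(patients)), key=lambda i: len(patients[i].reports))
        results: list[np.ndarray | None] = [None] * len(patients)
        for s in range(0, len(order), 128):
            idx = order[s : s + 128]
            chunk = [patients[i] for i in idx]
            logits, _ = self.batch_logits(chunk)
            probs = 1.0 / (1.0 + np.exp(-logits.value))
            offset = 0
            for i, p in zip(idx, chunk):
                results[i] = probs[offset : offset + len(p.reports)]
                offset += len(p.reports)
        return results

    def predict(self, patient: Patient) -> PredictionSeries:
        logits = self.patient_logits(patient).value
        return PredictionSeries(patient.patient_id, 1.0 / (1.0 + np.exp(-logits)))

    # -- checkpointing -----------------------------------------------------

    def state_values(self) -> list[np.ndarray]:
        return [t.value.copy() for t in self.trainable()]

    def load_state_values(self, values: list[np.ndarray]) -> None:
        tensors = self.trainable()
        if len(values) != len(tensors):
            raise InputError("state size mismatch")
        for t, v in zip(tensors, values):
            t.value = np.asarray(v, dtype=np.float64).reshape(t.value.shape)

    def save(self, path) -> None:
        payload = {
            "encoder_config": asdict(self.encoder_config),
            "aggregator_config": asdict(self.aggregator_config),
            "aggregator_params": {k: v.value.tolist() for k, v in self.params.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "MetastasisModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        enc = EncoderConfig(**payload["encoder_config"])
        agg = AggregatorConfig(**payload["aggregator_config"])
        model = cls(enc, agg)
        for k, v in payload["aggregator_params"].items():
            model.params[k].value = np.asarray(v, dtype=np.float64)
        return model
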