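"""Encoders and parameter-efficient adaptation (LoRA, deep prompts).

The tiny-transformer forward pass is checked against an independent
plain-numpy reimplementation (no autodiff graph), for the base model and
for both adaptation regimes.
"""

import numpy as np
import pytest

from metaug.encoder import (
    EncoderConfig,
    LoRASpec,
    PrefixSpec,
    ReportEmbedding,
    attach_lora,
    attach_prefix,
    embed_hashed,
    embed_hashed_text,
    hash_token,
    init_tiny_transformer,
    merge_lora,
    tiny_transformer_forward,
    tokenize,
    total_parameter_count,
    trainable_parameter_count,
    trainable_tensors,
)
from metaug.errors import ConfigurationError, NumericError, StateError

from conftest import make_report

TEXTS = [
    "New hepatic metastases are identified in the right lobe.",
    "Stable exam. No new or enlarging liver lesions are seen today.",
    "A tiny 3 mm calcified granuloma is unchanged from the prior study.",
    "Interval growth of the dominant segment seven lesion is noted.",
    "The pancreas, spleen and adrenal glands are normal in appearance.",
]


def tiny_config(**kwargs) -> EncoderConfig:
    base = dict(kind="tiny_transformer", dim=32, seed=0)
    base.update(kwargs)
    return EncoderConfig(**base)


# ---------------------------------------------------------------------------
# Independent numpy oracle for the tiny transformer
# ---------------------------------------------------------------------------


def np_forward(text, params, config, peft=None):
    P = {k: v.value for k, v in params.items()}
    ids = [hash_token(t, config.vocab_hash_size) for t in tokenize(text)]
    ids = ids[: config.max_tokens] or [0]
    x = P["tok_emb"][np.array(ids)] + P["pos_emb"][: len(ids)]

    def ln(x, g, b):
        mu = x.mean(-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(-1, keepdims=True)
        return xc / np.sqrt(var + 1e-5) * g + b

    dk = config.width // config.heads
    for i in range(config.layers):
        h = ln(x, P[f"l{i}.ln1.g"], P[f"l{i}.ln1.b"])
        Wq, Wv = P[f"l{i}.Wq"], P[f"l{i}.Wv"]
        if peft is not None and peft.kind == "lora":
            s = peft.spec
            if "query" in s.target_projections:
                Wq = Wq + s.scaling * (
                    peft.tensors[f"l{i}.query.B"].value
                    @ peft.tensors[f"l{i}.query.A"].value
                )
            if "value" in s.target_projections:
                Wv = Wv + s.scaling * (
                    peft.tensors[f"l{i}.value.B"].value
                    @ peft.tensors[f"l{i}.value.A"].value
                )
        Q, K, V = h @ Wq, h @ P[f"l{i}.Wk"], h @ Wv
        if peft is not None and peft.kind == "prefix":
            K = np.vstack([peft.tensors[f"l{i}.Pk"].value, K])
            V = np.vstack([peft.tensors[f"l{i}.Pv"].value, V])
        outs = []
        for j in range(config.heads):
            sl = slice(j * dk, (j + 1) * dk)
            scores = Q[:, sl] @ K[:, sl].T / np.sqrt(dk)
            scores -= scores.max(-1, keepdims=True)
            a = np.exp(scores)
            a /= a.sum(-1, keepdims=True)
            outs.append(a @ V[:, sl])
        x = x + np.hstack(outs) @ P[f"l{i}.Wo"]
        h = ln(x, P[f"l{i}.ln2.g"], P[f"l{i}.ln2.b"])
        ff = np.maximum(h @ P[f"l{i}.ff.W1"] + P[f"l{i}.ff.b1"], 0.0)
        x = x + ff @ P[f"l{i}.ff.W2"] + P[f"l{i}.ff.b2"]
    return x.mean(0) @ P["out.W"] + P["out.b"]


# ---------------------------------------------------------------------------
# Hashed encoder
# ---------------------------------------------------------------------------


class TestHashedEncoder:
    def test_tokenize_lowercases_and_keeps_digits(self):
        assert tokenize("A 8 mm CYST, stable.") == ["a", "8", "mm", "cyst", "stable"]

    def test_hash_token_stable_and_in_range(self):
        for tok in ("liver", "metastases", "8"):
            h = hash_token(tok, 2048)
            assert h == hash_token(tok, 2048)
            assert 0 <= h < 2048

    def test_unit_norm_and_determinism(self):
        v = embed_hashed_text(TEXTS[0], 768)
        assert np.linalg.norm(v) == pytest.approx(1.0)
        assert np.array_equal(v, embed_hashed_text(TEXTS[0], 768))

    def test_empty_text_is_zero_vector(self):
        assert np.all(embed_hashed_text("", 64) == 0.0)

    def test_report_embedding_shape(self):
        report = make_report("x-p1", 0, TEXTS[1])
        emb = embed_hashed(report, EncoderConfig(dim=768))
        assert emb.vector.shape == (768,)
        assert emb.report_id == report.report_id

    def test_non_finite_embedding_rejected(self):
        with pytest.raises(NumericError):
            ReportEmbedding(np.array([1.0, np.nan]), "x")

    @pytest.mark.parametrize(
        "kwargs",
        [dict(kind="bert"), dict(width=65), dict(dim=0), dict(input_mode="full")],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            EncoderConfig(**kwargs)


# ---------------------------------------------------------------------------
# Tiny transformer
# ---------------------------------------------------------------------------


class TestTinyTransformer:
    def test_forward_matches_numpy_oracle(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        for text in TEXTS:
            out = tiny_transformer_forward(text, params, config).value
            assert out.shape == (32,)
            np.testing.assert_allclose(out, np_forward(text, params, config), atol=1e-10)

    def test_deterministic_in_seed(self):
        config = tiny_config(seed=3)
        a = init_tiny_transformer(config)
        b = init_tiny_transformer(config)
        out_a = tiny_transformer_forward(TEXTS[0], a, config).value
        out_b = tiny_transformer_forward(TEXTS[0], b, config).value
        assert np.array_equal(out_a, out_b)

    def test_truncation_beyond_max_tokens(self):
        config = tiny_config(max_tokens=4)
        params = init_tiny_transformer(config)
        long_text = "alpha beta gamma delta epsilon zeta"
        head_text = "alpha beta gamma delta"
        out_long = tiny_transformer_forward(long_text, params, config).value
        out_head = tiny_transformer_forward(head_text, params, config).value
        assert np.array_equal(out_long, out_head)

    def test_empty_text_still_finite(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        out = tiny_transformer_forward("", params, config).value
        assert np.all(np.isfinite(out))

    def test_total_parameter_count_formula(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        w, L, V, T, d = 64, 2, 2048, 64, 32
        per_layer = 4 * w * w + 4 * w + (w * 2 * w + 2 * w + 2 * w * w + w)
        expected = V * w + T * w + w * d + d + L * per_layer
        assert total_parameter_count(params) == expected


# ---------------------------------------------------------------------------
# LoRA
# ---------------------------------------------------------------------------


class TestLoRA:
    def test_attachment_is_bit_exact_identity(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        peft = attach_lora(params, LoRASpec(), config, seed=1)
        for text in TEXTS:
            base = tiny_transformer_forward(text, params, config).value
            adapted = tiny_transformer_forward(text, params, config, peft).value
            assert np.array_equal(base, adapted)

    def test_trainable_count_formula(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        peft = attach_lora(params, LoRASpec(rank=4), config)
        # [DERIVED by hand: rank·(width + width) = 4·128 = 512 per
        #  target projection per layer; 2 targets × 2 layers -> 2048]
        assert trainable_parameter_count(params, peft) == 2048

    def test_trainable_fraction_small(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        peft = attach_lora(params, LoRASpec(), config)
        frac = trainable_parameter_count(params, peft) / total_parameter_count(params)
        assert frac < 0.05

    def test_base_weights_frozen_under_lora(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        peft = attach_lora(params, LoRASpec(), config)
        trainables = set(map(id, trainable_tensors(params, peft)))
        assert trainables == set(map(id, peft.tensors.values()))
        assert not trainables & set(map(id, params.values()))

    def test_adapted_forward_matches_numpy_oracle(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        peft = attach_lora(params, LoRASpec(rank=3, scaling=0.5), config, seed=2)
        rng = np.random.default_rng(0)
        for t in peft.tensors.values():  # make B nonzero, as after training
            t.value = rng.normal(0, 0.1, size=t.value.shape)
        for text in TEXTS:
            out = tiny_transformer_forward(text, params, config, peft).value
            np.testing.assert_allclose(
                out, np_forward(text, params, config, peft), atol=1e-10
            )

    def test_merge_matches_adapter_within_tolerance(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        peft = attach_lora(params, LoRASpec(rank=4, scaling=1.0), config, seed=3)
        rng = np.random.default_rng(7)
        for t in peft.tensors.values():
            t.value = rng.normal(0, 0.1, size=t.value.shape)
        merged = merge_lora(params, peft)
        texts = [f"report number {i} mentions a hepatic lesion measured at {i} mm." for i in range(100)]
        for text in texts:
            adapted = tiny_transformer_forward(text, params, config, peft).value
            folded = tiny_transformer_forward(text, merged, config).value
            np.testing.assert_allclose(folded, adapted, atol=1e-5)

    def test_double_merge_rejected(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        peft = attach_lora(params, LoRASpec(), config)
        merge_lora(params, peft)
        with pytest.raises(StateError):
            merge_lora(params, peft)

    def test_merge_requires_lora_state(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        prefix = attach_prefix(params, PrefixSpec(), config)
        with pytest.raises(StateError):
            merge_lora(params, prefix)

    def test_rank_exceeding_width_rejected(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        with pytest.raises(ConfigurationError):
            attach_lora(params, LoRASpec(rank=65), config)

    def test_invalid_target_rejected(self):
        with pytest.raises(ConfigurationError):
            LoRASpec(target_projections=("key",))


# ---------------------------------------------------------------------------
# Deep prompt-tuning
# ---------------------------------------------------------------------------


class TestPrefix:
    def test_trainable_count_formula(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        peft = attach_prefix(params, PrefixSpec(prompt_length=8), config)
        # [DERIVED by hand: layers·prompt_length·2·width = 2·8·2·64 = 2048]
        assert trainable_parameter_count(params, peft) == 2048

    def test_prefix_forward_matches_numpy_oracle(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        peft = attach_prefix(params, PrefixSpec(prompt_length=5), config, seed=4)
        for text in TEXTS:
            out = tiny_transformer_forward(text, params, config, peft).value
            np.testing.assert_allclose(
                out, np_forward(text, params, config, peft), atol=1e-10
            )

    def test_prefix_changes_output(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        peft = attach_prefix(params, PrefixSpec(), config, seed=1)
        base = tiny_transformer_forward(TEXTS[0], params, config).value
        adapted = tiny_transformer_forward(TEXTS[0], params, config, peft).value
        assert not np.allclose(base, adapted)

    def test_init_from_token_ids_cycles_embedding_rows(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        spec = PrefixSpec(prompt_length=5, init_token_ids=(3, 9))
        peft = attach_prefix(params, spec, config)
        emb = params["tok_emb"].value
        expected = np.array([emb[3], emb[9], emb[3], emb[9], emb[3]])
        for i in range(config.layers):
            assert np.array_equal(peft.tensors[f"l{i}.Pk"].value, expected)
            assert np.array_equal(peft.tensors[f"l{i}.Pv"].value, expected)

    def test_base_weights_frozen_under_prefix(self):
        config = tiny_config()
        params = init_tiny_transformer(config)
        peft = attach_prefix(params, PrefixSpec(), config)
        trainables = set(map(id, trainable_tensors(params, peft)))
        assert trainables == set(map(id, peft.tensors.values()))

    def test_invalid_prompt_length_rejected(self):
        with pytest.raises(ConfigurationError):
            PrefixSpec(prompt_length=0)
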