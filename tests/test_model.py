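"""Patchification, fusion, patch dropout and transformer forward contracts."""

import numpy as np
import pytest
from scipy import stats

from nmr2struct import autodiff as ad
from nmr2struct.model import (
    ModelConfig,
    SpectrumTransformer,
    patch_dropout,
    patch_dropout_indices,
    patchify_1d,
    patchify_2d,
    unpatchify_1d,
    unpatchify_2d,
)
from nmr2struct.tokenizer import build_vocab

from conftest import small_model_config

RNG = np.random.default_rng(7)


def tiny_model(**overrides):
    vocab = build_vocab([["C", "O", "1", "c", "(", ")", "="], ["H", "2", "6"]])
    return SpectrumTransformer(small_model_config(**overrides), vocab, seed=3)


class TestPatchify:
    @pytest.mark.parametrize("patch_len", [1, 8, 50, 125, 1000])
    def test_1d_roundtrip_bitwise(self, patch_len):
        x = RNG.random(1000)
        patches = patchify_1d(x, patch_len)
        assert patches.shape == (1000 // patch_len, patch_len)
        assert np.array_equal(unpatchify_1d(patches), x)

    def test_1d_default_geometry_patch_count(self):
        assert patchify_1d(RNG.random(10_000), 50).shape == (200, 50)

    def test_1d_whole_vector_single_patch(self):
        x = RNG.random(120)
        patches = patchify_1d(x, 120)
        assert patches.shape == (1, 120)
        assert np.array_equal(patches[0], x)

    def test_1d_nondivisible_is_error(self):
        with pytest.raises(ValueError, match="divide"):
            patchify_1d(RNG.random(100), 33)

    @pytest.mark.parametrize("patch_size", [1, 4, 16, 64])
    def test_2d_roundtrip_bitwise(self, patch_size):
        x = RNG.random((64, 64))
        patches = patchify_2d(x, patch_size)
        n = (64 // patch_size) ** 2
        assert patches.shape == (n, patch_size**2)
        assert np.array_equal(unpatchify_2d(patches, (64, 64)), x)

    def test_2d_default_geometry(self):
        patches = patchify_2d(RNG.random((256, 256)), 16)
        assert patches.shape == (256, 256)

    def test_2d_patch_order_row_major(self):
        x = np.arange(16.0).reshape(4, 4)
        patches = patchify_2d(x, 2)
        assert np.array_equal(patches[0], [0, 1, 4, 5])
        assert np.array_equal(patches[1], [2, 3, 6, 7])

    def test_2d_nondivisible_is_error(self):
        with pytest.raises(ValueError, match="divide"):
            patchify_2d(RNG.random((30, 30)), 7)


class TestPatchDropout:
    def test_exact_survivor_count(self):
        idx = patch_dropout_indices(656, 0.5, np.random.default_rng(0), batch=3)
        assert idx.shape == (3, 328)
        for row in idx:
            assert len(set(row)) == 328
            assert np.array_equal(row, np.sort(row))

    def test_rate_zero_and_inference_are_identity(self):
        x = ad.Tensor(RNG.random((2, 10, 4)).astype(np.float32))
        out, idx = patch_dropout(x, 0.0, training=True, rng=np.random.default_rng(0))
        assert idx is None and np.array_equal(out.data, x.data)
        out, idx = patch_dropout(x, 0.9, training=False)
        assert idx is None and np.array_equal(out.data, x.data)

    def test_invalid_rate_rejected(self):
        x = ad.Tensor(np.zeros((1, 4, 2), dtype=np.float32))
        for rate in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                patch_dropout(x, rate, training=True, rng=np.random.default_rng(0))

    def test_keep_frequency_uniform_across_tokens(self):
        # each token kept ~Binomial(500, 0.5): all within the 99% interval
        n, draws, rate = 64, 500, 0.5
        rng = np.random.default_rng(123)
        counts = np.zeros(n)
        for _ in range(draws):
            counts[patch_dropout_indices(n, rate, rng)[0]] += 1
        lo, hi = stats.binom.ppf([0.005, 0.995], draws, 1 - rate)
        assert counts.min() >= lo and counts.max() <= hi


class TestEncoder:
    def test_fused_length_is_sum_of_patch_counts(self):
        model = tiny_model(modalities=("H1", "C13", "HSQC"))
        patches = {
            "H1": RNG.random((2, 10, 50)).astype(np.float32),
            "C13": RNG.random((2, 10, 50)).astype(np.float32),
            "HSQC": RNG.random((2, 16, 64)).astype(np.float32),
        }
        fused = model.embed_and_fuse(patches)
        assert fused.shape == (2, 36, model.config.d_model)

    def test_single_modality_fusion_is_degenerate(self):
        model = tiny_model(modalities=("H1",))
        patches = {"H1": RNG.random((1, 10, 50)).astype(np.float32)}
        fused = model.embed_and_fuse(patches)
        assert fused.shape == (1, 10, 32)

    def test_projections_are_modality_specific(self):
        model = tiny_model(modalities=("H1", "C13"))
        a = RNG.random((1, 10, 50)).astype(np.float32)
        b = RNG.random((1, 10, 50)).astype(np.float32)
        fused_ab = model.embed_and_fuse({"H1": a, "C13": b})
        fused_ba = model.embed_and_fuse({"H1": b, "C13": a})
        assert not np.allclose(fused_ab.data, fused_ba.data)

    def test_encode_shape_and_determinism_at_inference(self):
        model = tiny_model()
        patches = {"H1": RNG.random((2, 10, 50)).astype(np.float32)}
        m1 = model.encode(patches, training=False)
        m2 = model.encode(patches, training=False)
        assert m1.shape == (2, 10, 32)
        assert np.array_equal(m1.data, m2.data)

    def test_empty_stream_rejected(self):
        model = tiny_model()
        with pytest.raises(ValueError, match="empty|no modalities"):
            model.encode({}, training=False)

    def test_encoder_permutation_equivariance(self):
        # positions travel with tokens, so permuting the fused stream
        # permutes the output identically
        model = tiny_model()
        tokens = model.embed_and_fuse({"H1": RNG.random((1, 10, 50)).astype(np.float32)})
        perm = np.random.default_rng(0).permutation(10)
        permuted = ad.Tensor(tokens.data[:, perm, :])
        out = model.encode_tokens(tokens).data
        out_perm = model.encode_tokens(permuted).data
        assert np.allclose(out[:, perm, :], out_perm, atol=1e-5)

    def test_adding_a_modality_adds_only_embedding_parameters(self):
        m1 = tiny_model(modalities=("H1",))
        m2 = tiny_model(modalities=("H1", "C13"))
        extra = {k for k in m2.params if k not in m1.params}
        assert extra == {"embed.C13.w", "embed.C13.b", "embed.C13.pos"}


class TestDecoder:
    def test_causality(self):
        model = tiny_model()
        memory = model.encode({"H1": RNG.random((1, 10, 50)).astype(np.float32)})
        ids = RNG.integers(0, len(model.vocab), size=(1, 12))
        with ad.no_grad():
            base = model.decode(memory, ids).data
        ids2 = ids.copy()
        ids2[0, 8] = (ids2[0, 8] + 1) % len(model.vocab)
        with ad.no_grad():
            changed = model.decode(memory, ids2).data
        assert np.allclose(base[0, :8], changed[0, :8], atol=1e-6)
        assert not np.allclose(base[0, 8:], changed[0, 8:], atol=1e-6)

    def test_formula_prefix_conditions_smiles_logits(self):
        model = tiny_model()
        memory = model.encode({"H1": RNG.random((1, 10, 50)).astype(np.float32)})
        ids = RNG.integers(5, len(model.vocab), size=(1, 20))
        ids2 = ids.copy()
        ids2[0, 0] = (ids2[0, 0] + 1) % len(model.vocab)
        with ad.no_grad():
            a = model.decode(memory, ids).data
            b = model.decode(memory, ids2).data
        assert not np.allclose(a[0, 16:], b[0, 16:], atol=1e-6)

    def test_cross_attention_is_live(self):
        model = tiny_model()
        memory = model.encode({"H1": RNG.random((1, 10, 50)).astype(np.float32)})
        zeroed = ad.Tensor(np.zeros_like(memory.data))
        ids = RNG.integers(0, len(model.vocab), size=(1, 8))
        with ad.no_grad():
            a = model.decode(memory, ids).data
            b = model.decode(zeroed, ids).data
        assert not np.allclose(a, b, atol=1e-6)

    def test_overlong_input_rejected(self):
        model = tiny_model()
        memory = model.encode({"H1": RNG.random((1, 10, 50)).astype(np.float32)})
        ids = np.zeros((1, model.config.max_decode_len + 1), dtype=np.int64)
        with pytest.raises(ValueError, match="max_decode_len"):
            model.decode(memory, ids)


class TestConfigAndCheckpoint:
    def test_config_invariants(self):
        with pytest.raises(ValueError, match="divisible"):
            small_model_config(d_model=30, n_heads=4)
        with pytest.raises(ValueError, match="rate"):
            small_model_config(patch_dropout_rate=1.0)
        with pytest.raises(ValueError, match="divide"):
            small_model_config(patch_len_1d=33)

    def test_checkpoint_roundtrip(self, tmp_path):
        model = tiny_model()
        path = tmp_path / "model.npz"
        model.save(path)
        back = SpectrumTransformer.load(path)
        assert back.config == model.config
        assert back.vocab.token_to_id == model.vocab.token_to_id
        for k in model.params:
            assert np.array_equal(back.params[k].data, model.params[k].data)

    def test_parameter_count_independent_of_input(self):
        model = tiny_model()
        n0 = model.parameter_count()
        model.encode({"H1": RNG.random((1, 10, 50)).astype(np.float32)})
        assert model.parameter_count() == n0
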