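"""Unit and property tests of the two building blocks and the tokenizer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafvit.blocks import (
    ConvBlock,
    ConvBlockConfig,
    MultiHeadAttention,
    PatchEmbed,
    PatchEmbedConfig,
    PatchExtract,
    TokensToGrid,
    TransformerBlock,
    TransformerBlockConfig,
    conv_block_apply,
    extract_patches,
    tokens_to_grid,
    transformer_block_apply,
)

RNG = np.random.default_rng(42)


def zero_weights(layer):
    for sub in getattr(layer, "sublayers", (layer,)):
        for k in sub.params:
            if k not in ("gamma",):  # keep layer-norm scale at 1
                sub.params[k] = np.zeros_like(sub.params[k])


# ---------------------------------------------------------------------------
# Convolutional block
# ---------------------------------------------------------------------------

class TestConvBlock:
    @pytest.mark.parametrize("side,expected", [(50, 23), (100, 48), (200, 98)])
    def test_output_side(self, side, expected):
        blk = ConvBlock(3, ConvBlockConfig(), rng=RNG)
        assert blk.out_shape((side, side, 3)) == (expected, expected, 16)

    def test_chained_shape_arithmetic(self):
        # two stacked blocks from side 200: 200 -> 98 -> 47
        b1 = ConvBlock(3, ConvBlockConfig(), rng=RNG)
        b2 = ConvBlock(16, ConvBlockConfig(), rng=RNG)
        s = b2.out_shape(b1.out_shape((200, 200, 3)))
        assert s == (47, 47, 16)

    @given(side=st.integers(min_value=6, max_value=80))
    @settings(max_examples=20, deadline=None)
    def test_shape_formula_property(self, side):
        blk = ConvBlock(3, ConvBlockConfig(filters=2), rng=RNG)
        h, w, c = blk.out_shape((side, side, 3))
        assert h == w == (side - 4) // 2
        assert c == 2

    def test_forward_shape_and_zero_weights(self):
        blk = ConvBlock(3, ConvBlockConfig(), rng=RNG)
        x = RNG.random((2, 50, 50, 3))
        out = blk.forward(x)
        assert out.shape == (2, 23, 23, 16)
        zero_weights(blk)
        assert np.all(blk.forward(x) == 0.0)

    def test_too_small_input_names_layer(self):
        blk = ConvBlock(3, ConvBlockConfig(), name="blk", rng=RNG)
        with pytest.raises(ValueError, match="conv"):
            blk.forward(RNG.random((1, 4, 4, 3)))

    def test_activation_only_after_second_conv(self):
        # first conv is linear: negating its weights negates its
        # contribution exactly (a nonlinearity in between would break this)
        blk = ConvBlock(3, ConvBlockConfig(filters=2, leaky_slope=0.3),
                        rng=RNG)
        x = RNG.random((1, 10, 10, 3))
        blk.conv2.params["w"] = np.zeros_like(blk.conv2.params["w"])
        blk.conv2.params["b"] = np.array([1.0, -1.0])
        out = blk.forward(x)
        # conv2 output is constant (+1, -1); leaky ReLU maps to (1, -0.3)
        assert np.allclose(out[..., 0], 1.0)
        assert np.allclose(out[..., 1], -0.3)

    def test_functional_wrapper_single_image(self):
        blk = ConvBlock(3, ConvBlockConfig(), rng=RNG)
        single = conv_block_apply(RNG.random((50, 50, 3)), blk)
        assert single.shape == (23, 23, 16)


# ---------------------------------------------------------------------------
# Patch extraction and embedding
# ---------------------------------------------------------------------------

class TestPatches:
    @pytest.mark.parametrize("side,patch,n,veclen", [
        (200, 20, 100, 1200),
        (50, 7, 49, 147),
    ])
    def test_patch_counts(self, side, patch, n, veclen):
        cfg = PatchEmbedConfig(patch_side=patch)
        out = extract_patches(RNG.random((side, side, 3)), cfg)
        assert out.shape == (n, veclen)

    def test_margin_dropped_and_retiling_inverse(self):
        img = RNG.random((50, 50, 3))
        cfg = PatchEmbedConfig(patch_side=7)
        pat = extract_patches(img, cfg)
        # re-tile: inverse of row-major extraction restores the cropped square
        g, p = 7, 7
        rebuilt = pat.reshape(g, g, p, p, 3).transpose(0, 2, 1, 3, 4)
        rebuilt = rebuilt.reshape(g * p, g * p, 3)
        assert np.array_equal(rebuilt, img[:49, :49, :])

    def test_patch_too_large_errors(self):
        with pytest.raises(ValueError, match="patch"):
            extract_patches(RNG.random((10, 10, 3)),
                            PatchEmbedConfig(patch_side=11))

    def test_embed_shape_and_zero_weights(self):
        emb = PatchEmbed(147, 49, 64, rng=RNG)
        pat = RNG.random((2, 49, 147))
        assert emb.forward(pat).shape == (2, 49, 64)
        emb.params["w"][:] = 0.0
        emb.params["b"][:] = 0.0
        emb.params["pos"][:] = 0.0
        assert np.all(emb.forward(pat) == 0.0)

    def test_positional_encoding_breaks_permutation_symmetry(self):
        emb = PatchEmbed(10, 4, 8, rng=RNG)
        emb.params["pos"] = RNG.normal(size=(4, 8))
        pat = RNG.random((1, 4, 10))
        out = emb.forward(pat)
        perm = pat[:, [1, 0, 2, 3], :]
        out_perm = emb.forward(perm)
        # tokens 0 and 1 differ from the merely-swapped originals
        assert not np.allclose(out_perm[:, 0], out[:, 1])


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

class TestAttention:
    def test_attention_rows_sum_to_one(self):
        attn = MultiHeadAttention(64, 4, rng=RNG)
        attn.forward(RNG.random((2, 9, 64)))
        sums = attn.last_attention.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_identical_tokens_give_identical_outputs(self):
        attn = MultiHeadAttention(8, 2, rng=RNG)
        tok = np.tile(RNG.random((1, 1, 8)), (1, 5, 1))
        out = attn.forward(tok)
        assert np.allclose(out, out[:, :1, :])

    def test_single_token_is_projected_value(self):
        attn = MultiHeadAttention(8, 2, rng=RNG)
        tok = RNG.random((1, 1, 8))
        out = attn.forward(tok)
        v = tok @ attn.params["wv"] + attn.params["bv"]
        expected = v @ attn.params["wo"] + attn.params["bo"]
        assert np.allclose(out, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# Transformer block
# ---------------------------------------------------------------------------

class TestTransformerBlock:
    def test_shape_preserving(self):
        blk = TransformerBlock(TransformerBlockConfig(), rng=RNG)
        tok = RNG.random((3, 49, 64))
        assert blk.forward(tok).shape == tok.shape

    def test_zero_weights_is_identity(self):
        blk = TransformerBlock(TransformerBlockConfig(), rng=RNG)
        zero_weights(blk)
        tok = RNG.random((2, 9, 64))
        assert np.max(np.abs(blk.forward(tok) - tok)) < 1e-6

    def test_matches_scalar_loop_oracle(self):
        """Vectorised block output equals a plain nested-loop recomputation
        of layer-norm, single-head attention, and the gelu MLP."""
        cfg = TransformerBlockConfig(num_heads=1, proj_dim=4,
                                     mlp_widths=(5, 4), dropout=0.0)
        blk = TransformerBlock(cfg, rng=np.random.default_rng(5))
        # nonzero norm offsets exercise the full formula
        blk.ln1.params["beta"] = np.array([0.1, -0.2, 0.0, 0.3])
        tok = np.random.default_rng(6).normal(size=(1, 3, 4))
        out = blk.forward(tok)[0]

        def layer_norm(vec, gamma, beta, eps=1e-6):
            m = sum(vec) / len(vec)
            var = sum((v - m) ** 2 for v in vec) / len(vec)
            return [(v - m) / math.sqrt(var + eps) * g + b
                    for v, g, b in zip(vec, gamma, beta)]

        def affine(vec, w, b):
            return [sum(vec[i] * w[i][j] for i in range(len(vec))) + b[j]
                    for j in range(len(b))]

        def gelu(v):
            return v * 0.5 * (1.0 + math.erf(v / math.sqrt(2.0)))

        x = [list(row) for row in tok[0]]
        p = {k: v.tolist() for k, v in
             {**{f"ln1.{k}": v for k, v in blk.ln1.params.items()},
              **{f"ln2.{k}": v for k, v in blk.ln2.params.items()},
              **{f"attn.{k}": v for k, v in blk.attn.params.items()},
              **{f"fc1.{k}": v for k, v in blk.fc1.params.items()},
              **{f"fc2.{k}": v for k, v in blk.fc2.params.items()}}.items()}

        normed = [layer_norm(row, p["ln1.gamma"], p["ln1.beta"]) for row in x]
        q = [affine(r, p["attn.wq"], p["attn.bq"]) for r in normed]
        k_ = [affine(r, p["attn.wk"], p["attn.bk"]) for r in normed]
        v_ = [affine(r, p["attn.wv"], p["attn.bv"]) for r in normed]
        scale = 1.0 / math.sqrt(4)  # head dim = proj_dim with one head
        ctx = []
        for qi in q:
            scores = [scale * sum(a * b for a, b in zip(qi, kj)) for kj in k_]
            mx = max(scores)
            es = [math.exp(s - mx) for s in scores]
            tot = sum(es)
            weights = [e / tot for e in es]
            ctx.append([sum(w * vj[d] for w, vj in zip(weights, v_))
                        for d in range(4)])
        attn_out = [affine(c, p["attn.wo"], p["attn.bo"]) for c in ctx]
        h = [[a + b for a, b in zip(r1, r2)] for r1, r2 in zip(x, attn_out)]
        normed2 = [layer_norm(r, p["ln2.gamma"], p["ln2.beta"]) for r in h]
        mlp = []
        for r in normed2:
            hid = [gelu(v) for v in affine(r, p["fc1.w"], p["fc1.b"])]
            mlp.append([gelu(v) for v in affine(hid, p["fc2.w"], p["fc2.b"])])
        expected = [[a + b for a, b in zip(r1, r2)] for r1, r2 in zip(h, mlp)]

        assert np.allclose(out, np.array(expected), atol=1e-5)

    def test_functional_wrapper(self):
        blk = TransformerBlock(TransformerBlockConfig(), rng=RNG)
        out = transformer_block_apply(RNG.random((9, 64)), blk)
        assert out.shape == (9, 64)


# ---------------------------------------------------------------------------
# Grid <-> token conversions
# ---------------------------------------------------------------------------

class TestGridTokenConversions:
    @pytest.mark.parametrize("side,expected_tokens", [(23, 9), (48, 36)])
    def test_feature_map_tokenisation(self, side, expected_tokens):
        pe = PatchExtract(7)
        n, plen = pe.out_shape((side, side, 16))
        assert n == expected_tokens
        assert plen == 7 * 7 * 16
        emb = PatchEmbed(plen, n, 64, rng=RNG)
        tok = emb.forward(pe.forward(RNG.random((1, side, side, 16))))
        assert tok.shape == (1, expected_tokens, 64)

    def test_tokens_to_grid_shape(self):
        out = tokens_to_grid(RNG.random((49, 64)))
        assert out.shape == (7, 7, 64)

    def test_round_trip_preserves_token_order(self):
        # grid layout then re-extraction with patch side 1 is the identity
        tok = RNG.random((1, 9, 5))
        grid = TokensToGrid().forward(tok)
        back = PatchExtract(1).forward(grid)
        assert np.array_equal(back, tok)

    def test_non_square_token_count_errors(self):
        with pytest.raises(ValueError, match="square"):
            tokens_to_grid(RNG.random((48, 64)))


# ---------------------------------------------------------------------------
# Config invariants
# ---------------------------------------------------------------------------

class TestConfigs:
    def test_mlp_width_must_match_proj_dim(self):
        with pytest.raises(ValueError, match="proj_dim"):
            TransformerBlockConfig(mlp_widths=(128, 32))

    def test_heads_must_divide_dim(self):
        with pytest.raises(ValueError, match="divisible"):
            TransformerBlockConfig(num_heads=3, proj_dim=64)

    def test_leaky_slope_range(self):
        with pytest.raises(ValueError):
            ConvBlockConfig(leaky_slope=1.5)
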