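"""Deformable transformer encoder: sampling, attention, equivariance."""

import numpy as np
import pytest

from dtdsmil import _autodiff as ad
from dtdsmil.encoder import (DeformableAttentionLayer,
                             DeformableTransformerEncoder, EncoderConfig,
                             bilinear_sample, deformable_self_attention,
                             encode, make_reference_points, project_tokens)
from dtdsmil.features import FeatureBag
from tests.conftest import make_bag


def small_cfg(**kw):
    defaults = dict(d_enc=8, n_layers=1, n_heads=2, n_points=2, d_ffn=16,
                    dropout=0.0, seed=0)
    defaults.update(kw)
    return EncoderConfig(**defaults)


class TestReferencePoints:
    def test_single_cell_center(self):
        np.testing.assert_allclose(make_reference_points((1, 1)), [[0.5, 0.5]])

    def test_two_by_two_centers(self):
        pts = make_reference_points((2, 2))
        assert {tuple(p) for p in pts} == {(0.25, 0.25), (0.75, 0.25),
                                           (0.25, 0.75), (0.75, 0.75)}

    def test_all_strictly_inside_unit_square(self):
        pts = make_reference_points((7, 3))
        assert (pts > 0).all() and (pts < 1).all()


class TestBilinearSample:
    def test_cell_center_returns_cell_vector(self, rng):
        vm = rng.normal(size=(3, 4, 5))
        np.testing.assert_allclose(
            bilinear_sample(vm, ((2 + 0.5) / 4, (1 + 0.5) / 3)), vm[1, 2],
            atol=1e-12)

    def test_outside_grid_is_zero(self, rng):
        vm = rng.normal(size=(3, 3, 2))
        np.testing.assert_array_equal(bilinear_sample(vm, (-1.0, -1.0)),
                                      np.zeros(2))

    def test_midpoint_of_adjacent_centers_is_their_mean(self, rng):
        vm = rng.normal(size=(2, 2, 6))
        mid = ((0.25 + 0.75) / 2, 0.25)  # halfway between (0,0) and (0,1)
        np.testing.assert_allclose(bilinear_sample(vm, mid),
                                   0.5 * (vm[0, 0] + vm[0, 1]), atol=1e-12)


class TestProjectTokens:
    def test_full_bag_gives_all_valid_mask(self, rng):
        bag = make_bag(rng, n=9, d=8, grid_shape=(3, 3))
        state = project_tokens(bag, small_cfg())
        assert state.validity_mask.all()

    def test_single_token_has_one_valid_cell(self, rng):
        bag = make_bag(rng, n=1, d=8, grid_shape=(4, 4))
        state = project_tokens(bag, small_cfg())
        assert state.validity_mask.sum() == 1
        assert (state.value_map[~state.validity_mask] == 0).all()

    def test_identity_projection_preserves_tokens(self, rng):
        bag = make_bag(rng, n=4, d=8, grid_shape=(2, 2))
        cfg = small_cfg()
        enc = DeformableTransformerEncoder(8, cfg)
        enc.input_proj.set_identity()
        state = project_tokens(bag, cfg, encoder=enc)
        np.testing.assert_allclose(
            state.value_map[bag.coords[:, 1], bag.coords[:, 0]], bag.tokens)


def identity_layer(cfg):
    layer = DeformableAttentionLayer(cfg, np.random.default_rng(0))
    layer.value_proj.W.data = np.eye(cfg.d_enc)
    layer.out_proj.set_identity()
    return layer


class TestDeformableAttention:
    def test_attention_weights_sum_to_one_per_head(self, rng):
        cfg = small_cfg(n_points=4)
        layer = DeformableAttentionLayer(cfg, rng)
        layer.logit_net.W.data = rng.normal(size=layer.logit_net.W.data.shape)
        tokens = ad.constant(rng.normal(size=(5, cfg.d_enc)))
        logits = layer.logit_net(tokens).reshape(5, cfg.n_heads, cfg.n_points)
        attn = ad.softmax(logits, axis=-1)
        np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-12)

    def test_identity_collapse_to_self_attention(self, rng):
        # zero offsets, one point, identity value/output maps: each token
        # attends exactly to itself
        cfg = small_cfg(n_points=1)
        bag = make_bag(rng, n=6, d=8, grid_shape=(3, 3))
        enc = DeformableTransformerEncoder(8, cfg)
        enc.input_proj.set_identity()
        state = project_tokens(bag, cfg, encoder=enc)
        layer = identity_layer(cfg)
        out = deformable_self_attention(state, bag.tokens, cfg, layer=layer)
        np.testing.assert_allclose(out, bag.tokens, atol=1e-10)

    def test_uniform_logits_with_neighbor_offsets_average(self, rng):
        # 4 points placed on the 4 cell-center neighbors with uniform
        # logits: the head output is the mean of the sampled vectors
        cfg = small_cfg(n_heads=1, n_points=4)
        bag = make_bag(rng, n=9, d=8, grid_shape=(3, 3))
        enc = DeformableTransformerEncoder(8, cfg)
        enc.input_proj.set_identity()
        state = project_tokens(bag, cfg, encoder=enc)
        layer = identity_layer(cfg)
        third = 1.0 / 3.0
        offsets = np.array([(third, 0), (-third, 0), (0, third), (0, -third)])
        layer.offset_net.b.data = offsets.reshape(-1)
        out = deformable_self_attention(state, bag.tokens, cfg, layer=layer)
        vm = state.value_map
        for i, (x, y) in enumerate(bag.coords):
            ref = state.reference_points[i]
            expected = np.mean([
                bilinear_sample(vm, ref + off) for off in offsets], axis=0)
            np.testing.assert_allclose(out[i], expected, atol=1e-10)


class TestEncode:
    def test_shape_and_coords_preserved(self, rng):
        bag = make_bag(rng, n=7, d=8, grid_shape=(4, 4))
        out = encode(bag, small_cfg(n_layers=2))
        assert out.tokens.shape == (7, 8)
        np.testing.assert_array_equal(out.coords, bag.coords)

    def test_permutation_equivariance(self, rng):
        bag = make_bag(rng, n=8, d=8, grid_shape=(4, 4))
        cfg = small_cfg(n_layers=2)
        enc = DeformableTransformerEncoder(8, cfg)
        out = encode(bag, cfg, encoder=enc)
        perm = rng.permutation(8)
        permuted = FeatureBag(bag.tokens[perm], bag.coords[perm],
                              bag.grid_shape)
        out_p = encode(permuted, cfg, encoder=enc)
        np.testing.assert_allclose(out_p.tokens, out.tokens[perm], atol=1e-9)

    def test_deterministic_reruns(self, rng):
        bag = make_bag(rng, n=5, d=8, grid_shape=(3, 3))
        cfg = small_cfg(n_layers=2, seed=11)
        np.testing.assert_array_equal(encode(bag, cfg).tokens,
                                      encode(bag, cfg).tokens)

    def test_zero_layers_is_identity_on_projected_tokens(self, rng):
        bag = make_bag(rng, n=5, d=8, grid_shape=(3, 3))
        cfg = small_cfg(n_layers=0)
        enc = DeformableTransformerEncoder(8, cfg)
        enc.input_proj.set_identity()
        out = encode(bag, cfg, encoder=enc)
        np.testing.assert_allclose(out.tokens, bag.tokens, atol=1e-12)


def test_checkpoint_round_trip(tmp_path, rng):
    bag = make_bag(rng, n=5, d=8, grid_shape=(3, 3))
    cfg = small_cfg(n_layers=1, seed=5)
    enc = DeformableTransformerEncoder(8, cfg)
    path = tmp_path / "enc.npz"
    enc.save(path)
    enc2 = DeformableTransformerEncoder.load(path)
    np.testing.assert_array_equal(encode(bag, cfg, encoder=enc).tokens,
                                  encode(bag, cfg, encoder=enc2).tokens)
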