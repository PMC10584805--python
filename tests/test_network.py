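"""Network contracts: scale sequence, attention oracle, constraint unit,
discriminator arithmetic, initialization statistics, checkpointing."""

import numpy as np
import pytest

from hippseg.network import (Discriminator, Generator, MFCM, discriminate,
                             encode, generator_forward, init_weights)
from hippseg.nn import Conv3d, Tensor
from hippseg.losses import info_constraint_loss


@pytest.fixture(scope="module")
def small_gen():
    gen = Generator(base_width=2)
    init_weights(gen, np.random.default_rng(0))
    return gen.eval()


class TestEncoder:
    def test_scale_sequence_for_reference_patch(self, small_gen):
        x = np.random.default_rng(1).normal(size=(48, 64, 48))
        skips, deepest = encode(x, small_gen)
        assert [s.shape[2:] for s in skips] == [
            (48, 64, 48), (24, 32, 24), (12, 16, 12), (6, 8, 6)]
        assert deepest.shape[2:] == (3, 4, 3)

    def test_four_exact_halvings_on_alternate_size(self, small_gen):
        x = np.zeros((32, 48, 32))
        _, deepest = encode(x, small_gen)
        assert deepest.shape[2:] == (2, 3, 2)

    def test_indivisible_input_rejected(self, small_gen):
        with pytest.raises(ValueError, match="divisible"):
            encode(np.zeros((50, 64, 48)), small_gen)

    def test_evaluation_mode_determinism(self, small_gen):
        x = np.random.default_rng(2).normal(size=(16, 16, 16))
        a = encode(x, small_gen)[1].data
        b = encode(x, small_gen)[1].data
        np.testing.assert_array_equal(a, b)


class TestICL:
    def test_gate_limits(self, small_gen):
        rng = np.random.default_rng(3)
        f = Tensor(rng.normal(size=(1, 32, 3, 4, 3)))
        icl = small_gen.icl
        # saturate the gate towards 1: constrained features vanish
        icl.flb.bias.data = np.full_like(icl.flb.bias.data, 50.0)
        constrained, _, v_saf = icl(f)
        assert np.abs(constrained.data).max() < 1e-15
        # gate near 0 is unreachable through relu->sigmoid (floor 0.5), so
        # check the algebraic identity instead: constrained = (1-gate)*f
        icl.flb.bias.data = np.zeros_like(icl.flb.bias.data)
        icl.flb.weight.data = np.zeros_like(icl.flb.weight.data)
        constrained, _, v_saf = icl(f)
        np.testing.assert_allclose(v_saf.data, 0.5)
        np.testing.assert_allclose(constrained.data, 0.5 * f.data)

    def test_gate_range_and_cl_nonnegative(self, small_gen):
        rng = np.random.default_rng(4)
        f = Tensor(rng.normal(size=(2, 32, 3, 4, 3)))
        constrained, cl, v_saf = small_gen.icl(f)
        assert np.all(v_saf.data > 0) and np.all(v_saf.data < 1)
        assert float(cl.data) >= 0

    def test_cl_closed_form_for_gaussian_moments(self):
        # moments (mu, s^2) per channel -> mean KL (mu^2+s^2-1-ln s^2)/2
        rng = np.random.default_rng(5)
        f = rng.normal(1.5, 0.7, size=(3, 4000))
        mu = f.mean(axis=1)
        s2 = f.var(axis=1)
        expected = np.mean((mu ** 2 + s2 - 1 - np.log(s2)) / 2)
        assert info_constraint_loss(f) == pytest.approx(expected, abs=1e-9)

    def test_stronger_gate_weakly_shrinks_features(self, small_gen):
        rng = np.random.default_rng(6)
        f = Tensor(rng.normal(size=(1, 32, 3, 4, 3)))
        icl = small_gen.icl
        norms = []
        for bias in (-2.0, 0.0, 2.0, 5.0):  # increasing gate values
            icl.flb.bias.data = np.full_like(icl.flb.bias.data, bias)
            constrained, _, _ = icl(f)
            norms.append(np.linalg.norm(constrained.data))
        assert all(a >= b for a, b in zip(norms, norms[1:]))


class TestMFCM:
    def test_toy_feature_matches_explicit_loop(self):
        c_ch, n_vox = 3, 8
        m = MFCM(c_ch)
        rng = np.random.default_rng(7)
        for p in m.parameters():
            p.data = rng.normal(size=p.data.shape) * 0.5
        f = Tensor(rng.normal(size=(1, c_ch, 2, 2, 2)))
        a, m_feat = m.attention(f)

        w_in = m.proj_in.weight.data.reshape(c_ch, c_ch)
        b_in = m.proj_in.bias.data
        fd = f.data[0].reshape(c_ch, n_vox)
        fp = np.zeros((c_ch, n_vox))
        for c in range(c_ch):
            for n in range(n_vox):
                fp[c, n] = sum(w_in[c, k] * fd[k, n]
                               for k in range(c_ch)) + b_in[c]
        scores = np.zeros((c_ch, c_ch))
        for i in range(c_ch):
            for j in range(c_ch):
                scores[i, j] = sum(fp[i, n] * fp[j, n] for n in range(n_vox))
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        a_oracle = e / e.sum(axis=1, keepdims=True)
        af = a_oracle @ fp
        w_out = m.proj_out.weight.data.reshape(c_ch, c_ch)
        m_oracle = (w_out @ af) + m.proj_out.bias.data[:, None]

        np.testing.assert_allclose(a.data[0], a_oracle, atol=1e-6)
        np.testing.assert_allclose(m_feat.data[0].reshape(c_ch, n_vox),
                                   m_oracle, atol=1e-6)

    def test_attention_rows_sum_to_one(self):
        m = MFCM(5)
        init_weights(m, np.random.default_rng(8))
        for p in m.parameters():
            p.data = np.random.default_rng(9).normal(size=p.data.shape) * 0.3
        f = Tensor(np.random.default_rng(10).normal(size=(2, 5, 2, 2, 2)))
        a, _ = m.attention(f)
        np.testing.assert_allclose(a.data.sum(axis=2), 1.0, atol=1e-6)

    def test_zero_delta_reduces_to_refined_input(self):
        m = MFCM(4)
        rng = np.random.default_rng(11)
        for p in m.parameters():
            p.data = rng.normal(size=p.data.shape) * 0.4
        m.delta.data = np.zeros(())
        f = Tensor(rng.normal(size=(1, 4, 2, 2, 2)))
        np.testing.assert_array_equal(m(f).data, m.refine(f).data)


class TestGeneratorForward:
    def test_output_resolutions_and_channels(self, small_gen):
        x = np.random.default_rng(12).normal(size=(1, 1, 48, 64, 48))
        out = generator_forward(x, small_gen)
        assert out.p_t4.shape == (1, 3, 48, 64, 48)
        assert out.p_t3.shape == (1, 3, 24, 32, 24)

    def test_probability_simplex_per_voxel(self, small_gen):
        x = np.random.default_rng(13).normal(size=(1, 1, 16, 32, 16))
        out = generator_forward(x, small_gen)
        for prob in (out.p_t4, out.p_t3):
            np.testing.assert_allclose(prob.data.sum(axis=1), 1.0, atol=1e-5)
            assert prob.data.min() >= 0
        assert float(out.cl.data) >= 0
        assert np.all(out.v_saf.data > 0) and np.all(out.v_saf.data < 1)


class TestDiscriminator:
    def test_exactly_five_conv_layers_with_quoted_kernels(self):
        d = Discriminator(3, 4)
        assert len(d.conv_layers) == 5
        assert [l.kernel for l in d.conv_layers] == [7, 5, 3, 3, 3]
        assert all(l.stride == 2 for l in d.conv_layers)

    def test_prepool_spatial_size_matches_stride_arithmetic(self):
        # padded stride-2 halving: 48->24->12->6->3->2 (and 64->...->2)
        d = Discriminator(3, 2)
        init_weights(d, np.random.default_rng(14))

        def oracle(n):
            for k in (7, 5, 3, 3, 3):
                p = (k - 1) // 2
                n = (n + 2 * p - k) // 2 + 1
            return n

        x = Tensor(np.random.default_rng(15).normal(size=(1, 3, 48, 64, 48)))
        feat = d.features(x)
        assert feat.shape[2:] == (oracle(48), oracle(64), oracle(48)) == (2, 2, 2)

    def test_output_strictly_inside_unit_interval(self):
        d = Discriminator(3, 2)
        init_weights(d, np.random.default_rng(16))
        for seed in range(3):
            x = np.abs(np.random.default_rng(seed).normal(
                size=(2, 3, 16, 32, 16)))
            p = discriminate(x, d).data
            assert np.all(p > 0) and np.all(p < 1)

    def test_wrong_rank_input_rejected(self):
        d = Discriminator(3, 2, name="D1")
        with pytest.raises(ValueError, match="D1"):
            d.features(Tensor(np.zeros((3, 16, 16))))


class TestInitWeights:
    def test_seeded_reproducibility(self):
        a = init_weights(Generator(base_width=2), np.random.default_rng(17))
        b = init_weights(Generator(base_width=2), np.random.default_rng(17))
        for (ka, pa), (kb, pb) in zip(a.named_parameters(),
                                      b.named_parameters()):
            assert ka == kb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_he_scaling_for_fan_100(self):
        # fan_in = 100 * 1^3 -> sd = sqrt(2/100) = 0.1414
        layer = Conv3d(100, 1000, 1)
        init_weights_holder = type("M", (), {})
        rng = np.random.default_rng(18)
        from hippseg.network import init_weights as iw
        from hippseg.nn import Module

        class Holder(Module):
            def __init__(self):
                super().__init__()
                self.conv = layer

        iw(Holder(), rng)
        w = layer.weight.data
        assert w.std() == pytest.approx(np.sqrt(2 / 100), rel=0.02)
        assert abs(w.mean()) < 3 * w.std() / np.sqrt(w.size)

    def test_gates_and_norm_parameters(self):
        gen = init_weights(Generator(base_width=2), np.random.default_rng(19))
        assert float(gen.mfcm0.delta.data) == 0.0
        assert float(gen.mfcm1.delta.data) == 0.0
        np.testing.assert_array_equal(gen.enc0.bn1.gamma.data, 1.0)
        np.testing.assert_array_equal(gen.enc0.bn1.beta.data, 0.0)


def test_checkpoint_roundtrip_bit_exact(tmp_path):
    from hippseg.training import (TrainConfig, build_models, load_checkpoint,
                                  save_checkpoint)
    cfg = TrainConfig.desk(seed=5)
    bundle = build_models(cfg)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, bundle, rng_state={"note": "test"})
    restored, meta = load_checkpoint(path)
    assert meta["rng_state"] == {"note": "test"}
    for model, other in ((bundle.generator, restored.generator),
                         (bundle.d1, restored.d1), (bundle.d2, restored.d2)):
        sd_a, sd_b = model.state_dict(), other.state_dict()
        assert sd_a.keys() == sd_b.keys()
        for k in sd_a:
            np.testing.assert_array_equal(sd_a[k], sd_b[k])
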