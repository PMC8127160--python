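"""Architecture contracts: layer table, attention gates, deformable
convolution semantics, determinism and checkpointing."""

import numpy as np
import pytest

from gpseg import autograd as ag
from gpseg.autograd import Tensor
from gpseg.network import (AttentionGate, ConfigError, DEFAULT_STAGE_SPECS,
                           GPNet, NetworkConfig, StageSpec, build_network,
                           deformable_conv3d, forward, load_checkpoint,
                           save_checkpoint)


@pytest.fixture(scope="module")
def tiny_net():
    return build_network(NetworkConfig(base_channels=2), seed=3)


class TestConfig:
    def test_default_layer_table(self):
        cfg = NetworkConfig()
        enc1 = cfg.stage("encoder", 1)
        assert (enc1.kernel_size, enc1.padding, enc1.dilation) == (11, 15, 3)
        assert cfg.stage("encoder", 2).kernel_size == 9
        assert cfg.stage("encoder", 3).layer_type == "deformable"
        assert cfg.stage("central", 5).kernel_size == 3
        assert cfg.stage("decoder", 1).kernel_size == 7
        assert cfg.stage("final", 0).kernel_size == 1
        assert len(DEFAULT_STAGE_SPECS) == 10

    def test_every_regular_conv_is_size_preserving(self):
        for s in NetworkConfig().stage_specs:
            if s.layer_type == "regular":
                assert 2 * s.padding == s.dilation * (s.kernel_size - 1)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigError):
            NetworkConfig(stage_specs=(
                StageSpec(1, "encoder", "regular", 11, 14, 3),))
        with pytest.raises(ConfigError):
            NetworkConfig(stage_specs=(
                StageSpec(1, "encoder", "deformable", 3, 1, 2),))

    def test_json_round_trip(self):
        cfg = NetworkConfig(base_channels=4, init_gain=0.25)
        back = NetworkConfig.from_json(cfg.to_json())
        assert back == cfg


class TestForward:
    def test_output_shape_matches_input(self, tiny_net):
        x = np.random.default_rng(0).standard_normal((32, 32, 32))
        y = forward(tiny_net, x)
        assert y.shape == (3, 32, 32, 32)
        assert np.isfinite(y).all()

    def test_non_divisible_input_names_axis(self, tiny_net):
        with pytest.raises(ValueError, match="axis 1"):
            forward(tiny_net, np.zeros((32, 40, 32)))

    def test_zero_input_gives_zero_output(self, tiny_net):
        # all biases and BN offsets are zero at initialization
        y = forward(tiny_net, np.zeros((16, 16, 16)))
        assert np.abs(y).max() == 0.0

    def test_same_seed_identical_build_and_forward(self):
        cfg = NetworkConfig(base_channels=2)
        a = build_network(cfg, seed=5)
        b = build_network(cfg, seed=5)
        pa = a.named_parameters()
        pb = b.named_parameters()
        assert pa.keys() == pb.keys()
        for k in pa:
            assert np.array_equal(pa[k].data, pb[k].data)
        x = np.random.default_rng(1).standard_normal((16, 16, 16))
        assert np.array_equal(forward(a, x), forward(b, x))

    def test_exactly_three_attention_gates(self, tiny_net):
        assert sum(g is not None for g in tiny_net.gates) == 3
        # level 1 (the shallowest decoder stage) has no gate
        assert tiny_net.gates[-1] is None


class TestDeformable:
    def test_zero_offsets_equal_standard_conv(self, rng):
        x = rng.standard_normal((2, 16, 16, 16))
        w = rng.standard_normal((3, 2, 3, 3, 3))
        offsets = np.zeros((81, 16, 16, 16))
        got = deformable_conv3d(Tensor(x), Tensor(offsets), Tensor(w)).data
        want = ag.conv3d(Tensor(x), Tensor(w), padding=1).data
        assert np.abs(got - want).max() < 1e-5

    def test_integer_offset_equals_shifted_conv_interior(self, rng):
        x = rng.standard_normal((1, 10, 10, 10))
        w = rng.standard_normal((1, 1, 3, 3, 3))
        offsets = np.zeros((81, 10, 10, 10))
        offsets[0::3] = 1.0  # +1 voxel along axis 0 for every tap
        got = deformable_conv3d(Tensor(x), Tensor(offsets), Tensor(w)).data
        shifted = np.zeros_like(x)
        shifted[:, :-1] = x[:, 1:]
        want = ag.conv3d(Tensor(shifted), Tensor(w), padding=1).data
        # compare away from the shifted boundary
        assert np.abs(got[:, 1:-2, 1:-1, 1:-1]
                      - want[:, 1:-2, 1:-1, 1:-1]).max() < 1e-10

    def test_brute_force_tap_oracle(self, rng):
        """Per-voxel loop over taps with trilinear reads reproduces the op."""
        x = rng.standard_normal((1, 5, 5, 5))
        w = rng.standard_normal((1, 1, 3, 3, 3))
        offsets = 0.4 * rng.standard_normal((81, 5, 5, 5))
        got = deformable_conv3d(Tensor(x), Tensor(offsets), Tensor(w)).data

        def read(vol, p):
            f = np.floor(p).astype(int)
            t = p - f
            acc = 0.0
            for dz in (0, 1):
                for dy in (0, 1):
                    for dx in (0, 1):
                        c = f + (dz, dy, dx)
                        if ((0 <= c).all() and (c < vol.shape).all()):
                            wgt = ((t[0] if dz else 1 - t[0])
                                   * (t[1] if dy else 1 - t[1])
                                   * (t[2] if dx else 1 - t[2]))
                            acc += wgt * vol[tuple(c)]
            return acc

        taps = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
                for c in (-1, 0, 1)]
        want = np.zeros((5, 5, 5))
        for v in np.ndindex(5, 5, 5):
            for t_idx, tap in enumerate(taps):
                off = offsets[3 * t_idx:3 * t_idx + 3, v[0], v[1], v[2]]
                p = np.array(v, float) + np.array(tap) + off
                want[v] += w[0, 0, tap[0] + 1, tap[1] + 1, tap[2] + 1] * \
                    read(x[0], p)
        assert np.abs(got[0] - want).max() < 1e-9

    def test_constant_field_invariant_to_smooth_offsets(self, rng):
        x = np.full((1, 8, 8, 8), 2.0)
        w = rng.standard_normal((1, 1, 3, 3, 3))
        offsets = 0.3 * rng.standard_normal((81, 8, 8, 8))
        got = deformable_conv3d(Tensor(x), Tensor(offsets), Tensor(w)).data
        want = ag.conv3d(Tensor(x), Tensor(w), padding=1).data
        assert np.abs(got[0, 2:-2, 2:-2, 2:-2]
                      - want[0, 2:-2, 2:-2, 2:-2]).max() < 1e-5

    def test_wrong_offset_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            deformable_conv3d(Tensor(rng.standard_normal((1, 4, 4, 4))),
                              Tensor(np.zeros((10, 4, 4, 4))),
                              Tensor(rng.standard_normal((1, 1, 3, 3, 3))))


class TestAttentionGate:
    def test_saturated_gate_is_identity(self, rng):
        gate = AttentionGate(2, 4, np.random.default_rng(0))
        gate.psi.bias.data = np.array([100.0], dtype=np.float32)  # sigmoid -> 1
        skip = Tensor(rng.standard_normal((2, 8, 8, 8)).astype(np.float32))
        gating = Tensor(rng.standard_normal((4, 4, 4, 4)).astype(np.float32))
        out = gate(skip, gating)
        assert np.allclose(out.data, skip.data, atol=1e-5)

    def test_null_gate_zeroes_output(self, rng):
        gate = AttentionGate(2, 4, np.random.default_rng(0))
        gate.psi.bias.data = np.array([-100.0], dtype=np.float32)  # sigmoid -> 0
        skip = Tensor(rng.standard_normal((2, 8, 8, 8)).astype(np.float32))
        gating = Tensor(rng.standard_normal((4, 4, 4, 4)).astype(np.float32))
        assert np.abs(gate(skip, gating).data).max() < 1e-6

    def test_multiplicative_bound(self, rng):
        gate = AttentionGate(2, 4, np.random.default_rng(2))
        skip = Tensor(rng.standard_normal((2, 8, 8, 8)).astype(np.float32))
        gating = Tensor(rng.standard_normal((4, 4, 4, 4)).astype(np.float32))
        out = gate(skip, gating)
        assert np.all(np.abs(out.data) <= np.abs(skip.data) + 1e-6)

    def test_incompatible_resolution_rejected(self, rng):
        gate = AttentionGate(2, 4, np.random.default_rng(0))
        with pytest.raises(ConfigError):
            gate(Tensor(np.zeros((2, 8, 8, 8))), Tensor(np.zeros((4, 3, 3, 3))))


class TestCheckpoint:
    def test_round_trip(self, tiny_net, tmp_path, rng):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(tiny_net, path, extra={"spacing": [1.0, 1.0, 1.0]})
        net2, extra = load_checkpoint(path)
        assert extra["spacing"] == [1.0, 1.0, 1.0]
        x = rng.standard_normal((16, 16, 16))
        assert np.array_equal(forward(tiny_net, x), forward(net2, x))
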