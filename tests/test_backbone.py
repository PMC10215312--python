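"""Split attention, block contracts, network assembly, parameter accounting."""

import numpy as np
import pytest

from fecnet import nn as fnn
from fecnet.backbone import (
    BlockConfig,
    InvalidConfigError,
    Network,
    NetworkConfig,
    ResBottleneck,
    SCHEMES,
    SCMBlock,
    SplitAttention,
    build_network,
    count_parameters,
    preset_config,
    scheme_config,
    split_attention,
)
from fecnet.nn import Conv2d, Linear, Tensor, cross_entropy

TINY = dict(base_width=8, stem_channels=8, stage_depths=(1, 1, 1, 1))


# ------------------------------------------------------------ split attention
def _randomize_gates(sa: SplitAttention, rng):
    # scoring layers are zero-initialized; give them structure for oracles
    for gate in sa.gates:
        last = gate._modules["3"]
        last.weight.data[:] = rng.normal(0, 0.5, last.weight.shape)
        last.bias.data[:] = rng.normal(0, 0.5, last.bias.shape)


def _oracle_split_attention(sa: SplitAttention, splits):
    """Loop-written reference of the grouped sum / pool / soft-weight / concat."""
    r, k, c = sa.radix, sa.cardinal, sa.channels
    B, _, H, W = splits[0].shape
    out = np.zeros((B, k * c, H, W))
    for ki in range(k):
        group = [splits[ki * r + i] for i in range(r)]
        u_hat = np.zeros((B, c, H, W))
        for u in group:
            u_hat += u
        s = np.zeros((B, c))
        for b in range(B):
            for ch in range(c):
                s[b, ch] = u_hat[b, ch].sum() / (H * W)
        gate = sa.gates[ki]
        w1 = gate._modules["0"].weight.data[:, :, 0, 0]
        b1 = gate._modules["0"].bias.data
        bn = gate._modules["1"]
        w2 = gate._modules["3"].weight.data[:, :, 0, 0]
        b2 = gate._modules["3"].bias.data
        hidden = s @ w1.T + b1
        hidden = (hidden - bn.running_mean) / np.sqrt(bn.running_var + bn.eps)
        hidden = hidden * bn.weight.data + bn.bias.data
        hidden = np.maximum(hidden, 0)
        logits = (hidden @ w2.T + b2).reshape(B, r, c)
        if r > 1:
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            a = e / e.sum(axis=1, keepdims=True)
        else:
            a = 1.0 / (1.0 + np.exp(-logits))
        for b in range(B):
            for i in range(r):
                for ch in range(c):
                    out[b, ki * c + ch] += a[b, i, ch] * group[i][b, ch]
    return out


def test_split_attention_r1_sigmoid_gate(rng):
    sa = SplitAttention(4, radix=1, cardinal=1)
    _randomize_gates(sa, rng)
    sa.eval()
    u = rng.normal(size=(2, 4, 3, 3)).astype(np.float32)
    v = sa([Tensor(u)])
    w = sa.last_weights
    assert (w > 0).all() and (w < 1).all()
    np.testing.assert_allclose(v.data, w[:, 0, 0][:, :, None, None] * u, rtol=1e-5)


def test_split_attention_identical_splits_uniform(rng):
    sa = SplitAttention(5, radix=2, cardinal=2)  # zero-init gate
    s = Tensor(rng.normal(size=(2, 5, 4, 4)).astype(np.float32))
    sa([s, s, s, s])
    np.testing.assert_allclose(sa.last_weights, 0.5, atol=1e-6)


def test_split_attention_matches_loop_oracle(rng):
    sa = SplitAttention(2, radix=3, cardinal=2)
    _randomize_gates(sa, rng)
    sa.eval()
    splits = [rng.normal(size=(1, 2, 4, 4)).astype(np.float32) for _ in range(6)]
    got = sa([Tensor(s) for s in splits]).data
    want = _oracle_split_attention(sa, splits)
    np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-6)


def test_split_attention_oracle_many_random_instances(rng):
    for _ in range(50):
        r = int(rng.integers(1, 4))
        k = int(rng.integers(1, 4))
        c = int(rng.integers(1, 6))
        sa = SplitAttention(c, radix=r, cardinal=k)
        _randomize_gates(sa, rng)
        sa.eval()
        splits = [rng.normal(size=(2, c, 3, 3)).astype(np.float32) for _ in range(k * r)]
        got = sa([Tensor(s) for s in splits]).data
        want = _oracle_split_attention(sa, splits)
        np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-5)
        if r > 1:
            np.testing.assert_allclose(
                sa.last_weights.sum(axis=2), 1.0, atol=1e-5
            )


def test_split_attention_weight_normalization(rng):
    sa = SplitAttention(8, radix=4, cardinal=2)
    _randomize_gates(sa, rng)
    splits = [Tensor(rng.normal(size=(3, 8, 2, 2)).astype(np.float32)) for _ in range(8)]
    sa(splits)
    np.testing.assert_allclose(sa.last_weights.sum(axis=2), 1.0, atol=1e-5)
    assert (sa.last_weights >= 0).all()


def test_split_attention_functional_and_errors(rng):
    splits = [Tensor(rng.normal(size=(1, 3, 2, 2)).astype(np.float32)) for _ in range(4)]
    v = split_attention(splits, radix=2, cardinal=2)
    assert v.shape == (1, 6, 2, 2)
    with pytest.raises(InvalidConfigError):
        split_attention(splits[:3], radix=2, cardinal=2)


# ------------------------------------------------------------------- blocks
def _block_cfg(**kw):
    base = dict(
        radix=2, cardinal=1, in_channels=8, bottleneck_channels=8,
        out_channels=8, stride=1,
    )
    base.update(kw)
    return BlockConfig(**base)


def test_block_config_validation():
    with pytest.raises(InvalidConfigError):
        _block_cfg(stride=3)
    with pytest.raises(InvalidConfigError):
        _block_cfg(bottleneck_channels=9)  # not divisible by k*r
    with pytest.raises(InvalidConfigError):
        _block_cfg(radix=0)


def test_scm_block_stride1_shape(rng):
    blk = SCMBlock(_block_cfg())
    x = Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))
    assert blk(x).shape == (1, 8, 6, 6)


def test_scm_block_stride2_halves(rng):
    blk = SCMBlock(_block_cfg(stride=2, out_channels=16, downsample="madm"))
    x = Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
    assert blk(x).shape == (1, 16, 4, 4)


def test_scm_block_residual_identity_when_main_zeroed(rng):
    blk = SCMBlock(_block_cfg())
    blk.eval()
    blk.expand._modules["0"].weight.data[:] = 0
    x = rng.random((1, 8, 5, 5)).astype(np.float32)  # nonnegative
    np.testing.assert_allclose(blk(Tensor(x)).data, x, rtol=1e-5, atol=1e-6)


def test_scm_block_stride1_channel_change_projects(rng):
    blk = SCMBlock(_block_cfg(out_channels=12))
    x = Tensor(rng.normal(size=(1, 8, 5, 5)).astype(np.float32))
    assert blk(x).shape == (1, 12, 5, 5)


def test_scm_block_dsc_and_clam_variants(rng):
    blk = SCMBlock(_block_cfg(conv="dsc", attention="split_clam"))
    x = Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))
    y = blk(x)
    (y * y).sum().backward()
    assert y.shape == (1, 8, 6, 6)


def test_res_bottleneck_matches_reference_shape(rng):
    cfg = _block_cfg(radix=1, cardinal=1, stride=2, out_channels=16)
    blk = ResBottleneck(cfg)
    x = Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
    assert blk(x).shape == (1, 16, 4, 4)


# ------------------------------------------------------------------ networks
def test_network_config_validation():
    with pytest.raises(InvalidConfigError):
        NetworkConfig(stage_depths=(1, 1, 1))
    with pytest.raises(InvalidConfigError):
        NetworkConfig(block="res", attention="split")
    with pytest.raises(InvalidConfigError):
        scheme_config(15)
    with pytest.raises(InvalidConfigError):
        preset_config("nope")


def test_presets_map_to_schemes():
    assert preset_config("resnet_ref").block == "res"
    assert preset_config("scmnet").block == "scm"
    cfg = preset_config("mc_scmnet")
    assert cfg.use_clam and cfg.use_dsc and cfg.use_madm
    assert cfg.radix == 2 and cfg.cardinal == 1


def test_full_network_logits_shape_224(rng):
    net = build_network(scheme_config(14, **TINY))
    x = Tensor(rng.normal(size=(1, 3, 224, 224)).astype(np.float32))
    logits = net(x)
    assert logits.shape == (1, 4)


def test_count_parameters_examples():
    assert count_parameters(Conv2d(16, 32, 3)) == 0.005
    assert count_parameters(Linear(2048, 1000)) == 2.049


def test_reference_baseline_param_count():
    net = build_network(scheme_config(1, num_classes=1000))
    assert net.num_parameters() == 25_557_032
    assert count_parameters(net) == 25.557


def test_param_count_monotone_in_radix():
    counts = [
        count_parameters(build_network(scheme_config(14, radix=r, cardinal=1)))
        for r in (2, 3, 4)
    ]
    assert counts[0] < counts[1] < counts[2]


def test_param_count_monotone_in_cardinal():
    counts = [
        count_parameters(build_network(scheme_config(14, radix=2, cardinal=k)))
        for k in (1, 2)
    ]
    assert counts[0] < counts[1]


@pytest.mark.parametrize("scheme", sorted(SCHEMES))
def test_every_scheme_builds_forward_backward(scheme, rng):
    """All ablation schemes run a 224x224 forward+backward (reduced width)."""
    net = build_network(scheme_config(scheme, **TINY))
    x = Tensor(rng.normal(size=(1, 3, 224, 224)).astype(np.float32))
    logits = net(x)
    assert logits.shape == (1, 4)
    loss = cross_entropy(logits, np.array([scheme % 4]))
    net.zero_grad()
    loss.backward()
    grads = [p.grad for p in net.parameters()]
    assert all(g is not None for g in grads)


def test_training_smoke_loss_decreases(easy_dataset, rng):
    """Two epochs on 200 synthetic images strictly decrease training loss."""
    from fecnet.harness import train_model

    fnn.set_seed(7)
    net = build_network(scheme_config(14, **TINY))
    idx = rng.permutation(len(easy_dataset))[:200]
    rows = train_model(
        net, easy_dataset, idx, epochs=2, learning_rate=1e-3, batch_size=8, seed=7
    )
    assert rows[1]["train_loss"] < rows[0]["train_loss"]
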