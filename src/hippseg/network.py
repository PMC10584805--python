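"""The adversarial segmentation networks.

Generator: a 3D U-shaped encoder-decoder feature extractor (FEM) with four
2x poolings (input dims must be divisible by 2^4), an information-constraint
unit at the deepest level, channel self-attention blocks (MFCM) at the last
two decoder levels, and two convolutional classification heads (FCM)
producing 3-class probability maps at full resolution (P_t4) and half
resolution (P_t3).

Discriminators: two identical 5-layer stride-2 convolutional critics with
kernel sizes 7/5/3/3/3 judging probability (or one-hot label) maps at the
two output resolutions; global average pooling and a sigmoid give a scalar
real-vs-generated probability.

Weight initialization is He-normal — N(0, sqrt(2/N)) with N the fan-in of
the layer — with batch-norm scale 1 / shift 0 and attention gates delta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .losses import info_constraint_loss
from .nn import (BatchNorm3d, Conv3d, ConvBlock, Module, Tensor, concat,
                 conv3d, maxpool2x, upsample2x)

__all__ = [
    "GeneratorOutputs", "ICLUnit", "MFCM", "Generator", "Discriminator",
    "init_weights", "encode", "generator_forward", "discriminate",
    "mfcm_attend", "ifc_constrain",
]

POOLING_DIVISOR = 16


@dataclass
class GeneratorOutputs:
    """The generator's two probability maps plus the constraint loss.

    ``p_t4``: (N,3,D,H,W) class probabilities at input resolution;
    ``p_t3``: (N,3,D/2,H/2,W/2) at half resolution; ``cl``: scalar
    information-constraint loss (>= 0); ``v_saf``: the sigmoid gate map of
    the constraint unit, elementwise in (0,1).
    """

    p_t4: Tensor
    p_t3: Tensor
    cl: Tensor
    v_saf: Tensor


def _check_input(shape) -> None:
    if len(shape) != 5:
        raise ValueError(f"expected (N,C,D,H,W) input, got shape {shape}")
    for dim in shape[2:]:
        if dim % POOLING_DIVISOR:
            raise ValueError(
                f"input spatial dim {dim} not divisible by 2^4; shape {shape}")


class ICLUnit(Module):
    """Information-constraint gate at the deepest encoder level.

    A feature-learning block (3x3x3 convolution -> ReLU -> sigmoid) produces
    the salience gate ``V_saf`` in (0,1); the constrained features are
    ``(1 - V_saf) * f``.  The constraint loss is the closed-form Gaussian
    divergence of the constrained features' per-channel moments from N(0,1).
    """

    def __init__(self, channels: int):
        super().__init__()
        self.flb = Conv3d(channels, channels, 3)

    def forward(self, f: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        v_saf = self.flb(f).relu().sigmoid()
        constrained = (1.0 - v_saf) * f
        cl = info_constraint_loss(constrained)
        return constrained, cl, v_saf


class MFCM(Module):
    """Channel self-attention with a zero-initialized residual gate.

    The input (N,C,D,H,W) is projected by a 1x1x1 convolution and flattened
    to F' (N,C,Nvox); the attention matrix A is the row-softmax of F' F'^T
    (each row sums to 1).  A F' is reshaped back and projected by a second
    1x1x1 convolution into M_feature; the output is
    ``delta * M_feature + refine(input)`` where ``refine`` is a 3x3x3
    convolution and ``delta`` a learnable scalar starting at 0, so the block
    begins as a plain residual refinement.
    """

    def __init__(self, channels: int):
        super().__init__()
        self.proj_in = Conv3d(channels, channels, 1)
        self.proj_out = Conv3d(channels, channels, 1)
        self.refine = Conv3d(channels, channels, 3)
        self.delta = Tensor(np.zeros(()), requires_grad=True)

    def attention(self, f: Tensor) -> tuple[Tensor, Tensor]:
        """Return (A, M_feature) for inspection and oracle tests."""
        n, c, d, h, w = f.shape
        fp = self.proj_in(f).reshape(n, c, d * h * w)          # F'
        a = fp.matmul(fp.transpose(0, 2, 1)).softmax(axis=2)   # (N,C,C)
        m = a.matmul(fp).reshape(n, c, d, h, w)
        return a, self.proj_out(m)

    def forward(self, f: Tensor) -> Tensor:
        _, m_feature = self.attention(f)
        return self.delta * m_feature + self.refine(f)


class FCMHead(Module):
    """Classification head: 3x3x3 then 1x1x1 convolution, 3-class softmax."""

    def __init__(self, in_ch: int, n_classes: int = 3):
        super().__init__()
        self.conv3 = Conv3d(in_ch, in_ch, 3)
        self.conv1 = Conv3d(in_ch, n_classes, 1)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv1(self.conv3(x).relu()).softmax(axis=1)


class Generator(Module):
    """FEM encoder-decoder with constraint unit, attention, and FCM heads."""

    def __init__(self, in_ch: int = 1, base_width: int = 32,
                 n_classes: int = 3):
        super().__init__()
        w = base_width
        self.base_width = w
        self.enc0 = ConvBlock(in_ch, w)
        self.enc1 = ConvBlock(w, 2 * w)
        self.enc2 = ConvBlock(2 * w, 4 * w)
        self.enc3 = ConvBlock(4 * w, 8 * w)
        self.enc4 = ConvBlock(8 * w, 16 * w)
        self.icl = ICLUnit(16 * w)
        self.dec3 = ConvBlock(16 * w + 8 * w, 8 * w)
        self.dec2 = ConvBlock(8 * w + 4 * w, 4 * w)
        self.dec1 = ConvBlock(4 * w + 2 * w, 2 * w)
        self.mfcm1 = MFCM(2 * w)
        self.dec0 = ConvBlock(2 * w + w, w)
        self.mfcm0 = MFCM(w)
        self.head4 = FCMHead(w, n_classes)       # full resolution -> P_t4
        self.head3 = FCMHead(2 * w, n_classes)   # half resolution -> P_t3

    def encode(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        """Run the encoder; returns (skip features at levels 0..3, deepest).

        For a 48x64x48 input the level spatial dims halve exactly:
        24x32x24, 12x16x12, 6x8x6 and 3x4x3 at the deepest level.
        """
        _check_input(x.shape)
        e0 = self.enc0(x)
        e1 = self.enc1(maxpool2x(e0))
        e2 = self.enc2(maxpool2x(e1))
        e3 = self.enc3(maxpool2x(e2))
        e4 = self.enc4(maxpool2x(e3))
        return [e0, e1, e2, e3], e4

    def forward(self, x: Tensor) -> GeneratorOutputs:
        skips, e4 = self.encode(x)
        e0, e1, e2, e3 = skips
        constrained, cl, v_saf = self.icl(e4)
        d3 = self.dec3(concat([upsample2x(constrained), e3], axis=1))
        d2 = self.dec2(concat([upsample2x(d3), e2], axis=1))
        d1 = self.mfcm1(self.dec1(concat([upsample2x(d2), e1], axis=1)))
        d0 = self.mfcm0(self.dec0(concat([upsample2x(d1), e0], axis=1)))
        return GeneratorOutputs(p_t4=self.head4(d0), p_t3=self.head3(d1),
                                cl=cl, v_saf=v_saf)


class Discriminator(Module):
    """Five stride-2 convolutions (kernels 7/5/3/3/3), ReLU between layers,
    the last layer mapping to one channel; global average pooling and a
    sigmoid give the scalar real-probability."""

    KERNELS = (7, 5, 3, 3, 3)

    def __init__(self, in_ch: int = 3, base_width: int = 32, name: str = "D"):
        super().__init__()
        b = base_width
        chans = (b, 2 * b, 4 * b, 4 * b, 1)
        self.name = name
        prev = in_ch
        for i, (k, c) in enumerate(zip(self.KERNELS, chans)):
            setattr(self, f"conv{i}", Conv3d(prev, c, k, stride=2))
            prev = c

    @property
    def conv_layers(self) -> list[Conv3d]:
        return [getattr(self, f"conv{i}") for i in range(5)]

    def features(self, x: Tensor) -> Tensor:
        """Pre-pooling map: spatial size follows padded stride-2 halving."""
        if x.ndim != 5:
            raise ValueError(
                f"{self.name}: expected (N,C,D,H,W), got shape {x.shape}")
        for i, layer in enumerate(self.conv_layers):
            if min(x.shape[2:]) < 1:
                raise ValueError(f"{self.name}: input collapsed at layer {i}")
            x = layer(x)
            if i < 4:
                x = x.relu()
        return x

    def forward(self, x: Tensor) -> Tensor:
        f = self.features(x)
        return f.mean(axis=(1, 2, 3, 4)).sigmoid()   # (N,) in (0,1)


def init_weights(model: Module, rng: np.random.Generator) -> Module:
    """He-normal initialization: conv weights N(0, sqrt(2/fan_in)), biases 0,
    batch-norm scale 1 / shift 0, attention gates delta = 0.  Deterministic
    given the rng state (modules visited in construction order)."""
    for m in model.modules():
        if isinstance(m, Conv3d):
            sd = np.sqrt(2.0 / m.fan_in)
            m.weight.data = rng.normal(0.0, sd, m.weight.data.shape)
            if m.bias is not None:
                m.bias.data = np.zeros_like(m.bias.data)
        elif isinstance(m, BatchNorm3d):
            m.gamma.data = np.ones_like(m.gamma.data)
            m.beta.data = np.zeros_like(m.beta.data)
        elif isinstance(m, MFCM):
            m.delta.data = np.zeros(())
    return model


# -- functional wrappers over the module API ----------------------------------


def _as_input(image) -> Tensor:
    x = image if isinstance(image, Tensor) else Tensor(np.asarray(image, float))
    if x.ndim == 3:
        x = x.reshape((1, 1) + x.shape)
    elif x.ndim == 4:
        x = x.reshape((x.shape[0], 1) + x.shape[1:])
    return x


def encode(image, gen: Generator):
    """Encoder feature maps for a patch image (levels 0..3 skips, deepest)."""
    return gen.encode(_as_input(image))


def ifc_constrain(f, icl: ICLUnit):
    """Apply the information-constraint unit to the deepest feature map."""
    return icl(f if isinstance(f, Tensor) else Tensor(np.asarray(f, float)))


def mfcm_attend(f, mfcm: MFCM) -> Tensor:
    """Apply a channel self-attention block to a feature map."""
    return mfcm(f if isinstance(f, Tensor) else Tensor(np.asarray(f, float)))


def generator_forward(image, gen: Generator) -> GeneratorOutputs:
    """Full generator pass on a patch image (3D, (N,D,H,W) or (N,1,D,H,W))."""
    return gen(_as_input(image))


def discriminate(prob_map, disc: Discriminator) -> Tensor:
    """Scalar real-probability of a 3-channel probability/one-hot map."""
    x = prob_map if isinstance(prob_map, Tensor) \
        else Tensor(np.asarray(prob_map, float))
    if x.ndim == 4:
        x = x.reshape((1,) + x.shape)
    return disc(x)
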