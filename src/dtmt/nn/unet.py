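"""2D U-Net with auxiliary heads, and its hybrid 2D/3D-teacher variant.

Both networks emit three sigmoid probability maps per input:

* ``final``      — 1x1 conv + sigmoid on the last decoder features (f_s),
* ``aux_last``   — a second 1x1 conv + sigmoid on the same last-upsampling
  features (f_s1),
* ``aux_penult`` — the penultimate (half-resolution) decoder features,
  upsampled to full resolution, then 1x1 conv + sigmoid (f_s2).

The hybrid variant consumes a pseudo-3D stack of adjacent slices.  Its stem
is a 3D convolution whose extent along the plane axis equals the stack depth
with valid padding there, which collapses the plane axis completely; such a
convolution is arithmetically identical to a 2D convolution that treats the
planes as input channels, and is implemented that way.  The collapsed stem
features are fused by channel concatenation with the 2D features of the
stack's centre plane, after which the network is the same U-Net decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, maxpool2, relu, reshape, sigmoid, upsample2
from .layers import Conv2d, InstanceNorm2d, Module

__all__ = ["NetworkOutputs", "UNet2D", "HybridUNet"]


@dataclass
class NetworkOutputs:
    """Triple of per-sample probability maps, each shaped (N, H, W).

    The auxiliary maps may be None when a forward pass skips the extra heads.
    """

    final: Tensor
    aux_last: Tensor | None
    aux_penult: Tensor | None

    def detached(self) -> "NetworkOutputs":
        return NetworkOutputs(
            self.final.detach(),
            self.aux_last.detach() if self.aux_last is not None else None,
            self.aux_penult.detach() if self.aux_penult is not None else None)


def _squeeze_channel(t: Tensor) -> Tensor:
    n, _, h, w = t.shape
    return reshape(t, (n, h, w))


class UNet2D(Module):
    """Encoder-decoder with one 3x3 conv + ReLU per resolution level."""

    def __init__(self, in_channels: int = 1, base_channels: int = 16, depth: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if depth < 2:
            raise ValueError("depth must be >= 2")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.base_channels = base_channels
        self.depth = depth
        ch = [base_channels * 2 ** i for i in range(depth)]
        self.channels = ch
        prev = in_channels
        for i in range(depth):
            setattr(self, f"enc{i}", Conv2d(prev, ch[i], 3, rng))
            setattr(self, f"enc{i}_norm", InstanceNorm2d(ch[i]))
            prev = ch[i]
        for i in range(depth - 2, -1, -1):
            setattr(self, f"dec{i}", Conv2d(ch[i + 1] + ch[i], ch[i], 3, rng))
            setattr(self, f"dec{i}_norm", InstanceNorm2d(ch[i]))
        self.head_final = Conv2d(ch[0], 1, 1, rng)
        self.head_aux_last = Conv2d(ch[0], 1, 1, rng)
        self.head_aux_penult = Conv2d(ch[1], 1, 1, rng)

    def _block(self, name: str, x):
        return relu(getattr(self, f"{name}_norm")(getattr(self, name)(x)))

    # hook overridden by the hybrid variant
    def _level0(self, x):
        return self._block("enc0", x)

    def _check_input(self, x: np.ndarray | Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        h, w = x.shape[-2], x.shape[-1]
        divisor = 2 ** (self.depth - 1)
        if h % divisor or w % divisor:
            raise ValueError(f"input size {h}x{w} not divisible by {divisor}")
        return x

    def forward(self, x, aux: bool = True) -> NetworkOutputs:
        """Three probability maps; ``aux=False`` skips the auxiliary heads
        (teacher forwards use only the final map)."""
        x = self._check_input(x)
        if x.ndim == 3:  # (N, H, W) single-channel
            x = reshape(x, (x.shape[0], 1, x.shape[1], x.shape[2]))
        h = self._level0(x)
        feats = [h]
        for i in range(1, self.depth):
            h = maxpool2(h)
            h = self._block(f"enc{i}", h)
            if i < self.depth - 1:
                feats.append(h)
        penult = None
        for i in range(self.depth - 2, -1, -1):
            if i == 0:
                penult = h  # half-resolution features feeding the last upsampling
            h = upsample2(h)
            h = concat([feats[i], h], axis=1)
            h = self._block(f"dec{i}", h)
        f_final = _squeeze_channel(sigmoid(self.head_final(h)))
        if not aux:
            return NetworkOutputs(f_final, None, None)
        f_aux1 = _squeeze_channel(sigmoid(self.head_aux_last(h)))
        f_aux2 = _squeeze_channel(sigmoid(self.head_aux_penult(upsample2(penult))))
        return NetworkOutputs(f_final, f_aux1, f_aux2)

    __call__ = forward


class HybridUNet(UNet2D):
    """Teacher network fusing a collapsed 3D stem with 2D centre-plane features.

    Input is a pseudo-3D stack shaped (N, P, H, W) with odd P.  All encoder,
    decoder and head parameters carry the same names and shapes as
    :class:`UNet2D`, so they can receive EMA updates from a student; only
    ``stem`` and ``fuse`` are specific to this architecture.
    """

    def __init__(self, stack_planes: int = 3, base_channels: int = 16, depth: int = 4,
                 rng: np.random.Generator | None = None):
        if stack_planes % 2 == 0 or stack_planes < 3:
            raise ValueError("stack_planes must be odd and >= 3")
        rng = rng if rng is not None else np.random.default_rng(0)
        super().__init__(in_channels=1, base_channels=base_channels, depth=depth, rng=rng)
        self.stack_planes = stack_planes
        # plane-collapsing 3D stem, expressed as planes-as-channels 2D conv
        self.stem = Conv2d(stack_planes, base_channels, 3, rng)
        self.stem_norm = InstanceNorm2d(base_channels)
        self.fuse = Conv2d(2 * base_channels, base_channels, 1, rng)
        self.fuse_norm = InstanceNorm2d(base_channels)

    def extra_parameter_names(self) -> set[str]:
        """Names of parameters absent from the 2D student (no EMA partner)."""
        return {n for n, _ in self.named_parameters()
                if n.startswith(("stem", "fuse"))}

    def _level0(self, x):
        # x: (N, P, H, W); centre plane keeps a singleton channel axis
        centre = Tensor(np.ascontiguousarray(
            x.data[:, self.stack_planes // 2: self.stack_planes // 2 + 1]))
        e0 = self._block("enc0", centre)
        s = relu(self.stem_norm(self.stem(x)))
        return relu(self.fuse_norm(self.fuse(concat([e0, s], axis=1))))

    def forward(self, x, aux: bool = True) -> NetworkOutputs:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim == 3:  # single stack (P, H, W)
            x = reshape(x, (1,) + x.shape)
        if x.shape[1] != self.stack_planes:
            raise ValueError(f"expected {self.stack_planes} planes, got {x.shape[1]}")
        self._check_input(x)
        return super().forward(x, aux=aux)

    __call__ = forward
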