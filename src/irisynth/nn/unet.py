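"""U-Net encoder/decoder and the patch discriminator.

The generator is a fully convolutional encoder/decoder with skip
connections at every level: each encoder stage is a stride-2 4x4
convolution followed by instance normalization and LeakyReLU; each
decoder stage is a stride-2 4x4 transposed convolution followed by
instance normalization and ReLU, with dropout on the first few decoder
stages.  At the nominal 256x256 working resolution and depth 8 the
bottleneck is a 1x1 map, so the innermost stages carry no normalization
(instance statistics are undefined on a single spatial position).

The discriminator stacks five stride-2 4x4 convolutions over the
(iris mask, periocular mask, image) triplet and emits a sigmoid patch
score map — 8x8 for a 256x256 input, with 16x16 feature maps after the
fourth convolution.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    ChannelSoftmax,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    InstanceNorm2d,
    LeakyReLU,
    Module,
    Parameter,
    ReLU,
    Sigmoid,
)


def _width(base: int, level: int, cap_mult: int = 8) -> int:
    return base * min(2**level, cap_mult)


class _EncBlock(Module):
    def __init__(self, cin: int, cout: int, norm: bool, rng: np.random.Generator) -> None:
        self.conv = Conv2d(cin, cout, rng=rng)
        self.norm = InstanceNorm2d(cout) if norm else None
        self.act = LeakyReLU(0.2)

    def children(self) -> list[Module]:
        return [m for m in (self.conv, self.norm, self.act) if m is not None]

    def parameters(self) -> list[Parameter]:
        return [p for m in self.children() for p in m.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv.forward(x)
        if self.norm is not None:
            h = self.norm.forward(h)
        return self.act.forward(h)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.act.backward(grad)
        if self.norm is not None:
            grad = self.norm.backward(grad)
        return self.conv.backward(grad)


class _DecBlock(Module):
    def __init__(
        self,
        cin: int,
        cout: int,
        norm: bool,
        dropout_p: float,
        rng: np.random.Generator,
        final_act: Module | None = None,
    ) -> None:
        self.conv = ConvTranspose2d(cin, cout, rng=rng)
        self.norm = InstanceNorm2d(cout) if norm else None
        self.drop = Dropout(dropout_p, rng) if dropout_p > 0 else None
        self.act: Module = final_act if final_act is not None else ReLU()

    def children(self) -> list[Module]:
        return [m for m in (self.conv, self.norm, self.drop, self.act) if m is not None]

    def parameters(self) -> list[Parameter]:
        return [p for m in self.children() for p in m.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv.forward(x)
        if self.norm is not None:
            h = self.norm.forward(h)
        if self.drop is not None:
            h = self.drop.forward(h)
        return self.act.forward(h)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.act.backward(grad)
        if self.drop is not None:
            grad = self.drop.backward(grad)
        if self.norm is not None:
            grad = self.norm.backward(grad)
        return self.conv.backward(grad)


class UNet(Module):
    """Skip-connected encoder/decoder.

    Parameters
    ----------
    in_channels, out_channels
        Channel counts of input and output maps (2 -> 1 for mask-to-image
        synthesis; 1 -> n_classes for segmentation).
    depth
        Number of stride-2 stages in each half; the input resolution must
        be divisible by ``2**depth``.
    base_width
        Channel count after the first encoder stage; doubles per stage,
        capped at ``8 * base_width``.
    dropout_layers
        Dropout (p=0.5) is applied to this many innermost decoder stages
        (clipped to ``depth - 1`` so the output stage never drops).
    final
        ``"sigmoid"`` for a single-channel image in (0, 1) or
        ``"softmax"`` for a per-pixel categorical distribution.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        depth: int = 8,
        base_width: int = 64,
        dropout_layers: int = 5,
        dropout_p: float = 0.5,
        final: str = "sigmoid",
        rng: np.random.Generator | None = None,
    ) -> None:
        if depth < 2:
            raise ValueError("depth must be at least 2")
        rng = rng if rng is not None else np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.depth = depth
        self.base_width = base_width
        ec = [_width(base_width, i) for i in range(depth)]
        # innermost encoder/decoder stages skip normalization: the
        # bottleneck can be 1x1, where instance statistics are undefined
        self.enc = [
            _EncBlock(in_channels if i == 0 else ec[i - 1], ec[i], norm=(i < depth - 1), rng=rng)
            for i in range(depth)
        ]
        n_drop = min(dropout_layers, depth - 1)
        self.dec: list[_DecBlock] = []
        for j in range(depth):
            cin = ec[depth - 1] if j == 0 else self.dec[j - 1].conv.cout + ec[depth - 1 - j]
            last = j == depth - 1
            cout = out_channels if last else ec[depth - 2 - j]
            final_act: Module | None = None
            if last:
                final_act = ChannelSoftmax() if final == "softmax" else Sigmoid()
            self.dec.append(
                _DecBlock(
                    cin,
                    cout,
                    norm=not last and j > 0,
                    dropout_p=dropout_p if (j < n_drop and not last) else 0.0,
                    rng=rng,
                    final_act=final_act,
                )
            )
        self._skip_channels = ec

    def children(self) -> list[Module]:
        return [*self.enc, *self.dec]

    def parameters(self) -> list[Parameter]:
        return [p for m in self.children() for p in m.parameters()]

    def _check_resolution(self, x: np.ndarray) -> None:
        if x.ndim != 4:
            raise ValueError("expected a (batch, channels, H, W) array")
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {x.shape[1]}")
        div = 2**self.depth
        if x.shape[2] % div or x.shape[3] % div or x.shape[2] < div or x.shape[3] < div:
            raise ValueError(
                f"resolution {x.shape[2]}x{x.shape[3]} not divisible by 2^{self.depth}"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check_resolution(x)
        x = np.ascontiguousarray(x, dtype=np.float32)
        feats: list[np.ndarray] = []
        h = x
        for blk in self.enc:
            h = blk.forward(h)
            feats.append(h)
        for j, blk in enumerate(self.dec):
            if j == 0:
                inp = feats[-1]
            else:
                inp = np.concatenate([h, feats[self.depth - 1 - j]], axis=1)
            h = blk.forward(inp)
        self._n_feats = len(feats)
        return h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        d = self.depth
        skip_grads: list[np.ndarray | None] = [None] * d
        g = grad
        for j in range(d - 1, -1, -1):
            gin = self.dec[j].backward(g)
            if j == 0:
                skip_grads[d - 1] = _acc(skip_grads[d - 1], gin)
            else:
                csplit = self.dec[j].conv.cin - self._skip_channels[d - 1 - j]
                g = gin[:, :csplit]
                skip_grads[d - 1 - j] = _acc(skip_grads[d - 1 - j], gin[:, csplit:])
        g = skip_grads[d - 1]
        for i in range(d - 1, -1, -1):
            g = self.enc[i].backward(g)
            if i > 0:
                g = _acc(g, skip_grads[i - 1]) if skip_grads[i - 1] is not None else g
        return g


def _acc(a: np.ndarray | None, b: np.ndarray) -> np.ndarray:
    return b if a is None else a + b


class PatchDiscriminator(Module):
    """Five stride-2 convolutions over a (masks + image) stack, sigmoid patch output."""

    def __init__(
        self,
        in_channels: int = 3,
        base_width: int = 64,
        n_layers: int = 5,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng if rng is not None else np.random.default_rng()
        self.in_channels = in_channels
        self.n_layers = n_layers
        widths = [_width(base_width, i) for i in range(n_layers - 1)]
        self.convs: list[Conv2d] = []
        self.norms: list[InstanceNorm2d | None] = []
        cin = in_channels
        for i in range(n_layers):
            cout = 1 if i == n_layers - 1 else widths[i]
            self.convs.append(Conv2d(cin, cout, rng=rng))
            self.norms.append(InstanceNorm2d(cout) if 0 < i < n_layers - 1 else None)
            cin = cout
        self.acts = [LeakyReLU(0.2) for _ in range(n_layers - 1)]
        self.out_act = Sigmoid()
        self.feature_shapes_: list[tuple[int, int]] = []

    def children(self) -> list[Module]:
        out: list[Module] = []
        for conv, norm in zip(self.convs, self.norms):
            out.append(conv)
            if norm is not None:
                out.append(norm)
        out.extend(self.acts)
        out.append(self.out_act)
        return out

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for conv, norm in zip(self.convs, self.norms):
            params.extend(conv.parameters())
            if norm is not None:
                params.extend(norm.parameters())
        return params

    def feature_map_sizes(self, h: int, w: int) -> list[tuple[int, int]]:
        """Spatial size after each convolution for an HxW input."""
        sizes = []
        for conv in self.convs:
            h, w = conv.out_hw(h, w)
            sizes.append((h, w))
        return sizes

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected (batch, {self.in_channels}, H, W) input")
        x = np.ascontiguousarray(x, dtype=np.float32)
        self.feature_shapes_ = []
        h = x
        for i, (conv, norm) in enumerate(zip(self.convs, self.norms)):
            h = conv.forward(h)
            self.feature_shapes_.append(h.shape[2:])
            if norm is not None:
                h = norm.forward(h)
            if i < self.n_layers - 1:
                h = self.acts[i].forward(h)
        return self.out_act.forward(h)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.out_act.backward(grad)
        for i in range(self.n_layers - 1, -1, -1):
            if i < self.n_layers - 1:
                g = self.acts[i].backward(g)
            if self.norms[i] is not None:
                g = self.norms[i].backward(g)
            g = self.convs[i].backward(g)
        return g
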