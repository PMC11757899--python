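"""The skeleton-guided dual-stream 3D segmentation network.

Architecture overview.  The *main segmentation stream* is a 3D
encoder–decoder with skip connections: each encoder level applies two
3x3x3 convolutions (ReLU) followed by 2x2x2 max pooling; the decoder
mirrors it with 2x2x2 transpose convolutions, concatenating the
matching encoder features — and, where available, the skeleton-stream
features — before two more convolutions.  A 1x1x1 convolution plus
sigmoid yields the segmentation likelihood map.

The *skeleton-guided stream* runs on the deepest encoder features.
Each skeleton-guided block applies a residual block (two 3x3x3 convs
with identity skip) to its stream input ``t_in``, then a
skeleton-attention block computes

    A = sigmoid(ReLU(Conv_1x1x1(t) + Conv_1x1x1(f_in)))

from the pair (stream feature, encoder feature) and gates the stream:
``out = A * t``.  Because ReLU output is nonnegative, every attention
value lies in [0.5, 1).  The gated map is upsampled (transpose conv)
and propagates to the next skeleton-guided block; the stream's own
1x1x1 + sigmoid head predicts the skeleton likelihood, and the gated
features are concatenated back into the decoder.

Channel widths double per level from ``base_channels``; which encoder
levels feed the skeleton stream is configurable (default: the two
deepest).  Disabling the stream (``sg_levels=()``) yields the plain
encoder–decoder ablation arm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["NetworkSpec", "DualPrediction", "SGCNN", "build_network",
           "Conv3x3", "Conv1x1", "UpConv", "AttentionGate", "ResidualBlock",
           "SkeletonGuidedBlock", "attention_map", "skeleton_guided_block"]


@dataclass(frozen=True)
class NetworkSpec:
    """Structural hyper-parameters of the network."""

    in_channels: int = 1
    base_channels: int = 8
    n_levels: int = 3
    sg_levels: tuple[int, ...] = (2, 3)
    norm: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.in_channels < 1 or self.base_channels < 1:
            raise ValueError("channel counts must be >= 1")
        sg = tuple(sorted(set(int(l) for l in self.sg_levels)))
        if any(l < 1 or l > self.n_levels for l in sg):
            raise ValueError(f"sg_levels must be within 1..{self.n_levels}")
        if self.norm not in ("none", "batch", "instance"):
            raise ValueError("norm must be one of none|batch|instance")
        object.__setattr__(self, "sg_levels", sg)

    @property
    def channels(self) -> tuple[int, ...]:
        """Widths per level, level 1 first; last entry is the bottleneck."""
        return tuple(self.base_channels * 2 ** l for l in range(self.n_levels + 1))


@dataclass
class DualPrediction:
    """Likelihood maps of both heads, sharing the input patch geometry."""

    seg_likelihood: np.ndarray
    skel_likelihood: np.ndarray | None = None


class _Module:
    """Tiny parameter-container base; children register Tensors."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "_Module"] = {}

    def _register(self, name: str, t: Tensor) -> Tensor:
        t.requires_grad = True
        t.name = name
        self._params[name] = t
        return t

    def _child(self, name: str, m: "_Module") -> "_Module":
        self._children[name] = m
        return m

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.parameters(prefix + name + "."))
        return out

    def zero_(self) -> None:
        """Zero all parameters in place (used in structural tests)."""
        for t in self.parameters().values():
            t.data[...] = 0.0


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3x3(_Module):
    def __init__(self, rng, c_in, c_out):
        super().__init__()
        self.w = self._register("w", Tensor(_he(rng, (c_out, c_in, 3, 3, 3), c_in * 27)))
        self.b = self._register("b", Tensor(np.zeros(c_out, dtype=np.float32)))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.w, self.b, pad=1)


class Conv1x1(_Module):
    def __init__(self, rng, c_in, c_out, bias_init: float = 0.0):
        super().__init__()
        self.w = self._register("w", Tensor(_he(rng, (c_out, c_in, 1, 1, 1), c_in)))
        self.b = self._register(
            "b", Tensor(np.full(c_out, bias_init, dtype=np.float32)))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.w, self.b, pad=0)


class UpConv(_Module):
    """2x2x2 stride-2 transpose convolution (doubles resolution)."""

    def __init__(self, rng, c_in, c_out):
        super().__init__()
        self.w = self._register("w", Tensor(_he(rng, (c_in, c_out, 2, 2, 2), c_in * 8)))
        self.b = self._register("b", Tensor(np.zeros(c_out, dtype=np.float32)))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv_transpose3d(x, self.w, self.b)


class _ConvBlock(_Module):
    """Two 3x3x3 convolutions with ReLU (and optional normalization)."""

    def __init__(self, rng, c_in, c_out, norm="none"):
        super().__init__()
        self.c1 = self._child("c1", Conv3x3(rng, c_in, c_out))
        self.c2 = self._child("c2", Conv3x3(rng, c_out, c_out))
        self.norm = norm

    def _act(self, x: Tensor) -> Tensor:
        # leaky slope guards the shared encoder against dead-unit collapse
        # under the strongly imbalanced skeleton loss
        if self.norm in ("batch", "instance"):
            x = ag.instance_norm(x)
        return ag.leaky_relu(x)

    def __call__(self, x: Tensor) -> Tensor:
        return self._act(self.c2(self._act(self.c1(x))))


class ResidualBlock(_Module):
    """Two 3x3x3 convolutions with an identity skip: out = x + f(x).

    With all-zero weights the block is the identity map.
    """

    def __init__(self, rng, channels):
        super().__init__()
        self.c1 = self._child("c1", Conv3x3(rng, channels, channels))
        self.c2 = self._child("c2", Conv3x3(rng, channels, channels))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(x, self.c2(ag.leaky_relu(self.c1(x))))


class AttentionGate(_Module):
    """Skeleton-attention map from a (stream, encoder) feature pair.

    ``A = sigmoid(ReLU(conv_t(t) + conv_f(f)))``; sigma after ReLU forces
    every attention value into [0.5, 1).
    """

    def __init__(self, rng, channels):
        super().__init__()
        self.conv_t = self._child("conv_t", Conv1x1(rng, channels, channels))
        self.conv_f = self._child("conv_f", Conv1x1(rng, channels, channels))

    def __call__(self, t_in: Tensor, f_in: Tensor) -> Tensor:
        if t_in.shape != f_in.shape:
            raise ValueError(f"misaligned inputs: {t_in.shape} vs {f_in.shape}")
        return ag.sigmoid(ag.relu(ag.add(self.conv_t(t_in), self.conv_f(f_in))))


class SkeletonGuidedBlock(_Module):
    """Residual block on the stream input, then attention gating.

    ``t = residual(t_in); A = attention(t, f_in); out = A * t``.
    """

    def __init__(self, rng, channels):
        super().__init__()
        self.residual = self._child("residual", ResidualBlock(rng, channels))
        self.attention = self._child("attention", AttentionGate(rng, channels))

    def __call__(self, t_in: Tensor, f_in: Tensor) -> Tensor:
        t = self.residual(t_in)
        a = self.attention(t, f_in)
        return ag.mul(a, t)


def attention_map(t_in, f_in, gate: AttentionGate) -> np.ndarray:
    """Evaluate a gate on raw feature-map arrays; returns the map A."""
    t = t_in if isinstance(t_in, Tensor) else Tensor(t_in)
    f = f_in if isinstance(f_in, Tensor) else Tensor(f_in)
    return gate(t, f).data


def skeleton_guided_block(t_in, f_in, block: SkeletonGuidedBlock) -> np.ndarray:
    """Evaluate a skeleton-guided block on raw feature-map arrays."""
    t = t_in if isinstance(t_in, Tensor) else Tensor(t_in)
    f = f_in if isinstance(f_in, Tensor) else Tensor(f_in)
    return block(t, f).data


class SGCNN(_Module):
    """The dual-stream network; see the module docstring for the layout."""

    #: sigmoid-head bias prior: initial foreground likelihood ~0.03,
    #: the log-odds of a typical tubular foreground fraction
    HEAD_BIAS = -3.5

    def __init__(self, spec: NetworkSpec):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        ch = spec.channels  # level l width = ch[l-1]; bottleneck = ch[n]
        n = spec.n_levels
        sg = spec.sg_levels

        self.enc = [self._child(f"enc{l}", _ConvBlock(
            rng, spec.in_channels if l == 1 else ch[l - 2], ch[l - 1], spec.norm))
            for l in range(1, n + 1)]
        self.bottleneck = self._child("bottleneck",
                                      _ConvBlock(rng, ch[n - 1], ch[n], spec.norm))

        # skeleton-guided stream: blocks from deepest to shallowest sg level
        self.sg_blocks: dict[int, SkeletonGuidedBlock] = {}
        self.sg_up: dict[int, list[UpConv]] = {}
        if sg:
            levels_desc = sorted(sg, reverse=True)
            for i, l in enumerate(levels_desc):
                self.sg_blocks[l] = self._child(f"sg{l}",
                                                SkeletonGuidedBlock(rng, ch[l - 1]))
                if i + 1 < len(levels_desc):
                    nxt = levels_desc[i + 1]
                    ups = [self._child(f"sgup{l}_{m}", UpConv(rng, ch[m - 1], ch[m - 2]))
                           for m in range(l, nxt, -1)]
                    self.sg_up[l] = ups
            # head: upsample to input resolution the way the main decoder
            # does (transpose conv, then a 3x3x3 conv + ReLU), then 1x1x1
            shallowest = levels_desc[-1]
            self.skel_out_up = []
            self.skel_out_conv = []
            for m in range(shallowest, 1, -1):
                self.skel_out_up.append(
                    self._child(f"skelup{m}", UpConv(rng, ch[m - 1], ch[m - 2])))
                self.skel_out_conv.append(
                    self._child(f"skelconv{m}", Conv3x3(rng, ch[m - 2], ch[m - 2])))
            self.skel_head = self._child(
                "skel_head", Conv1x1(rng, ch[0], 1, bias_init=self.HEAD_BIAS))

        self.dec_up = [self._child(f"up{l}", UpConv(rng, ch[l], ch[l - 1]))
                       for l in range(n, 0, -1)]
        self.dec = []
        for l in range(n, 0, -1):
            width = ch[l - 1] * (3 if l in sg else 2)
            self.dec.append(self._child(f"dec{l}",
                                        _ConvBlock(rng, width, ch[l - 1], spec.norm)))
        self.seg_head = self._child(
            "seg_head", Conv1x1(rng, ch[0], 1, bias_init=self.HEAD_BIAS))

    # -- forward ----------------------------------------------------------
    def forward_tensors(self, x) -> tuple[Tensor, Tensor | None]:
        """Run the network, returning head tensors (graph attached)."""
        if isinstance(x, Tensor):
            t = x
        else:
            arr = np.asarray(x, dtype=np.float32)
            if arr.ndim == 3:
                arr = arr[None]
            t = Tensor(arr)
        if t.data.ndim != 4:
            raise ValueError("input must be (C, D, H, W) or (D, H, W)")
        d, h, w = t.data.shape[1:]
        f = 2 ** self.spec.n_levels
        if d % f or h % f or w % f:
            raise ValueError(f"patch dims {(d, h, w)} must be divisible by {f}")

        skips: list[Tensor] = []
        cur = t
        for enc in self.enc:
            e = enc(cur)
            skips.append(e)
            cur = ag.maxpool2(e)
        cur = self.bottleneck(cur)

        sg_feats: dict[int, Tensor] = {}
        skel_pred: Tensor | None = None
        if self.spec.sg_levels:
            levels_desc = sorted(self.spec.sg_levels, reverse=True)
            stream: Tensor | None = None
            for l in levels_desc:
                f_in = skips[l - 1]
                t_in = f_in if stream is None else stream
                s = self.sg_blocks[l](t_in, f_in)
                sg_feats[l] = s
                stream = s
                for up in self.sg_up.get(l, []):
                    stream = up(stream)
            out = sg_feats[levels_desc[-1]]
            for up, conv in zip(self.skel_out_up, self.skel_out_conv):
                out = ag.leaky_relu(conv(up(out)))
            skel_pred = ag.sigmoid(self.skel_head(out))

        for i, l in enumerate(range(self.spec.n_levels, 0, -1)):
            cur = self.dec_up[i](cur)
            parts = [cur, skips[l - 1]]
            if l in sg_feats:
                # skeleton features are standardized per channel before the
                # concatenation: their scale drifts as the skeleton loss
                # reshapes them, and an unnormalized injection destabilizes
                # the shared encoder for some initializations
                parts.append(ag.instance_norm(sg_feats[l]))
            cur = self.dec[i](ag.concat(parts))
        seg_pred = ag.sigmoid(self.seg_head(cur))
        return seg_pred, skel_pred

    def predict_patch(self, x) -> DualPrediction:
        """Forward pass returning plain likelihood arrays ``(D, H, W)``."""
        p, ph = self.forward_tensors(x)
        return DualPrediction(p.data[0], None if ph is None else ph.data[0])

    # -- bookkeeping ------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.parameters().values())

    def summary(self) -> str:
        lines = [f"SGCNN(spec={self.spec})"]
        for name, t in sorted(self.parameters().items()):
            lines.append(f"  {name:40s} {t.data.shape}")
        lines.append(f"total parameters: {self.n_parameters}")
        return "\n".join(lines)

    # -- (de)serialization ------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(state) != set(params):
            raise ValueError("checkpoint parameter names do not match the network")
        for k, v in state.items():
            if params[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            params[k].data[...] = v

    def save(self, path) -> None:
        from dataclasses import asdict
        meta = json.dumps(asdict(self.spec))
        np.savez(path, __spec__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "SGCNN":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__spec__"]).decode())
            meta["sg_levels"] = tuple(meta["sg_levels"])
            model = cls(NetworkSpec(**meta))
            model.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
        return model


def build_network(spec: NetworkSpec) -> SGCNN:
    """Construct the network with seeded, reproducible initialization."""
    return SGCNN(spec)
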