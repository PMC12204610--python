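"""Convolutional-attention network predicting the three editing outcomes.

Pipeline (batch, 8 channels, 128 positions, 2 sequences):

  spatial conv-attention on the raw input
  -> multiscale convolution (MixConv): parallel 1x2, 3x2 and 9x2 kernels,
     each branch padded along the length axis and consuming the seq axis,
     outputs concatenated channel-wise
  -> channel attention (global average pool, 1-D conv across channels, sigmoid)
  -> 1x1 convolution compressing the concatenated channels
  -> two further convolution layers along the length axis, each followed by
     the hidden activation and spatial conv-attention
  -> flatten -> shared fully-connected trunk -> three branches with disjoint
     parameters, one per outcome (validly edited, unedited, erroneous),
     each ending in a sigmoid scaled to [0, 100].

Both attention stages are purely multiplicative gates: spatial attention
computes one weight per location from the per-location channel mean and max
convolved with an odd-sized kernel (default 5, sigmoid); channel attention
computes one weight per channel from pooled descriptors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, conv2d, softmax
from .encoder import FRAME_LENGTH, N_CHANNELS

__all__ = ["ModelConfig", "PrimeNet", "ConfigError", "HEAD_NAMES"]

HEAD_NAMES = ("valid", "unedited", "erroneous")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    mixconv_kernels: tuple = ((1, 2), (3, 2), (9, 2))
    mixconv_out_channels_per_branch: int = 16
    compress_channels: int = 32
    conv_channels: tuple = (32, 32)
    conv_kernel: int = 3
    conv_attention_kernel: int = 5
    conv_attention_activation: str = "sigmoid"
    channel_attention_enabled: bool = True
    channel_attention_kernel: int = 3
    conv_attention_enabled: bool = True
    trunk_widths: tuple = (256,)
    branch_widths: tuple = (64,)
    output_scale: float = 100.0

    def __post_init__(self):
        if self.conv_attention_kernel % 2 == 0:
            raise ConfigError("conv-attention kernel must be odd")
        if self.conv_kernel % 2 == 0:
            raise ConfigError("conv kernel must be odd")
        for kl, ks in self.mixconv_kernels:
            if kl % 2 == 0 or kl > FRAME_LENGTH:
                raise ConfigError(f"MixConv length extent {kl} must be odd and <= 128")
            if ks != 2:
                raise ConfigError("MixConv kernels must span both sequences (seq extent 2)")
        if self.conv_attention_activation not in ("sigmoid", "softmax"):
            raise ConfigError("conv-attention activation must be sigmoid or softmax")
        if self.compress_channels > len(self.mixconv_kernels) * self.mixconv_out_channels_per_branch:
            raise ConfigError("compression cannot increase the channel count")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mixconv_kernels"] = [list(k) for k in self.mixconv_kernels]
        for key in ("conv_channels", "trunk_widths", "branch_widths"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["mixconv_kernels"] = tuple(tuple(k) for k in d["mixconv_kernels"])
        for key in ("conv_channels", "trunk_widths", "branch_widths"):
            d[key] = tuple(d[key])
        return cls(**d)


def _gauss(rng, *shape, scale=None):
    fan_in = int(np.prod(shape[1:])) or 1
    scale = scale if scale is not None else 1.0 / np.sqrt(fan_in)
    return (rng.standard_normal(shape) * scale).astype(ad.DTYPE)


class PrimeNet:
    """The model: a named-parameter store plus the forward computation."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = self.config
        p: dict[str, Tensor] = {}

        def add(name, arr):
            p[name] = Tensor(arr, requires_grad=True)

        def add_conv_attention(prefix):
            add(f"{prefix}.W", _gauss(rng, 1, 2, c.conv_attention_kernel, 1))
            add(f"{prefix}.b", np.zeros(1, ad.DTYPE))

        if c.conv_attention_enabled:
            add_conv_attention("att_in")
        for i, (kl, ks) in enumerate(c.mixconv_kernels):
            add(f"mix{i}.W", _gauss(rng, c.mixconv_out_channels_per_branch,
                                    N_CHANNELS, kl, ks))
            add(f"mix{i}.b", np.zeros(c.mixconv_out_channels_per_branch, ad.DTYPE))
        n_mix = len(c.mixconv_kernels) * c.mixconv_out_channels_per_branch
        if c.channel_attention_enabled:
            add("chatt.W", _gauss(rng, 1, 1, c.channel_attention_kernel, 1))
            add("chatt.b", np.zeros(1, ad.DTYPE))
        add("compress.W", _gauss(rng, c.compress_channels, n_mix, 1, 1))
        add("compress.b", np.zeros(c.compress_channels, ad.DTYPE))
        prev = c.compress_channels
        for i, ch in enumerate(c.conv_channels):
            add(f"conv{i}.W", _gauss(rng, ch, prev, c.conv_kernel, 1))
            add(f"conv{i}.b", np.zeros(ch, ad.DTYPE))
            if c.conv_attention_enabled:
                add_conv_attention(f"att{i}")
            prev = ch
        flat = prev * FRAME_LENGTH
        widths = [flat] + list(c.trunk_widths)
        for i in range(len(c.trunk_widths)):
            add(f"trunk{i}.W", _gauss(rng, widths[i], widths[i + 1]))
            add(f"trunk{i}.b", np.zeros(widths[i + 1], ad.DTYPE))
        for head in HEAD_NAMES:
            bw = [widths[-1]] + list(c.branch_widths) + [1]
            for i in range(len(bw) - 1):
                add(f"branch_{head}.{i}.W", _gauss(rng, bw[i], bw[i + 1]))
                add(f"branch_{head}.{i}.b", np.zeros(bw[i + 1], ad.DTYPE))
        self.params = p
        self._attention_sink: dict | None = None
        self._shape_audit()

    # -- stages -----------------------------------------------------------
    def _conv_attention(self, x: Tensor, prefix: str) -> Tensor:
        """Spatial gating: weight per (position, seq) from channel mean+max."""
        stats = concat([x.mean(axis=1, keepdims=True), x.max(axis=1, keepdims=True)],
                       axis=1)  # (B,2,L,S)
        pad = (self.config.conv_attention_kernel - 1) // 2
        logits = conv2d(stats, self.params[f"{prefix}.W"], self.params[f"{prefix}.b"],
                        pad_length=pad)  # (B,1,L,S)
        if self.config.conv_attention_activation == "sigmoid":
            w = logits.sigmoid()
        else:
            B, _, L, S = logits.shape
            w = softmax(logits.reshape(B, 1, L * S), axis=2).reshape(B, 1, L, S)
        if self._attention_sink is not None:
            self._attention_sink.setdefault(prefix, []).append(w.data[:, 0])
        return x * w

    def _channel_attention(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3), keepdims=False)  # (B,C)
        B, C = pooled.shape
        pad = (self.config.channel_attention_kernel - 1) // 2
        logits = conv2d(pooled.reshape(B, 1, C, 1), self.params["chatt.W"],
                        self.params["chatt.b"], pad_length=pad)
        w = logits.sigmoid().reshape(B, 1, C, 1).transpose((0, 2, 1, 3))  # (B,C,1,1)
        return x * w

    def _mixconv(self, x: Tensor) -> Tensor:
        outs = []
        for i, (kl, ks) in enumerate(self.config.mixconv_kernels):
            outs.append(conv2d(x, self.params[f"mix{i}.W"], self.params[f"mix{i}.b"],
                               pad_length=(kl - 1) // 2))
        return concat(outs, axis=1)  # (B, branches*F, 128, 1)

    def _linear(self, x: Tensor, name: str) -> Tensor:
        return x @ self.params[f"{name}.W"] + self.params[f"{name}.b"]

    def forward(self, x, collect_attention: bool = False) -> Tensor:
        """Map (B, 128, 8, 2) pseudo-images to (B, 3) percent predictions."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=ad.DTYPE))
        if x.data.ndim == 3:
            x = x.reshape(1, *x.data.shape)
        B = x.data.shape[0]
        if x.data.shape[1:] != (FRAME_LENGTH, N_CHANNELS, 2):
            raise ConfigError(f"expected (B, 128, 8, 2) input, got {x.data.shape}")
        self._attention_sink = {} if collect_attention else None
        h = x.transpose((0, 2, 1, 3))  # (B, 8, 128, 2)
        c = self.config
        if c.conv_attention_enabled:
            h = self._conv_attention(h, "att_in")
        h = self._mixconv(h)
        if c.channel_attention_enabled:
            h = self._channel_attention(h)
        h = conv2d(h, self.params["compress.W"], self.params["compress.b"])
        pad = (c.conv_kernel - 1) // 2
        for i in range(len(c.conv_channels)):
            h = conv2d(h, self.params[f"conv{i}.W"], self.params[f"conv{i}.b"],
                       pad_length=pad).relu()
            if c.conv_attention_enabled:
                h = self._conv_attention(h, f"att{i}")
        h = h.reshape(B, -1)
        for i in range(len(c.trunk_widths)):
            h = self._linear(h, f"trunk{i}").relu()
        heads = []
        n_branch = len(c.branch_widths) + 1
        for head in HEAD_NAMES:
            b = h
            for i in range(n_branch - 1):
                b = self._linear(b, f"branch_{head}.{i}").relu()
            b = self._linear(b, f"branch_{head}.{n_branch - 1}")
            heads.append(b.sigmoid() * c.output_scale)
        return concat(heads, axis=1)  # (B, 3)

    def predict(
        self,
        X: np.ndarray,
        batch_size: int = 512,
        zero_channels: tuple[int, ...] = (),
    ) -> np.ndarray:
        """Batched inference; ``zero_channels`` ablates input channels."""
        X = np.asarray(X, dtype=ad.DTYPE)
        if X.ndim == 3:
            X = X[None]
        if zero_channels:
            X = X.copy()
            X[:, :, list(zero_channels), :] = 0.0
        outs = [
            self.forward(X[i : i + batch_size]).data
            for i in range(0, len(X), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    # -- persistence & audit ----------------------------------------------
    def state(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "params": {k: v.data.copy() for k, v in self.params.items()},
            "seed": self.seed,
        }

    def load_state(self, state: dict) -> None:
        from .io_formats import ValidationError

        cfg = ModelConfig.from_dict(state["config"])
        if cfg != self.config:
            raise ValidationError("checkpoint/model configuration mismatch")
        for k, t in self.params.items():
            arr = np.asarray(state["params"][k], dtype=ad.DTYPE)
            if arr.shape != t.data.shape:
                raise ValidationError(f"parameter {k} shape mismatch")
            t.data = arr.copy()

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self.params.values()))

    def _shape_audit(self) -> None:
        """Build-time dry run; any stage mismatch raises here, not at call time."""
        dummy = np.zeros((1, FRAME_LENGTH, N_CHANNELS, 2), dtype=ad.DTYPE)
        out = self.forward(dummy)
        if out.data.shape != (1, 3):
            raise ConfigError(f"head produced {out.data.shape}, expected (1, 3)")

    def summary(self) -> str:
        lines = [f"{'parameter':<24}{'shape':<20}{'count':>10}"]
        for k, t in self.params.items():
            lines.append(f"{k:<24}{str(t.data.shape):<20}{t.data.size:>10}")
        lines.append(f"total parameters: {self.n_parameters()}")
        return "\n".join(lines)
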