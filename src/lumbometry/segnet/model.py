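"""Multi-scale attention segmentation network.

Topology: a three-branch backbone (shared stem, branches at 1x / 2x / 4x
down-sampling, each ending in a channel-attention residual block), a fusion
module that unifies the branches at the smallest scale, then two parallel
heads — a residual dilated-convolution module and a plain convolutional
feature-extraction module — combined by elementwise addition and decoded
back to full resolution for per-class scores.

Widths, strides and dilation rates are configuration, not architecture:
`NetworkConfig` carries the defaults used throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ..errors import ConfigurationError
from . import autograd as ag
from .autograd import Parameter, Tensor


@dataclass(frozen=True)
class NetworkConfig:
    """Shape/width configuration of the segmentation network."""

    input_size: tuple[int, int] = (256, 128)  # (rows, cols)
    n_classes: int = 3
    base_channels: int = 8
    branch_channels: tuple[int, int, int] = (8, 16, 32)  # scales 1x, 2x, 4x
    fusion_channels: int = 32
    attention_reduction: int = 4
    # (kernel, dilation) triples of the residual dilated-convolution module.
    dilations: tuple[tuple[int, int], ...] = ((1, 1), (3, 2), (5, 2))
    seed: int = 0

    def validate(self) -> None:
        if len(self.branch_channels) != 3:
            raise ConfigurationError("exactly 3 scale branches are required")
        if any(c <= 0 for c in self.branch_channels) or self.base_channels <= 0:
            raise ConfigurationError("channel counts must be positive")
        for c in self.branch_channels:
            if c % self.attention_reduction:
                raise ConfigurationError(
                    f"attention reduction {self.attention_reduction} does not "
                    f"divide branch width {c}"
                )
        if any(s % 8 for s in self.input_size):
            raise ConfigurationError("input size must be divisible by 8")


class Module:
    """Tiny nn.Module analogue: parameter discovery + train/eval mode."""

    def __init__(self):
        self.training = True

    def children(self):
        for value in vars(self).items():
            yield value

    def _walk(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        params = [v for v in vars(self).values() if isinstance(v, Parameter)]
        for _, child in self._walk():
            params.extend(child.parameters())
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._walk():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                state[prefix + name] = value.data
            elif isinstance(value, np.ndarray):
                state[prefix + name] = value
        for name, child in self._walk():
            state.update(child.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                value.data = np.asarray(state[prefix + name], dtype=np.float32)
            elif isinstance(value, np.ndarray):
                value[...] = state[prefix + name]
        for name, child in self._walk():
            child.load_state_dict(state, prefix + name + ".")


def _he_init(rng: np.random.Generator, cout: int, cin: int, kh: int, kw: int):
    std = np.sqrt(2.0 / (cin * kh * kw))
    return rng.normal(0.0, std, size=(cout, cin, kh, kw)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng, cin, cout, k=3, stride=1, dilation=1, bias=True):
        super().__init__()
        self.stride = stride
        self.dilation = dilation
        self.padding = dilation * (k - 1) // 2
        self.weight = Parameter(_he_init(rng, cout, cin, k, k))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1):
        super().__init__()
        self.momentum = momentum
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                               self.running_var, self.training, self.momentum)


class ConvBNSiLU(Module):
    """3x3 Convolution + BN + SiLU feature-extraction unit."""

    def __init__(self, rng, cin, cout, k=3, stride=1, dilation=1):
        super().__init__()
        self.conv = Conv2d(rng, cin, cout, k=k, stride=stride,
                           dilation=dilation, bias=False)
        self.bn = BatchNorm2d(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.silu(self.bn(self.conv(x)))


class ResAttentionBlock(Module):
    """Residual unit with squeeze-excite channel attention.

    The excitation MLP uses 1x1 convolutions (not FC layers) and SiLU; the
    sigmoid gate rescales the residual branch before the identity add.  For
    testing, ``gate_override`` may force the gate to all ones or all zeros.
    """

    def __init__(self, rng, c, reduction=4):
        super().__init__()
        if c % reduction:
            raise ConfigurationError(
                f"reduction {reduction} does not divide channel count {c}"
            )
        self.body1 = ConvBNSiLU(rng, c, c)
        self.conv2 = Conv2d(rng, c, c, k=3, bias=False)
        self.bn2 = BatchNorm2d(c)
        self.squeeze = Conv2d(rng, c, c // reduction, k=1)
        self.excite = Conv2d(rng, c // reduction, c, k=1)
        self.gate_override: str | None = None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.bn2(self.conv2(self.body1(x)))
        if self.gate_override == "ones":
            return x + y
        if self.gate_override == "zeros":
            return x
        g = ag.sigmoid(self.excite(ag.silu(self.squeeze(ag.global_avg_pool(y)))))
        return x + g * y


class FusionModule(Module):
    """Unify the three branch maps at the smallest scale and fuse them.

    Down-samples the 1x and 2x maps to the 4x grid (average pooling),
    concatenates channels, applies a preliminary 1x1 fusion, adds the
    (projected) minimum-scale map back in, and finishes with a 3x3 conv.
    """

    def __init__(self, rng, channels: tuple[int, int, int], cout: int):
        super().__init__()
        self.prelim = Conv2d(rng, sum(channels), cout, k=1)
        self.project = Conv2d(rng, channels[2], cout, k=1)
        self.final = ConvBNSiLU(rng, cout, cout)
        self.residual_add = True  # ablation hook for tests

    def __call__(self, x1: Tensor, x2: Tensor, x3: Tensor) -> Tensor:
        h1, h2, h3 = x1.shape[2], x2.shape[2], x3.shape[2]
        w1, w2, w3 = x1.shape[3], x2.shape[3], x3.shape[3]
        if not (h1 == 2 * h2 == 4 * h3 and w1 == 2 * w2 == 4 * w3):
            raise ConfigurationError(
                f"branch scales must be 1:2:4, got {(h1, w1)}, {(h2, w2)}, {(h3, w3)}"
            )
        u1 = ag.avg_pool2d(x1, 4)
        u2 = ag.avg_pool2d(x2, 2)
        fused = self.prelim(ag.concat([u1, u2, x3], axis=1))
        if self.residual_add:
            fused = fused + self.project(x3)
        return self.final(fused)


class DilatedModule(Module):
    """Parallel dilated convolutions with a residual connection.

    Branch kernels/dilations come from NetworkConfig (default 1x1 d1,
    3x3 d2, 5x5 d2); branch outputs are concatenated, fused by a 1x1
    convolution, and added to the input.
    """

    def __init__(self, rng, c, dilations=((1, 1), (3, 2), (5, 2))):
        super().__init__()
        self.branches = [
            Conv2d(rng, c, c, k=k, dilation=d) for k, d in dilations
        ]
        self.fuse = Conv2d(rng, c * len(self.branches), c, k=1)

    def __call__(self, x: Tensor) -> Tensor:
        y = ag.concat([b(x) for b in self.branches], axis=1)
        return x + self.fuse(y)


class ConvFeatureExtraction(Module):
    """Two stacked Conv+BN+SiLU units that re-extract backbone features."""

    def __init__(self, rng, c):
        super().__init__()
        self.block1 = ConvBNSiLU(rng, c, c)
        self.block2 = ConvBNSiLU(rng, c, c)

    def __call__(self, x: Tensor) -> Tensor:
        return self.block2(self.block1(x))


class SegmentationNetwork(Module):
    """Full model: backbone -> fusion -> (dilated || conv) -> decode -> scores."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c0 = config.base_channels
        c1, c2, c3 = config.branch_channels
        cf = config.fusion_channels

        # The stem halves resolution; branches then sit at 1/2, 1/4 and
        # 1/8 of the input (still the required 1:2:4 relation), which keeps
        # the CPU cost of full-resolution convolutions out of the backbone.
        self.stem = ConvBNSiLU(rng, 1, c0, stride=2)
        self.branch1 = [ConvBNSiLU(rng, c0, c1),
                        ResAttentionBlock(rng, c1, config.attention_reduction)]
        self.branch2 = [ConvBNSiLU(rng, c0, c2, stride=2),
                        ResAttentionBlock(rng, c2, config.attention_reduction)]
        self.branch3 = [ConvBNSiLU(rng, c0, c2, stride=2),
                        ConvBNSiLU(rng, c2, c3, stride=2),
                        ResAttentionBlock(rng, c3, config.attention_reduction)]
        self.fusion = FusionModule(rng, (c1, c2, c3), cf)
        self.dilated = DilatedModule(rng, cf, config.dilations)
        self.convfeat = ConvFeatureExtraction(rng, cf)
        self.decode1 = ConvBNSiLU(rng, cf, cf // 2)
        self.decode2 = ConvBNSiLU(rng, cf // 2, cf // 4)
        self.decode3 = ConvBNSiLU(rng, cf // 4, cf // 4)
        self.head = Conv2d(rng, cf // 4, config.n_classes, k=1)

    @staticmethod
    def _run(blocks, x):
        for block in blocks:
            x = block(x)
        return x

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ConfigurationError(
                f"input spatial size {x.shape[2:]} must be divisible by 8"
            )
        s = self.stem(x)
        f1 = self._run(self.branch1, s)
        f2 = self._run(self.branch2, s)
        f3 = self._run(self.branch3, s)
        fused = self.fusion(f1, f2, f3)
        combined = self.dilated(fused) + self.convfeat(fused)
        d = self.decode1(ag.upsample2x(combined))
        d = self.decode2(ag.upsample2x(d))
        d = self.decode3(ag.upsample2x(d))
        return self.head(d)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_network(config: NetworkConfig | None = None) -> SegmentationNetwork:
    """Assemble the model from a config (validated; seeded init)."""
    return SegmentationNetwork(config or NetworkConfig())


def save_checkpoint(model: SegmentationNetwork, path) -> None:
    """Write weights + embedded NetworkConfig to an .npz checkpoint."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path) -> SegmentationNetwork:
    with np.load(path) as data:
        raw = {k: data[k] for k in data.files}
    cfg = json.loads(bytes(raw.pop("__config__")).decode())
    for key in ("input_size", "branch_channels"):
        cfg[key] = tuple(cfg[key])
    cfg["dilations"] = tuple(tuple(d) for d in cfg["dilations"])
    model = SegmentationNetwork(NetworkConfig(**cfg))
    model.load_state_dict(raw)
    return model
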