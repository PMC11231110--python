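"""Network assembly and exact cost accounting.

Builds the X-ODFCANet classifier — a ResNet-18-style backbone whose residual
3x3 convolutions are ODConv layers, with coordinate-attention gates after the
first three stages and an FCA head fusing those taps with the final pooled
feature — plus plain ResNet-18/50/101 baselines used to calibrate the
parameter/MAC accountant.

Accounting conventions: parameters are trainable scalars; MACs (one
multiply-accumulate) are counted for convolutions and affine maps only, per
sample at the configured input size. Normalization, pooling and elementwise
operations are free. Printed "FLOPs" figures for CNNs conventionally follow
the same 1-FLOP-per-MAC rule, which the ResNet-18 calibration pins down.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .attention import CoordAtt, FeatureCoordAtt
from .autodiff import Tensor
from .nn import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
)
from .odconv import ODConv2d

__all__ = [
    "ConfigError",
    "NetConfig",
    "ModelSummary",
    "ODConvBasicBlock",
    "XODFCANet",
    "build_odconv_resblock",
    "build_xodfcanet",
    "build_resnet18_baseline",
    "build_resnet50_baseline",
    "build_resnet101_baseline",
    "count_parameters",
    "count_macs",
    "summarize",
]


class ConfigError(ValueError):
    pass


@dataclass
class NetConfig:
    """Architecture hyperparameters of X-ODFCANet.

    The defaults mirror a ResNet-18 skeleton (stem 7x7/64, four stages of two
    basic blocks, widths doubling per stage). ``configs/xodfcanet.yaml`` holds
    the documented configuration used for the headline cost figures.
    """

    num_classes: int = 3
    in_channels: int = 3
    input_size: int = 224
    stem_channels: int = 64
    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: tuple[int, ...] = (2, 2, 2, 2)
    odconv_n: int = 4
    odconv_gamma: float = 1 / 16
    kernel_attention: str = "sigmoid"
    ca_r: int = 8
    ca_bn_after_reduce: bool = True
    fca_fusion: str = "sum"
    classifier_width: int | None = None  # None -> last stage width
    final_pool: str = "avg"
    seed: int = 0

    def validate(self) -> "NetConfig":
        if len(self.stage_widths) != 4:
            raise ConfigError(f"stage_widths must have four entries, got {self.stage_widths}")
        if len(self.blocks_per_stage) != 4:
            raise ConfigError(
                f"blocks_per_stage must have four entries, got {self.blocks_per_stage}"
            )
        for name in ("num_classes", "in_channels", "input_size", "stem_channels",
                     "odconv_n", "ca_r"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if any(b < 1 for b in self.blocks_per_stage):
            raise ConfigError(f"blocks_per_stage must be positive, got {self.blocks_per_stage}")
        w = self.stage_widths
        if any(v < 1 for v in w):
            raise ConfigError(f"stage_widths must be positive, got {w}")
        if any(w[i + 1] != 2 * w[i] for i in range(3)):
            raise ConfigError(f"stage_widths must double at each stage, got {w}")
        if not 0 < self.odconv_gamma <= 1:
            raise ConfigError(f"odconv_gamma must be in (0, 1], got {self.odconv_gamma}")
        if self.fca_fusion not in ("sum", "concat"):
            raise ConfigError(f"fca_fusion must be 'sum' or 'concat', got {self.fca_fusion}")
        if self.final_pool not in ("avg", "max"):
            raise ConfigError(f"final_pool must be 'avg' or 'max', got {self.final_pool}")
        if self.kernel_attention not in ("sigmoid", "softmax"):
            raise ConfigError(f"kernel_attention must be 'sigmoid' or 'softmax'")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        d = dict(d)
        flat: dict = {}
        for group, prefix in (("odconv", "odconv_"), ("ca", "ca_"), ("fca", "fca_")):
            sub = d.pop(group, {}) or {}
            for k, v in sub.items():
                key = {"n": "odconv_n", "gamma": "odconv_gamma",
                       "kernel_attention": "kernel_attention",
                       "r": "ca_r", "bn_after_reduce": "ca_bn_after_reduce",
                       "fusion": "fca_fusion"}.get(k, prefix + k)
                flat[key] = v
        flat.update(d)
        for key in ("stage_widths", "blocks_per_stage"):
            if key in flat:
                flat[key] = tuple(flat[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(flat) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat).validate()

    @classmethod
    def from_yaml(cls, path) -> "NetConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# --------------------------------------------------------------------- blocks
class ODConvBasicBlock(Module):
    """Residual basic block whose two 3x3 convolutions are ODConv layers.

    conv -> BN -> ReLU -> conv -> BN, plus an identity shortcut (1x1 static
    conv + BN when the shape changes), ReLU after the addition.
    """

    def __init__(self, c_in: int, c_out: int, stride: int, n: int = 4,
                 gamma: float = 1 / 16, kernel_attention: str = "sigmoid",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if stride not in (1, 2):
            raise ConfigError(f"block stride must be 1 or 2, got {stride}")
        rng = rng or np.random.default_rng()
        kw = dict(n=n, gamma=gamma, kernel_attention=kernel_attention, rng=rng)
        self.conv1 = ODConv2d(c_in, c_out, 3, stride=stride, padding=1, **kw)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = ODConv2d(c_out, c_out, 3, stride=1, padding=1, **kw)
        self.bn2 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.shortcut = Sequential(
                Conv2d(c_in, c_out, 1, stride=stride, rng=rng), BatchNorm2d(c_out)
            )
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        identity = self.shortcut(x) if self.shortcut is not None else x
        return (out + identity).relu()

    def _summary(self, in_shape):
        rows, shape = [], in_shape
        for name in ("conv1", "bn1", "conv2", "bn2"):
            sub, shape = getattr(self, name)._summary(shape)
            rows.extend((name, *r[1:]) for r in sub)
        if self.shortcut is not None:
            sub, _ = self.shortcut._summary(in_shape)
            rows.extend((f"shortcut.{r[0]}", *r[1:]) for r in sub)
        return rows, shape


def build_odconv_resblock(c_in: int, c_out: int, stride: int,
                          cfg: NetConfig | None = None,
                          rng: np.random.Generator | None = None) -> ODConvBasicBlock:
    cfg = cfg or NetConfig()
    return ODConvBasicBlock(c_in, c_out, stride, n=cfg.odconv_n,
                            gamma=cfg.odconv_gamma,
                            kernel_attention=cfg.kernel_attention, rng=rng)


class XODFCANet(Module):
    """The assembled classifier.

    Stem (7x7/2 static conv + BN + ReLU + 3x3/2 max pool), four ODConv
    residual stages, coordinate-attention gates after stages 1-3 (their
    outputs both feed the next stage and are tapped for fusion), global
    average pooling, FCA fusion of the three taps with the final pooled
    vector, and an affine classifier producing logits.
    """

    def __init__(self, cfg: NetConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.stage_widths
        self.stem = Sequential(
            Conv2d(cfg.in_channels, cfg.stem_channels, 7, stride=2, padding=3, rng=rng),
            BatchNorm2d(cfg.stem_channels),
            ReLU(),
            MaxPool2d(3, 2, 1),
        )
        c_prev = cfg.stem_channels
        for s in range(4):
            blocks = []
            for b in range(cfg.blocks_per_stage[s]):
                stride = 2 if (s > 0 and b == 0) else 1
                blocks.append(build_odconv_resblock(c_prev, w[s], stride, cfg, rng))
                c_prev = w[s]
            self.register(f"stage{s + 1}", Sequential(*blocks))
        for s in range(3):
            self.register(f"ca{s + 1}", CoordAtt(w[s], r=cfg.ca_r,
                                                 bn_after_reduce=cfg.ca_bn_after_reduce,
                                                 rng=rng))
        self.pool = GlobalAvgPool()
        d = cfg.classifier_width or w[3]
        self.fca = FeatureCoordAtt(
            [w[0], w[1], w[2], w[3]], d, fusion=cfg.fca_fusion,
            identity=[False, False, False, d == w[3] and cfg.fca_fusion == "sum"],
            rng=rng,
        )
        self.classifier = Linear(self.fca.fused_width, cfg.num_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        t1 = self.ca1(self.stage1(x))
        t2 = self.ca2(self.stage2(t1))
        t3 = self.ca3(self.stage3(t2))
        f4 = self.pool(self.stage4(t3))
        fused = self.fca([t1, t2, t3, f4])
        return self.classifier(fused)

    def _summary(self, in_shape):
        rows, shape = [], in_shape
        for name in ("stem", "stage1", "ca1", "stage2", "ca2", "stage3", "ca3",
                     "stage4", "pool"):
            sub, shape = getattr(self, name)._summary(shape)
            rows.extend((f"{name}.{r[0]}".rstrip("."), *r[1:]) for r in sub)
        sub, shape = self.fca._summary(shape)
        rows.extend(("fca", *r[1:]) for r in sub)
        sub, shape = self.classifier._summary(shape)
        rows.extend(("classifier", *r[1:]) for r in sub)
        return rows, shape


def build_xodfcanet(cfg: NetConfig | None = None) -> XODFCANet:
    return XODFCANet(cfg or NetConfig())


# ----------------------------------------------------------------- baselines
class _BasicBlock(Module):
    expansion = 1

    def __init__(self, c_in, width, stride, rng):
        super().__init__()
        self.conv1 = Conv2d(c_in, width, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = BatchNorm2d(width)
        self.conv2 = Conv2d(width, width, 3, stride=1, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(width)
        c_out = width * self.expansion
        if stride != 1 or c_in != c_out:
            self.shortcut = Sequential(Conv2d(c_in, c_out, 1, stride=stride, rng=rng),
                                       BatchNorm2d(c_out))
        else:
            self.shortcut = None

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        identity = self.shortcut(x) if self.shortcut is not None else x
        return (out + identity).relu()

    def _summary(self, in_shape):
        rows, shape = [], in_shape
        for name in ("conv1", "bn1", "conv2", "bn2"):
            sub, shape = getattr(self, name)._summary(shape)
            rows.extend((name, *r[1:]) for r in sub)
        if self.shortcut is not None:
            sub, _ = self.shortcut._summary(in_shape)
            rows.extend((f"shortcut.{r[0]}", *r[1:]) for r in sub)
        return rows, shape


class _Bottleneck(Module):
    expansion = 4

    def __init__(self, c_in, width, stride, rng):
        super().__init__()
        c_out = width * self.expansion
        self.conv1 = Conv2d(c_in, width, 1, rng=rng)
        self.bn1 = BatchNorm2d(width)
        self.conv2 = Conv2d(width, width, 3, stride=stride, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(width)
        self.conv3 = Conv2d(width, c_out, 1, rng=rng)
        self.bn3 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.shortcut = Sequential(Conv2d(c_in, c_out, 1, stride=stride, rng=rng),
                                       BatchNorm2d(c_out))
        else:
            self.shortcut = None

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        identity = self.shortcut(x) if self.shortcut is not None else x
        return (out + identity).relu()

    def _summary(self, in_shape):
        rows, shape = [], in_shape
        for name in ("conv1", "bn1", "conv2", "bn2", "conv3", "bn3"):
            sub, shape = getattr(self, name)._summary(shape)
            rows.extend((name, *r[1:]) for r in sub)
        if self.shortcut is not None:
            sub, _ = self.shortcut._summary(in_shape)
            rows.extend((f"shortcut.{r[0]}", *r[1:]) for r in sub)
        return rows, shape


class ResNet(Module):
    """Canonical ResNet (conv-stem, four stages, global average pool, fc)."""

    def __init__(self, block, layers, num_classes=3, seed=0):
        super().__init__()
        if num_classes < 2:
            raise ConfigError(f"need at least two classes, got {num_classes}")
        rng = np.random.default_rng(seed)
        self.stem = Sequential(
            Conv2d(3, 64, 7, stride=2, padding=3, rng=rng),
            BatchNorm2d(64),
            ReLU(),
            MaxPool2d(3, 2, 1),
        )
        c_prev = 64
        for s, (width, count) in enumerate(zip((64, 128, 256, 512), layers)):
            blocks = []
            for b in range(count):
                stride = 2 if (s > 0 and b == 0) else 1
                blocks.append(block(c_prev, width, stride, rng))
                c_prev = width * block.expansion
            self.register(f"stage{s + 1}", Sequential(*blocks))
        self.pool = GlobalAvgPool()
        self.fc = Linear(c_prev, num_classes, rng=rng)

    def forward(self, x):
        x = self.stem(x)
        for s in range(4):
            x = getattr(self, f"stage{s + 1}")(x)
        return self.fc(self.pool(x))

    def _summary(self, in_shape):
        rows, shape = [], in_shape
        for name in ("stem", "stage1", "stage2", "stage3", "stage4", "pool", "fc"):
            sub, shape = getattr(self, name)._summary(shape)
            rows.extend((f"{name}.{r[0]}".rstrip("."), *r[1:]) for r in sub)
        return rows, shape


def build_resnet18_baseline(num_classes: int = 3, seed: int = 0) -> ResNet:
    return ResNet(_BasicBlock, (2, 2, 2, 2), num_classes, seed)


def build_resnet50_baseline(num_classes: int = 3, seed: int = 0) -> ResNet:
    return ResNet(_Bottleneck, (3, 4, 6, 3), num_classes, seed)


def build_resnet101_baseline(num_classes: int = 3, seed: int = 0) -> ResNet:
    return ResNet(_Bottleneck, (3, 4, 23, 3), num_classes, seed)


# ---------------------------------------------------------------- accounting
@dataclass
class ModelSummary:
    """Per-layer parameter/MAC breakdown with totals."""

    rows: list[tuple[str, str, int, int, tuple]]
    total_params: int
    total_macs: int
    input_size: tuple[int, int, int]

    def table(self) -> str:
        header = f"{'layer':<38}{'type':<22}{'params':>12}{'MACs':>16}  out"
        lines = [header, "-" * len(header)]
        for name, kind, params, macs, shape in self.rows:
            lines.append(f"{name:<38}{kind:<22}{params:>12,}{macs:>16,}  {shape}")
        lines.append("-" * len(header))
        lines.append(f"{'total':<60}{self.total_params:>12,}{self.total_macs:>16,}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "input_size": list(self.input_size),
            "total_params": self.total_params,
            "total_macs": self.total_macs,
            "layers": [
                {"name": n, "type": t, "params": p, "macs": m, "out_shape": list(s)}
                for n, t, p, m, s in self.rows
            ],
        }


def summarize(model: Module, input_size: tuple[int, int, int] = (3, 224, 224)) -> ModelSummary:
    rows, _ = model._summary(tuple(input_size))
    total_params = sum(r[2] for r in rows)
    total_macs = sum(r[3] for r in rows)
    return ModelSummary(rows, total_params, total_macs, tuple(input_size))


def count_parameters(model: Module) -> int:
    """Number of trainable scalars registered by the model."""
    return model.num_parameters()


def count_macs(model: Module, input_size: tuple[int, int, int] = (3, 224, 224)) -> int:
    """Multiply-accumulate count of one forward pass for a single sample."""
    return summarize(model, input_size).total_macs


def save_checkpoint(model: XODFCANet, path) -> None:
    """Write weights plus the architecture config to an .npz checkpoint."""
    import json

    state = {f"state/{k}": v for k, v in model.state_dict().items()}
    cfg = dict(model.cfg.__dict__)
    cfg["stage_widths"] = list(cfg["stage_widths"])
    cfg["blocks_per_stage"] = list(cfg["blocks_per_stage"])
    np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> XODFCANet:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    import json

    with np.load(path) as data:
        cfg = NetConfig.from_dict(json.loads(bytes(data["__config__"]).decode()))
        model = build_xodfcanet(cfg)
        model.load_state_dict(
            {k[len("state/"):]: data[k] for k in data.files if k.startswith("state/")}
        )
    return model
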