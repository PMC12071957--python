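"""Configuration records for architecture and training.

``ArchConfig`` is the complete architectural hyperparameter record: a network
is a deterministic function of it, so two builds from the same config have
identical layer tables and parameter counts.  Configs round-trip through
YAML/JSON; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates an architectural invariant."""


@dataclass
class ArchConfig:
    """Hyperparameters of the lightweight attention U-Net.

    The default values describe the canonical model: grayscale 256x256 input,
    encoder stage widths 16/32/64/128 with a 128-wide bridge at 1/32
    resolution, complexity-reduction blocks (1x1 reduce -> depthwise 3x3 ->
    1x1 expand -> max-pool) after stages 2 and 4, residual blocks at the two
    deepest encoder stages, spatial attention on the two deepest skip
    connections, and a 1-channel sigmoid head.
    """

    input_size: int = 256
    input_channels: int = 1
    output_channels: int = 1
    base_channels: int = 16
    stage_channels: tuple[int, ...] = (16, 32, 64, 128)
    reduction_factor: int = 2
    reduction_block_stages: tuple[int, ...] = (2, 4)
    residual_stages: tuple[int, ...] = (3, 4)
    attention_sites: tuple[int, ...] = (4, 5)  # skip indices, 1 = shallowest
    convs_per_block: int = 3
    attention_kernel: int = 7
    double_reduction_core: bool = False
    use_depthwise: bool = True
    use_residual: bool = True
    use_attention: bool = True
    use_reduction_blocks: bool = True
    seed: int = 0

    def __post_init__(self):
        self.stage_channels = tuple(self.stage_channels)
        self.reduction_block_stages = tuple(self.reduction_block_stages)
        self.residual_stages = tuple(self.residual_stages)
        self.attention_sites = tuple(self.attention_sites)
        self.validate()

    @property
    def n_downsamplings(self) -> int:
        # one pool per stage transition plus the pool into the bridge
        return len(self.stage_channels) + 1

    def validate(self) -> None:
        div = 2 ** self.n_downsamplings
        if self.input_size % div:
            raise ConfigError(
                f"input_size {self.input_size} not divisible by {div} "
                f"({self.n_downsamplings} downsampling steps)")
        if any(c < 1 for c in (self.input_channels, self.output_channels,
                               self.convs_per_block)):
            raise ConfigError("channel and conv counts must be positive")
        if list(self.stage_channels) != sorted(set(self.stage_channels)):
            raise ConfigError("stage_channels must be strictly increasing")
        if self.reduction_factor < 2:
            raise ConfigError("reduction_factor must be >= 2")
        n2 = self.reduction_factor ** 2
        for s in self.reduction_block_stages:
            ch = self.stage_channels[s - 1]
            if ch % n2:
                raise ConfigError(
                    f"stage {s}: {ch} channels not divisible by n^2 = {n2}")
            if ch // n2 < 1:
                raise ConfigError(f"stage {s}: reduced channel count < 1")
        if self.attention_kernel % 2 == 0:
            raise ConfigError("attention_kernel must be odd")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ArchConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))


#: per-layer closed-form trainable-parameter counts, keyed by LayerSpec.kind
def _conv_params(k: int, cin: int, cout: int) -> int:
    return k * k * cin * cout + cout


@dataclass(frozen=True)
class LayerSpec:
    """One row of a network's layer table.

    ``kind`` names the operator; parameter counts follow the closed forms
    k^2*Cin*Cout + Cout for convolutions, k^2*C + C for depthwise
    convolutions, 2*C for batch normalization, and 0 for pooling, upsampling,
    activations, concatenation and identity addition.
    """

    kind: str
    in_channels: int
    out_channels: int
    spatial_in: int
    spatial_out: int
    kernel: int = 0

    def param_count(self) -> int:
        k = self.kind
        if k in ("conv3x3",):
            return _conv_params(3, self.in_channels, self.out_channels)
        if k in ("conv1x1", "conv1x1_reduce", "conv1x1_expand"):
            return _conv_params(1, self.in_channels, self.out_channels)
        if k == "depthwise3x3":
            return 9 * self.in_channels + self.in_channels
        if k == "conv_transpose2x2":
            return 4 * self.in_channels * self.out_channels + self.out_channels
        if k == "batchnorm":
            return 2 * self.in_channels
        if k.startswith("attention"):
            return self.kernel * self.kernel * 2 + 1
        if k in ("maxpool2x2", "upsample2x", "add_identity", "concat_skip",
                 "sigmoid_head", "relu"):
            return 0
        raise ValueError(f"unknown layer kind {k!r}")


def table_parameter_count(table: list[LayerSpec]) -> int:
    """Closed-form trainable-parameter total of a layer table."""
    return sum(spec.param_count() for spec in table)


@dataclass
class TrainConfig:
    """Training hyperparameters for the hybrid-loss optimizer loop."""

    arch: ArchConfig = field(default_factory=ArchConfig)
    alpha: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 50
    seed: int = 0
    augment: bool = True
    checkpoint_path: str | None = None
    patience: int = 20

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError("alpha must lie in [0, 1]")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
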