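"""Lightweight attention U-Net builder and its ablation variants.

The encoder follows a five-downsampling schedule (256 -> 128 -> 64 -> 32 ->
16 -> 8 at the default input size) with stage widths 16/32/64/128 and a
128-wide bridge.  Two of the five downsamplings are supplied by
complexity-reduction blocks — a ShuffleNet-inspired 1x1 reduce / depthwise
3x3 / 1x1 expand bottleneck ending in a 2x2 max-pool — placed after stages 2
and 4.  Residual blocks with batch normalization sit at the two deepest
encoder stages, and the two deepest skip connections pass through a
channel-pooled spatial-attention gate before concatenation.  The decoder
uses parameter-free nearest upsampling and three 3x3 convolutions per block;
the head is a 1x1 convolution with a sigmoid.

Every builder returns both the runtime network and a ``LayerSpec`` table, a
pure function of the configuration, whose closed-form parameter sum must
equal the engine's count exactly (tested).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine
from .config import ArchConfig, ConfigError, LayerSpec, table_parameter_count

VARIANTS = ("full", "no_depthwise", "no_residual", "no_attention",
            "no_reduction", "baseline_unet")


@dataclass
class NetworkHandle:
    """A built network plus its provenance: config, variant, layer table."""

    net: engine.Module
    config: ArchConfig
    layer_table: list[LayerSpec] = field(default_factory=list)
    variant: str = "full"

    def n_parameters(self) -> int:
        return self.net.n_parameters()


def _specs(*rows) -> list[LayerSpec]:
    return list(rows)


def make_conv_block(in_channels: int, out_channels: int, n_convs: int,
                    rng: np.random.Generator | None = None, spatial: int = 0,
                    dtype=np.float32) -> tuple[engine.Module, list[LayerSpec]]:
    """``n_convs`` same-padding 3x3 conv + ReLU layers; first widens in -> out."""
    if in_channels < 1 or out_channels < 1 or n_convs < 1:
        raise ConfigError("conv block needs positive channel and conv counts")
    rng = rng if rng is not None else np.random.default_rng(0)
    layers: list[engine.Module] = []
    table: list[LayerSpec] = []
    cin = in_channels
    for _ in range(n_convs):
        layers += [engine.Conv2d(cin, out_channels, 3, rng, dtype=dtype), engine.ReLU()]
        table += _specs(
            LayerSpec("conv3x3", cin, out_channels, spatial, spatial, 3),
            LayerSpec("relu", out_channels, out_channels, spatial, spatial))
        cin = out_channels
    return engine.Sequential(*layers), table


def make_reduction_block(channels: int, n: int, use_depthwise: bool = True,
                         rng: np.random.Generator | None = None, spatial: int = 0,
                         double_core: bool = False,
                         dtype=np.float32) -> tuple[engine.Module, list[LayerSpec]]:
    """Complexity-reduction block: 1x1 reduce x2 -> (depthwise) 3x3 -> 1x1 expand x2
    -> ReLU -> 2x2 max-pool.  Channel count is preserved; spatial dims halve."""
    if n < 2:
        raise ConfigError("reduction factor must be >= 2")
    if channels % (n * n):
        raise ConfigError(f"{channels} channels not divisible by n^2 = {n * n}")
    rng = rng if rng is not None else np.random.default_rng(0)
    mid, low = channels // n, channels // (n * n)
    layers: list[engine.Module] = []
    table: list[LayerSpec] = []
    for _ in range(2 if double_core else 1):
        layers += [
            engine.Conv2d(channels, mid, 1, rng, dtype=dtype),
            engine.Conv2d(mid, low, 1, rng, dtype=dtype),
        ]
        table += _specs(
            LayerSpec("conv1x1_reduce", channels, mid, spatial, spatial, 1),
            LayerSpec("conv1x1_reduce", mid, low, spatial, spatial, 1))
        if use_depthwise:
            layers.append(engine.DepthwiseConv2d(low, 3, rng, dtype=dtype))
            table.append(LayerSpec("depthwise3x3", low, low, spatial, spatial, 3))
        else:
            layers.append(engine.Conv2d(low, low, 3, rng, dtype=dtype))
            table.append(LayerSpec("conv3x3", low, low, spatial, spatial, 3))
        layers += [
            engine.Conv2d(low, mid, 1, rng, dtype=dtype),
            engine.Conv2d(mid, channels, 1, rng, dtype=dtype),
            engine.ReLU(),
        ]
        table += _specs(
            LayerSpec("conv1x1_expand", low, mid, spatial, spatial, 1),
            LayerSpec("conv1x1_expand", mid, channels, spatial, spatial, 1),
            LayerSpec("relu", channels, channels, spatial, spatial))
    layers.append(engine.MaxPool2x2())
    table.append(LayerSpec("maxpool2x2", channels, channels, spatial, spatial // 2))
    return engine.Sequential(*layers), table


def make_residual_block(channels: int, rng: np.random.Generator | None = None,
                        spatial: int = 0,
                        dtype=np.float32) -> tuple[engine.Module, list[LayerSpec]]:
    """Identity-shortcut block: two (3x3 conv -> BN -> ReLU) layers, input added
    to the body output.  Zeroed conv weights make it the identity map."""
    if channels < 1:
        raise ConfigError("residual block needs a positive channel count")
    rng = rng if rng is not None else np.random.default_rng(0)
    body = engine.Sequential(
        engine.Conv2d(channels, channels, 3, rng, dtype=dtype),
        engine.BatchNorm2d(channels, dtype=dtype),
        engine.ReLU(),
        engine.Conv2d(channels, channels, 3, rng, dtype=dtype),
        engine.BatchNorm2d(channels, dtype=dtype),
        engine.ReLU(),
    )
    table = _specs(
        LayerSpec("conv3x3", channels, channels, spatial, spatial, 3),
        LayerSpec("batchnorm", channels, channels, spatial, spatial),
        LayerSpec("relu", channels, channels, spatial, spatial),
        LayerSpec("conv3x3", channels, channels, spatial, spatial, 3),
        LayerSpec("batchnorm", channels, channels, spatial, spatial),
        LayerSpec("relu", channels, channels, spatial, spatial),
        LayerSpec("add_identity", channels, channels, spatial, spatial))
    return engine.Residual(body), table


def make_spatial_attention(kernel: int = 7, rng: np.random.Generator | None = None,
                           spatial: int = 0,
                           dtype=np.float32) -> tuple[engine.Module, list[LayerSpec]]:
    """Channel-pooled spatial attention gate (k*k*2 + 1 parameters)."""
    if kernel % 2 == 0:
        raise ConfigError("attention kernel must be odd")
    rng = rng if rng is not None else np.random.default_rng(0)
    mod = engine.SpatialAttention(kernel, rng, dtype=dtype)
    table = _specs(LayerSpec(f"attention{kernel}x{kernel}", 2, 1, spatial, spatial, kernel))
    return mod, table


class UNet(engine.Module):
    """Encoder-decoder network assembled from explicit block lists.

    ``downs[i]`` downsamples the output of ``stage_blocks[i]``; the stage
    outputs (plus, when ``extra_pool`` is set, the tensor entering it) are the
    skip connections, optionally gated by ``attentions``.  Decoder block ``j``
    upsamples, concatenates skip ``n_skips - j`` and applies a conv stack.
    """

    def __init__(self, stage_blocks, downs, attentions, extra_pool, bridge,
                 ups, dec_blocks, head_conv):
        self.stage_blocks = stage_blocks
        self.downs = downs
        self.attentions = attentions          # per-skip list, None = no gate
        self.extra_pool = extra_pool          # Module or None
        self.bridge = bridge
        self.ups = ups
        self.dec_blocks = dec_blocks
        self.head_conv = head_conv
        self.head_act = engine.Sigmoid()
        self._skip_channels: list[int] = []

    def forward(self, x, training=False):
        skips = []
        for block, down in zip(self.stage_blocks, self.downs):
            x = block.forward(x, training=training)
            skips.append(x)
            x = down.forward(x, training=training)
        if self.extra_pool is not None:
            skips.append(x)
            x = self.extra_pool.forward(x, training=training)
        x = self.bridge.forward(x, training=training)
        self._skip_channels = [s.shape[1] for s in skips]
        for j, (up, block) in enumerate(zip(self.ups, self.dec_blocks)):
            x = up.forward(x, training=training)
            skip = skips[-1 - j]
            att = self.attentions[-1 - j]
            if att is not None:
                skip = att.forward(skip, training=training)
            x = np.concatenate([skip, x], axis=1)
            x = block.forward(x, training=training)
        x = self.head_conv.forward(x, training=training)
        return self.head_act.forward(x, training=training)

    def backward(self, grad):
        grad = self.head_act.backward(grad)
        grad = self.head_conv.backward(grad)
        skip_grads: list = [None] * len(self._skip_channels)
        for j in range(len(self.dec_blocks) - 1, -1, -1):
            grad = self.dec_blocks[j].backward(grad)
            c_skip = self._skip_channels[-1 - j]
            g_skip, grad = grad[:, :c_skip], grad[:, c_skip:]
            att = self.attentions[-1 - j]
            if att is not None:
                g_skip = att.backward(g_skip)
            skip_grads[-1 - j] = g_skip
            grad = self.ups[j].backward(grad)
        grad = self.bridge.backward(grad)
        if self.extra_pool is not None:
            grad = self.extra_pool.backward(grad)
            grad = grad + skip_grads.pop()
        for i in range(len(self.stage_blocks) - 1, -1, -1):
            grad = self.downs[i].backward(grad)
            grad = grad + skip_grads[i]
            grad = self.stage_blocks[i].backward(grad)
        return grad


def _reduction_stage_replacement(channels: int, n_convs: int, rng, spatial, dtype):
    """Standard conv3x3 (+ReLU) stack at full width followed by a 2x2 pool,
    used when a reduction stage is ablated."""
    layers, table = [], []
    for _ in range(n_convs):
        layers += [engine.Conv2d(channels, channels, 3, rng, dtype=dtype), engine.ReLU()]
        table += _specs(LayerSpec("conv3x3", channels, channels, spatial, spatial, 3),
                        LayerSpec("relu", channels, channels, spatial, spatial))
    layers.append(engine.MaxPool2x2())
    table.append(LayerSpec("maxpool2x2", channels, channels, spatial, spatial // 2))
    return engine.Sequential(*layers), table


def assemble_model(config: ArchConfig, dtype=np.float32,
                   reduction_mode: str = "auto") -> NetworkHandle:
    """Build the canonical network (or an ablated form of it) from a config.

    ``reduction_mode`` controls the downsampler at reduction stages:
    ``"auto"`` honours the config flags, ``"plain_conv"`` substitutes one
    channel-preserving 3x3 conv + pool, and ``"standard_stage"`` substitutes a
    classic two-conv + pool stage at full width.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    size = config.input_size
    table: list[LayerSpec] = []

    stage_blocks, downs = [], []
    cin = config.input_channels
    spatial = size
    stage_out_spatial: list[int] = []
    for i, ch in enumerate(config.stage_channels, start=1):
        block_mods: list[engine.Module] = []
        block, t = make_conv_block(cin, ch, config.convs_per_block, rng, spatial, dtype)
        block_mods.append(block)
        table += t
        if config.use_residual and i in config.residual_stages:
            res, t = make_residual_block(ch, rng, spatial, dtype)
            block_mods.append(res)
            table += t
        stage_blocks.append(engine.Sequential(*block_mods))
        stage_out_spatial.append(spatial)
        if i in config.reduction_block_stages:
            if reduction_mode == "plain_conv" or not config.use_reduction_blocks:
                down, t = _reduction_stage_replacement(ch, 1, rng, spatial, dtype)
            elif reduction_mode == "standard_stage":
                down, t = _reduction_stage_replacement(ch, 2, rng, spatial, dtype)
            else:
                down, t = make_reduction_block(
                    ch, config.reduction_factor, config.use_depthwise, rng, spatial,
                    double_core=config.double_reduction_core, dtype=dtype)
        else:
            down = engine.MaxPool2x2()
            t = _specs(LayerSpec("maxpool2x2", ch, ch, spatial, spatial // 2))
        downs.append(down)
        table += t
        spatial //= 2
        cin = ch

    # deepest skip is taken after the final reduction stage, before the last pool
    stage_out_spatial.append(spatial)
    extra_pool = engine.MaxPool2x2()
    table.append(LayerSpec("maxpool2x2", cin, cin, spatial, spatial // 2))
    spatial //= 2

    bridge_ch = config.stage_channels[-1]
    bridge, t = make_conv_block(cin, bridge_ch, config.convs_per_block, rng, spatial, dtype)
    table += t

    n_skips = len(config.stage_channels) + 1
    skip_channels = list(config.stage_channels) + [config.stage_channels[-1]]
    attentions: list[engine.Module | None] = [None] * n_skips
    if config.use_attention:
        for site in config.attention_sites:
            att, t = make_spatial_attention(
                config.attention_kernel, rng, stage_out_spatial[site - 1], dtype)
            attentions[site - 1] = att
            table += t

    dec_widths = list(config.stage_channels[::-1]) + [config.stage_channels[0]]
    ups, dec_blocks = [], []
    cin = bridge_ch
    for j, width in enumerate(dec_widths):
        ups.append(engine.Upsample2x())
        spatial *= 2
        table.append(LayerSpec("upsample2x", cin, cin, spatial // 2, spatial))
        skip_ch = skip_channels[n_skips - 1 - j]
        table.append(LayerSpec("concat_skip", skip_ch + cin, skip_ch + cin, spatial, spatial))
        block, t = make_conv_block(skip_ch + cin, width, config.convs_per_block,
                                   rng, spatial, dtype)
        dec_blocks.append(block)
        table += t
        cin = width

    head = engine.Conv2d(cin, config.output_channels, 1, rng, dtype=dtype)
    table += _specs(
        LayerSpec("conv1x1", cin, config.output_channels, spatial, spatial, 1),
        LayerSpec("sigmoid_head", config.output_channels, config.output_channels,
                  spatial, spatial))

    net = UNet(stage_blocks, downs, attentions, extra_pool, bridge, ups, dec_blocks, head)
    return NetworkHandle(net=net, config=config, layer_table=table, variant="full")


def assemble_baseline_unet(config: ArchConfig | None = None,
                           dtype=np.float32) -> NetworkHandle:
    """Classic four-level U-Net: widths 32/64/128/256, 512-wide bridge, two
    3x3 conv+ReLU per block, 2x2 transposed-conv upsampling."""
    config = config or ArchConfig()
    rng = np.random.default_rng(config.seed)
    widths = (32, 64, 128, 256)
    bridge_ch = 512
    size = config.input_size
    if size % 2 ** len(widths):
        raise ConfigError(f"input size {size} not divisible by {2 ** len(widths)}")
    table: list[LayerSpec] = []

    stage_blocks, downs = [], []
    cin = config.input_channels
    spatial = size
    for ch in widths:
        block, t = make_conv_block(cin, ch, 2, rng, spatial, dtype)
        stage_blocks.append(block)
        table += t
        downs.append(engine.MaxPool2x2())
        table.append(LayerSpec("maxpool2x2", ch, ch, spatial, spatial // 2))
        spatial //= 2
        cin = ch

    bridge, t = make_conv_block(cin, bridge_ch, 2, rng, spatial, dtype)
    table += t

    ups, dec_blocks = [], []
    cin = bridge_ch
    for ch in widths[::-1]:
        ups.append(engine.ConvTranspose2x2(cin, ch, rng, dtype=dtype))
        spatial *= 2
        table.append(LayerSpec("conv_transpose2x2", cin, ch, spatial // 2, spatial, 2))
        table.append(LayerSpec("concat_skip", 2 * ch, 2 * ch, spatial, spatial))
        block, t = make_conv_block(2 * ch, ch, 2, rng, spatial, dtype)
        dec_blocks.append(block)
        table += t
        cin = ch

    head = engine.Conv2d(cin, config.output_channels, 1, rng, dtype=dtype)
    table += _specs(
        LayerSpec("conv1x1", cin, config.output_channels, spatial, spatial, 1),
        LayerSpec("sigmoid_head", config.output_channels, config.output_channels,
                  spatial, spatial))

    net = UNet(stage_blocks, downs, [None] * len(widths), None, bridge, ups,
               dec_blocks, head)
    return NetworkHandle(net=net, config=config, layer_table=table,
                         variant="baseline_unet")


def assemble_variant(config: ArchConfig, variant: str,
                     dtype=np.float32) -> NetworkHandle:
    """Build one of the ablation variants of the architecture.

    ``no_depthwise`` reverts each complexity-reduction stage to a classic
    two-standard-conv downsampling stage at full channel width — the
    counterfactual network one would build without the depthwise-separable
    bottleneck trick (a per-layer swap of only the bottleneck's depthwise
    conv is available via ``ArchConfig.use_depthwise = False``).
    """
    if variant not in VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; valid names: {', '.join(VARIANTS)}")
    if variant == "baseline_unet":
        return assemble_baseline_unet(config, dtype=dtype)
    import dataclasses as _dc
    if variant == "no_residual":
        config = _dc.replace(config, use_residual=False)
    elif variant == "no_attention":
        config = _dc.replace(config, use_attention=False)
    mode = {"no_reduction": "plain_conv", "no_depthwise": "standard_stage"}.get(
        variant, "auto")
    handle = assemble_model(config, dtype=dtype, reduction_mode=mode)
    handle.variant = variant
    return handle


def count_parameters(handle: NetworkHandle) -> int:
    """Exact count of trainable scalars in the built network."""
    return handle.net.n_parameters()


def layer_table_count(handle: NetworkHandle) -> int:
    """Closed-form parameter total from the layer table (must equal
    :func:`count_parameters` exactly)."""
    return table_parameter_count(handle.layer_table)


def forward(handle: NetworkHandle, batch: np.ndarray) -> np.ndarray:
    """Run inference; returns per-pixel foreground probabilities.

    Accepts ``(B, H, W)``, ``(B, H, W, 1)`` or ``(B, 1, H, W)`` batches and
    returns channels-last ``(B, H, W, C_out)`` probability maps.
    """
    x = np.asarray(batch)
    if x.ndim == 3:
        x = x[:, None]
    elif x.ndim == 4 and x.shape[-1] in (1, 3) and x.shape[1] not in (1, 3):
        x = x.transpose(0, 3, 1, 2)
    elif x.ndim != 4:
        raise ValueError(f"expected a batch of 2D images, got shape {batch.shape}")
    div = 2 ** handle.config.n_downsamplings if handle.variant != "baseline_unet" else 16
    h, w = x.shape[2], x.shape[3]
    if h % div or w % div:
        raise ValueError(
            f"spatial dims {h}x{w} must be divisible by {div} for this network")
    dtype = handle.net.params()[0].data.dtype
    y = handle.net.forward(x.astype(dtype), training=False)
    return y.transpose(0, 2, 3, 1)
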