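"""Two-phase encoder-decoder segmentation network with skip concatenations.

Feature-representation phase: two parallel modality branches (5x5 conv +
ReLU on CT and PET separately) fused by concatenation, then five
downsampling blocks (conv + ReLU + 2x2/stride-2 max pool; 5x5 kernels on the
first, 3x3 on the rest) with an extra 3x3 conv + ReLU interleaved after
blocks 2-5, reducing an S x S input to
(S/32) x (S/32); a convolution whose kernel spans the whole remaining map
("fully-connected-like") produces a 1x1 scores vector, refined by two 1x1
convolutions.

Scores-map reconstruction phase: five upsampling blocks, each a transposed
convolution (the first maps 1x1 -> (S/16) x (S/16) with kernel = stride =
S/16; the rest double the resolution with kernel = stride = 2), a
concatenation with the last same-resolution encoder feature map (U-style
skip), and a 1x1 conv + ReLU; a final 1x1 conv + ReLU emits the
single-channel non-negative scores map.

Progressive training attaches an output head after the third upsampling
block (stage 1, output S/4), the fourth (stage 2, output S/2), or the full
decoder (stage 3, output S).  Training minimises the Euclidean loss
sum((score - gold)^2) / (2 * batch).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .layers import Conv2D, Deconv, FullConv, MaxPool2
from .preprocess import SamplePair

__all__ = [
    "NetworkConfig",
    "ScoresMap",
    "Network",
    "build_network",
    "forward",
    "euclidean_loss",
    "euclidean_loss_grad",
    "arch_trace",
    "save_checkpoint",
    "load_checkpoint",
]

_BASE_CHANNELS = (32, 64, 128, 256, 512)
_BASE_BOTTLENECK = 512
_LATE_STAGE_INIT_SCALE = 1.0
_HEAD_BIAS_INIT = 0.1
_HEAD_TARGET_STD = 0.05


@dataclass
class NetworkConfig:
    """Architecture description.

    ``input_size`` S must be divisible by 32 (five halvings reach S/32 and
    the full-image bottleneck convolution must see a well-defined map).
    ``width_multiplier`` scales every channel count; ``stage`` selects which
    training head is attached (1: output S/4, 2: S/2, 3: S).
    """

    input_size: int = 512
    width_multiplier: float = 1.0
    channels_per_block: tuple[int, ...] = ()
    first_conv_kernel: int = 5
    inner_conv_kernel: int = 3
    bottleneck_fc_channels: int = 0
    stage: int = 3
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.input_size % 32 != 0 or self.input_size <= 0:
            raise ValueError(
                f"input_size must be a positive multiple of 32, "
                f"got {self.input_size}")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if not self.channels_per_block:
            self.channels_per_block = tuple(
                max(1, round(c * self.width_multiplier))
                for c in _BASE_CHANNELS)
        if len(self.channels_per_block) != 5 or min(
                self.channels_per_block) < 1:
            raise ValueError("channels_per_block must be 5 counts >= 1")
        if self.bottleneck_fc_channels <= 0:
            self.bottleneck_fc_channels = max(
                1, round(_BASE_BOTTLENECK * self.width_multiplier))
        if self.stage not in (1, 2, 3):
            raise ValueError("stage must be 1, 2 or 3")
        if self.first_conv_kernel % 2 != 1 or self.inner_conv_kernel % 2 != 1:
            raise ValueError("conv kernels must be odd")

    @property
    def output_size(self) -> int:
        return self.input_size // {1: 4, 2: 2, 3: 1}[self.stage]

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclass
class ScoresMap:
    """Dense non-negative per-pixel score image at the stage's output size."""

    values: np.ndarray
    stage: int = 3

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("scores map must be 2-D")
        if self.values.min() < 0:
            raise ValueError("scores map must be non-negative")


class Network:
    """The assembled layer graph with explicit forward/backward wiring.

    All three stage heads exist from construction (built from one seeded
    generator), so moving between training stages changes only which head is
    evaluated; shared weights carry over bit-exactly.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        dt = config.np_dtype
        c = config.channels_per_block
        S = config.input_size
        fc = config.bottleneck_fc_channels
        k1, k2 = config.first_conv_kernel, config.inner_conv_kernel

        half = c[0] // 2
        self.branch_ct = Conv2D(1, half, k1, rng, dt, name="branch_ct")
        self.branch_pet = Conv2D(1, c[0] - half, k1, rng, dt,
                                 name="branch_pet")
        self.pools = [MaxPool2() for _ in range(5)]
        self.enc_conv = []
        self.enc_extra = []
        for i in range(1, 5):
            self.enc_conv.append(Conv2D(c[i - 1], c[i], k2, rng, dt,
                                        name=f"enc_conv{i + 1}"))
            self.enc_extra.append(Conv2D(c[i], c[i], k2, rng, dt,
                                         name=f"enc_extra{i + 1}"))
        m = S // 32
        self.bottleneck = FullConv(m, m, c[4], fc, rng, dt, name="bottleneck")
        self.fc1 = Conv2D(fc, fc, 1, rng, dt, name="fc1")
        self.fc2 = Conv2D(fc, fc, 1, rng, dt, name="fc2")

        # decoder: deconv -> concat(skip) -> 1x1 conv + ReLU.  Upsampling
        # blocks 4-5 and the later heads are first exercised by training
        # stages 2-3; they start at reduced weight scale so each stage
        # transition begins near the previous stage's learned function
        # instead of swamping the pretrained trunk with fresh-layer error.
        skip_ch = [c[4], c[3], c[2], c[1], c[0]]
        out_ch = [c[4], c[3], c[2], c[1], c[0]]
        self.deconvs = []
        self.up_convs = []
        cin = fc
        for i in range(5):
            r = S // 16 if i == 0 else 2
            scale = 1.0 if i < 3 else _LATE_STAGE_INIT_SCALE
            self.deconvs.append(Deconv(cin, out_ch[i], r, rng, dt,
                                       name=f"deconv{i + 1}",
                                       weight_scale=scale))
            self.up_convs.append(Conv2D(out_ch[i] + skip_ch[i], out_ch[i], 1,
                                        rng, dt, name=f"up_conv{i + 1}",
                                        weight_scale=scale))
            cin = out_ch[i]
        # head biases start positive so the rectified scores map begins
        # active everywhere; an all-negative pre-activation under the final
        # ReLU would zero the mask and freeze training permanently
        self.head1 = Conv2D(out_ch[2], 1, 1, rng, dt, name="head1",
                            bias_init=_HEAD_BIAS_INIT)
        self.head2 = Conv2D(out_ch[3], 1, 1, rng, dt, name="head2",
                            weight_scale=_LATE_STAGE_INIT_SCALE,
                            bias_init=_HEAD_BIAS_INIT)
        self.head3 = Conv2D(out_ch[4], 1, 1, rng, dt, name="head3",
                            weight_scale=_LATE_STAGE_INIT_SCALE,
                            bias_init=_HEAD_BIAS_INIT)

    # ------------------------------------------------------------------
    @property
    def stage(self) -> int:
        return self.config.stage

    def set_stage(self, stage: int) -> None:
        if stage not in (1, 2, 3):
            raise ValueError("stage must be 1, 2 or 3")
        self.config.stage = stage

    def calibrate_head(self, x: np.ndarray,
                       target_std: float = _HEAD_TARGET_STD) -> None:
        """Data-dependent init of the active stage's output head.

        Rescales the head's weights so its pre-activation has a small fixed
        standard deviation on the probe batch and resets the bias to the
        positive default.  Internal activation scales drift freely during
        earlier training stages (there is no normalisation anywhere in the
        network), so a static weight scale can make a freshly attached
        head's initial output arbitrarily large (swamping the pretrained
        trunk with error) or arbitrarily small (starving the gradient);
        calibrating on data pins the starting point either way.  Intended
        for a head that has not been trained at its stage yet.
        """
        head = {1: self.head1, 2: self.head2, 3: self.head3}[self.stage]
        self.forward_batch(x)
        pre = head._col @ head.params["W"].reshape(head.cin, head.cout)
        std = float(pre.std())
        if std > 0:
            head.params["W"] = head.params["W"] * (target_std / std)
        head.params["b"][:] = _HEAD_BIAS_INIT

    def stage_new_layers(self, stage: int) -> list:
        """Layers first exercised by the given training stage.

        Stage transitions warm these up with the shared trunk frozen before
        joint fine-tuning; for stage 1 the whole network is new.
        """
        if stage == 2:
            return [self.deconvs[3], self.up_convs[3], self.head2]
        if stage == 3:
            return [self.deconvs[4], self.up_convs[4], self.head3]
        return list(self.layers())

    def layers(self):
        yield self.branch_ct
        yield self.branch_pet
        for conv, extra in zip(self.enc_conv, self.enc_extra):
            yield conv
            yield extra
        yield self.bottleneck
        yield self.fc1
        yield self.fc2
        yield from self.deconvs
        yield from self.up_convs
        yield self.head1
        yield self.head2
        yield self.head3

    def _check_input(self, x: np.ndarray) -> None:
        S = self.config.input_size
        if x.ndim != 4 or x.shape[1:] != (S, S, 2):
            raise ValueError(f"expected input of shape (N, {S}, {S}, 2), "
                             f"received {x.shape}")

    def forward_batch(self, x: np.ndarray) -> np.ndarray:
        """Run a (N, S, S, 2) batch to the active stage's (N, H, W) scores."""
        self._check_input(x)
        x = x.astype(self.config.np_dtype, copy=False)
        ct = self.branch_ct.forward(x[..., :1])
        pet = self.branch_pet.forward(x[..., 1:])
        e1 = np.concatenate([ct, pet], axis=-1)
        skips = [e1]
        h = self.pools[0].forward(e1)
        for i in range(4):
            h = self.enc_conv[i].forward(h)
            h = self.enc_extra[i].forward(h)
            skips.append(h)
            h = self.pools[i + 1].forward(h)
        h = self.bottleneck.forward(h)
        h = self.fc1.forward(h)
        h = self.fc2.forward(h)
        n_up = {1: 3, 2: 4, 3: 5}[self.stage]
        self._n_up = n_up
        for i in range(n_up):
            h = self.deconvs[i].forward(h)
            skip = skips[4 - i]
            self._split = skip.shape[-1]
            h = np.concatenate([h, skip], axis=-1)
            h = self.up_convs[i].forward(h)
        head = {1: self.head1, 2: self.head2, 3: self.head3}[self.stage]
        out = head.forward(h)
        return out[..., 0]

    def backward_batch(self, dscores: np.ndarray) -> None:
        """Backpropagate loss gradients, accumulating parameter grads."""
        head = {1: self.head1, 2: self.head2, 3: self.head3}[self.stage]
        dh = head.backward(dscores[..., None])
        dskips = [None] * 5
        for i in range(self._n_up - 1, -1, -1):
            d = self.up_convs[i].backward(dh)
            ch = self.deconvs[i].cout
            dh, dskip = d[..., :ch], d[..., ch:]
            dskips[4 - i] = dskip
            dh = self.deconvs[i].backward(dh)
        dh = self.fc2.backward(dh)
        dh = self.fc1.backward(dh)
        dh = self.bottleneck.backward(dh)
        for i in range(3, -1, -1):
            dh = self.pools[i + 1].backward(dh)
            if dskips[i + 1] is not None:
                dh = dh + dskips[i + 1]
            dh = self.enc_extra[i].backward(dh)
            dh = self.enc_conv[i].backward(dh)
        dh = self.pools[0].backward(dh)
        if dskips[0] is not None:
            dh = dh + dskips[0]
        half = self.branch_ct.cout
        self.branch_ct.backward(dh[..., :half], need_dx=False)
        self.branch_pet.backward(dh[..., half:], need_dx=False)

    # ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for idx, layer in enumerate(self.layers()):
            for pname, arr in layer.params.items():
                state[f"{idx:02d}.{layer.name or type(layer).__name__}"
                      f".{pname}"] = arr
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"checkpoint/config mismatch; differing keys "
                             f"{sorted(missing)[:4]}")
        for idx, layer in enumerate(self.layers()):
            for pname in layer.params:
                key = (f"{idx:02d}.{layer.name or type(layer).__name__}"
                       f".{pname}")
                if layer.params[pname].shape != state[key].shape:
                    raise ValueError(f"checkpoint/config mismatch at {key}")
                layer.params[pname] = state[key].astype(
                    self.config.np_dtype).copy()


def build_network(config: NetworkConfig) -> Network:
    """Construct the network with seeded He-uniform weight initialisation."""
    return Network(config)


def forward(network: Network, sample: SamplePair) -> ScoresMap:
    """Run one sample through the network; deterministic given the weights."""
    S = network.config.input_size
    if sample.ct_slice.shape != (S, S):
        raise ValueError(f"expected {S}x{S} sample slices, received "
                         f"{sample.ct_slice.shape}")
    x = np.stack([sample.ct_slice, sample.pet_slice], axis=-1)[None]
    scores = network.forward_batch(x)[0]
    return ScoresMap(values=scores, stage=network.stage)


def euclidean_loss(scores, gold) -> float:
    """Euclidean loss: sum of squared pixel differences over 2 * batch size.

    Accepts (H, W) pairs (batch of one) or (N, H, W) batches.  Zero iff the
    scores equal the gold map exactly.
    """
    s = np.asarray(scores.values if isinstance(scores, ScoresMap) else scores,
                   dtype=np.float64)
    g = np.asarray(gold, dtype=np.float64)
    if s.shape != g.shape:
        raise ValueError(f"shape mismatch: scores {s.shape} vs gold {g.shape}")
    batch = 1 if s.ndim == 2 else s.shape[0]
    diff = s - g
    return float((diff * diff).sum() / (2.0 * batch))


def euclidean_loss_grad(scores: np.ndarray, gold: np.ndarray):
    """Loss and its gradient with respect to the scores, for training."""
    if scores.shape != gold.shape:
        raise ValueError(f"shape mismatch: scores {scores.shape} vs "
                         f"gold {gold.shape}")
    batch = 1 if scores.ndim == 2 else scores.shape[0]
    diff = (scores - gold).astype(scores.dtype)
    loss = float((diff.astype(np.float64) ** 2).sum() / (2.0 * batch))
    return loss, diff / batch


def arch_trace(config: NetworkConfig) -> list[tuple[str, int, int]]:
    """Spatial/channel schedule of the layer graph, for audit and summaries.

    Returns (layer name, spatial size, channels) in forward order for the
    active stage, computed from the configuration alone.
    """
    S = config.input_size
    c = config.channels_per_block
    fc = config.bottleneck_fc_channels
    trace = [("input", S, 2), ("branch_concat", S, c[0])]
    size = S
    for i in range(1, 6):
        size //= 2
        trace.append((f"pool{i}", size, c[i - 1]))
        if i < 5:
            trace.append((f"enc_conv{i + 1}", size, c[i]))
            trace.append((f"enc_extra{i + 1}", size, c[i]))
    trace.append(("bottleneck", 1, fc))
    trace.append(("fc1", 1, fc))
    trace.append(("fc2", 1, fc))
    out_ch = [c[4], c[3], c[2], c[1], c[0]]
    size = 1
    n_up = {1: 3, 2: 4, 3: 5}[config.stage]
    for i in range(n_up):
        size = S // 16 if i == 0 else size * 2
        trace.append((f"deconv{i + 1}", size, out_ch[i]))
        trace.append((f"up_conv{i + 1}", size, out_ch[i]))
    trace.append((f"head{config.stage}", size, 1))
    return trace


def save_checkpoint(network: Network, path: str | Path) -> Path:
    """Serialise weights plus the embedded config to a single .npz file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = dict(vars(network.config))
    cfg["channels_per_block"] = list(cfg["channels_per_block"])
    np.savez(path, __config__=json.dumps(cfg), **network.state_dict())
    return path


def load_checkpoint(path: str | Path) -> Network:
    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["__config__"]))
        cfg["channels_per_block"] = tuple(cfg["channels_per_block"])
        net = Network(NetworkConfig(**cfg))
        net.load_state_dict({k: data[k] for k in data.files
                             if k != "__config__"})
    return net
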