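"""3D U-Net backbone with hybrid padding and exact shape bookkeeping.

The network is a standard encoder/decoder U-Net (two 3x3x3 convolutions
+ ReLU per resolution level, 2x2x2 max-pooling / learned up-convolution,
channel doubling/halving, skip connections, final 1x1x1 convolution +
sigmoid) with one twist that keeps the memory footprint low: the first
``n_valid_levels`` resolution levels use *valid* (non-padded)
convolutions, which progressively trim the outermost voxels of the
feature maps, while the deeper levels use zero-padding. Valid levels
are applied symmetrically in the encoder and the decoder, so the skip
connections crop the encoder maps centrally by an exact integer margin.

Because valid convolutions shrink the feature maps, not every input
size is usable: every pre-pooling size must divide by the pool factor
and every skip-crop margin must split evenly. ``compute_shape_table``
propagates sizes symbolically (no tensors allocated) and is the single
source of truth for admissibility; the realized forward pass is tested
to match it exactly.

The reference configuration is 5 levels, 16 first-level feature
channels, 3 valid levels, input 252^3 (which the shape table verifies
admissible, with output 196^3). No dropout and no batch normalization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .nn import Conv3d, MaxPool3d, Parameter, ReLU, Sigmoid, UpConv3d

__all__ = [
    "UNetConfig",
    "ShapeTable",
    "InadmissibleInputError",
    "compute_shape_table",
    "is_admissible_input",
    "find_admissible_size",
    "build_unet",
    "UNet3D",
    "save_checkpoint",
    "load_checkpoint",
]


class InadmissibleInputError(ValueError):
    """The input size cannot flow through the network's shape algebra."""


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    ``n_valid_levels`` counts, from the highest resolution down, the
    levels whose convolutions are non-padded (in both encoder and
    decoder); the remaining levels zero-pad.
    """

    n_levels: int = 5
    n_features_first: int = 16
    n_valid_levels: int = 3
    kernel_size: int = 3
    pool_factor: int = 2
    convs_per_level: int = 2
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.n_features_first < 1:
            raise ValueError("n_features_first must be >= 1")
        if not 0 <= self.n_valid_levels <= self.n_levels:
            raise ValueError("n_valid_levels must lie in [0, n_levels]")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        if self.pool_factor < 2:
            raise ValueError("pool_factor must be >= 2")
        if self.convs_per_level < 1:
            raise ValueError("convs_per_level must be >= 1")

    def features_at_level(self, level: int) -> int:
        """Feature channels at 1-based resolution ``level`` (doubling rule)."""
        return self.n_features_first * 2 ** (level - 1)


@dataclass
class ShapeTable:
    """Per-level spatial sizes for one (config, input_shape) pair.

    All per-level entries are dicts keyed by 1-based level, each value a
    (z, y, x) triple. ``skip_margins`` holds the one-sided central crop
    applied to the encoder map before concatenation; ``output_margin``
    is the one-sided offset of the network output inside the input.
    """

    input_shape: Tuple[int, int, int]
    encoder_pre_pool: Dict[int, Tuple[int, int, int]]
    encoder_post_pool: Dict[int, Tuple[int, int, int]]
    decoder_post_upsample: Dict[int, Tuple[int, int, int]]
    decoder_post_conv: Dict[int, Tuple[int, int, int]]
    skip_margins: Dict[int, Tuple[int, int, int]]
    output_shape: Tuple[int, int, int]

    @property
    def output_margin(self) -> Tuple[int, int, int]:
        return tuple(
            (i - o) // 2 for i, o in zip(self.input_shape, self.output_shape)
        )


def _propagate_axis(config: UNetConfig, size: int):
    """Symbolic size propagation along one axis; raises on inadmissibility."""
    k1 = config.kernel_size - 1
    pf = config.pool_factor
    enc_pre: Dict[int, int] = {}
    enc_post: Dict[int, int] = {}
    s = size
    for lvl in range(1, config.n_levels + 1):
        if lvl <= config.n_valid_levels:
            s -= k1 * config.convs_per_level
        if s <= 0:
            raise InadmissibleInputError(
                f"size {size}: encoder level {lvl} feature map collapses to {s}"
            )
        enc_pre[lvl] = s
        if lvl < config.n_levels:
            if s % pf:
                raise InadmissibleInputError(
                    f"size {size}: level {lvl} pre-pool size {s} not divisible by {pf}"
                )
            s //= pf
            enc_post[lvl] = s
    dec_up: Dict[int, int] = {}
    dec_post: Dict[int, int] = {}
    margins: Dict[int, int] = {}
    for lvl in range(config.n_levels - 1, 0, -1):
        s *= pf
        dec_up[lvl] = s
        diff = enc_pre[lvl] - s
        if diff < 0 or diff % 2:
            raise InadmissibleInputError(
                f"size {size}: level {lvl} skip margin ({enc_pre[lvl]}-{s})/2 "
                "is not a non-negative integer"
            )
        margins[lvl] = diff // 2
        if lvl <= config.n_valid_levels:
            s -= k1 * config.convs_per_level
        if s <= 0:
            raise InadmissibleInputError(
                f"size {size}: decoder level {lvl} feature map collapses to {s}"
            )
        dec_post[lvl] = s
    if (size - s) % 2:
        raise InadmissibleInputError(
            f"size {size}: output {s} is not centered (odd total margin)"
        )
    return enc_pre, enc_post, dec_up, dec_post, margins, s


def compute_shape_table(
    config: UNetConfig, input_shape: Sequence[int]
) -> ShapeTable:
    """Propagate an input size symbolically through the network.

    Raises :class:`InadmissibleInputError` if any intermediate size is
    non-positive, a pre-pool size does not divide by the pool factor, or
    a skip crop does not split evenly.
    """
    input_shape = tuple(int(s) for s in input_shape)
    if len(input_shape) != 3:
        raise ValueError(f"input_shape must be a triple, got {input_shape}")
    per_axis = [_propagate_axis(config, s) for s in input_shape]

    def gather(i: int) -> Dict[int, Tuple[int, int, int]]:
        keys = per_axis[0][i].keys()
        return {lvl: tuple(ax[i][lvl] for ax in per_axis) for lvl in keys}

    return ShapeTable(
        input_shape=input_shape,
        encoder_pre_pool=gather(0),
        encoder_post_pool=gather(1),
        decoder_post_upsample=gather(2),
        decoder_post_conv=gather(3),
        skip_margins=gather(4),
        output_shape=tuple(ax[5] for ax in per_axis),
    )


def is_admissible_input(config: UNetConfig, input_shape: Sequence[int]) -> bool:
    """True iff ``compute_shape_table`` succeeds for this input size."""
    try:
        compute_shape_table(config, input_shape)
    except InadmissibleInputError:
        return False
    return True


def find_admissible_size(
    config: UNetConfig, minimum: int, maximum: Optional[int] = None
) -> int:
    """Smallest cubic input size >= ``minimum`` admissible for ``config``."""
    if maximum is None:
        maximum = minimum + 8 * config.pool_factor ** config.n_levels + 64
    for s in range(max(minimum, 1), maximum + 1):
        if is_admissible_input(config, (s, s, s)):
            return s
    raise InadmissibleInputError(
        f"no admissible cubic size in [{minimum}, {maximum}] for {config}"
    )


def _nearest_admissible(config: UNetConfig, size: int) -> str:
    below = next(
        (s for s in range(size - 1, 0, -1) if is_admissible_input(config, (s,) * 3)),
        None,
    )
    try:
        above = find_admissible_size(config, size + 1)
    except InadmissibleInputError:
        above = None
    return f"nearest admissible cubic sizes: below={below}, above={above}"


class _Level:
    """Conv+ReLU stack of one resolution level (encoder or decoder side)."""

    def __init__(self, convs: List[Conv3d]) -> None:
        self.convs = convs
        self.relus = [ReLU() for _ in convs]

    def parameters(self) -> List[Parameter]:
        return [p for c in self.convs for p in c.parameters()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for conv, relu in zip(self.convs, self.relus):
            x = relu.forward(conv.forward(x, train), train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for conv, relu in zip(reversed(self.convs), reversed(self.relus)):
            grad = conv.backward(relu.backward(grad))
        return grad


class UNet3D:
    """The assembled network; operates on single-channel (D, H, W) volumes."""

    def __init__(self, config: UNetConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        n = config.n_levels
        f = config.n_features_first
        pad_mode = lambda lvl: "valid" if lvl <= config.n_valid_levels else "same"

        self.encoder: Dict[int, _Level] = {}
        for lvl in range(1, n + 1):
            out_ch = config.features_at_level(lvl)
            in_ch = 1 if lvl == 1 else config.features_at_level(lvl - 1)
            convs = []
            for i in range(config.convs_per_level):
                convs.append(
                    Conv3d(
                        in_ch if i == 0 else out_ch,
                        out_ch,
                        config.kernel_size,
                        pad_mode(lvl),
                        rng,
                        name=f"enc{lvl}.conv{i}",
                    )
                )
            self.encoder[lvl] = _Level(convs)
        self.pools: Dict[int, MaxPool3d] = {
            lvl: MaxPool3d(config.pool_factor) for lvl in range(1, n)
        }
        self.upconvs: Dict[int, UpConv3d] = {}
        self.decoder: Dict[int, _Level] = {}
        for lvl in range(n - 1, 0, -1):
            ch = config.features_at_level(lvl)
            self.upconvs[lvl] = UpConv3d(
                config.features_at_level(lvl + 1),
                ch,
                config.pool_factor,
                rng,
                name=f"up{lvl}",
            )
            convs = []
            for i in range(config.convs_per_level):
                convs.append(
                    Conv3d(
                        2 * ch if i == 0 else ch,
                        ch,
                        config.kernel_size,
                        pad_mode(lvl),
                        rng,
                        name=f"dec{lvl}.conv{i}",
                    )
                )
            self.decoder[lvl] = _Level(convs)
        self.final_conv = Conv3d(f, 1, 1, "valid", rng, name="final")
        self.sigmoid = Sigmoid()
        self._skip_shapes: Dict[int, Tuple[int, ...]] = {}
        self._skip_margins: Dict[int, Tuple[int, int, int]] = {}

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> List[Parameter]:
        params: List[Parameter] = []
        for lvl in sorted(self.encoder):
            params += self.encoder[lvl].parameters()
        for lvl in sorted(self.upconvs):
            params += self.upconvs[lvl].parameters()
            params += self.decoder[lvl].parameters()
        params += self.final_conv.parameters()
        return params

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for i, p in enumerate(params):
            val = np.asarray(state[f"p{i}"], dtype=np.float32)
            if val.shape != p.value.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.value = val.copy()
            p.grad = np.zeros_like(p.value)

    # -- forward / backward -------------------------------------------------

    def forward(self, patch: np.ndarray, train: bool = False) -> np.ndarray:
        """Map a (D, H, W) patch to its (smaller) probability patch."""
        patch = np.asarray(patch, dtype=np.float32)
        if patch.ndim != 3:
            raise ValueError(f"expected a 3D patch, got shape {patch.shape}")
        if not is_admissible_input(self.config, patch.shape):
            raise InadmissibleInputError(
                f"input shape {patch.shape} is not admissible; "
                + _nearest_admissible(self.config, max(patch.shape))
            )
        n = self.config.n_levels
        x = patch[None]  # (1, D, H, W)
        skips: Dict[int, np.ndarray] = {}
        for lvl in range(1, n + 1):
            x = self.encoder[lvl].forward(x, train)
            if lvl < n:
                skips[lvl] = x
                x = self.pools[lvl].forward(x, train)
        self._skip_shapes = {}
        self._skip_margins = {}
        for lvl in range(n - 1, 0, -1):
            x = self.upconvs[lvl].forward(x, train)
            skip = skips[lvl]
            margins = tuple(
                (s - u) // 2 for s, u in zip(skip.shape[1:], x.shape[1:])
            )
            mz, my, mx = margins
            sz, sy, sx = x.shape[1:]
            cropped = skip[:, mz : mz + sz, my : my + sy, mx : mx + sx]
            if train:
                self._skip_shapes[lvl] = skip.shape
                self._skip_margins[lvl] = margins
            x = np.concatenate([x, cropped], axis=0)
            x = self.decoder[lvl].forward(x, train)
        x = self.final_conv.forward(x, train)
        out = self.sigmoid.forward(x, train)
        return out[0]

    def backward(self, grad_out: np.ndarray) -> None:
        """Backpropagate d(loss)/d(output); accumulates parameter grads."""
        n = self.config.n_levels
        grad = self.final_conv.backward(self.sigmoid.backward(grad_out[None]))
        skip_grads: Dict[int, np.ndarray] = {}
        for lvl in range(1, n):
            grad = self.decoder[lvl].backward(grad)
            ch_up = self.upconvs[lvl].out_channels
            grad_up, grad_skip = grad[:ch_up], grad[ch_up:]
            full = np.zeros(self._skip_shapes[lvl], dtype=grad.dtype)
            mz, my, mx = self._skip_margins[lvl]
            sz, sy, sx = grad_skip.shape[1:]
            full[:, mz : mz + sz, my : my + sy, mx : mx + sx] = grad_skip
            skip_grads[lvl] = full
            grad = self.upconvs[lvl].backward(np.ascontiguousarray(grad_up))
        for lvl in range(n, 0, -1):
            if lvl < n:
                grad = self.pools[lvl].backward(grad)
                grad = grad + skip_grads[lvl]
            grad = self.encoder[lvl].backward(grad)

    # -- inference-facing helpers ------------------------------------------

    def output_margin(self, input_shape: Sequence[int]) -> Tuple[int, int, int]:
        """One-sided (z, y, x) offset of the output inside the input patch."""
        return compute_shape_table(self.config, input_shape).output_margin

    def predict_patch(self, patch: np.ndarray) -> np.ndarray:
        """Evaluation-mode forward pass (no caches kept)."""
        return self.forward(patch, train=False)


def build_unet(config: UNetConfig) -> UNet3D:
    """Construct the network for ``config`` with seeded initialization."""
    return UNet3D(config)


def save_checkpoint(model: UNet3D, path, extra: Optional[dict] = None) -> None:
    """Save weights with the embedded config, so checkpoints self-describe."""
    meta = {"config": asdict(model.config), "extra": extra or {}}
    arrays = model.state_dict()
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> Tuple[UNet3D, dict]:
    """Rebuild a model (and its metadata) from :func:`save_checkpoint`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = build_unet(UNetConfig(**meta["config"]))
    model.load_state_dict(state)
    return model, meta.get("extra", {})
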