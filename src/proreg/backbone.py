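"""Shared-weight UNet that predicts a displacement field from an image pair.

The same parameter set is reused for every progressive registration pass:
each pass feeds (current warped, fixed) in and gets a 3-channel
displacement field out.  Architecture:

* encoder — one 4x4x4 convolution with stride 2 per resolution stage
  (so each stage halves the grid), LeakyReLU after each;
* decoder — per stage, nearest x2 upsampling, concatenation with the
  matching encoder feature (the input pair itself at full resolution),
  then 3x3x3 stride-1 convolutions with LeakyReLU; the last two stages
  use two such convolutions for finer detail;
* head — a final 3x3x3 convolution, no activation, producing the DVF.

The head weights are initialized near zero (std 1e-5) so an untrained
network starts at (almost exactly) the identity transform, which keeps
the early progressive passes stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .grids import Flow, Volume

__all__ = ["BackboneConfig", "UNetBackbone", "predict_flow"]


@dataclass
class BackboneConfig:
    """Architecture hyperparameters of the flow-prediction UNet.

    ``dec_channels`` must have ``levels + 1`` entries: one per decoder
    stage, with the second-to-last stage repeating its width for its
    doubled convolution and the final stage consuming the last two
    entries.  Input extents must be divisible by ``2**levels``.
    """

    levels: int = 4
    enc_channels: tuple[int, ...] = (16, 32, 32, 32)
    dec_channels: tuple[int, ...] = (32, 32, 32, 16, 16)
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if len(self.enc_channels) != self.levels:
            raise ValueError(
                f"enc_channels needs {self.levels} entries, got {len(self.enc_channels)}")
        if len(self.dec_channels) != self.levels + 1:
            raise ValueError(
                f"dec_channels needs {self.levels + 1} entries, got {len(self.dec_channels)}")

    def check_shape(self, shape: tuple[int, int, int]) -> None:
        div = 2 ** self.levels
        for name, extent in zip("DHW", shape):
            if extent % div:
                raise ValueError(
                    f"axis {name} extent {extent} not divisible by 2^levels={div}")

    def decoder_plan(self) -> list[list[int]]:
        """Output widths of the convolutions in each decoder stage."""
        dec = list(self.dec_channels)
        plan = [[dec[i]] for i in range(self.levels - 2)]
        plan.append([dec[self.levels - 2]] * 2)        # doubled, repeated width
        plan.append([dec[self.levels - 1], dec[self.levels]])  # doubled, last two
        return plan


def _he_init(rng: np.random.Generator, cout: int, cin: int, k: int,
             std: float | None = None) -> np.ndarray:
    fan_in = cin * k ** 3
    scale = std if std is not None else np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, scale, size=(cout, cin, k, k, k)).astype(np.float32)


class UNetBackbone:
    """Flow-prediction network with explicit parameter arrays.

    Parameters live in ``self.params``, an ordered dict name -> Tensor
    with ``requires_grad=True``; the optimizer mutates exactly this set
    regardless of how many progressive passes reuse it.
    """

    def __init__(self, config: BackboneConfig | None = None, seed: int = 0):
        self.config = config or BackboneConfig()
        self.params: dict[str, Tensor] = {}
        self._build(np.random.default_rng(seed))

    # -- construction --------------------------------------------------------

    def _add_conv(self, name: str, rng, cout: int, cin: int, k: int,
                  std: float | None = None) -> None:
        self.params[f"{name}.w"] = Tensor(_he_init(rng, cout, cin, k, std))
        self.params[f"{name}.w"].requires_grad = True
        self.params[f"{name}.b"] = Tensor(np.zeros(cout, dtype=np.float32))
        self.params[f"{name}.b"].requires_grad = True

    def _build(self, rng) -> None:
        cfg = self.config
        cin = 2
        self._enc_out = []
        for i, cout in enumerate(cfg.enc_channels):
            self._add_conv(f"enc{i}", rng, cout, cin, 4)
            self._enc_out.append(cout)
            cin = cout
        plan = cfg.decoder_plan()
        cur = cfg.enc_channels[-1]
        for stage, widths in enumerate(plan):
            skip = self._enc_out[cfg.levels - 2 - stage] if stage < cfg.levels - 1 else 2
            cur = cur + skip
            for j, cout in enumerate(widths):
                self._add_conv(f"dec{stage}_{j}", rng, cout, cur, 3)
                cur = cout
        self._add_conv("head", rng, 3, cur, 3, std=1e-5)

    # -- forward --------------------------------------------------------------

    def forward(self, moving: np.ndarray, fixed: np.ndarray) -> Tensor:
        """Predict a (3, D, H, W) flow tensor from two (D, H, W) arrays.

        Both inputs are min-max rescaled to [0, 1] independently before
        entering the network.
        """
        cfg = self.config
        cfg.check_shape(moving.shape)
        x = ad.concat(Tensor(_rescale01(moving)[None]), Tensor(_rescale01(fixed)[None]))
        slope = cfg.leaky_slope
        feats = [x]
        h = x
        for i in range(cfg.levels):
            h = ad.conv3d(h, self.params[f"enc{i}.w"], self.params[f"enc{i}.b"],
                          stride=2, pad=1).leaky_relu(slope)
            feats.append(h)
        for stage, widths in enumerate(cfg.decoder_plan()):
            h = ad.upsample_nearest2x(h)
            h = ad.concat(h, feats[cfg.levels - 1 - stage])
            for j in range(len(widths)):
                h = ad.conv3d(h, self.params[f"dec{stage}_{j}.w"],
                              self.params[f"dec{stage}_{j}.b"],
                              stride=1, pad=1).leaky_relu(slope)
        return ad.conv3d(h, self.params["head.w"], self.params["head.b"],
                         stride=1, pad=1)

    # -- utilities ------------------------------------------------------------

    def param_count(self) -> int:
        return sum(int(t.value.size) for t in self.params.values())

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: t.value for k, t in self.params.items()}

    def checksum(self) -> float:
        return float(sum(np.abs(t.value).sum() for t in self.params.values()))

    def save(self, path) -> None:
        """Serialize weights + config to a single ``.npz`` checkpoint."""
        meta = json.dumps({
            "levels": self.config.levels,
            "enc_channels": list(self.config.enc_channels),
            "dec_channels": list(self.config.dec_channels),
            "leaky_slope": self.config.leaky_slope,
        })
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.state_arrays())

    @classmethod
    def load(cls, path) -> "UNetBackbone":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__config__"]).decode())
            cfg = BackboneConfig(levels=meta["levels"],
                                 enc_channels=tuple(meta["enc_channels"]),
                                 dec_channels=tuple(meta["dec_channels"]),
                                 leaky_slope=meta["leaky_slope"])
            net = cls(cfg, seed=0)
            for k in net.params:
                net.params[k].value = data[k].astype(np.float32)
        return net


def _rescale01(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float32)
    lo, hi = float(a.min()), float(a.max())
    if hi - lo < 1e-12:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def predict_flow(moving: Volume, fixed: Volume, net: UNetBackbone) -> Flow:
    """Predict the displacement field aligning ``moving`` onto ``fixed``."""
    if moving.shape != fixed.shape:
        raise ValueError(f"shape mismatch: {moving.shape} vs {fixed.shape}")
    with ad.no_grad():
        out = net.forward(moving.data, fixed.data)
    return Flow(out.value)
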