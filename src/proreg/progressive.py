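"""Progressive self-calibrating registration: inference, training, search.

The registration network is applied repeatedly with one shared parameter
set.  Pass 1 registers (moving, fixed); every later pass registers the
*previous pass's warped output* against the fixed image, so the network
learns to correct its own residual error ("self-calibration").  The
per-pass flows are folded into one total field by the flow aggregator,
and the primary moving image is interpolated exactly once per output —
repeated interpolation of already-interpolated images (the information
loss of conventional cascades) never occurs.

A two-scale hierarchical mode first registers 2x-downsampled images,
upsamples the resulting flow (doubling both the grid and the
displacement values), and uses it to initialize the full-resolution
chain.

Training is unsupervised: per pass, the objective is
``-LNCC(warp(moving, aggregate), fixed) + lambda * smooth(flow_n)`` and
by default one Adam update is applied per pass, with the previous warped
image and the running aggregate treated as constants (gradients flow
only through the newest flow).  A per-sweep mode (one update after all
passes, summed gradients) is available via ``TrainConfig.update``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .backbone import BackboneConfig, UNetBackbone, predict_flow
from .flow_algebra import compose_pair
from .grids import (Flow, LabelMap, Volume, counters, downsample_labels,
                    downsample_volume, upsample_flow, warp_image, warp_labels)
from .losses import LossWeights, objective_t
from .evaluation import dice_report

__all__ = [
    "IterationSchedule", "TrainConfig", "RegistrationResult", "Adam",
    "progressive_infer", "cascade_infer", "train_step", "train",
    "hierarchical_infer", "train_hierarchical", "grid_search",
]


@dataclass
class IterationSchedule:
    """Progressive pass counts: ``n_train`` per training step, ``n_test``
    at inference.  The two are tuned independently."""

    n_train: int = 3
    n_test: int = 2

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must both be >= 1")


@dataclass
class TrainConfig:
    """Optimization settings for one backbone.

    Defaults are desk-scale; the full-scale settings used on real brain
    volumes (learning rate 1e-4, batch 1, 30000 steps, LNCC window 9)
    are reachable through the same fields.
    """

    learning_rate: float = 1e-4
    steps: int = 150
    batch: int = 1
    seed: int = 0
    weights: LossWeights = field(default_factory=lambda: LossWeights(lambda_smooth=1.0,
                                                                     lncc_window=5))
    schedule: IterationSchedule = field(default_factory=IterationSchedule)
    update: str = "per_pass"  # or "per_sweep"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.steps < 0 or self.batch < 1:
            raise ValueError("steps must be >= 0 and batch >= 1")
        if self.update not in ("per_pass", "per_sweep"):
            raise ValueError("update must be 'per_pass' or 'per_sweep'")


@dataclass
class RegistrationResult:
    """Outcome of a progressive registration run.

    ``interp_count`` is the number of interpolations separating ``warped``
    from the primary moving image — 1 for the progressive strategy,
    ``n_test`` for the conventional cascade provided for comparison.
    """

    total_flow: Flow
    warped: Volume
    per_pass: list[tuple[float, float, float]]
    interp_count: int


class Adam:
    """Adam optimizer over a backbone's parameter dict."""

    def __init__(self, net: UNetBackbone, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in net.params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in net.params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for k, p in self.net.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p.value -= self.lr * (self.m[k] / corr1) / (np.sqrt(self.v[k] / corr2) + self.eps)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _pass_diagnostics(warped: Volume, fixed: Volume, flow: Flow,
                      w: LossWeights) -> tuple[float, float, float]:
    from .losses import lncc, smooth_energy
    sim = lncc(warped, fixed, w.lncc_window)
    smo = smooth_energy(flow)
    return (sim, smo, -sim + w.lambda_smooth * smo)


def progressive_infer(moving: Volume, fixed: Volume, net: UNetBackbone,
                      n_test: int, weights: LossWeights | None = None,
                      init_agg: Flow | None = None) -> RegistrationResult:
    """Run ``n_test`` shared-weight passes and return the single-warp result.

    Each pass predicts a residual flow from (current warped, fixed),
    folds it into the running aggregate, and re-warps the *primary*
    moving image with the aggregate — never the previous warped output.
    """
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    w = weights or LossWeights(lncc_window=5)
    agg = init_agg
    current = moving if agg is None else warp_image(moving, agg)
    per_pass = []
    for _ in range(n_test):
        f = predict_flow(current, fixed, net)
        agg = f if agg is None else compose_pair(agg, f)
        current = warp_image(moving, agg)
        per_pass.append(_pass_diagnostics(current, fixed, f, w))
    return RegistrationResult(total_flow=agg, warped=current, per_pass=per_pass,
                              interp_count=current.interp_count - moving.interp_count)


def cascade_infer(moving: Volume, fixed: Volume, net: UNetBackbone,
                  n_test: int, weights: LossWeights | None = None) -> RegistrationResult:
    """Conventional recursive cascade: re-warp the warped image every pass.

    Provided for the information-loss comparison; its output accumulates
    one interpolation per pass, progressively blurring sharp boundaries.
    """
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    w = weights or LossWeights(lncc_window=5)
    current = moving
    flows, per_pass = [], []
    for _ in range(n_test):
        f = predict_flow(current, fixed, net)
        current = warp_image(current, f)
        flows.append(f)
        per_pass.append(_pass_diagnostics(current, fixed, f, w))
    from .flow_algebra import compose_chain
    return RegistrationResult(total_flow=compose_chain(flows), warped=current,
                              per_pass=per_pass,
                              interp_count=current.interp_count - moving.interp_count)


def hierarchical_infer(moving: Volume, fixed: Volume,
                       low_net: UNetBackbone, orig_net: UNetBackbone,
                       sched_low: IterationSchedule | None = None,
                       sched_orig: IterationSchedule | None = None,
                       weights: LossWeights | None = None) -> RegistrationResult:
    """Two-scale coarse-to-fine registration with a single final warp.

    The default schedules (low 5/3, original 9/2) are the grid-search
    optima reported for full-scale brain registration; desk-scale runs
    typically pass smaller ones.
    """
    sched_low = sched_low or IterationSchedule(n_train=5, n_test=3)
    sched_orig = sched_orig or IterationSchedule(n_train=9, n_test=2)
    m_low = downsample_volume(moving)
    f_low = downsample_volume(fixed)
    low_res = progressive_infer(m_low, f_low, low_net, sched_low.n_test, weights)
    flow_up = upsample_flow(low_res.total_flow)
    res = progressive_infer(moving, fixed, orig_net, sched_orig.n_test, weights,
                            init_agg=flow_up)
    res.per_pass = low_res.per_pass + res.per_pass
    return res


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class TrainingError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the pass index."""

    def __init__(self, pass_index: int, loss: float):
        super().__init__(f"non-finite loss {loss} at pass {pass_index}")
        self.pass_index = pass_index


def train_step(moving: Volume, fixed: Volume, net: UNetBackbone, opt: Adam,
               cfg: TrainConfig, init_agg: Flow | None = None) -> list[dict]:
    """One training step: ``cfg.schedule.n_train`` self-calibrating passes.

    Per pass: predict a flow from the detached previous warped result,
    fold it into the detached running aggregate, warp the primary moving
    image once, evaluate the objective (smoothness on the newest flow
    only), back-propagate, and — in the default per-pass mode — apply one
    optimizer update immediately.
    """
    w = cfg.weights
    agg_np = None if init_agg is None else init_agg.data
    moving_np = moving.data[None]  # (1, D, H, W) constant
    current = moving.data if agg_np is None else _warp_np(moving.data, agg_np)
    fixed_t_val = fixed.data
    diagnostics = []
    if cfg.update == "per_sweep":
        net.zero_grad()
    for n in range(1, cfg.schedule.n_train + 1):
        if cfg.update == "per_pass":
            net.zero_grad()
        flow_t = net.forward(current, fixed_t_val)
        if agg_np is None:
            agg_t = flow_t
        else:
            agg_t = flow_t + ad.sample_displaced(agg_np, flow_t)
        counters.warp_calls += 1  # one interpolation of the primary moving image
        warped_t = ad.sample_displaced(moving_np, agg_t)
        loss, sim, smo = objective_t(_squeeze0(warped_t), Tensor(fixed_t_val),
                                     flow_t, w)
        if not np.isfinite(loss.value):
            raise TrainingError(n, float(loss.value))
        loss.backward()
        if cfg.update == "per_pass":
            opt.step()
        diagnostics.append({"pass": n, "similarity": sim, "smoothness": smo,
                            "objective": float(loss.value)})
        agg_np = agg_t.value
        current = warped_t.value[0]
    if cfg.update == "per_sweep":
        opt.step()
    return diagnostics


def _squeeze0(t: Tensor) -> Tensor:
    """View channel 0 of a (1, D, H, W) tensor as (D, H, W)."""
    out = Tensor._node(t.value[0], (t,), None)
    if out.parents:
        out._backward = lambda g: t._accum(g[None])
    return out


def _warp_np(moving: np.ndarray, flow: np.ndarray) -> np.ndarray:
    with ad.no_grad():
        return ad.sample_displaced(moving[None], Tensor(flow)).value[0]


def train(pairs: list, net: UNetBackbone, cfg: TrainConfig,
          low_net: UNetBackbone | None = None,
          sched_low: IterationSchedule | None = None,
          log_every: int = 0, log=print) -> list[dict]:
    """Optimize a backbone over a dataset of (moving, fixed) pairs.

    ``pairs`` holds objects with ``.moving`` and ``.fixed`` Volumes (the
    synthetic-pair type qualifies).  If ``low_net`` is given, every step
    is initialized by the frozen low-scale network's upsampled flow, as
    in hierarchical inference.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net, lr=cfg.learning_rate)
    history = []
    for step in range(cfg.steps):
        for _ in range(cfg.batch):
            pair = pairs[int(rng.integers(len(pairs)))]
            init_agg = None
            if low_net is not None:
                m_low = downsample_volume(pair.moving)
                f_low = downsample_volume(pair.fixed)
                low = progressive_infer(m_low, f_low, low_net,
                                        (sched_low or IterationSchedule(5, 3)).n_test,
                                        cfg.weights)
                init_agg = upsample_flow(low.total_flow)
            diag = train_step(pair.moving, pair.fixed, net, opt, cfg, init_agg)
        rec = {"step": step, "objective": diag[-1]["objective"],
               "similarity": diag[-1]["similarity"],
               "smoothness": diag[-1]["smoothness"]}
        history.append(rec)
        if log_every and step % log_every == 0:
            log(f"step {step:5d}  sim {rec['similarity']:+.4f}  "
                f"smooth {rec['smoothness']:.5f}  obj {rec['objective']:+.4f}")
    return history


def train_hierarchical(pairs: list, cfg_low: TrainConfig, cfg_orig: TrainConfig,
                       bb_low: BackboneConfig | None = None,
                       bb_orig: BackboneConfig | None = None,
                       log_every: int = 0, log=print):
    """Two-phase training of the two-scale cascade.

    Phase 1 trains the low-scale backbone on 2x-downsampled pairs; phase
    2 freezes it and trains the original-scale backbone with every step
    initialized by the frozen low-scale output.  Returns
    ``(low_net, orig_net, history_low, history_orig)``.
    """
    low_net = UNetBackbone(bb_low or BackboneConfig(), seed=cfg_low.seed)
    orig_net = UNetBackbone(bb_orig or BackboneConfig(), seed=cfg_orig.seed + 1)

    low_pairs = [_DownsampledPair(downsample_volume(p.moving), downsample_volume(p.fixed))
                 for p in pairs]
    hist_low = train(low_pairs, low_net, cfg_low, log_every=log_every, log=log)
    hist_orig = train(pairs, orig_net, cfg_orig, low_net=low_net,
                      sched_low=cfg_low.schedule, log_every=log_every, log=log)
    return low_net, orig_net, hist_low, hist_orig


@dataclass
class _DownsampledPair:
    moving: Volume
    fixed: Volume


# ---------------------------------------------------------------------------
# n_train / n_test grid search
# ---------------------------------------------------------------------------

def grid_search(train_pairs: list, test_pairs: list, base_cfg: TrainConfig,
                n_train_range: list[int], n_test_range: list[int],
                bb: BackboneConfig | None = None, log_every: int = 0,
                log=print):
    """Sweep pass counts: one model per ``n_train``, evaluated at every
    ``n_test``; returns ``(mean-Dice matrix, (i, j) argmax)``.

    Because pass ``k`` trains on the warped output of pass ``k-1``, each
    extra training pass implicitly enlarges the training distribution —
    the sweep therefore doubles as the dynamic-augmentation study.
    """
    if not n_train_range or not n_test_range:
        raise ValueError("ranges must be non-empty")
    matrix = np.zeros((len(n_train_range), len(n_test_range)))
    for i, n_train in enumerate(n_train_range):
        cfg = replace(base_cfg,
                      schedule=IterationSchedule(n_train, base_cfg.schedule.n_test))
        net = UNetBackbone(bb or BackboneConfig(), seed=cfg.seed)
        train(train_pairs, net, cfg, log_every=log_every, log=log)
        for j, n_test in enumerate(n_test_range):
            scores = []
            for p in test_pairs:
                res = progressive_infer(p.moving, p.fixed, net, n_test, cfg.weights)
                wl = warp_labels(p.moving_labels, res.total_flow)
                scores.append(dice_report(wl, p.fixed_labels).mean)
            matrix[i, j] = float(np.mean(scores))
    argmax = np.unravel_index(int(np.argmax(matrix)), matrix.shape)
    return matrix, (int(argmax[0]), int(argmax[1]))
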