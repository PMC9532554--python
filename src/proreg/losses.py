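"""Similarity and regularization terms of the unsupervised objective.

The per-iteration training objective is

    Loss = -LNCC(warped_total, fixed) + lambda * L_smooth(flow_latest)

where ``warped_total`` is the primary moving image warped **once** by the
aggregated flow, and the smoothness penalty acts only on the newest
per-iteration flow — never on the aggregate.

LNCC is the local (windowed) normalized cross-correlation, evaluated
densely at every voxel with windows truncated at the borders, signed (not
squared), with a small variance guard in the denominator.  It is
invariant to positive affine intensity maps of either argument and
bounded in [-1, 1].

The smoothness energy is the mean squared forward difference of the flow
over all voxels, components and axes — a discrete Dirichlet energy.  The
mean (rather than raw-sum) normalization makes the weight ``lambda``
comparable across resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .grids import Flow, Volume

__all__ = ["LossWeights", "lncc", "smooth_energy", "objective",
           "lncc_t", "smooth_energy_t", "objective_t"]

#: variance guard added under the square root of the LNCC denominator
LNCC_EPS = 1e-5


@dataclass
class LossWeights:
    """Weights and window of the training objective.

    Parameters
    ----------
    lambda_smooth : float
        Nonnegative weight of the smoothness penalty.
    lncc_window : int
        Odd edge length (voxels) of the LNCC window.  9 matches
        full-resolution brain volumes; 5 is appropriate for the small
        synthetic fixtures used on a desktop CPU.
    """

    lambda_smooth: float = 1.0
    lncc_window: int = 9

    def __post_init__(self) -> None:
        if self.lambda_smooth < 0:
            raise ValueError("lambda_smooth must be nonnegative")
        if self.lncc_window < 3 or self.lncc_window % 2 == 0:
            raise ValueError("lncc_window must be odd and >= 3")


# ---------------------------------------------------------------------------
# differentiable (Tensor) forms — used by the training loop
# ---------------------------------------------------------------------------

def lncc_t(a: Tensor, b: Tensor, window: int) -> Tensor:
    """Differentiable mean local NCC of two (D, H, W) tensors.

    Each input is conditioned to [0, 1] by a constant min-max affine map
    first; NCC is invariant to positive affine intensity maps, so this
    changes nothing analytically but keeps the windowed variance
    cancellation well inside float precision for 8-bit-range data.
    """
    a = _condition01(a)
    b = _condition01(b)
    n = ad.boxsum(Tensor(np.ones_like(a.value)), window)  # window voxel counts
    sa = ad.boxsum(a, window)
    sb = ad.boxsum(b, window)
    sab = ad.boxsum(a * b, window)
    saa = ad.boxsum(a * a, window)
    sbb = ad.boxsum(b * b, window)
    cross = sab - sa * sb / n
    # float32 roundoff can push a flat window's variance slightly negative
    var_a = (saa - sa * sa / n).leaky_relu(0.0)
    var_b = (sbb - sb * sb / n).leaky_relu(0.0)
    cc = cross / (var_a * var_b + LNCC_EPS).sqrt()
    return cc.mean()


def _condition01(t: Tensor) -> Tensor:
    lo = float(t.value.min())
    hi = float(t.value.max())
    if hi - lo < 1e-12:
        return t * 0.0
    return (t - lo) * (1.0 / (hi - lo))


def smooth_energy_t(u: Tensor) -> Tensor:
    """Differentiable mean squared forward-difference energy of a (3,D,H,W) flow."""
    total = None
    n_terms = 0
    for axis in (1, 2, 3):
        d = ad.axis_diff(u, axis)
        n_terms += d.value.size
        term = (d * d).sum()
        total = term if total is None else total + term
    return total * (1.0 / n_terms)


def objective_t(warped_total: Tensor, fixed: Tensor, latest_flow: Tensor,
                w: LossWeights) -> tuple[Tensor, float, float]:
    """Differentiable objective; returns (loss, similarity, smoothness)."""
    sim = lncc_t(warped_total, fixed, w.lncc_window)
    smo = smooth_energy_t(latest_flow)
    loss = -sim + w.lambda_smooth * smo
    return loss, sim.item(), smo.item()


# ---------------------------------------------------------------------------
# plain (numpy) public API
# ---------------------------------------------------------------------------

def _vol_array(v) -> np.ndarray:
    return v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float32)


def lncc(a, b, window: int = 9) -> float:
    """Mean local normalized cross-correlation of two volumes, in [-1, 1].

    Windows are centered at every voxel and truncated at the borders; a
    variance guard of 1e-5 keeps flat windows finite (they contribute ~0).
    Symmetric in its arguments and invariant to positive affine intensity
    rescaling of either one.
    """
    av, bv = _vol_array(a), _vol_array(b)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if any(window > s for s in av.shape):
        raise ValueError(f"window {window} exceeds volume extents {av.shape}")
    with ad.no_grad():
        return lncc_t(Tensor(av), Tensor(bv), window).item()


def smooth_energy(u: Flow) -> float:
    """Mean squared forward-difference energy of a flow (0 iff constant)."""
    with ad.no_grad():
        return smooth_energy_t(Tensor(u.data)).item()


def objective(warped_total: Volume, fixed: Volume, latest_flow: Flow,
              w: LossWeights) -> float:
    """``-lncc(warped_total, fixed) + lambda * smooth_energy(latest_flow)``.

    ``warped_total`` must be the primary moving image warped once by the
    aggregated flow; the smoothness term sees only the newest
    per-iteration flow.
    """
    if warped_total.shape != fixed.shape:
        raise ValueError(f"shape mismatch: {warped_total.shape} vs {fixed.shape}")
    if latest_flow.spatial_shape != fixed.shape:
        raise ValueError(
            f"flow shape {latest_flow.spatial_shape} does not match {fixed.shape}")
    return (-lncc(warped_total, fixed, w.lncc_window)
            + w.lambda_smooth * smooth_energy(latest_flow))
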