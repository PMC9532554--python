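"""Aggregation of per-iteration displacement fields into one total field.

Two displacement fields applied in sequence are equivalent to a single
field

    u_total(x) = u_next(x) + u_prev(x + u_next(x)),

because ``(M∘phi_prev)∘phi_next (x) = M(x + u_next(x) + u_prev(x + u_next(x)))``.
Folding a whole chain of per-iteration flows through this rule yields one
total field, so the moving image is interpolated exactly once no matter
how many registration passes produced the chain — the mechanism that
avoids the progressive blurring ("information loss") of conventional
cascades, which re-interpolate an already-interpolated image at every
stage.

``u_prev`` is resampled trilinearly at the displaced positions with the
same clamp-to-edge policy as image warping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import Flow, _identity_grid, _trilinear

__all__ = ["compose_pair", "compose_chain", "FlowChain"]


def compose_pair(u_prev: Flow, u_next: Flow) -> Flow:
    """Fold two sequential displacement fields into one.

    Parameters
    ----------
    u_prev : Flow
        The earlier (already aggregated) field.
    u_next : Flow
        The newly predicted field, applied first in backward-warping
        order: ``warp(warp(M, u_prev), u_next) == warp(M, compose_pair(u_prev, u_next))``
        up to interpolation error.
    """
    if u_prev.spatial_shape != u_next.spatial_shape:
        raise ValueError(
            f"shape mismatch: {u_prev.spatial_shape} vs {u_next.spatial_shape}")
    coords = _identity_grid(u_next.spatial_shape) + u_next.data
    prev_at = _trilinear(u_prev.data, coords)
    return Flow(u_next.data + prev_at)


def compose_chain(flows: list[Flow]) -> Flow:
    """Left-fold a chain of per-iteration flows into the total field.

    ``agg <- flows[0]; agg <- compose_pair(agg, f)`` for each subsequent
    flow — exactly ``len(flows) - 1`` pairwise aggregations.
    """
    if len(flows) == 0:
        raise ValueError("compose_chain requires a non-empty list of flows")
    agg = flows[0]
    for f in flows[1:]:
        agg = compose_pair(agg, f)
    return agg


@dataclass
class FlowChain:
    """An ordered chain of per-iteration flows plus its running aggregate."""

    flows: list[Flow] = field(default_factory=list)
    aggregated: Flow | None = None

    def append(self, f: Flow) -> None:
        if self.flows and f.spatial_shape != self.flows[0].spatial_shape:
            raise ValueError("all flows in a chain must share one spatial shape")
        self.flows.append(f)
        self.aggregated = f if self.aggregated is None else compose_pair(self.aggregated, f)

    def verify(self, atol: float = 1e-4) -> bool:
        """Recompute the aggregate from scratch and compare."""
        if not self.flows:
            return self.aggregated is None
        ref = compose_chain(self.flows)
        return bool(np.allclose(self.aggregated.data, ref.data, atol=atol))
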