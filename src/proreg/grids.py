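"""Core grid types and resampling operators.

Conventions used throughout the package:

* Volumes are scalar grids of shape ``(D, H, W)``; voxel centers sit at
  integer coordinates, 0-based.
* Displacement fields ("flows") carry one 3-vector per voxel, stored as
  ``(3, D, H, W)`` with component order = displacement along the D, H, W
  axes, in **voxel units**.  The deformation is never stored explicitly:
  ``phi(x) = x + u(x)`` is formed on demand.
* All warping is backward warping, ``warped(x) = moving(x + u(x))``, the
  sampling direction of spatial-transformer layers.
* Out-of-bounds sample coordinates are clamped to the valid range
  (clamp-to-edge) before interpolation, for both intensities and flows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Volume",
    "LabelMap",
    "Flow",
    "counters",
    "trilinear_sample",
    "warp_image",
    "warp_labels",
    "downsample_volume",
    "upsample_flow",
]


class _Counters:
    """Module-level instrumentation of interpolation passes.

    ``warp_calls`` counts every image-warp invocation; tests use it to
    verify that the progressive strategy interpolates the primary moving
    image exactly once per output, rather than compounding warps of warps.
    """

    def __init__(self) -> None:
        self.warp_calls = 0

    def reset(self) -> None:
        self.warp_calls = 0


counters = _Counters()


def _as_f32(a: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(a, dtype=np.float32))


@dataclass
class Volume:
    """A 3D scalar-intensity grid.

    Attributes
    ----------
    data : ndarray, shape (D, H, W)
        Voxel intensities; must be finite.
    spacing : tuple of 3 floats
        Physical voxel size, informational only — registration runs in
        voxel space.
    interp_count : int
        Number of interpolation passes that separate ``data`` from raw,
        never-resampled data.  A freshly loaded or generated volume has 0;
        every :func:`warp_image` adds 1.  This is the lineage used to
        assert the single-interpolation property of the method.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    interp_count: int = 0

    def __post_init__(self) -> None:
        self.data = _as_f32(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 2:
            raise ValueError(f"every spatial extent must be >= 2, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelMap:
    """Integer anatomical-region labels on a grid; 0 is background."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"LabelMap data must be 3D, got shape {data.shape}")
        if not np.issubdtype(data.dtype, np.integer):
            if not np.array_equal(data, np.round(data)):
                raise ValueError("LabelMap data must be integer-valued")
            data = data.astype(np.int32)
        if data.min() < 0:
            raise ValueError("labels must be non-negative")
        self.data = np.ascontiguousarray(data.astype(np.int32))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def label_ids(self) -> np.ndarray:
        """Sorted nonzero labels present."""
        ids = np.unique(self.data)
        return ids[ids != 0]


@dataclass
class Flow:
    """A dense displacement-vector field, ``(3, D, H, W)`` in voxel units."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = _as_f32(self.data)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError(f"Flow data must have shape (3, D, H, W), got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Flow displacements must be finite")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]  # type: ignore[return-value]

    @classmethod
    def zeros(cls, shape: tuple[int, int, int]) -> "Flow":
        return cls(np.zeros((3, *shape), dtype=np.float32))


# ---------------------------------------------------------------------------
# trilinear interpolation core (shared by image warping and flow resampling)
# ---------------------------------------------------------------------------

def _clamped_corners(coords: np.ndarray, shape: tuple[int, int, int]):
    """Clamp continuous coords and return corner indices + weights.

    coords: (3, N) or (3, D, H, W).  Returns (i0, i1, frac) per axis with
    clamp-to-edge applied first, so out-of-hull points sample the boundary.
    """
    idx0, idx1, frac = [], [], []
    for ax in range(3):
        c = np.clip(coords[ax], 0.0, shape[ax] - 1.0)
        f0 = np.floor(c)
        i0 = f0.astype(np.int64)
        i1 = np.minimum(i0 + 1, shape[ax] - 1)
        idx0.append(i0)
        idx1.append(i1)
        frac.append((c - f0).astype(np.float32))
    return idx0, idx1, frac


def _trilinear(values: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of ``values`` (C, D, H, W) at ``coords`` (3, ...)."""
    spatial = values.shape[1:]
    idx0, idx1, frac = _clamped_corners(coords, spatial)
    (d0, h0, w0), (d1, h1, w1) = idx0, idx1
    fd, fh, fw = frac
    gd, gh, gw = 1.0 - fd, 1.0 - fh, 1.0 - fw

    out = np.zeros((values.shape[0], *coords.shape[1:]), dtype=np.float32)
    for (di, wd) in ((d0, gd), (d1, fd)):
        for (hi, wh) in ((h0, gh), (h1, fh)):
            for (wi, ww) in ((w0, gw), (w1, fw)):
                weight = wd * wh * ww
                out += values[:, di, hi, wi] * weight
    return out


def _identity_grid(shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel-center coordinates, shape (3, D, H, W), float32."""
    axes = np.meshgrid(*(np.arange(n, dtype=np.float32) for n in shape), indexing="ij")
    return np.stack(axes, axis=0)


# ---------------------------------------------------------------------------
# public operators
# ---------------------------------------------------------------------------

def trilinear_sample(v: Volume, points: np.ndarray) -> np.ndarray:
    """Sample a volume at continuous 3D points (N, 3) with clamp-to-edge.

    Points live in 0-based voxel coordinates; voxel centers are at
    integers.  Returns an (N,) float array.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must have shape (N, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("sample points must be finite")
    out = _trilinear(v.data[None], pts.T.astype(np.float32))
    return out[0]


def warp_image(m: Volume, u: Flow) -> Volume:
    """Backward-warp an image by a displacement field in one interpolation.

    ``warped(x) = m(x + u(x))`` with trilinear interpolation and
    clamp-to-edge.  Exactly one interpolation pass; the result's
    ``interp_count`` is the input's plus one.
    """
    if m.shape != u.spatial_shape:
        raise ValueError(f"shape mismatch: image {m.shape} vs flow {u.spatial_shape}")
    counters.warp_calls += 1
    coords = _identity_grid(m.shape) + u.data
    warped = _trilinear(m.data[None], coords)[0]
    return Volume(warped, spacing=m.spacing, interp_count=m.interp_count + 1)


def warp_labels(l: LabelMap, u: Flow) -> LabelMap:
    """Warp a label map by nearest-neighbor lookup at ``x + u(x)``.

    The nearest index per axis is ``floor(coord + 0.5)`` (ties round up),
    clamped to bounds, so the output label set is a subset of the input's
    plus background.
    """
    if l.shape != u.spatial_shape:
        raise ValueError(f"shape mismatch: labels {l.shape} vs flow {u.spatial_shape}")
    coords = _identity_grid(l.shape) + u.data
    idx = []
    for ax in range(3):
        i = np.floor(coords[ax] + 0.5).astype(np.int64)
        idx.append(np.clip(i, 0, l.shape[ax] - 1))
    return LabelMap(l.data[idx[0], idx[1], idx[2]], spacing=l.spacing)


def downsample_volume(v: Volume, factor: int = 2) -> Volume:
    """Average-pool a volume by ``factor`` along every axis."""
    if factor != 2:
        raise ValueError("only factor 2 is supported")
    d, h, w = v.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"every extent must be divisible by 2, got {v.shape}")
    pooled = v.data.reshape(d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(1, 3, 5))
    return Volume(pooled, spacing=tuple(s * 2 for s in v.spacing),
                  interp_count=v.interp_count)


def downsample_labels(l: LabelMap, factor: int = 2) -> LabelMap:
    """Downsample labels by strided nearest sampling (every other voxel)."""
    if factor != 2:
        raise ValueError("only factor 2 is supported")
    d, h, w = l.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"every extent must be divisible by 2, got {l.shape}")
    return LabelMap(l.data[::2, ::2, ::2], spacing=tuple(s * 2 for s in l.spacing))


def upsample_flow(u: Flow, factor: int = 2) -> Flow:
    """Double the resolution of a flow and rescale displacements to match.

    Spatial trilinear upsampling to doubled extents followed by a global
    multiplication of every displacement component by 2, converting
    low-scale voxel units into fine-scale voxel units.
    """
    if factor != 2:
        raise ValueError("only factor 2 is supported")
    low_shape = u.spatial_shape
    fine_shape = tuple(2 * n for n in low_shape)
    # Fine voxel i maps to low-scale coordinate i/2 - 0.25 (cell-aligned
    # grids: low voxel j covers fine voxels 2j, 2j+1).
    coords = np.stack(
        np.meshgrid(*(np.arange(n, dtype=np.float32) / 2.0 - 0.25 for n in fine_shape),
                    indexing="ij"),
        axis=0,
    )
    up = _trilinear(u.data, coords)
    return Flow(up * 2.0)
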