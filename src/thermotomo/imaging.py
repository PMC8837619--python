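"""Planar thermal-image rendering and unfiltered backprojection.

An orthographic thermal camera circles the phantom: at each view angle
every detector pixel records the ΔT of the first support voxel its ray
meets (infrared radiation does not penetrate the object, so only the
surface is seen).  The initial tomographic reconstruction sums, per
voxel and per angle, the projection value at the voxel's detector
coordinate s = x·cosθ + y·sinθ and divides by the number of views —
plain unfiltered backprojection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .heatsim import ContractError, TemperatureVolume
from .phantom import VoxelGridSpec


@dataclass
class ProjectionSet:
    """Angle-indexed stack of planar thermal images.

    ``images`` has shape (n_angles, n_rows, n_cols): one row per axial
    slice, one column per detector bin.  Background pixels (rays that
    miss the phantom) are exactly zero.
    """

    images: np.ndarray
    angles_deg: np.ndarray
    detector_spacing: float              # m

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.images.shape[0] != self.angles_deg.shape[0]:
            raise ContractError("one image per angle required")
        if (np.any(np.diff(self.angles_deg) <= 0)
                or self.angles_deg[0] < 0 or self.angles_deg[-1] >= 360):
            raise ContractError("angles must be strictly increasing in [0, 360)")


def _detector_centers(n_bins: int, spacing: float) -> np.ndarray:
    """Detector-bin centre coordinates, centred on the rotation axis."""
    return (np.arange(n_bins) + 0.5) * spacing - n_bins * spacing / 2.0


def _surface_sample_points(n_bins: int, dx: float, radius: float,
                           angles_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) surface-entry sample points per (angle, detector bin).

    The detector axis at angle θ is (cosθ, sinθ); rays travel along
    (−sinθ, cosθ) and enter the cylinder at t = −√(R² − s²).  The sample
    point is pulled half a voxel inward along the ray so it lies inside
    the discretized support.  Bins whose ray misses the cylinder get NaN.
    """
    s = _detector_centers(n_bins, dx)
    chord = radius ** 2 - s ** 2
    miss = chord <= 0.0
    half = np.sqrt(np.maximum(chord, 0.0))
    # pulled far enough inward that every bilinear corner voxel centre
    # lies inside the stair-step support (1.25 Δx covers the half-voxel
    # pull plus the Δx/√2 corner reach)
    t_in = -np.maximum(half - 1.25 * dx, 0.0)
    theta = np.radians(angles_deg)
    cos_t, sin_t = np.cos(theta)[:, None], np.sin(theta)[:, None]
    px = s[None, :] * cos_t - t_in[None, :] * sin_t
    py = s[None, :] * sin_t + t_in[None, :] * cos_t
    px[:, miss] = np.nan
    py[:, miss] = np.nan
    return px, py


def render_projections(volume: TemperatureVolume, n_angles: int = 360
                       ) -> ProjectionSet:
    """Render orthographic surface-temperature images around the phantom.

    One image per angle (default 360 views at 1° resolution); pixel
    (row z, column s) carries the ΔT of the phantom surface where the
    ray through detector bin s enters the cylinder at axial slice z —
    infrared imaging sees only the first surface, never through it.
    Values are sampled by support-aware bilinear interpolation at the
    analytic surface-entry point, so an axisymmetric field renders to
    near-identical views at every angle.  Rays missing the phantom give
    exactly-zero background pixels.
    """
    support = volume.support
    if not support.any():
        raise ContractError("volume has empty support")
    nx, ny, nz = volume.values.shape
    dx = volume.grid.spacing
    angles = np.arange(n_angles) * (360.0 / n_angles)
    radius = nx * dx / 2.0
    px, py = _surface_sample_points(nx, dx, radius, angles)
    valid = np.isfinite(px)
    # fractional voxel coordinates (voxel centre i at (i + 0.5) dx - R)
    fx = np.where(valid, px, 0.0) / dx + nx / 2.0 - 0.5
    fy = np.where(valid, py, 0.0) / dx + ny / 2.0 - 0.5
    i0 = np.clip(np.floor(fx).astype(np.int64), 0, nx - 2)
    j0 = np.clip(np.floor(fy).astype(np.int64), 0, ny - 2)
    wx = np.clip(fx - i0, 0.0, 1.0)
    wy = np.clip(fy - j0, 0.0, 1.0)
    vol2d = volume.values.reshape(nx * ny, nz)
    sup_flat = support.any(axis=2).astype(np.float64).ravel()
    images = np.zeros((n_angles, nz, nx))
    corners = ((i0, j0, (1 - wx) * (1 - wy)), (i0 + 1, j0, wx * (1 - wy)),
               (i0, j0 + 1, (1 - wx) * wy), (i0 + 1, j0 + 1, wx * wy))
    num = np.zeros((n_angles, nx, nz))
    den = np.zeros((n_angles, nx))
    for ci, cj, w in corners:
        flat = ci * ny + cj
        m = sup_flat[flat]                            # in-support corners only
        num += (w * m)[:, :, None] * vol2d[flat]
        den += w * m
    ok = valid & (den > 1e-12)
    num[ok] /= den[ok][:, None]
    num[~ok] = 0.0
    images = np.swapaxes(num, 1, 2)                   # (angle, z, bin)
    return ProjectionSet(images=images, angles_deg=angles,
                         detector_spacing=dx)


class _BackprojectPlan:
    """Precomputed per-angle detector interpolation weights for a grid."""

    def __init__(self, grid: VoxelGridSpec, support2d: np.ndarray,
                 angles_deg: np.ndarray, n_bins: int, spacing: float):
        x, y, _ = grid.axes()
        xs = x[:, None] + 0.0 * y[None, :]
        ys = 0.0 * x[:, None] + y[None, :]
        self.support_flat = support2d.ravel()
        xv = xs.ravel()[self.support_flat]
        yv = ys.ravel()[self.support_flat]
        centers0 = _detector_centers(n_bins, spacing)[0]
        theta = np.radians(angles_deg)
        # s = x cosθ + y sinθ mapped onto fractional bin coordinates
        sval = (np.outer(np.cos(theta), xv) + np.outer(np.sin(theta), yv))
        f = (sval - centers0) / spacing
        # s never exceeds the detector half-width by more than half a bin;
        # clamp to the bin-centre range (nearest-bin extrapolation at edges)
        f = np.clip(f, 0.0, n_bins - 1.0)
        self.i0 = np.floor(f).astype(np.int64)
        self.i0 = np.minimum(self.i0, n_bins - 2) if n_bins > 1 else self.i0 * 0
        self.w1 = f - self.i0
        self.i1 = np.minimum(self.i0 + 1, n_bins - 1)


def backproject(projections: ProjectionSet, grid: VoxelGridSpec,
                support: np.ndarray) -> TemperatureVolume:
    """Unfiltered backprojection of a projection stack onto the grid.

    Each in-support voxel of each axial slice accumulates the linearly
    interpolated projection value at its detector coordinate over all
    angles, then the sum is divided by the number of projections.
    Out-of-support voxels are zero.
    """
    n_angles, nz, n_bins = projections.images.shape
    nx, ny, nz_g = grid.shape
    if nz != nz_g:
        raise ContractError("projection row count does not match grid height")
    if support.shape != tuple(grid.shape):
        raise ContractError("support mask does not match grid")
    support2d = support.any(axis=2)
    plan = _BackprojectPlan(grid, support2d, projections.angles_deg,
                            n_bins, projections.detector_spacing)
    acc = np.zeros((nz, plan.support_flat.sum()))
    for a in range(n_angles):
        img = projections.images[a]                  # (nz, n_bins)
        acc += (img[:, plan.i0[a]] * (1.0 - plan.w1[a])
                + img[:, plan.i1[a]] * plan.w1[a])
    acc /= n_angles
    out = np.zeros((nx * ny, nz))
    out[plan.support_flat] = acc.T
    out = out.reshape(nx, ny, nz)
    out[~support] = 0.0
    return TemperatureVolume(values=out, grid=grid, support=support)


# ---------------------------------------------------------------------------
# Persistence: multi-page float TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def save_projections(projections: ProjectionSet, tiff_path) -> None:
    import json
    import tifffile

    tifffile.imwrite(str(tiff_path), projections.images.astype(np.float32))
    sidecar = str(tiff_path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"angles_deg": projections.angles_deg.tolist(),
                   "detector_spacing_m": projections.detector_spacing}, fh)


def load_projections(tiff_path) -> ProjectionSet:
    import json
    import tifffile

    images = tifffile.imread(str(tiff_path)).astype(np.float64)
    with open(str(tiff_path) + ".json") as fh:
        meta = json.load(fh)
    return ProjectionSet(images=images,
                         angles_deg=np.array(meta["angles_deg"]),
                         detector_spacing=meta["detector_spacing_m"])
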