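"""Phantom, heat-source and voxel-grid specifications.

The phantom is a homogeneous cylinder with muscle-like thermal properties
(conductivity 0.49 W/(m·°C), density 1103 kg/m³, specific heat
3322 J/(kg·°C)), radius 5 cm and height 5 cm.  Spherical heat sources of
5 mm diameter are held at a fixed temperature above the 20 °C ambient
(Dirichlet condition).  All lengths are metres, all temperatures °C.

Coordinate convention: x and y are centred on the cylinder axis, z is
measured upward from the base; voxel values live at voxel centres.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

STEFAN_BOLTZMANN = 5.670374419e-8  # W/(m^2 K^4)


class SpecificationError(ValueError):
    """An invalid phantom / source / grid specification."""


class SamplingError(RuntimeError):
    """Rejection sampling failed to produce a feasible configuration."""


class ResolutionError(ValueError):
    """A geometric feature is smaller than the voxel grid can resolve."""


@dataclass(frozen=True)
class PhantomSpec:
    """Cylindrical phantom geometry and thermal/radiative material properties."""

    radius: float = 0.05          # m
    height: float = 0.05          # m
    thermal_conductivity: float = 0.49   # W/(m·°C)
    mass_density: float = 1103.0         # kg/m³
    specific_heat: float = 3322.0        # J/(kg·°C)
    emissivity: float = 0.95             # dimensionless
    ambient_temp: float = 20.0           # °C
    initial_temp: float = 20.0           # °C

    def __post_init__(self) -> None:
        for name in ("radius", "height", "thermal_conductivity",
                     "mass_density", "specific_heat"):
            if not getattr(self, name) > 0:
                raise SpecificationError(f"{name} must be strictly positive")
        if not 0.0 < self.emissivity <= 1.0:
            raise SpecificationError("emissivity must lie in (0, 1]")
        if not math.isfinite(self.diffusivity) or self.diffusivity <= 0:
            raise SpecificationError("thermal diffusivity must be finite and positive")

    @property
    def diffusivity(self) -> float:
        """Thermal diffusivity alpha = k / (rho * Cp) in m²/s."""
        return self.thermal_conductivity / (self.mass_density * self.specific_heat)


@dataclass(frozen=True)
class HeatSource:
    """Spherical Dirichlet heat source inside the phantom.

    Position is cylindrical: radial offset ``d`` from the axis, azimuth
    ``phi`` and height ``h`` above the base.  ``delta_temp`` is the source
    temperature above ambient (°C).
    """

    radial_offset: float                 # d, m
    height: float                        # h, m
    azimuth: float = 0.0                 # phi, rad
    radius: float = 0.0025               # m (0.5 cm diameter sphere)
    delta_temp: float = 30.0             # °C above ambient

    def __post_init__(self) -> None:
        if self.delta_temp <= 0:
            raise SpecificationError("delta_temp must be > 0")
        if self.radius <= 0 or self.radial_offset < 0:
            raise SpecificationError("radius must be > 0 and radial_offset >= 0")

    def validate_inside(self, phantom: PhantomSpec) -> None:
        """Raise unless the sphere lies fully inside the cylinder."""
        if self.radial_offset + self.radius > phantom.radius + 1e-12:
            raise SpecificationError(
                f"source at (d={self.radial_offset}, h={self.height}) "
                f"exceeds the phantom radius")
        if not (self.radius - 1e-12 <= self.height
                <= phantom.height - self.radius + 1e-12):
            raise SpecificationError(
                f"source at (d={self.radial_offset}, h={self.height}) "
                f"exceeds the phantom height")

    @property
    def center_xyz(self) -> tuple[float, float, float]:
        return (self.radial_offset * math.cos(self.azimuth),
                self.radial_offset * math.sin(self.azimuth),
                self.height)


@dataclass(frozen=True)
class VoxelGridSpec:
    """Regular voxel grid spanning the phantom bounding box.

    Default: 100×100×50 voxels at 1 mm isotropic spacing, spanning the
    0.1 × 0.1 × 0.05 m bounding box of the default phantom.
    """

    shape: tuple[int, int, int] = (100, 100, 50)
    spacing: float = 0.001               # m, isotropic

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise SpecificationError("grid shape must be a positive integer triple")
        if self.spacing <= 0:
            raise SpecificationError("grid spacing must be > 0")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @classmethod
    def for_phantom(cls, phantom: PhantomSpec, spacing: float) -> "VoxelGridSpec":
        """Grid spanning the phantom bounding box at the given spacing."""
        nx = int(round(2 * phantom.radius / spacing))
        nz = int(round(phantom.height / spacing))
        return cls(shape=(nx, nx, nz), spacing=spacing)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates (x, y, z) in metres.

        x and y are centred on the cylinder axis; z runs up from the base.
        """
        nx, ny, nz = self.shape
        x = (np.arange(nx) + 0.5) * self.spacing - nx * self.spacing / 2.0
        y = (np.arange(ny) + 0.5) * self.spacing - ny * self.spacing / 2.0
        z = (np.arange(nz) + 0.5) * self.spacing
        return x, y, z

    def check_spans(self, phantom: PhantomSpec) -> None:
        nx, ny, nz = self.shape
        if not (math.isclose(nx * self.spacing, 2 * phantom.radius, rel_tol=1e-9)
                and math.isclose(ny * self.spacing, 2 * phantom.radius, rel_tol=1e-9)
                and math.isclose(nz * self.spacing, phantom.height, rel_tol=1e-9)):
            raise SpecificationError(
                "grid shape × spacing must span the phantom bounding box")


@dataclass(frozen=True)
class MultiSourceSpec:
    """One to five heat sources with a minimum pairwise centre distance."""

    sources: tuple[HeatSource, ...]
    min_center_distance: float = 0.010   # m

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        if not 1 <= len(self.sources) <= 5:
            raise SpecificationError("source count must be between 1 and 5")
        centers = np.array([s.center_xyz for s in self.sources])
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                dist = float(np.linalg.norm(centers[i] - centers[j]))
                if dist < self.min_center_distance - 1e-12:
                    raise SpecificationError(
                        f"sources {i} and {j} are {dist * 1e3:.2f} mm apart "
                        f"(minimum {self.min_center_distance * 1e3:.1f} mm)")

    @classmethod
    def single(cls, source: HeatSource) -> "MultiSourceSpec":
        return cls(sources=(source,))


# ---------------------------------------------------------------------------
# Source-configuration generators
# ---------------------------------------------------------------------------

_DEFAULT_RANGE = tuple(0.005 * i for i in range(1, 10))  # 0.5 .. 4.5 cm


def enumerate_single_source_grid(
    d_range=_DEFAULT_RANGE,
    h_range=_DEFAULT_RANGE,
    phantom: PhantomSpec | None = None,
    delta_temp: float = 30.0,
) -> list[HeatSource]:
    """Deterministic (d, h) grid of single sources at azimuth 0.

    Defaults enumerate d and h from 0.5 to 4.5 cm in 0.5 cm steps,
    yielding the 81 unique source locations.  Ordering is d-major then h.
    """
    phantom = phantom or PhantomSpec()
    d_range, h_range = list(d_range), list(h_range)
    if not d_range or not h_range:
        raise SpecificationError("d_range and h_range must be non-empty")
    sources = []
    for d in d_range:
        for h in h_range:
            src = HeatSource(radial_offset=d, height=h, azimuth=0.0,
                             delta_temp=delta_temp)
            src.validate_inside(phantom)
            sources.append(src)
    return sources


def sample_multi_source(
    rng_seed: int,
    phantom: PhantomSpec | None = None,
    n_sources_range: tuple[int, int] = (1, 5),
    dt_range: tuple[float, float] = (1.0, 5.0),
    min_center_distance: float = 0.010,
    source_radius: float = 0.0025,
    max_iter: int = 10_000,
) -> MultiSourceSpec:
    """Sample a random multi-source configuration.

    The source count is uniform on ``n_sources_range``, each temperature
    uniform on ``dt_range`` (°C), and centres are uniform over the
    admissible region (sphere strictly inside the cylinder) subject to the
    minimum pairwise centre distance, via rejection sampling.  The same
    seed always reproduces the same specification.
    """
    phantom = phantom or PhantomSpec()
    rng = np.random.default_rng(rng_seed)
    n = int(rng.integers(n_sources_range[0], n_sources_range[1] + 1))
    r_max = phantom.radius - source_radius
    h_lo, h_hi = source_radius, phantom.height - source_radius
    centers: list[np.ndarray] = []
    sources: list[HeatSource] = []
    attempts = 0
    while len(sources) < n:
        if attempts >= max_iter:
            raise SamplingError(
                f"rejection sampling exceeded {max_iter} iterations (seed {rng_seed})")
        attempts += 1
        # uniform over the admissible disk via sqrt radius transform
        d = r_max * math.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * math.pi)
        h = rng.uniform(h_lo, h_hi)
        c = np.array([d * math.cos(phi), d * math.sin(phi), h])
        if any(np.linalg.norm(c - prev) < min_center_distance for prev in centers):
            continue
        dt = float(rng.uniform(dt_range[0], dt_range[1]))
        sources.append(HeatSource(radial_offset=d, height=h, azimuth=phi,
                                  radius=source_radius, delta_temp=dt))
        centers.append(c)
    return MultiSourceSpec(sources=tuple(sources),
                           min_center_distance=min_center_distance)


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

def support_mask(phantom: PhantomSpec, grid: VoxelGridSpec) -> np.ndarray:
    """Boolean mask of voxel centres inside the cylinder cross-section."""
    x, y, _ = grid.axes()
    r2 = x[:, None] ** 2 + y[None, :] ** 2
    disk = r2 <= phantom.radius ** 2
    return np.broadcast_to(disk[:, :, None], grid.shape).copy()


def voxelize(
    phantom: PhantomSpec,
    sources: MultiSourceSpec | HeatSource,
    grid: VoxelGridSpec,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Discretize phantom support and source spheres on the voxel grid.

    Returns ``(support, per_source_masks)`` where membership is decided by
    voxel centres (stair-step geometry).  Every source mask is a subset of
    the support mask; an empty source mask raises :class:`ResolutionError`.
    """
    if isinstance(sources, HeatSource):
        sources = MultiSourceSpec.single(sources)
    support = support_mask(phantom, grid)
    x, y, z = grid.axes()
    masks = []
    for idx, src in enumerate(sources.sources):
        src.validate_inside(phantom)
        cx, cy, cz = src.center_xyz
        dist2 = ((x[:, None, None] - cx) ** 2
                 + (y[None, :, None] - cy) ** 2
                 + (z[None, None, :] - cz) ** 2)
        mask = dist2 <= src.radius ** 2
        if not mask.any():
            raise ResolutionError(
                f"source {idx} (radius {src.radius * 1e3:.2f} mm) discretizes "
                f"to zero voxels at {grid.spacing * 1e3:.2f} mm spacing")
        masks.append(mask & support)
    return support, masks


# ---------------------------------------------------------------------------
# Serialization (YAML / JSON, SI units)
# ---------------------------------------------------------------------------

def _spec_to_dict(obj) -> dict:
    if isinstance(obj, MultiSourceSpec):
        return {"sources": [asdict(s) for s in obj.sources],
                "min_center_distance": obj.min_center_distance}
    return asdict(obj)


_KINDS = {"phantom": PhantomSpec, "source": HeatSource,
          "grid": VoxelGridSpec, "multi_source": MultiSourceSpec}


def save_spec(obj, path) -> None:
    """Write a spec as YAML (or JSON if the path ends in .json)."""
    kind = next(k for k, cls in _KINDS.items() if isinstance(obj, cls))
    payload = {"kind": kind, "units": {"length": "m", "temperature": "degC"},
               "spec": _spec_to_dict(obj)}
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(payload, fh, indent=2)
        else:
            yaml.safe_dump(payload, fh, sort_keys=False)


def load_spec(path):
    path = str(path)
    with open(path) as fh:
        payload = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    kind, spec = payload["kind"], payload["spec"]
    if kind == "multi_source":
        return MultiSourceSpec(
            sources=tuple(HeatSource(**s) for s in spec["sources"]),
            min_center_distance=spec["min_center_distance"])
    if kind == "grid":
        spec = dict(spec, shape=tuple(spec["shape"]))
    return _KINDS[kind](**spec)


def rotated(source: HeatSource, angle_deg: float) -> HeatSource:
    """The same source rotated about the cylinder axis by ``angle_deg``."""
    return replace(source, azimuth=source.azimuth + math.radians(angle_deg))
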