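"""Paired-dataset construction for the reconstruction network.

Each sample is a (backprojection input, simulated ground-truth target)
pair of ΔT volumes on the same grid.  Three experiment presets are
provided:

``single_hot``
    81 single-source locations × 10 capture times (minute 15 to 60 in
    5-minute steps) at ΔT = 30 °C — 810 samples.
``single_low``
    81 locations × ΔT ∈ {1..5} °C, one capture at 300 min — 405 samples.
``multi_low``
    1000 seeded random phantoms with 1–5 sources of random 1–5 °C,
    one capture at 300 min.

Datasets are persisted as HDF5 (`/inputs`, `/targets` float32 arrays,
JSON-encoded provenance per sample) with a YAML manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .heatsim import ContractError, SolverConfig, TemperatureVolume, simulate
from .imaging import backproject, render_projections
from .phantom import (
    HeatSource,
    MultiSourceSpec,
    PhantomSpec,
    enumerate_single_source_grid,
    sample_multi_source,
)

PRESETS = ("single_hot", "single_low", "multi_low")


@dataclass
class PairedSample:
    """Backprojection input with its simulation target and provenance."""

    input: TemperatureVolume
    target: TemperatureVolume
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input.values.shape != self.target.values.shape:
            raise ContractError("input and target must share a grid")
        if not np.array_equal(self.input.support, self.target.support):
            raise ContractError("input and target must share a support mask")


@dataclass
class DatasetManifest:
    experiment: str
    n_samples: int
    seeds: dict = field(default_factory=dict)
    splits: dict = field(default_factory=dict)   # name -> list of indices

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Experiment builders
# ---------------------------------------------------------------------------

def _sample_from_simulation(phantom, spec, volume, n_angles, provenance,
                            output_spacing=None):
    if output_spacing is not None and not math.isclose(
            output_spacing, volume.grid.spacing, rel_tol=1e-9):
        from .heatsim import resample_volume

        volume = resample_volume(volume, output_spacing, phantom)
    projections = render_projections(volume, n_angles=n_angles)
    bp = backproject(projections, volume.grid, volume.support)
    bp.timestamp = volume.timestamp
    centers = [s.center_xyz for s in spec.sources]
    provenance = dict(provenance,
                      capture_time_s=volume.timestamp,
                      source_centers_xyz=[list(c) for c in centers],
                      source_delta_temps=[s.delta_temp for s in spec.sources],
                      n_sources=len(spec.sources))
    return PairedSample(input=bp, target=volume, provenance=provenance)


def iter_experiment(
    preset: str,
    solver: SolverConfig | None = None,
    phantom: PhantomSpec | None = None,
    n_angles: int = 360,
    n_multi: int = 1000,
    multi_seed_base: int = 0,
    locations: list[HeatSource] | None = None,
    output_spacing: float | None = None,
):
    """Yield the PairedSamples of an experiment preset, in order."""
    if preset not in PRESETS:
        raise ContractError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    phantom = phantom or PhantomSpec()
    if preset == "single_hot":
        solver = solver or SolverConfig()
        grid_sources = locations if locations is not None else \
            enumerate_single_source_grid(phantom=phantom, delta_temp=30.0)
        for li, src in enumerate(grid_sources):
            spec = MultiSourceSpec.single(src)
            for vol in simulate(phantom, spec, solver):
                yield _sample_from_simulation(
                    phantom, spec, vol, n_angles,
                    {"preset": preset, "location_index": li,
                     "d_m": src.radial_offset, "h_m": src.height,
                     "rotation_deg": 0.0}, output_spacing)
    elif preset == "single_low":
        solver = solver or SolverConfig(duration=300 * 60.0,
                                        capture_times=(300 * 60.0,))
        grid_sources = locations if locations is not None else \
            enumerate_single_source_grid(phantom=phantom, delta_temp=30.0)
        for li, base in enumerate(grid_sources):
            for dt in (1.0, 2.0, 3.0, 4.0, 5.0):
                src = HeatSource(radial_offset=base.radial_offset,
                                 height=base.height, azimuth=base.azimuth,
                                 radius=base.radius, delta_temp=dt)
                spec = MultiSourceSpec.single(src)
                for vol in simulate(phantom, spec, solver):
                    yield _sample_from_simulation(
                        phantom, spec, vol, n_angles,
                        {"preset": preset, "location_index": li,
                         "d_m": src.radial_offset, "h_m": src.height,
                         "delta_temp": dt, "rotation_deg": 0.0},
                        output_spacing)
    else:  # multi_low
        solver = solver or SolverConfig(duration=300 * 60.0,
                                        capture_times=(300 * 60.0,))
        for i in range(n_multi):
            spec = sample_multi_source(multi_seed_base + i, phantom=phantom)
            for vol in simulate(phantom, spec, solver):
                yield _sample_from_simulation(
                    phantom, spec, vol, n_angles,
                    {"preset": preset, "phantom_seed": multi_seed_base + i,
                     "rotation_deg": 0.0}, output_spacing)


def build_experiment(
    preset: str,
    out_path,
    solver: SolverConfig | None = None,
    phantom: PhantomSpec | None = None,
    n_angles: int = 360,
    n_multi: int = 1000,
    multi_seed_base: int = 0,
    split_seed: int = 0,
    locations: list[HeatSource] | None = None,
    output_spacing: float | None = None,
) -> DatasetManifest:
    """Build an experiment dataset, write it to HDF5, return its manifest.

    Backprojection inputs are computed once here, at build time.  The
    manifest records seeds and the 80/10/10 split assignment.
    """
    samples = list(iter_experiment(preset, solver=solver, phantom=phantom,
                                   n_angles=n_angles, n_multi=n_multi,
                                   multi_seed_base=multi_seed_base,
                                   locations=locations,
                                   output_spacing=output_spacing))
    manifest = DatasetManifest(
        experiment=preset, n_samples=len(samples),
        seeds={"multi_seed_base": multi_seed_base, "split_seed": split_seed})
    manifest.splits = partition(manifest, seed=split_seed)
    save_pairs(out_path, samples)
    return manifest


def partition(manifest: DatasetManifest, ratios=(80, 10, 10), seed: int = 0
              ) -> dict:
    """Random train/val/test assignment at the given percentage ratios.

    Deterministic under the seed; the three index lists are disjoint and
    exhaustive.  810 samples at 80/10/10 give 648/81/81.
    """
    if sum(ratios) != 100:
        raise ContractError("split ratios must sum to 100")
    n = manifest.n_samples
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(n * ratios[0] / 100.0))
    n_val = int(round(n * ratios[1] / 100.0))
    return {"train": sorted(int(i) for i in order[:n_train]),
            "val": sorted(int(i) for i in order[n_train:n_train + n_val]),
            "test": sorted(int(i) for i in order[n_train + n_val:])}


# ---------------------------------------------------------------------------
# Rotation augmentation
# ---------------------------------------------------------------------------

def rotate_volume(volume: TemperatureVolume, angle_deg: float
                  ) -> TemperatureVolume:
    """In-plane rotation of a volume about the cylinder axis.

    Slice-wise bilinear interpolation; multiples of 90° use the exact
    axis-aligned permutation; values outside the support are zeroed.
    """
    from scipy import ndimage

    angle = float(angle_deg) % 360.0
    if math.isclose(angle % 90.0, 0.0, abs_tol=1e-12):
        k = int(round(angle / 90.0)) % 4
        out = np.rot90(volume.values, k=k, axes=(0, 1)).copy()
    else:
        out = ndimage.rotate(volume.values, angle, axes=(0, 1),
                             reshape=False, order=1, mode="constant", cval=0.0)
    out[~volume.support] = 0.0
    return volume.copy_with(values=out)


def rotate_sample(sample: PairedSample, angle_deg: float) -> PairedSample:
    prov = dict(sample.provenance)
    prov["rotation_deg"] = float(prov.get("rotation_deg", 0.0) + angle_deg)
    if "source_centers_xyz" in prov:
        th = math.radians(angle_deg)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        prov["source_centers_xyz"] = [
            [*(rot @ np.array(c[:2])).tolist(), c[2]]
            for c in prov["source_centers_xyz"]]
    return PairedSample(input=rotate_volume(sample.input, angle_deg),
                        target=rotate_volume(sample.target, angle_deg),
                        provenance=prov)


def augment_epoch(samples, rng: np.random.Generator, n_rotations: int = 10):
    """Per epoch: each sample yields ``n_rotations`` randomly rotated pairs.

    The same angle is applied to the input and target of each pair;
    angles are uniform on [0°, 360°).
    """
    for sample in samples:
        angles = rng.uniform(0.0, 360.0, size=n_rotations)
        for angle in angles:
            yield rotate_sample(sample, float(angle))


def expand_test_rotations(samples, n_rotations: int = 10) -> list[PairedSample]:
    """Original plus (n_rotations − 1) rotations at 360/n_rotations° steps.

    The default expands each test case tenfold with a 36° increment
    ({0°, 36°, …, 324°}); provenance records the applied angle so the
    location-error reference can be rotated accordingly.
    """
    step = 360.0 / n_rotations
    out = []
    for sample in samples:
        for i in range(n_rotations):
            out.append(sample if i == 0 else rotate_sample(sample, i * step))
    return out


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def save_pairs(path, samples: list[PairedSample]) -> None:
    import h5py

    inputs = np.stack([s.input.values for s in samples]).astype(np.float32)
    targets = np.stack([s.target.values for s in samples]).astype(np.float32)
    meta = [json.dumps(s.provenance) for s in samples]
    with h5py.File(path, "w") as fh:
        fh.create_dataset("inputs", data=inputs)
        fh.create_dataset("targets", data=targets)
        fh.create_dataset("support", data=samples[0].input.support)
        fh.attrs["spacing_m"] = samples[0].input.grid.spacing
        fh.create_dataset("meta", data=np.array(meta, dtype=object),
                          dtype=h5py.string_dtype())


def load_pairs(path) -> list[PairedSample]:
    import h5py

    from .phantom import VoxelGridSpec

    with h5py.File(path, "r") as fh:
        inputs = fh["inputs"][...]
        targets = fh["targets"][...]
        support = fh["support"][...].astype(bool)
        spacing = float(fh.attrs["spacing_m"])
        meta = [json.loads(m) for m in fh["meta"].asstr()[...]]
    grid = VoxelGridSpec(shape=inputs.shape[1:], spacing=spacing)
    out = []
    for i in range(inputs.shape[0]):
        ts = meta[i].get("capture_time_s", 0.0)
        out.append(PairedSample(
            input=TemperatureVolume(values=inputs[i].astype(np.float64),
                                    grid=grid, support=support, timestamp=ts),
            target=TemperatureVolume(values=targets[i].astype(np.float64),
                                     grid=grid, support=support, timestamp=ts),
            provenance=meta[i]))
    return out
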