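"""Projection rendering and unfiltered backprojection."""

import numpy as np
import pytest

from thermotomo.heatsim import ContractError, TemperatureVolume
from thermotomo.imaging import (
    ProjectionSet,
    backproject,
    load_projections,
    render_projections,
    save_projections,
)
from thermotomo.phantom import PhantomSpec, VoxelGridSpec, support_mask

from conftest import gaussian_volume


def _uniform_volume(grid, support, c=3.0):
    return TemperatureVolume(values=np.where(support, c, 0.0),
                             grid=grid, support=support)


class TestRender:
    def test_uniform_surface_fills_silhouette(self, coarse_grid,
                                              coarse_support):
        vol = _uniform_volume(coarse_grid, coarse_support)
        ps = render_projections(vol, n_angles=90)
        assert ps.images.shape == (90, coarse_grid.shape[2],
                                   coarse_grid.shape[0])
        hit = ps.images != 0.0
        assert np.allclose(ps.images[hit], 3.0)
        # every detector bin sees the 10 cm silhouette
        assert hit.all()

    def test_axisymmetric_field_gives_identical_views(self, coarse_grid,
                                                      coarse_support):
        x, y, z = coarse_grid.axes()
        r2 = x[:, None, None] ** 2 + y[None, :, None] ** 2 + 0.0 * z
        vol = TemperatureVolume(
            values=np.where(coarse_support, np.exp(-r2 / 1e-4), 0.0),
            grid=coarse_grid, support=coarse_support)
        ps = render_projections(vol, n_angles=120)
        assert np.abs(ps.images - ps.images[0]).max() < 1e-6

    def test_hot_column_tracks_source_azimuth(self, coarse_grid,
                                              coarse_support):
        """A surface hot spot appears at its projected detector coordinate
        whenever it faces the camera, sweeping with the view angle."""
        x, y, _ = coarse_grid.axes()
        vals = np.zeros(coarse_grid.shape)
        spot = gaussian_volume(coarse_grid, coarse_support,
                               (0.045, 0.0, 0.025), sigma=0.004).values
        vol = TemperatureVolume(values=spot, grid=coarse_grid,
                                support=coarse_support)
        ps = render_projections(vol, n_angles=36)
        nx = coarse_grid.shape[0]
        s = (np.arange(nx) + 0.5) * ps.detector_spacing \
            - nx * ps.detector_spacing / 2.0
        peak = ps.images.max()
        seen = 0
        for a, theta in enumerate(np.radians(ps.angles_deg)):
            img = ps.images[a]
            if img.max() < 0.5 * peak:
                continue          # spot on the far side, hidden by the surface
            seen += 1
            col = img.max(axis=0).argmax()
            expected = 0.045 * np.cos(theta)   # spot at azimuth 0
            assert abs(s[col] - expected) <= 2.0 * ps.detector_spacing
        assert seen >= 10

    def test_empty_support_rejected(self, coarse_grid):
        empty = np.zeros(coarse_grid.shape, dtype=bool)
        vol = TemperatureVolume(values=np.zeros(coarse_grid.shape),
                                grid=coarse_grid, support=empty)
        with pytest.raises(ContractError):
            render_projections(vol)


class TestBackproject:
    def test_constant_projections_average_to_constant(self, coarse_grid,
                                                      coarse_support):
        n_angles, (nx, _, nz) = 48, coarse_grid.shape
        ps = ProjectionSet(images=np.full((n_angles, nz, nx), 2.0),
                           angles_deg=np.arange(n_angles) * 360.0 / n_angles,
                           detector_spacing=coarse_grid.spacing)
        bp = backproject(ps, coarse_grid, coarse_support)
        assert np.allclose(bp.values[coarse_support], 2.0)
        assert np.all(bp.values[~coarse_support] == 0.0)

    def test_linearity(self, coarse_grid, coarse_support, rng):
        nx, _, nz = coarse_grid.shape
        angles = np.arange(24) * 15.0
        im1 = rng.normal(size=(24, nz, nx))
        im2 = rng.normal(size=(24, nz, nx))
        mk = lambda im: ProjectionSet(images=im, angles_deg=angles,
                                      detector_spacing=coarse_grid.spacing)
        b1 = backproject(mk(im1), coarse_grid, coarse_support).values
        b2 = backproject(mk(im2), coarse_grid, coarse_support).values
        b12 = backproject(mk(im1 + im2), coarse_grid, coarse_support).values
        assert np.allclose(b12, b1 + b2, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        """Naive per-voxel angle-loop oracle on a small 20×20×5 grid."""
        grid = VoxelGridSpec(shape=(20, 20, 5), spacing=0.005)
        support = np.zeros(grid.shape, dtype=bool)
        x, y, _ = grid.axes()
        support[(x[:, None] ** 2 + y[None, :] ** 2 <= 0.05 ** 2), :] = True
        angles = np.arange(24) * 15.0
        images = rng.normal(size=(24, 5, 20))
        ps = ProjectionSet(images=images, angles_deg=angles,
                           detector_spacing=grid.spacing)
        got = backproject(ps, grid, support).values

        c0 = (0.5) * grid.spacing - 20 * grid.spacing / 2.0
        expected = np.zeros(grid.shape)
        for a, ang in enumerate(angles):
            th = np.radians(ang)
            for i in range(20):
                for j in range(20):
                    if not support[i, j, 0]:
                        continue
                    f = (x[i] * np.cos(th) + y[j] * np.sin(th)
                         - c0) / grid.spacing
                    f = min(max(f, 0.0), 19.0)
                    i0 = min(int(np.floor(f)), 18)
                    w = f - i0
                    for k in range(5):
                        expected[i, j, k] += (images[a, k, i0] * (1 - w)
                                              + images[a, k, i0 + 1] * w)
        expected /= len(angles)
        expected[~support] = 0.0
        assert np.abs(got - expected).max() < 1e-9

    def test_values_within_projection_sample_range(self, coarse_grid,
                                                   coarse_support, rng):
        nx, _, nz = coarse_grid.shape
        images = rng.uniform(1.0, 4.0, size=(36, nz, nx))
        ps = ProjectionSet(images=images, angles_deg=np.arange(36) * 10.0,
                           detector_spacing=coarse_grid.spacing)
        bp = backproject(ps, coarse_grid, coarse_support)
        vals = bp.values[coarse_support]
        assert vals.min() >= images.min() - 1e-12
        assert vals.max() <= images.max() + 1e-12

    def test_angle_offset_invariance_for_axisymmetric_volume(
            self, coarse_grid, coarse_support):
        vol = gaussian_volume(coarse_grid, coarse_support, (0.0, 0.0, 0.025),
                              sigma=0.020)
        ps = render_projections(vol, n_angles=90)
        shifted = ProjectionSet(images=np.roll(ps.images, 7, axis=0),
                                angles_deg=ps.angles_deg,
                                detector_spacing=ps.detector_spacing)
        b0 = backproject(ps, coarse_grid, coarse_support).values
        b1 = backproject(shifted, coarse_grid, coarse_support).values
        assert np.abs(b1 - b0).max() <= 1e-3 * vol.values.max()

    def test_mismatched_angle_count_rejected(self, coarse_grid,
                                             coarse_support):
        nx, _, nz = coarse_grid.shape
        with pytest.raises(ContractError):
            ProjectionSet(images=np.zeros((10, nz, nx)),
                          angles_deg=np.arange(9) * 10.0,
                          detector_spacing=coarse_grid.spacing)


class TestRoundTrip:
    def test_render_backproject_localizes_source_azimuth(self, offaxis_volume,
                                                         offaxis_source):
        """Backprojection smears heat radially toward the rim (the surface
        is where the camera sees it), but stays centred on the source's
        radial axis: the (x, y) maximum lies within 10 mm of the line from
        the cylinder axis through the source centre."""
        ps = render_projections(offaxis_volume, n_angles=120)
        bp = backproject(ps, offaxis_volume.grid, offaxis_volume.support)
        idx = np.unravel_index(np.argmax(bp.values), bp.values.shape)
        x, y, _ = bp.grid.axes()
        p = np.array([x[idx[0]], y[idx[1]]])
        cx, cy, _ = offaxis_source.center_xyz
        axis_dir = np.array([cx, cy]) / np.hypot(cx, cy)
        along = float(p @ axis_dir)
        perp = float(np.linalg.norm(p - along * axis_dir))
        assert along > 0            # same half-plane as the source
        assert perp <= 0.010

    def test_tiff_round_trip(self, coarse_grid, coarse_support, tmp_path):
        vol = _uniform_volume(coarse_grid, coarse_support)
        ps = render_projections(vol, n_angles=30)
        save_projections(ps, tmp_path / "proj.tiff")
        again = load_projections(tmp_path / "proj.tiff")
        assert np.allclose(again.images, ps.images, atol=1e-6)
        assert np.array_equal(again.angles_deg, ps.angles_deg)
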