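"""Reconstruction-quality metric definitions and report summaries."""

import numpy as np
import pytest

from thermotomo.heatsim import ContractError, TemperatureVolume
from thermotomo.metrics import (
    PSNR_CAP_DB,
    cc,
    evaluate_pairs,
    hsle,
    nmse,
    psnr,
    ssim,
    summarize,
)

from conftest import gaussian_volume


def _toy_volumes(coarse_grid, coarse_support, rng, noise=0.0):
    ref = gaussian_volume(coarse_grid, coarse_support, (0.01, 0.0, 0.025))
    rec = ref.copy_with(values=ref.values
                        + noise * rng.normal(size=ref.values.shape)
                        * coarse_support)
    return rec, ref


class TestNmse:
    def test_identical_volumes_zero(self, coarse_grid, coarse_support, rng):
        rec, ref = _toy_volumes(coarse_grid, coarse_support, rng)
        assert nmse(rec, ref) == 0.0

    def test_doubled_reconstruction_is_one(self, coarse_grid, coarse_support, rng):
        _, ref = _toy_volumes(coarse_grid, coarse_support, rng)
        rec = ref.copy_with(values=2.0 * ref.values)
        assert nmse(rec, ref) == pytest.approx(1.0, rel=1e-12)

    def test_three_voxel_hand_computation(self):
        # ref (1,2,3), recon (1,2,4): error 1, sum ref^2 = 14
        assert nmse(np.array([1.0, 2.0, 4.0]),
                    np.array([1.0, 2.0, 3.0])) == pytest.approx(1.0 / 14.0)

    def test_all_zero_reference_rejected(self, coarse_grid, coarse_support):
        zero = TemperatureVolume(values=np.zeros(coarse_grid.shape),
                                 grid=coarse_grid, support=coarse_support)
        with pytest.raises(ContractError):
            nmse(zero, zero)


class TestCc:
    def test_identical_volumes_one(self, coarse_grid, coarse_support, rng):
        rec, ref = _toy_volumes(coarse_grid, coarse_support, rng)
        assert cc(rec, ref) == pytest.approx(1.0)

    def test_negated_shifted_is_minus_one(self, coarse_grid, coarse_support, rng):
        _, ref = _toy_volumes(coarse_grid, coarse_support, rng)
        rec = ref.copy_with(values=(-ref.values + 5.0) * coarse_support)
        assert cc(rec, ref) == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self, rng):
        a = rng.normal(size=200)
        b = 0.3 * a + rng.normal(size=200)
        n = len(a)
        manual = ((a * b).sum() - n * a.mean() * b.mean()) / (
            np.sqrt((a ** 2).sum() - n * a.mean() ** 2)
            * np.sqrt((b ** 2).sum() - n * b.mean() ** 2))
        assert cc(a, b) == pytest.approx(manual, abs=1e-12)


class TestPsnr:
    def test_identical_volumes_hit_cap(self, coarse_grid, coarse_support, rng):
        rec, ref = _toy_volumes(coarse_grid, coarse_support, rng)
        assert psnr(rec, ref) == PSNR_CAP_DB

    def test_closed_form_twenty_db(self):
        # peak 30, MSE 9 -> 10 log10(900/9) = 20 dB
        ref = np.full(100, 30.0)
        rec = ref + 3.0
        assert psnr(rec, ref) == pytest.approx(20.0, abs=1e-12)

    def test_halving_mse_adds_three_db(self, coarse_grid, coarse_support, rng):
        _, ref = _toy_volumes(coarse_grid, coarse_support, rng)
        e = rng.normal(size=ref.values.shape) * coarse_support
        p1 = psnr(ref.copy_with(values=ref.values + e), ref)
        p2 = psnr(ref.copy_with(values=ref.values + e / np.sqrt(2.0)), ref)
        assert p2 - p1 == pytest.approx(10.0 * np.log10(2.0), abs=1e-9)

    def test_monotone_in_noise_amplitude(self, coarse_grid, coarse_support, rng):
        _, ref = _toy_volumes(coarse_grid, coarse_support, rng)
        e = rng.normal(size=ref.values.shape) * coarse_support
        values = [psnr(ref.copy_with(values=ref.values + a * e), ref)
                  for a in (0.1, 0.2, 0.4, 0.8, 1.6)]
        assert all(x > y for x, y in zip(values, values[1:]))


class TestSsim:
    def test_identical_volumes_one(self, coarse_grid, coarse_support, rng):
        rec, ref = _toy_volumes(coarse_grid, coarse_support, rng)
        assert ssim(rec, ref) == pytest.approx(1.0)

    def test_bounded_on_random_pairs(self, rng):
        for _ in range(50):
            a = rng.normal(size=(16, 16, 3))
            b = rng.normal(size=(16, 16, 3))
            assert -1.0 <= ssim(a, np.abs(b) + 0.1) <= 1.0

    def test_matches_independent_implementation(self, rng):
        """Oracle: directly coded Gaussian-window SSIM on one slice."""
        from scipy.ndimage import gaussian_filter

        a = np.abs(rng.normal(size=(24, 24, 1))) + 0.5
        b = a + 0.2 * rng.normal(size=(24, 24, 1))
        peak = float(a.max())
        c1, c2 = (0.01 * peak) ** 2, (0.03 * peak) ** 2
        x, y = a[:, :, 0], b[:, :, 0]
        blur = lambda im: gaussian_filter(im, sigma=1.5, truncate=3.5)
        mx, my = blur(x), blur(y)
        vx = blur(x * x) - mx ** 2
        vy = blur(y * y) - my ** 2
        vxy = blur(x * y) - mx * my
        smap = ((2 * mx * my + c1) * (2 * vxy + c2)
                / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
        pad = 5  # skimage crops the filter-radius border before averaging
        oracle = float(smap[pad:-pad, pad:-pad].mean())
        assert ssim(b, a) == pytest.approx(oracle, abs=1e-9)


class TestHsle:
    def test_ground_truth_recovers_center(self, coarse_grid, coarse_support):
        center = (0.012, -0.004, 0.022)
        vol = gaussian_volume(coarse_grid, coarse_support, center, sigma=0.006)
        assert hsle(vol, center) <= 0.5

    def test_bounded_by_half_voxel_diagonal(self, centered_volume,
                                            centered_source):
        err = hsle(centered_volume, centered_source.center_xyz)
        half_diag = np.sqrt(3.0) * centered_volume.grid.spacing * 1e3 / 2.0
        assert err <= half_diag

    def test_translation_returns_distance(self, coarse_grid, coarse_support):
        center = (0.0, 0.0, 0.025)
        vol = gaussian_volume(coarse_grid, coarse_support, center, sigma=0.006)
        shifted = vol.copy_with(values=np.roll(vol.values, 5, axis=0))
        shift_mm = 5 * coarse_grid.spacing * 1e3
        assert hsle(shifted, center) == pytest.approx(shift_mm, abs=0.3)

    def test_rotation_equivariance(self):
        from thermotomo.dataset import rotate_volume
        from thermotomo.phantom import PhantomSpec, VoxelGridSpec, support_mask

        # production 1 mm grid: interpolation error stays sub-voxel
        phantom = PhantomSpec()
        grid = VoxelGridSpec.for_phantom(phantom, 0.001)
        support = support_mask(phantom, grid)
        center = np.array([0.015, 0.0, 0.025])
        vol = gaussian_volume(grid, support, center, sigma=0.006)
        e0 = hsle(vol, center)
        th = np.radians(36.0)
        rot_center = (center[0] * np.cos(th), center[0] * np.sin(th), center[2])
        e1 = hsle(rotate_volume(vol, 36.0), rot_center)
        assert abs(e1 - e0) <= 0.2


class TestRotationInvariance:
    def test_intensity_metrics_stable_under_common_rotation(
            self, coarse_grid, coarse_support, rng):
        """Smooth fields: bilinear rotation barely perturbs the metrics
        (white noise would be smoothed away by interpolation)."""
        from thermotomo.dataset import rotate_volume

        ref = gaussian_volume(coarse_grid, coarse_support, (0.01, 0.0, 0.025))
        rec = gaussian_volume(coarse_grid, coarse_support,
                              (0.013, 0.002, 0.027), sigma=0.011)
        before = (nmse(rec, ref), psnr(rec, ref), ssim(rec, ref))
        rrec, rref = rotate_volume(rec, 36.0), rotate_volume(ref, 36.0)
        after = (nmse(rrec, rref), psnr(rrec, rref), ssim(rrec, rref))
        for b, a in zip(before, after):
            assert a == pytest.approx(b, rel=0.05)


class TestReport:
    def test_perfect_reconstructions(self, coarse_grid, coarse_support, rng):
        rec, ref = _toy_volumes(coarse_grid, coarse_support, rng)
        report = evaluate_pairs([rec, rec], [ref, ref],
                                true_centers=[(0.01, 0.0, 0.025)] * 2)
        assert report.summary["nmse"]["mean"] == 0.0
        assert report.summary["cc"]["mean"] == pytest.approx(1.0)
        assert report.summary["ssim"]["mean"] == pytest.approx(1.0)

    def test_summary_columns_and_recomputation(self, coarse_grid,
                                               coarse_support, rng, tmp_path):
        import pandas as pd

        rec, ref = _toy_volumes(coarse_grid, coarse_support, rng, noise=0.2)
        report = evaluate_pairs([rec] * 3, [ref] * 3)
        for metric in ("nmse", "cc", "psnr", "ssim"):
            assert set(report.summary[metric]) == {
                "mean", "std", "median", "p25", "p75"}
        report.to_csv(tmp_path / "per_sample.csv")
        again = summarize(pd.read_csv(tmp_path / "per_sample.csv"))
        for metric, stats in report.summary.items():
            for key, val in stats.items():
                assert again[metric][key] == pytest.approx(val, abs=1e-10)

    def test_hsle_omitted_without_centers(self, coarse_grid, coarse_support,
                                          rng):
        rec, ref = _toy_volumes(coarse_grid, coarse_support, rng, noise=0.1)
        report = evaluate_pairs([rec], [ref], true_centers=[None])
        assert "hsle" not in report.per_sample.columns


from hypothesis import given, settings
from hypothesis import strategies as st


class TestMetricProperties:
    """Algebraic properties over randomized inputs."""

    @staticmethod
    @given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_nmse_scales_quadratically_in_error(scale, seed):
        rng = np.random.default_rng(seed)
        ref = np.abs(rng.normal(size=50)) + 0.5
        err = rng.normal(size=50)
        base = nmse(ref + err, ref)
        assert nmse(ref + scale * err, ref) == pytest.approx(
            scale ** 2 * base, rel=1e-9)

    @staticmethod
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_cc_invariant_under_affine_rescaling(seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        assert cc(3.0 * a + 7.0, b) == pytest.approx(cc(a, b), abs=1e-9)
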