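"""Volumetric reconstruction-quality metrics.

Five measures compare a reconstructed ΔT volume against its simulated
ground truth: normalized mean square error (NMSE), Pearson correlation
coefficient (CC), peak signal-to-noise ratio (PSNR, dB), structural
similarity (SSIM, slice-wise 2D with a Gaussian window), and the heat
source location error (HSLE, mm) — the Euclidean distance between the
true source centre and the reconstructed hot-spot midpoint.

All intensity metrics are computed over support voxels only: the
background is identically zero in both volumes and would otherwise
inflate correlation-type scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heatsim import ContractError, TemperatureVolume

PSNR_CAP_DB = 100.0   # reported for exact (zero-MSE) reconstructions


def _pair(recon, reference):
    if isinstance(recon, TemperatureVolume):
        support = recon.support
        recon = recon.values
    else:
        support = None
    if isinstance(reference, TemperatureVolume):
        support = reference.support if support is None else support
        reference = reference.values
    recon = np.asarray(recon, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if recon.shape != reference.shape:
        raise ContractError("volumes must share a shape")
    if support is None:
        support = np.ones(recon.shape, dtype=bool)
    return recon, reference, support


def nmse(recon, reference) -> float:
    """Σ(recon − ref)² / Σ ref² over support voxels."""
    r, g, sup = _pair(recon, reference)
    denom = float((g[sup] ** 2).sum())
    if denom == 0.0:
        raise ContractError("reference is all-zero over the support")
    return float(((r[sup] - g[sup]) ** 2).sum() / denom)


def cc(recon, reference) -> float:
    """Pearson correlation over support voxels."""
    r, g, sup = _pair(recon, reference)
    rv, gv = r[sup], g[sup]
    if rv.std() == 0.0 or gv.std() == 0.0:
        raise ContractError("correlation requires nonzero variance")
    return float(np.corrcoef(rv, gv)[0, 1])


def psnr(recon, reference) -> float:
    """10·log₁₀(peak² / MSE) in dB; peak is the reference maximum.

    Identical volumes (zero MSE) are reported as the documented cap of
    100 dB so summary statistics stay finite.
    """
    r, g, sup = _pair(recon, reference)
    peak = float(g.max())
    if peak <= 0.0:
        raise ContractError("reference peak must be positive")
    mse = float(((r[sup] - g[sup]) ** 2).mean())
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, float(10.0 * np.log10(peak ** 2 / mse)))


def ssim(recon, reference) -> float:
    """Mean slice-wise 2D SSIM with a Gaussian window (σ = 1.5).

    Stability constants K₁ = 0.01, K₂ = 0.03; dynamic range is the
    reference volume's peak.  Each axial slice is scored in 2D and the
    slice scores are averaged.
    """
    from skimage.metrics import structural_similarity

    r, g, sup = _pair(recon, reference)
    if min(r.shape[0], r.shape[1]) < 7:
        raise ContractError("slices are too small for the 7x7 SSIM window")
    peak = float(g.max())
    if peak <= 0.0:
        raise ContractError("reference peak must be positive")
    scores = [
        structural_similarity(
            g[:, :, k], r[:, :, k], data_range=peak,
            gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
            K1=0.01, K2=0.03)
        for k in range(r.shape[2])
    ]
    return float(np.mean(scores))


def hsle(recon: TemperatureVolume, true_center_xyz, threshold: float = 0.90
         ) -> float:
    """Heat source location error in millimetres (single-source only).

    The reconstructed midpoint is the intensity-weighted centroid of all
    voxels at or above ``threshold`` × the volume maximum; the result is
    its Euclidean distance to the true source centre.  Sub-voxel
    localization comes from the weighting.
    """
    if not isinstance(recon, TemperatureVolume):
        raise ContractError("hsle requires a TemperatureVolume")
    vals = np.where(recon.support, recon.values, -np.inf)
    vmax = float(vals.max())
    if not np.isfinite(vmax) or vmax <= 0:
        raise ContractError("reconstruction has no positive values in support")
    mask = vals >= threshold * vmax
    w = np.where(mask, recon.values, 0.0)
    x, y, z = recon.grid.axes()
    total = w.sum()
    cx = (w.sum(axis=(1, 2)) * x).sum() / total
    cy = (w.sum(axis=(0, 2)) * y).sum() / total
    cz = (w.sum(axis=(0, 1)) * z).sum() / total
    d = np.array([cx, cy, cz]) - np.asarray(true_center_xyz, dtype=np.float64)
    return float(np.linalg.norm(d) * 1e3)


# ---------------------------------------------------------------------------
# Dataset-level report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-sample metric values plus the summary layout of the result tables:
    mean ± SD, median and the 25–75 percentile range per metric."""

    per_sample: "object"                 # pandas DataFrame, one row per case
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary:
            self.summary = summarize(self.per_sample)

    def to_csv(self, per_sample_path, summary_path=None) -> None:
        import pandas as pd

        self.per_sample.to_csv(per_sample_path, index=False)
        if summary_path is not None:
            pd.DataFrame(self.summary).T.to_csv(summary_path)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.summary, fh, indent=2)


def summarize(per_sample) -> dict:
    """Mean ± SD / median / 25–75 percentile summaries per metric column."""
    out = {}
    for col in per_sample.columns:
        if col in ("case", "rotation_deg"):
            continue
        v = per_sample[col].dropna().to_numpy(dtype=float)
        if v.size == 0:
            continue
        out[col] = {
            "mean": float(v.mean()),
            "std": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "median": float(np.median(v)),
            "p25": float(np.percentile(v, 25)),
            "p75": float(np.percentile(v, 75)),
        }
    return out


def evaluate_pairs(recons, targets, true_centers=None, case_ids=None
                   ) -> MetricsReport:
    """Score a list of reconstruction/ground-truth pairs.

    ``true_centers`` supplies per-case single-source centres for the HSLE
    column; pass ``None`` (or per-case None entries, e.g. multi-source
    phantoms) to omit HSLE, as the location error is only defined for
    single-source setups.
    """
    import pandas as pd

    rows = []
    for i, (r, g) in enumerate(zip(recons, targets)):
        row = {"case": case_ids[i] if case_ids is not None else i,
               "nmse": nmse(r, g), "cc": cc(r, g), "psnr": psnr(r, g),
               "ssim": ssim(r, g)}
        if true_centers is not None and true_centers[i] is not None:
            row["hsle"] = hsle(r, true_centers[i])
        rows.append(row)
    return MetricsReport(per_sample=pd.DataFrame(rows))
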