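"""Quantitative evaluation of the scanning strategies against ground truth.

Covers: dose accounting (full scan / tight bounding box / shell-scan /
propagative scan, as percentages of the full voxel space), the fraction
of epithelial bright voxels captured by the estimated shell, the fraction
of bright contour pixels recovered in a strategy's maximum-intensity
projection, and the photobleaching comparison of a hybrid half-full-scan
/ half-shell-scan acquisition.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .acquisition import DoseLedger, oracle_from_stack
from .phantom import GroundTruth
from .surface import Shell, SurfaceModel, build_shell

__all__ = ["ground_truth_shell", "bright_capture", "contour_capture",
           "dose_table", "bleaching_curves"]


def ground_truth_shell(gt: GroundTruth, epsilon: float = 3.0) -> Shell:
    """Voxelize the true surface into the reference shell."""
    surf = SurfaceModel(z=gt.z_true, support=gt.tissue_mask)
    return build_shell(surf, epsilon, gt.config.nz, gt.config.dz)


def bright_capture(estimated_shell: Shell, gt: GroundTruth,
                   gt_shell: Optional[Shell] = None,
                   epsilon: float = 3.0) -> float:
    """% of epithelial bright voxels (bright voxels inside the ground-truth
    shell) that fall in the estimated shell."""
    if gt_shell is None:
        gt_shell = ground_truth_shell(gt, epsilon)
    bright = np.argwhere(gt.bright_mask)
    if len(bright) == 0:
        raise ValueError("phantom has no bright voxels")
    epithelial = bright[gt_shell.contains(bright)]
    if len(epithelial) == 0:
        raise ValueError("no bright voxel lies in the ground-truth shell")
    captured = estimated_shell.contains(epithelial)
    return 100.0 * float(captured.sum()) / len(epithelial)


def contour_capture(strategy_mip: np.ndarray, gt_mip: np.ndarray, T: float) -> float:
    """% of bright ground-truth MIP pixels also bright in the strategy MIP.

    "Bright" means normalized value strictly above T in both projections
    (NaN, i.e. never acquired, is not bright).
    """
    with np.errstate(invalid="ignore"):
        gt_bright = gt_mip > T
        s_bright = strategy_mip > T
    n_gt = int(gt_bright.sum())
    if n_gt == 0:
        raise ValueError("ground-truth projection has no bright pixel")
    return 100.0 * int((gt_bright & s_bright).sum()) / n_gt


def tight_bounding_box_fraction(gt: GroundTruth, epsilon: float = 3.0) -> float:
    """Voxel fraction of the tight 3D bounding box around the tissue:
    lateral extents of the tissue mask, z extent of the surface padded by
    half a shell thickness."""
    cfg = gt.config
    if not gt.tissue_mask.any():
        return 0.0
    xs, ys = np.nonzero(gt.tissue_mask)
    ex = int(xs.max() - xs.min() + 1)
    ey = int(ys.max() - ys.min() + 1)
    zvals = gt.z_true[gt.tissue_mask]
    zlo = max(int(np.floor((np.nanmin(zvals) - epsilon / 2) / cfg.dz)), 0)
    zhi = min(int(np.ceil((np.nanmax(zvals) + epsilon / 2) / cfg.dz)), cfg.nz - 1)
    ez = zhi - zlo + 1
    return ex * ey * ez / cfg.n_voxels


def dose_table(ledgers: dict[str, DoseLedger], gt: GroundTruth,
               epsilon: float = 3.0) -> pd.DataFrame:
    """Scanned-volume percentages per strategy, plus the full-scan (100%)
    and tight-bounding-box reference rows."""
    rows = [("full scan", 100.0),
            ("tight bounding box", 100.0 * tight_bounding_box_fraction(gt, epsilon))]
    for name, ledger in ledgers.items():
        rows.append((name, 100.0 * ledger.dose_fraction))
    return pd.DataFrame(rows, columns=["strategy", "scanned_volume_pct"])


def bleaching_curves(gt: GroundTruth, epsilon: float = 3.0,
                     bleach_rate: Optional[float] = None,
                     n_frames: int = 10) -> pd.DataFrame:
    """Hybrid time series: left half of the field imaged by full scan,
    right half by shell-scan, for ``n_frames`` repeated acquisitions.

    Per frame and half, the mean of the raw maximum-intensity projection
    over the ground-truth shell is reported, relative to its first-frame
    value.  With bleaching on, the full-scan half decays strictly faster
    because every frame exposes each of its columns nz times versus the
    shell-scan half's n_layers times.
    """
    cfg = gt.config
    b = cfg.bleach_rate if bleach_rate is None else bleach_rate
    oracle = oracle_from_stack(gt.volume, bleach_rate=b)
    shell = ground_truth_shell(gt, epsilon)
    nx, ny, nz = cfg.shape
    half_x = nx // 2
    full_cols = shell.support.copy()
    full_cols[half_x:, :] = False
    shell_cols = shell.support.copy()
    shell_cols[:half_x, :] = False

    shell_coords = shell.all_coords()
    left = shell_coords[:, 0] < half_x
    # full-scan half: every z of its columns; shell half: shell voxels only
    xs, ys = np.nonzero(full_cols)
    full_coords = np.column_stack([
        np.repeat(xs, nz), np.repeat(ys, nz), np.tile(np.arange(nz), len(xs))])
    records = []
    ref = {}
    for frame in range(n_frames):
        vals_full = oracle.read(full_coords) if len(full_coords) else np.empty(0)
        vals_shell = oracle.read(shell_coords[~left]) if (~left).any() else np.empty(0)
        mip_full = np.full((nx, ny), np.nan)
        if len(full_coords):
            inshell = shell.contains(full_coords)
            c = full_coords[inshell]
            np.fmax.at(mip_full, (c[:, 0], c[:, 1]), vals_full[inshell])
        mip_shell = np.full((nx, ny), np.nan)
        if (~left).any():
            c = shell_coords[~left]
            np.fmax.at(mip_shell, (c[:, 0], c[:, 1]), vals_shell)
        m_full = float(np.nanmean(mip_full[full_cols])) if full_cols.any() else np.nan
        m_shell = float(np.nanmean(mip_shell[shell_cols])) if shell_cols.any() else np.nan
        if frame == 0:
            ref = {"full": m_full, "shell": m_shell}
        records.append({"frame": frame,
                        "full_scan_mean_mip": m_full / ref["full"],
                        "shell_scan_mean_mip": m_shell / ref["shell"]})
    return pd.DataFrame(records)
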