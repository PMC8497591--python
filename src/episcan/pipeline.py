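"""End-to-end surface estimation: pre-scan -> normalization -> detection
-> robust surface fit -> shell.

This is the shared front end of both scanning strategies; the shell and
the frozen normalization model it returns feed directly into
:func:`episcan.scans.shell_scan` and :func:`episcan.scans.propagative_scan`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .acquisition import DoseLedger, SampleSet, VoxelOracle, acquire, oracle_from_stack
from .phantom import Volume
from .prescan import (DetectionParams, NormalizationModel, detect_bright,
                      draw_prescan, fit_background, normalize)
from .surface import Shell, SurfaceModel, build_shell, estimate_surface

__all__ = ["ShellEstimate", "estimate_shell"]


@dataclass
class ShellEstimate:
    """Everything the pre-scan stage produces."""

    prescan: SampleSet
    model: NormalizationModel
    params: DetectionParams
    bright: SampleSet
    surface: SurfaceModel
    shell: Shell
    oracle: VoxelOracle
    ledger: DoseLedger


def estimate_shell(volume: Volume | VoxelOracle,
                   eta: float = 0.001,
                   pfa: float = 0.01,
                   epsilon: float = 3.0,
                   seed: int = 0,
                   width_fraction: float = 1 / 3,
                   overlap_fraction: float = 0.5,
                   ransac_trials: int = 500,
                   inlier_tol: Optional[float] = None,
                   outlier_removal: bool = True,
                   ledger: Optional[DoseLedger] = None) -> ShellEstimate:
    """Run the fractional pre-scan and estimate the epsilon-shell.

    ``volume`` may be a dense stack (emulation mode) or an existing
    oracle.  The RANSAC inlier tolerance defaults to ``epsilon / 2`` so
    that inliers are exactly the shell-compatible points.
    """
    oracle = volume if isinstance(volume, VoxelOracle) else oracle_from_stack(volume)
    shape = oracle.shape
    if ledger is None:
        ledger = DoseLedger(shape)
    ss = np.random.SeedSequence(seed)
    s_draw, s_fit = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))

    coords = draw_prescan(shape, eta, s_draw)
    prescan = acquire(oracle, coords, ledger, iteration=0)
    model = fit_background(prescan, shape=shape)
    prescan = normalize(prescan, model)
    params = DetectionParams.from_pfa(pfa, eta)
    bright = detect_bright(prescan, params.T)

    dz = oracle.volume.pitch[2]
    surf, _, _ = estimate_surface(
        bright.coords[:, :2].astype(float),
        bright.coords[:, 2].astype(float) * dz,
        lateral_shape=shape[:2],
        width_fraction=width_fraction,
        overlap_fraction=overlap_fraction,
        n_trials=ransac_trials,
        inlier_tol=epsilon / 2 if inlier_tol is None else inlier_tol,
        outlier_removal=outlier_removal,
        seed=s_fit)
    shell = build_shell(surf, epsilon, shape[2], dz)
    return ShellEstimate(prescan=prescan, model=model, params=params,
                         bright=bright, surface=surf, shell=shell,
                         oracle=oracle, ledger=ledger)
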