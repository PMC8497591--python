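"""The two smart-scanning strategies, executed against a voxel oracle.

The *shell-scan* exhaustively acquires the thin shell around the
estimated surface.  The *propagative scan* acquires far fewer voxels: it
iteratively extrapolates the normalized intensity of unexplored shell
voxels from their nearest acquired neighbour within the same shell layer
(xy-Euclidean distance, capped at ``beta`` pixels), acquires only the
voxels predicted bright (prediction > T, one voxel per lateral column per
iteration, skipping columns where a brighter voxel is already acquired),
and stops at the first iteration without new acquisitions.  Because the
nearest-neighbour rule tends to follow lines, the scan path naturally
propagates along the bright cell contours.

Normalization parameters are frozen from the pre-scan for all iterations;
they are never refit mid-scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .acquisition import DoseLedger, SampleSet, VoxelOracle, acquire
from .prescan import NormalizationModel, normalize
from .surface import Shell

__all__ = ["PropagativeParams", "ScanState", "ScanResult", "shell_scan",
           "seed_in_shell", "nn_predict", "select_new_acquisitions",
           "propagative_scan", "max_intensity_projection"]


@dataclass
class PropagativeParams:
    """Settings of the propagative scan.

    ``beta`` is the maximum nearest-neighbour prediction distance in xy
    pixels; ``n0`` the number of additional random in-shell seeds acquired
    at iteration 1 (None means: same budget as the pre-scan).
    """

    T: float
    beta: float = 1.0
    n0: Optional[int] = None
    max_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1 pixel")
        if self.n0 is not None and self.n0 < 0:
            raise ValueError("n0 must be >= 0")


class ScanState:
    """Growing acquisition set of a propagative scan.

    Within one layer every lateral column holds at most one voxel, so the
    acquired normalized values live on ``(n_layers, nx, ny)`` maps with
    NaN marking unexplored positions.  ``best_col`` is the highest
    normalized intensity acquired in the shell so far per column (shell
    voxels only); ``acq_count`` counts acquisitions along z per column,
    including pre-scan points anywhere in the stack.
    """

    def __init__(self, shell: Shell):
        self.shell = shell
        nx, ny = shell.z0.shape
        self.values = np.full((shell.n_layers, nx, ny), np.nan, dtype=np.float32)
        self.best_col = np.full((nx, ny), np.nan, dtype=np.float32)
        self.acq_count = np.zeros((nx, ny), dtype=np.int32)
        self.iteration = 0
        self.per_iteration_counts: list[int] = []
        self._parts: list[SampleSet] = []

    @property
    def layer_valid(self) -> np.ndarray:
        masks = []
        for off in self.shell.layer_offsets:
            valid, _ = self.shell.layer_plane(off)
            masks.append(valid)
        return np.stack(masks)

    def ingest(self, samples: SampleSet) -> int:
        """Record acquired samples; returns the number of newly explored
        shell voxels."""
        if samples.normalized is None:
            raise ValueError("samples must carry normalized intensities")
        self._parts.append(samples)
        coords = samples.coords
        np.add.at(self.acq_count, (coords[:, 0], coords[:, 1]), 1)
        inside = self.shell.contains(coords)
        if not inside.any():
            return 0
        c = coords[inside]
        r = samples.normalized[inside].astype(np.float32)
        layer = self.shell.layer_of(c) + self.shell.half_layers
        fresh = np.isnan(self.values[layer, c[:, 0], c[:, 1]])
        self.values[layer, c[:, 0], c[:, 1]] = r
        np.fmax.at(self.best_col, (c[:, 0], c[:, 1]), r)
        # count distinct voxels newly explored (duplicates within the batch
        # would each see NaN before assignment, so dedupe)
        new_coords = c[fresh]
        if len(new_coords) == 0:
            return 0
        return len(np.unique(new_coords, axis=0))

    def samples(self) -> SampleSet:
        return SampleSet.concatenate(self._parts)


@dataclass
class ScanResult:
    """Sparse outcome of a scan: unacquired voxels are missing, not zero."""

    samples: SampleSet
    mip: np.ndarray
    acquisitions_per_column: np.ndarray
    dose: dict
    per_iteration_counts: Optional[list[int]] = None
    converged: Optional[bool] = None

    @property
    def n_acquired(self) -> int:
        return int(self.dose["n_unique"])


def shell_scan(oracle: VoxelOracle, shell: Shell, model: NormalizationModel,
               ledger: DoseLedger) -> ScanResult:
    """Acquire every shell voxel exactly once."""
    coords = shell.all_coords()
    if len(coords) == 0:
        raise ValueError("shell is empty: nothing to scan")
    samples = acquire(oracle, coords, ledger, iteration=1)
    samples = normalize(samples, model)
    nx, ny = shell.z0.shape
    mip = np.full((nx, ny), np.nan, dtype=np.float32)
    np.fmax.at(mip, (coords[:, 0], coords[:, 1]), samples.normalized.astype(np.float32))
    counts = np.zeros((nx, ny), dtype=np.int32)
    np.add.at(counts, (coords[:, 0], coords[:, 1]), 1)
    return ScanResult(samples=samples, mip=mip, acquisitions_per_column=counts,
                      dose=ledger.snapshot())


def seed_in_shell(shell: Shell, n0: int, seed: int | np.random.Generator) -> np.ndarray:
    """``n0`` distinct voxels drawn uniformly over the shell."""
    if shell.n_voxels() == 0:
        raise ValueError("shell is empty")
    if n0 == 0:
        return np.empty((0, 3), dtype=np.int64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return shell.random_voxels(n0, rng)


def _nn_offset_groups(beta: float) -> list[np.ndarray]:
    """Lattice offsets with 0 < d <= beta, grouped by distance, ascending."""
    b = int(np.floor(beta))
    dx, dy = np.mgrid[-b:b + 1, -b:b + 1]
    d2 = dx * dx + dy * dy
    keep = (d2 > 0) & (d2 <= beta * beta)
    offs = np.column_stack([dx[keep], dy[keep], d2[keep]])
    groups = []
    for val in np.unique(offs[:, 2]):
        groups.append(offs[offs[:, 2] == val, :2])
    return groups


def _shift2d(a: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """out[x, y] = a[x - dx, y - dy], NaN outside."""
    out = np.full_like(a, np.nan)
    nx, ny = a.shape
    xs0, xs1 = max(dx, 0), nx + min(dx, 0)
    ys0, ys1 = max(dy, 0), ny + min(dy, 0)
    if xs0 >= xs1 or ys0 >= ys1:
        return out
    out[xs0:xs1, ys0:ys1] = a[xs0 - dx:xs1 - dx, ys0 - dy:ys1 - dy]
    return out


def nn_predict(state: ScanState, shell: Shell, beta: float) -> np.ndarray:
    """Nearest-neighbour extrapolation of the normalized intensity.

    For each unexplored shell voxel, the candidate set is the acquired
    shell voxels *in the same layer*; the NN is the candidate at smallest
    xy-Euclidean distance, ties resolved to the highest normalized
    intensity.  Voxels farther than ``beta`` pixels from any candidate
    receive no prediction (NaN).  Returns a ``(n_layers, nx, ny)`` array.
    """
    pred = np.full_like(state.values, np.nan)
    groups = _nn_offset_groups(beta)
    valid = state.layer_valid
    for li in range(shell.n_layers):
        cand = state.values[li]
        unassigned = valid[li] & np.isnan(cand)
        if not unassigned.any() or not np.isfinite(cand).any():
            continue
        out = pred[li]
        for group in groups:
            acc = np.full_like(cand, np.nan)
            for gdx, gdy in group:
                acc = np.fmax(acc, _shift2d(cand, int(gdx), int(gdy)))
            newly = unassigned & np.isfinite(acc)
            out[newly] = acc[newly]
            unassigned &= ~newly
            if not unassigned.any():
                break
    return pred


def select_new_acquisitions(pred: np.ndarray, state: ScanState, shell: Shell,
                            T: float) -> np.ndarray:
    """Coordinates to acquire this iteration.

    Keep predictions strictly above T; within each lateral column keep
    only the voxel with the highest prediction (ties resolved to the
    lowest layer index); drop the column if a voxel with normalized
    intensity >= that prediction has already been acquired in the shell.
    """
    with np.errstate(invalid="ignore"):
        bright = pred > T
    scores = np.where(bright, pred, -np.inf)
    best_layer = np.argmax(scores, axis=0)
    best_val = np.take_along_axis(scores, best_layer[None], axis=0)[0]
    candidate = best_val > -np.inf
    with np.errstate(invalid="ignore"):
        blocked = state.best_col >= best_val
    sel = candidate & ~blocked
    if not sel.any():
        return np.empty((0, 3), dtype=np.int64)
    xs, ys = np.nonzero(sel)
    zs = shell.z0[xs, ys] + (best_layer[xs, ys] - shell.half_layers)
    return np.column_stack([xs, ys, zs]).astype(np.int64)


def propagative_scan(oracle: VoxelOracle, shell: Shell, model: NormalizationModel,
                     params: PropagativeParams, ledger: DoseLedger,
                     prescan_samples: SampleSet) -> ScanResult:
    """Iterate predict -> select -> acquire until convergence.

    Iteration 0 is the pre-scan (its samples, wherever they fall, are
    carried in with their normalized values; only those inside the shell
    ever serve as NN candidates).  Iteration 1 acquires ``n0`` additional
    random in-shell seeds.  Iterations >= 2 acquire the voxels predicted
    bright.  Convergence is the first iteration without new acquisitions.
    """
    if prescan_samples.normalized is None:
        raise ValueError("pre-scan samples lack normalization; fit the background first")
    if shell.n_voxels() == 0:
        raise ValueError("shell is empty: nothing to scan")
    rng = np.random.default_rng(params.seed)
    state = ScanState(shell)
    state.ingest(prescan_samples)

    n0 = len(prescan_samples) if params.n0 is None else params.n0
    n0 = min(n0, shell.n_voxels())
    state.iteration = 1
    if n0 > 0:
        seeds = seed_in_shell(shell, n0, rng)
        seeded = normalize(acquire(oracle, seeds, ledger, iteration=1), model)
        state.per_iteration_counts.append(state.ingest(seeded))
    else:
        state.per_iteration_counts.append(0)

    converged = False
    for i in range(2, params.max_iterations + 1):
        state.iteration = i
        pred = nn_predict(state, shell, params.beta)
        coords = select_new_acquisitions(pred, state, shell, params.T)
        if len(coords) == 0:
            state.per_iteration_counts.append(0)
            converged = True
            break
        batch = normalize(acquire(oracle, coords, ledger, iteration=i), model)
        state.per_iteration_counts.append(state.ingest(batch))

    mip = np.nanmax(np.where(np.isfinite(state.values), state.values, -np.inf),
                    axis=0).astype(np.float32)
    mip[~np.isfinite(mip)] = np.nan
    return ScanResult(samples=state.samples(), mip=mip,
                      acquisitions_per_column=state.acq_count.copy(),
                      dose=ledger.snapshot(),
                      per_iteration_counts=state.per_iteration_counts,
                      converged=converged)


def max_intensity_projection(samples: SampleSet, shell: Shell) -> np.ndarray:
    """Per-column maximum normalized intensity among acquired shell voxels;
    NaN for columns without any acquisition in the shell."""
    if samples.normalized is None:
        raise ValueError("samples must be normalized")
    if len(samples) == 0:
        raise ValueError("no acquisitions to project")
    nx, ny = shell.z0.shape
    mip = np.full((nx, ny), np.nan, dtype=np.float32)
    inside = shell.contains(samples.coords)
    c = samples.coords[inside]
    np.fmax.at(mip, (c[:, 0], c[:, 1]), samples.normalized[inside].astype(np.float32))
    return mip
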