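"""Voxel oracle and dose accounting.

The oracle abstracts "the microscope": given integer voxel coordinates it
returns an intensity, whether the backing store is a synthetic phantom or
a user-supplied full-scan stack (emulation mode).  The light dose of any
strategy is the number of *uniquely* scanned voxels, tracked by a
:class:`DoseLedger` so that dose fractions are first-class, testable
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .phantom import Volume

__all__ = ["SampleSet", "DoseLedger", "VoxelOracle", "oracle_from_stack",
           "acquire", "dose_fraction"]


@dataclass
class SampleSet:
    """Sparse list of acquired voxels.

    ``coords`` is ``(n, 3)`` integer ``(x, y, z)``; ``normalized`` is None
    until Eq.-style background normalization has been applied; ``iteration``
    tags the acquisition round (0 = pre-scan).
    """

    coords: np.ndarray
    raw: np.ndarray
    normalized: Optional[np.ndarray] = None
    iteration: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 3)
        self.raw = np.asarray(self.raw, dtype=float).reshape(-1)
        if len(self.raw) != len(self.coords):
            raise ValueError("coords and raw lengths differ")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float).reshape(-1)
        if self.iteration is not None:
            self.iteration = np.asarray(self.iteration, dtype=np.int32).reshape(-1)

    def __len__(self) -> int:
        return len(self.raw)

    @property
    def n(self) -> int:
        return len(self.raw)

    def with_normalized(self, values: np.ndarray) -> "SampleSet":
        return replace(self, normalized=np.asarray(values, dtype=float))

    def subset(self, index: np.ndarray) -> "SampleSet":
        return SampleSet(
            coords=self.coords[index],
            raw=self.raw[index],
            normalized=None if self.normalized is None else self.normalized[index],
            iteration=None if self.iteration is None else self.iteration[index],
        )

    @classmethod
    def empty(cls) -> "SampleSet":
        return cls(coords=np.empty((0, 3), dtype=np.int64), raw=np.empty(0))

    @classmethod
    def concatenate(cls, parts: Sequence["SampleSet"]) -> "SampleSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls.empty()
        norm = None
        if all(p.normalized is not None for p in parts):
            norm = np.concatenate([p.normalized for p in parts])
        itr = None
        if all(p.iteration is not None for p in parts):
            itr = np.concatenate([p.iteration for p in parts])
        return cls(coords=np.concatenate([p.coords for p in parts]),
                   raw=np.concatenate([p.raw for p in parts]),
                   normalized=norm, iteration=itr)

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame({
            "x": self.coords[:, 0], "y": self.coords[:, 1], "z": self.coords[:, 2],
            "raw_intensity": self.raw,
            "normalized_intensity": (np.full(n, np.nan) if self.normalized is None
                                     else self.normalized),
            "iteration_tag": (np.zeros(n, dtype=int) if self.iteration is None
                              else self.iteration),
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleSet":
        norm = frame["normalized_intensity"].to_numpy(float)
        return cls(coords=frame[["x", "y", "z"]].to_numpy(np.int64),
                   raw=frame["raw_intensity"].to_numpy(float),
                   normalized=None if np.isnan(norm).all() else norm,
                   iteration=frame["iteration_tag"].to_numpy(np.int32))


class DoseLedger:
    """Set of acquired voxels (Omega) plus a total-query counter.

    Dose fraction counts each voxel once however often it is re-imaged;
    ``n_queries`` counts every query including repeats.
    """

    def __init__(self, shape: tuple[int, int, int]):
        self.shape = tuple(int(s) for s in shape)
        self._mask = np.zeros(self.shape, dtype=bool)
        self.n_queries = 0

    def record(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=np.int64).reshape(-1, 3)
        self.n_queries += len(coords)
        self._mask[coords[:, 0], coords[:, 1], coords[:, 2]] = True

    @property
    def n_unique(self) -> int:
        return int(self._mask.sum())

    @property
    def n_total(self) -> int:
        return int(np.prod(self.shape))

    @property
    def dose_fraction(self) -> float:
        return self.n_unique / self.n_total

    @property
    def acquired_mask(self) -> np.ndarray:
        return self._mask

    def snapshot(self) -> dict:
        return {"n_unique": self.n_unique, "n_queries": self.n_queries,
                "dose_fraction": self.dose_fraction}


class VoxelOracle:
    """Intensity-on-demand backed by a dense stack.

    Out-of-bounds queries raise ``IndexError`` naming the offending
    coordinate; they are never clamped.  With ``bleach_rate = b > 0`` a
    voxel's value decays as ``(1 - b) ** e`` where ``e`` counts prior
    exposures anywhere in its (x, y) column -- out-of-focus excitation
    irradiates the whole column.  Exposures accrue batch-wise: all values
    of one :meth:`read` call see the exposure counts at the start of the
    call (frame-level bleaching), then the batch's exposures are added.
    """

    def __init__(self, volume: Volume, bleach_rate: float = 0.0):
        if not 0 <= bleach_rate < 1:
            raise ValueError("bleach_rate must be in [0, 1)")
        self.volume = volume
        self.bleach_rate = float(bleach_rate)
        nx, ny, _ = volume.shape
        self._col_exposures = np.zeros((nx, ny), dtype=np.int64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volume.shape

    def _check_bounds(self, coords: np.ndarray) -> None:
        shape = np.asarray(self.shape)
        bad = np.any((coords < 0) | (coords >= shape[None, :]), axis=1)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise IndexError(
                f"voxel coordinate {tuple(int(c) for c in coords[i])} "
                f"outside stack of shape {self.shape}")

    def read(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=np.int64).reshape(-1, 3)
        self._check_bounds(coords)
        values = self.volume.data[coords[:, 0], coords[:, 1], coords[:, 2]].astype(float)
        if self.bleach_rate > 0:
            exp = self._col_exposures[coords[:, 0], coords[:, 1]]
            values = values * (1.0 - self.bleach_rate) ** exp
        np.add.at(self._col_exposures, (coords[:, 0], coords[:, 1]), 1)
        return values


def oracle_from_stack(volume: Volume, bleach_rate: float = 0.0) -> VoxelOracle:
    """Emulation mode: treat a full-scan stack as the voxel oracle."""
    return VoxelOracle(volume, bleach_rate=bleach_rate)


def acquire(oracle: VoxelOracle, coords: np.ndarray, ledger: DoseLedger,
            iteration: Optional[int] = None) -> SampleSet:
    """Query a coordinate list and record the dose.

    The returned sample set has exactly one row per requested coordinate
    (duplicates included); the ledger counts each voxel once.
    """
    coords = np.asarray(coords, dtype=np.int64).reshape(-1, 3)
    if len(coords) == 0:
        return SampleSet.empty()
    values = oracle.read(coords)
    ledger.record(coords)
    itr = None if iteration is None else np.full(len(coords), iteration, dtype=np.int32)
    return SampleSet(coords=coords, raw=values, iteration=itr)


def dose_fraction(ledger: DoseLedger) -> float:
    """Unique scanned voxels as a fraction of the full voxel space."""
    return ledger.dose_fraction
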