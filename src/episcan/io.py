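"""Reading and writing of stacks, height maps, masks and sample tables.

Stacks are multi-page TIFFs with one page per z-plane (rows = y,
columns = x); the in-memory convention is ``data[x, y, z]``.  Sparse
sample sets are plain tabular text with columns
x, y, z, raw_intensity, normalized_intensity, iteration_tag.
"""

from __future__ import annotations

from pathlib import Path
from dataclasses import asdict

import numpy as np
import pandas as pd
import tifffile
import yaml

from .acquisition import SampleSet
from .phantom import PhantomConfig, Volume

__all__ = ["read_stack", "write_stack", "write_mask_stack", "write_heightmap",
           "read_heightmap", "write_samples", "read_samples",
           "load_phantom_config", "dump_phantom_config"]


def read_stack(path: str | Path) -> Volume:
    """Load a multi-page TIFF z-stack as a Volume (emulation oracle input)."""
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    data = np.ascontiguousarray(pages.transpose(2, 1, 0)).astype(np.float32)
    return Volume(data=data, pitch=(0.27, 0.27, 0.5))


def write_stack(volume: Volume, path: str | Path) -> None:
    """Write a Volume as a 16-bit multi-page TIFF (one page per plane)."""
    data = np.clip(np.rint(volume.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), data.transpose(2, 1, 0), photometric="minisblack")


def write_mask_stack(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), (mask.transpose(2, 1, 0) > 0).astype(np.uint8))


def write_heightmap(z: np.ndarray, path: str | Path) -> None:
    """32-bit single-page TIFF height map (um; NaN outside support)."""
    tifffile.imwrite(str(path), np.asarray(z, dtype=np.float32).T)


def read_heightmap(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=np.float32).T


def write_samples(samples: SampleSet, path: str | Path) -> None:
    samples.to_frame().to_csv(path, index=False)


def read_samples(path: str | Path) -> SampleSet:
    return SampleSet.from_frame(pd.read_csv(path))


def load_phantom_config(path: str | Path) -> PhantomConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PhantomConfig(**raw)


def dump_phantom_config(config: PhantomConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
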