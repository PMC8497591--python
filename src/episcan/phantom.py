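"""Synthetic epithelial phantoms with voxel-level ground truth.

The generator emulates a fluorescence z-stack of a cell sheet: a smooth
surface ``z = Z(x, y)`` carries a bright polygonal mesh of cell contours
(the junctional marker), embedded in a smoothly inhomogeneous background
with multiplicative Gaussian-like noise.  Every downstream stage of the
adaptive-scanning pipeline can therefore be tested against an exactly
known surface, contour mask and bright-voxel set, without any microscope.

Coordinates are 0-based voxel indices ``(x, y, z)``; the physical depth of
plane ``z`` is ``z * dz`` micrometres.  Intensity arrays are indexed
``data[x, y, z]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "ConfigurationError",
    "PhantomConfig",
    "Volume",
    "GroundTruth",
    "make_surface",
    "tissue_mask",
    "make_cell_mesh",
    "render_stack",
    "generate",
    "SURFACE_KINDS",
]

SURFACE_KINDS = ("flat", "quadratic", "sinusoidal", "step", "double-surface")


class ConfigurationError(ValueError):
    """Raised for an invalid phantom configuration."""


def _default_background() -> dict:
    # gentle +-20-30% inhomogeneity over the field, strictly positive
    return {"base": 100.0, "x": 0.15, "y": -0.1, "z": 0.2, "xx": -0.1, "yy": 0.05}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, optics and noise parameters of a synthetic stack.

    Defaults reproduce a typical wing-disc-like acquisition: a
    915 x 915 x 50 stack at 0.27 x 0.27 x 0.5 um voxel pitch, small
    (~2.5 um) cells on a curved surface covering ~30% of the lateral
    field.  ``contour_amplitude`` is the brightness of the junctional
    mesh as a multiple of the local background; ``contour_width``
    doubles as the lateral width of the junction lines and the sigma
    scale of the isotropic blur standing in for the excitation PSF.
    """

    nx: int = 915
    ny: int = 915
    nz: int = 50
    dx: float = 0.27
    dy: float = 0.27
    dz: float = 0.5
    surface_kind: str = "quadratic"
    surface_params: Optional[dict] = None
    cell_diameter: float = 2.5
    contour_width: float = 0.4
    contour_amplitude: float = 2.0
    structure_thickness: float = 3.0
    background_params: dict = field(default_factory=_default_background)
    noise_cv: float = 0.1
    outlier_fraction: float = 0.0
    tissue_xy_coverage: float = 0.3
    bleach_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ConfigurationError("voxel counts must be >= 1")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ConfigurationError("voxel pitches must be positive")
        if self.surface_kind not in SURFACE_KINDS:
            raise ConfigurationError(f"unknown surface_kind {self.surface_kind!r}")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if not 0 <= self.outlier_fraction < 1:
            raise ConfigurationError("outlier_fraction must be in [0, 1)")
        if not 0 < self.tissue_xy_coverage <= 1:
            raise ConfigurationError("tissue_xy_coverage must be in (0, 1]")
        if self.contour_amplitude <= 0:
            raise ConfigurationError("contour_amplitude must be positive")
        if not 0 <= self.bleach_rate < 1:
            raise ConfigurationError("bleach_rate must be in [0, 1)")
        if self.structure_thickness <= 0:
            raise ConfigurationError("structure_thickness must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def z_extent(self) -> float:
        """Physical depth of the deepest plane, in um."""
        return (self.nz - 1) * self.dz


@dataclass
class Volume:
    """Dense 3D intensity stack, indexed ``data[x, y, z]``."""

    data: np.ndarray
    pitch: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("volume intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class GroundTruth:
    """Phantom with every hidden variable exposed.

    ``z_true`` is the surface height in um on the lateral grid (NaN where
    there is no tissue); ``contour_mask`` marks the cell-contour mesh;
    ``bright_mask`` marks the true bright voxels (contours extruded half a
    structure-thickness either side of the surface, plus any injected
    off-surface outliers).
    """

    config: PhantomConfig
    z_true: np.ndarray
    contour_mask: np.ndarray
    bright_mask: np.ndarray
    volume: Volume
    tissue_mask: np.ndarray
    z_secondary: Optional[np.ndarray] = None
    contour_secondary: Optional[np.ndarray] = None


def _surface_defaults(config: PhantomConfig) -> dict:
    ze = config.z_extent
    lateral = min(config.nx * config.dx, config.ny * config.dy)
    kind = config.surface_kind
    if kind == "flat":
        return {"offset": 0.5 * ze}
    if kind in ("quadratic", "double-surface"):
        params = {"z_min": 0.08 * ze, "z_max": 0.88 * ze}
        if kind == "double-surface":
            params.update({"separation": min(8.0, 0.3 * ze), "secondary_density": 0.25})
        return params
    if kind == "sinusoidal":
        return {"offset": 0.5 * ze, "amplitude": 0.25 * ze, "period": 0.5 * lateral}
    if kind == "step":
        return {"low": 0.35 * ze, "high": 0.65 * ze,
                "width": 20 * config.dx, "position": 0.5}
    raise ConfigurationError(f"unknown surface_kind {kind!r}")


def make_surface(config: PhantomConfig) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Evaluate the ground-truth height field on the full lateral grid.

    Returns ``(Z, Z2)`` in um; ``Z2`` is None except for the
    ``double-surface`` kind, whose decoy sheet sits ``separation`` um
    above the primary one and is rendered less densely populated.
    """
    params = dict(_surface_defaults(config))
    if config.surface_params:
        params.update(config.surface_params)
    xs = np.arange(config.nx, dtype=float) * config.dx
    ys = np.arange(config.ny, dtype=float) * config.dy
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    kind = config.surface_kind
    if kind == "flat":
        Z = np.full_like(X, float(params["offset"]))
    elif kind in ("quadratic", "double-surface"):
        z_min, z_max = float(params["z_min"]), float(params["z_max"])
        cx, cy = xs[-1] / 2 if len(xs) > 1 else 0.0, ys[-1] / 2 if len(ys) > 1 else 0.0
        r2 = (X - cx) ** 2 + (Y - cy) ** 2
        # z_min is reached at the corner of the tissue rectangle (whose side
        # scales as sqrt(coverage)), so the surface spans the full stated
        # range over the tissue; the field is clipped at z_min beyond it
        r2ref = r2.max() * config.tissue_xy_coverage
        if r2ref == 0:
            Z = np.full_like(X, z_max)
        else:
            Z = np.clip(z_max - (z_max - z_min) * r2 / r2ref, z_min, z_max)
    elif kind == "sinusoidal":
        amp, per = float(params["amplitude"]), float(params["period"])
        Z = params["offset"] + 0.5 * amp * (
            np.sin(2 * np.pi * X / per) + np.cos(2 * np.pi * Y / per))
    elif kind == "step":
        low, high = float(params["low"]), float(params["high"])
        width = float(params["width"])
        x0 = float(params["position"]) * xs[-1] if len(xs) > 1 else 0.0
        ramp = np.clip((X - (x0 - width / 2)) / max(width, 1e-9), 0.0, 1.0)
        Z = low + (high - low) * ramp
    else:  # pragma: no cover - guarded by config validation
        raise ConfigurationError(f"unknown surface_kind {kind!r}")
    Z2 = None
    if kind == "double-surface":
        Z2 = np.minimum(Z + float(params["separation"]), config.z_extent)
    return Z, Z2


def tissue_mask(config: PhantomConfig) -> np.ndarray:
    """Centred axis-aligned rectangle occupying ``tissue_xy_coverage``
    of the lateral field (side fraction = sqrt(coverage) per axis)."""
    frac = float(np.sqrt(config.tissue_xy_coverage))
    wx = max(1, int(round(frac * config.nx)))
    wy = max(1, int(round(frac * config.ny)))
    x0 = (config.nx - wx) // 2
    y0 = (config.ny - wy) // 2
    mask = np.zeros((config.nx, config.ny), dtype=bool)
    mask[x0:x0 + wx, y0:y0 + wy] = True
    return mask


def _disk_offsets(radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius_px))
    dx, dy = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dx * dx + dy * dy <= radius_px * radius_px
    return dx[keep], dy[keep]


def _poisson_disc_seeds(mask: np.ndarray, radius_px: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Maximal Poisson-disc sample inside ``mask`` by dart throwing over a
    random permutation of the admissible pixels."""
    free = mask.copy()
    idx = np.flatnonzero(mask)
    order = rng.permutation(idx)
    odx, ody = _disk_offsets(radius_px)
    nx, ny = mask.shape
    seeds = []
    for flat in order:
        x, y = divmod(int(flat), ny)
        if not free[x, y]:
            continue
        seeds.append((x, y))
        px = x + odx
        py = y + ody
        ok = (px >= 0) & (px < nx) & (py >= 0) & (py < ny)
        free[px[ok], py[ok]] = False
    return np.asarray(seeds, dtype=np.intp).reshape(-1, 2)


def make_cell_mesh(height_field: np.ndarray, cell_diameter: float, seed: int, *,
                   pitch: float = 0.27, contour_width: float = 0.4) -> np.ndarray:
    """Boolean contour mask of a Voronoi-like planar partition of the tissue.

    Cell centres are a Poisson-disc sample of radius ``cell_diameter / 2``;
    the contour is the set of boundary pixels between adjacent cells,
    thickened to ``contour_width`` um.  The tissue region is wherever
    ``height_field`` is finite.  A single-cell partition has no internal
    boundary, so its contour mask is empty.
    """
    mask = np.isfinite(np.asarray(height_field, dtype=float))
    if cell_diameter < 2 * pitch:
        raise ConfigurationError(
            f"cell_diameter {cell_diameter} um is below two pixels "
            f"({2 * pitch} um): cells would be unresolvable")
    rng = np.random.default_rng(seed)
    radius_px = (cell_diameter / 2) / pitch
    seeds = _poisson_disc_seeds(mask, radius_px, rng)
    contour = np.zeros_like(mask)
    if len(seeds) < 2:
        return contour
    tree = cKDTree(seeds)
    pts = np.argwhere(mask)
    _, lab = tree.query(pts)
    labels = np.full(mask.shape, -1, dtype=np.int32)
    labels[pts[:, 0], pts[:, 1]] = lab
    diff_x = (labels[:-1, :] != labels[1:, :]) & mask[:-1, :] & mask[1:, :]
    diff_y = (labels[:, :-1] != labels[:, 1:]) & mask[:, :-1] & mask[:, 1:]
    contour[:-1, :] |= diff_x
    contour[1:, :] |= diff_x
    contour[:, :-1] |= diff_y
    contour[:, 1:] |= diff_y
    width_px = contour_width / pitch
    if width_px > 2.0:
        odx, ody = _disk_offsets((width_px - 2.0) / 2)
        structure = np.zeros((odx.max() - odx.min() + 1,) * 2, dtype=bool)
        structure[odx - odx.min(), ody - ody.min()] = True
        contour = ndimage.binary_dilation(contour, structure=structure)
    return contour & mask


def _background_field(config: PhantomConfig) -> np.ndarray:
    """Smooth positive low-order polynomial background a(x, y, z)."""
    p = config.background_params
    u = np.linspace(-1, 1, config.nx) if config.nx > 1 else np.zeros(config.nx)
    v = np.linspace(-1, 1, config.ny) if config.ny > 1 else np.zeros(config.ny)
    w = np.linspace(-1, 1, config.nz) if config.nz > 1 else np.zeros(config.nz)
    U = u[:, None, None]
    V = v[None, :, None]
    W = w[None, None, :]
    rel = np.ones((config.nx, config.ny, config.nz))
    terms = {"x": U, "y": V, "z": W, "xx": U * U, "yy": V * V, "zz": W * W,
             "xy": U * V, "xz": U * W, "yz": V * W}
    for key, term in terms.items():
        c = float(p.get(key, 0.0))
        if c:
            rel = rel + c * term
    a = float(p.get("base", 100.0)) * rel
    if a.min() <= 0:
        raise ConfigurationError("background_params yield a non-positive field")
    return a


def render_stack(config: PhantomConfig,
                 z_true: np.ndarray,
                 contour_mask: np.ndarray,
                 z_secondary: Optional[np.ndarray] = None,
                 contour_secondary: Optional[np.ndarray] = None,
                 rng: Optional[np.random.Generator] = None) -> GroundTruth:
    """Render the intensity volume ``s = a * (1 + cv*g + A*B)``.

    ``a`` is the smooth background, ``g`` unit-variance zero-mean noise
    (multiplicative, so the background of ``s / a - 1`` has a spatially
    constant spread), and ``B`` the bright structure: the contour mesh
    extruded half a ``structure_thickness`` either side of the surface,
    plus ``outlier_fraction`` scattered off-surface bright voxels.  ``B``
    is softened by an isotropic Gaussian blur standing in for the
    excitation PSF but kept at exactly 1 on true bright voxels.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nx, ny, nz = config.shape
    half = config.structure_thickness / 2
    zpos = np.arange(nz) * config.dz

    bright = np.zeros(config.shape, dtype=bool)
    zt = np.asarray(z_true, dtype=float)
    on = np.isfinite(zt) & np.asarray(contour_mask, dtype=bool)
    if on.any():
        bright[on] = np.abs(zpos[None, :] - zt[on][:, None]) <= half
    if z_secondary is not None and contour_secondary is not None:
        z2 = np.asarray(z_secondary, dtype=float)
        on2 = np.isfinite(z2) & np.asarray(contour_secondary, dtype=bool)
        if on2.any():
            bright[on2] |= np.abs(zpos[None, :] - z2[on2][:, None]) <= half

    if config.outlier_fraction > 0:
        n_out = int(round(config.outlier_fraction * config.n_voxels))
        placed = 0
        while placed < n_out:
            cand = rng.integers(0, [nx, ny, nz], size=(2 * (n_out - placed) + 8, 3))
            zt_c = zt[cand[:, 0], cand[:, 1]]
            depth = cand[:, 2] * config.dz
            off_surface = ~np.isfinite(zt_c) | (np.abs(depth - zt_c) > half)
            cand = cand[off_surface][: n_out - placed]
            bright[cand[:, 0], cand[:, 1], cand[:, 2]] = True
            placed += len(cand)

    B = bright.astype(np.float32)
    sigma_vox = (config.contour_width / 2) / np.array(
        [config.dx, config.dy, config.dz])
    if np.any(sigma_vox > 0.05) and bright.any():
        blurred = ndimage.gaussian_filter(B, sigma=sigma_vox)
        B = np.maximum(B, blurred.astype(np.float32))

    a = _background_field(config).astype(np.float32)
    rel = np.ones(config.shape, dtype=np.float32)
    if config.noise_cv > 0:
        rel += config.noise_cv * rng.standard_normal(config.shape).astype(np.float32)
    rel += np.float32(config.contour_amplitude) * B
    data = a * np.clip(rel, 0.0, None)
    volume = Volume(data=data, pitch=(config.dx, config.dy, config.dz))
    return GroundTruth(config=config, z_true=zt, contour_mask=np.asarray(contour_mask, bool),
                       bright_mask=bright, volume=volume,
                       tissue_mask=np.isfinite(zt),
                       z_secondary=z_secondary, contour_secondary=contour_secondary)


def generate(config: PhantomConfig) -> GroundTruth:
    """Full phantom: surface -> tissue mask -> cell mesh -> rendered stack.

    All randomness derives from ``config.seed``; generation is
    bit-reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    s_mesh, s_mesh2, s_render, s_thin = (s.generate_state(1)[0] % (2 ** 31)
                                         for s in ss.spawn(4))
    Z, Z2 = make_surface(config)
    tmask = tissue_mask(config)
    z_true = np.where(tmask, Z, np.nan)
    contour = make_cell_mesh(z_true, config.cell_diameter, int(s_mesh),
                             pitch=config.dx, contour_width=config.contour_width)
    z2_masked = None
    contour2 = None
    if Z2 is not None:
        params = dict(_surface_defaults(config))
        if config.surface_params:
            params.update(config.surface_params)
        z2_masked = np.where(tmask, Z2, np.nan)
        contour2 = make_cell_mesh(z2_masked, config.cell_diameter, int(s_mesh2),
                                  pitch=config.dx, contour_width=config.contour_width)
        # the decoy sheet is less densely populated: keep a random subset
        density = float(params.get("secondary_density", 0.25))
        thin_rng = np.random.default_rng(int(s_thin))
        contour2 &= thin_rng.random(contour2.shape) < density
    return render_stack(config, z_true, contour, z2_masked, contour2,
                        rng=np.random.default_rng(int(s_render)))
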