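"""Surface estimation from detected bright points, and the epsilon-shell.

Bright points are noisy samples of the epithelial surface z = Z(x, y):
they scatter half a junction-thickness either side of it and are
contaminated by false alarms and by fluorophores on other, less populated
surfaces.  The estimate is therefore robust: local second-order
polynomial fits with RANSAC consensus in overlapping lateral windows,
fusion of the per-window fits into denoised z-coordinates of the inlier
points, and a biharmonic (thin-plate) spline interpolation through them.
The surface is finally voxelized into a thin shell of thickness epsilon
(3 um by default, slightly thicker than an adherens-junction belt)
decomposed into one-voxel-deep layers parallel to the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import Delaunay

__all__ = ["Window", "WindowGrid", "LocalFit", "SurfaceModel", "Shell",
           "make_windows", "ransac_fit_window", "lstsq_fit_window",
           "fuse_and_filter", "interpolate_surface", "build_shell",
           "estimate_surface"]


@dataclass(frozen=True)
class Window:
    """Axis-aligned lateral rectangle, half-open pixel bounds."""

    x0: int
    x1: int
    y0: int
    y1: int

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1 - 1) / 2, (self.y0 + self.y1 - 1) / 2)

    @property
    def halfwidth(self) -> tuple[float, float]:
        return ((self.x1 - self.x0) / 2, (self.y1 - self.y0) / 2)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return ((x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1))

    def weight(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Separable tent weight peaking at the window centre, 0 at edges."""
        cx, cy = self.center
        hx, hy = self.halfwidth
        wx = np.clip(1.0 - np.abs(np.asarray(x, float) - cx) / hx, 0.0, None)
        wy = np.clip(1.0 - np.abs(np.asarray(y, float) - cy) / hy, 0.0, None)
        return wx * wy


@dataclass
class WindowGrid:
    windows: list[Window]
    nx: int
    ny: int


def _axis_starts(length: int, width: int, step: int) -> list[int]:
    starts = list(range(0, max(length - width, 0) + 1, step))
    if starts[-1] + width < length:
        starts.append(length - width)
    return starts


def make_windows(lateral_shape: tuple[int, int],
                 width_fraction: float = 1 / 3,
                 overlap_fraction: float = 0.5) -> WindowGrid:
    """Overlapping window layout covering the full lateral extent."""
    if not 0 < width_fraction <= 1:
        raise ValueError("width_fraction must be in (0, 1]")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    nx, ny = lateral_shape
    wx = max(1, int(round(width_fraction * nx)))
    wy = max(1, int(round(width_fraction * ny)))
    sx = max(1, int(round(wx * (1 - overlap_fraction))))
    sy = max(1, int(round(wy * (1 - overlap_fraction))))
    windows = [Window(x0, x0 + wx, y0, y0 + wy)
               for x0 in _axis_starts(nx, wx, sx)
               for y0 in _axis_starts(ny, wy, sy)]
    covered = np.zeros((nx, ny), dtype=bool)
    for win in windows:
        covered[win.x0:win.x1, win.y0:win.y1] = True
    if not covered.all():
        raise ValueError("window layout does not cover the lateral extent")
    return WindowGrid(windows=windows, nx=nx, ny=ny)


def _design2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x, dtype=float), x, y,
                            x * x, x * y, y * y])


@dataclass
class LocalFit:
    """Second-order polynomial z = c0 + c1 x + c2 y + c3 x^2 + c4 xy + c5 y^2.

    ``x, y`` in pixels, ``z`` in um.  ``inlier_ids`` index into the bright
    point array the fit was computed from.
    """

    coefficients: np.ndarray
    inlier_ids: np.ndarray
    window: Window
    window_id: int = -1

    def predict(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return _design2(np.asarray(x, float), np.asarray(y, float)) @ self.coefficients


# annealing schedule of the local refinement, as multiples of inlier_tol
_REFINE_SCHEDULE = (1.0, 1.0, 0.5, 0.5, 0.25)
_TOP_HYPOTHESES = 5


def ransac_fit_window(xy: np.ndarray, z: np.ndarray,
                      n_trials: int = 500,
                      inlier_tol: float = 1.5,
                      min_inliers: Optional[int] = None,
                      seed: int | np.random.Generator = 0,
                      window: Optional[Window] = None) -> Optional[LocalFit]:
    """Robust second-order fit of bright-point z-coordinates.

    Hypotheses are generated from minimal 3-point *plane* samples -- at
    the >2/3 outlier ratios the method must survive, a clean 6-point
    quadratic sample is too rare for any practical trial count, whereas a
    clean 3-point sample is drawn reliably.  The few best-consensus plane
    hypotheses are then locally refined into the full quadratic model:
    least-squares refit on the inliers with re-selection at an annealed
    tolerance (down to ``inlier_tol / 4``), so that structureless points
    that fall inside the band by chance cannot bias the final
    coefficients.  ``inlier_ids`` are the points within ``inlier_tol`` of
    the refined model.  Returns None (no-fit, not an exception) when
    fewer than 6 points are available or the consensus falls below
    ``min_inliers`` (default 6 + 10% of the points).
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    z = np.asarray(z, dtype=float).reshape(-1)
    n = len(z)
    if n < 6:
        return None
    if min_inliers is None:
        min_inliers = 6 + int(np.ceil(0.1 * n))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = _design2(xy[:, 0], xy[:, 1])
    P = np.column_stack([np.ones(n), xy])
    hypotheses: list[tuple[int, np.ndarray]] = []
    for _ in range(n_trials):
        pick = rng.choice(n, size=3, replace=False)
        pc, _, rank, _ = np.linalg.lstsq(P[pick], z[pick], rcond=None)
        if rank < 3:
            continue
        inliers = np.abs(z - P @ pc) <= inlier_tol
        hypotheses.append((int(inliers.sum()), inliers))
    hypotheses.sort(key=lambda h: -h[0])

    def _refine(inliers: np.ndarray):
        # annealing floor adapts to the observed inlier noise: with tight
        # residuals (clean points plus chance outliers) the tolerance
        # shrinks to tol/4 and purges the stragglers; with residuals at the
        # scale of the tolerance (genuinely noisy surface points) it stays
        # wide so the fit averages over all of them
        coeffs = None
        for frac in _REFINE_SCHEDULE:
            if inliers.sum() < 6:
                break
            new_coeffs, *_ = np.linalg.lstsq(X[inliers], z[inliers], rcond=None)
            res = z - X @ new_coeffs
            r_in = res[inliers]
            sigma = 1.4826 * np.median(np.abs(r_in - np.median(r_in)))
            tol = float(np.clip(2.5 * sigma, frac * inlier_tol, inlier_tol))
            new_inliers = np.abs(res) <= tol
            if new_inliers.sum() < 6:
                break
            coeffs, inliers = new_coeffs, new_inliers
        return coeffs

    best_coeffs = None
    best_tight = 0
    final_tol = _REFINE_SCHEDULE[-1] * inlier_tol
    for count, inliers in hypotheses[:_TOP_HYPOTHESES]:
        if count < 3:
            break
        coeffs = _refine(inliers.copy())
        if coeffs is None:
            continue
        tight = int((np.abs(z - X @ coeffs) <= final_tol).sum())
        if tight > best_tight:
            best_tight = tight
            best_coeffs = coeffs
    if best_coeffs is None:
        return None
    coeffs = best_coeffs
    ids = np.flatnonzero(np.abs(z - X @ coeffs) <= inlier_tol)
    if len(ids) < max(min_inliers, 6):
        return None
    if window is None:
        window = Window(int(np.floor(xy[:, 0].min())), int(np.ceil(xy[:, 0].max())) + 1,
                        int(np.floor(xy[:, 1].min())), int(np.ceil(xy[:, 1].max())) + 1)
    return LocalFit(coefficients=coeffs, inlier_ids=ids, window=window)


def lstsq_fit_window(xy: np.ndarray, z: np.ndarray,
                     window: Optional[Window] = None) -> Optional[LocalFit]:
    """Plain least-squares window fit with every point an inlier.

    This is the no-outlier-removal baseline against which the RANSAC
    variant is compared (a decoy surface or scattered false alarms pull
    this fit off the dominant sheet).
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    z = np.asarray(z, dtype=float).reshape(-1)
    if len(z) < 6:
        return None
    X = _design2(xy[:, 0], xy[:, 1])
    coeffs, *_ = np.linalg.lstsq(X, z, rcond=None)
    if window is None:
        window = Window(int(np.floor(xy[:, 0].min())), int(np.ceil(xy[:, 0].max())) + 1,
                        int(np.floor(xy[:, 1].min())), int(np.ceil(xy[:, 1].max())) + 1)
    return LocalFit(coefficients=coeffs, inlier_ids=np.arange(len(z)), window=window)


def fuse_and_filter(fits: Sequence[Optional[LocalFit]],
                    grid: WindowGrid,
                    xy: np.ndarray,
                    z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fuse per-window fits: keep cross-window inliers, denoise their z.

    A bright point is retained iff it is an inlier of at least one valid
    fit whose window covers it.  Its denoised z is the tent-weighted
    average of the covering valid fits' predictions at its (x, y); if all
    covering tent weights vanish (point exactly on every window edge) the
    unweighted mean of the covering predictions is used.

    Returns ``(xy_retained, z_denoised, retained_index)``.
    """
    fits = list(fits)
    valid = [f for f in fits if f is not None]
    if not valid:
        raise ValueError("no valid window fit: surface cannot be estimated")
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    z = np.asarray(z, dtype=float).reshape(-1)
    n = len(z)
    inlier_any = np.zeros(n, dtype=bool)
    wsum = np.zeros(n)
    wz = np.zeros(n)
    csum = np.zeros(n, dtype=int)
    cz = np.zeros(n)
    for fit in valid:
        cover = fit.window.contains(xy[:, 0], xy[:, 1])
        if not cover.any():
            continue
        inl = np.zeros(n, dtype=bool)
        inl[fit.inlier_ids] = True
        inlier_any |= inl & cover
        pred = fit.predict(xy[cover, 0], xy[cover, 1])
        wgt = fit.window.weight(xy[cover, 0], xy[cover, 1])
        wsum[cover] += wgt
        wz[cover] += wgt * pred
        csum[cover] += 1
        cz[cover] += pred
    retained = np.flatnonzero(inlier_any)
    if len(retained) == 0:
        raise ValueError("no bright point is an inlier of any window fit")
    denoised = np.where(wsum[retained] > 0,
                        wz[retained] / np.where(wsum[retained] > 0, wsum[retained], 1.0),
                        cz[retained] / np.maximum(csum[retained], 1))
    return xy[retained], denoised, retained


def filter_scattered(xy: np.ndarray, min_neighbors: int = 3,
                     radius_factor: float = 4.0) -> np.ndarray:
    """Boolean keep-mask dropping laterally isolated points.

    False alarms surviving the RANSAC stage (background voxels that happen
    to lie within the inlier tolerance of the local fit) are scattered over
    the whole field, whereas genuine surface points are dense over the
    tissue.  A point is kept iff at least ``min_neighbors`` other points lie
    within ``radius_factor`` times the median nearest-neighbour distance.
    The interpolation support (convex hull) then tracks the tissue instead
    of ballooning around stray detections.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    n = len(xy)
    if n <= min_neighbors + 1:
        return np.ones(n, dtype=bool)
    from scipy.spatial import cKDTree
    tree = cKDTree(xy)
    nn_dist, _ = tree.query(xy, k=2)
    radius = radius_factor * float(np.median(nn_dist[:, 1]))
    counts = np.array([len(ids) - 1 for ids in tree.query_ball_point(xy, radius)])
    keep = counts >= min_neighbors
    if keep.sum() < 3:
        return np.ones(n, dtype=bool)
    return keep


@dataclass
class SurfaceModel:
    """Estimated height field Z_hat (um) on the lateral grid.

    ``z`` is NaN outside ``support``; the support is the convex hull of
    the interpolation points -- thin-plate extrapolation far outside the
    data is meaningless and would inflate the shell (and the dose) over
    tissue-free regions.
    """

    z: np.ndarray
    support: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape


def interpolate_surface(xy: np.ndarray, z: np.ndarray,
                        lateral_shape: tuple[int, int],
                        chunk: int = 50_000) -> SurfaceModel:
    """Biharmonic (thin-plate Green's function) spline through the points.

    Exact interpolation: the surface passes through every (deduplicated)
    denoised inlier.  Duplicate (x, y) locations are averaged first.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    z = np.asarray(z, dtype=float).reshape(-1)
    uniq, inv = np.unique(xy, axis=0, return_inverse=True)
    zm = np.zeros(len(uniq))
    cnt = np.zeros(len(uniq))
    np.add.at(zm, inv, z)
    np.add.at(cnt, inv, 1)
    zm /= cnt
    if len(uniq) < 3:
        raise ValueError("need at least 3 distinct (x, y) points to interpolate")
    centered = uniq - uniq.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("interpolation points are collinear in (x, y)")
    rbf = RBFInterpolator(uniq, zm, kernel="thin_plate_spline", smoothing=0.0)
    hull = Delaunay(uniq)
    nx, ny = lateral_shape
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    support = hull.find_simplex(pts) >= 0
    zfull = np.full(nx * ny, np.nan)
    sel = np.flatnonzero(support)
    for lo in range(0, len(sel), chunk):
        sl = sel[lo:lo + chunk]
        zfull[sl] = rbf(pts[sl])
    return SurfaceModel(z=zfull.reshape(nx, ny), support=support.reshape(nx, ny))


@dataclass
class Shell:
    """Voxelized thin shell of thickness epsilon around a surface.

    The surface is first snapped to its nearest z-plane per column,
    ``z0 = rint(Z_hat / dz)``; the shell column is then the planes with
    ``|z - z0| <= floor(eps / (2 dz))``, clipped to the stack.  This keeps
    the layer decomposition symmetric: 2*floor(eps/(2 dz)) + 1 layers (7
    at the 3 um / 0.5 um defaults, a single layer in the degenerate
    eps = dz case), each one voxel deep and parallel to the surface, with
    layer 0 the plane nearest the surface.
    """

    z0: np.ndarray           # nearest-plane index per column (int, invalid where ~support)
    support: np.ndarray      # columns where the surface (and hence shell) exists
    half_layers: int         # floor(eps / (2 dz))
    nz: int
    dz: float
    epsilon: float

    @property
    def n_layers(self) -> int:
        return 2 * self.half_layers + 1

    @property
    def layer_offsets(self) -> np.ndarray:
        return np.arange(-self.half_layers, self.half_layers + 1)

    def column_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        zlo = np.clip(self.z0 - self.half_layers, 0, self.nz - 1)
        zhi = np.clip(self.z0 + self.half_layers, 0, self.nz - 1)
        return zlo, zhi

    def n_voxels(self) -> int:
        zlo, zhi = self.column_bounds()
        return int(np.sum((zhi - zlo + 1)[self.support]))

    def layer_plane(self, offset: int) -> tuple[np.ndarray, np.ndarray]:
        """(valid_mask, z_index) of the layer at signed offset from the surface."""
        zp = self.z0 + offset
        valid = self.support & (zp >= 0) & (zp < self.nz)
        return valid, zp

    def contains(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=np.int64).reshape(-1, 3)
        x, y, z = coords.T
        inside = self.support[x, y]
        off = z - self.z0[x, y]
        return inside & (np.abs(off) <= self.half_layers) & (z >= 0) & (z < self.nz)

    def layer_of(self, coords: np.ndarray) -> np.ndarray:
        """Signed layer index z - z0 of each coordinate (only meaningful
        where :meth:`contains` is True)."""
        coords = np.asarray(coords, dtype=np.int64).reshape(-1, 3)
        return coords[:, 2] - self.z0[coords[:, 0], coords[:, 1]]

    def all_coords(self) -> np.ndarray:
        parts = []
        for off in self.layer_offsets:
            valid, zp = self.layer_plane(off)
            xs, ys = np.nonzero(valid)
            parts.append(np.column_stack([xs, ys, zp[xs, ys]]))
        if not parts:
            return np.empty((0, 3), dtype=np.int64)
        coords = np.concatenate(parts).astype(np.int64)
        return np.unique(coords, axis=0)  # clipping can duplicate boundary planes

    def member_mask(self) -> np.ndarray:
        nx, ny = self.z0.shape
        mask = np.zeros((nx, ny, self.nz), dtype=bool)
        c = self.all_coords()
        mask[c[:, 0], c[:, 1], c[:, 2]] = True
        return mask

    def random_voxels(self, n: int, rng: np.random.Generator) -> np.ndarray:
        coords = self.all_coords()
        if n > len(coords):
            raise ValueError(f"requested {n} voxels but the shell has {len(coords)}")
        pick = rng.choice(len(coords), size=n, replace=False)
        return coords[pick]


def build_shell(surface: SurfaceModel, epsilon: float, nz: int, dz: float) -> Shell:
    """Voxelize the epsilon-thick shell around an estimated surface.

    Columns whose snapped surface plane falls outside the stack are
    dropped from the support; layers are clipped to the stack bounds.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    z0f = np.rint(np.asarray(surface.z, dtype=float) / dz)
    support = surface.support & np.isfinite(z0f)
    z0 = np.where(support, z0f, 0).astype(np.int64)
    support = support & (z0 >= 0) & (z0 < nz)
    half_layers = int(np.floor(epsilon / (2 * dz) + 1e-9))
    return Shell(z0=z0, support=support, half_layers=half_layers,
                 nz=int(nz), dz=float(dz), epsilon=float(epsilon))


def estimate_surface(bright_xy: np.ndarray, bright_z_um: np.ndarray,
                     lateral_shape: tuple[int, int],
                     width_fraction: float = 1 / 3,
                     overlap_fraction: float = 0.5,
                     n_trials: int = 500,
                     inlier_tol: float = 1.5,
                     min_inliers: Optional[int] = None,
                     outlier_removal: bool = True,
                     seed: int = 0) -> tuple[SurfaceModel, WindowGrid, list]:
    """Windowed (RANSAC) fits -> fusion -> biharmonic interpolation."""
    grid = make_windows(lateral_shape, width_fraction, overlap_fraction)
    xy = np.asarray(bright_xy, dtype=float).reshape(-1, 2)
    z = np.asarray(bright_z_um, dtype=float).reshape(-1)
    ss = np.random.SeedSequence(seed)
    fits: list[Optional[LocalFit]] = []
    for wid, (win, sub) in enumerate(zip(grid.windows, ss.spawn(len(grid.windows)))):
        inside = win.contains(xy[:, 0], xy[:, 1])
        ids = np.flatnonzero(inside)
        if outlier_removal:
            fit = ransac_fit_window(xy[ids], z[ids], n_trials=n_trials,
                                    inlier_tol=inlier_tol, min_inliers=min_inliers,
                                    seed=np.random.default_rng(sub), window=win)
        else:
            fit = lstsq_fit_window(xy[ids], z[ids], window=win)
        if fit is not None:
            fit.inlier_ids = ids[fit.inlier_ids]  # back to global indexing
            fit.window_id = wid
        fits.append(fit)
    fxy, fz, _ = fuse_and_filter(fits, grid, xy, z)
    keep = filter_scattered(fxy)
    model = interpolate_surface(fxy[keep], fz[keep], lateral_shape)
    return model, grid, fits
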