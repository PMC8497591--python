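"""Fractional pre-scan, background normalization and bright-point detection.

A pre-scan samples a fraction eta (~0.1%) of the voxel space.  From those
samples alone, a smooth multiplicative background a(x, y, z) and a scalar
spread sigma are estimated so that the normalized signal

    r = (s - a) / (a * sigma)

is approximately N(0, 1) on background voxels.  Bright voxels are then the
samples with r > T, where T is set from a chosen probability of false
alarm via the Gaussian tail:  pfa = (1/2) * (1 - erf(T / sqrt(2))).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .acquisition import SampleSet

__all__ = ["NormalizationModel", "DetectionParams", "draw_prescan",
           "fit_background", "normalize", "threshold_from_pfa",
           "pfa_from_threshold", "detect_bright"]

# quadratic background model: 10 monomials in normalized (u, v, w)
_N_TERMS = 10


def _design(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(u), u, v, w,
                            u * u, v * v, w * w, u * v, u * w, v * w])


@dataclass
class NormalizationModel:
    """Background estimate a(x, y, z) (low-order polynomial) and scalar sigma.

    ``center``/``halfwidth`` map voxel indices onto [-1, 1] per axis for
    numerical conditioning; ``coeffs`` act on the 10 quadratic monomials.
    """

    coeffs: np.ndarray
    center: np.ndarray
    halfwidth: np.ndarray
    sigma_hat: float
    fit_meta: dict = field(default_factory=dict)

    def background(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        u, v, w = ((coords - self.center) / self.halfwidth).T
        return _design(u, v, w) @ self.coeffs

    def background_volume(self, shape: tuple[int, int, int],
                          chunk: int = 2_000_000) -> np.ndarray:
        """Evaluate a(x, y, z) on the full grid (chunked)."""
        nx, ny, nz = shape
        out = np.empty(nx * ny * nz, dtype=np.float32)
        idx = np.arange(nx * ny * nz)
        for lo in range(0, len(idx), chunk):
            sl = idx[lo:lo + chunk]
            coords = np.column_stack(np.unravel_index(sl, shape))
            out[sl] = self.background(coords)
        return out.reshape(shape)


@dataclass
class DetectionParams:
    """Bundle of the detection settings actually used in a run."""

    pfa: float
    T: float
    eta: float

    def __post_init__(self) -> None:
        if not 0 < self.eta < 1:
            raise ValueError("eta must be in (0, 1)")
        if not np.isclose(self.T, threshold_from_pfa(self.pfa), atol=1e-9):
            raise ValueError("T inconsistent with pfa")

    @classmethod
    def from_pfa(cls, pfa: float, eta: float) -> "DetectionParams":
        return cls(pfa=pfa, T=threshold_from_pfa(pfa), eta=eta)


def draw_prescan(shape: tuple[int, int, int], eta: float, seed: int) -> np.ndarray:
    """Draw ``round(eta * N)`` distinct voxels uniformly over the volume.

    The physical instrument projects random lattices of point
    illumination; here this is realized as uniform sampling without
    replacement, which has the same per-voxel inclusion statistics.
    """
    if not 0 < eta <= 1:
        raise ValueError("eta must be in (0, 1]")
    n_total = int(np.prod(shape))
    count = int(round(eta * n_total))
    if count == 0:
        raise ValueError(f"eta={eta} yields zero pre-scan points")
    rng = np.random.default_rng(seed)
    if count >= n_total:
        flat = np.arange(n_total)
    else:
        chosen = np.empty(0, dtype=np.int64)
        while len(chosen) < count:
            draw = rng.integers(0, n_total, size=int(1.2 * (count - len(chosen)) + 16))
            chosen = np.unique(np.concatenate([chosen, draw]))
        flat = rng.choice(chosen, size=count, replace=False)
    return np.column_stack(np.unravel_index(np.sort(flat), shape)).astype(np.int64)


def fit_background(samples: SampleSet,
                   shape: tuple[int, int, int] | None = None,
                   n_iterations: int = 3,
                   trim_quantile: float = 0.9) -> NormalizationModel:
    """Robust low-order polynomial background fit from pre-scan samples.

    Iteratively trimmed least squares: after each fit, samples whose
    absolute median-centred relative residual ``|s/a - 1 - med|`` exceeds
    the ``trim_quantile`` of the retained set are dropped (3 iterations by
    default), which strips the bright tail while leaving the symmetric
    background population unbiased.  ``sigma_hat`` is the scaled median
    absolute deviation (1.4826 * MAD) of ``s/a - 1`` over *all* samples --
    the MAD itself is robust to the bright minority, and computing it
    untrimmed keeps it a consistent Gaussian spread estimate.
    """
    n = len(samples)
    if n < _N_TERMS * 10:
        raise ValueError(f"need at least {_N_TERMS * 10} samples, got {n}")
    coords = samples.coords.astype(float)
    if shape is not None:
        hi = np.asarray(shape, dtype=float) - 1
        lo = np.zeros(3)
    else:
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
    center = (hi + lo) / 2
    halfwidth = np.maximum((hi - lo) / 2, 1.0)
    u, v, w = ((coords - center) / halfwidth).T
    X = _design(u, v, w)
    s = samples.raw

    keep = np.ones(n, dtype=bool)
    coeffs = None
    for _ in range(n_iterations):
        coeffs, _, rank, _ = np.linalg.lstsq(X[keep], s[keep], rcond=None)
        if rank < _N_TERMS:
            if len(np.unique(coords[keep], axis=0)) < _N_TERMS:
                raise ValueError("degenerate samples: background fit is rank-deficient")
        a = X @ coeffs
        res = s / np.clip(a, 1e-12, None) - 1.0
        med = np.median(res[keep])
        dev = np.abs(res - med)
        thr = np.quantile(dev[keep], trim_quantile)
        keep &= dev <= thr
        if keep.sum() < _N_TERMS:
            raise ValueError("trimming left too few samples for the background fit")
    coeffs, *_ = np.linalg.lstsq(X[keep], s[keep], rcond=None)
    a = X @ coeffs
    if np.any(a[keep] <= 0):
        raise ValueError("background fit is non-positive on retained samples")
    res = s / np.clip(a, 1e-12, None) - 1.0
    mad = np.median(np.abs(res - np.median(res)))
    sigma = 1.4826 * float(mad)
    if sigma <= 0:
        sigma = max(float(np.std(res)), 1e-12)  # noise-free degenerate floor
    return NormalizationModel(
        coeffs=coeffs, center=center, halfwidth=halfwidth, sigma_hat=sigma,
        fit_meta={"n_samples": n, "n_retained": int(keep.sum()),
                  "n_iterations": n_iterations, "trim_quantile": trim_quantile})


def normalize(samples: SampleSet, model: NormalizationModel) -> SampleSet:
    """Apply the background normalization r = (s - a) / (a * sigma)."""
    a = model.background(samples.coords)
    if np.any(a <= 0):
        i = int(np.flatnonzero(a <= 0)[0])
        raise ValueError(
            f"background estimate non-positive at voxel {tuple(samples.coords[i])}")
    r = (samples.raw - a) / (a * model.sigma_hat)
    return samples.with_normalized(r)


def normalize_values(coords: np.ndarray, raw: np.ndarray,
                     model: NormalizationModel) -> np.ndarray:
    """Array-level variant of :func:`normalize`."""
    a = model.background(coords)
    if np.any(a <= 0):
        raise ValueError("background estimate non-positive at a queried voxel")
    return (np.asarray(raw, dtype=float) - a) / (a * model.sigma_hat)


def threshold_from_pfa(pfa: float) -> float:
    """Detection threshold T solving pfa = (1/2)(1 - erf(T / sqrt(2)))."""
    if not 0 < pfa < 0.5:
        raise ValueError("pfa must be in (0, 0.5)")
    return float(-special.ndtri(pfa))


def pfa_from_threshold(T: float) -> float:
    """Gaussian upper-tail probability beyond T (inverse of the above)."""
    return float(0.5 * (1.0 - special.erf(T / np.sqrt(2.0))))


def detect_bright(samples: SampleSet, T: float) -> SampleSet:
    """Samples whose normalized intensity strictly exceeds T."""
    if samples.normalized is None:
        raise ValueError("samples must be normalized before detection")
    return samples.subset(samples.normalized > T)
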