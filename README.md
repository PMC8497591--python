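# episcan — adaptive smart-scanning for epithelial surfaces

Scanning fluorescence microscopes deposit light on the whole voxel grid,
yet when the structure of interest is a junctional mesh (e.g.
E-cadherin:GFP adherens junctions) lying on a curved epithelial sheet,
the informative voxels occupy only a few percent of the stack.  Since
photobleaching and phototoxicity scale with the number of scanned
voxels, a raster scan wastes most of its light budget on dark volume.

`episcan` implements, entirely in software, the computational stack of an
adaptive scan-path microscope, for microscopists and image analysts who
want to study, tune or emulate such acquisition schemes:

1. **Fractional pre-scan** — a random subset Ω₀ of ~0.1% of the voxels.
2. **Normalization** — a robust low-order background fit â(x, y, z) and
   spread σ̂ from Ω₀ alone give the normalized signal
   r̂ = (s − â) / (â·σ̂), ≈ N(0, 1) on background.  Bright voxels are
   detected by the significance test r̂ > T with
   pfa = ½[1 − erf(T/√2)]; pfa = 1% ⇒ T ≈ 2.33.
3. **Surface estimation** — local second-order polynomial fits of the
   bright-point z-coordinates in overlapping lateral windows with
   RANSAC-style outlier rejection, fused and interpolated by a
   biharmonic (thin-plate) spline into Ẑ(x, y).
4. **Shell** — Ŝ = {(x, y, z) : |z − Ẑ(x, y)| ≤ ε/2}, ε = 3 µm,
   decomposed into one-voxel layers parallel to the surface.
5. **Shell-scan** — exhaustive acquisition of Ŝ (typically <5% of the
   volume for a curved tissue).
6. **Propagative scan** — iterative acquisition inside Ŝ: the normalized
   intensity of unexplored voxels is extrapolated from the nearest
   acquired neighbour in the same layer (xy distance ≤ β pixels), only
   voxels predicted bright (r > T, at most one per lateral column and
   only if no brighter voxel is already acquired there) are scanned, and
   the scan stops at the first iteration without new acquisitions.
   The nearest-neighbour rule naturally propagates along cell contours.

There is no microscope here: a **voxel oracle** serves intensities on
demand either from a synthetic phantom (curved surface, Voronoi cell
mesh, inhomogeneous background, multiplicative noise, optional decoy
surface, outliers and photobleaching — with exact ground truth) or from
any user-supplied multi-page TIFF full-scan stack (emulation mode).  A
dose ledger makes "light dose = number of uniquely scanned voxels" a
first-class quantity.

## Worked example

```python
import numpy as np
import episcan as ep

cfg = ep.PhantomConfig(nx=256, ny=256, nz=50, surface_kind="quadratic",
                       tissue_xy_coverage=0.3, cell_diameter=2.5, seed=1)
gt = ep.generate(cfg)

est = ep.estimate_shell(gt.volume, eta=0.002, pfa=0.01, epsilon=3.0, seed=2)
shell_res = ep.shell_scan(est.oracle, est.shell, est.model, est.ledger)

led = ep.DoseLedger(cfg.shape); led.record(est.prescan.coords)
params = ep.PropagativeParams(T=est.params.T, beta=1, seed=3)
prop = ep.propagative_scan(est.oracle, est.shell, est.model, params,
                           led, est.prescan)
```

which prints, with the bookkeeping shown in the repository's test suite:

```
pre-scan samples      : 6554
detected bright points: 270  (T = 2.326)
sigma_hat             : 0.1054
shell-scan dose       : 4.01 % of the volume
propagative dose      : 1.69 %  (15 iterations, converged=True)
columns never sampled : 65.9 %
bright-voxel capture  : 87.6 %
```

Reading: from a 0.2% pre-scan of a curved small-cell phantom (tissue
covering ~30% of the field), 270 voxels are flagged bright; the robust
fit recovers the noise level (σ̂ ≈ 0.105 for a generator coefficient of
variation of 0.1).  Scanning only the 3 µm shell costs 4% of a full
scan, the contour-following propagative scan 1.7%, and ~88% of the true
epithelial bright voxels fall inside the estimated shell.

A thin CLI wraps the same pipeline (`episcan phantom`,
`episcan shell-scan`, `episcan prop-scan`), accepting either a phantom
config YAML or a TIFF stack to emulate on; see `episcan --help`.

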