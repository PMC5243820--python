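# canopyefd

Canopy outline morphometrics with elliptic Fourier descriptors (EFD).

The package turns top-down RGB canopy photographs into closed outlines and
compact shape descriptors:

1. **Segmentation** — HSV thresholding (green hue band + saturation floor),
   largest-connected-component cleanup, hole filling, and Moore-neighbor
   boundary tracing. Contours are reported in an `(x, y)` frame with y
   increasing upward and are traced counter-clockwise.
2. **Descriptors** — chain coding, elliptic Fourier coefficient quadruples
   `(a_n, b_n, c_n, d_n)` plus DC terms `(A0, C0)`, truncation by a
   reconstruction-error sweep (max pointwise deviation normalized by the
   first-harmonic major axis), and Kuhl–Giardina-style standardization
   making descriptors invariant to size, rotation, and contour start point
   (`a_1* = 1`, `b_1* = 0`, `c_1* = 0`).
3. **Morphometrics** — aspect ratio, roundness, circularity, solidity from
   either the original contour or its reconstruction, computed on the
   traced polygon (moment-equivalent ellipse, shoelace area, convex hull).
4. **Diversity / genetics** — mean-centered PCA on standardized
   coefficients, per-group convex-hull spread in PC space, per-group CV,
   Tukey 1.5×IQR outlier flags, and RCBD ANOVA with broad-sense
   heritability `H² = σ²_g / (σ²_g + σ²_e / k)`.
5. **Synthetic data** — seeded star-convex canopy images with ground-truth
   masks/contours/traits, and RCBD trait simulations with known variance
   components, so everything is testable offline.

## CLI

The console script `canopyefd` exposes the workflow:

```bash
# generate a 20-image synthetic suite with ground truth
canopyefd simulate canopy --out-dir scratch/suite --n 20 --seed 7

# full batch pipeline: probe outlines at N=10, find the most complex,
# select the optimal harmonic count on it, re-express all outlines,
# standardize, and compute traits
canopyefd run scratch/suite --out scratch/run

# individual steps
canopyefd segment scratch/suite/canopy_000.png --out-contour c.csv --out-mask m.png
canopyefd efd compute c.csv --n-harmonics 100 --out efd.csv
canopyefd efd select-n c.csv --threshold 1.0 --sweep-max 1000
canopyefd efd standardize efd.csv --out std.csv
canopyefd efd reconstruct efd.csv --n 100 --points 512 --out reco.csv
canopyefd traits compute --from contour --out traits.csv c.csv
canopyefd diversity pca std.csv --out-scores scores.csv
canopyefd simulate rcbd --n-genotypes 300 --blocks 3 --sigma2-g 2 --out rcbd.csv
canopyefd diversity herit rcbd.csv --out herit.csv
```

Segmentation thresholds (`hue_min`, `hue_max`, `saturation_min`,
`min_component_fraction`) can be supplied as a JSON file via `--config`;
the defaults accept green-through-yellow hues at saturation ≥ 0.25.

## Notes on conventions

- EFD tables are CSVs (`id, A0, C0, T, a_1, b_1, c_1, d_1, …`) written at
  full float precision; write→read round trips are lossless. Standardized
  tables add the normalization frame (`L, psi, theta, A0, C0, xm, ym`).
- The start-point phase of the standardization is defined modulo π; the
  implementation resolves the ambiguity by requiring the first significant
  even-harmonic coefficient to be positive, making the normal form unique,
  idempotent, and invariant under similarity transforms. Reflection is
  never applied, so mirrored shapes get different descriptors.
- Perimeters of pixel chains are summed chain-code step lengths (1 / √2)
  with no smoothing correction; digitized perimeters are biased upward,
  which affects circularity comparisons between differently smoothed
  versions of the same outline.
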