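# Methods

## Camera model and the pixel-to-area map

The package treats the phone camera as a thin lens imaging a planar
food surface perpendicular to the optical axis.  With object distance
*u*, image distance *v* and focal length *f* related by
1/*v* + 1/*u* = 1/*f*, the magnification is *v*/*u* = *f*/(*u* − *f*),
so a feature of length *L* on the image frame corresponds to
*L*·(*u* − *f*)/*f* in the object plane.

Sensor size is eliminated by working on the *35-mm-equivalent frame*:
the frame a full-frame (36 × 24 mm) camera would use for the same
field of view.  A 4:3 photo behaves as if formed on a frame with the
full-frame diagonal (43.27 mm) and 4:3 sides — 34.61 × 25.96 mm,
carried at the conventional 3-significant-figure values 34.6 and
26.0 mm; a 3:2 photo uses 36 × 24 mm itself.  The same geometry gives
the focal-length conversions *f*₃₅ = 34.6·*f*/*w* (4:3, sensor width),
36.0·*f*/*w* (3:2), and 43.3·*f*/*d* (diagonal, aspect-independent,
preferred when both dimensions are known).  The acceptance script
re-derives all four constants from first principles.

**Units.** Object distance is in centimetres, focal lengths in
millimetres, outputs in cm/cm².  In this mixed convention the inverse
magnification (*u*ₘₘ/*f* − 1) becomes (*u*/*f*₃₅ − 0.1), which is why
that bracket appears throughout.  The convention is load-bearing: a
property test asserts the cm-route and an all-mm thin-lens oracle
agree to 1 × 10⁻⁹ relative over a grid of (u, f₃₅) pairs, which would
fail for any other unit pairing.

Pixel → area: the short image side (*a* pixels) spans 26.0 mm on the
equivalent frame, so one pixel covers
[(26.0/*a*)·(*u*/*f*₃₅ − 0.1)]² cm² and a region of *n* pixels covers
*n* times that.  The short-side form is canonical; the long-side form
(34.6/*b*) must agree within the 1% aspect-consistency tolerance
enforced on `CameraSpec` and serves as a cross-check only.
Orientation is normalised on construction (short side first), since a
pixel count pairs with a frame side by physical length, not by file
orientation.  *f*₃₅ resolution order: explicit argument, then the
`FocalLengthIn35mmFilm` EXIF tag, then config default.

Assumptions and limits: planar food viewed top-down, negligible lens
distortion, no perspective correction for food height.  Tall foods
project a larger area than their base; that bias is inherent to the
method, not to this implementation.

## Segmentation

The food region is delineated classically inside a caller-supplied
region box (whole image by default; subject detection is a pluggable
interface, deliberately not a trained model).  Stages: grayscale,
Canny (σ = 1.6, scikit-image's default hysteresis thresholds — food
against a white background is a strong step), morphological closing
(disk radius 3) to seal gaps, hole filling, largest connected
component, then one erosion by a disk of radius 1 to strip the
half-edge band that closing leaves outside the true boundary — without
it the recovered area carries a systematic positive bias of roughly
one pixel of perimeter.  The component boundary is traced at the 0.5
level into a sub-pixel polygon.

**Pixel-inclusion rule.** A pixel belongs to a region iff its centre
lies strictly inside the boundary polygon under the even-odd rule;
boundary pixels are excluded.  Coordinates are 0-based (row, col) with
pixel (i, j) occupying [i, i+1) × [j, j+1), centre at (i+0.5, j+0.5);
boxes are half-open.  The rule is exact and oracle-checkable: tests
compare the vectorised ray-casting count against an independent
per-pixel crossing loop on random polygons, and the reported
`pixel_count` is always computed from the returned polygon, so the two
cannot drift apart.

Plate detection is a circular Hough search (coarse radius grid, then
1-px refinement) with deliberately low Canny hysteresis thresholds
(0.01/0.03 absolute) because a white-plate rim on a white table is a
weak step.  Candidates above a normalised score of 0.25 are ranked by
total edge support (score × radius), which prefers the dominant
tableware circle over smaller, equally crisp circles.  The plate is
reported for tableware area only — physical scale always comes from
capture geometry, never from an assumed plate size.  "No plate" and
"no food contour" are not-found results (`None`), not exceptions;
the CLI maps them to a distinct exit code.

## Area → weight calibration

Each of the three morphology traits (Block/Thick bar, Slice/Silk,
Grain/Granule) has a shipped linear model weight = slope·area +
intercept fitted on 204 machine-recognised-area observations (slopes
2.5757 / 1.9684 / 2.2069 g cm⁻², intercepts −49.03 / −46.3 /
−62.13 g).  Trait assignment is a vocabulary lookup over the 51
registered dishes, never inferred from pixels.  Negative predictions —
possible below 19–28 cm² because of the negative intercepts — are
clipped to zero and flagged rather than returned as impossible
weights.

A separate shipped line relates machine-recognised to actual area
(machine = 0.7378·actual + 12.765, R² = 0.9591): segmentation
systematically under-measures dishes larger than ~49 cm².  Its inverse
is available as an area correction but is **off by default**: the
trait models already regress on machine areas, so correcting first
would double-count the bias.  The response-variable orientation (y =
machine area) is itself an interpretation — the source material does
not name the variables — chosen because it is the only one consistent
with machine areas being systematically smaller than actual areas over
the relevant range; the switch exists for models calibrated against
physically measured areas.

User calibration uses unweighted OLS (`scipy.stats.linregress`) per
trait, requiring ≥ 3 records and non-degenerate area variance, and
reports slope/intercept standard errors for Student-t confidence
intervals.

## Validation statistics

Two-sided throughout: paired t (implemented, and tested, as the
one-sample t of the differences, df = n − 1), Pearson r with r², and
per-class accuracy aggregation.  Zero-variance inputs return an
explicitly flagged degenerate result instead of ±∞ — identical
vectors give t = 0, p = 1; a constant nonzero difference gives
flagged NaNs.  No multiple-testing correction is applied; the handful
of tests reported together are treated as descriptive.

## Synthetic scenes and calibration sets

The generator emulates the controlled capture protocol the shipped
calibration assumes: top view at 40.6 cm with *f*₃₅ = 46 mm (the
field of view is then 20.4 × 27.1 cm regardless of resolution; the
default render is 480 × 640 px, ≈ 0.0424 cm/px), white background
(0.97), plate disk (radius 9 cm, intensity 0.88), one convex food
polygon (intensity 0.25), Gaussian pixel noise (σ = 0.02).  Scenes are
specified in centimetres and mapped to pixels through the same
geometry the estimator inverts, so ground truth is exact: shoelace
area of the cm polygon, interior pixel count of the mapped polygon
under the same centre-inclusion rule, and weight = trait model(area)
plus a recorded noise draw, truncated at zero.  Rendering is
bit-reproducible per seed.

Calibration sets draw machine areas uniformly on **60–150 cm²**
(configurable) and add N(0, σ) weight noise with σ chosen per trait so
the fitted R² matches the shipped models' (σ² = signal
variance · (1/R² − 1), giving ≈ 11.6 / 19.3 / 14.1 g for
block/slice/grain over the default range).  The lower bound of
60 cm² is deliberate: the trait lines cross zero at up to 28.2 cm²,
and with ~12–19 g of residual noise a lower bound near the zero
crossing would make the zero-truncation censor a substantial fraction
of draws, biasing OLS and invalidating both noiseless recovery and
confidence-interval coverage; from 60 cm² the smallest mean weight is
≈ 4.8σ above zero and truncation is vanishingly rare.  Each record
also carries the actual area implied by inverting the shipped
machine-vs-actual line, mirroring the systematic under-recognition of
large dishes.

What passing closed-loop tests shows — and does not.  Recovery of
area within 3% and of the generative weight on 50-scene suites shows
the geometry, segmentation, counting and calibration stages compose
correctly and without systematic bias on high-contrast planar scenes.
It does not certify performance on real photographs, where texture,
shadow, specular highlights, food height and imperfect distance
measurement dominate the error budget.

## Numerical and design choices

- Problem sizes: closed-loop suites use 50 scenes at 480 × 640 px
  with food areas 30–100 cm²; parameter-recovery uses 204 records per
  trait and 100 replicates — large enough for stable coverage
  estimates while keeping the full suite fast.
- Sub-3% closed-loop tolerance decomposes as ≈ 1 px of boundary
  uncertainty on a ≥ 97 px-radius region (≲ 2%) plus rasterisation
  noise; the erosion step removes the otherwise-dominant systematic
  term.
- Degenerate inputs: zero-size food renders to ground truth n = 0 and
  a not-found segmentation; polygons with < 3 vertices, empty boxes,
  u/f₃₅ ≤ 0.1, and zero-variance fits all raise typed errors mapped
  to distinct CLI exit codes (3 geometry, 4 segmentation, 5 model).
- Boundary polygon rings longer than 4000 vertices are subsampled
  before the point-in-polygon count; at that density the decimation
  error is far below the discretisation noise.
- The classifier is a deterministic stub (sidecar label files /
  explicit labels) behind a `Classifier` protocol; recognition
  accuracy is therefore out of this package's validated scope.
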