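# foodscale

Estimate the weight of food on a plate from a single top-view phone
photograph — no kitchen scale, no wearable, no fiducial marker.  The
package is aimed at dietary-monitoring and nutrition-assessment work
where the only instruments available are a phone camera and a known
shooting height.

## How it works

1. **Segment** the food region in the photo (Canny edges inside a
   region-of-interest box, morphological closing, boundary tracing)
   and count its interior pixels *n*.  A circular Hough transform can
   additionally report the tableware circle.
2. **Convert pixels to physical area** with 35-mm-equivalent
   focal-length geometry.  For a 4:3 image whose short side holds *a*
   pixels, taken at object distance *u* (cm) with equivalent focal
   length *f*₃₅ (mm), the real-world area is

   &nbsp;&nbsp;&nbsp;&nbsp;*S* = *n* · [(26.0 / *a*) · (*u*/*f*₃₅ − 0.1)]²  cm²

   where 26.0 mm is the short side of the 4:3 equivalent frame (same
   diagonal as a 36 × 24 mm full frame) and the bracket is the inverse
   thin-lens magnification in this deliberate mixed cm/mm unit
   convention (`foodscale.camera_geometry` documents and tests the
   derivation from 1/*v* + 1/*u* = 1/*f*).
3. **Map area to weight** with a linear calibration specific to the
   food's morphology trait — Block/Thick bar, Slice/Silk, or
   Grain/Granule:

   | trait | model (x = machine area, cm²) | r | R² |
   |---|---|---|---|
   | Block/Thick bar | y = 2.5757 x − 49.03 | 0.986 | 0.971 |
   | Slice/Silk | y = 1.9684 x − 46.3 | 0.937 | 0.878 |
   | Grain/Granule | y = 2.2069 x − 62.13 | 0.972 | 0.944 |

   The trait comes from a label→trait lookup over a 51-dish
   vocabulary (recognition itself is a pluggable interface with a
   deterministic offline stub).  An OLS fitter lets you calibrate your
   own models from `(area, weight)` tables, and a synthetic scene
   generator renders plate images with exactly known geometry and
   weight for end-to-end testing.

## Worked example

Render a synthetic scene with known ground truth, then estimate:

```sh
foodscale simulate --n-scenes 1 --seed 0 --out demo/
foodscale estimate demo/scene_000.png --distance-cm 40.6 --f35 46 --label "Steak"
```

```json
{
  "image": "scene_000.png",
  "label": "Steak",
  "trait": "Block/Thick bar",
  "pixel_count": 41183,
  "area_cm2": 74.00678520793953,
  "weight_g": 141.58927666008984,
  "clipped": false,
  "f35_mm": 46.0,
  "distance_cm": 40.6,
  "model_id": "BLOCK_THICK_BAR:shipped-default"
}
```

The segmenter counted 41,183 food pixels; at 40.6 cm and *f*₃₅ = 46 mm
each pixel covers 1.797 × 10⁻³ cm², giving 74.0 cm² (the scene's
generative truth is 74.6 cm², a 0.8% error), and the block-trait line
turns that into 141.6 g against a true 143.1 g.  `clipped` would flag
a prediction forced up to zero by the negative intercept.

Other verbs: `foodscale calibrate` (measure areas for photographed
dishes with known weights into a calibration CSV), `foodscale fit`
(OLS per trait from that CSV), `foodscale validate` (paired t,
Pearson r, and one-sample t of estimated − measured weights).

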