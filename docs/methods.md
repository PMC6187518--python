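# Methods

## Detection model

The detector assumes one denudated metaphase-II oocyte per image, roughly
circular to mildly elliptical (eccentricity near a circle), with at most
one polar body lying in the perivitelline space between the oolemma and
the zona pellucida. It operates on a single still image — no frame-to-
frame tracking — and makes no assumption about background colour or
contrast polarity: all stages work on gradient magnitudes, and Hough votes
are cast along both gradient polarities.

### Preprocessing

RGB is collapsed to grayscale by the unweighted channel mean, then
linearly stretched so the observed intensity range maps onto
`[0, 2^n − 1]` (n = bit depth, 8 by default). A constant image cannot be
stretched and passes through unchanged with a warning. Smoothing is 2-D
correlation with a normalised binomial weighted-average mask; borders are
edge-replicated so no artificial boundary gradients are injected into the
vote. The 5×5 mask (outer product of `[1 4 6 4 1]`, normaliser 256) is the
default working size; the 3×3 `[1 2 1; 2 4 2; 1 2 1]/16` mask is
selectable (`mask_size=3`). Rounding, wherever intensities are quantised,
is nearest-integer with ties to even; internal arithmetic stays in
floating point and is quantised only at file-output boundaries.

### Gradients and edge selection

Gradients come from the 3×3 Sobel operator (edge-replicated borders),
with `x` the column axis and `y` the row axis pointing down; orientation
is `atan2(Gy, Gx)`, so `cosθ = Gx/‖∇f‖` and `sinθ = Gy/‖∇f‖`. The edge
set is the top `keep_fraction` (default 0.10) of nonzero-magnitude
pixels. The quantile rule moves the threshold up through ties so at most
that fraction survives, except when a tie block extends to the maximum
value, which is kept whole. The fraction bounds the Hough cost on large
rasters; there is no hysteresis or non-maximum suppression — the vote
stage tolerates thick edge bands.

### Gradient-weighted circular Hough transform

Each edge point casts, for every radius in the user range (1-px steps by
default), two votes at `(x ∓ r·cosθ, y ∓ r·sinθ)`, weighted by its
gradient magnitude and binned to the nearest cell of a 2-D accumulator
over centres (the radius is marginalised; sizing is a separate stage).
Alongside the scalar vote sum, the accumulator tracks the vector sum of
vote weights along the cell→voter direction. The peak search runs on the
**isotropic component** `votes − ‖vector sum‖`: a genuine circle centre
receives votes from all around it, so its vector sum cancels, whereas the
offset rings that any larger concentric boundary (oolemma, zona) deposits
receive votes from a single direction and are discounted. Without this
correction the oocyte rim's inward votes focus onto a ring at distance
`a − r` that out-votes any polar-body candidate in polar-body-absent
images.

The peak is the argmax of the 3×3-binomial-smoothed isotropic surface
(ties: smallest row, then column), refined to sub-cell precision by the
centroid of the surrounding window. The window half-width is
`max(1, ⌈0.04·r_min⌉)`: the vote cluster of a true centre spreads roughly
in proportion to the radius, because an orientation error δθ displaces a
vote by `r·δθ`.

**Confidence** is the background-corrected vote mass of the peak window
(raw mass minus the searched region's per-cell median, which removes the
near-uniform plateau concentric structures leave behind) divided by the
vote mass an ideal full circle at `r_min` would deposit:
`2π·r_min × mean vote weight × T²`, with `T = 4.5 px` the nominal
thickness of the gradient band a blurred boundary leaves in the
thresholded edge set (a band of thickness T casts ≈T² times the mass of a
1-px circle: T rings, each matching ≈T radius steps). On this scale a
full sharp boundary scores well above 1 and structureless regions well
below; the detection gate is `min_confidence = 0.25`. The gate is what
produces the "polar body not located" message and rejects out-of-range
radius requests.

### Polar-body search

The oocyte is detected first. The polar-body stage reuses the same
gradient field and edge set, but (i) restricts accumulator cells to the
perivitelline annulus — between 0.95× the fitted rim and the rim padded
by `3·r_max` of the polar-body range, both expressed in the fitted
ellipse's normalised radius so the annulus tracks elliptical rims — and
(ii) drops edge points lying inside the rim before voting. The second
restriction matters: ooplasm granularity just inside the oolemma casts
isotropic vote clusters that land beyond the rim and mimic a small-circle
centre; physically, polar-body boundary evidence can only lie outside the
oolemma. The outer padding admits polar bodies pressed against the zona.

### Elliptical sizing

With the centre fixed from the Hough stage (it is not re-estimated), every
axis-aligned pair `(a, b)` on the radius grid is scored by the mean
gradient magnitude at `K = max(64, ⌈2π·r_max⌉)` equally spaced boundary
points of `x = x₀ + a·cosφ, y = y₀ + b·sinφ`, sampled bilinearly inside
the `2·r_max` window around the centre (no rotation term — the model is
axis-aligned by construction). Ties break to the smaller `a + b`, then
the smaller `a`. The integer-grid optimum is polished by 1-D parabolic
interpolation of the score profile along each axis (clamped to ±½ step
and to the radius range); this sub-pixel step matters at coarse scales,
where one pixel of a 10 px polar-body radius is 10%. The equivalent
diameter `2√(ab)` is the single size figure in the report.

### Report conventions

The image centre `((H−1)/2, (W−1)/2)` stands in for the centre of the
microscope's vision field. Relative positions are
`(Δcol·s, −Δrow·s)` µm — y is negated so bearings are counter-clockwise-
positive from the +x axis (90° points up in the displayed image), and the
polar-body bearing is reported in `[0, 360)`. µm quantities are exactly
the pixel quantities times the calibration; without a calibration the
report stays in pixels. Identical input and configuration produce a
byte-identical JSON report. Per-stage runtimes are logged for information
only; wall-clock speed is hardware-dependent and nothing asserts it.

## Synthetic scenes

The generator renders what the detector needs to be tested against, not
photorealistic optics (no Hoffman/DIC modelling, no pipette or sperm):

- concentric anti-aliased ellipses for the ooplasm (default semi-axes
  70 µm — a 140 µm cell), the perivitelline gap, and the zona pellucida
  ring (16 µm), over an arbitrary background colour;
- band-limited multiplicative granularity inside the ooplasm (Gaussian
  noise at ~1.5 µm correlation length, amplitude 10 intensity units) —
  the texture the weighted-average filter exists to suppress;
- an optional 20 µm polar body placed wholly inside the gap at a given
  bearing and radial fraction;
- optional cumulus-like dark blobs (8–24 µm) near and outside the zona;
- Gaussian blur (default σ = 1.5 px) and additive Gaussian noise
  (default σ = 3 intensity units), then clipping to 8 bits.

The perivitelline gap defaults to 24 µm — wider than physiological —
because the rendered polar body must fit wholly inside the gap, and
because it keeps the zona boundaries outside the standard oocyte radius
range (55–85 µm), so a user range taken from the literature isolates the
oolemma. Scene truth is exact by construction; with a fixed (spec, seed)
pair rendering is bit-reproducible, and in the magnification suite the µm
geometry is invariant while the scale varies over 0.25–1.0 µm/px (0.5×–2×
of the default), with the raster auto-sized to keep the zona in frame.

Suites mirror the four evaluation categories: distinct background
colours; polar-body bearings evenly spanning [0, 360) with small random
oocyte offsets; magnification sweeps; and clutter counts of 5–20. The
default suite size is 80 scenes per category, with smaller sizes for
quick runs; `scripts/acceptance.py` uses an 80-scene clean mix plus
20-scene single-factor suites, which keeps the full regeneration around a
minute on one CPU.

What passing these benchmarks does **not** show: robustness to real
cumulus morphology (the blob clutter is a geometric stand-in, so the
clutter suite is only required to degrade polar-body detection relative
to clean scenes), to debris inside the perivitelline space, to
out-of-focus polar bodies, to uneven illumination, or to multi-oocyte
fields.

## Numerical and design choices

- **Rounding**: ties-to-even everywhere an intensity is quantised;
  documented and fixed rather than left to chance.
- **Border policy**: edge replication for smoothing and gradients.
- **Vote binning**: nearest cell; out-of-image votes discarded.
- **Degenerate inputs**: constant images pass preprocessing unchanged
  (warning) and yield "not found"; an empty edge set yields an empty
  accumulator (warning); an all-zero or fully masked accumulator is a
  no-detection; a zero-gradient fitting window is a no-fit; coincident
  centres make the bearing undefined (error).
- **Centre bias**: gradient-magnitude weighting lets granular texture
  modulate rim votes, which costs the oocyte centre a few pixels
  (≈1–2 µm at 0.5 µm/px) relative to an unweighted vote on clean
  renders. This is the accepted price of the weighting's robustness to
  blur; the positional error budget (10 µm) absorbs it.
- **Known limitations**: no rotated-ellipse model; the polar-body stage
  needs a found oocyte; confidence calibration assumes the boundary band
  thickness of moderately blurred micrographs (T = 4.5 px) — heavily
  defocused images are rejected by the gate rather than measured, which
  is the intended failure mode.
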