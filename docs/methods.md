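# Methods

## Recognition pipeline

The localization problem is single-object: each brightfield frame contains
at most one zebrafish embryo or larva, plus possible debris. The pipeline
assumes the sample is distinguishable from the background by intensity
(bright-on-dark by default; a polarity flag handles the opposite
contrast), that the injection target is the largest near-circular
structure in the segmented frame — the chorion outline of an embryo, the
yolk sac of a larva — and that debris blobs are smaller than the sample.

**Graying.** Mean of the three RGB channels. The exact mean is quantized
to 8 bits by flooring (configurable to nearest-integer or kept exact);
the choice only moves histogram mass by one bin and has no measurable
effect downstream.

**Maximum-entropy threshold.** Kapur's criterion: choose the threshold
`k` maximizing the sum of Shannon entropies of the normalized background
(`i ≤ k`) and foreground (`i > k`) gray-level distributions. Conventions:
`0·ln 0 = 0`; candidates where either class is empty are excluded;
a histogram with a single occupied bin raises a degenerate-histogram
error naming the bin; argmax ties break toward the smallest `k` so runs
are reproducible. The scan is computed with cumulative sums via the
identity `H0(k) = ln P0 + s(k)/P0`, `s(k) = −Σ_{i≤k} p_i ln p_i`, and the
full per-candidate audit trail (`p`, `P0`, `P1`, `H0`, `H1`, `H_sum`) is
returned, not just `K`. A brute-force per-`k` evaluation straight from the
definition serves as the test oracle.

Entropy-based thresholding presumes both classes have non-trivial
intensity spread; on a near-delta histogram (e.g. a synthetic flat
background) the entropy-optimal split lands inside the only mode, which is
the mathematically correct answer to the wrong question. The synthetic
scenes therefore model the spread real frames have (see below).

**Binarization.** Pixels `≤ K` are background. The `bright` polarity makes
bright pixels foreground; `inverted` swaps classes; `auto` takes the
minority class as foreground, on the grounds that the sample occupies a
minority of the field of view.

**Particle filter.** Connected-component area filtering (8-connectivity
default): components below `min_area` (default 50 px) are erased. This is
the "low-pass" debris-rejection step; it is idempotent and leaves
surviving components untouched.

**Excessive dilation.** Iterated binary dilation with a full 9×9
structuring element, 11 iterations — growth of 44 px in Chebyshev
distance. Its purpose is to close the foreground holes produced where the
transparent larval body falls below threshold, while preserving the
center of the outer contour (verified as a ≤ 0.5 px centroid-shift
property on centered discs). `dilate` itself is defined as the
neighborhood maximum under the structuring element with background
padding, which for the symmetric elements used everywhere coincides with
the Minkowski-sum formulation.

**Circle detection.** Two methods are provided.

- `inscribed` (default): per foreground component, the largest inscribed
  circle via the Euclidean distance transform; the center is refined as
  the centroid of the near-maximal plateau (within 2.5 px of the peak),
  which averages out noise-induced bumps along the flat distance ridge
  that a dilated body+yolk union produces. This method was made the
  default because iterated dilation with a *square* element is
  anisotropic: a disc of radius `r` becomes a rounded square whose
  boundary arcs are centered 44 px off the true center, so a Hough
  transform run on the post-dilation boundary — where the pipeline places
  circle detection — systematically mislocates centers, while the largest
  inscribed circle remains exactly centered.
- `hough`: circular Hough transform on component boundaries with a
  contour-circularity fallback (`4πA/P² ≥ 0.6` → centroid + equivalent
  radius). Appropriate for undilated frames with true circular contours;
  tested against the generator on those.

The radius search window (default 12–120 px, pre-dilation scale) is
widened internally by the dilation growth; no camera calibration is
assumed, so the window is configuration, not physics.

**Target selection.** ROI = particle of maximal area (ties → smallest
label); target = center of the maximal-radius circle (ties → higher
score, then smaller row, column). The winning circle is cross-checked to
lie inside the ROI bounding box; if it does not, the largest circle that
does is used. No particle or no circle yields a recognition-unsuccessful
result — a valid outcome the batch workflow responds to by skipping the
cell — rather than an exception.

## Synthetic scenes

The generator renders what the pipeline must cope with, with exact ground
truth recorded at generation time:

- **Embryo scenes**: a bright disc (default radius 48 px in a 256×256
  frame) with a random second-order harmonic boundary perturbation
  (relative amplitude 0.02). Only even harmonics are used, so the shape
  stays centrally symmetric and "true center" remains well defined.
- **Larva scenes**: a body capsule (half-width 10 px, length 170 px,
  orientation within ±10° of horizontal, random direction), a head disc
  (radius 13 px), and the yolk disc (radius 26 px) as the strictly widest
  structure — asserted at generation time. `transparency_holes`
  background-colored discs (radius 5–9 px) are punched into the
  foreground; the first lands near the yolk center, so ablating the
  hole-closing dilation visibly corrupts or defeats yolk localization,
  which is exactly the comparative property the tests assert.
- **Photometry**: background 60 ± a random linear illumination ramp of
  amplitude 20; foreground shaded 155→210 from structure center to rim;
  per-channel Gaussian noise (σ = 6) added to all three RGB channels.
  The spread in both classes is what entropy thresholding needs and what
  real frames provide. A `dark_field` flag inverts the contrast to
  exercise polarity handling.
- **Debris**: bright discs of radius 3–8 px placed at least
  `impurity_clearance` (default 96 px) from the sample boundary. The
  clearance models the typical case where debris resolves as a separate
  particle after dilation; two blobs closer than ~125 px can fuse under
  the square element's diagonal growth (44·√2), and tests that need
  guaranteed separation use a wider field and clearance.
- **Plates**: the full 8×11 prototype layout holds 48 embryos (columns
  1–6) and 40 larvae (columns 7–11; the counts and the left/right zoning
  are fixed by the prototype plate, the exact column split is this
  package's convention), with larva frames in the lower half of the plate flipped
  vertically to emulate the head-down placement zone. A seeded draw marks
  `round(failure_rate·M·N)` cells unrecognizable; these are rendered as
  featureless frames whose degenerate histogram triggers the workflow's
  skip branch. Plate cells use slightly smaller geometry (embryo radius
  36 px in 224×224; yolk 24 px in 224×320) to keep a full 88-cell cycle
  fast.

What the generator does **not** emulate: chorion internals and texture,
pigmentation, developmental stages, optical blur, multiple samples per
field of view, or debris touching the sample. Passing tests therefore
demonstrate correctness of the pipeline's logic and its behavior under
the stated noise model — not recognition accuracy on real acquisitions.

## Workflow simulation

The cycle is pure coordinate and time bookkeeping. The serpentine plan
visits odd rows left-to-right and even rows right-to-left so every hop is
one grid step. Per cell: detect; on success, compute the XY-stage
displacement `(B − C)·scale` that moves the target pixel onto the fixed
injection point (frame center), count the sample as injected; on failure,
skip (failed cells consume detection time but no injection time, and are
not retried). The needle's standby point A sits 2000 µm behind the
injection point B in both x and z, making the approach stroke a 45°
diagonal; this is tracked as coordinates only — no contact, force or
fluidics model. Grid indices are 1-based `(m, n)`; stage coordinates are
µm with x rightward and y downward.

The timing model is constant-per-step plus optional seeded Gaussian
jitter (defaults: move 2.3 s, detect 0.9 s, inject 10.5 s). The defaults
are an explicit calibration to land a full 88-sample cycle near the
total duration a complete robotic run achieves; they carry no mechanistic
content and every study-relevant statistic (success counts, rates) is
independent of them.

## Metric calculus

`compute_rates` implements `R_suc`, `R_sur`, `T_suc`, `T_sur` with strict
domain checks (`N_sur ≤ N_suc ≤ N_total`; zero denominators raise
undefined-rate errors rather than returning NaN). `cumulative_table`
accumulates per-group logs (one group = one plate row of 11 samples) into
the standard cumulative report; survival columns appear only on the final
row, where next-day survival is scored for the whole run. Values are kept
unrounded internally; report formatting is two decimals.

Dispersion statistics follow the conventions under which the bundled
reference runs' published statistics reproduce exactly: the **range** is
taken over the cumulative `T_suc` column at its 2-decimal report
precision, while the **standard deviation** uses the sample (n−1)
denominator over the unrounded per-group `T_suc` values recovered by
differencing consecutive cumulative rows. Both recomputations match the
reference values (1.51 s / 1.53242 automatic, 7.80 s / 10.54446 manual)
only under this split, which is why it is exposed as two separately
documented statistics. Run comparisons at equal `N_total` report relative
total-time reduction and relative success-count increase.

## Reference data

`zfinject.benchmarks` bundles the raw cumulative measurements of two
88-sample reference runs (automatic system vs. manual operator): per-row
cumulative time and success count, plus the final survival count. All
derived cells are recomputed, never stored. One row of the published
automatic table omits its trailing placeholder block; survival columns
are treated as final-row-only regardless, which makes the table
well-formed under the same rule as every other run.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical seed + configuration gives bit-identical scenes, logs
  and CSV/JSON outputs.
- The threshold scan restricts candidates to splits with two nonempty
  classes; on histograms where every valid split gives `H_sum = 0`
  (two occupied bins) the smallest valid `k` is returned.
- Degenerate inputs are errors where silence would corrupt results
  (empty images, single-bin histograms, non-monotone cumulative tables,
  zero-success groups in differencing) and valid outcomes where the
  workflow has a defined response (no particle/circle → unsuccessful
  recognition → skip).
- The simulator does not re-attempt failed recognitions later in the
  cycle; a permanent skip is the simplest defensible reading of the
  flowchart and keeps `N_suc` deterministic given the failure draw.
- Problem sizes used by the test suite and the acceptance script
  (200 scenes for the recovery rate, 500 histograms and 100 images for
  the operator oracles, one full 8×11 plate for the cycle) were chosen to
  give stable statistics at interactive runtimes.
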