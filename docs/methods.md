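# Methods

## The measurement model

Structome analysis reconstructs one cell quantitatively from a complete
ordered stack of serial ultrathin sections. The package treats each section
as a planar measurement of two closed contours — the outer membrane (OM),
bounding the whole cell, and the plasma membrane (PM), bounding the
cytoplasm — with perimeter, enclosed area, minor/major axes, membrane
thicknesses and a cytoplasmic ribosome count. From a stack of `n` sections
of thickness `t`:

| quantity | estimator |
|---|---|
| length | `n · t` (or an externally supplied length) |
| diameter | median of minor axes over the central 50% of sections |
| surface area | `Σ (p_i + p_{i−1})/2 · t` (trapezoid rule) |
| compartment volume | `Σ a_i · t` (Cavalieri estimator) |
| membrane shell volume | `Σ p_i · τ_i · t` (`τ` = membrane thickness) |
| periplasm | `V_whole − V_cytoplasm − V_OM − V_PM` |
| ribosome density | `total / V_cytoplasm × 0.1` (per 0.1 fl) |

Assumptions: sections are complete (pole to pole), ordered, of uniform
nominal thickness, and traced at the outer edge of each membrane; the
cytoplasm is the PM-enclosed space; fl ≡ µm³ throughout.

### Design choices in the estimators

- **Section thickness is always an explicit parameter** (default 0.040 µm,
  the conventional ultrathin-section thickness). Source reports of this
  kind have used both 40 nm and 55 nm in different roles; nothing is
  hard-coded.
- **Two length modes.** `section_count` is the self-consistent
  `n · t`; `supplied` carries an externally measured length, because
  published per-cell lengths are not always consistent with section count ×
  thickness (the bundled reference table is such a case, and ships the
  printed lengths verbatim).
- **Periplasm by subtraction** defaults to removing the membrane shells as
  well (`table_consistent`); the plain `whole − cytoplasm` difference
  (`text_literal`) is retained as an option. The default reproduces the
  published per-cell volume tables; by construction it also makes the four
  compartments sum exactly to the whole-cell volume.
- **Diameter estimator** defaults to the median over the central half of
  the stack: it ignores the tapering polar sections and is noise-robust.
  `mean_all` and `max` are available since published reports rarely state
  which convention was used.
- **No end-cap correction** is applied to the trapezoid surface area. The
  method measures `∫ p(z) dz`; on a hemispherical pole of radius `r` this
  integral is `π²r²/2` while the true cap area is `2πr²`, so the estimator
  has a deterministic deficit of `(4−π)/(2π) · r/L ≈ 0.43·r/L` relative to
  the true spherocylinder surface `2πrL`. For a typical rod (`r/L ≈ 0.08`)
  that is ≈ 3–4%; for stubby cells (`r/L > 0.12`) it exceeds 5%. The bias
  is documented here and measurable against the synthetic ground truth; it
  is deliberately not corrected, because the uncorrected sum is the
  estimator whose published outputs this package reproduces.
- **Rounding is report-time only**: computations run at full precision;
  table writers round half-away-from-zero to 2 decimals (lengths, areas,
  volumes, aspect ratio) and to the nearest 10 (ribosome totals and
  densities), matching the conventions of the printed tables.
- **Degenerate inputs**: noise-driven negative periplasm volumes clamp to
  zero with a logged warning; a single-section stack has no defined surface
  area (error) but well-defined length and volumes.

## The synthetic generator

`SpherocylinderModel` idealises a rod cell as a straight spherocylinder
with circular cross-sections: OM radius `r`, pole-to-pole length `L`, an
envelope of width `w` (OM outer surface → PM outer surface) so the PM
spherocylinder has radius `r − w` and length `L − 2w`, and membrane
thicknesses for the shell volumes. Closed forms
(`V = πr²(L−2r) + 4/3·πr³`, `S = 2πrL`) give exact ground truth.

- **Slicing** emulates serial sectioning: slabs of thickness `t` on a grid
  with optional offset; each slab intersecting the cell yields one
  measurement evaluated at the slab mid-plane (the simplest consistent
  convention; the discretisation error it contributes is far below the
  stated recovery tolerances — midpoint sampling of the quadratic area
  profile is nearly exact, ≤ 0.06% volume error across the tested sweep).
- **Measurement noise** is multiplicative lognormal with unit mean and a
  chosen coefficient of variation, independent per section and per measured
  quantity — a generic positive-valued tracing-error model; after noising,
  PM values are clamped to their OM counterparts so the containment
  invariant survives. No noise model is claimed to match any particular
  microscope.
- **Ribosomes** are placed homogeneously in the cytoplasm, consistent with
  the even cytoplasmic distribution seen in 3D reconstructions of these
  cells: the cell total is Poisson with mean `density × V_cyt / 0.1` and is
  split multinomially across slabs proportionally to exact per-slab
  cytoplasmic volumes (equivalent to independent Poisson counts per slab).
  Counts are conserved exactly.
- **Defaults are the average measured rod** of the seven-cell reference
  table: `r = 0.29 µm`, `L = 3.54 µm`, `w = 0.015 µm` (from the 0.58 vs
  0.55 µm OM/PM diameters), PM thickness 6 nm and OM thickness 2 nm (the
  scales implied by the published shell volumes against the surface areas),
  density 1170 per 0.1 fl.
- **Seeding**: one explicit integer seed per call; `simulate_cell` derives
  independent child streams for noise and ribosome placement, so noise-free
  slicing is bit-reproducible regardless of seed.

What the generator does *not* emulate: cell curvature and bending (real
rods bend; only axis-aligned metrics are modelled, so straightness is
harmless for them), septation and division, elliptical cross-sections,
section-thickness variability, compression/tearing artefacts, and any
pixel-level image structure. Recovery tests on this generator therefore
validate the estimator algebra and its discretisation behaviour — not
segmentation or tracing accuracy on real micrographs.

## Statistics

Per-metric summaries use the sample SD (n−1). Two-sample comparisons use
the Welch t-test by default — the species groups compared have unequal
variances and sizes — with the pooled-variance variant available; both are
two-sided, and can be computed from summary statistics alone (needed when
only published n/mean/SD are available for the comparison species). The
value-based entry point is defined as the summary-based test applied to the
two summaries, so the two paths agree bit-for-bit. One-way fixed-effects
ANOVA is provided with the convention F = 0, p = 1 for identical groups.
No multiplicity correction is applied by default (matching the practice of
the source reports); a Bonferroni option exists. Text reports floor
p-values at `< 1e-15`; JSON keeps full precision.

## Growth calibration

Doubling time is modelled as `y = a·e^(−b·x)` against ribosome density `x`
per 0.1 fl cytoplasm; the shipped default is the published `(a, b) =
(4998.5 min, 0.002)`. Fitting uses ordinary least squares of `ln y` on `x`
(log-linear): the published presentation of the curve offers no variance
information that would justify a weighting scheme or a nonlinear
refinement, and the anchor doubling times behind the published fit are not
printed, so the default model is the printed constant pair rather than a
refit. The inverse `x = ln(a/y)/b` is defined for `0 < y ≤ a`. A fit whose
decay rate comes out non-positive is rejected as meaningless.

## Problem sizes and determinism

The test and acceptance runs use: a 5 × 4 (radius × length) noise-free
recovery sweep at 0.04 µm sections; 200 seeded synthetic cells for density
recovery (per-cell Poisson totals ≈ 9250 give ≈ 1% CV, so the 3-SE band on
the 200-cell mean is ≈ ±2 per 0.1 fl); and 10,000 null replicates (two
groups of 20) for the t-test type-I-error check, where the Monte-Carlo SE
of the rejection rate is ≈ 0.0022. All randomness flows through explicit
integer seeds; noise-free outputs are byte-identical across runs (file
writers take a `--no-timestamp` switch for that purpose).

## Known limitations

- The trapezoid surface estimator's polar-cap deficit (above) grows with
  `r/L`; surface areas of low-aspect cells are systematically low by more
  than 5%.
- Quantities recomputed from *rounded published tables* inherit the input
  rounding: a recomputed SD or a recomputed nearest-10 density can land one
  rounding unit away from the printed value even though the underlying
  full-precision data agree. The bundled fixtures carry the printed values,
  so such one-unit discrepancies are visible in strict reproduction checks.
- Welch and pooled t-tests from the same published summaries can fall on
  opposite sides of a quoted p-bound when the bound is tight; the package
  reports both rather than choosing the variant that matches.
- No curvature correction: lengths of strongly bent cells are chord-like
  underestimates in both the generator and the estimators.
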