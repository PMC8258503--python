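# Methods

This note records the models behind `simquant`'s three texture metrics,
the conventions and numerical choices they depend on, what the phantom
generator does and does not emulate, and the known limitations.

## Spectral conventions

All metrics consume square, even-sided, single-channel ROIs (reference
size 128×128 px; other even sizes are scored with a logged warning, since
band fractions scale with N while biological periods do not). The forward
DFT is unnormalized with the 1/N² factor on the inverse; spectra are
stored centered, DC at index (N/2, N/2). Coordinates are 0-based with
x = column, y = row, origin top-left; the centered integer frequency of a
bin is (u, v) with u horizontal. The unpaired Nyquist row/column
(u = −N/2 or v = −N/2) is excluded wherever exact conjugate symmetry is
asserted. No apodization window is applied before the FFT: the metrics
are defined on the raw periodogram, and spectral leakage of
non-integer-period structure is part of the measured quantity (see
"Linear vs squared magnitude" below).

A frequency band is the concentric-square annulus between side fractions
`(f_outer, f_inner)`: bin membership is
`f_inner·N/2 ≤ max(|u|,|v|) < f_outer·N/2`, half-open so nested bands
tile the non-DC plane exactly; DC is never a member. At N = 128 the
default band (1/4, 1/16) contains exactly 912 bins
(31² − 7² lattice points).

## Foot-process integrity score

`score_normalized = Σ_band |F| / Σ_non-DC |F|`, with the denominator over
*all* non-DC bins including the Nyquist row/column. Excluding DC makes
the score exactly invariant to additive offsets; the ratio form makes it
invariant to multiplicative gain — together, affine illumination
invariance, which matters across sections stained and exposed
differently. `score_raw` (mean |F| per band bin) is reported alongside
for workflows that want absolute contrast. An exactly constant image has
no non-DC energy; the normalized score is then undefined and raised as an
error rather than returned as 0.

**Linear vs squared magnitude.** Whether "spectral intensity" means |F|
or |F|² is a genuine modeling choice. The default sums the linear
magnitude |F|. The choice is visible in the numbers: for the
demonstration wave sin(0.4x+0.4y), whose 8.15-cycle period is not an
integer divisor of 128, leakage tails of |F| decay only like 1/Δ per
axis, so the in-band fraction is 0.632 under the linear definition but
>0.95 under the squared one. `band_power_score(..., magnitude_exponent=2)`
selects the power-sum variant; all defaults, tests and documented numbers
use the linear form. Both share the affine invariance, the white-noise
expectation (flat expected spectrum ⇒ score ≈ 912/16383 ≈ 0.0557 at
N = 128), and the monotone effacement response.

Per-subject aggregation in batch scoring is the arithmetic mean over that
subject's ROIs.

## Mitochondrial damage index

Pipeline per ROI: circular window → DFT → |F| → 8-sector means → 4 axes →
minor/major ratio.

* **Circular window.** Pixels farther than N/2 from the image center
  ((N−1)/2, (N−1)/2) are replaced by the in-disc mean (default) or zero.
  Mean fill is the default because zero fill reintroduces a step edge at
  the disc boundary and *increases* axis-aligned leakage; with mean fill
  the cross-shaped artifact of the periodic-wraparound edge measurably
  decreases (asserted in the test suite on a half-bright image).
* **Sectors.** Sector s covers angles [45s − 22.5°, 45s + 22.5°),
  sector 0 centered on +u; boundaries half-open, so exact-45° diagonal
  bins fall in the odd sectors. Sector means are taken over the whole
  spectrum (no radial restriction), excluding DC and the Nyquist
  row/column. Because |F(u,v)| = |F(−u,−v)| analytically for real images,
  the magnitude grid is first symmetrized on the Nyquist-excluded
  subgrid (averaging each bin with its point reflection, which only
  cancels FFT roundoff), and sectors 4–7 are computed as the mirror of
  0–3 — their bin sets are point reflections, so the mirrored means are
  the exact values and opposite-sector equality holds bitwise.
* **Axes and index.** Axis j ∈ {0..3} (directions 0°/45°/90°/135°) is the
  average of sectors j and j+4; the major axis is the largest (ties,
  logged when within 1e-12, go to the smallest label), the minor axis is
  the orthogonal one, and `DI = minor/major`. This polygon reading of the
  radar chart is the default because conjugate symmetry makes opposite
  sectors redundant and the chart has only four independent values; a
  least-squares centered-ellipse fit through the eight polar points
  (`estimator="ellipse"`) is provided for sensitivity analysis.

One geometric consequence of whole-square sectors: diagonal sectors
include the spectrum's corner regions, so even a perfectly isotropic
texture has slightly lower diagonal-sector means than axis-sector means
(≈20% for a pure ring texture). This cancels in the damage index — the
major and its orthogonal minor axis always share geometry — so an
isotropic ring phantom scores DI = 1.0 exactly, but raw sector means
should only be compared between same-geometry sectors.

DI is invariant to global intensity scaling but, unlike the band score,
not to additive offsets (the offset interacts with the circular window's
disc edge); in practice ROIs are windowed identically so comparisons are
unaffected.

## Membrane CV

The polyline is re-parameterized by arc length and sampled at exactly
`target_length` (default 180) equally spaced positions, endpoints
included; intensities are read by bilinear interpolation (exact on affine
images; nearest-neighbor available). Traces shorter than the target in
arc length are upsampled with a warning. The trace is 1 sample wide — no
perpendicular averaging. `CV = σ/μ` uses the population σ (divisor n):
the 180 samples are the entire traced object, not a sample from a larger
population; `ddof=1` switches conventions. An exactly constant trace
short-circuits to σ = 0 so that CV = 0 holds despite summation roundoff.
A trace with nonpositive mean has no defined CV and is rejected.

## Phantom generator

Each generator is a pure function of its spec including the seed
(`numpy.random.default_rng`), giving bit-identical output per spec.

* **Plane waves** evaluate `offset + A·sin(ωx·x + ωy·y + φ)` exactly on
  the integer grid; |ω| ≥ π rad/px is rejected as aliased.
* **Foot-process phantoms** mix a sinusoidal ridge of period 12 px
  (fundamental at centered index ≈10.7, inside the default band at
  N = 128) with a heavily low-passed Gaussian field (σ = N/8, spectrum
  confined to the inner square) by the effacement parameter λ:
  `(1−λ)·ridge + λ·smooth`, plus clipped additive Gaussian noise
  (σ = 0.02 on a 0.4-amplitude texture over offset 1.0). The smooth field
  is rescaled to the ridge's RMS contrast so total contrast is roughly
  λ-independent and the score responds to *structure*, not contrast. The
  default 45° ridge orientation keeps the fundamental off the frequency
  axes, where boundary-wraparound leakage concentrates; users rendering
  axis-aligned ridges should expect a lower (but still monotone) score.
* **Rod fields** render additive segments with Gaussian cross-section.
  Tubular defaults: 40 rods, mean length 100 px (≈3.2 µm tubes at
  32.27 nm/px, spanning most of a 4.13 µm ROI), cross-section σ = 2 px
  (FWHM ≈ 150 nm, a SIM-resolved tube width), lengths normal with 20% sd
  (floor 1 px). Orientations follow an axial von Mises law — 2θ sampled
  from von Mises(0, κ) and halved, respecting the 180°-periodic topology
  of undirected rods; κ = 0 is uniform. The fragmented condition uses
  κ = 0, mean length 3 px, 300 rods (many small fragments). Under these
  conditions the aligned field scores median DI ≈ 0.44 and the fragmented
  field ≈ 0.96 (20 seeds). Between κ = 100 and κ ≈ 4 the field is already
  effectively aligned and median DI is flat to sampling noise; the
  dispersion-monotonicity property is therefore validated on the grid
  κ ∈ {100, 1, 0.25, 0}, which spans meaningfully distinct dispersions.
* **Membrane traces** are `base·exp(g)` with g a wrap-smoothed
  (σ = 3 samples) standard-normal field rescaled to the requested
  irregularity sd, so traces are strictly positive and CV ≈ irregularity
  for small values; irregularity 0 returns an exactly constant trace.

**What the phantoms do not emulate:** the SIM point-spread function and
reconstruction artifacts, stain chemistry and uneven staining, background
tissue context, out-of-focus light, and detector noise statistics.
Passing phantom tests therefore demonstrates that each metric responds
correctly and monotonically to the targeted structural degradation under
controlled texture statistics — not that clinical effect sizes or cohort
correlations are reproduced. Cohort-level results require the original
patient images and clinical covariates, which are outside this package's
scope.

## Containers, degenerate inputs, and edge rules

`GrayImage` carries a float64 pixel grid plus a pixel-size tag
(default 32.27 nm/px = 4.13 µm / 128 px; metadata only — no metric
depends on it). File readers and phantom generators guarantee nonnegative
intensities; band-limited reconstructions, whose DC term is removed by
construction, are returned as `GrayImage`s with real (possibly negative)
values. Rectangular or odd-sided ROIs are rejected, not padded. TIFF
input is single-channel 8/16-bit (or float); multi-channel files are
rejected with a hint to extract a channel. Inverse transforms assert that
the imaginary residual is below 1e-8 of the real peak.

## Statistics layer

Implemented directly so validation runs are self-contained and each
routine is checkable against independent oracles (closed-form normal
equations, full permutation enumeration, scipy in the test suite only):

* simple linear regression (least squares; R² = squared Pearson r;
  constant x rejected);
* Mann-Whitney U, U reported for the first group: exact permutation
  enumeration of the mid-rank null when n₁+n₂ ≤ 16 (handles ties
  correctly, two-sided p = P(|U−μ| ≥ |u_obs−μ|)), otherwise the
  tie-corrected normal approximation with 0.5 continuity correction,
  two-sided p doubling the smaller tail capped at 1;
* Spearman ρ as Pearson correlation of mid-ranks; constant input
  rejected.

## Problem sizes used in validation

The shipped validation suite runs entirely on generated data at the
reference ROI size (128×128; engine correctness also at 16–256): 20 seeds
per condition for the rod-field and membrane group comparisons, 20 seeds
× 10 effacement levels for the monotonicity check, and 100 seeds for the
white-noise expectation — sizes at which the medians and rank
correlations involved are stable to well within the asserted margins.

## Known limitations

* Band fractions are relative to N while biological periods are absolute;
  scores at non-reference ROI sizes are comparable only within one size.
* The damage index measures orientation dispersion of the whole ROI
  texture; a field of long tubes in locally varying directions scores as
  isotropic ("damaged") even though individual tubes are intact.
* The membrane CV conflates structural irregularity with any
  along-trace staining gradient; it has no shape information.
* The plane-wave fitter assumes a single dominant periodicity; on
  multi-component textures it returns the locally dominant one.
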