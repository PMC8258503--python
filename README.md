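# simquant

Fourier-spectrum quantification of kidney microstructures in
super-resolution micrographs of routinely stained sections.

Super-resolution imaging (e.g. structured illumination microscopy) of
ordinary trichrome- and PAS-stained kidney biopsy sections resolves three
microstructures whose degradation marks disease, but whose assessment is
usually qualitative: podocyte foot processes (effaced in nephrotic
disease), tubular mitochondria (fragmented under injury), and glomerular
basement membranes (irregular in early membranous nephropathy). `simquant`
turns each into a number computed from the image texture alone — no
segmentation, no tracing of individual structures (membranes excepted,
which use a single manual polyline):

* **Foot-process integrity score.** The centered 2-D DFT of a 128×128-px
  ROI (≈4.13 µm at 32.27 nm/px) is summed over the concentric-square
  annulus between side fractions 1/4 and 1/16 of the spectrum — the band
  that carries normal foot-process periodicity — and normalized by the
  total non-DC spectral magnitude:
  `score = Σ_band |F(u,v)| / Σ_non-DC |F(u,v)|`.
  High for crisp periodic foot processes, low after effacement.
* **Mitochondrial damage index.** The ROI is cut to a circle (suppressing
  the cross-shaped spectral artifact of square edges), transformed, and
  the mean |F| taken in eight 45° sectors. Opposite sectors are averaged
  into four radar-chart axes; the damage index is
  `DI = minor axis / major axis ∈ (0, 1]` — near 1 for isotropic
  (fragmented) textures, well below 1 for aligned tube-like mitochondria.
* **Membrane irregularity.** Intensity along a manually traced capillary-
  wall polyline is resampled to a 1×180 linearized profile and summarized
  by the coefficient of variation `CV = σ/μ` (population convention).

Because clinical micrographs are rarely shareable, the package ships a
seeded phantom generator (plane waves, effacement-graded ridge textures,
rod fields with tunable orientation dispersion and fragment length, and
1-D membrane traces) so every metric is testable against ground-truth
degradation labels, plus self-contained statistics (simple linear
regression, exact/asymptotic Mann-Whitney U, Spearman rank correlation)
for phantom-based validation runs.

## Worked example

`examples/` holds one narrative script per capability. The defining
demonstration (`examples/01_sine_waves_and_spectra.py`) builds the two
plane waves `z = sin(0.4x + 0.4y)` and `z = sin(0.05x + 0.05y)` on a
128×128 grid, reconstructs each from the spectral annulus and from its
complement, and re-measures the generating frequency:

```
wave omega = 0.40 rad/px
  correlation with annulus reconstruction:    +0.996
  correlation with complement reconstruction: +0.084
  recovered frequency: omega_x = 0.400000, omega_y = 0.400000
wave omega = 0.05 rad/px
  correlation with annulus reconstruction:    +0.019
  correlation with complement reconstruction: +1.000
  recovered frequency: omega_x = 0.050000, omega_y = 0.050000
```

The steep (foot-process-like) wave lives inside the annulus, the shallow
(primary-process-like) wave in its complement — the frequency dichotomy
the integrity score is built on. On phantoms
(`examples/02_footprocess_score.py`), the median score falls
monotonically from 0.446 at effacement λ = 0 to 0.104 at λ = 0.9 with
Spearman ρ = −0.995; aligned tubular rod fields score a median damage
index of 0.436 versus 0.944 for fragmented fields (Mann-Whitney
p = 1.8×10⁻⁴; `examples/03_mitochondria_damage.py`).

A thin CLI mirrors the library for directory-scale batch work:

```bash
simquant synth fixtures --out-dir rois --seed 1
simquant footprocess --roi-dir rois --out scores.csv
simquant mito --roi-dir rois --out damage.csv
simquant membrane --image img.tif --roi trace.csv --out cv.csv
```

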