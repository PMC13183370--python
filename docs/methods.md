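# Methods notes

This note records the models, conventions and numerical choices behind
`vocalmap`, and what the synthetic validation does and does not establish.

## Coordinate and unit conventions

Image coordinates are micrometres with the origin at the top-left corner and y
increasing ventrally; bregma coordinates are millimetres, positive anterior.
Densities are cells/mm²; ROI areas are polygon areas divided by 10⁶.

## USV segmentation

The detector reconstructs a spectral-bandwidth segmentation from its stated
parameters (the vendor tool's internals are proprietary): band-limit 30–120 kHz,
50% energy bandwidth criterion, 20 ms hold time, 1 ms post-filter.

* **STFT**: 512-sample Hann window, 75% overlap (≈0.5 ms hop at 250 kHz — fine
  enough to resolve the 1 ms post-filter). Magnitudes are dB re full scale
  (a full-scale sine peaks at 0 dB); silent bins floor at −200 dB.
* **Call criterion**: a frame is call-positive iff its in-band energy is at
  least `energy_threshold_db` (default 6 dB) above the recording's median
  in-band frame energy — a robust per-recording noise floor needing no
  calibration file — *and* the minimal contiguous frequency interval around the
  spectral peak holding 50% of the frame's in-band energy is narrower than
  20 kHz. The second clause separates tonal syllables from broadband noise;
  white noise spreads its 50%-energy interval over roughly half the 90 kHz
  analysis band, far above the ceiling.
* **Merging and trimming**: positive runs with gaps ≤ 20 ms merge into one
  event. Each merged run is then trimmed at half power (edges more than 6 dB
  below the run's peak frame energy are dropped), which undoes the temporal
  smearing of the 2 ms analysis window at event edges; runs whose trimmed span
  of frame centres is shorter than 1 ms are discarded. Event boundaries are
  reported at frame centres.
* **Limitation**: at very high tone-to-noise ratios (≫30 dB) window smearing can
  stretch a sub-millisecond transient past the post-filter even after
  half-power trimming; at the 15–25 dB levels typical of real recordings the
  rules behave as specified.

Per event, features are read at three loci — first frame, last frame, and the
frame with the largest in-band magnitude: peak frequency is the argmax in-band
bin of that frame, peak amplitude its dB value.

## ROI quantification

* Boundary cells count as inside (shapely `covers`); boundary bregma values go
  to the more rostral subregion — both deterministic documented conventions.
* Hemispheres are pooled within a section before densities are computed; the
  per-mouse value is the unweighted mean of per-section densities (not
  area-weighted), and double-label percentages are averaged per mouse the same
  way. Pooling across mice instead is possible by aggregating the summed counts
  the tables retain.
* **Double-label matching**: a tdTomato/c-Fos pair is valid if the centroids
  are ≤ 8 μm apart (≈ one nuclear radius at the 10 μm detection scale; the
  geometric definition of "double-labeled" is otherwise unstated). The matching
  is a Hungarian assignment that maximises the number of valid pairs and then
  minimises their total distance — unlike nearest-first greedy matching it
  always equals the exhaustive optimal-assignment oracle.
* The optional blob detector (synthetic images only) runs rolling-ball
  background subtraction (10 μm), a median filter (10 μm tdTomato / 8 μm c-Fos)
  and a global threshold (20 / 10) before connected-component centroids.

## Statistics

* **Normality routing**: Shapiro–Wilk per group at α = 0.05 (the specific
  normality test used with SPSS is unstated; Shapiro–Wilk is the conventional
  small-sample choice). All groups normal → t family; otherwise Mann–Whitney U
  (between groups) or Wilcoxon signed-rank (within subject). Mann–Whitney uses
  exact enumeration for n ≤ 8 without ties, the tie-corrected normal
  approximation otherwise. Zero-variance equal groups return p = 1 by
  convention.
* **Outliers**: Tukey 1.5×IQR fences (the exclusion criterion behind the
  heatmap's missing cells is unstated; the fences are robust and
  parameter-free). Flagged entries are excluded from μ and σ and rendered
  missing.
* **z-scores**: sample SD (n − 1) — material at n = 7–9; whether the source
  analysis used population or sample SD is unstated, so this is a config-visible
  package decision. σ = 0 populations produce z = 0 with a degenerate flag
  rather than an error, keeping heatmaps renderable on degenerate synthetic
  input.
* **Ordering**: exposed mice sort descending by USV count (stable, so equal
  counts preserve input order); controls keep input order in their own block.
* No multiple-testing correction is applied across regions by default,
  matching per-region reporting; a Benjamini–Hochberg pass can be layered on
  the returned p-values by the caller.

## Correlation classification

Correlations use exposed mice only: controls emit no USVs, and including their
zeros would manufacture correlation. p is the two-tailed t transform with
df = n − 2; the 95% CI uses Fisher's z. The decision table: significant
correlation → `usv-positive`/`usv-negative` by sign of r; otherwise significant
group effect → `social-interaction-related`; otherwise `unrelated`. The strong
flag (|r| > 0.7 and R² > 0.5) is independent of the category. n is carried
explicitly per region and never assumed global.

Anteroposterior profiles use 0.2 mm bins anchored at atlas-round coordinates
(multiples of the bin width); per bin, per-mouse densities are averaged and then
correlated, bins with fewer than 3 mice are flagged insufficient, and the peak
is the max-R² bin among bins with p < 0.05 (no significant bin → no peak).
Note that with ~6 bins tested at α = 0.05 an entirely uncoupled region still
yields at least one significant bin in roughly a quarter of cohorts; the
per-bin type-I rate is what stays at the nominal level.

## Striatal quadrants and compartments

Line 1 is the tangent through the two dorsal CP edge points; Line 2 runs through
the anterior commissure parallel to Line 1; Line 3 joins the lateral CP boundary
to the NAcs tip; Line 4 runs through the NAcs tip perpendicular to Line 1.
Lines 5 and 6 (the dividers) pass through the midpoints of those lines *clipped
to the CP extent* — clipping to the CP is the only midpoint construction that is
well-defined for arbitrary CP shapes. Points on Line 5 go medial, on Line 6
dorsal; the medial side is the side holding the anterior commissure (falling
back to the NAcs tip when the AC lies on the divider), the dorsal side holds the
Line-1 chord midpoint. Tangent chords are intersected against a hair-buffered
polygon when floating-point error makes the exact intersection empty, keeping
the construction rigid-motion equivariant to ~1e−7 relative.

Striosomes are consumed as MOR1⁺ polygons; matrix is the CP minus their union.
Compartment areas within a quadrant are polygon intersections; counts use the
divider-side point assignment, so striosome + matrix counts conserve the in-CP
total exactly. Fold-changes divide each exposed density by the control-group
mean of the same compartment within the same quadrant. The quadrant/compartment
analysis is intended for rostral CP sections (selected with the bregma rules of
the ROI module).

## Synthetic data generator

The generator emulates the statistical structure of a double-label mapping
study so that every downstream stage can be validated against known truth, with
no raw data download.

* **USV counts**: negative binomial, mean 120, dispersion 2, for exposed mice
  (overdispersion mimics the wide per-animal range implied by USV-sorted
  heatmaps; real per-mouse count distributions are not published, so these
  defaults are placeholders, not estimates); controls emit 0.
* **Density–USV coupling**: for exposed mouse *i* with standardized count z_i,
  the latent density is baseline × multiplier × exp(βz_i + ε_i), ε_i ~ N(0, σ²)
  with σ = 0.10. β is solved numerically (moment approximation + Brent root
  finding over the cohort's realized z values) so the *expected sample Pearson
  correlation* of measured density with USV count — including lognormal and
  Poisson counting noise — equals the requested coupling. σ = 0.10 was fixed
  once: the maximum achievable correlation β/√(exp(β²+σ²)−1) falls to ≈0.83 at
  σ = 0.25, so only a mild noise level makes a 0.9 target attainable. Negative
  couplings use β < 0; a coupling span can confine the effect to a bregma
  sub-interval for localization studies.
* **Sections**: 30 μm thickness × 12 series → 360 μm within-series spacing; each
  mouse gets a random sectioning phase, so bregma bins are populated across mice.
  Cell counts per section are Poisson (density × area), centroids uniform in the
  hemisphere ROI polygons. A Binomial(reactivation_prob) fraction of tdTomato
  cells receives a co-located c-Fos partner with Gaussian jitter clipped inside
  2 μm — far inside the 8 μm matching tolerance, so the ground truth is
  unambiguous. Independent c-Fos cells keep channel totals comparable.
* **Audio**: linearly frequency-modulated tones with 1 ms raised-cosine ramps
  over white Gaussian noise; the tone-to-noise level is the difference between
  tone peak and noise RMS in dBFS.
* **Striatal sections**: striosomes are disjoint equal-radius disks packed by
  bounded rejection sampling (default 12% of CP area, 60 μm radius); cells are
  an inhomogeneous Poisson process thinned from the maximum compartment ×
  quadrant rate.
* All randomness flows from one master seed through per-purpose child
  sequences; identical seeds give identical fixtures.

**What the validation does and does not show.** Synthetic cohorts have uniform
cell placement, exactly polygonal ROIs, no registration error, no staining
variability, and effects that follow the generator's own log-linear model.
Passing recovery suites therefore demonstrates that the *analysis* is correct
and well-calibrated under its assumed statistical model — not that those
assumptions hold in any particular real dataset.

## Validation problem sizes

The validation suites (shared by the tests and `scripts/acceptance.py`) use:
100-seed cohorts at 9 exposed / 7 control with four canonical effect types for
classification recovery; 100 seeds of a 1.2 mm region sectioned at 180 μm (two
stained series' worth) for anteroposterior localization; five 10-call files at
20 dB SNR for detector scoring; 10,000-point Monte-Carlo samples for quadrant
geometry; 80 random ≤8×8 instances against the exhaustive matching oracle; and
60-seed striatal cohorts at 6 sections/mouse, base density 10/mm² — a full
stained series through the rostral CP — for compartment-pattern recovery, where
the limiting noise is Poisson counting in the ~0.1 mm² striosome-within-quadrant
control areas. The permutation p-value comparison uses n ∈ [8, 12] fixtures and
allows three Monte-Carlo standard errors plus 0.02 for the inherent O(1/n) gap
between the t approximation and the exact permutation null.
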