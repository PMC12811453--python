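# Methods

## Grid and dB scale

The 10-2 stimulus grid is the lattice {±1, ±3, ±5, ±7, ±9}² in field
degrees (origin at fixation, y up), restricted to eccentricity ≤ 9.2°.
The radial cut is the one free choice in reconstructing the 68-locus
membership: any value in the open interval (9.06°, 9.49°) — between the
eccentricity of the outermost retained locus (√82 ≈ 9.055°) and the nearest
excluded lattice point (√90 ≈ 9.487°) — yields the same 68 loci, and the
cut is exposed in configuration for transparency. Locus ids are assigned
row-major from the superior-left and are stable under reconstruction.
Each locus owns the closed 2° × 2° square centred on it; the squares tile
the grid without interior overlap.

Sensitivity values are attenuations relative to the brightest stimulus
(317.04 cd/m² at 0 dB; 0.08 cd/m² at 36 dB, i.e. 317.04·10⁻³·⁶). The
−1 dB export code means "not seen at maximum" and is treated as data, not
as a luminance: it participates arithmetically in MMS/ESS/mFTP means and in
the mFTP drop test (an 8 dB locus with a −1 dB neighbour has a 9 dB drop),
because that is how computations on raw integer exports behave.

Two built-in adjacency schemes are provided: `orthogonal4` (Euclidean
distance exactly 2°; neighbour counts 2–4 on this grid) and `chebyshev8`
(Chebyshev distance ≤ 2°; counts 3–8). The default for ESS/mFTP is
`chebyshev8`, the densest defensible neighbourhood. Published schematics
that use other neighbourhoods (e.g. counts of 2–5 per locus, or
peripheral-only neighbours) can be transcribed as a validated `custom`
table, and a `peripheral_only` option restricts neighbourhoods to
more-eccentric loci; it defaults off.

## Registration

The transform family is fixed to a 2-D similarity (uniform scale, rotation,
translation), estimated from ≥ 2 landmark pairs by least squares: both
instruments are fundus cSLOs imaging the same eye, so a richer family would
only overfit the few manual landmarks. The reported `rmse` is the RMS
landmark residual per coordinate, √(RSS/2n). Ring vertices in
autofluorescence pixels are mapped to MAIA pixels through the fitted
transform, offset by the grid centre (default: the MAIA image centre,
overridable for fixation offsets), scaled by 36°/1024 px, and y-negated
(image rows grow downward, field y grows upward).

Transection is tested against the *closed* square — a boundary that merely
touches a square counts, the inclusive reading of "transects into". Circles
and ellipses are polygonized at ≤ 0.25° chord length, bounding the
discretization error of the transection test below 0.05°. Incomplete rings
(boundary eroded by atrophy) are represented explicitly and rejected by the
analyses that need a closed boundary, rather than silently analyzed.

## Selections

All four selections are frozen at baseline and reused at every visit.
Design points that the metric definitions leave open, resolved here:

- **ESS** excludes the scotomatous loci themselves: the metric measures the
  *seeing* edge of the scotoma (an all-floor mean carries no longitudinal
  information).
- **mFTP** tier expansion adds entire tied proportion tiers, so the
  selection may exceed 5 loci; ties are never broken arbitrarily.
  Zero-proportion loci are never selectable — an eye without 5
  positive-proportion loci is flagged ineligible rather than padded,
  because proportion 0 carries no transition-zone signal. Loci left
  without neighbours (possible under a custom scheme) are excluded from
  ranking: the proportion's denominator would be undefined.
- **HRS** keeps baseline-scotomatous loci in the selection (they count for
  provenance and floor diagnostics) but excludes them from trend means.
- Event eligibility (≥ 5 prespecified loci at ≥ 8 dB baseline) is tracked
  per selection; the empty-selection mean is NaN, never a silent 0.

## Trend and event analyses

Eligibility requires ≥ 2 years of follow-up and ≥ 3 follow-up-mode tests.
Trend slopes are per-eye OLS of the metric mean against years. Windows at
0.5/1/1.5/2 years include visits up to the window + 0.1 years, matching the
slight overshoot of real visit schedules. The event target visit is the
final visit ("all") or the visit nearest 2.0 years within ±0.5 years
("2y") — nearest-visit selection reflects schedule jitter around a nominal
2-year trial horizon. The event boundary is inclusive (mean change exactly
−7 dB is an event) and the mean rate divides the mean change by the target
visit's elapsed years; per-locus slope averaging was rejected as an
alternative convention and the choice is isolated in one function.

The floor-mitigation rule (drop a locus from the metric mean from its
second consecutive −1 dB visit onward) is implemented but defaults off,
since progression rates are conventionally reported without it.

## Cohort statistics

The metric comparison is a one-way within-subject ANOVA (F = MS_metric /
MS_error, df (k−1, (k−1)(n−1))), complete cases only, with no sphericity
correction by default (a Greenhouse–Geisser option exists). When every
subject is constant across metrics both mean squares vanish; that
degenerate case is reported as F = 0, p = 1. Post hoc comparisons are
paired t-tests over the 6 metric pairs with Bonferroni correction
(p_corr = min(1, 6·p)), run only after a significant omnibus test.
Identical columns give t = 0, p = 1; a constant *nonzero* paired difference
has zero variance and is reported as a degenerate sentinel instead of an
arbitrary extreme statistic.

## Synthetic cohort

The generator emulates the measurement situation the pipeline is built
for: a latent hill of vision
s(r, t) = floor + (s_max − floor)·σ((R(t) − r)/width) with ring radius
R(t) = R₀ − c·t. Defaults: s_max = 24 dB (preserved central plateau),
floor = −5 dB (latent level of degenerate retina, below the measurable
floor so that censoring actually occurs), R₀ ~ U[3°, 8°] per eye,
contraction c = 0.25°/year, transition width w = 1.5°, nine 6-monthly
visits (4 years of follow-up), 30 eyes. Test-retest noise is Gaussian with
sd = σ₀ + σ₁·|∂s/∂r| (σ₀ = 1 dB, σ₁ = 0.5 dB per dB/°), encoding the
observation that retest variability is highest at scotoma borders.
Observed values are rounded to integer dB and censored: < 0 dB → −1
("not seen"), > 36 dB → 36. The 4-2 staircase is not simulated; its ±2 dB
quantization is subsumed by σ₀ and analyses operate on exported integers.
With these settings the simulated cohort means (MMS ≈ −0.6, ESS ≈ −0.9,
HRS ≈ −1.1, mFTP ≈ −1.5 dB/year over the full window) sit in the range
reported for rod-cone degeneration natural-history series, and the
transition-zone metrics decline faster than the whole-grid mean — the
qualitative structure the pipeline is meant to detect.

Each eye also carries a registration exercise consistent with its
degree-space ring: a random AF→MAIA similarity (nominal pixel-scale ratio
jittered by ±10 % scale, ±0.1 rad rotation, ±20 px translation), four
corner landmarks, and the ring re-expressed in AF pixels through the
inverse transform. Ground truth exposes the latent field, its radial
gradient and the exact time-averaged decline (s(t_end) − s(0))/t_end per
selection — the oracle used by parameter-recovery tests.

What the generator does **not** emulate: fixation instability and
mislocalization, staircase quantization structure, non-annular atrophy
(incomplete rings), intereye correlation, media opacity or cystoid macular
edema confounders, and learning effects. Passing parameter-recovery tests
therefore shows the pipeline is internally correct under a plausible
disease model, not that any particular clinical effect size will be
observed in patients.

## Problem sizes and numerical choices

The test suite runs the brute-force oracle comparisons at 500 random fields
and 1,000 random rings × 68 squares, the ANOVA oracle at 100 random
matrices (10⁻⁸ relative tolerance), the Bonferroni null at 10⁴ replicates,
and parameter recovery at 20 seeds × 30 eyes — sizes chosen to make the
Monte-Carlo margins small while keeping the whole suite around a minute.
Registration recovery is checked to 10⁻⁹ on noiseless landmarks.
Determinism: all randomness flows through a single seeded generator per
cohort; re-running any selection or pipeline on the same inputs is
bit-identical.

## Known limitations

- The exact neighbourhood schematic used by the original transition-point
  adaptation (2–5 neighbours per locus) is not published in reusable form;
  the package's built-in schemes bracket it and the custom-table mechanism
  accepts a transcription without code changes.
- Event and trend conventions (nearest-visit targets, window tolerances,
  mean-rate denominator) follow the stated reporting practice where it is
  explicit and document a single fixed choice where it is not.
- Cohort statistics are complete-case; eyes missing a metric (e.g. no
  scotoma at baseline → empty ESS) are dropped from the ANOVA with counts
  reported, not imputed.
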