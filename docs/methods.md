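# Methods

`octfovea` implements the full measurement chain used in foveal layer
morphometry of pediatric SD-OCT B-scans: a synthetic data generator with
known ground truth, graph shortest-path segmentation of the nine
intra-retinal boundaries, magnification-corrected foveal sampling, and the
three-group ANCOVA comparison stage. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Synthetic B-scan phantom

The phantom is a stack of ten intensity compartments — vitreous, the eight
layers (NFL, GCL+IPL, INL, OPL, HFL+ONL, MEZ, OS, IZ+RPE), choroid —
separated by nine boundary curves. The flat periphery places the boundaries
at `base_boundary_rows`; by default these encode the built-in reference
control-eye nasal layer thicknesses at 3.87 μm/px axial sampling. The
foveal pit is a Gaussian depression: with center column *c*, depth *D* (μm)
and lateral sigma `pit_radius / 3`,

    b_i(x) = base_i + p(x) · (T − base_i),   i = 1…5,
    p(x)   = exp(−(x−c)² / 2σ²),   T = base_1 + D / axial_scale,

so the inner surface and the four inner-layer boundaries coalesce exactly
at the center (inner-layer thickness ≡ 0 there), while B6–B9 stay flat.
`pit_depth = 0` disables the pit entirely (flat phantom). Defaults:
`pit_depth` 81.79 μm (peripheral total 215.10 minus central total 133.31 of
the reference control eyes), `pit_radius` 750 μm.

Rendering is anti-aliased — a boundary at row coordinate *r* centres its
intensity transition on sample index *r*, so the noiseless gradient peaks
exactly at the stored sub-pixel truth. The image is then blurred with a
Gaussian PSF (`blur_sigma`, default 0.8 px ≈ 3 μm sigma, the axial
resolution class of the instrument) and multiplied by speckle: a
gamma-distributed factor with mean 1 and coefficient of variation
`noise_level` (default 0.1, the residual contrast after frame averaging).
Identical spec + seed ⇒ bit-identical output.

**Default intensities** (20, 170, 75, 45, 120, 70, 150, 50, 160, 120)
follow the qualitative SD-OCT appearance — bright NFL, dark INL, moderately
bright OPL, dark ONL/Henle, bright ellipsoid band, dark outer segments,
hyperreflective IZ+RPE, mid-bright choroid (EDI) — and are additionally
arranged so that each boundary's interface is the dominant gradient feature
of its polarity within the band the sequential protocol searches. That is
what the spec-level minimum-contrast invariant exists for; a phantom whose
interfaces cannot be told apart would test nothing.

**What a green test establishes.** The phantom has no vessels, shadows,
motion, curvature (unless flattened inputs are simulated externally), or
3-D context; speckle is first-order (uncorrelated, gamma). Passing
recovery tests therefore demonstrate the correctness of the operator chain,
not clinical-grade robustness on pathology.

## Synthetic cohorts

`generate_cohort` draws one row per analysed eye from group-wise Gaussians
whose defaults are the built-in reference tables (18 eyes per group:
amblyopic, fellow, control; central total 133.58 ± 8.16 μm in amblyopic
eyes, etc., plus refraction, axial length, logMAR acuity). Amblyopic and
fellow eyes of a subject share id, age and sex and have correlated
thickness deviations (ρ, default 0.7 — a mid-range interocular correlation;
the analysis stage deliberately ignores the pairing, and ρ exists so users
can quantify the consequence). Controls contribute one left eye each.
Ages are normal(7.8, 1.9) truncated to [5, 12] years; sex is Bernoulli
with P(male) = 14/18. Thickness draws are floored at 0.1 μm (physical
lengths; some configured SDs are large enough to produce negatives
otherwise). Optional linear `age_effect` (μm/year) and `sex_effect` (μm)
slopes let users generate non-null covariate structure.

## Boundary segmentation

Gradient maps: the image is smoothed with an anisotropic Gaussian —
default (0.7, 3.0) px (axial, lateral). Speckle is uncorrelated along a
boundary while the boundary varies slowly, so heavy lateral smoothing
suppresses noise without degrading the axial localization that thickness
depends on. The vertical derivative is split into its positive
(dark-to-light) and negative (light-to-dark) parts, each min-max
normalized to [0, 1].

Each boundary is the minimum-cost left-to-right path where node weight
`w = 1 − g + w_min` (`w_min = 1e-5`), edges join adjacent columns with
vertical step ≤ `max_jump` (default 1 px; with the virtual zero-cost end
columns this is the classic 8-connectivity), and edge cost is `w(a)+w(b)`.
Every admissible path visits one node per column, so the optimum is found
by dynamic programming over per-column node sums; ties prefer the upper
row. Sub-pixel refinement fits a parabola to the gradient over ±1 px per
column.

The sequential protocol detects B1 (ILM), then B7, B9, B8, B6 (the
outer-retinal complex), then B2, B4, B3, B5, restricting each search to the
band between the nearest accepted boundaries above and below. Three
operator details matter:

* **Polarity-aware margins.** An exclusion margin (default 15 μm) is
  applied only against the nearest accepted neighbour *of the same
  polarity* — an opposite-polarity edge has no response in the target's
  gradient map, so no margin is needed, and omitting it lets boundaries
  touch where layers vanish. Margins shrink automatically where the band
  is too narrow to absorb them.
* **Lipschitz band relaxation.** Both band edges are relaxed to vary at
  most `max_jump` per column, which guarantees every non-empty band is
  traversable; the sequential stage therefore cannot fail on degenerate
  geometry (an explicit `InfeasibleRegionError`, naming the first bad
  column, remains for user-supplied regions).
* **Pinch handling.** Inside the foveola the inner layers are thinner than
  the PSF and leave no gradient signal. Two mechanisms keep the estimates
  anatomical there: a tiny node-cost tilt (0.002/px) toward the top of the
  band, and a *pinch snap* — an inner boundary (B2–B5) whose own gradient
  support stays below 0.06 for ≥ 4 consecutive columns has lost its layer
  and is clamped onto the boundary above, making the vanished layer
  measure exactly 0 μm. A final running-maximum clamp enforces
  B1 ≤ … ≤ B9 everywhere.

On the default phantom this yields per-boundary MAE < 0.5 px noiseless and
< 1.5 px at speckle 0.15 (20 seeds); accuracy degrades monotonically with
noise. The polarity contract is exactly equivariant under contrast
inversion with swapped polarities.

## Magnification and foveal sampling

Axial thickness is magnification-independent to first order, so thickness
is always `(B(k+1) − Bk) · axial_scale` at the nominal axial scale. The
lateral scale is corrected with Bennett's formula, `q = 0.01306 (x − 1.82)`
(x = axial length, mm), in ratio form against the instrument's assumed
model eye (`reference_axial_length`, default 23.95 mm — the instrument's
assumption is rarely documented, and the ratio form cancels it out of
relative comparisons). A shorter eye gets a smaller corrected scale, so a
fixed 0.5-mm eccentricity maps to more columns. A flag disables the
correction entirely; whether the original analysis corrected offsets,
thickness or both is not determinable, and correcting the lateral geometry
only is the physically defensible reading.

The foveal center is the argmin of the moving-average-smoothed (window 5)
total thickness restricted to columns where smoothed inner-layer thickness
< 5 μm (the "inner layers absent" definition). Because the pit floor is
nearly flat (< 0.3 px depth change over ±7 columns), the raw argmin
jitters under speckle; everything within 1 μm of the minimum counts as the
minimal plateau, its median seeds the estimate, and a parabola fitted to
the smoothed total over ±20 columns refines it to the vertex — the same
idea as the sub-pixel boundary refinement, and it recovers phantom centers
within 1–2 columns at speckle 0.1. Central values are the mean of the two
meridians at their centers; peripheral values are nearest-column samples
at 500 μm (corrected) in the four quadrants, with nasal/temporal read from
the horizontal scan using the sidecar's declared column direction (never
inferred from pixels).

## Cohort statistics

Per outcome (region × layer), the group comparison fits
`thickness ~ group + age + sex` by OLS (age centered, sex as a male
indicator, treatment coding with the amblyopic group as baseline), reports
the group-term F-test against the covariates-only model, and compares
covariate-adjusted group means pairwise via model-based t contrasts with
Bonferroni correction over the three pairs (adjusted p = min(1, 3p);
values above 0.9995 display as ">0.999"). Eyes are treated as independent
— replicating the clinical analysis this package mirrors — even though
amblyopic/fellow eyes are paired; the generator's ρ quantifies the cost of
that simplification. Baseline variables (SE = sphere + cyl/2, axial
length, logMAR) use Welch's t-test (the safer default when only "t test"
is specified); correlations are Pearson's r with the t-transform p-value
(n − 2 df), computed on amblyopic eyes by default and configurable.

Numerical notes: the ANCOVA F reduces to the one-way ANOVA F on balanced
covariate designs only after matching residual degrees of freedom (n−5 vs
n−3 — the covariates still consume two df even with zero slopes); the
type-I error of the group test is calibrated at 5% ± 1.5% over 1000 null
replicates of the generator with independent eyes.

## Pipeline

`run_pipeline` composes simulate (or load) → segment → measure → compare
from one declarative config; the global seed derives every stage seed, and
all CSV outputs (schema-tagged, dot-decimal, fixed float format) are
byte-reproducible under a fixed seed. In image mode each eye-row of the
cohort is rendered as a phantom pair (flank thicknesses = the row's mean of
the two opposite quadrants per meridian), segmented and measured, so the
statistics run on measured rather than drawn values.

## Known limitations

* The phantom's peripheral 0.5-mm samples sit on the pit's Gaussian tail,
  as in real eyes, so sampled peripheral totals are below the flat-flank
  values; forward-computed ground truth accounts for this.
* The segmentation is a faithful member of the graph shortest-path /
  dynamic-programming family, not a bit-exact clone of any published
  implementation; operator constants (order, margins, weights) are
  documented defaults, all configurable.
* No vessels, shadows, curvature or 3-D context are simulated; see the
  phantom section for what green tests do and do not establish.
* The statistics stage intentionally reproduces the independent-eyes
  analysis; mixed-effects or paired models are out of scope.
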