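# Methods

## Phantom model

A phantom is a continuous geometric description of a rib cross-section —
five elliptical muscles, a target-field polygon, an SF band of configurable
width along the field boundary, IF channels of configurable width around the
muscles — rasterized at a linear calibration (pixels per cm).  All random
structure (marbling) is sampled in centimetre coordinates, so a fixed seed
defines one continuous phantom that can be rendered at any resolution; this
is what makes resolution-invariance checks of the extraction meaningful.

Marbling in each muscle is a Boolean ellipse process: particle count
~ Poisson(intensity × muscle area), particle area ~ log-normal
(median 0.2 cm², log-SD 0.8 by default), aspect ratio ~ U(1, 3), orientation
uniform.  Overlapping particles merge by union, which matches what a
connected-component extractor sees.  Defaults give ~45–50 % marbling in the
rib eye, the level typical of high-grade steers.  The default calibration is
25 px/cm (0.4 mm/px), in the range of commercial carcass imaging, so a
median fleck spans >100 px and boundary-length estimates are stable.

Ground truth is defined on the *rasterized* masks, not the continuous
shapes, and is computed with the extraction module's own particle/geometry
code.  On a noiseless render the intensity threshold reproduces the marbling
mask bit-for-bit, so extraction equals ground truth exactly for every
pixel-count trait — quantization never enters the round trip.  What the
phantom does **not** emulate: photographic texture and lighting, colour,
muscle-boundary ambiguity (the label map is an input downstream), and
anatomically curved region outlines.  Passing round-trip tests therefore
validates the measurement arithmetic, not photographic segmentation.

## Image traits

* Areas are pixel counts divided by (px/cm)².
* Particles are 8-connected components of above-threshold pixels inside the
  muscle mask; components under 4 px are dropped.  The commercial grading
  software's segmentation is undisclosed, so the threshold rule (fixed value
  or Otsu-within-mask), connectivity and minimum size are explicit settings.
* Perimeters default to crack length with the standard isotropic weights
  (scikit-image's estimator); a raw boundary-pixel count is available
  because the fineness index inherits whatever estimator is chosen.  At the
  default particle scale the fineness index changes by <5 % between 1× and
  2× renders of the same phantom.
* The **coarseness index** is implemented as the area percentage contributed
  by particles at least 0.5 cm² in size.  The published index it mirrors is
  described only qualitatively, so the size-threshold definition was adopted
  and the threshold is a parameter.  The fineness denominator "square root
  of the muscle" is read as √area.
* Thickness is the chord of the region along the **second** inertia
  principal axis (smaller eigenvalue of the second central moment matrix)
  through the centroid.  The chord is computed exactly by clipping the line
  against every mask pixel's unit square and measuring the union of the
  parameter intervals; re-entrant lines contribute the sum of their in-mask
  segments, which is robust to concavity.  Equal eigenvalues (a disk) fall
  back deterministically to the image row/column axes.  Thickness is
  reported in mm, areas in cm².

## Price model

The full model regresses unit price on grading date, month of age, sex,
farm, meat-quality grade (MQ), one image trait, and the MQ×trait
interaction.  Designs use full dummy coding plus an intercept; the
minimum-norm least-squares solution handles the deliberate rank deficiency,
and all reported quantities are estimable.  F tests are marginal: each term
is deleted and the model refitted, F = (ΔRSS/Δrank)/(RSS/df).  The
interaction block uses sum-to-zero contrasts so the trait main effect stays
testable as the level-averaged slope (the convention SAS-style Type III
tests use).  Per-grade models drop MQ and farm (grade subsets are too small
to support ~166 farm levels) and report b·s_x/s_y together with its t
statistic; the two differ only by a factor and both are emitted because
published tables are ambiguous about which scale they print.

## Pedigree machinery

Pedigrees are traced from the phenotyped animals back a fixed number of
generations (default 5), counting an animal's generation as its shortest
parent-path distance to a phenotyped descendant (a proband's parents are
generation 1); parents beyond the cutoff become unknown.  Inbreeding uses
the Meuwissen–Luo ancestor-walk recursion; the A-inverse uses Henderson's
rules with the inbreeding-adjusted Mendelian variances
D_i ∈ {1, 0.75 − F_p/4, 0.5 − (F_s+F_d)/4}.  Unknown parents are unrelated
founders — no genetic groups.  The dense tabular A is kept only as the test
oracle.

## Animal model and sampler

Single trait: y = Xβ + Za + e, a ~ N(0, A σ²ₐ), e ~ N(0, I σ²ₑ); fixed
effects are farm, season, sex and month-of-age classes.  Two traits: the
same per trait with 2×2 G₀ and R₀ and complete records on both traits.

The Gibbs sampler draws location parameters single-site in pedigree order
from their scalar normal conditionals (residual-update form, so each sweep
is O(records + A-inverse non-zeros); the loops are JIT-compiled).  Fixed
effects carry flat priors and are sampled unconstrained — all levels of all
factors, no reference level — so individual levels random-walk along
non-estimable directions while fitted values and variance components remain
well defined, the standard behaviour of unconstrained mixed-model samplers.
Variances are drawn from scaled inverse chi-square conditionals
(σ²ₐ from u'A⁻¹u over χ²(q+ν); σ²ₑ from e'e over χ²(n+ν)) and, for two
traits, from inverse-Wishart conditionals with quadratic-form scale
matrices.  Priors are weak: ν = 4, scale set from an OLS split of the
phenotypic (co)variance at h² = 0.5; the choice is recorded in the chain
metadata.  A near-singular trait covariance (e.g., a trait paired with
itself) gets a small ridge added to the prior scales, with a warning.

Derived quantities — h², r_g, r_e, r_p — are computed per retained cycle
and summarised as means/SDs of those per-cycle values, never as ratios of
posterior means.  Chains are deterministic given the seed.  Effective sample
size and a split-chain R̂ are reported; there is no adaptive stopping, the
chain length is fixed by configuration.

Identifiability note: with unrelated animals (A = I) and one record each,
only σ²ₐ + σ²ₑ is identified; the heritability posterior then reflects the
prior.  Recovery tests therefore always run on pedigreed simulations.

## Simulation design and problem sizes

The generator mirrors the shape of a one-plant, one-year Wagyu study at
roughly one-third scale, the package's desk-scale default: 1,000 founders
plus three 1,000-offspring cohorts (4,000 pedigree animals), the last 1,500
animals phenotyped, fixed effects farm (collapsed to 40 levels so the
design stays estimable at this n), season (4), sex (2), month-of-age (9)
with level effects of SD 0.5/0.25/0.25/0.25 on a unit-phenotypic-variance
scale.  Breeding values are gene-dropped with Mendelian variance
D_i σ²ₐ — the same D_i as the relationship matrix, so simulation and
estimator share one covariance model.  In two-trait recoveries the residual
correlation defaults to half the genetic correlation.

Recovery runs use 20,000 cycles, 5,000 burn-in, thinning 10 (1,500 retained
samples), a scaled-down version of the production configuration of 500,000
cycles / 100,000 burn-in / thinning 10.  At this scale a single-trait run
takes seconds and posterior SDs for h² are ≈ 0.04–0.06, so the ±0.10
recovery tolerance sits at roughly two posterior SDs.

## Known limitations

* Marbling at realistic coverage (~50 %) percolates: merged particles form
  large components, so the coarseness index runs higher than on real
  carcasses where flecks are more regularly spaced than a Poisson process.
* The per-grade price models assume the farm effect is ignorable within
  grade; the full model keeps it.
* The two-trait sampler requires complete cases, matching carcass data
  where every trait is measured on every animal.
* Single-site location updates mix more slowly than block updates on
  strongly confounded designs; effective sample sizes are reported so this
  is visible.
* Posterior means of genetic correlations near the ±1 boundary carry a
  small skew toward zero (the posterior is one-sided at the boundary), on
  the order of 0.01–0.03 at desk scale; this is a property of reporting
  posterior means for a bounded parameter, not of the sampler.
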