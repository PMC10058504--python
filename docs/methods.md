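# Methods

## System and modelling scope

The package models a bead-compartmentalized co-culture: a dilute 1:1 mixture
of two near-isogenic *E. coli* strains (B and Y, distinguishable by
fluorescence) dispersed into monodisperse agarose beads of ~240 nL.  Each
founder cell grows into one immobilized colony; colonies are measured in 2D
by microscopy (area, perimeter, fitted-ellipse axes, integrated fluorescence)
at a fixed imaging schedule.  The pipeline starts from such measurement
tables; image acquisition and segmentation are outside its scope.

## Encapsulation statistics

Founder counts per bead are modelled as independent Poissons with means λ·r
(strain B) and λ·(1−r) (strain Y) — equivalent to thinning one
Poisson(λ) stream by the mixing ratio; no aggregation or clumping term is
included.  Closed forms follow directly: the empty-bead fraction is e^{−λ},
the co-culture fraction (1−e^{−λr})(1−e^{−λ(1−r)}), monoculture the
remainder.  For r = 1/2 the co-culture fraction first exceeds the
monoculture fraction at λ = 2·ln 3 (root of e^{−λ/2} = 1/3); the
`dominance_crossover` grid scan agrees with this root to one grid step and
is cross-checked by Monte Carlo.  Goodness of fit of simulated loadings uses
a chi-square on the joint (n_B, n_Y) support with cells of expected count
< 5 pooled.  λ can be calibrated from an observed mean colonies/bead by its
maximum-likelihood estimator, the sample mean.

## Colony geometry

Colonies are treated as prolate spheroids: one major axis and two equal
minor axes, so V = (4/3)π·(major/2)·(minor/2)².  The alternate form
V = (π/6)·AR·(4·area/(π·AR))^{3/2} is algebraically identical for an exact
ellipse and is verified by a property test.  Circularity is
4π·area/perimeter²; digital masks can exceed 1 slightly because polygonal
perimeter estimators under-measure smooth contours, so values > 1 raise a
warning but are reported raw.  Completed generations use
floor(log₂(V_colony/V_cell)) with V_cell = 1.3 μm³ — a partially completed
doubling is not counted.  Occupancy O = n_strain·V_colony/V_bead·100%
defaults to n/2 founders per strain (1:1 inoculation) but accepts explicit
per-strain counts.  Mask measurement uses scikit-image's moment-based
fitted-ellipse axes and its perimeter estimator; measured AR is within 2% of
the analytic value for axes ≥ 20 px.

## Growth models

Monoculture growth follows dA/dT = r·A·(1 − (A/A₂)^γ) with colony area A
proportional to cell number; r is the initial per-capita rate (1/h), γ a
dimensionless deceleration parameter (γ = 1 is logistic), A₁ = A(0) and A₂
the capacity.  The implementation uses the Richards-type closed form
A(T) = A₂·[1 + ((A₂/A₁)^γ − 1)·e^{−rγT}]^{−1/γ}, which is validated as the
exact ODE solution against an adaptive integrator (< 1e-6 relative over a
parameter grid) — this oracle pins down the correct reading of the closed
form.

The two-strain competition model couples two such laws through coefficients
c_Y (effect of Y on B, appearing in B's equation) and c_B (effect of B on
Y).  The cross term divides the competitor's density raised to the
*competitor's* γ by the *focal* strain's capacity raised to the focal γ;
this dimensional asymmetry is retained deliberately as the model's stated
form, with `normalization="competitor"` available to normalize by the
competitor's own capacity.

**Fitting.**  Two-stage by default, mirroring the experimental procedure:
raw points (from 4 h, when colonies become detectable) are smoothed with a
Boltzmann sigmoid A(T) = A₂ + (A₁−A₂)/(1+e^{(T−T₀)/dT}), then the
mechanistic model is fitted to the smoothed curve; direct raw-point fitting
is available (`smooth=False`) and is what the exact-recovery tests use.
Optimization is bounded nonlinear least squares (scipy `least_squares`,
TRF) with five seeded, jittered starts; A₂ > A₁ is enforced by
reparameterizing A₂ = A₁ + δ.  Monoculture confidence intervals come from a
residual bootstrap.  The co-culture fit holds all monoculture parameters
fixed and estimates only (c_B, c_Y) ≥ 0 from the summed curve; whether A₁
should be re-estimated is genuinely open, and fixing it is the default.
Two-stage smoothing matters here: with 5% multiplicative noise on a 7-point
total curve, direct refits recover the coefficients with ~30–45% median
error, while smoothing first brings both below 25% (the figure the
acceptance suite checks over 100 seeds).

**Identifiability.**  For identical strains the total curve is invariant to
first order under (c_B + ε, c_Y − ε), so only the sum is practically
identified.  The fit probes the cost at ±0.02 along the (1,1) and (1,−1)
directions from the optimum and flags the result non-identifiable when the
soft direction's sensitivity falls below 5% of the stiff one; an RMSE
profile over a (c_B, c_Y) grid is returned for inspection.

**Integration.**  LSODA with rtol 1e-8 (1e-7 inside fitting loops) and
atol 1e-10·A₂; states are clipped at zero.  Intensity curves can be fitted
with the same machinery up to the stationary peak; the post-peak decay is
excluded from model fits.

## Interaction classification

Final values (size or intensity at 12 h, the stationary onset) from
co-culture beads are randomly paired — independent uniform shuffles, without
replacement, n_pairs = min(|B|, |Y|) — and classified against the
*monoculture* medians (midpoint convention; ties count as "below", a
conservative and deterministic choice with probability ~0 for continuous
data).  The four quadrants are labelled mutual facilitation (both above),
one-way inhibition (mixed), and mutual inhibition (both below); only the
last is standard terminology.  The procedure repeats over 1000 random data
sets (pairing only by default; `bootstrap=True` also resamples values with
replacement, since either reading of "random data sets" is defensible).

**Standard error definition.**  The reported `se` is the SD of each
quadrant's fraction across resamples divided by √n_resamples — the standard
error of the reported mean.  The raw across-resample SD is also exposed as
`resample_sd`; for ~370 pairs it is bounded by the binomial envelope
√(p(1−p)/n_pairs)·100 ≤ 2.6 percentage points.  Note a structural property
of the statistic: if *every* value of one strain lies on the same side of
its reference median, the quadrant counts no longer depend on the pairing
and both spreads collapse to zero.  Strongly suppressed co-cultures (as the
default generator produces for strain B) therefore show SE ≈ 0.

## Synthetic-data generator

The generator emulates the measurement tables of a bead experiment under
the default study conditions: λ = 2 cells/bead, ratio 0.5, 240 nL beads,
imaging at 4, 6, 8, 10, 12, 22, 32 h.  Design choices:

* **Nutrient sharing.**  Each bead carries a fixed nutrient budget, so each
  colony's capacity is A₂/(total founders in the bead).  This reproduces,
  by construction, the inverse relationship between mean final colony size
  and inoculum and an inoculum-independent final population per bead.
* **Growth truth.**  r_B = 0.85/h, r_Y = 1.05/h (rate ratio 0.81, the
  asymmetric regime where Y outgrows B), γ = 1.2, A₁ = 5 μm²,
  A₂,B = 9000, A₂,Y = 11000 μm², c_B = 0.5, c_Y = 0.6 (mild mutual
  inhibition, Y suppressing B more).  These put the stationary onset at
  ≈ 11–12 h, consistent with growth slowing between 10 and 12 h.
* **Shapes.**  Exact ellipses; per-colony aspect ratio from a normal with
  mode 1.3 and spread 0.15 truncated at 1 (the typical monoculture shape),
  perimeter by Ramanujan's second approximation, axes derived from the area
  trajectory so area = π·(major/2)·(minor/2) holds exactly.
* **Noise.**  Mean-one multiplicative log-normal noise on area with 5% CV
  (no noise magnitude is established experimentally; 5% is a defaults
  choice), and an independent 5% CV on intensity on top of the inherited
  area noise.
* **Intensity.**  I = k·area per strain until the noiseless trajectory
  reaches 99% of its final size, then an exponential decay at 0.08/h — a
  single phenomenological rate standing in for photobleaching and/or
  starvation, which the data cannot distinguish.
* **Determinism.**  One root seed feeds three independent substreams
  (loading, shapes, noise) via `SeedSequence` spawning; a fixed seed gives a
  byte-identical CSV.

What the generator does *not* emulate: spatial structure within beads
(shading, colony overlap — negligible at low inoculum), bead-volume
variability, segmentation artifacts, lag-phase mechanics, and
nutrient-explicit kinetics.  Passing tests therefore demonstrate
correctness of the statistical machinery under the stated assumptions, not
the fidelity of those assumptions to any particular instrument.

One consequence of the nutrient-sharing rule is worth noting: co-culture
beads necessarily hold ≥ 2 founders while monoculture experiments include
many single-founder beads, so aggregated co-culture curves are suppressed
relative to monoculture fits even before competition acts.  Fitting the
competition model to generator output consequently *over*-estimates the
microscopic coefficients (the fit attributes sharing to competition);
parameter-recovery benchmarks therefore generate data directly from the
competition model, while pipeline runs on generator output should read the
fitted coefficients as effective, not microscopic, interaction strengths.

## Problem sizes and tolerances

Law-of-large-numbers checks use 10⁵ beads (loading draws and full generated
tables); parameter-recovery benchmarks use 100 seeded data sets; the
interaction analysis uses ≥ 370 colonies per strain and 1000 resamples; mask
benchmarks use 500 masks with minor axis 30 px.  Closed-form/ODE agreement
is asserted at 1e-6 relative, algebraic identities at 1e-9, Monte Carlo
agreement at 2–3 standard errors or chi-square p > 0.001.

## Known limitations

* The generator's representative-colony approximation lets all colonies of
  a strain within one bead share a noiseless trajectory; within-bead
  between-colony variability enters only through measurement noise.
* Quadrant classification is descriptive; no formal test of interaction
  sign is provided.
* The competition model defaults to the focal-capacity cross-term normalization; with
  very dissimilar capacities the coefficients are not directly comparable
  across strains unless the competitor-normalized variant is selected.
* Intensity decay is a single exponential; real bleaching/starvation
  kinetics are richer.
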