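# Methods

## Psychometric model

Detection is modeled by Quick's form of the Weibull frequency-of-seeing
function

    Ψ(c) = γ + (1 − γ − λ) · (1 − 2^−(C/A)^β),

where `c` is log10 Weber contrast, `C = 10^c`, `A = 10^α` is the linear
threshold, `β` the slope, `γ` the false-positive (guess) rate and `λ` the
false-negative (lapse) rate. With `γ = λ` the curve passes through 0.5 at
`c = α`, the standard definition of threshold. Defaults throughout are
`γ = λ = 0.02` and `β = 3.5`; 3.5 sits mid-range among published perimetric
slopes and is used both as the ZEST likelihood slope and as the synthetic
observer's slope (both configurable). An infinite `α` encodes an unseeable
location (inside the blind spot): `Ψ` collapses to the guess rate `γ` at
every contrast the device can produce.

## Contrast ladder

The device ladder spans −0.9 to +0.6 log units (74 levels). The exact level
set of the original instrument is not published, so two conventions are
offered: the default places levels uniformly on the *linear* contrast scale
between 10^−0.9 and 10^0.6 of background — reproducing the non-uniform log
spacing characteristic of luminance-stepped hardware (median log step
≈ 0.02) — and `scale="log"` gives uniform log spacing. The +0.6 log-unit
maximum corresponds to the 400% Weber limit (80 cd/m² increment on a
20 cd/m² background).

## ZEST

The threshold posterior is a probability mass over the ladder levels,
initialized uniform (a broad-Gaussian prior is available; the source
procedure does not state its prior). Each stimulus is placed at the
posterior mean snapped to the nearest ladder level, ties toward the lower
contrast (`placement="mode"` is offered as an alternative, since published
variants use either). After each response the pmf is multiplied by the
per-level likelihood `Ψ(c | α = level)` (or its complement) and
renormalized; after six presentations the estimate is the posterior mean.
Catch trials (blank false-positive probes and maximum-contrast
false-negative probes) can be inserted at configurable per-trial rates,
default off; they are recorded separately and never enter the posterior.

Recovery under the default conditions (six presentations, `β = 3.5`,
uniform prior, 500 runs per level) gives mean absolute errors near
0.07–0.11 log units and biases under 0.04 across true thresholds from −0.5
to +0.3 — comfortably within the 0.25 / 0.1 bands the test suite asserts.

## Gaze filtering

Three fundus frames are acquired per presentation (every 40 ms; two during
the 60 ms stimulus, one after). Frame displacements in camera pixels are
converted at 1.64 arcmin/pixel (0.027°/px); the trial displacement is the
per-axis median. Exclusion rules: any missing frame (blink or disc out of
image); per-axis displacement range among the three frames > 0.5°; any
frame shifted > 1° from the reference on either axis. Whether the original
0.5°/1° rules were per-axis or Euclidean is not stated; per-axis is the
default (simplest reading) and a Euclidean-diameter option is provided.
All rules are evaluated on every trial, so the excluded set is independent
of rule order; the reported reason uses the priority missing > jitter >
shift. The inferred retinal location is nominal + displacement — a single
documented sign convention (rightward eye shift → more temporal retinal
patch) with a round-trip test; the opposite convention would only mirror
the displacement field.

At a microsaccade rate of 0.8/s the probability that a 120 ms three-frame
window contains one is taken as rate × window = 0.096 (the linear
arithmetic behind the "≈10%" figure; the Poisson form 1 − e^−0.096 = 0.092
differs negligibly at this rate).

## Weighted maximum-likelihood threshold map

At each point of a fine estimation lattice, all valid presentations whose
inferred location lies within 0.5° enter a weighted ML fit of `(α, β)` with
`γ = λ = 0.02` fixed, maximizing `Σ wᵢ [rᵢ ln Ψ(cᵢ) + (1−rᵢ) ln(1−Ψ(cᵢ))]`
with Gaussian kernel weights `wᵢ = exp(−dᵢ²/2σ²)`, `σ = 0.5°`. The kernel
is therefore truncated at one SD (weight e^−0.5 ≈ 0.607 at the cutoff);
the discontinuity is retained deliberately to match the published
procedure. Numerical choices: L-BFGS-B on the negative log-likelihood with
bounds `α ∈ [−1.2, 0.9]` (ladder extent ± 0.3) and `β ∈ [0.5, 20]`, four
deterministic starts (lowest/highest local contrast at β = 2, midpoint at
β = 6, weighted mean at β = 3.5), and a coarse grid-search fallback.
Because the likelihood surface in `α` is monotone when the local data never
straddle threshold (e.g. an all-seen neighborhood), such fits pin `α` at a
bound and are flagged `boundary`; fits with fewer than 4 trials in radius
(an anti-degeneracy floor; the original minimum is unspecified) are
`insufficient` and appear as gaps. A map is exactly the pointwise fit at
every lattice point — there is no shortcut path to diverge from.

## Slice display

For a display threshold C₀, the *crossover* trials are those seen at a
contrast strictly below C₀ or not seen at a contrast at-or-above C₀
(boundary inclusive on the not-seen side, exactly as defined); the rest are
concordant. The three subsets partition the valid trials for every C₀, and
as C₀ falls the crossover-seen set can only shrink while the
crossover-not-seen set can only grow (set containment) — both are asserted
across the default sweep of 0.5 → −0.5 log units in −0.01 steps
(101 frames). The two-contrast principle follows: in a region with a
0.3 log-unit step scotoma and steep slopes, a stimulus at the normal
threshold is seen ~50% outside and almost never inside, while a stimulus
0.3 higher is almost always seen outside and missed ~50% inside, so the
crossover subsets at those two display thresholds localize the scotoma.

## Wave search

Candidate locations lie on circles of radius k·0.5° around the blind-spot
center with `max(4, round(2πr/spacing))` points per circle (spacing ≈ 1°),
the first point at angle 0 and no angular stagger between rings — a fixed
convention chosen for determinism where the source says only
"approximately 1°". Wave 1 tests the innermost circle exhaustively, two
presentations per location. Adjacency is computed by Voronoi tessellation
over all candidate points generated so far; cells sharing only a vertex
are not neighbors. Each later wave opens ring-k locations adjacent to any
tested location with ≥ 1 miss (this rule wins when a location also borders
2/2-seen neighbors), repeating within the ring until no further locations
open. A location opened outside the 13°×19° extents is never tested and
marks the run; the search continues elsewhere and ends either
`edges_closed` (a wave opens nothing — every frontier location was seen
twice) or `out_of_range` (expansion touched the area boundary), with a
wave-cap guard against pathological observers. The fixed run contrast is
an input; following the two-contrast principle above, the test suite and
acceptance script use baseline + 0.3 log units, at which normal locations
rarely miss twice while blind-spot and vessel locations do — giving run
sizes near 70–110 locations on the synthetic subjects, within the low
hundreds expected for this geometry. The algorithm is blind-spot-specific
by design (it assumes the start lies inside a deep scotoma) and is not a
general scotoma finder.

## Synthetic observer

The ground-truth surface is baseline `α = −0.35` log units (chosen to sit
inside the −0.50…−0.15 range of slice contrasts appropriate to this
region), plus additive vessel depressions with Gaussian cross-section of
scale width/2 (width 0.5°, depth 0.3 log units; a rectangular profile is
available), plus an elliptical blind spot (center ≈ (15, 1.5)°, semi-axes
≈ (2.5, 3.5)°, slightly jittered per seed) where `α = ∞`. The default
subject has superior and inferior arcades and a nasal branch leaving the
disc.

Eye movement: per-trial drift drawn i.i.d. N(0, 0.15°) per axis, constant
across the three frames; with probability rate × 120 ms ≈ 0.096 a
microsaccade fires mid-trial and shifts the later frames by N(0, 0.4°) per
axis (a typical microsaccade amplitude — large enough that many, not all,
such trials trip the 0.5° rule); with probability 0.05 per trial a blink
blanks one frame. These defaults put total exclusions near 8%, inside the
6.4–15.8% range reported for real fixating observers. The response is
drawn from Ψ at the *drifted* retinal location, so eye movement corrupts
nominal-location analyses exactly as in real data. Not emulated: saccadic
main-sequence dynamics, optical blur, within-trial drift, frame
measurement noise, and learning/fatigue — so passing recovery tests show
the pipeline's statistical behavior under idealized tracking, not clinical
performance.

Identical seeds give byte-identical CSV outputs.

## Problem sizes in the test suite

The estimation-lattice contract (121 × 181 = 21,901 points at 0.05°) is
asserted arithmetically; map-recovery tests evaluate the identical
per-point fit on coarser lattices (0.25° over a 4°×4° flat region; 0.1°
over the 1°-wide nasal strip for the end-to-end vessel-localization check)
— the package's own choice of test scale, since the fit at one lattice
point does not depend on how many others are evaluated. The end-to-end
check asserts that the median over transects of the distance from each
transect's deepest map point to the true vessel centerline is ≤ 0.5°
(half a degree being both the vessel width and the reported worst-case
tracking error), and that vessel-free background is recovered to ≤ 0.15
log units median absolute error.

## Known limitations

- The per-block test structure of the original protocol (8 interleaved
  blocks of 27–40 locations combining 2° grids into 0.5°) cannot be
  reconstructed from its description; `block_id` is assigned by a simple
  configurable interleave and nothing is asserted about it.
- The optional heuristic for choosing the wave-search contrast from a
  slice sweep is not validated; the original choice was made by visual
  inspection.
- `boundary` fits report the bound value, not a censored estimate; treat
  them as "no crossing information here", not as measurements.
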