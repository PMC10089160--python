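# Methods

## The scientific problem

In a crowded, expanding cell population (a microbial colony edge, a
biofilm, the rim of a solid tumour) proliferation is confined to a growth
layer of depth λ behind the front; deeper cells are in stationary phase.
A neutral mutation arising at depth Δ behind the front is pushed out of
the layer by the cells proliferating in front of it, and its clone stops
growing when no member remains within λ of the front ("washout").
Because everything in the layer grows at the same rate, the clone's final
size is set by geometry alone:

    n ≈ λ / Δ            (final size, in cells, of a clone born at depth Δ)

If the mutation rate is proportional to the growth rate, birth depths are
uniform on (0, λ], so the induced clone-size density is P(n) = n⁻² and the
cumulative distribution is P(size > n) = 1/n, from n = 1 up to the ceiling
n = λ/σ set by the cell width σ.  This is the same 1/n law as the classic
well-mixed Luria–Delbrück fluctuation test, produced here by a purely
mechanical mechanism.  Clones born within one cell width of the front
instead surf the expansion and reach much larger sizes with a shallower
spectrum.  This package implements the cell-based simulator, the
continuum predictions, a well-mixed Luria–Delbrück reference generator,
spectrum estimators, and the spatial-subsampling machinery that lets the
whole-population spectrum be reconstructed from small samples.

## Mechanical model

Cells are 2D budding particles: a mother disk of fixed radius σ/2 rigidly
attached to a bud disk growing from 0 to σ/2, at which point the bud
detaches as a new cell (the mother's bud resets to zero).  Growing cells
increase their total area as exp(g·dt) per step, realized entirely as bud
growth, so the generation time is ln 2 / g.

* **Contacts.** Disks of distinct cells repel with a linear (Hookean)
  force k·overlap along the line of centers; there are no attractive
  forces.  Forces on a cell's two disks reduce to one net force and one
  torque about the area centroid.  Coincident centers fall back to a
  deterministic direction chosen by cell-id order (logged).
* **Dynamics.** Overdamped: velocity = force / (γ·area), angular velocity
  = torque / (γ·area·(σ/2)²), with γ the drag per unit area.  Only the
  force law's existence matters for the population-genetic observables;
  the constants set time scales.
* **Geometry.** The box is periodic in x (minimum-image convention); the
  front advances in +y.  Cells deeper than `removal_depth`
  (default λ + 6σ) are frozen: they leave the integrator but remain, for
  a band of ~4σ, as static obstacles so the live column keeps resting on
  a floor — without this the expansion leaks downward and the front speed
  and washout times are wrong.  Frozen cells keep their positions and
  clone labels for snapshots and sampling.
* **Growth layer.** Per-column front heights are the top edge of the
  highest disk in each column (the material surface; column width σ,
  empty columns take the taller of their nearest neighbours).  This
  definition is continuous through divisions — a newborn's top edge
  coincides with the bud top it replaces — and is used consistently for
  the growth cutoff (cells with depth < λ grow), birth-depth recording,
  surfing classification and washout detection.  Measuring heights at
  mother centers instead biases recorded depths by ≈0.8σ and adds ~σ of
  flicker, which visibly distorts the size–position law.
* **Initial condition.** A row of touching cells spanning the box at
  y = 0.  `run()` randomizes the division phases and jitters positions by
  ≤0.2σ (keeping the row overlap-free): a perfectly regular, synchronous
  row grows as a columnar crystal of non-interacting vertical stacks with
  quantized birth depths; the jitter seeds the disorder that real
  packings sustain on their own.

### Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| `sigma` | 1 | length | the unit of length (cell width) |
| `lambda_depth` | 14 | σ | growth-layer depth of the study conditions |
| `box_width` | 30 | σ | wide enough for a disordered front, cheap enough for a desk |
| `growth_rate` | 1 | 1/time | sets the unit of time; generation = ln 2 |
| `spring_constant` | 1000 | force/σ | keeps the 99th-percentile overlap < 0.15σ under the pressure of a 14-cell layer |
| `damping` | 1 | force·time/σ² | arbitrary positive mobility scale |
| `dt` | 0.1·γ·(πσ²/4)/k ≈ 7.9e-5 | time | a free 0.1σ overlap relaxes over ≥10 steps; stability, not realism |
| `label_rate` | 0.05 | per division | neutral-labelling probability |
| `selection_s` | 0 | – | labeled cells grow at g·(1+s) |
| `removal_depth` | λ+6σ | σ | frozen cells cannot grow again; keeps the force set O(box·λ) |

`growth_profile` accepts a tabulated g(Δ) on [0, λ] for nonuniform-growth
runs; `bud_rule` switches between polar (bud inherits the mother's
orientation) and random bud placement.

## Clone labelling

Labelling happens only at division: each newborn founds a new clone with
probability `label_rate`, which makes the mutation rate proportional to
the growth rate — condition for the uniform birth-depth distribution.
Under the default infinite-alleles policy a newborn of a labelled mother
can also found a (new) clone; a cell's clone is the most recent founding
event on its ancestry, so clones are always disjoint.  The alternative
`unlabeled-only` policy emulates an irreversible colour switch, but in a
finite box some clone eventually fixes at the front and founding then
stops — that mode is unsuitable for collecting large clone ensembles.
Exactly one uniform draw is consumed per division so the random stream
layout does not depend on outcomes.

Birth depth Δ is recorded against the current front profile at the
division instant; a clone is *surfing* iff Δ ≤ σ (boundary inclusive).
A clone is finalized at the first division event at which no member lies
within λ of the front; clones still in the layer at the end of the run
are flagged active (censored) and excluded from spectra by default.

**Clone size.** Washout interrupts members mid-cycle, so raw cell counts
systematically undershoot the clone's area growth by the mean mid-cycle
area factor (≈1.44); measured against the area-based λ/Δ law this looks
like a spurious ~0.7 prefactor.  `final_size` is therefore the
*area-equivalent* count: the summed member area in units of the newborn
area, rounded — the same measure as using clone area as a size proxy,
the standard practice when clones are read out from images.  The areas
are summed before rounding: mother and daughter reset their bud phases
together at division, so rounding per member would cross thresholds in
lockstep and make odd counts artificially rare.  The raw member count is
kept in `final_cell_count` and is the quantity that satisfies exact
membership conservation.

## Continuum theory and the Luria–Delbrück generator

`theory` evaluates n = λ/Δ, the density C·n⁻² (C = 1/(1−σ/λ) normalizes
it on [1, λ/σ]; the bare "ideal" form is available for plotting), and the
cumulative 1/n with the analogous normalized variant, all with domain
checks.  The fluctuation-test generator doubles a well-mixed population
synchronously from N₀ to N (G = ⌈log₂(N/N₀)⌉ generations, the realized N
is reported); clones are founded per generation as a Poisson draw with
mean μ × wild-type divisions (the wild-type count is debited by the
standing mutant population).  Deterministic mode assigns the exact sizes
2^(G−g).  Stochastic mode grows each clone as a continuous-time Yule
(pure-birth) process over the remaining (G−g)·ln 2 time, whose exact law
is Geometric with mean 2^(G−g); a literal "every member doubles each
generation" branching has zero per-clone variance and would duplicate the
deterministic mode, so the Yule process is the stochastic variant
offered.  The classic amplitude E[#clones ≥ n] = μN/n serves as the
deterministic-mode oracle and as the basis of mutation-rate estimation.

## Spectrum estimation

All cumulative curves use the "≥ n" convention (stated in output
metadata).  The power-law exponent is estimated by conditional maximum
likelihood for an upper-truncated continuous power law (the truncated
generalization of the Hill estimator), solved by bracketed root finding
of the mean-log equation to 1e-8, and reported in the cumulative
convention (density exponent minus 1) with standard error (β−1)/√m.  For
integer data — clone counts on the narrow range [2, λ/σ] — the continuous
approximation is badly biased (≈2 instead of 1 on synthetic 1/n data), so
a half-integer continuity correction widens the support to
[n_min−½, n_max+½]; it is applied automatically exactly when every
in-range size is an integer.  The default nonsurfing fit range [2, λ/σ]
excludes the n = 1 pile-up of clones born at the back edge of the layer.

## Sampling and reconstruction

Snapshots (every cell ever created, with positions and labels) can be
sampled randomly (each cell kept with probability p — sequencing at
finite coverage) or by a contiguous rectangle in (x, depth-from-front)
coordinates — a spatial biopsy.  Rescaling to the whole-population scale
uses only N_total and the sample:

* region: crowding keeps clones contiguous, so an in-region count
  estimates the true size; f = n_s/N_total, and the clone-count axis is
  multiplied by N_total/N_sample;
* random: true size estimated as n_s/p; the count axis is unchanged.

The defaults operationalize the flat-front analogues of a deep biopsy
(depth band [λ, 3λ], nonsurfing-dominated) and a front segment
([0, λ], surfing-dominated).  Each estimator is restricted to its domain
of validity: region samples drop clones whose sampled cells touch a depth
boundary (within 1σ) — a sliced surfing streak would otherwise enter with
the full count multiplier while carrying only a slice of its size — and
random samples are trusted only above the detection scale of ~3 sampled
cells per clone (frequencies ≥ 3/(p·N)), below which Poisson noise on the
inflated sizes overstates clone counts.  Merged curves report per-source
cumulative counts ordered by frequency; on overlaps the ratio of the
curves is an agreement diagnostic (a factor-2 disagreement logs a
warning), and point evaluation combines overlapping sources by geometric
mean.  The
rescaling rule is validated against the directly computed
whole-population spectrum of a simulation rather than against any
external formula.  Mutation-rate estimation fits the cumulative count
M(n) to (μ̂N)/n by least squares over the declared 1/n range, evaluated
at the distinct observed sizes.

## Problem sizes used in the shipped analyses

The simulation used by the test suite and by `scripts/acceptance.py` runs
λ = 14σ, a 30σ box, labelling rate 0.06 and 50,000 divisions (≈5×10⁴
cells ever created, ≈2,300 finalized nonsurfing clones) — enough for
stable medians and exponent fits while staying desk-scale.  The
fluctuation-test checks pool 300–400 cultures of N = 2²⁰.  These sizes
are the package's own choice of study conditions.

## What the synthetic data do and do not show

The simulator emulates mechanically crowded, neutral, flat-front growth
with a sharp growth-layer cutoff and deterministic exponential cell-cycle
progression.  It does not include cell death, nutrient fields, motility,
mechanical feedback on growth rate, radial colony geometry, rod-shaped
cells, or sequencing noise.  Passing tests therefore demonstrate the
crowding mechanism and the estimators' correctness on populations obeying
the model's assumptions, not the behaviour of any particular organism;
the robustness claims covered are limited to bud-placement rules,
nonuniform growth profiles g(Δ), and the labelling-policy variants.

## Numerical choices and degenerate inputs

Ties between simultaneous divisions are processed in cell-id order;
random draws occur in a fixed order (labelling, then bud angle) — both
for exact reproducibility given a seed.  Coincident disk centers use a
deterministic fallback direction and log a warning.  Overlaps beyond σ/2
abort the run with advice to reduce dt or stiffen contacts.  Empty
sampling regions warn and return empty objects instead of raising.
Power-law fits refuse fewer than 10 in-range points or degenerate
(all-equal) data.  The truncated-MLE root is bracketed on β ∈ [−10, 60]
and clamped at the bracket edge if the data mean-log sits at a support
boundary.

## Known limitations

* The area-equivalent size definition makes `final_size` differ from the
  raw member count by up to a factor ~1.5 for individual clones; analyses
  that need exact membership should use `final_cell_count`.
* Front-height columns of width σ resolve roughness only down to the
  cell scale; recorded birth depths carry O(0.5σ) noise, which widens the
  scatter of the size–position law at shallow depths.
* The surfing-clone spectrum is shaped at large sizes by the recurrent
  relabelling of the default policy (descendant founding events truncate
  giant clones); the qualitative contrast with the nonsurfing spectrum is
  robust, but surfing exponents are not calibrated quantities here.
* With `unlabeled-only` labelling, founding saturates once a clone fixes
  at the front; ensembles collected in that mode are small by nature.
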