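# Methods

This note records the model, its numerical conventions, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish.

## The interacting-cell-system model

The tumor microenvironment of a tissue-microarray core is reduced to four
cell types on a 2D chamber lattice: melanoma cells, activated CD8⁺ T
cells, exhausted CD8⁺ T cells, and tumor-associated macrophages (TAMs).
Chambers are squares of side `l0` (default 10 μm, about one cell
diameter); a hard per-chamber cap (default 4 cells) stands in for volume
exclusion.  Cells in the *same or neighboring* chambers are "in contact".

Dynamics are a continuous-time Markov jump process simulated by exact
kinetic Monte Carlo: all event classes are enumerated with their aggregate
rates, a waiting time is drawn exponentially in the total rate, and one
event is executed.  The event set and conservation rules:

* melanoma division (+1 melanoma),
* lysis of a contacted melanoma by an active T cell (−1 melanoma),
* exhaustion of an active T cell by melanoma contact or TAM co-occupancy
  (−1 active T, +1 exhausted T, in place),
* active-T division (+1 active T) and slide-wide recruitment (+1 active T
  into a uniformly chosen chamber with capacity),
* exhausted-T death (−1 exhausted T),
* diffusive hops of T cells and TAMs (conserve all counts).

Exhausted T cells never lyse, divide, or revert: the only event that
creates them is exhaustion and the only events that read them are death
and hops.  Melanoma cells do not move (tissue-bound tumor mass).

### Feedback

Successful lysis promotes T-cell proliferation and recruitment.  The
model keeps these rates *piecewise constant*: `L` is the number of
melanoma cells lysed during the most recent completed window of length
`dt_feedback` (default 24 h, a cell-cycle-scale memory).  Between window
boundaries all rates are constant, so exponential waiting times remain
exact; at a boundary the clock is simply redrawn (valid by
memorylessness).  A linear gain (`k_prolif`, `k_recruit` per lysed cell)
is the simplest monotone coupling; nothing downstream depends on this
particular functional form.

### Geometry conventions

* Coordinates are continuous μm, origin at the slide's lower-left corner;
  the slide is the half-open box `[0, W) × [0, H)`.
* A cell at `(x, y)` rasterizes to chamber `(⌊y/l0⌋, ⌊x/l0⌋)`; `x = k·l0`
  belongs to column `k`.  If a chamber would exceed the cap at
  initialization the surplus cell moves to the nearest chamber with spare
  capacity (center distance, ties row-major); relocations are logged and
  conserve per-type totals.
* Contact neighborhood: Moore-8 plus the shared chamber (diagonal chamber
  centers sit 14.1 μm apart, within contact range of ~10 μm cells).
  TAM-induced exhaustion is same-chamber only — macrophage–T synapses
  require tighter apposition than a diagonal neighbor.
* Hop neighborhood: von Neumann-4, the standard lattice diffusion stencil
  (`D = r_hop·l0²/4`).  Both neighborhoods are configurable.
* Boundaries are reflecting: hops, spillover placements, and recruitment
  targets that fall off-grid or into a full chamber are *null events*
  (time advances, nothing changes).  A TMA core is a closed observation
  window; periodic wrapping would glue together biologically unrelated
  tissue.
* Division places the daughter in the parent's chamber if it has
  capacity, else in a uniformly chosen hop-neighborhood chamber with
  capacity, else the division is null (contact inhibition at confluence).

### Default rates

The defaults (`RateParams`) are *placeholders of plausible magnitude*,
not fitted values: melanoma division 0.02 h⁻¹ (~35 h doubling), lysis 0.1
h⁻¹ per contact pair, exhaustion rates `bC = bM = 0.05` h⁻¹ per pair (the
two parameters the calibration stage is designed to estimate),
exhausted-T death 0.01 h⁻¹, hop rates 1.2 h⁻¹ (D ≈ 30 μm²/h, a T-cell
motility scale), baseline T division 0.005 h⁻¹ and recruitment 0.5 h⁻¹
slide-wide with gains 10⁻⁴ and 10⁻² per lysed cell.  Every analysis that
matters either estimates the exhaustion rates or states its rates
explicitly.

### Implementation

The event loop is a single numba-jitted kernel.  Interaction pair counts
(active-T–melanoma contact pairs; active-T–TAM co-occupancy pairs) are
maintained incrementally as exact integers, so aggregate rates never
drift.  Cells of a type are sampled uniformly by rejection from the
occupied-chamber list with a monotone per-type occupancy bound as the
envelope; the T cell of a contact pair is accepted proportionally to its
local partner count.  Randomness comes from an inline splitmix64 stream:
a fixed seed gives a bit-identical trajectory.  Populations are recorded
on a fixed grid by carrying the last state forward; full lattice
snapshots can be requested at arbitrary times.

## Outcome classification and calibration

The melanoma **fold change** between t = 0 and T = 333 h (about one
therapy cycle) classifies a simulated slide: < 1 responder, > 1
nonresponder.  A fold change of exactly 1 is classified nonresponder —
"no net shrinkage" is the conservative clinical reading of no response;
the tie rule is an explicit argument.

The **prediction success frequency** `f_i(θ)` is the fraction of
independent simulations from slide *i*'s rasterized initial condition
whose predicted label matches the clinical label.  The cohort **score**

    score(θ) = Π_i [(1 − b)·f_i(θ) + b/2],     b = 0.1

discounts each slide's evidence: a 1 mm core undersamples the tumor, so
even a perfect model is capped at `1 − b/2` per slide while chance gets
`b/2`.  Scores are accumulated in log space.

`(bC, bM)` are estimated by maximizing the score over a log-spaced grid
with **common random numbers**: the simulation seeds of slide *i* depend
only on (seed, slide index), not on θ, so the stochastic surface is
smooth across the grid and the argmax is reproducible.  Whether the
original analysis shared draws across parameter sets is unknowable from
the outside; common draws are strictly a variance-reduction choice and
are recorded in the fit metadata.  Ties break toward the smaller
(bC, bM) lexicographically.

## Hypothesis testing

An alternate mechanism hypothesis ("TAMs do not exhaust T cells", "tumor
cells do not exhaust T cells") zeroes the corresponding rate and re-fits
the remaining one (one-parameter re-estimation).  With per-slide
frequencies cached for both models, each bootstrap replicate β draws N
slides with replacement and computes

    DSS_β = ln score_alt(β) − ln score_base(β)

from the cached values — no re-simulation inside the loop, which is what
makes 100,000 replicates cheap.  Resampling is *paired*: one slide
multiset per replicate feeds both scores.  The p-value is the fraction of
replicates with DSS ≥ 0 (alternate at least as good); equality is
rejected at level α when the one-sided (1 − α) upper confidence bound of
DSS lies below 0 — the two statements agree by construction, and the tail
convention is recorded because only the CI rule, not the tail, is
standard.  Bonferroni adjustment multiplies each p-value by the number of
tests, capped at 1.

## Spatial statistics

`C(r)` for a (reference, target) type pair: for each reference cell,
count target cells at center distance in `[r − δ/2, r + δ/2)` (δ default
3 μm; the annulus thickness has no canonical value, and symmetric binning
centers the estimate at r), divide by the annulus area *clipped to the
slide rectangle* (edge correction on by default; the clipped area is an
exact circle–rectangle intersection up to 256-gon approximation of the
circles, and interior annuli short-circuit to πδ(2r)), average over
reference cells, subtract the slide-wide target density, and divide by a
normalization constant — by convention the cohort-mean target count, so
curves are comparable across slides.  Same-type curves exclude each
reference cell from its own annulus.  The headline radius 10.5 μm is a
nearest-neighbor spacing: `C(10.5)` measures contact-range attraction.

Group comparisons (responder vs nonresponder means) default to Welch's
t-test, with an exact-style permutation test (|mean difference|, add-one
p-value) available; the original analysis does not name its test, so the
method label travels with every result.

## Fencing

A *fencing cluster* is a connected component of exhausted T cells —
lattice adjacency: same or neighboring chamber (Moore-8, matching the
simulator's contact rule); point-cloud adjacency: center distance ≤ 15 μm
(a nucleus-to-nucleus contact distance; configurable, with a radius-sweep
helper) — in which at least one member touches a melanoma cell under the
same adjacency.  The **fencing fraction** is the share of all exhausted T
cells in melanoma-touching clusters of ≥ 3 members; with no exhausted
cells the fraction is defined as 0 so the metric can be traced from
t = 0.  Components are computed by sparse-graph connected components and
are cross-checked against a brute-force union-find oracle in the tests.

The null keeps every position fixed and permutes type labels over a pool
of non-melanoma cells (simulation pool: the immune compartment; imaging
pool: all cells except melanoma).  All pool labels are shuffled, so TAM
and active-T positions may swap as well — the pool defines exchangeable
*positions*, and every permutation preserves all type counts exactly.

## Trajectory statistics

Ensemble moments use the population (divisor-N) convention throughout —
the autocorrelation definition is an explicit 1/N sum, and mixing sample
and population conventions would silently rescale it.  The transition
time τ* is the argmin of the ensemble mean (first minimum under ties,
endpoint hits flagged): the crossover from the early "mixing" stage
(trajectories crossing, autocorrelation with an early reference time
decaying fast) to the late "dispersed" stage where trajectories keep
their rank.  Argmin-of-mean is the one operationally crisp estimator of
that crossover; the estimator label is stored so alternatives can be
added.

Late-time growth is summarized by a Yule (linear pure birth) fit:
least-squares slope of `ln μ(t)` on a window — the Yule *mean* is exactly
exponential, whereas the mean of logs is biased for branching processes —
with `n₀` the fitted mean extrapolated to the window start.  Closed forms
used for comparison, derived from the branching property
`E[N(t) | N(t_i)] = N(t_i)·e^{λ(t−t_i)}`:

    E[N(t)] = n₀e^{λt}
    Var[N(t)] = n₀e^{λt}(e^{λt} − 1)
    Corr[N(t_i), N(t)] = e^{λ(t−t_i)/2} · √((e^{λt_i} − 1)/(e^{λt} − 1))

The correlation is independent of n₀ and tends to `√(1 − e^{−λt_i})` < 1
as t → ∞ — the slow late-time decay that distinguishes committed
exponential growth from the mixing stage.  The formula was verified
against pure-birth simulations before being frozen into the tests.

## Synthetic data: what it emulates, what it does not

Generators produce 1 × 1 mm slides (dimensions configurable) with exact
per-type counts and three spatial motifs: uniform (complete spatial
randomness), clustered (Thomas-like parent/offspring process;
out-of-bounds offspring are re-drawn, not clipped, to keep counts exact),
and segregated (axis-aligned bands — the one-parameter version of the
segregated tumor/immune compartments seen in patient cores).  Forward
labeling runs `n_sims` (default 20) simulations per slide and labels by
majority fold-change direction; it is a deliberately coarse, fast
stand-in for thresholding `f_i`.

Two preconfigured harnesses keep analysis-level tests within a CPU
budget; both scale the *slide*, never the model:

* `calibration_cohort_specs` — twelve 200 × 200 μm slides in four
  composition motifs chosen for identifiability of (bC, bM): T-poor/no-TAM
  slides progress unless bC is small (anchoring bC from below),
  T-rich/no-TAM slides regress unless bC is large (from above), and the
  TAM-bearing analogues anchor bM.  Densities match a 1 mm core; the full
  T = 333 h horizon is kept.
* `flip_experiment_slide` / `flip_experiment_params` — a 600 × 600 μm
  slide with melanoma and T-cell bands separated by a 300 μm gap, wider
  than the T-cell diffusion length `√(4Dt) ≈ 130 μm` at the chosen hop
  rate, under lysis-favoring rates (`l = 0.25`, `bC = bM = 0.03`,
  `r_hop_T = 0.6`).  Segregated, the tumor escapes; uniformly re-seeded,
  the same cells eliminate it.

What a green synthetic test establishes: the estimator recovers the rates
that generated the labels; randomizing positions flips the predicted
outcome through the stated spatial mechanism; simulated exhaustion
produces above-null fencing.  What it does not establish: that the
placeholder rates, the 4-type reduction, or the 2D lattice describe any
real patient cohort — synthetic slides have exact counts, stationary
phenotypes, no imaging segmentation error, and no inter-patient biology
beyond what the spec'd motifs encode.

## Numerical and degenerate-input conventions

* All-zero rates with a nonempty lattice is not an error: the trajectory
  is constant (total rate 0 terminates the loop).
* Zero initial melanoma makes the fold change undefined → error naming
  the slide.
* Zero ensemble variance makes the autocorrelation undefined → error
  (deterministic ensembles), as does a zero mean for the CV.
* Permutation group test on two identical groups returns exactly p = 1
  (add-one estimator).
* Fencing fraction with zero exhausted T cells is 0 by definition.
* Recording carries the pre-event state onto grid times strictly before
  an event; snapshots follow the same convention.
* Seeds: every public entry point takes an integer seed; per-simulation
  seeds derive from `numpy.random.SeedSequence(seed, spawn_key=...)`, and
  the kernel RNG is splitmix64 seeded with that value.

## Known limitations

* No vasculature, cytokine fields, pharmacodynamics of the checkpoint
  drugs, or 3D tissue structure; drug effect is implicit in the rates.
* Phenotypes are fixed at the model's four types; input cells with other
  labels are carried through I/O but dropped at rasterization (logged).
* The feedback's linear-in-L form and all default rate magnitudes are
  conventions, not measurements.
* The grid fit reports the full score surface but no uncertainty on
  (bC, bM); the bootstrap quantifies model-comparison uncertainty only.
* Lattice fencing treats all cells in one chamber as mutually adjacent;
  at cap 4 this slightly coarsens cluster geometry relative to
  point-cloud mode.
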