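# Methods

## Model and assumptions

The package models a plant cell suspension whose growth is co-limited by
a carbon source (sucrose, `S1`) and a nitrogen source (potassium
nitrate, `S2`) and inhibited by either substrate at high concentration.
The state is `(X, S1, S2, V)` — biomass in g DW L⁻¹, substrates in
g L⁻¹, broth volume in L — and time is measured in days. Modelling
assumptions: the two tracked substrates are the only limiting nutrients;
temperature, pH and dissolved oxygen play no role; sucrose is treated as
a single pool (no glucose/fructose hydrolysis sub-model); there is no
cell death or lysis term, so biomass is non-decreasing while both
substrates are present; feed adds medium but no cells.

Three growth kernels are available, differing in the limitation term per
substrate: Monod on both, Monod on sucrose with a sigmoid (Hill) term on
nitrate, and sigmoid on both. All three carry two Luong-type inhibition
factors. They have 11, 12 and 13 free parameters respectively (the
unused Hill exponents are inert by construction, which the sensitivity
module verifies: their finite-difference sensitivity is exactly zero).

### Form of the inhibition factor

The Luong-type factor is implemented as `1 − (S/S_m)^n`, clamped to
`[0, 1]` and exactly zero for `S ≥ S_m`. The other common printing of
the Luong bracket, `(1 − S/S_m)^n`, agrees at both endpoints (1 at
`S = 0`, 0 at `S = S_m`) but differs in between. The implemented form
was chosen because it is the one consistent with this culture's
published numbers: with the published Monod/sigmoid parameter values it
gives μ = 0.140 d⁻¹ in the optimized starting medium, matching the
observed log-phase rate (7 → 21.7 g DW L⁻¹ over roughly eight growing
days ⇒ ln(21.7/7)/8 ≈ 0.14 d⁻¹), and it reproduces the reported
fed-batch prediction to within ~6%, whereas the alternative form gives
0.204 d⁻¹ and overshoots the fed-batch prediction by ~14%. The clamp at
the ceiling keeps the vector field defined during fed-batch overshoot
excursions above `S_m`.

### Maintenance and depletion

Substrate uptake is `dS/dt = −(μ/Y + m_S)·X`: growth-coupled
consumption plus growth-independent maintenance. At depletion
(`S ≤ 0`) the consumption of that substrate, including maintenance, is
switched off and the concentration is clamped to zero after every
integrator step; without the guard, maintenance would drive
concentrations negative.

## Numerical integration

Classical fixed-step fourth-order Runge–Kutta with default step
`dt = 0.01` d (about 10⁻⁶ relative step-to-step error on these
trajectories — far below measurement noise; a run takes tens of
milliseconds). Fed-batch runs integrate the batch phase and the feeding
phase as separate segments with phase-constant flow, so no RK4 stage
ever samples the wrong side of the flow discontinuity and fourth-order
accuracy is preserved; the same mechanism lands exactly on requested
output times, so model predictions at measurement times are exact
samples, not interpolants (this supersedes interpolating a dense
trajectory, which a fixed output grid would otherwise require).
Non-finite derivatives abort integration with the offending time in the
error message.

## Parameter estimation

The objective is the weighted SSE `Σ ((c − ĉ)/W_j)²` over every
measured value (replicates enter as individual residuals, not means —
configurable). The per-species weight `W_j` defaults to the maximum
observed value of that species, which rescales residuals of quantities
living on very different scales (biomass ~20, nitrate ~2 g L⁻¹) to
comparable magnitude. Because the weights used in the original analysis
of this culture are not published, absolute SSE values are not
comparable across weighting conventions; the discrimination statistics
take SSE values as given inputs.

Minimization uses Rosenbrock's rotating-directions method: trial steps
along an orthonormal direction set, step expansion (×3) on success,
reversal-contraction (×−0.5) on failure, and Gram–Schmidt rotation of
the direction set onto the aggregate successful displacement once every
direction has seen at least one success and one failure. Box bounds are
enforced by projecting trial points onto the box (a pinned trial counts
as a failure); an objective returning NaN counts as a failed step.
Termination: all step lengths below 10⁻⁹ of the box width, or the
evaluation budget (default 4000 calls per start) is spent. The method is
derivative-free, which suits the simulate-then-compare objective. Fits
run from `n_restarts` Latin-hypercube start points inside the bounds
(seeded, default 20) plus any user-supplied starts; the best result
wins, and identical seeds give identical results.

Default estimation bounds are the published box for this culture (e.g.
μmax ∈ [0.1, 1] d⁻¹, K_S1 ∈ [10⁻³, 44.9] g L⁻¹, S_m1 ∈ [44.9, 200]
g L⁻¹, S_m2 ∈ [2, 20] g L⁻¹, exponents ∈ [10⁻³, 5]).

The window growth-rate estimator (`estimate_mu_series`) fits ln X
against t over every contiguous window of ≥ 4 points and returns the
slope of the highest-R² window (ties to the longer, then earlier,
window). Windows with no variation in ln X are excluded: after substrate
depletion the simulated plateau is exactly flat, and a flat segment is a
degenerate "perfect" linear fit with slope zero that would otherwise
shadow the exponential phase.

## Model discrimination

Residual variance is `SSE/(n − p)`. The variance-ratio test puts the
larger variance in the numerator (so F ≥ 1) with the numerator degrees
of freedom taken from the larger-variance model, and uses unrounded
variances. The nested-SSE test compares the SSE drop per extra parameter
against the larger model's residual variance on `(p2 − p1, n − p2)`
degrees of freedom. Critical values are upper-α F quantiles (α = 0.05
default). A separate plausibility screen rejects fits whose inhibition
ceilings deviate more than 30% (default) from the experimentally
observed complete-inhibition concentrations. Note the variance-ratio
test is conventionally applied here to non-nested fits of the same
data; the package reproduces the procedure without endorsing its
distributional assumptions.

## Sensitivity analysis

Absolute parameter sensitivity is the central difference
`(f(P+h) − f(P−h))/2h` with `h = rel_step·P` (default 1%); if `P − h`
would cross zero the difference becomes one-sided, and a parameter at
exactly zero requires an explicit absolute step. Relative sensitivity is
the elasticity `(P/f)·APS`, invariant to response units, and parameters
are ranked by |RPS|. The response is the simulated batch biomass
concentration at a reference time (default day 20, the end of the batch
horizon) from the optimized starting state; published sensitivity
rankings for this culture do not state the perturbation size, scheme or
evaluation time, so rankings are comparable only qualitatively (the
nitrate yield and the maximum growth rate dominate, which the table
reproduces).

## Fed-batch feed design

The design grid spans the studied control ranges — feed start day 5–15,
feed sucrose 45–400 g L⁻¹, feed nitrate 2–30 g L⁻¹, flow 0.014–1.44
L d⁻¹, initial volume 0.8–1.5 L — with default level counts
11×8×8×6×7 = 29,568 combinations (the published total; the
factorization per control is this package's choice since only ranges
and the total are reported, and every level count is configurable).
Harvest is fixed at day 17 by default. A strategy is infeasible if the
broth volume exceeds the reactor working-volume ceiling (default 2.4 L)
or either substrate reaches its inhibition ceiling anywhere on the
dense trajectory (not only at output times). Feasible strategies beating
the batch-baseline productivity are ranked by productivity
(final biomass concentration / harvest day), ties broken by earlier
harvest, then by smaller total feed mass. The module is fully
deterministic.

## Synthetic data

The generator emulates the study designs: batch cultures sampled every
24 h for 20 d in triplicate from the optimized medium (7 g DW L⁻¹
inoculum, 45.6/2.1 g L⁻¹ sucrose/nitrate), and inhibition flask series
at initial sucrose {45, 75, 105, 145} and nitrate {2, 4, 8, 12} g L⁻¹
sampled every 2 d. Measurement noise is multiplicative Gaussian with
CV 5% by default (the reported triplicate scatter of this culture is
roughly 4%; 5% is a conservative stand-in), truncated at zero.
Inhibition series report the growth rate estimated from the simulated
time course by the window fit — the same path flask data would take —
rather than the analytic μ. What the generator does **not** emulate:
lag phase (the model has none, so synthetic data show immediate
growth), sugar hydrolysis, autocorrelated instrument drift, or missing
samples. Recovery tests on these data therefore demonstrate the
correctness of the estimation machinery under the model, not
identifiability on real cultures.

## Problem sizes used by the test suite and acceptance script

Fitting inside tests and the recovery study uses integrator step 0.05 d
(trajectory error far below the 5% noise floor), 0–2 Latin-hypercube
restarts plus the generating parameters as a start, and 400–2500
objective evaluations per start; production fits default to dt 0.05,
20 restarts and 4000 evaluations. The design-module tests use reduced
grids (2 levels per control) at dt 0.05; the full 29,568-point grid is
enumerated, not simulated, where only its size matters.

## Known limitations

* No lag-phase or death term; early-time fits to cultures with a
  multi-day lag will bias μmax downward.
* Maintenance at near-zero substrate switches off discontinuously;
  trajectories are continuous but not smooth at depletion.
* Local, one-at-a-time sensitivity only; no global (Sobol/Morris)
  measures.
* The Rosenbrock optimizer is local; multi-start mitigates but does not
  guarantee escape from local minima of the 11–13 dimensional objective.
* Weakly identifiable parameters (maintenance coefficients, Hill
  exponents, ceilings far above the data range) recover poorly from
  noisy single-condition batch data — expected, and visible in the
  recovery report.
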