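# Methods

## The model

`multiddm` analyzes choice and reaction-time data from a reaction-time
heading-discrimination task in which evidence arrives through optic flow
(visual), inertial motion (vestibular), or both (combined), with the
visual motion coherence varied across interleaved trials.  The behavioral
model is a drift-diffusion process with time-varying drift: a particle
x(t) accumulates

    dx = mu(t) dt + dW,        x(0) = bias * theta,

with unit diffusion variance, and a decision is triggered when x reaches
one of two absorbing bounds at +/- theta (rightward = upper).  If the
2 s stimulus ends first, the choice is forced by the sign of the
accumulated evidence.  Reaction time is decision time plus a per-modality
non-decision time with a uniform +/-50 ms jitter.

Because the diffusion variance is normalized to one, all bounds are
*scaled* bounds (actual bound / diffusion SD) and stimulus reliability
lives in the drift:

- vestibular: mu(t) = k_vest * sin(h) * |a(t)|, with a(t) the
  peak-normalized acceleration profile.  The magnitude of the
  acceleration is used, re-signed by the heading, so the informative
  evidence keeps a constant sign over the trial; whether the original
  task's vestibular evidence is biphasic is not determinable from the
  behavioral data alone, and the rectified choice makes the three drift
  channels directly comparable.
- visual: mu(t) = k_vis(c) * sin(h) * v(t), with v(t) the peak-normalized
  velocity profile and k_vis(c) a free sensitivity per coherence c.
- combined: the root-sum-square combination
  mu(t) = sin(h) * sqrt(k_vis^2 v^2 + k_vest^2 a^2), the unit-variance
  reduction of reliability-weighted optimal cue combination.

The velocity profile is a Gaussian bell centred at mid-stimulus with
standard deviation duration/6, baseline-subtracted so it vanishes exactly
at stimulus onset and offset and peak-normalized.  This is a smooth
stand-in for the physical motion profile of such tasks; its exact shape
only enters through the time course of evidence reliability.

Bounds come in two variants.  The *free* variant gives every
modality-coherence cell its own scaled bound: 2C+1 parameters for C
coherence levels (7 for three, 13 for six).  The *parametric* variant
uses one bound per modality plus a linear coherence-to-standard-deviation
map sigma(c) = 1 - s*c (kept positive), so the scaled bound of a
visual/combined cell is theta_mod / sigma(c); the normalization sigma(0)=1
absorbs the overall scale into theta_mod.

The start-point bias is a single shared offset bias*theta in bound units
(start-point rather than drift bias; with interleaved conditions a
stimulus-independent preference is most naturally a start-point effect).
An optional lapse parameter (default 0, capped at 0.1) mixes in
stimulus-independent guesses at uniform RTs.

## First-passage solver

Choice/RT predictions are defective first-passage-time densities of the
Fokker-Planck equation, solved on the bound-normalized domain
x in (-1, 1):

    p_t = -(mu(t)/theta) p_x + (1 / (2 theta^2)) p_xx,   p(+/-1, t) = 0,

by Crank-Nicolson with central differences (numba-compiled, batched over
condition cells and headings).  Numerical choices:

- The delta initial condition is damped by a Rannacher start-up (the
  first two steps are taken as backward-Euler half-steps), which removes
  Crank-Nicolson's oscillatory transients.
- Absorbed probability per step is split between the two boundaries in
  proportion to the discrete boundary fluxes
  (D/dx^2 +/- a/2dx) * p_edge, which conserves total mass to machine
  precision by construction; tiny negative bin values from residual
  oscillation are clipped, keeping the mass defect far below the 1e-4
  contract.
- Surviving mass at the deadline is assigned to the forced-choice point
  masses by the sign partition of the surviving density (ties split
  evenly).
- theta = 0 short-circuits to an immediate decision with
  P(upper) = (1 + bias)/2 at t = 0.
- Default grids: 201 interior spatial points at 1 ms steps for reference
  solutions; fitting and optimization use 81-101 points at 5-10 ms,
  which stays within the closed-form oracle tolerances (choice
  probabilities within 0.005, mean decision times within 0.01 s of the
  constant-drift analytic results) while being ~50x cheaper.

The Monte-Carlo twin (`simulate_trials`) integrates the same SDE by
Euler-Maruyama with a Brownian-bridge correction for bound crossings
between grid points, so simulated statistics are unbiased against the
continuum solution even at 10 ms steps; solver and simulator agree within
binomial error at n = 10,000, which is the cross-oracle both are tested
against.

## Likelihood and fitting

The likelihood of a trial is the defective density of the chosen boundary
at decision time rt - t_nd, box-smoothed by the +/-50 ms non-decision
jitter; trials at the deadline use the forced-choice mass smeared over
the same window; the lapse mixture adds 0.5 * uniform.  Trials are
grouped by (cell, heading) so one batched solve serves all trials of a
group.

`fit_subject` maximizes the summed log-likelihood over sensitivities,
free bounds, non-decision times and bias with Powell's direction-set
method on transformed parameters (log for positive quantities, atanh for
the bias), from a method-of-moments start (non-decision time from
minimum RTs minus 100 ms; per-cell bounds and drifts from inverting the
constant-drift accuracy and mean-RT formulas) plus optional perturbed
restarts.  Powell replaced a simplex search during development: on
13-15 parameter problems the simplex reliably stalled far above the
optimum, while Powell reaches it from the same start.  Inside the
optimizer, per-trial densities are floored at 1e-12 so the objective
stays finite; `trial_loglik` itself reports -inf for impossible RTs.
The posterior-sampling stage of the original fitting recipe is not
reproduced: every downstream stage only consumes the maximum-likelihood
point.

Recovery on synthetic subjects (five seeds, 100 trials per cell and
heading): median relative error of bounds <= 10%, sensitivities <= 15%,
bias within 0.05, non-decision times within 30 ms — asserted by the test
suite at exactly these sizes.

## Reward rate and its maximization

For a bound setting theta over cells with design weights w,

    f(theta) = (sum w*p_correct - cost * sum w*mean_dt)
               / (sum w*mean_rt + iti),

with reward 1 per correct choice, a 6 s mean inter-trial interval, and an
optional evidence-accumulation cost (0.1-0.2 reward/s variants)
multiplied by mean decision time and subtracted from the numerator.
Cell summaries are marginalized over the design's headings (equal
weights); the empirical twin computes the same ratio directly from
trials, crediting heading-zero trials 0.5.

`optimize_bounds` runs projected gradient ascent in log-bound space:
central finite differences (step 1e-3), Barzilai-Borwein step sizes with
backtracking, bounds clipped to [1e-3, 8].  Free-variant gradients
exploit the structure of f: perturbing one cell's bound only changes
that cell's condition combos, so a full gradient costs about two
objective evaluations; the parametric variant chain-rules the cell-space
gradient through the (theta_mod, s) -> cell-bounds map.  A restart is
"converged" when the gradient norm falls below 1e-6 or the objective
gains less than 1e-9 per iteration (or 1e-8 over 20 iterations), capped
at 500 iterations; the default 50 random restarts are drawn log-uniform
in [theta_hat/5, 5*theta_hat] per coordinate, and the best endpoint
(never worse than the fitted bounds themselves) is returned.  Analyses in
the tests and the acceptance run use 2-3 restarts: on these surfaces the
ascent from the fitted bounds already reaches the best endpoint found by
any wider restart set, and the extra restarts only re-find it.

The 'unbiased' variants zero the choice bias before maximization while
the subject's own reward rate keeps the bias; the 'parametric' variant
restricts the maximization to the parametric bound map, initialized from
per-modality means of the free fitted bounds.

`bound_scaling_curve` evaluates f along the ray s*theta_opt, and
`project_to_bound_line` finds where the iso-reward contour through the
fitted bounds meets that ray by solving f(s*theta_opt) = f(theta_hat)
(Brent's method), on the branch chosen by the scalar projection of
theta_hat onto theta_opt; a plain vector-projection mode is provided as
the robustness check.

## Curvature diagnostics

`reward_rate_hessian` computes the Hessian of f at the fitted bounds by
central finite differences (step 1e-2 in bound units, symmetrized), with
a Richardson consistency check at half the step flagged above 10%
relative mismatch.  Eigenvalues are reported signed; analyses use their
magnitudes, and |eigenvector| loadings are exposed so eigenspace/bound
alignment can be inspected.  `curvature_distance_analysis` projects
theta_opt - theta_hat into the eigenspace and pairs each |curvature|
with its |projected distance| (dimensions with |lambda| < 1e-8 are
retained but tagged untestable).  `quadratic_loss_check` compares the
actual reward-rate loss rr_opt - rr_hat with the quadratic prediction
0.5 |Delta' H Delta|.

`simulate_learning` implements the gradient learning rule
theta_n = theta_{n-1} + alpha * grad f (central-difference gradient), and
a stochastic variant that perturbs one random bound per step (Gaussian,
sd alpha) and accepts iff f(new) > f(old) + eps with zero-mean Gaussian
eps.  On separable quadratics the deterministic rule follows the
closed-form geometric decay (1 - alpha*lambda_i)^n exactly, which is the
oracle the implementation is tested against.

## Synthetic subjects

The generator emulates the experiment's structure: interleaved
modality/coherence cells, signed headings, 2 s stimulus, 6 s mean ITI,
per-modality non-decision times, shared start-point bias,
coherence-dependent visual reliability.  Template defaults: coherences
{25, 37, 70}% (only the highest is constrained by the task description;
the others are plausible and configurable), headings +/-{1,2,4,8,16}
degrees, k_vest = 8/s, k_vis = 25c/s (so visual reliability crosses the
vestibular one between 25% and 70% coherence), scaled bounds 1.1-1.5,
non-decision times 300-350 ms, bias 0.03.  These produce accuracies of
~65-90% at 8 degrees and mean RTs of 1.3-1.5 s — the operating range of
such tasks.  Cohorts perturb sensitivities and bounds log-normally
(sd 0.15 by default) and the bias additively.

*Truncated learners* replace a subject's bounds with the endpoint of a
prematurely stopped gradient ascent on that subject's own reward-rate
surface: start at 0.1*theta_opt, step size alpha = 0.3/|lambda|_max
(from the Hessian at the optimum), 10 steps.  These defaults were chosen
so that the learner embodies the incomplete-learning construction the
generator exists to provide: steep eigendirections close most of their
gap within the run while shallow ones barely move, leaving the subject
distinctly below optimum (relative reward rate ~0.93) with a strongly
negative curvature-distance rank correlation.  A larger step
(0.5/|lambda|_max) lets every direction converge and destroys the
signature; stopping after only a few steps leaves the subject too far
from the optimum for the quadratic analysis to apply.  Because
reward-rate surfaces have a locally attractive zero-bound basin for
weakly informative cells, the shallow (low-coherence visual) bounds of a
default learner typically end near zero — the subject effectively
ignores the visual cue in those cells, mirroring extreme speed-accuracy
settings rather than moderate mistuning.

What the generator does *not* emulate: staircase history and feedback
effects from training, across-session drift, non-stationary ITIs,
RT-dependent lapses, and any within-condition bound variability.  Tests
passing on this generator therefore certify the pipeline's correctness
and the internal consistency of the incomplete-learning analysis — not
that human subjects behave this way.

## Problem sizes

The test suite and the acceptance script run the pipeline at reduced but
statistically meaningful sizes, chosen so every stage is exercised end to
end: one or three coherence levels, headings +/-{2,8,16} degrees, 25-200
trials per cell and heading, 10 ms solver steps with 81 spatial points
for fitting/optimization, 1-3 ascent restarts, and cohorts of 2-10
subjects.  Reference-resolution solves (1 ms, 201 points) back the
oracle comparisons.

## Known limitations

- The parametric variant is optimized (as a restriction of the optimum)
  but not fitted directly; a parametric ML fit would need its own
  parameter map.
- The Wilcoxon test is exact only up to n = 25 pairs (enumeration via
  the rank-sum generating function); larger cohorts are out of scope.
- Reward-rate surfaces can have a locally attractive theta = 0 basin for
  weakly informative cells; gradient ascent (whether inside
  `optimize_bounds` or a simulated learner) can be captured there, which
  is why the maximization uses many random restarts.
- A near-zero bound produces chance-level choices at non-decision-time
  RTs, from which that cell's sensitivity cannot be recovered; the
  fitted surface then places that cell's optimal bound near zero as
  well.  Curvature-versus-distance analyses on *fitted* parameters are
  therefore unstable at desk-scale trial counts for default truncated
  learners, and the acceptance pipeline reports both the truth-based
  and fitted-based versions of that statistic.
- Heading-zero trials are credited 0.5 by convention everywhere;
  designs dominated by zero-heading trials would make reward rates
  insensitive to behavior.
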