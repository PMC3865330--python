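# Methods

This note records the modelling assumptions, parameter conventions and
numerical choices behind `expertsde`, and what its validation suite does
and does not establish.

## Evidence accumulators (`expertsde.sde_core`)

The core object is the linear-drift SDE

    dx = (mu + lambda * x) dt + sigma dW,

in dimensionless model units (time arbitrary, evidence arbitrary; `sigma`
has units evidence per square-root time).  `lambda = 0` gives the
constant-drift drift-diffusion model; `lambda < 0` a mean-reverting
Ornstein-Uhlenbeck process with stationary law
`N(-mu/lambda, sigma^2 / (2 |lambda|))`.  The drift may be book-kept as a
signed sum of labelled components (`DriftComponents`); composition uses
exact floating summation so it is invariant to reordering.

**Integration.** Fixed-step Euler-Maruyama with default `dt = 1e-3`.
For constant drift the Gaussian increments are exact in distribution, so
the only discretization artefact is *boundary monitoring*: by default a
crossing is declared when the state at a step endpoint lies at or beyond
a boundary.  Endpoint monitoring misses interior excursions and
therefore behaves like a boundary pushed outward by approximately
`0.5826 * sigma * sqrt(dt)`; at `dt = 1e-3` this shifts binary crossing
probabilities by a few parts in a thousand.  Two consequences shaped the
design:

- `detect="bridge"` supplements endpoint detection with the
  Brownian-bridge interior-crossing probability
  `exp(-2 d0 d1 / (sigma^2 dt))` per step and boundary.  For constant
  drift this makes simulated crossing statistics exact up to the
  (exponentially negligible) chance of reaching both boundaries within
  one step.  Quantitative comparisons against the closed-form crossing
  law use this mode, so their error budget is purely binomial.
- `coupled_refinement_fractions` simulates one set of paths at a fine
  step and monitors crossings at `dt`, `dt/2`, `dt/4` simultaneously.
  Sharing paths across levels isolates the monitoring bias from
  Monte-Carlo noise, which is what makes the observed gap-shrinkage as
  `dt` halves a stable, monotone measurement.

**First-passage semantics.** Boundaries are absorbing; the state is not
clipped, so the recorded crossing value may overshoot.  A finite horizon
is always required and exhausting it yields a *censored* result rather
than an exception — zero-drift processes have heavy-tailed passage
times, so censoring is an expected outcome, and all empirical choice
fractions are computed over decided trials with the censored count
reported.

**Races.** Independent accumulators advance in lockstep; the winner is
the first to reach its own upper boundary.  A racer that falls through
its lower boundary is eliminated and cannot win (categorization races
sidestep this by using `lower = -inf`: recognition is reaching the
threshold, never rejection).  If two racers cross in the same step the
larger overshoot relative to its boundary magnitude wins; exact ties go
to the lowest index — a deterministic rule that only distinguishes
exactly tied cases.

**Randomness.** Every simulator takes one master seed.  Substreams come
from `numpy.random.SeedSequence(seed, spawn_key=...)`, keyed by
accumulator (or node) index, so appending an accumulator never perturbs
the draws of existing ones, and identical `(spec, dt, horizon, seed)`
yield bit-identical output.

## Expert categorization (`expertsde.categorization`)

Six nonnegative rates describe the cell groups feeding one category
neuron: its exclusive excitors, the two shared groups that also act on
the rival category, and the three inhibitory counterparts.  The net
drift is the excitatory sum minus the inhibitory sum; swapping the two
triples negates it exactly.

All `k` categories share one symmetric threshold `z > 0` and one noise
scale `sigma > 0`; the recognition law is the softmax of
`beta * mu*` with `beta = 2 z / sigma^2`, computed with max-subtraction
(shift-invariant to 1e-12, exactly normalized, stable to `k = 10^4` with
logits spanning ±50).  Shifted logits below −700 are clamped with a
`RuntimeWarning`; they are indistinguishable from −inf in double
precision anyway.

The softmax is exact for `k = 2` in the *difference-process* sense: two
racers with common `sigma` reduce to one accumulator between ±z.  An
independent race with per-racer upper boundaries is a different process,
and the measured gaps are a property of the model worth knowing:

- `k = 2`, drifts (0.5, 0), `z = sigma = 1`: race frequency ≈ 0.66 vs
  softmax 0.731 (gap ≈ 0.07);
- `k = 4`, drifts (1.0, 0.8, 0.5, 0.2): top-category gap ≈ 0.10.

Tests therefore bound the binary race/softmax gap at 0.1 and require
order agreement, rather than asserting an identity the model does not
have; the acceptance script reports both gaps.  Per-category thresholds
and noise are accepted in simulation mode only.

## Strategic theory of mind (`expertsde.strategic_tom`)

A validated `GameTree` has parentless base moves owned by the root
player, strictly alternating players, one parent per node, an edge
weight on every edge and a value on every leaf, and at least one
opponent ply under every base move.  Weights and leaf values are
unconstrained reals — a continuation can be disadvantageous.

**Dynamics.** Every non-leaf node carries an activity
`dX_i = (sum_j w_ij a_j + lambda X_i) dt + sigma_i dW_i`, where `a_j` is
a child's current activity or its fixed leaf payoff.  `lambda <= 0`
(default 0) is an optional self-decay; the system is linear-drift, which
is what guarantees softmax-form stationary choice behaviour.  The drift
is advanced with an explicit trapezoidal (Heun) stage — with additive
noise this keeps strong order 1 and integrates the noise-free two-ply
cascade *exactly*, so the polynomial closed form (reply activities
`~ t`, base-move activities `~ t^2`) is reproduced to machine precision
rather than to O(dt).  Decisions commit when a base move's |activity|
reaches the threshold at a step endpoint; overshoot then lowest index
break ties.

**Choice distributions.** Backward propagation: at the deepest level a
move's valuation is `f_i = sum(edge weight × leaf value)`; one level up,
`f_i = sum over children of (weight × child probability × child f)`,
with sibling probabilities from the softmax at the child player's
`beta`.  Mixed leaf/internal children are allowed: leaves enter at
probability 1, internal siblings share a softmax.  `beta`, noise, and
the decision threshold are free per-player parameters with no canonical
values; defaults (`beta = 2`, `sigma = 1`) sit in the regime where
choice probabilities are informative but unsaturated.  The relation
between the ToM-level `beta` and `(threshold, sigma)` is deliberately
left free: threshold-decision frequencies and softmax probabilities are
compared empirically (they agree on symmetric scenarios by
exchangeability; elsewhere the gap is measured, not assumed zero).

**Equilibrium.** For a plain tree the backward map does not depend on
its own output, so `solve_equilibrium` returns the backward-induction
answer in one iteration with residual 0.  Genuine mutual dependence is
introduced by an optional coupling that makes leaf payoffs affine in the
root player's own move probabilities (`{leaf: {const, base_move:
coef}}`).  The solver then runs damped fixed-point iteration (damping
0.5, tolerance 1e-10, max 10^4 iterations) from the uniform start,
verifies the direct-substitution residual, and re-solves from 5 random
Dirichlet starts; disagreement beyond 10× tolerance clears the
uniqueness flag.  Non-convergence raises with the last residual
attached.  Small `beta` keeps the map contractive; no global uniqueness
is claimed for large `beta`.

## Scenario generation (`expertsde.fixtures`)

`chess_scenario_tree()` encodes the canonical chess scenario: Black weighs
Knight-to-f6 against pawn-to-d6; White answers with {Ng5, Nc3} or
{c3, h3}; below every White reply Black's continuations are the same two
moves (d5, Bc5), though each carries its own edge weight because their
appeal differs by line.  All weights and values default to 1 (the
symmetric case); overrides break the symmetry.  `random_scenario` draws
seed-deterministic instances of any family, sampling uniformly from
ranges whose defaults keep `beta * drift` within roughly ±10 so softmax
outputs do not saturate in generated scenarios.

## What the validation shows — and does not

The test suite checks the framework against independent mathematics:
the logistic crossing law (binomial 3-SE at n = 10^5 per parameter set,
unbiased bridge detection), monotone shrinkage of the endpoint
monitoring bias under coupled dt-refinement, O-U stationary moments over
effective sample sizes of ~140 independent correlation times, exact
deterministic limits, softmax algebra to 1e-12, hand-computed backward
induction on the two-ply scenario, fixed-point residuals by direct
substitution, and byte-level reproducibility.  Monte-Carlo problem sizes
(10^5 first-passage trials, 2×10^4 race trials, 2–4×10^3 threshold
decisions) were chosen so statistical error, not runtime, dominates each
comparison.

All of this validates internal consistency on synthetic inputs.  The
generators emulate the *structure* of the models — not real neural
recordings, eye movements, or behavioural data; rates, weights and
payoffs have no calibrated physical scale.  Passing tests therefore show
the implementation realizes the stated mathematics, not that the
mathematics describes any particular organism or player.  Known
limitations: no exact (non-discretized) first-passage densities, no
time-varying boundaries, no analytic multi-alternative corrections
beyond the softmax law, no learning of templates or weights from data,
and no chess legality.
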