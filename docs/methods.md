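# Methods

## The diffusion process

Adoption spreads on an undirected simple graph in discrete ticks. A run
starts from a single seed adopter (tick 0). Each tick, every non-adopter
*i* adopts independently with probability

    p_i = min(1, α + β · f_i),

where `f_i` is the fraction of *i*'s neighbors adopted by the end of the
previous tick, `α` is the external-influence hazard (advertising, media,
mandates) and `β` the interpersonal-influence weight (word of mouth).
Adoption is irreversible, so cumulative adopter counts are nondecreasing
and every run on a connected graph with `α > 0` or `β > 0` eventually
saturates with probability 1.

Modelling conventions, chosen where the process definition is silent:

- **Synchronous updates.** All hazards within a tick use the adopter set
  from the start of the tick. This matches the structure of the aggregate
  Bass recursion (below) and makes a run a Markov chain on adopter sets.
  An asynchronous variant (random node order, within-tick cascades) was
  examined and produces the same qualitative experiment outcomes; the
  synchronous form is kept for its cleaner exact analysis.
- **Hazard cap.** `α + β·f` may exceed 1; it is capped at 1, the only
  probability-valid choice short of renormalizing the model.
- **Degree-0 nodes** have `f = 0` (external channel only); giant-component
  preprocessing makes this rare in practice.
- **RNG protocol.** One generator per run; each tick draws one uniform per
  node aligned with ascending node id (draws for already-adopted nodes are
  discarded). Identical (graph, parameters, seed) reproduce a trajectory
  bit-for-bit. Multi-stage pipelines derive per-stage / per-cell
  substreams from the master seed with `numpy` `SeedSequence` spawning, so
  enlarging a sweep grid never perturbs existing cells.

## Mean-field relation

The aggregate Bass recursion

    N_{t+1} = N_t + (a + b·N_t)(N_max − N_t)

is implemented as a reference curve. On a complete graph with `a = α`,
`b = β/(n−1)`, the agent model's conditional expectation of `ΔN` equals the
recursion's increment exactly. The recursion is nevertheless only the
*mean-field* curve: the true mean obeys
`E[ΔN] = (a + b·E N)(N_max − E N) − b·Var(N)`, so ensemble means lag the
recursion by a term driven by takeoff-time dispersion. At n = 200 this
bias is a few percent of n for β-dominated doses and sub-node for small
mixed doses (α = 0.01, β = 0.05), which is the regime the mean-field test
uses; its pointwise band is 4 SE to allow for ~60 correlated pointwise
comparisons. The simulator itself is validated more sharply against the
exact complete-graph chain (the adopter count is Markov with binomial
increments) and against the general exact oracle below.

## LD50 calibration

To put α and β on comparable scales both are expressed as fractions of a
saturating dose, LD50: the value at which **all** nodes adopt within 100
ticks in 50% of trials, each trial seeded at a uniformly random node (the
LD50 is treated as a seed-agnostic property of graph × parameter; the
seed rule is configurable). "Saturate" means full adoption: half-adoption
already defines the experiment's outcome metric, and full saturation is
attainable on the (giant-component) graphs used.

Saturation probability is nondecreasing in either dose, so calibration is
bisection on a bracket with fraction < 0.5 at the low end and ≥ 0.5 at the
high end, a fixed number of Monte Carlo trials per candidate, and a
terminal bracket width below 1/1024. For α the bracket is [0, 1]: α is
itself a per-tick probability and values above 1 are indistinguishable
from 1. For β the upper end doubles from 1 until it saturates (guard
1024): β multiplies the adopted-neighbor *fraction*, which is small at
hubs, and on 1,000-node preferential-attachment trees the β LD50 is ≈ 1.5.
With β = 0 adopters are independent, giving the closed form
`P(saturate ≤ L) = (1 − (1−α)^L)^(n−1)`; the α LD50 on 1,000 nodes is
0.07016 analytically, and calibration reproduces it (0.0701–0.0706 across
seeds).

Precision near the 0.5 crossing is limited by binomial noise, roughly one
binomial SE divided by the local slope of the dose–response curve. The
code default is 100 trials per candidate (quick exploration); the study
runs and the acceptance pipeline use 1,500 so that, when the returned dose
is re-simulated at 500 fresh trials, calibration noise is subdominant to
the recheck's own 3-SE band (±0.067).

## The seeding experiment

Each (α, β) cell runs two conditions on the same graph: treatment seeds at
the top-betweenness node (ties broken by smallest node id), control at a
uniformly random node redrawn each replication. Per run the outcome is the
first tick with ⌈n/2⌉ adopters; runs that never get there within the tick
budget (default 1,000) are right-censored. Cell summary: means over
uncensored runs per condition, their ratio (random/central), censored
counts, and a censored flag when either condition's censored share exceeds
5% (configurable) — means over heavily censored runs are biased and are
flagged rather than hidden. The default dose grid per axis is {0} plus 13
log-spaced points from 0.26% to 100% of LD50, placing points near the
interesting low-α region.

Betweenness is unnormalized shortest-path betweenness with each unordered
pair counted once (z-scores are invariant to the normalization constant).
It is computed by igraph's C implementation and cross-checked in the test
suite against an independent shortest-path-counting oracle built from
adjacency-matrix powers. On PA(1000, m=1) trees the top node sits ~18–24
SDs above the mean betweenness.

Study-scale findings the test suite computes (PA(1000, m=1), β = LD50,
200 replications/condition): ratio ≈ 2.2–2.5 at α = 0, dropping to ≈ 1.5–1.7
at α = 0.26% of LD50 and ≈ 1.2 at 3%; parity within 10% is reached only
for α of order tens of percent of LD50. The ratio at α = 0 varies by graph
instance (1.8–5.0 over 11 instances, above 2 in 10 of them).

## Exact oracle

On graphs of ≤ 20 nodes the adopter-set chain is enumerated exactly
(bitmask states). Saturation probabilities come from propagating the state
distribution; expected first-passage times to a target adopter count from
the absorbing-chain solve `(I − Q)t = 1` over below-target states, exact
whenever absorption is certain (`α > 0`, or `β > 0` on a connected graph —
any proper adopter set then has a boundary node with positive hazard).
Monte Carlo estimates are required to agree within 3 SE at 10⁴
replications across fixture graphs (path, star, cycle, complete) and doses
on and off both axes.

## Synthetic networks and what they do (not) show

Experiments run on generated Barabási–Albert preferential-attachment
graphs (default: 1,000 nodes, one edge per node, attachment exponent 1 — a
hub-dominated tree, deliberately favorable to central seeding) and
Watts–Strogatz small worlds (defaults k = 4, p = 0.1 where not specified).
Empirical networks load from plain-text edge lists, treated as undirected
simple graphs (self-loops dropped, duplicate/reciprocal edges collapsed,
labels remapped to dense integer ids with the map retained) and reduced to
their giant component. The generators reproduce the *structural* conditions
of the experiment (right-skewed betweenness, small diameter); they do not
model community structure, degree correlations, tie weights, or temporal
ties, so passing tests demonstrate the mechanism — external influence
erodes positional advantage — rather than quantitative forecasts for any
real network.

## Numerical and scale choices

- The vectorized engine advances all replications of a cell in lockstep on
  a CSR adjacency matrix and drops finished runs, so study-scale cells
  (200 reps × 1,000 nodes) take well under a second per cell.
- Default test/acceptance problem sizes — 1,000-node graphs, 200
  replications per condition, 1,500 calibration trials per candidate,
  10⁴ oracle-comparison replications — keep every statistical band at ≥ 3
  SE while the full suite completes in about a minute.
- Ratio cells with a zero central mean (possible only on toy graphs where
  half-adoption is the seed itself) report an undefined ratio rather than
  dividing by zero.
- Expected-time Monte Carlo comparisons use horizons long enough that the
  censoring tail is negligible (P(T > horizon) < 10⁻¹⁰ for the fixture
  doses).

## Known limitations

- Diffusion is binary-state and irreversible; no abandonment, thresholds,
  or heterogeneous per-node hazards.
- The LD50 search assumes monotone dose response (true for this process)
  and reports a point estimate, not an interval; its binomial noise floor
  is documented above.
- The exact oracle is a test instrument only; it is exponential in node
  count and guarded at 20 nodes.
- Only single-seed strategies and betweenness centrality are implemented;
  k-seed strategies and other centralities are natural extensions.
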