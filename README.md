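# bassnet

Agent-based **Bass mixed-influence diffusion** on networks, with a
calibration and experiment pipeline for one question: *how much does
seeding an innovation at the most central node actually speed its spread,
and does that advantage survive external influence such as advertising?*

Marketers and public-health planners are often advised to recruit
"opinion leaders" — structurally central people — to launch a product or
behavior. That advice comes from diffusion models in which information
moves only along network ties. Real adopters also hear about innovations
from mass media, advertising, search, and mandates. `bassnet` implements
the agent-based Bass model that mixes both channels, and measures the
central-seed advantage as a function of how strong the external channel is.

## Model

On an undirected simple graph, each non-adopter *i* adopts at tick *t*
(independently, irreversibly) with probability

```
P(i adopts at t | not yet adopted) = min(1, α + β · f_i(t))
```

where `f_i(t)` is the fraction of *i*'s neighbors that had adopted before
tick *t*, `α ≥ 0` is the constant external-influence hazard, and `β ≥ 0`
weights interpersonal influence. Updates are synchronous. On a complete
graph with *n* nodes this reduces, in expectation, to the aggregate Bass
recursion `ΔN_t = (a + b·N_t)(N_max − N_t)` with `a = α`, `b = β/(n−1)`.

Because α and β live on different scales, experiments express both as
fractions of their **LD50** — the dose at which the network fully adopts
within 100 ticks in 50% of trials (a toxicology metaphor). LD50s are
estimated by bisection driven by Monte Carlo saturation fractions; on
hub-dominated graphs the β LD50 typically exceeds 1, since the hazard is β
times the adopted-neighbor *fraction*.

The seeding experiment compares two conditions per (α, β) cell: seed at
the **top-betweenness node** vs. a **uniformly random node** (redrawn
every replication), and reports the ratio of mean times to 50% adoption
(random / central). Runs that never reach half-adoption are right-censored
and cells with too many censored runs are flagged.

An exact finite-Markov-chain oracle (adopter sets as states) validates the
Monte Carlo simulator on small graphs.

## Worked example

```
$ bassnet demo --seed 1 --reps 200
network: preferential attachment, 1000 nodes, 999 edges
LD50_alpha = 0.0700684 (saturation fraction 0.506)
LD50_beta = 1.50757 (saturation fraction 0.486)

ratio of mean time to half-adoption, random seed / central seed (beta = LD50):
  alpha =   0.00% of LD50: ratio = 2.542  <- central seed over twice as fast
  alpha =   0.26% of LD50: ratio = 1.671
  alpha =   3.00% of LD50: ratio = 1.207
  alpha =  10.00% of LD50: ratio = 1.120
  alpha = 100.00% of LD50: ratio = 1.005  <- advantage gone
```

Reading: on a 1,000-node preferential-attachment tree with interpersonal
influence at its saturating dose and **no** external influence, the
central seed reaches half the network ~2.5× faster than a random seed.
The advantage drops steeply at the first positive external dose (0.26% of
the α LD50) and decays toward parity as α grows — by the full LD50 the
seed's position is irrelevant.

The same pipeline is scriptable:

```python
import bassnet as bn

g = bn.generate_preferential_attachment(1000, 1, 1.0, rng_seed=1)
ld50_b = bn.estimate_ld50(g, "beta", n_trials=500, rng_seed=2)
cell = bn.run_cell(g, alpha=0.0, beta=ld50_b.value, n_reps=100, rng_seed=3)
print(cell.ratio)        # ~2.3: central seed more than twice as fast
```

Config-driven runs (`bassnet calibrate|sweep|gen-network --config cfg.yaml`)
write CSV tables plus a manifest that fully determines every output.

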