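# Methods

## Model and assumptions

The game couples a deterministic renewable-resource model to stochastic
agent decision-making. The stock follows discrete-time logistic growth
minus a Cobb–Douglas harvest; all randomness in a simulation comes from
the agents' exploration, never from the environment. The Cobb–Douglas
form treats the stock as capital and effort as labour: with effort
elasticity `α = 0.35`, harvests depend more on the stock than on effort,
so returns on extra effort diminish quickly. Harvest is never negative,
and a zero stock or zero effort yields a zero harvest regardless of
exponent edge cases.

Stock updates are clamped to `[0, N_max]`. The model itself does not say
what a negative stock would mean, and physically there is none, so the
clamp is the only sensible completion; `N = 0` is then absorbing, because
both growth and harvest vanish there. Round diagnostics (growth, harvest,
net growth) are reported *unclamped* so that reward signals and analysis
see the true net change even in the round in which the clamp fires.

Payoffs are proportional to effort share, `π_i = (x_i/X)H − c·x_i`, and
sum exactly to the total `Π = H − cX`. Assets accumulate payoffs with no
floor: agents may go arbitrarily negative, and no one exits the game.

## Analytical quantities

The sustainable and profitable effort bounds are closed forms obtained by
inverting `G − H ≥ 0` and `H − cX ≥ 0`; the profitable bound is exactly
linear in the stock. The MSY maximization over `[X_min, X_max]` is
implemented as written even though its argmax is trivially `X_min`
(harvest rises strictly with effort); the informative object is the
bound. The MEY interior optimum `X* = (αβ/c)^(1/(1−α))·N` is clipped to
the feasible interval; grid search is used only as a test oracle.

Equilibria: the two sustainability equilibria are the roots of
`sustainable_bound(N) = X_min`, found by bisection (`brentq`, absolute
tolerance 1e−6) after a coarse bracketing scan; the profitability
equilibrium has the closed form `X_min·(c/β)^(1/(1−α))` with the numeric
root kept as a cross-check in tests. The optimal equilibrium maximizes
the length of the viable effort interval over a dense stock scan (default
step 0.5 stock units; first maximum wins on ties). The interval is
measured on the continuous effort axis, not on any agent's discrete
action grid, since the analysis is independent of group size.

The viable-region share is computed by dense grid classification over the
full feasible rectangle `[X_min, X_max] × [0, N_max]` (default 2001²
points; stable well under 0.1 percentage point against refinement, which
the acceptance script verifies by doubling the grid until converged). The
reference area is a normalization choice — the reported ~6.1% counts the
whole rectangle, including stock levels below any operating point a
harvester would accept; both the resolution and the rectangle are
config-exposed so alternative normalizations can be computed.

## Learning agents

Each agent is a tabular Q-learner. The learned state is the stock level
alone, discretized into equal-width bins (default 10) — own effort,
cumulative effort and payoff enter through the reward, not the state,
which keeps the table small and the process Markov from the individual's
viewpoint. Actions are a per-agent effort grid spanning
`[X_min/n, X_max/n]` (default 10 levels), so symmetric play spans exactly
the group effort bounds for any group size. Agents observe only
`(N, X, x_i, π_i, Π)`; the `Observation` container exposes exactly those
fields and nothing else, and never other agents' actions or payoffs.

Rewards are pure trends: `λ = sign(net growth)` (computed from the
unclamped net growth of the round in which the action was taken),
`ξ = sign(π_i)`, blended as `R = w·ξ + (1−w)·λ`. Magnitudes are
deliberately discarded — the two raw quantities live on incomparable
scales (stock units vs currency per agent), and sign-only signals need no
normalization. `w` here weighs the *profit* trend; a `weight_on`
switch flips the convention for studies that define the weight on the
sustainability side. At `w = 0.5` (the default and the baseline used in
the regime tests) the two conventions coincide.

### Hyperparameters (defaults and why)

| parameter | default | rationale |
|---|---|---|
| learning rate η | 0.1 | conventional tabular setting; ~dozens of visits to settle a value |
| discount γ | 0.9 | values ~10 rounds of lookahead, enough to link restraint to future reward |
| ε schedule | 0.1 → ×0.999/round → floor 0.01 | persistent but modest exploration; ~0.01 after 2,000 rounds |
| Q init | 5.0 | optimistic: above the best reachable discounted return (≈ 1/(1−γ) scaled by achievable rewards), so untried actions get probed systematically |
| tie-break | smallest effort | see below; `"random"` available |
| state bins × actions | 10 × 10 | coarse enough to be visited often at the simulated scales |

**Restraint-first exploration is structural, not cosmetic.** The largest
sustainable cumulative effort over all stock levels is ≈208, while
uniformly random play by 10 agents has expected cumulative effort 300.
A population that explores uniformly from the start therefore drives the
stock monotonically to the absorbing depleted state in a few dozen
rounds — before any action values have been learned — in every replicate.
Optimistic initialization with smallest-effort tie-breaking starts the
population at minimum effort and probes larger efforts gradually as
optimism erodes, which reproduces the characteristic
decline-then-stabilize learning phase. The smallest-effort rule also
matches the tie convention of the analytical best-response operation.

## Simulation engine

Per round: agents observe the binned stock, select efforts ε-greedily,
payoffs are computed at the observed (pre-update) stock, the stock is
stepped, trend rewards are computed, Q tables are updated with the new
stock's bin as successor state, and payoffs are credited to assets.
Replicate `r` draws its generator tree from `base_seed + r`, with one
independent child stream per agent, so runs are bit-reproducible and
adding agents does not perturb existing agents' draws.

Defaults mirror the reference experiment scale: 5,000 rounds, 50
replicates, initial assets 1,000 per agent, stock starting at carrying
capacity (a pristine resource), group sizes 1–15 for the size sweep, and
cost/weight grids over {0.1, …, 0.9} at step 0.1. The "after learning"
summary window is the final 1,000 rounds (config-exposed; the learning
phase has no sharp endpoint, this is a reporting choice). The test suite
and the regime checks run scaled-down conditions — typically 1,200–2,000
rounds and 4–10 replicates with the window shortened proportionally —
which are past the settling point of these learners at the default
hyperparameters.

## What the regime checks show (and don't)

At the reference cost and balanced weighting, learned populations of up
to ~10 agents settle the stock inside the viable band `[E_prof, E2]` with
growing assets. At `c = 0.2` the profit trend loses its discriminating
power (almost everything is profitable), excursions below the band go
unpunished on the wealth signal, and the settled stock is measurably
lower. At `c = 0.8` the population suffers deep losses. These are
*regime* statements over replicate medians; exact trajectories depend on
the (unreported in any reference) RL hyperparameters and are not a
reproduction target.

Known limitations:

- At `c = 0.8` our learners typically also collapse the stock, rather
  than holding it high while losing money. In this reward structure
  "sustain and lose" is not a stable symmetric outcome — a settled
  population at minimum effort with a high stock would in fact profit —
  so widespread unprofitability instead destabilizes learned restraint.
- The weight extremes are asymmetric in an instructive way: a pure
  sustainability reward (`R = λ`) is a purely collective signal that
  cannot differentiate an agent's own actions, so learning fails and the
  stock collapses, whereas a pure profit reward still sustains at
  moderate cost because depletion destroys profit and the trend signal
  registers it. Interpretations of weight sweeps should fix the
  convention (`weight_on`) first.
- Larger groups dilute individual influence on the collective signals
  (the self-efficacy problem); beyond ~15 agents learning degrades and is
  not a supported regime.
- The environment is deterministic by design; all stochasticity is in
  action selection. Real common-pool systems add environmental noise,
  heterogeneous agents, entry/exit and institutional responses, none of
  which are modelled, so passing regime checks here says nothing about
  robustness to those forces.
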