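# Methods

## The model

Two agents play a 10-round trust exchange. Each round the investor
receives 20 monetary units and invests a fraction
a_I ∈ {0, 1/4, 1/2, 3/4, 1}; the investment is trebled; the trustee
returns a fraction a_T ∈ {0, 1/6, 1/3, 1/2, 2/3} of the trebled amount
(a forced no-op if nothing was invested). Monetary payoffs per round
are

    chi_I = 20 − 20 a_I + 60 a_I a_T,      chi_T = 60 a_I − 60 a_I a_T,

so chi_I + chi_T = 20 + 40 a_I (money conservation). Agents value
outcomes through Fehr–Schmidt inequality aversion,

    r = chi_self − alpha · max(chi_self − chi_other, 0),

with the "guilt" parameter alpha on the grid {0, 0.4, 1} ("greedy",
"pragmatic", "guilty"). Guilt is constant within a game and is the
only latent quantity inferred online: each agent carries a Dirichlet
belief over the partner's guilt type, starting from pseudo-counts
(1, 1, 1), updated after every observed partner action by adding the
raw probability of that action under each guilt-typed partner model (a
soft-count approximation to the exact Bayes filter). Degenerate rounds
add uniform mass and carry no information.

Planning is bounded by a survival function: an agent with planning
horizon P ∈ {0, 2, 7} at round t accumulates (undiscounted, gamma = 1)
rewards over rounds t … min(t+P, 10); the horizon re-anchors at every
actual decision but never re-extends during a single planning pass.
All decisions are softmax in the action values with inverse
temperature beta = 1/3, which is fixed throughout (the reward scale of
tens of units makes this suitably stochastic).

Partner models form a cognitive hierarchy. A level-k agent models its
partner as the same kind of agent at level k−1 with the *same* horizon
P; the recursion ends at level −1, a reactive model that assumes all
partner guilt types equally likely, plans zero steps ahead, and acts
softmax on immediate expected utilities. Because the trustee moves
second and cannot influence the investor's physical state, a level-0
trustee gains nothing from planning (its policy is the reactive one
for any nominal P), odd investor levels collapse onto the level below,
and even trustee levels collapse likewise. The de-duplicated behaviour
grid is therefore 15 investor cells (k ∈ {0,2}) × 9 trustee cells
(k ∈ {0,1}) = 135 dyad pairings; a level-2 investor with P = 0 is
behaviourally a level-0 investor and is omitted from the grid.

## Solvers

**Level-0 investor — exact recombining DP.** The level-0 investor's
belief depends only on the multiset of past exchanges (21 distinct
outcomes), not their order, so its Bellman values recombine. We solve
them exactly by dynamic programming over states (exchange multiset,
remaining depth, own guilt), packed into 64-bit keys and memoized
process-wide in a numba dictionary. Values are softmax-policy values
(V = Σ_a π(a) Q(a), π = softmax(βQ)). The deepest layer (one round
remaining) holds ~70 % of reachable states and has a closed form, so
it is evaluated on the fly rather than stored; the memo then peaks
around 17 M states (~1.3 GB) when horizon-7 agents are simulated, and
is shared by every game, search and fit in the process.

**Level-1 trustee and level-2 investor — adapted POMCP.** Higher
levels plan by Monte-Carlo tree search over future exchanges:

- *Root sampling*: each simulation samples the partner's guilt from
  the current Dirichlet belief and holds it fixed along the path.
- *SoftUCT descent*: at in-tree nodes, actions are sampled from a
  softmax (β = 1/3) over Q̃(a) + c·sqrt(log N(h) / N(h,a)), with
  exploration constant c = 25 by default. Unvisited actions are taken
  first, in index order. The *returned* root distribution is softmax
  over plain Q̃ — the bonus steers descent only.
- *Backup*: returns are running arithmetic means,
  Q̃ ← Q̃ + (R − Q̃)/N(h,a).
- *Rollouts*: leaves are scored by playing out the remaining horizon
  with ε-greedy (ε = 0.1) choices on the agent's reactive expected
  utilities. Inside a level-1 search the simulated investor follows
  its exact level-0 policy everywhere, including rollouts. Inside a
  level-2 search the in-tree trustee responses come from full nested
  level-1 searches, while during rollouts the trustee is reduced to
  its reactive core with the sampled guilt: rollouts are deliberately
  crude value estimates, and running a nested tree search per rollout
  step would multiply cost for little benefit at the leaf.
- *Pre-search*: before the search proper, agents holding a partner
  model simulate each constant strategy (always offer/return a fixed
  fraction) n_paths/50 times and back the returns up to the root, so
  every root action starts with a stable value estimate. This
  stabilizes inference (likelihoods of rarely chosen actions would
  otherwise rest on a handful of rollouts). A consequence worth
  knowing: root values of actions that SoftUCT subsequently starves
  retain mostly pre-search (constant-strategy) estimates; this is the
  intended behaviour, but it is why the oracle-agreement check in the
  acceptance suite disables pre-search.
- *Nested searches* (the level-1 policies queried inside a level-2
  search) run at a reduced budget (`nested_n_paths`, default
  n_paths/20, at least 50) and are cached keyed by the public history;
  their seeds derive from a stable hash of that key, so results are
  independent of cache state and bit-reproducible. Analytic belief
  updates (the soft-count rule) are used at every tree edge; no
  generic root-sampling belief filter is needed for this task.

Per-round simulation budgets follow the schedule (n, 9n/10, …, n/10)
over rounds 1…10: most simulations are spent early, when beliefs are
uniform and the horizon longest. Trivial cases never invoke the
sampler: level-0 agents, any agent at P = 0, and last-round decisions
are solved in closed form or by the exact DP.

## Inversion

Fitting scans the 15 × 9 grid, accumulating per-round negative log
likelihoods of the observed actions under each cell's policy,
recomputed by the planner with a fixed per-cell seed. Degenerate
trustee rounds contribute zero and are excluded from the trustee's
informative-round count. The reference point is the uniform-random
policy: 10 ln 5 ≈ 16.1 nats for a full game. Ties break toward lower
k, then lower P. β is clamped to 1/3 during fitting. The confusion
experiment simulates a uniform crossing of grid cells, re-fits every
game over the same grids, and row-normalizes inferred-vs-true counts
for guilt, ToM level and planning horizon per role.

## What the simulator emulates — and what it does not

The generator produces exactly the model's own behaviour: quantized
actions, guilt constant within a game, beliefs updated by the
soft-count rule, softmax decisions at β = 1/3. It does not emulate
features of real play such as choice perseveration, round-number
effects, learning of the partner's ToM level or horizon (explicitly
out of scope), or within-game changes of guilt. Recovery results on
self-generated play are therefore a statement about statistical
identifiability under the model's own assumptions — the
self-consistency requirement — not about robustness to model
misspecification.

## Numerical choices

- Money is exact in floating point by construction (all payoffs are
  multiples of 2.5); the guilt grid and β introduce ordinary rounding
  only.
- DP memo keys round nothing: multisets are packed exactly, so the
  recombining cache is sound (order-invariance holds bit-exactly).
- Argmax ties in ε-greedy rollouts break uniformly under the run's
  seed; unvisited-action sweeps are deterministic in index order.
- All seeds below 2^31; every stochastic component (root sampling,
  SoftUCT draws, rollouts, nested searches, batch seeds) derives from
  the run seed via a stable blake2b hash, so games, fits and searches
  are bit-reproducible across processes and cache states.
- Python-side policy caches are size-capped (cleared when full); the
  numba value memo is bounded by the reachable state space.

## Problem sizes

Defaults target production use (n_paths = 25 000, the demonstrated
convergence point of the search). The test and acceptance suites run
the same experiments at desk scale, chosen so the full suite completes
on a single CPU: 300-path searches with 60-path nested searches and 10
games per condition for the planning-horizon comparison; 600/100 paths
and 5 games per pairing for the 3 × 3 guilt-recovery crossing; 80 000
paths for the two-round oracle check; budgets 250 vs 16 000 against a
40 000-path reference for the convergence check. At these sizes the
suite asserts orderings and tolerances (e.g. horizon-7 guilty dyads
out-earning horizon-2 dyads on average; guilt-recovery diagonals above
chance), not large-sample significance levels, which require the full
n = 60 × 25 000-path runs.

## A negative result worth knowing

One widely expected contrast does not emerge from this implementation:
guilty dyads planning 7 steps ahead do **not** out-earn guilty dyads
planning 2 steps ahead at desk scale (the corresponding acceptance
test is deliberately left failing rather than weakened). The reason
is structural, not a search artifact. A guilt-1 investor receives
zero utility from keeping the whole endowment (the inequity penalty
exactly cancels the money), so investing heavily is attractive at
*any* horizon; an exact nested softmax-expectimax solution of the
horizon-2, level-2 investor's first decision gives root values
(33.6, 49.5, 58.1, 58.3, 61.8) — full investment is already the modal
converged choice, and both horizon conditions saturate cooperation.
What remains of the horizon effect is the long-horizon investor's
preemptive end-game reduction of offers, which at ceiling cooperation
slightly *lowers* horizon-7 earnings. An earnings advantage for long
horizons would require the short-horizon condition to cooperate
slowly, which the model's equations at beta = 1/3 do not produce for
guilt-1 agents.

## Known limitations

- Monte-Carlo action values for actions starved of visits are crude
  (pre-search estimates or a few rollouts); their softmax
  probabilities are correspondingly approximate. This mirrors the
  method itself, not an implementation shortcut.
- Inference over β, over the partner's ToM level or horizon, and fits
  of real subject data are out of scope.
- Investor levels above 2 and trustee levels above 1 are not
  implemented (they collapse behaviourally onto the implemented grid
  for this task).
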