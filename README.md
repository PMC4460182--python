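# trustpomcp

Monte-Carlo planning for interactive-POMDP agents in the multi-round
trust game, with maximum-likelihood inversion of observed play.

## The problem

In the 10-round trust task an **investor** repeatedly decides how much
of a 20-unit endowment to send to a **trustee**; the amount is trebled
and the trustee decides how much to return. Behaviour in such dyadic
exchanges reflects each player's aversion to unequal outcomes
("guilt"), their model of the partner (theory of mind), and how far
ahead they plan. Modelling the interaction as an interactive POMDP —
a POMDP whose state includes a model of the other agent, which itself
contains a model of the first — makes these quantities estimable from
behaviour, but solving such nested POMDPs exactly is intractable for
realistic planning horizons. This package solves them approximately
with an adaptation of partially observable Monte-Carlo planning
(POMCP): a generative tree search with softmax-UCT action selection,
root sampling of the partner's type, and analytic Dirichlet belief
updates. It is aimed at computational modellers of social exchange
who need (a) a generative simulator of trust-game dyads and (b) a
likelihood machine to invert observed exchanges.

## The model in brief

An agent is the triplet **(k, α, P)**: theory-of-mind level
k (investor ∈ {0, 2}, trustee ∈ {0, 1}), Fehr–Schmidt guilt
α ∈ {0, 0.4, 1}, and planning horizon P ∈ {0, 2, 7}. Round payoffs
are χ_I = 20 − 20a_I + 60a_I·a_T and χ_T = 60a_I − 60a_I·a_T with
quantized actions a_I, a_T; utilities are
r = χ_self − α·max(χ_self − χ_other, 0); decisions are softmax in the
action values with inverse temperature β = 1/3. A level-k agent
models its partner at level k−1 with the same P, holding a Dirichlet
belief over the partner's guilt updated by the soft-count rule
a′_i = a_i + P[observed action | α_i]. Level-0 investors are solved
exactly on a recombining tree (their values depend only on the
multiset of past exchanges); level-1 trustees and level-2 investors
are solved by POMCP with nested partner simulation. Fitting scans
the de-duplicated 15 × 9 grid of (k, α, P) cells and accumulates
negative log likelihoods of the observed actions; the uniform-random
reference is 10 ln 5 ≈ 16.1 nats per game. See `docs/methods.md` for
the full account.

## Worked example

```python
from trustpomcp import AgentSpec, SearchConfig, play_game, fit_dyad

cfg = SearchConfig(n_paths=600, nested_n_paths=100)
investor = AgentSpec("investor", k=0, alpha=1.0, P=2)   # guilty, plans 2 ahead
trustee = AgentSpec("trustee", k=1, alpha=1.0, P=2)     # guilty, models the investor

record = play_game(investor, trustee, cfg, seed=1)
print(record.exchanges)
print(record.total_gains)

fit_inv, fit_tru = fit_dyad(
    record.exchanges, cfg,
    investor_cells=[AgentSpec("investor", 0, a, 2) for a in (0.0, 0.4, 1.0)],
    trustee_cells=[AgentSpec("trustee", 1, a, 2) for a in (0.0, 0.4, 1.0)],
    seed=1,
)
print(fit_inv.best.alpha, fit_tru.best.alpha)
```

prints

```
[(2, 2), (1, 2), (2, 2), (4, 3), (4, 3), (4, 3), (3, 3), (4, 3), (4, 3), (4, 3)]
(267.5, 252.5)
1.0 1.0
```

The exchange list holds (investor, trustee) action categories 0–4 per
round: this guilty dyad ramps up to full investments (category 4 = 20
units) answered by the fair-split return (category 3 at full
investment equalizes payoffs at 30/30), earning 267.5 and 252.5 units
over ten rounds. The guilt-only maximum-likelihood fit recovers
α = 1 for both roles from this single game.

The same functionality is available from the shell:

```sh
trustpomcp simulate --investor 2,1,7 --trustee 1,1,7 --reps 5 \
    --n-paths 600 --seed 1 --out runs/guilty_p7
trustpomcp fit runs/guilty_p7/game_000.csv --n-paths 600 --seed 2 --out runs/fit
trustpomcp confusion --reduced-grid --reps 5 --n-paths 600 --seed 3 --out runs/conf
trustpomcp converge --investor 2,1,2 --budgets 500,2000,8000 --seed 4 --out runs/conv
```

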