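# rbnxcs — evolving ternary control rules for random Boolean networks

`rbnxcs` learns compact rule sets that *steer* an NK random Boolean network
— a minimal model of gene-regulatory dynamics — from any state into a chosen
target attractor.  The controller is an XCS learning classifier system: a
population of condition–action rules whose conditions are ternary strings
over `{0, 1, #}` (one character per network node, `#` = "don't care") and
whose actions are single bit flips (`0` = leave the network alone).  Rules
are discovered from scratch by reinforcement learning plus a niche genetic
algorithm: the system never sees the network's wiring, only its state.

The intended audience is researchers in network controllability and systems
biology who want a reproducible, fast reference implementation of the
approach: Boolean-network simulation and exhaustive state-space analysis,
the full classifier engine, the control environment with its reward program,
and the numerosity-ordered rule-set compression.

## The model in brief

An NK Boolean network has `N` binary nodes, each wired to `K` randomly
chosen input nodes through a random truth table; all nodes update
synchronously.  The `2^N` states form a functional graph that decomposes
into attractor cycles and their basins.  A *control task* fixes one
attractor as the target.  In every trial the network starts at a random
state off the target cycle and the controller repeatedly either flips one
bit (an *intervention*, always followed by one natural update) or lets the
network run free.  On entering the target cycle the reinforcement program
pays

```
reward = 1000 · (steps − interventions) / steps
```

(0 if the target is never reached), so the best policies coast to the
target with as few interventions as possible.  Multi-step credit assignment
follows the standard XCS scheme: the previous action set is updated toward
`P = γ · max(current prediction array)`, classifier accuracy is
`κ = 1` for prediction error `ε < ε₀` and `α(ε/ε₀)^−ν` above it, and
fitness tracks the numerosity-weighted relative accuracy within the action
set.  After training, the population is sorted by numerosity and every
prefix is evaluated as a standalone greedy controller from every start
state; the smallest-average-intervention prefix that covers the whole state
space is the *compact rule set* (CR = its size, AS/AI = its average steps
and interventions per start).

## Worked example

```python
import rbnxcs as rx

net, _ = rx.generate_controllable_network(5, 2, seed=1)   # >= 2 attractors
graph = rx.map_state_space(net)
for i, a in enumerate(graph.attractors):
    print("attractor", i, " -> ".join(a.cycle), "basin", graph.basin_sizes()[i])

target = rx.select_target(graph, "smallest_basin")
task = rx.ControlTask(net, target)
result = rx.run_training(task, rx.XcsParams(), rx.Rng(rx.child_seed(1, 1, 1)))
print("covered:", result.success, "after", result.trials, "trials;",
      len(result.population), "macroclassifiers")

comp = rx.compact_ruleset(result.population, task)
print(f"compact set: CR={comp.size} AS={comp.avg_steps:.3f} "
      f"AI={comp.avg_interventions:.3f}")
for c in comp.ruleset[:5]:
    print(" ", rx.format_rule(c))
```

prints

```
attractor 0 00000 -> 00110 -> 11110 -> 01101 basin 16
attractor 1 01000 -> 10101 -> 11000 -> 11101 basin 16
covered: True after 250000 trials; 301 macroclassifiers
compact set: CR=13 AS=3.321 AI=0.571
  ##### : 4 [446.56/0.9882]
  ##### : 1 [439.19/0.9913]
  ##### : 0 [671.55/0.2059]
  ####1 : 2 [467.74/0.5912]
  ##0## : 5 [503.61/0.1010]
```

Thirteen ternary rules control all 32 states of this network: on average a
trajectory needs 3.3 steps and 0.57 interventions to reach the target
cycle.  Each rule line shows `condition : action [prediction/fitness]`.
Note the over-general `##### : a` rules at the top — the engine leans on a
few high-numerosity generalists and patches them with more specific rules.

The same pipeline is scriptable from the shell:

```bash
rbnxcs generate-network --n 5 --k 2 --seed 1 --out net.json
rbnxcs map-state-space net.json --dot statespace.dot
rbnxcs train net.json --seed 7 --out population.tsv
rbnxcs compress net.json population.tsv --out rules.txt
rbnxcs evaluate net.json rules.txt --out evaluation.tsv
rbnxcs experiment --config experiment.yaml
```

`rbnxcs experiment` writes a results table with one `Net / Run / CR / AS /
AI / Time` row per training run plus all per-run artifacts (population,
compact rule set, per-state evaluation, training log, state-space DOT
graph, configuration snapshot).

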