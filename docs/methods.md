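# Methods

## Random Boolean networks

An NK network has `N` binary nodes; each node reads `K` input nodes —
sampled uniformly *without replacement*, self-loops allowed — through a
truth table whose `2^K` output bits are fair coin flips.  Updating is
synchronous: every node's next value is computed from the pre-step state
and all nodes commit together.  A state is rendered as a bit string with
node 1 leftmost; a truth-table row index reads the input bits in stored
input order with the first input as the most significant bit.  Neither the
sampling-without-replacement choice nor the row-index convention is forced
by the model; both are fixed here, documented, and covered by tests.

`map_state_space` enumerates all `2^N` successors (vectorised over the
state integer range), finds attractors by trajectory-following with
visited-set cycle detection, and assigns every state the basin of the
attractor its trajectory reaches.  Attractor cycles are stored in canonical
rotation (lexicographically smallest state first) so that attractors
compare by value.  Exhaustive mapping is guarded at `N ≤ 24` and control
tasks at `N ≤ 20`; both bounds are resource guards, not model limits.

The bit-flip distance between two attractors is the minimum Hamming
distance over all pairs of cycle states — the number of simultaneous flips
needed to hop directly between them.  A distance above 1 means no single
intervention can move the system between those attractors; the controller
must route through intermediate basin states.

## The classifier engine

A classifier is a ternary condition over `{0, 1, #}` plus an action in
`[0, N]` (0 = no action, `i` flips node `i`), carrying prediction `p`,
prediction error `ε`, fitness `F`, numerosity, experience, an
action-set-size estimate and a GA time stamp.  The population holds at most
`R` micro-classifiers (numerosity-weighted copies).

Engine cycle per step: build the match set; while it advocates fewer than
`θ_mna` *distinct actions*, create covering classifiers (condition = the
state with each character turned to `#` with probability `P_#`; action
uniform over missing actions; statistics at the configured initial values)
— `θ_mna` counts actions, not raw rules, because covering explicitly picks
actions that are absent and the parameter's role is to guarantee every
action is represented.  The prediction array holds the fitness-weighted
mean prediction per action (unweighted mean if the total fitness of an
action is zero).  Action choice is the deterministic payoff-threshold rule:
exploit (argmax, ties to the smallest action index) when the best entry
exceeds 500, otherwise explore uniformly over the present actions; a best
entry of exactly 500 explores.  Evaluation mode is always greedy.

Reinforcement: from the second step of a trial on, the *previous* action
set is updated with `P = r_prev + γ · max(prediction array)`, where the
intermediate reward `r_prev` is always 0 in this environment; on reaching
the target the *current* action set receives a final update with the trial
payoff and a final GA invocation.  Updates use the two-tier scheme: a
component with experience below `1/β` is updated by incremental averaging
(`Δ / experience`), afterwards by the Widrow–Hoff rate `β`.  The error is
updated first, toward `|P − p|` computed with the *pre-update* prediction
(the temporal-difference error actually observed); then the prediction,
then the action-set-size estimate toward the action set's numerosity sum.
The source descriptions do not fix this ordering; it is pinned here and
exercised by the frozen-value tests.  Fitness uses the plain rate `β` on
the numerosity-weighted relative accuracy `κ·num / Σκ·num`, with
`κ = 1` if `ε < ε₀`, else `α (ε/ε₀)^{−ν}`.

Action-set subsumption (enabled by default) lets the most general member
with experience above `θ_sub` and error below `ε₀` absorb every strictly
less general member with the same action; numerosity is conserved.  The GA
runs on an action set when the engine clock exceeds its numerosity-weighted
mean time stamp by more than `θ_ga`: two parents are drawn by
fitness-proportionate roulette, children are copies (numerosity 1,
experience 0) that cross over two-point with probability `χ`, mutate
per-index with probability `μ` (niche mutation: a literal becomes `#`, a
`#` becomes the current situation's bit, so mutants still match the
situation; the action is re-drawn to a different action with probability
`μ`), and take the parents' mean `p`, `ε`, `F` (and mean action-set-size
estimate — unspecified in the sources, fixed here).  An eligible more
general parent subsumes its child instead of inserting it.  Insertions
merge duplicates by numerosity; capacity is then enforced by roulette
deletion with votes `as_size · num`, inflated by `meanF / (F/num)` for
experienced classifiers whose per-copy fitness is below `δ` times the
population mean.

### Parameters

Defaults (see `XcsParams`): `R=790`, `γ=0.76`, `θ_mna=6`, `P_#=0.4`,
`p_I=7.4`, `ε_I=1.0`, `F_I=0.03`, `ε₀=18.5`, `θ_ga=260`, `θ_del=32`,
`β=0.01`, `α=0.087`, `ν=0.01`, `χ=0.711`, `μ=0.263`, `δ=0.05`,
`θ_sub=31.579`, both subsumption flags on.  The unusually tolerant accuracy
settings (`ε₀` high, `ν` tiny, so accuracy drops to ≈ `α` at the threshold
and stays almost flat beyond it) compensate for the intrinsic payoff
fluctuation of this environment: the same rule participates in action
chains of different lengths, so its payoff — and hence its error — cannot
converge to a point value.  `θ_mna` equals the `N+1` available actions for
the 5-node tasks, so covering guarantees every action is represented in
every match set.  The probabilistic exploration rate of the original XCS is
not implemented; the deterministic payoff-threshold chooser replaces it.

## Control environment

Steps are counted as *natural updates plus interventions*: a non-zero
action contributes 2 (the flip and the forced natural update that follows
it), a no-action step contributes 1.  This is the convention tied to the
reported average-steps statistic; it is isolated in `environment_step` so
the alternative reading (one count per engine cycle) could be swapped in
one place.  Start states are sampled uniformly from the states *outside*
the target cycle — a trial starting on the target would pay reward on zero
steps — and evaluation averages are taken over those same states.  Trials
are truncated at `max_steps` (default 100, generous for 32-state networks)
with reward 0; on truncation the current action set receives a final update
with payoff 0 (the same shape as the terminal update, using the
reinforcement program's "not reached ⇒ 0" payoff) and no GA.

The training driver runs learning trials and evaluates the population
greedily from every start state after `min_trials` (default 250,000) and
every `eval_interval` (default 10,000) trials thereafter, stopping at the
first evaluation with full coverage and no failures, or giving up at
`max_trials` (default 1,000,000; the run is then flagged failed but the
population is still returned).  The schedule counts trials; a trial is one
episode from a random start to the target or the cap.

## Rule-set compression

Macroclassifiers are ordered by numerosity, with deterministic tie-breaks
(fitness, then prediction, then condition lexicographically, then action —
the sources leave ties open).  Every prefix length is evaluated as a
standalone greedy controller; among the fully covering prefixes the one
with the minimum average intervention count is returned, ties to the
smaller prefix.  Compression never edits rules.  Unmatched states during
evaluation take action 0, so a prefix fails by *behaviour* (target not
reached), not by raising.

## Implementation notes

The trial loop runs as numba-compiled kernels over an array-backed
population (conditions are stored as mask/value integer pairs, so matching
is two integer operations); slot re-use after deletion is guarded by
per-slot generation counters so stale action-set references are skipped
rather than corrupting an unrelated rule.  All randomness — engine and
environment alike — flows through a single hand-rolled PCG32 generator that
is itself JIT-compiled, so the fine-grained Python operations and the fused
trial kernel consume the identical stream: a test recomposes the documented
engine cycle from the public operations and checks bit-exact equality of
the resulting population with the fused kernel.  A `(seed, parameters,
network)` triple fully determines a run.  Network generation uses numpy's
`default_rng` (it never interleaves with the engine stream).

One full 250,000-trial training run takes seconds to a few tens of seconds
on one CPU core depending on network difficulty, after a one-off JIT
compilation cost at first use in a process.

## What the synthetic generator does and does not emulate

Generated `N=5, K=2` networks reproduce the study conditions: random
wiring with distinct inputs, random truth tables, synchronous updates, and
(for experiments) regeneration until at least two attractors exist, since
cross-basin control is the interesting case.  Real gene-regulatory networks
differ in ways this model deliberately ignores: asynchronous or stochastic
updating, non-random degree distributions and logic, and noisy or partial
observability.  Passing tests therefore demonstrate correctness of the
algorithmics and controllability of the model class, not performance on
biological networks.

## Known limitations

- Exhaustive enumeration (state-space mapping, whole-space evaluation)
  limits tasks to desk scale; the method itself has no such bound.
- Compact-set sizes are stochastic: most runs compress to well under one
  rule per state, but on some networks the minimum-average-intervention
  prefix lies deep in the numerosity tail, echoing the over-general
  classifier problem — a small set of `#…#` rules with high numerosity
  dominates while many numerosity-1 specialists contribute marginal
  intervention savings.
- Only single-bit interventions are modelled; one flip per step, always
  followed by a natural update.
- The compression searches numerosity-ordered prefixes only, not arbitrary
  rule subsets.
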