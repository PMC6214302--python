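"""Coupling the classifier engine to a Boolean network control task.

A trial instantiates the network at a random state outside the target
attractor's cycle and repeats: sense the state, pick a bit-flip action (or
no action), execute it — an intervention is always followed immediately by
one natural synchronous update, a no-action step is a natural update alone —
until the target cycle is entered or the step cap is hit.  The reinforcement
program pays 1000 * (steps - interventions) / steps on success and 0
otherwise, so reward is maximal for trajectories that coast to the target
without touching the network.

Step accounting: ``steps`` counts natural updates plus interventions (an
intervention step therefore adds 2), matching the statistic reported as the
average number of steps (AS) in evaluations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import _kernels as K
from ._rng import Rng, rand_below
from .network import (
    Attractor,
    BooleanNetwork,
    flip_bit,
    int_to_state,
    map_state_space,
    state_to_int,
    successor_table,
    synchronous_step,
)
from .params import XcsParams
from .xcs import Classifier, Population, condition_to_masks

__all__ = [
    "ControlTask",
    "TrialLedger",
    "EvaluationReport",
    "TrainingResult",
    "reward",
    "environment_step",
    "run_trial",
    "run_training",
    "evaluate_all_states",
]

#: node count above which exhaustive training/evaluation is refused
MAX_TRAIN_NODES = 20


@dataclass(frozen=True)
class ControlTask:
    """A network, a target attractor, and a per-trial step cap.

    The target must be exactly the state set of one attractor of the
    network (validated against the exhaustively mapped state space).
    """

    network: BooleanNetwork
    target: Attractor
    max_steps: int = 100

    def __post_init__(self) -> None:
        if self.network.n_nodes > MAX_TRAIN_NODES:
            raise ValueError(
                f"control tasks are limited to N <= {MAX_TRAIN_NODES} nodes"
            )
        if self.max_steps < 1:
            raise ValueError("max_steps must be positive")
        graph = map_state_space(self.network)
        if not any(a.states == self.target.states for a in graph.attractors):
            raise ValueError(
                "target cycle is not an attractor of the network: "
                f"{sorted(self.target.states)}"
            )

    @property
    def n_nodes(self) -> int:
        return self.network.n_nodes

    @property
    def n_actions(self) -> int:
        return self.network.n_nodes + 1

    @property
    def target_states(self) -> frozenset[str]:
        return self.target.states

    # cached integer tables for the compiled trial loop -----------------

    def _tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        succ = successor_table(self.network)
        target = np.zeros(2**self.n_nodes, np.bool_)
        for s in self.target.states:
            target[state_to_int(s)] = True
        starts = np.flatnonzero(~target).astype(np.int64)
        return succ, target, starts

    def start_states(self) -> list[str]:
        """All states outside the target cycle, in numeric order."""
        _, target, starts = self._tables()
        return [int_to_state(int(s), self.n_nodes) for s in starts]


@dataclass
class TrialLedger:
    """Step and intervention counters of one trial."""

    steps: int = 0
    interventions: int = 0
    reached: bool = False
    reward: float = 0.0

    def reset(self) -> None:
        self.steps = 0
        self.interventions = 0
        self.reached = False
        self.reward = 0.0


def reward(ledger: TrialLedger) -> float:
    """The reinforcement program's payoff for a finished trial.

    1000 * (steps - interventions) / steps when the target was reached,
    otherwise 0.
    """
    if not ledger.reached:
        return 0.0
    if ledger.steps < 1:
        raise ValueError("a reached trial cannot have zero steps")
    return 1000.0 * (ledger.steps - ledger.interventions) / ledger.steps


class StepDelta(NamedTuple):
    state: str
    steps: int
    interventions: int


def environment_step(task: ControlTask, state: str, action: int) -> StepDelta:
    """Execute one action: flip (if any) followed by one natural update.

    A non-zero action flips the addressed bit and the network then performs
    one synchronous update (steps += 2, interventions += 1); action 0 is a
    natural update alone (steps += 1).
    """
    if action < 0 or action > task.n_nodes:
        raise ValueError(f"action {action} outside [0, {task.n_nodes}]")
    if action != 0:
        nxt = synchronous_step(task.network, flip_bit(state, action))
        return StepDelta(nxt, 2, 1)
    return StepDelta(synchronous_step(task.network, state), 1, 0)


# ---------------------------------------------------------------------------
# greedy (non-learning) trials over an explicit rule list


class _RulePolicy:
    """Greedy, stationary policy induced by a fixed rule list.

    The action for a state is the argmax of the fitness-weighted prediction
    array over the matching rules (ties to the smallest action index); a
    state with no matching rule takes action 0.  Actions are memoised, so
    evaluation over many start states stays cheap.
    """

    def __init__(self, rules: Sequence[Classifier]):
        self._rules = [
            (condition_to_masks(r.condition) + (r.action, r.prediction, r.fitness))
            for r in rules
        ]
        self._cache: dict[int, int] = {}

    def action(self, s: int) -> int:
        act = self._cache.get(s)
        if act is not None:
            return act
        psum: dict[int, float] = {}
        fsum: dict[int, float] = {}
        usum: dict[int, float] = {}
        nsup: dict[int, int] = {}
        for mask, val, a, p, f in self._rules:
            if (s & mask) == val:
                psum[a] = psum.get(a, 0.0) + p * f
                fsum[a] = fsum.get(a, 0.0) + f
                usum[a] = usum.get(a, 0.0) + p
                nsup[a] = nsup.get(a, 0) + 1
        if not nsup:
            act = 0
        else:
            best, bv = -1, -math.inf
            for a in sorted(nsup):
                v = psum[a] / fsum[a] if fsum[a] > 0 else usum[a] / nsup[a]
                if v > bv:
                    best, bv = a, v
            act = best
        self._cache[s] = act
        return act


def _greedy_trial(
    task: ControlTask,
    policy: _RulePolicy,
    start: str,
    succ: np.ndarray,
    target: np.ndarray,
) -> TrialLedger:
    n = task.n_nodes
    ledger = TrialLedger()
    s = state_to_int(start)
    while True:
        a = policy.action(s)
        if a != 0:
            s = int(succ[s ^ (1 << (n - a))])
            ledger.steps += 2
            ledger.interventions += 1
        else:
            s = int(succ[s])
            ledger.steps += 1
        if target[s]:
            ledger.reached = True
            ledger.reward = reward(ledger)
            return ledger
        if ledger.steps >= task.max_steps:
            return ledger


# ---------------------------------------------------------------------------
# learning trials and the training driver


def run_trial(
    task: ControlTask,
    pop: Population,
    params: XcsParams,
    rng: Rng,
    learning: bool = True,
    start: str | None = None,
) -> TrialLedger:
    """One trial of the multi-step loop.

    With ``learning=True`` the full engine runs (covering, reinforcement of
    the previous action set with P = gamma * max of the current prediction
    array, GA scheduling, and the final update with the trial payoff).  With
    ``learning=False`` the trial is a greedy, update-free walk over the
    population's current rules, with action 0 on unmatched states.

    ``start`` defaults to a uniform draw over states outside the target
    cycle.
    """
    succ, target, starts = task._tables()
    if start is None:
        s0 = int(starts[rng.randbelow(len(starts))])
    else:
        s0 = state_to_int(start)
        if target[s0]:
            raise ValueError("start state lies inside the target cycle")
    if not learning:
        return _greedy_trial(
            task, _RulePolicy(pop.classifiers()), int_to_state(s0, task.n_nodes),
            succ, target,
        )
    cap = len(pop._cmask)
    n_act = task.n_actions
    steps, interv, reached, rew = K._run_one_trial(
        *pop._args, succ, target, np.int64(s0), np.int64(task.max_steps),
        np.int64(task.n_nodes), np.int64(n_act), params.to_array(), rng.state,
        np.empty(cap, np.int64), np.zeros(n_act, np.bool_),
        np.zeros(n_act, np.float64), np.zeros(n_act, np.float64),
        np.zeros(n_act, np.float64), np.zeros(n_act, np.int64),
        np.empty(cap, np.int64), np.empty(cap, np.int64),
        np.empty(cap, np.int64), np.empty(cap, np.int64),
    )
    return TrialLedger(int(steps), int(interv), bool(reached), float(rew))


@dataclass(frozen=True)
class EvaluationReport:
    """Greedy evaluation of a rule set from every non-target start state."""

    covered: bool
    avg_steps: float
    avg_interventions: float
    records: tuple[tuple[str, bool, int, int], ...]  # (start, reached, steps, interv)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            list(self.records),
            columns=["start", "reached", "steps", "interventions"],
        )
        return df

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        summary = pd.DataFrame(
            [
                {
                    "start": "AVERAGE",
                    "reached": self.covered,
                    "steps": round(self.avg_steps, 3),
                    "interventions": round(self.avg_interventions, 3),
                }
            ]
        )
        pd.concat([df, summary], ignore_index=True).to_csv(
            path, sep="\t", index=False
        )


def evaluate_all_states(
    task: ControlTask,
    rules: Sequence[Classifier] | Population,
    max_steps: int | None = None,
) -> EvaluationReport:
    """Run a greedy, non-learning trial from every state outside the target.

    ``covered`` is True iff every start reaches the target within the step
    cap; the step and intervention averages are taken over those start
    states only (states already on the target cycle are excluded — they
    would make the reward formula degenerate).
    """
    if isinstance(rules, Population):
        rules = rules.classifiers()
    if max_steps is not None and max_steps != task.max_steps:
        task = ControlTask(task.network, task.target, max_steps)
    succ, target, starts = task._tables()
    policy = _RulePolicy(rules)
    records = []
    tot_steps = 0
    tot_interv = 0
    covered = True
    for s in starts:
        start = int_to_state(int(s), task.n_nodes)
        ledger = _greedy_trial(task, policy, start, succ, target)
        records.append((start, ledger.reached, ledger.steps, ledger.interventions))
        covered = covered and ledger.reached
        tot_steps += ledger.steps
        tot_interv += ledger.interventions
    n = max(len(records), 1)
    return EvaluationReport(
        covered=covered,
        avg_steps=tot_steps / n,
        avg_interventions=tot_interv / n,
        records=tuple(records),
    )


@dataclass(frozen=True)
class TrainingResult:
    """Trained population plus the scheduled-evaluation log."""

    population: Population
    success: bool
    trials: int
    log: tuple[dict, ...]

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.log))


def run_training(
    task: ControlTask,
    params: XcsParams,
    rng: Rng,
    min_trials: int = 250_000,
    eval_interval: int = 10_000,
    max_trials: int = 1_000_000,
) -> TrainingResult:
    """Train until the evolved rules cover the whole state space.

    Learning trials run from uniformly drawn non-target starts; after
    ``min_trials`` — and every ``eval_interval`` thereafter — the current
    rules are evaluated greedily from every start state.  Training stops at
    the first evaluation that covers the state space with no failures, or
    gives up at ``max_trials`` (the population and log are still returned,
    flagged unsuccessful).
    """
    if min_trials < 1:
        raise ValueError("min_trials must be at least 1")
    if eval_interval < 1:
        raise ValueError("eval_interval must be positive")
    succ, target, starts = task._tables()
    pop = Population.for_params(params, task.n_nodes)
    prm = params.to_array()
    log: list[dict] = []
    trials_done = 0
    next_eval = min_trials
    success = False
    while True:
        chunk = min(next_eval, max_trials) - trials_done
        if chunk > 0:
            K._run_trials(
                *pop._args, succ, target, starts, np.int64(chunk),
                np.int64(task.max_steps), np.int64(task.n_nodes),
                np.int64(task.n_actions), prm, rng.state,
            )
            trials_done += chunk
        report = evaluate_all_states(task, pop)
        log.append(
            {
                "trials": trials_done,
                "covered": report.covered,
                "avg_steps": report.avg_steps,
                "avg_interventions": report.avg_interventions,
                "macro_rules": len(pop),
                "micro_rules": pop.micro_count,
            }
        )
        if report.covered:
            success = True
            break
        if trials_done >= max_trials:
            break
        next_eval += eval_interval
    return TrainingResult(pop, success, trials_done, tuple(log))
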