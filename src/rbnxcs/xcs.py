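"""Ternary-rule classifier engine: population, matching, covering, GA.

A classifier pairs a ternary condition over ``{0, 1, #}`` with a bit-flip
action (0 = no action) and carries the usual XCS bookkeeping: prediction,
prediction error, accuracy-based fitness, numerosity, experience, an
action-set-size estimate and a GA time stamp.  The population is a
collection of macroclassifiers with unique (condition, action) pairs whose
summed numerosity is capped at R by roulette deletion.

The heavy lifting lives in the compiled kernels of :mod:`rbnxcs._kernels`;
every public operation here is a thin wrapper over the same kernels the
fused trial loop uses, so the fine-grained API and the trainer consume the
identical random stream and produce identical populations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from . import _kernels as K
from ._rng import Rng
from .network import state_to_int
from .params import XcsParams

__all__ = [
    "Classifier",
    "ClassifierSet",
    "Population",
    "matches",
    "build_match_set",
    "cover",
    "build_prediction_array",
    "select_action",
    "compute_target_P",
    "classifier_accuracy",
    "update_action_set",
    "run_ga",
    "crossover_two_point",
    "mutate_classifier",
    "is_more_general",
    "action_set_subsumption",
    "delete_to_capacity",
    "insert_classifier",
    "deletion_votes",
    "format_rule",
    "parse_rule",
    "write_ruleset",
    "read_ruleset",
]


def condition_to_masks(condition: str) -> tuple[int, int]:
    """Encode a ternary condition as (mask, value) bit pair (char 1 = MSB)."""
    mask = 0
    val = 0
    for c in condition:
        mask <<= 1
        val <<= 1
        if c == "1":
            mask |= 1
            val |= 1
        elif c == "0":
            mask |= 1
        elif c != "#":
            raise ValueError(f"invalid condition character {c!r}")
    return mask, val


def masks_to_condition(mask: int, val: int, n_bits: int) -> str:
    out = []
    for i in range(n_bits - 1, -1, -1):
        b = 1 << i
        if mask & b:
            out.append("1" if val & b else "0")
        else:
            out.append("#")
    return "".join(out)


@dataclass
class Classifier:
    """One macroclassifier: a ternary condition, an action, and statistics."""

    condition: str
    action: int
    prediction: float = 0.0
    error: float = 0.0
    fitness: float = 0.0
    numerosity: int = 1
    experience: int = 0
    as_size: float = 1.0
    time_stamp: int = 0

    def __post_init__(self) -> None:
        condition_to_masks(self.condition)  # validates characters
        if self.action < 0 or self.action > len(self.condition):
            raise ValueError(
                f"action {self.action} outside [0, {len(self.condition)}]"
            )
        if self.numerosity < 1:
            raise ValueError("numerosity must be at least 1")

    def copy(self) -> "Classifier":
        return replace(self)


def matches(condition: str, state: str) -> bool:
    """True iff every condition character equals the state bit or is '#'."""
    if len(condition) != len(state):
        raise ValueError("condition and state have different lengths")
    return all(c == "#" or c == s for c, s in zip(condition, state))


def is_more_general(general: Classifier, specific: Classifier) -> bool:
    """Strict generality with equal actions.

    True iff both actions are equal, ``general`` has strictly more '#'
    symbols, and every literal of ``general`` equals the corresponding
    character of ``specific``.
    """
    if len(general.condition) != len(specific.condition):
        raise ValueError("conditions have different lengths")
    if general.action != specific.action:
        return False
    gm, gv = condition_to_masks(general.condition)
    sm, sv = condition_to_masks(specific.condition)
    return bool(K._more_general(np.int64(gm), np.int64(gv), np.int64(sm), np.int64(sv)))


@dataclass(frozen=True)
class ClassifierSet:
    """Slot references into a population (match set or action set).

    Generation snapshots detect members that were deleted (and whose slot
    was possibly re-used) after the set was formed.
    """

    slots: np.ndarray
    gens: np.ndarray

    def __len__(self) -> int:
        return len(self.slots)

    def classifiers(self, pop: "Population") -> list[Classifier]:
        return [
            pop.classifier_at(int(s))
            for s, g in zip(self.slots, self.gens)
            if pop._alive[s] and pop._gen[s] == g
        ]

    def restrict_to_action(self, pop: "Population", action: int) -> "ClassifierSet":
        keep = [
            t for t, s in enumerate(self.slots) if int(pop._cact[s]) == int(action)
        ]
        return ClassifierSet(self.slots[keep], self.gens[keep])


class Population:
    """Array-backed macroclassifier population with capacity bookkeeping."""

    def __init__(self, n_bits: int, capacity: int):
        if n_bits < 1:
            raise ValueError("n_bits must be positive")
        self.n_bits = int(n_bits)
        self.n_actions = self.n_bits + 1
        cap = int(capacity)
        self._cmask = np.zeros(cap, np.int64)
        self._cval = np.zeros(cap, np.int64)
        self._cact = np.zeros(cap, np.int64)
        self._pred = np.zeros(cap, np.float64)
        self._err = np.zeros(cap, np.float64)
        self._fit = np.zeros(cap, np.float64)
        self._num = np.zeros(cap, np.int64)
        self._expn = np.zeros(cap, np.int64)
        self._asz = np.zeros(cap, np.float64)
        self._ts = np.zeros(cap, np.int64)
        self._gen = np.zeros(cap, np.int64)
        self._alive = np.zeros(cap, np.bool_)
        self._free = np.zeros(cap, np.int64)
        self._meta = np.zeros(4, np.int64)

    @classmethod
    def for_params(cls, params: XcsParams, n_bits: int) -> "Population":
        """Population sized for capacity R plus transient headroom."""
        return cls(n_bits, params.R + 64)

    # -- kernel plumbing ----------------------------------------------------

    @property
    def _args(self) -> tuple:
        return (
            self._cmask, self._cval, self._cact, self._pred, self._err,
            self._fit, self._num, self._expn, self._asz, self._ts, self._gen,
            self._alive, self._free, self._meta,
        )

    # -- bookkeeping --------------------------------------------------------

    @property
    def micro_count(self) -> int:
        """Total numerosity across all macroclassifiers."""
        return int(self._meta[K.META_MICRO])

    def __len__(self) -> int:
        """Number of macroclassifiers."""
        return int(self._meta[K.META_HW] - self._meta[K.META_FREE])

    @property
    def time(self) -> int:
        """The engine step counter used for GA scheduling."""
        return int(self._meta[K.META_TIME])

    def advance_time(self, by: int = 1) -> int:
        self._meta[K.META_TIME] += by
        return self.time

    def slots(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self._alive[: self._meta[K.META_HW]])]

    def classifier_at(self, slot: int) -> Classifier:
        if not self._alive[slot]:
            raise KeyError(f"slot {slot} is empty")
        return Classifier(
            condition=masks_to_condition(
                int(self._cmask[slot]), int(self._cval[slot]), self.n_bits
            ),
            action=int(self._cact[slot]),
            prediction=float(self._pred[slot]),
            error=float(self._err[slot]),
            fitness=float(self._fit[slot]),
            numerosity=int(self._num[slot]),
            experience=int(self._expn[slot]),
            as_size=float(self._asz[slot]),
            time_stamp=int(self._ts[slot]),
        )

    def classifiers(self) -> list[Classifier]:
        return [self.classifier_at(s) for s in self.slots()]

    def __iter__(self) -> Iterator[Classifier]:
        return iter(self.classifiers())

    def add(self, cl: Classifier) -> int:
        """Insert a classifier, merging into an existing (condition, action)."""
        if len(cl.condition) != self.n_bits:
            raise ValueError("condition length does not match the population")
        m, v = condition_to_masks(cl.condition)
        return int(
            K._insert(
                *self._args,
                np.int64(m), np.int64(v), np.int64(cl.action),
                float(cl.prediction), float(cl.error), float(cl.fitness),
                np.int64(cl.numerosity), np.int64(cl.experience),
                float(cl.as_size), np.int64(cl.time_stamp),
            )
        )

    def copy(self) -> "Population":
        other = Population(self.n_bits, len(self._cmask))
        for name in (
            "_cmask", "_cval", "_cact", "_pred", "_err", "_fit", "_num",
            "_expn", "_asz", "_ts", "_gen", "_alive", "_free", "_meta",
        ):
            getattr(other, name)[:] = getattr(self, name)
        return other

    def state_equal(self, other: "Population") -> bool:
        """Exact equality of the live classifier content of two populations."""
        def snapshot(p: Population):
            return sorted(
                (c.condition, c.action, c.prediction, c.error, c.fitness,
                 c.numerosity, c.experience, c.as_size, c.time_stamp)
                for c in p.classifiers()
            )
        return snapshot(self) == snapshot(other)

    # -- persistence --------------------------------------------------------

    _FRAME_COLS = [
        "condition", "action", "prediction", "error", "fitness",
        "numerosity", "experience", "as_size", "time_stamp",
    ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {k: getattr(c, k) for k in self._FRAME_COLS} for c in self.classifiers()
        ]
        return pd.DataFrame(rows, columns=self._FRAME_COLS)

    def save(self, path) -> None:
        """Persist the full population (with numerosities) as TSV."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path, capacity: int | None = None) -> "Population":
        df = pd.read_csv(path, sep="\t", dtype={"condition": str})
        if df.empty:
            raise ValueError(f"population file {path} is empty")
        n_bits = len(df.iloc[0]["condition"])
        pop = cls(n_bits, capacity or (len(df) + 64))
        for _, row in df.iterrows():
            pop.add(Classifier(**{k: row[k] for k in cls._FRAME_COLS}))
        return pop


# ---------------------------------------------------------------------------
# operations


def build_match_set(
    pop: Population,
    state: str,
    params: XcsParams,
    rng: Rng | None = None,
    covering: bool = True,
) -> ClassifierSet:
    """All matching macroclassifiers, covering until theta_mna actions exist.

    Covering creates new classifiers (inserted with capacity enforcement and
    the match set rebuilt) while fewer than ``theta_mna`` *distinct actions*
    are represented.  With ``covering=False`` the raw filter is returned.
    """
    if len(state) != pop.n_bits:
        raise ValueError("state length does not match the population")
    s = np.int64(state_to_int(state))
    midx = np.empty(len(pop._cmask), np.int64)
    if covering:
        if params.theta_mna > pop.n_actions:
            raise ValueError(
                f"theta_mna={params.theta_mna} exceeds the {pop.n_actions} "
                "available actions; covering cannot terminate"
            )
        if rng is None:
            raise ValueError("covering requires a random source")
        present = np.zeros(pop.n_actions, np.bool_)
        cnt = K._match_covering(
            *pop._args, s, np.int64(pop.n_bits), np.int64(pop.n_actions),
            params.to_array(), rng.state, midx, present,
        )
    else:
        cnt = K._find_matches(
            pop._cmask, pop._cval, pop._alive, pop._meta[K.META_HW], s, midx
        )
    slots = midx[:cnt].copy()
    return ClassifierSet(slots, pop._gen[slots].copy())


def cover(
    state: str,
    present_actions: Iterable[int],
    params: XcsParams,
    rng: Rng,
    n_actions: int | None = None,
) -> Classifier:
    """Create one covering classifier for ``state``.

    The condition starts as the state and each character independently
    becomes '#' with probability ``p_hash``; the action is uniform over the
    actions not already present; statistics start at the configured initial
    prediction, error and fitness.
    """
    n_bits = len(state)
    n_act = n_actions if n_actions is not None else n_bits + 1
    present = np.zeros(n_act, np.bool_)
    for a in present_actions:
        present[a] = True
    if present.all():
        raise ValueError("no absent action to cover (theta_mna exceeds actions)")
    m, v, act = K._cover_new(
        np.int64(state_to_int(state)), present, np.int64(n_bits),
        np.int64(n_act), params.to_array(), rng.state,
    )
    return Classifier(
        condition=masks_to_condition(int(m), int(v), n_bits),
        action=int(act),
        prediction=params.p_init,
        error=params.eps_init,
        fitness=params.f_init,
    )


def build_prediction_array(
    pop: Population, match_set: ClassifierSet
) -> dict[int, float]:
    """Fitness-weighted mean prediction per advocated action.

    Actions with no supporting classifier are absent; an action whose total
    fitness is zero falls back to the unweighted mean of its predictions.
    """
    n_act = pop.n_actions
    pa = np.zeros(n_act, np.float64)
    fsum = np.zeros(n_act, np.float64)
    usum = np.zeros(n_act, np.float64)
    nsup = np.zeros(n_act, np.int64)
    K._prediction_array(
        pop._cact, pop._pred, pop._fit, match_set.slots,
        np.int64(len(match_set.slots)), pa, fsum, usum, nsup,
    )
    return {int(a): float(pa[a]) for a in range(n_act) if nsup[a] > 0}


def select_action(
    prediction_array: dict[int, float],
    rng: Rng | None = None,
    greedy: bool = False,
    n_actions: int | None = None,
) -> int:
    """Deterministic payoff-threshold action chooser.

    In greedy (evaluation) mode, or when the best predicted payoff exceeds
    500, returns the argmax with ties broken toward the smallest action
    index; otherwise (including a best prediction of exactly 500) a uniform
    random present action.
    """
    if not prediction_array:
        raise ValueError("no action available: empty prediction array")
    n_act = n_actions if n_actions is not None else max(prediction_array) + 1
    pa = np.zeros(n_act, np.float64)
    nsup = np.zeros(n_act, np.int64)
    for a, v in prediction_array.items():
        pa[a] = v
        nsup[a] = 1
    if not greedy and rng is None:
        raise ValueError("non-greedy selection requires a random source")
    state = rng.state if rng is not None else np.zeros(1, np.uint64)
    return int(K._select_action(pa, nsup, greedy, state))


def compute_target_P(
    prev_reward: float, prediction_array: dict[int, float], gamma: float
) -> float:
    """Backed-up payoff target: previous reward plus discounted best payoff."""
    best = max(prediction_array.values()) if prediction_array else 0.0
    return prev_reward + gamma * best


def classifier_accuracy(error: float, params: XcsParams) -> float:
    """Accuracy kappa: 1 below eps_0, else alpha * (eps / eps_0) ** -nu."""
    if error < params.eps_0:
        return 1.0
    return params.alpha * (error / params.eps_0) ** (-params.nu)


def update_action_set(
    pop: Population, action_set: ClassifierSet, target_p: float, params: XcsParams
) -> None:
    """Reinforce one action set toward the payoff target ``target_p``.

    Experience, prediction, error and action-set-size use the two-tier MAM
    rule; fitness moves toward the numerosity-weighted relative accuracy at
    rate beta; action-set subsumption runs afterwards if enabled.
    """
    K._update_action_set(
        *pop._args, action_set.slots, action_set.gens,
        np.int64(len(action_set.slots)), float(target_p),
        np.int64(pop.n_bits), params.to_array(),
    )


def action_set_subsumption(
    pop: Population, action_set: ClassifierSet, params: XcsParams
) -> None:
    """Let the most general accurate, experienced member absorb the rest."""
    K._action_set_subsumption(
        *pop._args, action_set.slots, action_set.gens,
        np.int64(len(action_set.slots)), np.int64(pop.n_bits), params.to_array(),
    )


def run_ga(
    pop: Population,
    action_set: ClassifierSet,
    situation: str,
    params: XcsParams,
    rng: Rng,
) -> None:
    """Run the niche GA on one action set (no-op unless theta_ga has lapsed)."""
    K._run_ga(
        *pop._args, action_set.slots, action_set.gens,
        np.int64(len(action_set.slots)), np.int64(state_to_int(situation)),
        np.int64(pop.n_bits), np.int64(pop.n_actions), params.to_array(),
        rng.state,
    )


def crossover_two_point(cond1: str, cond2: str, rng: Rng) -> tuple[str, str]:
    """Two cut points drawn uniformly in [0, N]; characters in [x, y) swapped."""
    if len(cond1) != len(cond2):
        raise ValueError("conditions have different lengths")
    n = len(cond1)
    m1, v1 = condition_to_masks(cond1)
    m2, v2 = condition_to_masks(cond2)
    nm1, nv1, nm2, nv2 = K._crossover_two_point(
        np.int64(m1), np.int64(v1), np.int64(m2), np.int64(v2),
        np.int64(n), rng.state,
    )
    return (
        masks_to_condition(int(nm1), int(nv1), n),
        masks_to_condition(int(nm2), int(nv2), n),
    )


def mutate_classifier(
    cl: Classifier, situation: str, params: XcsParams, rng: Rng
) -> Classifier:
    """Niche mutation: '#' <-> the situation's literal; action re-drawn.

    Each condition index mutates with probability mu (a literal becomes '#',
    a '#' becomes the situation's bit); with probability mu the action is
    replaced by a uniformly random different action.  The result always
    still matches the situation.
    """
    if len(situation) != len(cl.condition):
        raise ValueError("situation length does not match the condition")
    n = len(cl.condition)
    m, v = condition_to_masks(cl.condition)
    nm, nv, na = K._mutate(
        np.int64(m), np.int64(v), np.int64(cl.action),
        np.int64(state_to_int(situation)), np.int64(n), np.int64(n + 1),
        params.to_array(), rng.state,
    )
    out = cl.copy()
    out.condition = masks_to_condition(int(nm), int(nv), n)
    out.action = int(na)
    return out


def delete_to_capacity(pop: Population, params: XcsParams, rng: Rng) -> None:
    """Roulette-delete micro-classifiers until the population fits in R."""
    K._delete_to_capacity(*pop._args, params.to_array(), rng.state)


def insert_classifier(pop: Population, cl: Classifier) -> int:
    """Insert ``cl`` (duplicates merge by numerosity); returns the slot."""
    return pop.add(cl)


def deletion_votes(pop: Population, params: XcsParams) -> dict[int, float]:
    """The deletion vote of every live slot (for inspection and testing).

    A classifier's vote is its action-set-size estimate times numerosity;
    experienced classifiers whose per-copy fitness falls below ``delta``
    times the population mean have the vote inflated by mean / own fitness.
    """
    hw = int(pop._meta[K.META_HW])
    votes = np.empty(hw, np.float64)
    K._deletion_votes(
        pop._fit, pop._num, pop._expn, pop._asz, pop._alive,
        np.int64(hw), params.to_array(), votes,
    )
    return {s: float(votes[s]) for s in pop.slots()}


# ---------------------------------------------------------------------------
# rule-line serialization: `####1 : 2 [174.82/0.9105]`

_RULE_RE = re.compile(
    r"^\s*(?P<cond>[01#]+)\s*:\s*(?P<act>\d+)\s*"
    r"\[\s*(?P<pred>-?\d+(?:\.\d+)?)\s*/\s*(?P<fit>-?\d+(?:\.\d+)?)\s*\]\s*$"
)


def format_rule(cl: Classifier) -> str:
    """One rule line: condition, action, and [prediction/fitness]."""
    return f"{cl.condition} : {cl.action} [{cl.prediction:.2f}/{cl.fitness:.4f}]"


def parse_rule(line: str) -> Classifier:
    m = _RULE_RE.match(line)
    if not m:
        raise ValueError(f"malformed rule line: {line!r}")
    return Classifier(
        condition=m.group("cond"),
        action=int(m.group("act")),
        prediction=float(m.group("pred")),
        fitness=float(m.group("fit")),
    )


def write_ruleset(rules: Sequence[Classifier], path) -> None:
    with open(path, "w") as fh:
        for cl in rules:
            fh.write(format_rule(cl) + "\n")


def read_ruleset(path) -> list[Classifier]:
    rules = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rules.append(parse_rule(line))
    return rules
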