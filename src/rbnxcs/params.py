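"""The XCS parameter ledger and its flat key-value serialization.

Defaults are the tuned settings for controlling N=5, K=2 networks; every
field is documented with its role in the engine.  The probabilistic
exploration rate of the original XCS is not a field here: this engine always
uses the deterministic payoff-threshold action chooser (explore when the best
predicted payoff is at most half of the 1000 maximum), which is what
``use_new_action_chooser`` records.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
import yaml

__all__ = ["XcsParams"]

# fixed slot layout of XcsParams.to_array(), consumed by the numba kernels
P_R = 0
P_GAMMA = 1
P_THETA_MNA = 2
P_HASH = 3
P_INIT = 4
P_EPS_INIT = 5
P_F_INIT = 6
P_EPS0 = 7
P_THETA_GA = 8
P_THETA_DEL = 9
P_BETA = 10
P_ALPHA = 11
P_NU = 12
P_CHI = 13
P_MU = 14
P_DELTA = 15
P_THETA_SUB = 16
P_DO_AS_SUB = 17
P_DO_GA_SUB = 18
N_PARAMS = 19

# accepted spelling variants in parameter files
_ALIASES = {
    "r": "R",
    "eps0": "eps_0",
    "epsI": "eps_init",
    "pI": "p_init",
    "fI": "f_init",
    "pHash": "p_hash",
    "thetaMna": "theta_mna",
    "thetaGa": "theta_ga",
    "thetaDel": "theta_del",
    "thetaSub": "theta_sub",
    "doActionSetSubsumption": "do_action_set_subsumption",
    "doGaSubsumption": "do_ga_subsumption",
    "useNewActionChooser": "use_new_action_chooser",
}


@dataclass(frozen=True)
class XcsParams:
    """Complete parameter record of the classifier engine.

    Attributes
    ----------
    R : int
        Maximum rule population size in micro-classifiers; deletion enforces
        this capacity after every insertion.
    gamma : float
        Discount factor linking the payoff backed up to the previous action
        set to the best prediction of the current step.
    theta_mna : int
        Minimum number of *distinct actions* required in a match set before
        covering stops creating new rules; must not exceed the number of
        available actions (N + 1, including "no action").
    p_hash : float
        Per-character probability that a covering condition generalises a
        state bit to '#'.
    p_init, eps_init, f_init : float
        Initial prediction, prediction error and fitness of covered rules.
    eps_0 : float
        Error threshold: below it a classifier counts as fully accurate and
        becomes eligible to subsume.
    theta_ga : float
        Mean action-set age (in engine steps) that triggers a GA invocation.
    theta_del : float
        Experience beyond which unfit classifiers receive inflated deletion
        votes.
    beta : float
        Learning rate of the Widrow-Hoff updates; classifiers younger than
        1/beta updates use straight incremental averaging instead (the
        two-tier "moyenne adaptive modifiee" scheme).
    alpha, nu : float
        Accuracy fall-off outside eps_0: accuracy = alpha * (eps/eps_0)**-nu.
    chi : float
        Two-point crossover probability in the GA.
    mu : float
        Per-index mutation probability in the GA (niche mutation).
    delta : float
        Fraction of the mean population fitness below which experienced
        classifiers are deleted more aggressively.
    theta_sub : float
        Experience a classifier needs before it may subsume others.
    do_action_set_subsumption, do_ga_subsumption : bool
        Enable subsumption in the action set / in the GA.
    use_new_action_chooser : bool
        Record that the deterministic payoff-threshold chooser is in use;
        only ``True`` is supported.
    """

    R: int = 790
    gamma: float = 0.76
    theta_mna: int = 6
    p_hash: float = 0.4
    p_init: float = 7.4
    eps_init: float = 1.0
    f_init: float = 0.03
    eps_0: float = 18.5
    theta_ga: float = 260.0
    theta_del: float = 32.0
    beta: float = 0.01
    alpha: float = 0.087
    nu: float = 0.01
    chi: float = 0.711
    mu: float = 0.263
    delta: float = 0.05
    theta_sub: float = 31.579
    do_action_set_subsumption: bool = True
    do_ga_subsumption: bool = True
    use_new_action_chooser: bool = True

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be a positive micro-classifier capacity")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.theta_mna < 1:
            raise ValueError("theta_mna must be at least 1")
        for name in ("p_hash", "chi", "mu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")
        if self.eps_0 <= 0:
            raise ValueError("eps_0 must be positive")
        if not self.use_new_action_chooser:
            raise ValueError(
                "only the deterministic payoff-threshold action chooser is "
                "implemented; use_new_action_chooser must be True"
            )

    def to_array(self) -> np.ndarray:
        """Pack the numeric fields into the fixed float64 kernel layout."""
        a = np.zeros(N_PARAMS, dtype=np.float64)
        a[P_R] = self.R
        a[P_GAMMA] = self.gamma
        a[P_THETA_MNA] = self.theta_mna
        a[P_HASH] = self.p_hash
        a[P_INIT] = self.p_init
        a[P_EPS_INIT] = self.eps_init
        a[P_F_INIT] = self.f_init
        a[P_EPS0] = self.eps_0
        a[P_THETA_GA] = self.theta_ga
        a[P_THETA_DEL] = self.theta_del
        a[P_BETA] = self.beta
        a[P_ALPHA] = self.alpha
        a[P_NU] = self.nu
        a[P_CHI] = self.chi
        a[P_MU] = self.mu
        a[P_DELTA] = self.delta
        a[P_THETA_SUB] = self.theta_sub
        a[P_DO_AS_SUB] = 1.0 if self.do_action_set_subsumption else 0.0
        a[P_DO_GA_SUB] = 1.0 if self.do_ga_subsumption else 0.0
        return a

    def replace(self, **kw) -> "XcsParams":
        return replace(self, **kw)

    def to_yaml(self, path) -> None:
        """Write the parameters as a flat key-value document."""
        doc = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "XcsParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        kw = {}
        for key, value in raw.items():
            name = _ALIASES.get(key, key)
            if name not in known:
                raise ValueError(f"unknown parameter {key!r}")
            kw[name] = value
        return cls(**kw)
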