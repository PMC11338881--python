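"""Functional-contextual expected utility and values-shaped MDP evaluation.

Functional contextualism insists that the worth of an action is a function
of the outcome *and* its context.  With a context Con = (w, s, t, i) —
world state, internal state, time, individual — expected utility becomes

    EU(A) = Σ_{o ∈ O} P_A(o | w, s, t, i) · U(o, w, s, t, i).

For sequential decisions the same idea enters a tabular MDP by shaping the
reward with a values score AV(s, a) (how well the action aligns with the
agent's adopted values, supplied as a table in the spirit of acceptance and
commitment therapy):

    R'(s, a) = R(s, a) + λ·AV(s, a)

and the policy value functions are the usual discounted Bellman fixed
points of the shaped reward.  The weight λ trades off task reward against
values alignment; above a problem-specific threshold it flips the optimal
policy away from reward-greedy but misaligned behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, DomainError, ValidationError

__all__ = [
    "WILDCARD",
    "Context",
    "OutcomeModel",
    "TabularMDP",
    "PolicyValue",
    "contextual_expected_utility",
    "act_reward",
    "evaluate_policy",
]

PROB_TOL = 1e-9
#: Declared wildcard usable for any context component.
WILDCARD = "*"


@dataclass(frozen=True)
class Context:
    """Functional context Con = (w, s, t, i)."""

    w: str
    s: str
    t: str
    i: str

    def key(self) -> tuple[str, str, str, str]:
        return (self.w, self.s, self.t, self.i)


@dataclass
class OutcomeModel:
    """Outcome probabilities and utilities conditioned on action and context.

    ``prob[(action, context_key, outcome)]`` and
    ``utility[(outcome, context_key)]`` with ``context_key = Context.key()``.
    For every (action, context) row present, probabilities must sum to 1.
    """

    outcomes: set[str]
    prob: dict[tuple[str, tuple, str], float] = field(default_factory=dict)
    utility: dict[tuple[str, tuple], float] = field(default_factory=dict)

    def row(self, action: str, con: Context) -> dict[str, float]:
        key = con.key()
        row = {
            o: p for (a, c, o), p in self.prob.items() if a == action and c == key
        }
        if not row:
            raise DomainError(
                f"outcome model has no row for action {action!r} in context {key}"
            )
        total = sum(row.values())
        if abs(total - 1.0) > PROB_TOL:
            raise ValidationError(
                f"probabilities for ({action!r}, {key}) sum to {total!r}, not 1"
            )
        return row


def contextual_expected_utility(
    action: str, con: Context, model: OutcomeModel
) -> float:
    """EU(A) = Σ_o P_A(o | Con) · U(o, Con) for the given action and context."""
    row = model.row(action, con)
    key = con.key()
    eu = 0.0
    for outcome, p in row.items():
        try:
            u = model.utility[(outcome, key)]
        except KeyError:
            raise DomainError(
                f"utility undefined for outcome {outcome!r} in context {key}"
            ) from None
        eu += p * u
    return eu


@dataclass
class TabularMDP:
    """Finite MDP with a base reward and a values (AV) table.

    ``transition[(s, a)]`` maps successor states to probabilities (each row
    sums to 1); ``base_reward`` and ``act_value`` are (s, a) tables; ``gamma``
    is the discount, ``lam`` the values-shaping weight λ.
    """

    states: tuple[str, ...]
    actions: tuple[str, ...]
    transition: dict[tuple[str, str], dict[str, float]]
    base_reward: dict[tuple[str, str], float]
    act_value: dict[tuple[str, str], float]
    gamma: float
    lam: float = 0.0

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        self.actions = tuple(self.actions)
        if not 0 <= self.gamma < 1:
            raise ConfigurationError("discount gamma must lie in [0, 1)")
        if self.lam < 0:
            raise ConfigurationError("shaping weight lambda must be non-negative")
        for (s, a), row in self.transition.items():
            if s not in self.states or a not in self.actions:
                raise ConfigurationError(f"transition row for unknown pair ({s!r}, {a!r})")
            total = sum(row.values())
            if abs(total - 1.0) > PROB_TOL:
                raise ValidationError(
                    f"transition row ({s!r}, {a!r}) sums to {total!r}, not 1"
                )
            unknown = set(row) - set(self.states)
            if unknown:
                raise ConfigurationError(
                    f"transition row ({s!r}, {a!r}) targets unknown states {sorted(unknown)}"
                )


def act_reward(mdp: TabularMDP, s: str, a: str) -> float:
    """Shaped reward R'(s, a) = R(s, a) + λ·AV(s, a)."""
    if s not in mdp.states or a not in mdp.actions:
        raise DomainError(f"unknown state/action pair ({s!r}, {a!r})")
    return mdp.base_reward[(s, a)] + mdp.lam * mdp.act_value[(s, a)]


@dataclass
class PolicyValue:
    """A policy with its state and action value tables under shaped reward."""

    policy: dict[str, dict[str, float]]
    V: dict[str, float]
    Q: dict[tuple[str, str], float]


def evaluate_policy(
    mdp: TabularMDP,
    policy: Mapping[str, Mapping[str, float]],
    *,
    max_direct_states: int = 500,
    tol: float = 1e-12,
) -> PolicyValue:
    """Solve the Bellman expectation equations for the shaped reward.

        V(s)    = Σ_a π(a|s) · Q(s, a)
        Q(s, a) = R'(s, a) + γ · Σ_{s'} T(s'|s, a) · V(s')

    The linear system is solved directly for up to ``max_direct_states``
    states, otherwise by value iteration to residual ``tol``.  The fixed
    point is unique for γ < 1.
    """
    states = mdp.states
    n = len(states)
    idx = {s: k for k, s in enumerate(states)}
    for s in states:
        if s not in policy:
            raise DomainError(f"policy undefined for state {s!r}")
        total = sum(policy[s].values())
        if abs(total - 1.0) > PROB_TOL:
            raise ValidationError(f"policy row for {s!r} sums to {total!r}, not 1")

    # policy-averaged reward and transition matrix
    r_pi = np.zeros(n)
    P_pi = np.zeros((n, n))
    for s in states:
        for a, pa in policy[s].items():
            if pa == 0:
                continue
            r_pi[idx[s]] += pa * act_reward(mdp, s, a)
            for s2, p in mdp.transition[(s, a)].items():
                P_pi[idx[s], idx[s2]] += pa * p

    if n <= max_direct_states:
        v = np.linalg.solve(np.eye(n) - mdp.gamma * P_pi, r_pi)
    else:
        v = np.zeros(n)
        while True:
            v_new = r_pi + mdp.gamma * P_pi @ v
            if np.max(np.abs(v_new - v)) < tol:
                v = v_new
                break
            v = v_new

    V = {s: float(v[idx[s]]) for s in states}
    Q = {}
    for s in states:
        for a in mdp.actions:
            if (s, a) not in mdp.transition:
                continue
            q = act_reward(mdp, s, a) + mdp.gamma * sum(
                p * V[s2] for s2, p in mdp.transition[(s, a)].items()
            )
            Q[(s, a)] = float(q)
    return PolicyValue({s: dict(policy[s]) for s in states}, V, Q)
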