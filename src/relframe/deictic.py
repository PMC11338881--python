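"""Deictic (perspective-taking) frames and observer-centric belief rules.

Deictic frames locate experience relative to the speaker along three
dimensions — interpersonal (I/YOU), spatial (HERE/THERE), temporal
(NOW/THEN).  Shifting a deictic frame swaps the pole: the same machinery
that answers "what do *I* feel" answers "what would *you* feel".  On top of
the frames this module provides:

* ``i_see`` — the observer's internal representation of another agent's
  state (the elementary theory-of-mind read-out);
* ``take_perspective`` — the observer's state temporarily transforms to
  match the target's (reversible via the returned event);
* two observer-centric belief utilities: the subjective-Bayesian
  (QBist) reformulation of outcome probability in terms of a reference
  measurement, and the Born rule on state vectors.

State labels are an open vocabulary: emotional states (pain, joy, neutral)
and value labels (kindness, patience, ...) flow through identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, MissingStateError, ValidationError

__all__ = [
    "DeicticFrame",
    "INTERPERSONAL",
    "SPATIAL",
    "TEMPORAL",
    "STANDARD_FRAMES",
    "AgentState",
    "AgentStateMap",
    "PerspectiveEvent",
    "BeliefModel",
    "StateVector",
    "shift_perspective",
    "i_see",
    "take_perspective",
    "revert_perspective",
    "qbism_probability",
    "born_probability",
]

#: Tolerance for probability-normalization checks (pure arithmetic, no noise).
NORM_TOL = 1e-9


@dataclass(frozen=True)
class DeicticFrame:
    """One deictic dimension with its ordered pair of poles."""

    dimension: str
    poles: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.poles) != 2 or len(set(self.poles)) != 2:
            raise DomainError("a deictic frame has exactly two distinct poles")


INTERPERSONAL = DeicticFrame("interpersonal", ("I", "YOU"))
SPATIAL = DeicticFrame("spatial", ("HERE", "THERE"))
TEMPORAL = DeicticFrame("temporal", ("NOW", "THEN"))
STANDARD_FRAMES = {f.dimension: f for f in (INTERPERSONAL, SPATIAL, TEMPORAL)}


def shift_perspective(frame: DeicticFrame, pole: str) -> str:
    """Return the opposite pole of ``frame``; an involution (shift∘shift = id)."""
    a, b = frame.poles
    if pole == a:
        return b
    if pole == b:
        return a
    raise DomainError(f"pole {pole!r} does not belong to the {frame.dimension} frame")


@dataclass(frozen=True)
class AgentState:
    """An agent's state label at a time point."""

    agent: str
    state: str
    time: str = "t0"

    def __post_init__(self) -> None:
        if not self.state:
            raise DomainError("state label must be non-empty")


class AgentStateMap:
    """Mutable map (agent, time) → state label."""

    def __init__(self, states: "AgentStateMap | list[AgentState] | None" = None):
        if isinstance(states, AgentStateMap):
            self._states = dict(states._states)
        else:
            self._states = {(s.agent, s.time): s.state for s in (states or [])}

    def set(self, agent: str, state: str, time: str = "t0") -> None:
        self._states[(agent, time)] = state

    def get(self, agent: str, time: str | None = None) -> str:
        if time is not None:
            try:
                return self._states[(agent, time)]
            except KeyError:
                raise MissingStateError(
                    f"agent {agent!r} has no state at time {time!r}"
                ) from None
        hits = sorted(t for (a, t) in self._states if a == agent)
        if not hits:
            raise MissingStateError(f"agent {agent!r} has no recorded state")
        if len(hits) > 1:
            raise MissingStateError(
                f"agent {agent!r} has states at several times {hits}; pass `time`"
            )
        return self._states[(agent, hits[0])]

    def items(self):
        return sorted(self._states.items())

    def copy(self) -> "AgentStateMap":
        return AgentStateMap(self)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AgentStateMap) and self._states == other._states

    def __repr__(self) -> str:
        return f"AgentStateMap({self._states!r})"


@dataclass(frozen=True)
class PerspectiveEvent:
    """Record of one perspective-taking act, sufficient to revert it."""

    observer: str
    target: str
    time: str
    acquired_state: str
    prior_state: str
    persistent: bool = False


def i_see(
    observer: str,
    target: str,
    states: AgentStateMap | list[AgentState],
    time: str | None = None,
) -> str:
    """The observer's representation of the target's current state.

    ``i_see(I, YOU)`` returns YOU's state label — self-observation
    (``observer == target``) simply reads the observer's own state.
    """
    smap = states if isinstance(states, AgentStateMap) else AgentStateMap(states)
    return smap.get(target, time)


def take_perspective(
    observer: str,
    target: str,
    t: str,
    states: AgentStateMap | list[AgentState],
    *,
    persistent: bool = False,
) -> tuple[AgentStateMap, PerspectiveEvent]:
    """Observer's state at ``t`` transforms to match the target's.

    Returns the updated state map and a :class:`PerspectiveEvent` recording
    the prior state so :func:`revert_perspective` can undo the (by default
    temporary) transformation.  The target is never modified.
    """
    smap = states if isinstance(states, AgentStateMap) else AgentStateMap(states)
    prior = smap.get(observer, t)
    acquired = smap.get(target, t)
    out = smap.copy()
    out.set(observer, acquired, t)
    event = PerspectiveEvent(observer, target, t, acquired, prior, persistent)
    return out, event


def revert_perspective(
    states: AgentStateMap, event: PerspectiveEvent
) -> AgentStateMap:
    """Undo a perspective-taking event, restoring the observer's prior state."""
    out = states.copy()
    out.set(event.observer, event.prior_state, event.time)
    return out


@dataclass
class BeliefModel:
    """Observer's probabilities for a reference measurement of dimension ``d``.

    ``p`` holds the observer's probabilities for the d² outcomes of an
    informationally complete reference measurement; ``r[i][j]`` is the
    conditional probability of outcome ``j`` of the measurement of interest
    given reference outcome ``i`` (rows are indexed by ``i`` and each row
    sums to 1).
    """

    d: int
    p: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        n = self.d * self.d
        if self.d < 1:
            raise ValidationError("system dimension d must be a positive integer")
        if self.p.shape != (n,):
            raise ValidationError(f"p must have d²={n} entries, got {self.p.shape}")
        if self.r.shape[0] != n:
            raise ValidationError(f"r must have d²={n} rows, got {self.r.shape}")
        if np.any(self.p < -NORM_TOL) or np.any(self.p > 1 + NORM_TOL):
            raise ValidationError("entries of p must lie in [0, 1]")
        if np.any(self.r < -NORM_TOL) or np.any(self.r > 1 + NORM_TOL):
            raise ValidationError("entries of r must lie in [0, 1]")
        if abs(self.p.sum() - 1.0) > NORM_TOL:
            raise ValidationError(f"p must sum to 1, got {self.p.sum()!r}")
        rowsums = self.r.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > NORM_TOL):
            raise ValidationError("each row r(·|i) must sum to 1")

    @property
    def n_outcomes(self) -> int:
        return self.r.shape[1]


def qbism_probability(model: BeliefModel, j: int) -> float:
    """Probability of outcome ``j`` via the reference-measurement rule.

        p(j) = Σ_{i=1..d²} [ (d+1)·p(i) − 1/d ] · r(j|i)

    ``j`` is 1-based to match the conventional Σ_{i=1}^{d²} indexing.  For a
    valid model (p on the simplex, r row-stochastic) the outputs over all j
    sum to (d+1) − d²/d = 1, so the rule returns a genuine distribution.
    """
    if not 1 <= j <= model.n_outcomes:
        raise DomainError(f"outcome index {j} out of range 1..{model.n_outcomes}")
    coeff = (model.d + 1) * model.p - 1.0 / model.d
    return float(coeff @ model.r[:, j - 1])


@dataclass(frozen=True)
class StateVector:
    """A unit-norm complex state vector."""

    amplitudes: tuple = field()

    def __init__(self, amplitudes) -> None:
        arr = np.asarray(amplitudes, dtype=complex)
        if arr.ndim != 1:
            raise ValidationError("state vector must be one-dimensional")
        norm2 = float(np.vdot(arr, arr).real)
        if abs(norm2 - 1.0) > NORM_TOL:
            raise ValidationError(f"state vector must be unit norm, |ψ|²={norm2!r}")
        object.__setattr__(self, "amplitudes", tuple(arr.tolist()))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.amplitudes, dtype=complex)


def born_probability(phi: StateVector, psi: StateVector) -> float:
    """Transition probability ``|⟨Φ|Ψ⟩|²`` between two unit-norm states."""
    a, b = phi.as_array(), psi.as_array()
    if a.shape != b.shape:
        raise DomainError(f"dimension mismatch: {a.shape} vs {b.shape}")
    amp = np.vdot(a, b)
    return float(min(1.0, abs(amp) ** 2))
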