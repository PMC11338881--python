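"""Relational algebra for arbitrarily applicable relational responding (AARR).

Relational frame theory treats verbal cognition as responding to *relations*
between stimuli rather than to stimuli in isolation.  A trained relation is a
triple ``(x, y, rel)`` — "x stands in relation *rel* to y".  From a set of
trained relations an agent derives new ones without further training:

* **mutual entailment** — from ``(a, b, rel)`` derive ``(b, a, opposite(rel))``
  (for symmetric frames such as coordination the relation is its own opposite);
* **combinatorial entailment** — from chains ``a rel c``, ``c rel b`` of the
  same transitive relation type derive ``a rel b``, for chains of any length;
* **transformation of stimulus function (ToF)** — a stimulus acquires the
  psychological function (fear, appetitive, ...) of a stimulus it is related
  to under a licensing contextual cue.

This module provides the relation store, the derivation engine, full
entailment closure with an inconsistency report, and the ToF operator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .errors import ConfigurationError, DegenerateQueryError, DomainError

__all__ = [
    "CANNOT_BE_DETERMINED",
    "INCONSISTENT",
    "RelationType",
    "Relation",
    "TypeRegistry",
    "RelationStore",
    "FunctionMap",
    "ContextCue",
    "ClosureResult",
    "default_registry",
    "add_relation",
    "derive_relation",
    "entailment_closure",
    "transform_function",
]

logger = logging.getLogger(__name__)

#: Sentinel returned when no trained or derivable relation links two stimuli.
CANNOT_BE_DETERMINED = "cannot be determined"
#: Sentinel returned when distinct derivation paths yield conflicting types.
INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class RelationType:
    """A registered family of relational responding.

    Parameters
    ----------
    name:
        Label of the relation type (``"greater_than"``, ``"coordination"`` ...).
    opposite:
        Name of the type obtained by reversing the relata, if one is defined
        (``greater_than`` ↔ ``less_than``).  Symmetric types are implicitly
        their own opposite and must not declare a different one.
    symmetric:
        ``(x, y, rel)`` implies ``(y, x, rel)``.
    transitive:
        Same-type chains entail the end-to-end relation (combinatorial
        entailment).
    """

    name: str
    opposite: str | None = None
    symmetric: bool = False
    transitive: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("relation type name must be non-empty")
        if self.symmetric and self.opposite not in (None, self.name):
            raise ConfigurationError(
                f"symmetric type {self.name!r} must be its own opposite, "
                f"got {self.opposite!r}"
            )


@dataclass(frozen=True)
class Relation:
    """A single trained (or derived) relation ``(x, y, rel)`` with a weight."""

    x: str
    y: str
    rel: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.x or not self.y:
            raise DomainError("stimulus ids must be non-empty")
        if self.weight < 0:
            raise ConfigurationError("relation weight must be non-negative")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.x, self.y, self.rel)


class TypeRegistry:
    """Registry of relation types with opposite/symmetry/transitivity flags."""

    def __init__(self, types: Iterable[RelationType] = ()):
        self._types: dict[str, RelationType] = {}
        for t in types:
            self.register(t)

    def register(self, t: RelationType) -> None:
        self._types[t.name] = t
        self._check_opposites(t)

    def _check_opposites(self, t: RelationType) -> None:
        # opposite(opposite(r)) = r whenever both directions are registered
        if t.opposite is not None and t.opposite in self._types:
            back = self._types[t.opposite].opposite
            if back is not None and back != t.name:
                raise ConfigurationError(
                    f"opposite of {t.opposite!r} is {back!r}, expected {t.name!r}"
                )
        for other in self._types.values():
            if other.opposite == t.name and t.opposite not in (None, other.name):
                raise ConfigurationError(
                    f"{other.name!r} declares opposite {t.name!r}, but {t.name!r} "
                    f"declares opposite {t.opposite!r}"
                )

    def __contains__(self, name: str) -> bool:
        return name in self._types

    def __getitem__(self, name: str) -> RelationType:
        try:
            return self._types[name]
        except KeyError:
            raise ConfigurationError(f"relation type {name!r} is not registered") from None

    def __iter__(self) -> Iterator[RelationType]:
        return iter(self._types.values())

    def names(self) -> list[str]:
        return sorted(self._types)

    def opposite_of(self, name: str) -> str | None:
        """Name of the reversed-relata type: itself for symmetric types."""
        t = self[name]
        if t.symmetric:
            return t.name
        return t.opposite


def default_registry() -> TypeRegistry:
    """Registry preloaded with the frame families used throughout the toolkit.

    The comparative opposites (greater/less, bigger/smaller) and the kinship
    pair child_of/parent_of are exemplary, not exhaustive; callers register
    further types as needed.
    """
    return TypeRegistry(
        [
            RelationType("greater_than", opposite="less_than", transitive=True),
            RelationType("less_than", opposite="greater_than", transitive=True),
            RelationType("bigger_than", opposite="smaller_than", transitive=True),
            RelationType("smaller_than", opposite="bigger_than", transitive=True),
            RelationType("coordination", symmetric=True, transitive=True),
            RelationType("distinction", symmetric=True),
            RelationType("opposition", symmetric=True),
            RelationType("hierarchy", transitive=True),
            RelationType("causality", transitive=True),
            RelationType("contains", transitive=True),
            RelationType("child_of", opposite="parent_of"),
            RelationType("parent_of", opposite="child_of"),
            RelationType("deictic"),
            RelationType("temporal"),
            RelationType("spatial"),
        ]
    )


class RelationStore:
    """A set of relations plus the registry interpreting their types.

    Duplicate ``(x, y, rel)`` triples collapse (set semantics); a symmetric
    relation is stored once and its mirror is implied at query time.
    """

    def __init__(self, registry: TypeRegistry | None = None,
                 relations: Iterable[Relation] = ()):
        self.registry = registry if registry is not None else default_registry()
        self._relations: dict[tuple[str, str, str], Relation] = {}
        for r in relations:
            self.add(r)

    # -- basic container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._relations)

    def __iter__(self) -> Iterator[Relation]:
        return iter(sorted(self._relations.values(), key=lambda r: r.key))

    def __contains__(self, key: tuple[str, str, str] | Relation) -> bool:
        if isinstance(key, Relation):
            key = key.key
        return key in self._relations

    def add(self, r: Relation) -> "RelationStore":
        if r.rel not in self.registry:
            raise ConfigurationError(
                f"relation type {r.rel!r} is not registered; known types: "
                f"{', '.join(self.registry.names())}"
            )
        self._relations[r.key] = r
        return self

    def copy(self) -> "RelationStore":
        return RelationStore(self.registry, self._relations.values())

    @property
    def stimuli(self) -> set[str]:
        out: set[str] = set()
        for r in self._relations.values():
            out.add(r.x)
            out.add(r.y)
        return out

    # -- indexed views used by the derivation engine ------------------------------

    def edges_of_type(self, name: str) -> set[tuple[str, str]]:
        """Directed ``(x, y)`` pairs of the given type, mirrored if symmetric."""
        t = self.registry[name]
        pairs = {(r.x, r.y) for r in self._relations.values() if r.rel == name}
        if t.symmetric:
            pairs |= {(y, x) for (x, y) in pairs}
        return pairs

    def types_between(self, a: str, b: str) -> set[str]:
        """Types of trained relations from ``a`` to ``b`` (symmetry-aware)."""
        out = set()
        for r in self._relations.values():
            if (r.x, r.y) == (a, b):
                out.add(r.rel)
            elif (r.x, r.y) == (b, a) and self.registry[r.rel].symmetric:
                out.add(r.rel)
        return out


def add_relation(store: RelationStore, r: Relation) -> RelationStore:
    """Insert ``r`` into ``store`` (set semantics) and return the store."""
    return store.add(r)


def _reachable(pairs: set[tuple[str, str]], start: str) -> set[str]:
    """Vertices reachable from ``start`` through ≥1 edge, with cycle detection."""
    adj: dict[str, set[str]] = {}
    for x, y in pairs:
        adj.setdefault(x, set()).add(y)
    seen: set[str] = set()
    frontier = list(adj.get(start, ()))
    while frontier:
        v = frontier.pop()
        if v in seen:
            continue
        seen.add(v)
        frontier.extend(adj.get(v, ()))
    return seen


def derive_relation(store: RelationStore, a: str, b: str) -> str:
    """Derive the relation holding from ``a`` to ``b``.

    Applies, in order: (1) direct lookup of a trained relation; (2) mutual
    entailment — a trained ``(b, a, rel)`` yields the opposite of ``rel``;
    (3) combinatorial entailment through same-type chains of transitive
    relations of any length (in either direction, the reverse chain yielding
    the opposite type); (4) otherwise :data:`CANNOT_BE_DETERMINED`.

    All derivation routes are evaluated; if they disagree on the relation
    type, :data:`INCONSISTENT` is returned rather than an arbitrary winner.
    """
    if a == b:
        raise DegenerateQueryError(f"cannot relate stimulus {a!r} to itself")
    if not a or not b:
        raise DomainError("stimulus ids must be non-empty")

    candidates: set[str] = set()

    # (1) direct lookup (symmetry-aware)
    candidates |= store.types_between(a, b)

    # (2) mutual entailment via registered opposites
    for rel in store.types_between(b, a):
        opp = store.registry.opposite_of(rel)
        if opp is not None:
            candidates.add(opp)

    # (3) combinatorial entailment: same-type transitive chains, any length
    for t in store.registry:
        if not t.transitive:
            continue
        pairs = store.edges_of_type(t.name)
        if not pairs:
            continue
        if b in _reachable(pairs, a):
            candidates.add(t.name)
        if a in _reachable(pairs, b):
            opp = store.registry.opposite_of(t.name)
            if opp is not None:
                candidates.add(opp)

    if not candidates:
        return CANNOT_BE_DETERMINED
    if len(candidates) > 1:
        return INCONSISTENT
    return candidates.pop()


@dataclass
class ClosureResult:
    """Entailment closure of a store plus any conflicts found on the way.

    ``inconsistencies`` lists ordered pairs that end up carrying both a
    relation type and its registered opposite — a genuine contradiction in
    the relational network (e.g. ``a greater_than b`` and ``a less_than b``).
    Conflicts are reported, never silently dropped: the closure retains both
    triples.
    """

    store: RelationStore
    inconsistencies: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)


def entailment_closure(store: RelationStore) -> ClosureResult:
    """Close a store under mutual and combinatorial entailment.

    Repeatedly (a) mirrors symmetric relations, (b) adds the registered
    opposite for reversed relata, and (c) joins same-type transitive chains,
    until a fixpoint is reached.  Idempotent and monotone: the result
    contains the input, and closing a closure changes nothing.  Derived
    relations carry weight 1.
    """
    reg = store.registry
    triples: set[tuple[str, str, str]] = {r.key for r in store}
    weights = {r.key: r.weight for r in store}

    changed = True
    while changed:
        changed = False
        new: set[tuple[str, str, str]] = set()
        by_type: dict[str, set[tuple[str, str]]] = {}
        for x, y, rel in triples:
            by_type.setdefault(rel, set()).add((x, y))
            t = reg[rel]
            if t.symmetric:
                new.add((y, x, rel))
            elif t.opposite is not None:
                new.add((y, x, t.opposite))
        for rel, pairs in by_type.items():
            if not reg[rel].transitive:
                continue
            succ: dict[str, set[str]] = {}
            for x, y in pairs:
                succ.setdefault(x, set()).add(y)
            for x, y in pairs:
                for z in succ.get(y, ()):
                    if z != x:
                        new.add((x, z, rel))
        if not new <= triples:
            triples |= new
            changed = True

    closed = RelationStore(reg)
    for x, y, rel in sorted(triples):
        closed.add(Relation(x, y, rel, weights.get((x, y, rel), 1.0)))

    # conflict scan: a pair related by both a type and its opposite
    by_pair: dict[tuple[str, str], set[str]] = {}
    for x, y, rel in triples:
        by_pair.setdefault((x, y), set()).add(rel)
    inconsistencies = []
    for (x, y), rels in sorted(by_pair.items()):
        conflict = any(
            reg.opposite_of(r) in rels and not reg[r].symmetric for r in rels
        )
        if conflict:
            inconsistencies.append((x, y, tuple(sorted(rels))))
    return ClosureResult(closed, inconsistencies)


class FunctionMap:
    """Mapping ``Cfunc`` from stimuli to psychological function labels."""

    def __init__(self, entries: Mapping[str, str] | None = None):
        self.entries: dict[str, str] = dict(entries or {})

    def __getitem__(self, stimulus: str) -> str:
        try:
            return self.entries[stimulus]
        except KeyError:
            raise DomainError(f"no function recorded for stimulus {stimulus!r}") from None

    def __contains__(self, stimulus: str) -> bool:
        return stimulus in self.entries

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FunctionMap) and self.entries == other.entries

    def __repr__(self) -> str:
        return f"FunctionMap({self.entries!r})"

    def copy(self) -> "FunctionMap":
        return FunctionMap(self.entries)


@dataclass(frozen=True)
class ContextCue:
    """Contextual cue ``Crel`` licensing a transformation of stimulus function."""

    crel: str


def transform_function(
    fmap: FunctionMap,
    store: RelationStore,
    cue: ContextCue,
    *,
    direction: str = "acquire_from_target",
    fixpoint: bool = False,
) -> FunctionMap:
    """Propagate stimulus functions along cue-licensed relations.

    For every relation ``(s1, s2, crel)`` in the store the function label of
    the bearer stimulus transfers to its partner.  The default direction,
    ``"acquire_from_target"``, has ``s1`` acquire the function of ``s2``:
    with ``Cfunc(snake) = fear`` and the trained relation
    ``(woods, snake, contains)`` the woods acquire the fear function.  The
    alternative ``"acquire_from_source"`` transfers ``s1``'s function onto
    ``s2`` instead.

    One call performs a single simultaneous pass (labels are read from the
    input map, so a chain propagates one hop per call); ``fixpoint=True``
    re-applies passes until the map stabilises.  Stimuli not touching a
    cue-licensed relation are never modified.  If the cue relation is absent
    from the store, the map is returned unchanged (logged, not an error).
    """
    if cue.crel not in store.registry:
        raise ConfigurationError(f"cue relation {cue.crel!r} is not registered")
    if direction not in ("acquire_from_target", "acquire_from_source"):
        raise ConfigurationError(f"unknown ToF direction {direction!r}")

    licensed = sorted(
        (r for r in store if r.rel == cue.crel), key=lambda r: r.key
    )
    if not licensed:
        logger.info("ToF no-op: no %r relations in store", cue.crel)
        return fmap.copy()

    for r in licensed:
        bearer = r.y if direction == "acquire_from_target" else r.x
        if bearer not in fmap:
            raise DomainError(
                f"function of bearer stimulus {bearer!r} undefined for ToF via "
                f"({r.x!r}, {r.y!r}, {r.rel!r})"
            )

    current = fmap.copy()
    max_passes = len(licensed) + 1 if fixpoint else 1
    for _ in range(max_passes):
        new = current.copy()
        for r in licensed:
            if direction == "acquire_from_target":
                new.entries[r.x] = current[r.y]
            else:
                new.entries[r.y] = current[r.x]
        if new == current:
            break
        current = new
    return current
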