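"""Four-state progression graph for GADA-first islet autoimmunity.

States: 1 = single GADA positive, 2 = multiple islet autoantibodies without
IA-2A, 3 = multiple islet autoantibodies with IA-2A, 4 = type 1 diabetes
(absorbing).  The allowed transitions form an acyclic directed graph: a child
can skip state 2 or 3 but never move backwards, and nothing leaves state 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Tuple

Transition = Tuple[int, int]

STATE_LABELS: Dict[int, str] = {
    1: "single GADA",
    2: "multiple without IA-2A",
    3: "multiple with IA-2A",
    4: "type 1 diabetes",
}

ALLOWED_TRANSITIONS: FrozenSet[Transition] = frozenset(
    {(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)}
)


@dataclass(frozen=True)
class StateSpace:
    """State labels and legal transition pairs of the progression model."""

    states: Tuple[int, ...] = (1, 2, 3, 4)
    allowed_transitions: FrozenSet[Transition] = ALLOWED_TRANSITIONS
    labels: Dict[int, str] = field(default_factory=lambda: dict(STATE_LABELS))

    def __post_init__(self) -> None:
        for q, r in self.allowed_transitions:
            if q not in self.states or r not in self.states:
                raise ValueError(f"transition ({q},{r}) uses unknown state")
            if q >= r:
                raise ValueError(f"transition ({q},{r}) is not forward in stage order")

    @property
    def absorbing(self) -> Tuple[int, ...]:
        out = {q for q, _ in self.allowed_transitions}
        return tuple(s for s in self.states if s not in out)

    def transitions_from(self, state: int) -> List[Transition]:
        return sorted(k for k in self.allowed_transitions if k[0] == state)

    def is_allowed(self, q: int, r: int) -> bool:
        return (q, r) in self.allowed_transitions

    def reachable(self, q: int, r: int) -> bool:
        """Whether state r can be reached from q through allowed transitions."""
        if q == r:
            return True
        frontier = [q]
        seen = {q}
        while frontier:
            s = frontier.pop()
            for _, t in self.transitions_from(s):
                if t == r:
                    return True
                if t not in seen:
                    seen.add(t)
                    frontier.append(t)
        return False

    def path_is_legal(self, states: Sequence[int]) -> bool:
        """A visited-state sequence is legal iff consecutive pairs are allowed."""
        if not states:
            return False
        if any(s not in self.states for s in states):
            return False
        return all(self.is_allowed(a, b) for a, b in zip(states, states[1:]))


DEFAULT_STATE_SPACE = StateSpace()
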