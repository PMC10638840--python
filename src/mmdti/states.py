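"""Disease state space and transition structure for the progression model.

The default model has three ordered clinical states — normal control (NC),
amnestic mild cognitive impairment (aMCI) and Alzheimer's disease (AD) —
with AD absorbing: once a subject is in AD the model allows no recovery.
Direct NC→AD conversion is structurally excluded (panel cohorts of this
kind rarely observe it between annual visits, and the two-step path
NC→aMCI→AD still gives the chain positive NC→AD probability over any
positive horizon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

NC = "NC"
AMCI = "aMCI"
AD = "AD"


@dataclass(frozen=True)
class StateSpace:
    """Ordered set of disease states with absorbing flags.

    Parameters
    ----------
    names : tuple of str
        State labels in order; indices into rate matrices follow this order.
    absorbing : tuple of str
        Labels of absorbing states (no exit transitions allowed).
    """

    names: tuple[str, ...] = (NC, AMCI, AD)
    absorbing: tuple[str, ...] = (AD,)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("state names must be unique")
        unknown = set(self.absorbing) - set(self.names)
        if unknown:
            raise ValueError(f"absorbing states not in state space: {sorted(unknown)}")
        if len(self.absorbing) != 1:
            raise ValueError("exactly one absorbing state is required")

    @property
    def n_states(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown state {name!r}; expected one of {self.names}") from None

    def is_absorbing(self, name: str) -> bool:
        return name in self.absorbing


DEFAULT_STATES = StateSpace()


@dataclass(frozen=True)
class TransitionStructure:
    """Set of allowed directed transitions between states.

    The default allows NC↔aMCI and aMCI→AD only: AD is absorbing and the
    direct NC→AD jump is excluded.
    """

    transitions: tuple[tuple[str, str], ...] = ((NC, AMCI), (AMCI, NC), (AMCI, AD))
    states: StateSpace = field(default_factory=StateSpace)

    def __post_init__(self) -> None:
        seen = set()
        for frm, to in self.transitions:
            if frm == to:
                raise ValueError(f"self-transition {frm}->{to} is not a transition")
            for s in (frm, to):
                if s not in self.states.names:
                    raise ValueError(f"transition references unknown state {s!r}")
            if self.states.is_absorbing(frm):
                raise ValueError(f"transition out of absorbing state {frm!r}")
            if (frm, to) in seen:
                raise ValueError(f"duplicate transition {frm}->{to}")
            seen.add((frm, to))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.transitions

    def __iter__(self):
        return iter(self.transitions)

    def __len__(self) -> int:
        return len(self.transitions)

    def index_pairs(self) -> list[tuple[int, int]]:
        """Allowed transitions as (row, col) indices into the rate matrix."""
        ix = self.states.index
        return [(ix(a), ix(b)) for a, b in self.transitions]


DEFAULT_STRUCTURE = TransitionStructure()
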