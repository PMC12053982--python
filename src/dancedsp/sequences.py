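"""Dance-step sequences and rotation counterbalancing.

A dance DSP (discrete sequence production) trial presents a short ordered
pattern of the four mat directions (up, down, left, right) which the
participant reproduces by stepping.  To cancel position- and foot-specific
effects across participants, each base sequence is remapped by a common
quarter turn ("rotation"), so different participants practice positionally
distinct but structurally identical sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, List, Tuple

from .errors import DegenerateCounterbalanceError, InvalidInputError


class StepDirection(Enum):
    """One of the four dance-mat directions.

    Each direction maps 1:1 to a keyboard response label (the mat is read
    by a joystick-to-key mapper) and to an arrow glyph used on screen.
    """

    UP = "U"
    DOWN = "D"
    LEFT = "L"
    RIGHT = "R"

    @property
    def key_label(self) -> str:
        """Keyboard key registered for this direction (W/S/A/D layout)."""
        return {"U": "W", "D": "S", "L": "A", "R": "D"}[self.value]

    @property
    def arrow(self) -> str:
        return {"U": "↑", "D": "↓", "L": "←", "R": "→"}[self.value]

    @classmethod
    def from_symbol(cls, sym: str) -> "StepDirection":
        """Parse a single-character direction: U/D/L/R letter or arrow glyph."""
        arrows = {"↑": "U", "↓": "D", "←": "L", "→": "R"}
        letter = arrows.get(sym, sym.upper())
        try:
            return cls(letter)
        except ValueError:
            raise InvalidInputError(f"unknown step direction symbol: {sym!r}") from None


# Clockwise quarter-turn map of the mat layout: left -> up -> right -> down -> left.
_CLOCKWISE = {
    StepDirection.LEFT: StepDirection.UP,
    StepDirection.UP: StepDirection.RIGHT,
    StepDirection.RIGHT: StepDirection.DOWN,
    StepDirection.DOWN: StepDirection.LEFT,
}


@dataclass(frozen=True)
class DanceSequence:
    """An ordered pattern of dance steps — the unit of sequence learning.

    Default length is 6; lengths 3-7 are typical for DSP designs.
    """

    steps: Tuple[StepDirection, ...]

    def __post_init__(self) -> None:
        if len(self.steps) < 1:
            raise InvalidInputError("a dance sequence needs at least one step")
        if not all(isinstance(s, StepDirection) for s in self.steps):
            raise InvalidInputError("sequence elements must be StepDirection values")

    @classmethod
    def from_string(cls, text: str) -> "DanceSequence":
        """Build from a compact string of letters ("LRUDRL") or arrows ("←→↑↓→←")."""
        return cls(tuple(StepDirection.from_symbol(c) for c in text.strip()))

    def to_string(self) -> str:
        return "".join(s.value for s in self.steps)

    def to_arrows(self) -> str:
        return "".join(s.arrow for s in self.steps)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self) -> Iterator[StepDirection]:
        return iter(self.steps)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.to_string()


def rotate_sequence(seq: DanceSequence, quarter_turns: int) -> DanceSequence:
    """Remap every step of ``seq`` by ``quarter_turns`` clockwise quarter turns.

    ``quarter_turns`` may be any integer; it is reduced modulo 4.  Rotating
    four times is the identity.
    """
    if len(seq) == 0:  # defensive; DanceSequence forbids this
        raise InvalidInputError("cannot rotate an empty sequence")
    k = quarter_turns % 4
    steps = tuple(seq.steps)
    for _ in range(k):
        steps = tuple(_CLOCKWISE[s] for s in steps)
    return DanceSequence(steps)


def build_counterbalance_set(
    seq_a: DanceSequence, seq_b: DanceSequence
) -> List[DanceSequence]:
    """All four rotations of both base sequences: eight distinct sequences.

    Ordered as [A rotated 0..3, B rotated 0..3].  Raises
    :class:`DegenerateCounterbalanceError` if any two members coincide
    (e.g. the two base sequences are rotations of each other).
    """
    if len(seq_a) != len(seq_b):
        raise InvalidInputError("base sequences must have equal length")
    members = [rotate_sequence(seq_a, k) for k in range(4)]
    members += [rotate_sequence(seq_b, k) for k in range(4)]
    seen: dict = {}
    for i, m in enumerate(members):
        key = m.to_string()
        if key in seen:
            raise DegenerateCounterbalanceError(
                f"counterbalance entries {seen[key]} and {i} coincide ({key})"
            )
        seen[key] = i
    return members


def assign_participant_pair(
    cb_set: List[DanceSequence], participant_index: int
) -> Tuple[DanceSequence, DanceSequence]:
    """Deterministic rotation assignment: participant p gets rotation p mod 4.

    ``cb_set`` must be ordered as produced by :func:`build_counterbalance_set`.
    Participants 0..3 collectively cover all eight set members.
    """
    if participant_index < 0:
        raise InvalidInputError("participant_index must be >= 0")
    if len(cb_set) != 8:
        raise InvalidInputError("counterbalance set must have 8 members")
    k = participant_index % 4
    return cb_set[k], cb_set[4 + k]


# The rotation direction is pinned by a worked example of the task design:
# one clockwise quarter turn of ←→↑↓→← must give ↑↓→←↓↑.  Checked at import.
_example = rotate_sequence(DanceSequence.from_string("LRUDRL"), 1)
assert _example.to_string() == "UDRLDU", "clockwise rotation self-test failed"
del _example
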