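"""Componentwise operator vectors acting place-by-place on sequence vectors.

An :class:`OpVector` is an (in principle infinite) tuple of Z5 shifts, one
per place, stored sparsely: only non-identity components are kept.  These
vectors form an Abelian group under componentwise composition; applying one
to a :class:`~basefive.sequence_model.SeqVector` rewrites the base at every
place in the union of supports, so any substitution edit — including writing
a base into a gap (E) or erasing a base to E — is a single group action.

``diff`` recovers the unique operator carrying one sequence to another
place-by-place; it never aligns, inserts or deletes (that bookkeeping lives
in the sequence model's E insertion/deletion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

from .core_group import BaseSymbol, GroupElement, complement_shift, to_alias
from .sequence_model import SeqVector, FIVE_TO_THREE, THREE_TO_FIVE

__all__ = [
    "OpVector",
    "compose_ops",
    "inverse_op",
    "apply",
    "diff",
    "complement_operator",
    "complement_seq",
]


@dataclass(frozen=True)
class OpVector:
    """Sparse map place-number -> shift exponent (1..4); absent places are n."""

    entries: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for place, exp in self.entries.items():
            if not (isinstance(place, int) and place >= 1):
                raise ValueError(f"place numbers must be positive integers, got {place}")
            if not 1 <= exp <= 4:
                raise ValueError(
                    f"stored exponent at place {place} must be 1..4, got {exp}"
                )
        object.__setattr__(self, "entries", dict(sorted(self.entries.items())))

    @classmethod
    def from_elements(cls, elements: Dict[int, GroupElement]) -> "OpVector":
        return cls({p: g.exponent for p, g in elements.items() if g.exponent != 0})

    @classmethod
    def from_aliases(cls, aliases: Iterable[str], start_place: int = 1) -> "OpVector":
        """Build from a dense run of linear aliases, e.g. ["n","r","u"]."""
        from .core_group import parse_alias

        entries = {}
        for offset, token in enumerate(aliases):
            g = parse_alias(token)
            if g.exponent:
                entries[start_place + offset] = g.exponent
        return cls(entries)

    def element_at(self, place: int) -> GroupElement:
        return GroupElement(self.entries.get(place, 0))

    def exponent_at(self, place: int) -> int:
        return self.entries.get(place, 0)

    @property
    def is_identity(self) -> bool:
        return not self.entries

    def __mul__(self, other: "OpVector") -> "OpVector":
        return compose_ops(self, other)

    def inverse(self) -> "OpVector":
        return inverse_op(self)

    def shift(self, delta: int) -> "OpVector":
        """Translate the support by ``delta`` places (pattern re-anchoring)."""
        return OpVector({p + delta: e for p, e in self.entries.items()})

    def aliases(self, notation: str = "linear") -> Dict[int, str]:
        """Human-readable rendering of the non-identity components."""
        return {p: to_alias(GroupElement(e), notation) for p, e in self.entries.items()}

    def __str__(self) -> str:
        return (
            "["
            + " ".join(f"{to_alias(GroupElement(e))}{p}" for p, e in self.entries.items())
            + "]"
        )


B0 = OpVector({})


def compose_ops(b1: OpVector, b2: OpVector) -> OpVector:
    """Componentwise composition over the union of supports."""
    entries = {}
    for place in set(b1.entries) | set(b2.entries):
        exp = (b1.exponent_at(place) + b2.exponent_at(place)) % 5
        if exp:
            entries[place] = exp
    return OpVector(entries)


def inverse_op(b: OpVector) -> OpVector:
    """Componentwise inverse: the unique vector composing with b to identity."""
    return OpVector({p: (-e) % 5 for p, e in b.entries.items()})


def apply(s: SeqVector, b: OpVector) -> SeqVector:
    """Act on a sequence: at each place the base index shifts by the exponent.

    Operators may act at implicit places (the background E), materializing an
    explicit base.  An explicit base mapped to E stays an explicit E so that
    it can be deleted later; an untouched implicit place stays implicit.
    """
    entries = {}
    for place in set(s.entries) | set(b.entries):
        idx = (s.index_at(place) + b.exponent_at(place)) % 5
        if idx != 0 or place in s.entries:
            entries[place] = idx
    return SeqVector(entries, alphabet=s.alphabet, direction=s.direction)


def diff(s_from: SeqVector, s_to: SeqVector) -> OpVector:
    """The operator with components (to_index - from_index) mod 5 per place.

    Strictly positional: both vectors are compared place-by-place over the
    union of supports, absent places reading as E.  Indel alignment is the
    caller's job via insert_E/delete_E.
    """
    if s_from.alphabet != s_to.alphabet:
        raise ValueError(
            f"alphabet mismatch: {s_from.alphabet} vs {s_to.alphabet}"
        )
    entries = {}
    for place in set(s_from.entries) | set(s_to.entries):
        exp = (s_to.index_at(place) - s_from.index_at(place)) % 5
        if exp:
            entries[place] = exp
    return OpVector(entries)


def complement_operator(s: SeqVector) -> OpVector:
    """The operator carrying s to its base-wise complement.

    At each explicit place with base index m the component exponent is
    (-2m) mod 5; E places (index 0) contribute the identity.
    """
    return OpVector.from_elements(
        {p: complement_shift(BaseSymbol(i, s.alphabet)) for p, i in s.entries.items()}
    )


def complement_seq(s: SeqVector) -> SeqVector:
    """Base-wise complement with the direction label flipped.

    Place numbers and ordering are unchanged (the antiparallel re-reading is
    available separately via SeqVector.reverse).
    """
    entries = {p: (5 - i) % 5 for p, i in s.entries.items()}
    flipped = THREE_TO_FIVE if s.direction == FIVE_TO_THREE else FIVE_TO_THREE
    return SeqVector(entries, alphabet=s.alphabet, direction=flipped)
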