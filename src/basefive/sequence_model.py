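"""Sequence vectors with an explicit gap base and place-number bookkeeping.

A :class:`SeqVector` models a single-stranded DNA/RNA sequence as a sparse
map from 1-based place numbers to explicit bases, over an implicit infinite
background of E's.  An E stored at a place ("explicit E") is tracked through
edits; a place absent from the map is an untracked implicit E.  This makes
insertions and deletions expressible as substitutions to/from E plus a
deterministic renumbering, which is the point of the five-letter alphabet.

Two notational transforms are provided: ``braces`` demotes explicit E's to
implicit ones while keeping all place numbers (sparse gaps remain), and
``angle`` deletes them and renumbers the surviving bases 1..N contiguously.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

from .core_group import DNA, RNA, BaseSymbol

__all__ = [
    "SeqVector",
    "FIVE_TO_THREE",
    "THREE_TO_FIVE",
    "parse_explicit",
    "random_seq",
]

FIVE_TO_THREE = "5to3"
THREE_TO_FIVE = "3to5"

_TOKEN = re.compile(r"([A-Za-z])(\d+)")


@dataclass(frozen=True)
class SeqVector:
    """Sparse base vector: place number -> phase index, plus labels.

    ``entries`` maps each explicit place to its base index (0 encodes an
    explicit E).  Equality is label-sensitive by default; use
    :meth:`same_bases` for comparison up to explicit/implicit-E status.
    """

    entries: Dict[int, int] = field(default_factory=dict)
    alphabet: str = DNA
    direction: str = FIVE_TO_THREE

    def __post_init__(self) -> None:
        for place, idx in self.entries.items():
            if not (isinstance(place, int) and place >= 1):
                raise ValueError(f"place numbers must be positive integers, got {place}")
            if not 0 <= idx <= 4:
                raise ValueError(f"base index out of range at place {place}: {idx}")
        if self.alphabet not in (DNA, RNA):
            raise ValueError(f"alphabet must be DNA or RNA, got {self.alphabet!r}")
        if self.direction not in (FIVE_TO_THREE, THREE_TO_FIVE):
            raise ValueError(f"bad direction label {self.direction!r}")
        # canonical ascending iteration order
        object.__setattr__(self, "entries", dict(sorted(self.entries.items())))

    # -- accessors ---------------------------------------------------------

    def base_at(self, place: int) -> BaseSymbol:
        """The base at a place; absent places read as (implicit) E."""
        return BaseSymbol(self.entries.get(place, 0), self.alphabet)

    def index_at(self, place: int) -> int:
        return self.entries.get(place, 0)

    @property
    def max_place(self) -> int:
        """Highest explicit place number (0 for the all-E identity vector)."""
        return max(self.entries) if self.entries else 0

    def length_N(self) -> int:
        """N: the count of explicit non-E bases (the real sequence length)."""
        return sum(1 for idx in self.entries.values() if idx != 0)

    def iter_bases(self) -> Iterable[Tuple[int, BaseSymbol]]:
        for place, idx in self.entries.items():
            yield place, BaseSymbol(idx, self.alphabet)

    def same_bases(self, other: "SeqVector", check_direction: bool = True) -> bool:
        """Equality of the base at every place, explicit E == implicit E."""
        if self.alphabet != other.alphabet:
            return False
        if check_direction and self.direction != other.direction:
            return False
        places = set(self.entries) | set(other.entries)
        return all(self.index_at(p) == other.index_at(p) for p in places)

    # -- edits -------------------------------------------------------------

    def _with(self, entries: Dict[int, int], **kw) -> "SeqVector":
        return SeqVector(
            entries,
            alphabet=kw.get("alphabet", self.alphabet),
            direction=kw.get("direction", self.direction),
        )

    def set_base(self, place: int, base: BaseSymbol) -> "SeqVector":
        if base.alphabet != self.alphabet:
            raise ValueError("alphabet mismatch")
        new = dict(self.entries)
        new[place] = base.index
        return self._with(new)

    def insert_E(self, after_place: int, count: int = 1) -> "SeqVector":
        """Insert ``count`` explicit E's after ``after_place``.

        Every entry beyond ``after_place`` shifts up by ``count``; the new
        E's occupy places after_place+1 .. after_place+count and are tracked.
        """
        if count < 1:
            raise ValueError(f"count must be >= 1, got {count}")
        if after_place < 0:
            raise ValueError(f"after_place must be >= 0, got {after_place}")
        new = {}
        for place, idx in self.entries.items():
            new[place + count if place > after_place else place] = idx
        for k in range(1, count + 1):
            new[after_place + k] = 0
        return self._with(new)

    def delete_E(self, places: Iterable[int]) -> "SeqVector":
        """Delete explicit E's at the named places, shifting higher places down.

        Only places that hold an explicit E may be deleted; deleting a real
        base or an implicit (absent) place is an error.
        """
        places = sorted(set(places))
        for p in places:
            if p not in self.entries:
                raise ValueError(f"place {p} is implicit (absent), cannot delete")
            if self.entries[p] != 0:
                raise ValueError(f"place {p} holds a non-E base, cannot delete")
        new = {}
        for place, idx in self.entries.items():
            if place in places:
                continue
            shift = sum(1 for p in places if p < place)
            new[place - shift] = idx
        return self._with(new)

    def braces(self) -> "SeqVector":
        """{ } transform: drop explicit E's, keep every other place number."""
        return self._with({p: i for p, i in self.entries.items() if i != 0})

    def angle(self) -> "SeqVector":
        """< > transform: drop explicit E's and gaps, renumber bases 1..N."""
        kept = [i for _, i in sorted(self.entries.items()) if i != 0]
        return self._with({k + 1: idx for k, idx in enumerate(kept)})

    def angle_t(self, t: int) -> "SeqVector":
        """Apply the < > transform t times (t = 0 is the identity)."""
        if t < 0:
            raise ValueError(f"t must be >= 0, got {t}")
        out = self
        for _ in range(t):
            out = out.angle()
        return out

    def reverse(self) -> "SeqVector":
        """Reverse base order over the span 1..max_place and flip direction."""
        span = self.max_place
        new = {span + 1 - p: i for p, i in self.entries.items()}
        flipped = THREE_TO_FIVE if self.direction == FIVE_TO_THREE else FIVE_TO_THREE
        return self._with(new, direction=flipped)

    # -- rendering ---------------------------------------------------------

    def to_text(self, mode: str = "conventional") -> str:
        """Render as text.

        ``explicit`` lists letter+place for every explicit entry and marks
        the notional infinite tail; ``conventional`` drops all E's and gaps
        and emits the plain base string.
        """
        if mode == "explicit":
            body = " ".join(
                f"{BaseSymbol(i, self.alphabet).letter}{p}"
                for p, i in self.entries.items()
            )
            return body + (" |E..." if body else "|E...")
        if mode == "conventional":
            return "".join(
                BaseSymbol(i, self.alphabet).letter
                for _, i in sorted(self.entries.items())
                if i != 0
            )
        raise ValueError(f"unknown mode {mode!r}")

    def __str__(self) -> str:
        return self.to_text("conventional")


def parse_explicit(
    text: str, alphabet: str = DNA, direction: str = FIVE_TO_THREE
) -> SeqVector:
    """Parse either plain letters ("CTGATAAC") or spaced letter+place tokens
    ("C1 T2 E3 G4") into a SeqVector.

    Plain-letter input assigns places 1..L (explicit E's included as typed).
    Tokenized input places each letter at its stated place number; duplicate
    or non-positive places are rejected.
    """
    text = text.strip()
    if not text:
        return SeqVector({}, alphabet=alphabet, direction=direction)
    if any(ch.isdigit() for ch in text):
        entries: Dict[int, int] = {}
        pos = 0
        for match in _TOKEN.finditer(text):
            if text[pos : match.start()].strip():
                raise ValueError(f"unparseable input near {text[pos:match.start()]!r}")
            letter, place = match.group(1), int(match.group(2))
            if place < 1:
                raise ValueError(f"non-positive place number {place}")
            if place in entries:
                raise ValueError(f"duplicate place number {place}")
            entries[place] = BaseSymbol.from_letter(letter, alphabet).index
            pos = match.end()
        if text[pos:].strip():
            raise ValueError(f"unparseable trailing input {text[pos:]!r}")
        return SeqVector(entries, alphabet=alphabet, direction=direction)
    letters = [ch for ch in text if not ch.isspace()]
    entries = {
        k + 1: BaseSymbol.from_letter(ch, alphabet).index
        for k, ch in enumerate(letters)
    }
    return SeqVector(entries, alphabet=alphabet, direction=direction)


def random_seq(
    seed: int,
    length: int,
    p_explicit_E: float = 0.0,
    alphabet: str = DNA,
    direction: str = FIVE_TO_THREE,
) -> SeqVector:
    """Seeded random sequence for fixtures and property tests.

    Letters are uniform over the four real bases; each position independently
    becomes an explicit E with probability ``p_explicit_E``.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    if not 0.0 <= p_explicit_E <= 1.0:
        raise ValueError("p_explicit_E must be in [0, 1]")
    rng = random.Random(seed)
    entries = {}
    for place in range(1, length + 1):
        if rng.random() < p_explicit_E:
            entries[place] = 0
        else:
            entries[place] = rng.randint(1, 4)
    return SeqVector(entries, alphabet=alphabet, direction=direction)
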