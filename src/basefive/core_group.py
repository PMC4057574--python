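"""Order-5 cyclic algebra on the five-letter nucleotide alphabet.

The alphabet {E, C, A, T/U, G} is arranged on a wallpaper-style grid whose
five one-step moves r (right), u (up), d (down), l (left) and n (stay) form
the cyclic group Z5 generated by r, with u = r^2, d = r^3, l = r^4.  The same
group acts on the bases themselves: each base carries a phase index m in
{0..4} (E=0, C=1, A=2, T/U=3, G=4, i.e. the fifth roots of unity
Exp(m*2*pi*i/5)), and a shift with exponent k sends index m to (m+k) mod 5.

Three equivalent notations for a group element are supported: linear
("r", "u", "d", "l", "n"), rotational ("w0".."w4") and wallpaper
("x[a,b]" meaning r^a * u^b, canonical exponent (a+2b) mod 5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Tuple

__all__ = [
    "GroupElement",
    "BaseSymbol",
    "DNA",
    "RNA",
    "R",
    "U",
    "D",
    "L",
    "N",
    "compose",
    "inverse",
    "apply_base",
    "from_xy",
    "complement_base",
    "complement_shift",
    "to_alias",
    "parse_alias",
    "cayley_table",
    "xy_pairs",
    "u_exponent",
]

#: alphabet tags
DNA = "DNA"
RNA = "RNA"

# linear aliases ordered by r-exponent: n=r^0, r=r^1, u=r^2, d=r^3, l=r^4
_LINEAR = "nrudl"
_LETTERS = {DNA: "ECATG", RNA: "ECAUG"}


@dataclass(frozen=True, order=True)
class GroupElement:
    """A shift operation, stored canonically as an exponent of the generator r."""

    exponent: int

    def __post_init__(self) -> None:
        if not 0 <= self.exponent <= 4:
            raise ValueError(f"exponent must be in 0..4, got {self.exponent}")

    def __mul__(self, other: "GroupElement") -> "GroupElement":
        return compose(self, other)

    def inverse(self) -> "GroupElement":
        return inverse(self)

    @property
    def alias(self) -> str:
        return _LINEAR[self.exponent]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GroupElement({self.alias!r})"


N = GroupElement(0)
R = GroupElement(1)
U = GroupElement(2)
D = GroupElement(3)
L = GroupElement(4)

ELEMENTS: Tuple[GroupElement, ...] = (N, R, U, D, L)


@dataclass(frozen=True)
class BaseSymbol:
    """One of the five letters, as a phase index m plus an alphabet tag.

    The letter rendering depends on the alphabet only at m=3 (T for DNA,
    U for RNA); index arithmetic never does.
    """

    index: int
    alphabet: str = DNA

    def __post_init__(self) -> None:
        if not 0 <= self.index <= 4:
            raise ValueError(f"base index must be in 0..4, got {self.index}")
        if self.alphabet not in (DNA, RNA):
            raise ValueError(f"alphabet must be DNA or RNA, got {self.alphabet!r}")

    @classmethod
    def from_letter(cls, letter: str, alphabet: str = DNA) -> "BaseSymbol":
        try:
            return cls(_LETTERS[alphabet].index(letter.upper()), alphabet)
        except ValueError:
            raise ValueError(
                f"letter {letter!r} is not a {alphabet} base (expected one of "
                f"{_LETTERS[alphabet]})"
            ) from None

    @property
    def letter(self) -> str:
        return _LETTERS[self.alphabet][self.index]

    def apply(self, g: GroupElement) -> "BaseSymbol":
        return apply_base(self, g)

    def complement(self) -> "BaseSymbol":
        return complement_base(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BaseSymbol({self.letter!r}, {self.alphabet})"


def compose(g1: GroupElement, g2: GroupElement) -> GroupElement:
    """Compose two shifts; exponents add modulo 5 (commutative, associative)."""
    return GroupElement((g1.exponent + g2.exponent) % 5)


def inverse(g: GroupElement) -> GroupElement:
    """The unique element with compose(g, inverse(g)) = n."""
    return GroupElement((-g.exponent) % 5)


def apply_base(b: BaseSymbol, g: GroupElement) -> BaseSymbol:
    """Act on a base: index shifts by the exponent, alphabet is preserved."""
    return BaseSymbol((b.index + g.exponent) % 5, b.alphabet)


def from_xy(a: int, b: int) -> GroupElement:
    """The wallpaper displacement x[a,b] = r^a * u^b, i.e. exponent (a+2b) mod 5.

    a and b may be any integers, negative included; the grid is 5-periodic
    in both directions.
    """
    return GroupElement((a + 2 * b) % 5)


def u_exponent(m: int) -> int:
    """The u-power realizing base index m from E: u^k = r^(2k), so k = 3m mod 5."""
    return (3 * m) % 5


def complement_base(b: BaseSymbol) -> BaseSymbol:
    """Watson-Crick complement via index reflection: m -> (5-m) mod 5.

    Gives A<->T (or A<->U), C<->G, and E its own complement; an involution.
    """
    return BaseSymbol((5 - b.index) % 5, b.alphabet)


def complement_shift(b: BaseSymbol) -> GroupElement:
    """The shift carrying b to its complement: exponent (-2m) mod 5."""
    return GroupElement((-2 * b.index) % 5)


def to_alias(g: GroupElement, notation: str = "linear") -> str:
    """Render in one of the three notations: linear, rotational, wallpaper."""
    if notation == "linear":
        return _LINEAR[g.exponent]
    if notation == "rotational":
        return f"w{g.exponent}"
    if notation == "wallpaper":
        return f"x[{g.exponent},0]"
    raise ValueError(f"unknown notation {notation!r}")


def parse_alias(token: str) -> GroupElement:
    """Parse any of the three notations back to a canonical element."""
    token = token.strip()
    if len(token) == 1 and token in _LINEAR:
        return GroupElement(_LINEAR.index(token))
    if len(token) == 2 and token[0] == "w" and token[1].isdigit():
        k = int(token[1])
        if 0 <= k <= 4:
            return GroupElement(k)
    if token.startswith("x[") and token.endswith("]"):
        parts = token[2:-1].split(",")
        if len(parts) == 2:
            return from_xy(int(parts[0]), int(parts[1]))
    raise ValueError(f"cannot parse group element token {token!r}")


def cayley_table() -> List[List[GroupElement]]:
    """The full 5x5 composition table, rows/columns ordered n, r, u, d, l."""
    return [[compose(x, y) for y in ELEMENTS] for x in ELEMENTS]


def xy_pairs(g: GroupElement) -> Iterator[Tuple[int, int]]:
    """All five in-cell (a, b) pairs with (a+2b) mod 5 equal to g's exponent."""
    for a in range(5):
        for b in range(5):
            if (a + 2 * b) % 5 == g.exponent:
                yield (a, b)
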