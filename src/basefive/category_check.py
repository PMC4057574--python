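"""Category- and functor-law verifiers for the sequence morphisms.

The morphisms of the central-dogma category are: f (an operator vector on
DNA), rho (complement), tau (the DNA->RNA relabel), g = rho then tau, h (an
operator vector on RNA) and j (intron intervals -> E).  tau and g change
the object (DNA vs RNA) and so are relabel steps, not group elements; all
others are realized by operator vectors.  Laws are checked by evaluation:
exhaustively at the component level (the algebra is finite, order 5) and on
sample sequences at the vector level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core_group import ELEMENTS, GroupElement, compose
from .central_dogma import mature, splice, transcribe
from .operator_vector import B0, OpVector, apply, complement_seq, compose_ops
from .sequence_model import SeqVector

__all__ = [
    "MorphismRecord",
    "CheckReport",
    "RotationalOpVector",
    "apply_morphism",
    "compose_morphisms",
    "check_identity_laws",
    "check_associativity",
    "functor_to_rotational",
    "functor_from_rotational",
    "check_functor_laws",
]

#: object labels: X = DNA, Y = complemented DNA, Z = RNA transcripts,
#: Zs = spliced transcripts
OBJECTS = ("X", "Y", "Z", "Zs")

_TYPING: Dict[str, Tuple[str, str]] = {
    "f": ("X", "X"),
    "rho": ("X", "Y"),
    "tau": ("Y", "Z"),
    "g": ("X", "Z"),
    "h": ("Z", "Z"),
    "j": ("Z", "Zs"),
}


@dataclass(frozen=True)
class MorphismRecord:
    """One arrow of the category, with its concrete realization.

    ``realization`` is an OpVector for f/h, None for the relabel morphisms
    rho/tau/g (their action is fixed), and a tuple of intron intervals for j.
    """

    tag: str
    realization: object = None

    def __post_init__(self) -> None:
        if self.tag not in _TYPING:
            raise ValueError(f"unknown morphism tag {self.tag!r}")
        if self.tag in ("f", "h") and not isinstance(self.realization, OpVector):
            raise ValueError(f"morphism {self.tag} requires an OpVector realization")
        if self.tag == "j" and self.realization is not None:
            object.__setattr__(
                self, "realization", tuple(tuple(map(int, iv)) for iv in self.realization)
            )

    @property
    def source(self) -> str:
        return _TYPING[self.tag][0]

    @property
    def target(self) -> str:
        return _TYPING[self.tag][1]


def apply_morphism(m: MorphismRecord, s: SeqVector) -> SeqVector:
    if m.tag in ("f", "h"):
        return apply(s, m.realization)
    if m.tag == "rho":
        return complement_seq(s)
    if m.tag == "tau":
        return transcribe(s)
    if m.tag == "g":
        return transcribe(complement_seq(s))
    if m.tag == "j":
        return splice(s, m.realization or ())
    raise ValueError(f"unknown morphism tag {m.tag!r}")  # pragma: no cover


def compose_morphisms(chain: Sequence[MorphismRecord]):
    """Return the evaluated composite of a composable chain (left to right)."""
    for inner, outer in zip(chain, chain[1:]):
        if inner.target != outer.source:
            raise ValueError(
                f"non-composable chain: {inner.tag}: ->{inner.target} then "
                f"{outer.tag}: {outer.source}->"
            )

    def run(s: SeqVector) -> SeqVector:
        for m in chain:
            s = apply_morphism(m, s)
        return s

    return run


@dataclass(frozen=True)
class CheckReport:
    name: str
    passed: bool
    n_cases: int
    failures: Tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "passed": self.passed,
            "n_cases": self.n_cases,
            "failures": list(self.failures),
        }


def check_identity_laws(
    m: MorphismRecord,
    samples: Sequence[SeqVector],
    identity: OpVector = B0,
) -> CheckReport:
    """Verify 1∘m = m = m∘1 on every sample, with 1 the identity OpVector.

    Pre- and post-composing with the identity operator must leave the
    morphism's action unchanged; a non-identity ``identity`` argument serves
    as a negative control.
    """
    failures: List[str] = []
    for k, s in enumerate(samples):
        direct = apply_morphism(m, s)
        pre = apply_morphism(m, apply(s, identity))
        post = apply(direct, identity)
        if not (direct.same_bases(pre) and direct.same_bases(post)):
            failures.append(f"sample {k}: identity law violated for {m.tag}")
    return CheckReport(
        f"identity[{m.tag}]", not failures, len(samples), tuple(failures)
    )


def check_associativity(
    m1: MorphismRecord,
    m2: MorphismRecord,
    m3: MorphismRecord,
    samples: Sequence[SeqVector],
) -> CheckReport:
    """Verify m1∘(m2∘m3) = (m1∘m2)∘m3 by evaluation on every sample."""
    left = compose_morphisms([m1, m2, m3])  # validates composability

    failures: List[str] = []
    for k, s in enumerate(samples):
        inner_first = apply_morphism(
            m3, compose_morphisms([m1, m2])(s)
        )
        outer_first = compose_morphisms([m2, m3])(apply_morphism(m1, s))
        if not (
            inner_first.same_bases(outer_first)
            and inner_first.same_bases(left(s))
        ):
            failures.append(
                f"sample {k}: association orders differ for "
                f"{m1.tag}*{m2.tag}*{m3.tag}"
            )
    return CheckReport(
        f"associativity[{m1.tag}*{m2.tag}*{m3.tag}]",
        not failures,
        len(samples),
        tuple(failures),
    )


# -- the functor to the rotational representation ---------------------------


@dataclass(frozen=True)
class RotationalOpVector:
    """An operator vector rendered in the phasor notation w0..w4."""

    entries: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(sorted(self.entries.items())))

    def aliases(self) -> Dict[int, str]:
        return {p: f"w{e}" for p, e in self.entries.items()}

    def compose(self, other: "RotationalOpVector") -> "RotationalOpVector":
        entries = {}
        for place in set(self.entries) | set(other.entries):
            e = (self.entries.get(place, 0) + other.entries.get(place, 0)) % 5
            if e:
                entries[place] = e
        return RotationalOpVector(entries)


def functor_to_rotational(b: OpVector) -> RotationalOpVector:
    """Map r->w1, u->w2, d->w3, l->w4, n->w0 componentwise (exponents fixed)."""
    return RotationalOpVector(dict(b.entries))


def functor_from_rotational(b: RotationalOpVector) -> OpVector:
    """Inverse rendering back to the linear/wallpaper notation."""
    return OpVector(dict(b.entries))


def check_functor_laws(
    b1: OpVector,
    b2: OpVector,
    component_map: Optional[Dict[int, int]] = None,
) -> CheckReport:
    """Verify F(b1∘b2) = F(b1)∘F(b2) and F(identity) = identity.

    Also checks the component-level law exhaustively over all 25 pairs of
    Z5 elements.  ``component_map`` (exponent -> exponent) substitutes for
    the canonical identity mapping as a negative-control hook.
    """
    cmap = component_map or {k: k for k in range(5)}

    def fmap(b: OpVector) -> RotationalOpVector:
        return RotationalOpVector(
            {p: cmap[e] for p, e in b.entries.items() if cmap[e] != 0}
        )

    failures: List[str] = []
    if fmap(compose_ops(b1, b2)).entries != fmap(b1).compose(fmap(b2)).entries:
        failures.append("F(b1*b2) != F(b1)*F(b2)")
    if fmap(B0).entries != {}:
        failures.append("F(identity) != identity")
    n = 2
    for x in ELEMENTS:
        for y in ELEMENTS:
            n += 1
            if cmap[compose(x, y).exponent] != (cmap[x.exponent] + cmap[y.exponent]) % 5:
                failures.append(
                    f"component pair ({x.alias},{y.alias}) breaks the functor law"
                )
    return CheckReport("functor", not failures, n, tuple(failures))
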