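"""Aggregate self-check: exhaustive component-level laws plus seeded
sequence-level property suites, reported as stable JSON-able dicts.
"""

from __future__ import annotations

import random
from typing import Callable, Dict, List, Optional

from .core_group import ELEMENTS, GroupElement, compose, from_xy, inverse
from .category_check import (
    MorphismRecord,
    check_associativity,
    check_functor_laws,
    check_identity_laws,
)
from .operator_vector import (
    B0,
    OpVector,
    apply,
    complement_operator,
    complement_seq,
    compose_ops,
    diff,
    inverse_op,
)
from .sequence_model import SeqVector, random_seq

__all__ = ["run_selfcheck"]


def _random_op(rng: random.Random, length: int, density: float = 0.6) -> OpVector:
    entries = {}
    for place in range(1, length + 1):
        if rng.random() < density:
            exp = rng.randint(1, 4)
            entries[place] = exp
    return OpVector(entries)


def run_selfcheck(
    seed: int = 0,
    n_samples: int = 200,
    compose_table: Optional[Callable[[GroupElement, GroupElement], GroupElement]] = None,
) -> Dict:
    """Run all checks; returns {"passed": bool, "checks": [...]}.

    ``compose_table`` substitutes for the canonical composition as a
    negative-control hook (a corrupted table must be reported as a failure
    naming the violated axiom).
    """
    comp = compose_table or compose
    rng = random.Random(seed)
    checks: List[Dict] = []

    def record(name: str, n: int, failures: List[str]) -> None:
        checks.append(
            {"name": name, "passed": not failures, "n_cases": n, "failures": failures}
        )

    # exhaustive group axioms on the five components
    failures = []
    closure = {comp(x, y) for x in ELEMENTS for y in ELEMENTS}
    if closure != set(ELEMENTS):
        failures.append(f"closure: composition yields {len(closure)} elements, not 5")
    for x in ELEMENTS:
        for y in ELEMENTS:
            if comp(x, y) != comp(y, x):
                failures.append(f"commutativity fails at ({x.alias},{y.alias})")
            for z in ELEMENTS:
                if comp(comp(x, y), z) != comp(x, comp(y, z)):
                    failures.append(
                        f"associativity fails at ({x.alias},{y.alias},{z.alias})"
                    )
    for x in ELEMENTS:
        if comp(x, inverse(x)).exponent != 0:
            failures.append(f"inverse fails at {x.alias}")
    record("group_axioms_Z5", 25 + 125 + 5 + 1, failures)

    # wallpaper representation consistency and modular identities
    failures = []
    for a in range(-10, 11):
        for b in range(-10, 11):
            expected = GroupElement(0)
            step = GroupElement(1) if a >= 0 else inverse(GroupElement(1))
            for _ in range(abs(a)):
                expected = comp(expected, step)
            step = GroupElement(2) if b >= 0 else inverse(GroupElement(2))
            for _ in range(abs(b)):
                expected = comp(expected, step)
            if from_xy(a, b) != expected:
                failures.append(f"from_xy({a},{b}) != stepped composition")
    for a in range(5):
        for b in range(5):
            if from_xy(a + 5, b) != from_xy(a, b) or from_xy(a, b + 5) != from_xy(a, b):
                failures.append(f"period-5 identity fails at ({a},{b})")
        if any(
            from_xy(*pair).exponent != 0
            for pair in [(2 * a, -a), (a, 2 * a), (-2 * a, a), (-a, -2 * a)]
        ):
            failures.append(f"null-displacement identity fails at a={a}")
    record("wallpaper_identities", 21 * 21 + 25 + 5, failures)

    # operator-vector group laws and diff/apply round trips on random data
    failures = []
    for k in range(n_samples):
        length = rng.randint(0, 30)
        a = random_seq(rng.randrange(2**31), length, p_explicit_E=0.2)
        b = random_seq(rng.randrange(2**31), length, p_explicit_E=0.2)
        c = random_seq(rng.randrange(2**31), length, p_explicit_E=0.2)
        if not apply(a, diff(a, b)).same_bases(b):
            failures.append(f"case {k}: apply(a, diff(a,b)) != b")
        if diff(b, a).entries != inverse_op(diff(a, b)).entries:
            failures.append(f"case {k}: diff(b,a) != inverse(diff(a,b))")
        if (
            compose_ops(diff(a, b), diff(b, c)).entries
            != diff(a, c).entries
        ):
            failures.append(f"case {k}: diff decomposition fails")
        if not apply(a, complement_operator(a)).same_bases(
            complement_seq(a), check_direction=False
        ):
            failures.append(f"case {k}: complement operator disagrees")
        b1 = _random_op(rng, 20)
        b2 = _random_op(rng, 20)
        b3 = _random_op(rng, 20)
        if (
            compose_ops(compose_ops(b1, b2), b3).entries
            != compose_ops(b1, compose_ops(b2, b3)).entries
        ):
            failures.append(f"case {k}: operator associativity fails")
        if compose_ops(b1, inverse_op(b1)).entries != {}:
            failures.append(f"case {k}: operator inverse fails")
    record("operator_vector_laws", n_samples, failures)

    # category identity/associativity and functor laws
    samples = [
        random_seq(rng.randrange(2**31), rng.randint(0, 20), 0.2) for _ in range(20)
    ]
    rep = check_identity_laws(MorphismRecord("f", _random_op(rng, 15)), samples)
    record(rep.name, rep.n_cases, list(rep.failures))
    rep = check_associativity(
        MorphismRecord("f", _random_op(rng, 15)),
        MorphismRecord("f", _random_op(rng, 15)),
        MorphismRecord("f", _random_op(rng, 15)),
        samples,
    )
    record(rep.name, rep.n_cases, list(rep.failures))
    rep = check_functor_laws(_random_op(rng, 15), _random_op(rng, 15))
    record(rep.name, rep.n_cases, list(rep.failures))

    return {
        "seed": seed,
        "passed": all(c["passed"] for c in checks),
        "checks": checks,
    }
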