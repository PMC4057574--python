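"""Higher-level sequence procedures: edit scripts, recombination, and the
complement -> transcription -> splicing -> maturation pipeline.

Every procedure here is a composition of the primitive moves from
``sequence_model`` (E insertion/deletion, renumbering) and
``operator_vector`` (componentwise substitution), so each step is tracked
and invertible where the algebra permits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

from .core_group import DNA, RNA
from .operator_vector import OpVector, apply, complement_seq, inverse_op
from .sequence_model import SeqVector

__all__ = [
    "InsertE",
    "DeleteE",
    "Substitute",
    "EditScript",
    "RecombinationResult",
    "PipelineTrace",
    "apply_edit_script",
    "invert_edit_script",
    "recombine",
    "transcribe",
    "splice",
    "mature",
    "central_dogma_pipeline",
    "codon_partition",
]

logger = logging.getLogger(__name__)


# -- edit scripts -----------------------------------------------------------


@dataclass(frozen=True)
class InsertE:
    after_place: int
    count: int = 1


@dataclass(frozen=True)
class DeleteE:
    places: Tuple[int, ...]

    def __init__(self, places: Iterable[int]):
        object.__setattr__(self, "places", tuple(places))


@dataclass(frozen=True)
class Substitute:
    op: OpVector


EditStep = Union[InsertE, DeleteE, Substitute]


@dataclass(frozen=True)
class EditScript:
    """An ordered list of edit steps, applied left to right."""

    steps: Tuple[EditStep, ...] = field(default_factory=tuple)

    def __init__(self, steps: Iterable[EditStep] = ()):
        object.__setattr__(self, "steps", tuple(steps))

    def __iter__(self):
        return iter(self.steps)

    def __len__(self) -> int:
        return len(self.steps)


def apply_edit_script(
    s: SeqVector, script: EditScript, trace: bool = False
) -> Union[SeqVector, Tuple[SeqVector, List[SeqVector]]]:
    """Apply each step in order; with ``trace`` also return every intermediate."""
    states = [s]
    current = s
    for step in script:
        if isinstance(step, InsertE):
            current = current.insert_E(step.after_place, step.count)
        elif isinstance(step, DeleteE):
            current = current.delete_E(step.places)
        elif isinstance(step, Substitute):
            current = apply(current, step.op)
        else:  # pragma: no cover - defensive
            raise TypeError(f"unknown edit step {step!r}")
        logger.debug("edit step %r -> %s", step, current.to_text("explicit"))
        states.append(current)
    if trace:
        return current, states
    return current


def invert_edit_script(script: EditScript) -> EditScript:
    """The reverse script: inverse substitutions, deletes matching inserts.

    Valid when, as in the standard two-step insertion idiom, every InsertE
    block is still made of explicit E's at the time the reversed DeleteE
    runs (i.e. any bases written into it have first been erased back to E
    by the reversed substitution).
    """
    inverted: List[EditStep] = []
    for step in reversed(script.steps):
        if isinstance(step, InsertE):
            inverted.append(
                DeleteE(range(step.after_place + 1, step.after_place + step.count + 1))
            )
        elif isinstance(step, DeleteE):
            # deleted places were explicit E's; re-insert them one block at a
            # time from the lowest place so earlier insertions shift later ones
            for p in sorted(step.places):
                inverted.append(InsertE(after_place=p - 1, count=1))
        elif isinstance(step, Substitute):
            inverted.append(Substitute(inverse_op(step.op)))
    return EditScript(inverted)


# -- recombination ----------------------------------------------------------


@dataclass(frozen=True)
class RecombinationResult:
    """Outcome of a segment swap between two sequences.

    ``out_c``/``out_d`` are the post-swap vectors (explicit E's retained
    where bases were erased); ``op_c``/``op_d`` the substitution operators
    applied after E-padding.  Their edit patterns are componentwise inverses
    of each other; as stored vectors ``inverse_op(op_c) == op_d`` exactly
    when both segments start at the same place number.
    """

    out_c: SeqVector
    out_d: SeqVector
    op_c: OpVector
    op_d: OpVector
    padded_c: SeqVector
    padded_d: SeqVector


def _check_segment(s: SeqVector, seg: Sequence[int], label: str) -> Tuple[int, int]:
    first, last = int(seg[0]), int(seg[1])
    if first < 1 or last < first:
        raise ValueError(f"invalid segment bounds {label}: ({first}, {last})")
    if last > s.max_place:
        raise ValueError(
            f"segment {label} ({first}, {last}) extends beyond the explicit span "
            f"(max place {s.max_place})"
        )
    return first, last


def recombine(
    s_c: SeqVector,
    seg_c: Sequence[int],
    s_d: SeqVector,
    seg_d: Sequence[int],
) -> RecombinationResult:
    """Swap segment ``seg_c`` of ``s_c`` with segment ``seg_d`` of ``s_d``.

    Procedure: insert len(seg_d) E's immediately *before* the segment in the
    first sequence and len(seg_c) E's immediately *after* the segment in the
    second; then a single operator per sequence writes the partner's segment
    into the fresh E block and erases the native segment to E's.  Segments
    are inclusive 1-based [first, last] place ranges and must lie within the
    explicit span; length-0 segments are rejected.
    """
    if s_c.alphabet != s_d.alphabet:
        raise ValueError("alphabet mismatch between recombination partners")
    fc, lc = _check_segment(s_c, seg_c, "seg_c")
    fd, ld = _check_segment(s_d, seg_d, "seg_d")
    len_c = lc - fc + 1
    len_d = ld - fd + 1
    seg_c_idx = [s_c.index_at(p) for p in range(fc, lc + 1)]
    seg_d_idx = [s_d.index_at(p) for p in range(fd, ld + 1)]

    # E-padding: before the segment in c, after the segment in d
    padded_c = s_c.insert_E(after_place=fc - 1, count=len_d)
    padded_d = s_d.insert_E(after_place=ld, count=len_c)

    # operator on c: write d's segment into places fc..fc+len_d-1,
    # erase the shifted native segment at fc+len_d..fc+len_d+len_c-1
    entries_c = {}
    for k, m in enumerate(seg_d_idx):
        if m:
            entries_c[fc + k] = m
    for k, m in enumerate(seg_c_idx):
        if m:
            entries_c[fc + len_d + k] = (-m) % 5
    op_c = OpVector(entries_c)

    # operator on d: erase the native segment at fd..ld,
    # write c's segment into places ld+1..ld+len_c
    entries_d = {}
    for k, m in enumerate(seg_d_idx):
        if m:
            entries_d[fd + k] = (-m) % 5
    for k, m in enumerate(seg_c_idx):
        if m:
            entries_d[ld + 1 + k] = m
    op_d = OpVector(entries_d)

    out_c = apply(padded_c, op_c)
    out_d = apply(padded_d, op_d)
    logger.debug(
        "recombine seg_c=%s seg_d=%s -> %s / %s", seg_c, seg_d, out_c, out_d
    )
    return RecombinationResult(out_c, out_d, op_c, op_d, padded_c, padded_d)


# -- central dogma ----------------------------------------------------------


def transcribe(s: SeqVector) -> SeqVector:
    """Relabel DNA as RNA (every T reads as U); indices and places unchanged."""
    if s.alphabet != DNA:
        raise ValueError("transcribe expects a DNA vector")
    return SeqVector(dict(s.entries), alphabet=RNA, direction=s.direction)


def splice(s: SeqVector, introns: Sequence[Sequence[int]]) -> SeqVector:
    """Replace every base inside each intron interval by an explicit E.

    Intervals are inclusive 1-based [first, last] in the transcript's own
    place numbers, must be disjoint and lie within the explicit span.  Place
    numbers are unchanged; renumbering is maturation's job.
    """
    if s.alphabet != RNA:
        raise ValueError("splice expects an RNA (transcript) vector")
    norm = sorted((int(a), int(b)) for a, b in introns)
    prev_end = 0
    for a, b in norm:
        if a < 1 or b < a:
            raise ValueError(f"invalid intron interval ({a}, {b})")
        if a <= prev_end:
            raise ValueError("intron intervals overlap")
        if b > s.max_place:
            raise ValueError(
                f"intron ({a}, {b}) outside the explicit span (max {s.max_place})"
            )
        prev_end = b
    entries = dict(s.entries)
    for a, b in norm:
        for p in range(a, b + 1):
            entries[p] = 0
    return SeqVector(entries, alphabet=RNA, direction=s.direction)


def mature(s: SeqVector) -> SeqVector:
    """Delete all explicit non-trailing E's and renumber: the < > transform."""
    if s.alphabet != RNA:
        raise ValueError("mature expects an RNA vector")
    return s.angle()


@dataclass(frozen=True)
class PipelineTrace:
    template: SeqVector
    antisense: SeqVector
    pre_mrna: SeqVector
    spliced: SeqVector
    mrna: SeqVector


def central_dogma_pipeline(
    s: SeqVector,
    introns: Sequence[Sequence[int]] = (),
    complement: bool = True,
    trace: bool = False,
) -> Union[SeqVector, PipelineTrace]:
    """Run complement -> transcription -> splicing -> maturation on DNA.

    ``introns`` are intervals in the transcript's (pre-mRNA) place numbers.
    ``complement=False`` skips the complement step (transcribing the given
    strand directly); the default follows the standard template-strand chain.
    """
    if s.alphabet != DNA:
        raise ValueError("central_dogma_pipeline expects a DNA vector")
    antisense = complement_seq(s) if complement else s
    pre_mrna = transcribe(antisense)
    spliced = splice(pre_mrna, introns) if introns else pre_mrna
    mrna = mature(spliced)
    logger.info(
        "pipeline: %s -> %s -> %s -> %s -> %s",
        s, antisense, pre_mrna, spliced, mrna,
    )
    if trace:
        return PipelineTrace(s, antisense, pre_mrna, spliced, mrna)
    return mrna


def codon_partition(s: SeqVector, frame: int = 0) -> List[str]:
    """Group the conventional letters in threes after skipping ``frame`` letters.

    The skipped leading letters form their own group; the final group may be
    shorter than three.  The vector must be matured: an explicit interior E
    (before the last real base) is an error.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    last_base = max((p for p, i in s.entries.items() if i != 0), default=0)
    for p, i in s.entries.items():
        if i == 0 and p < last_base:
            raise ValueError(f"explicit interior E at place {p}; mature the vector first")
    letters = s.to_text("conventional")
    if not letters:
        return []
    groups: List[str] = []
    if frame:
        groups.append(letters[:frame])
    groups.extend(letters[i : i + 3] for i in range(frame, len(letters), 3))
    return groups
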