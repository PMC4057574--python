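"""Readers and writers: FASTA (via Biopython) and the JSON sidecar formats.

FASTA carries conventional or explicit sequences; the letter E is written
inline as a first-class base (it participates in the group arithmetic, so
it is not an alignment gap), with an optional '-' <-> E conversion for
interop.  The record description carries ``alphabet=`` and ``direction=``
tags and round-trips through read_fasta.

The "evec" sidecar stores an explicit vector with its place numbers:
    {"alphabet": "DNA"|"RNA", "direction": "5to3"|"3to5",
     "entries": [[place, letter], ...]}  (ascending places)
and the "editlog" sidecar stores an operator vector:
    {"entries": [[place, exponent], ...]}  (exponents 1..4, ascending)
Both serializations are canonical (sorted, fixed separators) so identical
objects produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core_group import DNA, RNA, BaseSymbol
from .operator_vector import OpVector
from .sequence_model import FIVE_TO_THREE, THREE_TO_FIVE, SeqVector, parse_explicit

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_evec",
    "write_evec",
    "read_editlog",
    "write_editlog",
    "load_sequence",
    "save_sequence",
]

PathLike = Union[str, Path]


def _infer_alphabet(letters: str) -> str:
    has_t = "T" in letters
    has_u = "U" in letters
    if has_t and has_u:
        raise ValueError("record mixes T and U; cannot infer a single alphabet")
    return RNA if has_u else DNA


def _parse_description(desc: str):
    alphabet = None
    direction = FIVE_TO_THREE
    for token in desc.split():
        if token.startswith("alphabet="):
            alphabet = token.split("=", 1)[1]
        elif token.startswith("direction="):
            direction = token.split("=", 1)[1]
    return alphabet, direction


def read_fasta(path: PathLike, gap_as_E: bool = False) -> List[SeqVector]:
    """Read every record into a SeqVector with places 1..L.

    The alphabet is taken from an ``alphabet=`` description tag if present,
    else inferred (U => RNA, T => DNA, neither => DNA).  With ``gap_as_E``
    the alignment gap '-' is imported as the letter E.
    """
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        letters = str(record.seq).upper()
        if gap_as_E:
            letters = letters.replace("-", "E")
        tagged_alphabet, direction = _parse_description(record.description)
        alphabet = tagged_alphabet or _infer_alphabet(letters)
        if alphabet == RNA and "T" in letters:
            raise ValueError(f"record {record.id}: T present in an RNA record")
        if alphabet == DNA and "U" in letters:
            raise ValueError(f"record {record.id}: U present in a DNA record")
        out.append(parse_explicit(letters, alphabet=alphabet, direction=direction))
    return out


def write_fasta(
    seqs: List[SeqVector],
    path: PathLike,
    mode: str = "conventional",
    ids: List[str] = None,
    E_as_gap: bool = False,
) -> None:
    """Write records; ``conventional`` strips E's, ``explicit`` writes them inline."""
    records = []
    for k, s in enumerate(seqs):
        if mode == "conventional":
            letters = s.to_text("conventional")
        elif mode == "explicit":
            letters = "".join(
                BaseSymbol(s.index_at(p), s.alphabet).letter
                for p in range(1, s.max_place + 1)
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if E_as_gap:
            letters = letters.replace("E", "-")
        name = ids[k] if ids else f"seq{k + 1}"
        records.append(
            SeqRecord(
                Seq(letters),
                id=name,
                description=f"alphabet={s.alphabet} direction={s.direction}",
            )
        )
    SeqIO.write(records, str(path), "fasta")


def write_evec(s: SeqVector, path: PathLike) -> None:
    payload = {
        "alphabet": s.alphabet,
        "direction": s.direction,
        "entries": [
            [p, BaseSymbol(i, s.alphabet).letter] for p, i in sorted(s.entries.items())
        ],
    }
    Path(path).write_text(json.dumps(payload, separators=(",", ":")) + "\n")


def read_evec(path: PathLike) -> SeqVector:
    payload = json.loads(Path(path).read_text())
    alphabet = payload.get("alphabet", DNA)
    direction = payload.get("direction", FIVE_TO_THREE)
    if alphabet not in (DNA, RNA):
        raise ValueError(f"bad alphabet {alphabet!r} in evec file")
    if direction not in (FIVE_TO_THREE, THREE_TO_FIVE):
        raise ValueError(f"bad direction {direction!r} in evec file")
    entries = {}
    last = 0
    for place, letter in payload.get("entries", []):
        if place <= last:
            raise ValueError("evec entries must have strictly ascending places")
        entries[int(place)] = BaseSymbol.from_letter(letter, alphabet).index
        last = place
    return SeqVector(entries, alphabet=alphabet, direction=direction)


def write_editlog(b: OpVector, path: PathLike, with_alias: bool = True) -> None:
    payload = {"entries": [[p, e] for p, e in sorted(b.entries.items())]}
    if with_alias:
        payload["alias"] = ["nrudl"[e] for _, e in sorted(b.entries.items())]
    Path(path).write_text(json.dumps(payload, separators=(",", ":")) + "\n")


def read_editlog(path: PathLike) -> OpVector:
    payload = json.loads(Path(path).read_text())
    entries = {}
    last = 0
    for place, exp in payload.get("entries", []):
        if place <= last:
            raise ValueError("editlog entries must have strictly ascending places")
        if not 1 <= exp <= 4:
            raise ValueError(f"editlog exponent at place {place} must be 1..4")
        entries[int(place)] = int(exp)
        last = place
    return OpVector(entries)


def load_sequence(path: PathLike) -> SeqVector:
    """Load one sequence; format selected by extension (.evec/.json vs FASTA)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".evec", ".json"):
        return read_evec(path)
    seqs = read_fasta(path)
    if len(seqs) != 1:
        raise ValueError(f"{path}: expected exactly one record, found {len(seqs)}")
    return seqs[0]


def save_sequence(s: SeqVector, path: PathLike, mode: str = "conventional") -> None:
    suffix = Path(path).suffix.lower()
    if suffix in (".evec", ".json"):
        write_evec(s, path)
    else:
        write_fasta([s], path, mode=mode)
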