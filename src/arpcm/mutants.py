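"""Mutant specifications on the canonical AR sequence.

Mutants are named in the field's usual shorthand — ``W742C`` for a single
substitution, ``T878A+L702H`` for a double — with 1-based positions on the
canonical full-length receptor sequence.  Substitutions are applied to the
full sequence first; trimming to the mutated region happens afterwards so
canonical numbering is preserved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import EmptyInputError, MutantParseError, SequenceMismatchError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class Substitution:
    """A single point substitution, e.g. (W, 742, C)."""

    wt_residue: str
    position: int
    mut_residue: str

    def __post_init__(self) -> None:
        if self.wt_residue not in AMINO_ACIDS:
            raise MutantParseError(f"unknown wild-type residue {self.wt_residue!r}")
        if self.mut_residue not in AMINO_ACIDS:
            raise MutantParseError(f"unknown mutant residue {self.mut_residue!r}")
        if self.position < 1:
            raise MutantParseError(f"position must be 1-based positive, got {self.position}")
        if self.wt_residue == self.mut_residue:
            raise MutantParseError(
                f"silent substitution {self.wt_residue}{self.position}{self.mut_residue}"
            )

    def __str__(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mut_residue}"


@dataclass(frozen=True)
class MutantSpec:
    """An ordered, position-unique set of substitutions with its name."""

    mutant_id: str
    substitutions: tuple[Substitution, ...]

    def __post_init__(self) -> None:
        if not self.substitutions:
            raise MutantParseError(f"mutant {self.mutant_id!r} has no substitutions")
        positions = [s.position for s in self.substitutions]
        if len(set(positions)) != len(positions):
            raise MutantParseError(
                f"mutant {self.mutant_id!r} repeats a position: {positions}"
            )

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.substitutions)


def parse_mutant_spec(token: str) -> MutantSpec:
    """Parse a mutant token such as ``"W742C"`` or ``"T878A+L702H"``."""
    token = token.strip()
    if not token:
        raise MutantParseError("empty mutant token")
    subs = []
    for unit in token.split("+"):
        m = _SUB_RE.match(unit)
        if m is None:
            raise MutantParseError(f"malformed substitution {unit!r} in token {token!r}")
        subs.append(Substitution(m.group(1), int(m.group(2)), m.group(3)))
    return MutantSpec(mutant_id=token, substitutions=tuple(subs))


def apply_substitutions(wt_sequence: str, spec: MutantSpec) -> str:
    """Apply a mutant spec to the wild-type sequence.

    Every substitution's expected wild-type residue is checked against the
    sequence; a mismatch usually means the sequence and the mutant names use
    different numbering.
    """
    seq = list(wt_sequence)
    for sub in spec.substitutions:
        idx = sub.position - 1
        if idx >= len(seq):
            raise SequenceMismatchError(
                f"{spec.mutant_id}: position {sub.position} beyond sequence "
                f"length {len(seq)}"
            )
        if seq[idx] != sub.wt_residue:
            raise SequenceMismatchError(
                f"{spec.mutant_id}: expected {sub.wt_residue} at position "
                f"{sub.position}, sequence has {seq[idx]}"
            )
        seq[idx] = sub.mut_residue
    return "".join(seq)


@dataclass(frozen=True)
class TrimRegion:
    """1-based inclusive sequence window covering all mutated positions."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid trim region [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def extract(self, sequence: str) -> str:
        """Slice the region from a sequence, capping the end at its length."""
        return sequence[self.start - 1 : min(self.end, len(sequence))]


def compute_trim_region(specs: Iterable[MutantSpec], padding: int = 0) -> TrimRegion:
    """Window [min position − padding, max position + padding] over all specs.

    The start is floored at 1; the end is capped at sequence length when the
    region is applied (:meth:`TrimRegion.extract`).
    """
    specs = list(specs)
    if not specs:
        raise EmptyInputError("cannot compute a trim region from zero mutants")
    if padding < 0:
        raise ValueError(f"padding must be non-negative, got {padding}")
    positions = [p for spec in specs for p in spec.positions]
    return TrimRegion(max(1, min(positions) - padding), max(positions) + padding)
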