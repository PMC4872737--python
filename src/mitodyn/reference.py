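"""Circular mitochondrial reference genome and trinucleotide contexts.

The human mitochondrial genome is a circular molecule conventionally
addressed with 1-based coordinates (the rCRS numbering used by
MITOMAP-style variant nomenclature).  All context extraction here wraps
around the origin, so every position of the molecule — including
position 1 and the last position — has a well-defined 5'/3' flanking
base pair.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Union

from Bio import SeqIO

__all__ = [
    "MtReference",
    "load_reference",
    "context_at",
    "trinucleotide_frequencies",
    "AMBIGUOUS_KEY",
]

#: Key under which N-containing contexts are reported by
#: :func:`trinucleotide_frequencies`.
AMBIGUOUS_KEY = "ambiguous"

_ALLOWED = set("ACGTN")


@dataclass(frozen=True)
class MtReference:
    """A circular DNA reference sequence.

    Attributes
    ----------
    name:
        Identifier taken from the FASTA header.
    sequence:
        Upper-case base string over ``{A, C, G, T, N}``.
    circular:
        Always ``True`` for mitochondrial genomes; kept explicit so the
        context logic reads unambiguously.
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) < 3:
            raise ValueError(
                f"reference {self.name!r} has length {len(self.sequence)}; "
                "need at least 3 bases for trinucleotide contexts"
            )
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(
                f"reference {self.name!r} contains illegal characters: "
                f"{sorted(bad)} (only A, C, G, T, N allowed)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        """Base at a 1-based position."""
        _check_position(self, position)
        return self.sequence[position - 1]


def _check_position(ref: MtReference, position: int) -> None:
    if not 1 <= position <= ref.length:
        raise IndexError(
            f"position {position} outside reference {ref.name!r} "
            f"(1..{ref.length})"
        )


def load_reference(fasta_source: Union[str, Path, IO[str]]) -> MtReference:
    """Load a single-record FASTA into an :class:`MtReference`.

    The file must contain exactly one record over the unambiguous DNA
    alphabet plus ``N``; any other IUPAC ambiguity code is rejected so
    that downstream spectrum binning never sees a soft base.
    """
    records = list(SeqIO.parse(fasta_source, "fasta"))
    if len(records) == 0:
        raise ValueError(f"no FASTA records found in {fasta_source!r}")
    if len(records) > 1:
        raise ValueError(
            f"expected exactly one reference record, found {len(records)} "
            f"in {fasta_source!r}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    return MtReference(name=rec.id, sequence=seq)


def context_at(ref: MtReference, position: int) -> str:
    """Trinucleotide context (5' flank, base, 3' flank) at a 1-based position.

    The genome is circular: position 1 borrows its 5' flank from the last
    base and the last position borrows its 3' flank from the first.
    """
    _check_position(ref, position)
    s, n = ref.sequence, ref.length
    i = position - 1
    return s[(i - 1) % n] + s[i] + s[(i + 1) % n]


def trinucleotide_frequencies(ref: MtReference) -> dict[str, float]:
    """Frequency of every trinucleotide context over the circular genome.

    Exactly ``ref.length`` contexts are counted (one per position, with
    wrap-around), so the frequencies over non-ambiguous 3-mers sum to 1
    unless N bases are present; N-containing contexts are pooled under
    :data:`AMBIGUOUS_KEY` and excluded from the unit-sum guarantee.
    """
    counts: Counter[str] = Counter()
    for pos in range(1, ref.length + 1):
        ctx = context_at(ref, pos)
        counts[AMBIGUOUS_KEY if "N" in ctx else ctx] += 1
    total = ref.length
    return {k: v / total for k, v in counts.items()}
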