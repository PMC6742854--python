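"""Circular genome model: FASTA I/O, strand and coordinate arithmetic.

Coordinates are 0-based half-open internally.  User-facing reports
(FASTA headers, annotation tables) are 1-based inclusive, matching the
convention of published mitogenome coordinate tables.  Reading frames are
numbered 1-6: frames 1-3 are the + strand at offsets 0-2, frames 4-6 the
reverse-complement (-) strand read 5'->3' at offsets 0-2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


class AlphabetError(ValueError):
    """Sequence contains a character outside {A,C,G,T,U} (case-insensitive)."""


class FormatError(ValueError):
    """Malformed or empty input file."""


class BoundsError(IndexError):
    """Locus extends beyond a linear genome."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class StrandedLocus:
    """A span of ``span`` nucleotides starting at 0-based ``start`` on the
    5'->3' sequence of ``strand`` ('+' or '-')."""

    strand: str
    start: int
    span: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.span < 1:
            raise ValueError("span must be >= 1")


def normalize_sequence(raw: str) -> str:
    """Uppercase, map U->T, and reject ambiguity codes (1-based position
    reported in the error)."""
    seq = raw.upper().replace("U", "T")
    for i, c in enumerate(seq):
        if c not in _VALID:
            raise AlphabetError(
                f"invalid nucleotide {c!r} at position {i + 1}"
            )
    return seq


@dataclass
class Genome:
    """A single (by default circular) nucleotide sequence over {A,C,G,T}."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.seq = normalize_sequence(self.seq)
        if not self.seq:
            raise FormatError("empty genome sequence")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def strand_seq(self, strand: str) -> str:
        """The 5'->3' sequence of the requested strand."""
        if strand == "+":
            return self.seq
        if strand == "-":
            return reverse_complement(self.seq)
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    def fetch(self, locus: StrandedLocus) -> str:
        """Nucleotides of ``locus`` read 5'->3' on its strand, wrapping
        modulo the genome length when circular."""
        L = self.length
        start = locus.start % L if self.circular else locus.start
        if not self.circular and locus.start + locus.span > L:
            raise BoundsError(
                f"locus {locus} extends past the end of linear genome "
                f"{self.id!r} (length {L})"
            )
        s = self.strand_seq(locus.strand)
        end = start + locus.span
        if end <= L:
            return s[start:end]
        reps = end // L + 1
        return (s * reps)[start:end]


# Back-compat alias used by call sites written against the module contract.
def fetch_subseq(g: Genome, locus: StrandedLocus) -> str:
    return g.fetch(locus)


def read_fasta(path: Union[str, Path]) -> Genome:
    """Read a single-record FASTA into a :class:`Genome`.

    The first record is used; additional records trigger a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path} contains {len(records)} records; using the first "
            f"({records[0].id})",
            stacklevel=2,
        )
    rec = records[0]
    return Genome(id=rec.id, seq=str(rec.seq))


def write_fasta(g: Genome, path: Union[str, Path], width: int = 60) -> None:
    rec = SeqRecord(Seq(g.seq), id=g.id, description="")
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file([rec])


def frame_number(strand: str, frame_offset: int) -> int:
    """Map (strand, offset 0-2) to the 1-6 frame numbering."""
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    base = 1 if strand == "+" else 4
    return base + frame_offset


def frame_strand_offset(frame: int) -> tuple:
    """Inverse of :func:`frame_number`."""
    if not 1 <= frame <= 6:
        raise ValueError("frame must be in 1..6")
    strand = "+" if frame <= 3 else "-"
    return strand, (frame - 1) % 3


def frame_translation_coordinate(
    strand: str, frame_offset: int, aa_index: int, length: int | None = None
) -> StrandedLocus:
    """Locus of the codon at 1-based amino-acid index ``aa_index`` in the
    full-genome translation of the given frame.

    ``length`` (genome length) is applied modulo when given, so indices
    past the wrap point of a circular genome remain valid.
    """
    if aa_index < 1:
        raise ValueError("aa_index is 1-based and must be >= 1")
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    start = frame_offset + 3 * (aa_index - 1)
    if length is not None:
        start %= length
    return StrandedLocus(strand=strand, start=start, span=3)


def frame_translation_index(frame_offset: int, start: int, length: int) -> int:
    """1-based amino-acid index of the codon starting at strand offset
    ``start`` in the frame with the given offset (inverse of
    :func:`frame_translation_coordinate` up to the circular wrap)."""
    return ((start - frame_offset) % length) // 3 + 1
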