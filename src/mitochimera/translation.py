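"""Genetic-code translation under regular tricodons and expanded codons.

An expanded codon carries k (1 or 2) silent *trailing* nucleotides: a
tetracodon (k=1) or pentacodon (k=2) is read from its first three
nucleotides only.  Translating a sequence by expanded codons is therefore
equivalent to deleting every 4th (and 5th) nucleotide after each
nucleotide triplet and translating the remainder by tricodons — the
"delRNA" equivalence, kept as a tested invariant.

The default code is the vertebrate mitochondrial code (NCBI translation
table 2: AGA/AGG are stops, ATA is Met, TGA is Trp).  Stops are carried
as unassigned residues until a stop-substitution letter is chosen; the 19
mass-distinguishable substitution letters merge Leu and Ile, which have
identical monoisotopic masses and cannot be told apart by MS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, Optional, Sequence

from Bio.Data import CodonTable

#: The 19 mass-distinguishable amino-acid letters (L and I merged onto L).
STOP_SUBSTITUTIONS = "ACDEFGHKLMNPQRSTVWY"

#: Full 20-letter alphabet.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class FrameError(ValueError):
    """Sequence length incompatible with the requested codon size."""


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry trinucleotide -> amino-acid mapping with explicit stops."""

    name: str
    table: dict  # codon -> one-letter aa, stops excluded
    stop_codons: frozenset

    @classmethod
    def from_ncbi_id(cls, table_id: int = 2) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(
            name=t.names[0],
            table=dict(t.forward_table),
            stop_codons=frozenset(t.stop_codons),
        )

    def __post_init__(self) -> None:
        n = len(self.table) + len(self.stop_codons)
        if n != 64:
            raise ValueError(f"genetic code must cover 64 codons, got {n}")

    def decode(self, codon: str):
        """Return (aa or None, is_stop) for a trinucleotide."""
        if codon in self.stop_codons:
            return None, True
        try:
            return self.table[codon], False
        except KeyError:
            raise ValueError(f"invalid codon {codon!r}") from None


@lru_cache(maxsize=None)
def default_code(table_id: int = 2) -> GeneticCode:
    """Cached genetic code by NCBI table id (default: vertebrate mito)."""
    return GeneticCode.from_ncbi_id(table_id)


@dataclass(frozen=True)
class TranslatedResidue:
    """One translated residue with its source-codon bookkeeping.

    ``offset`` is the 0-based nucleotide offset of the codon within the
    translated sequence; ``mode`` is ``tri`` or ``expanded``.  For stops,
    ``aa`` is None until a stop substitution is applied.
    """

    aa: Optional[str]
    from_stop: bool
    offset: int
    mode: str

    def letter(self, stop_aa: Optional[str] = None) -> str:
        """Render as one character; stop-translated residues lowercase."""
        if not self.from_stop:
            return self.aa
        if stop_aa is None:
            raise ValueError("stop residue rendered without a substitution")
        return stop_aa.lower()


def translate_tricodons(seq: str, code: GeneticCode | None = None) -> List[TranslatedResidue]:
    """Translate by regular 3-nt codons; stops are flagged, not raised."""
    code = code or default_code()
    if len(seq) % 3:
        raise FrameError(f"length {len(seq)} not divisible by 3")
    out = []
    for i in range(0, len(seq), 3):
        aa, is_stop = code.decode(seq[i : i + 3])
        out.append(TranslatedResidue(aa=aa, from_stop=is_stop, offset=i, mode="tri"))
    return out


def translate_expanded(
    seq: str, k: int, code: GeneticCode | None = None
) -> List[TranslatedResidue]:
    """Translate by codons expanded with k silent trailing nucleotides."""
    if k not in (1, 2):
        raise ValueError("k must be 1 (tetracodons) or 2 (pentacodons)")
    code = code or default_code()
    size = 3 + k
    if len(seq) % size:
        raise FrameError(f"length {len(seq)} not divisible by {size}")
    out = []
    for i in range(0, len(seq), size):
        aa, is_stop = code.decode(seq[i : i + 3])
        out.append(
            TranslatedResidue(aa=aa, from_stop=is_stop, offset=i, mode="expanded")
        )
    return out


def delete_silent(seq: str, k: int) -> str:
    """Drop the k silent nucleotides after each triplet (delRNA transform)."""
    size = 3 + k
    return "".join(seq[i : i + 3] for i in range(0, len(seq), size))


def substitute_stops(
    residues: Sequence[TranslatedResidue], stop_aa: Optional[str]
) -> str:
    """Render residues as a string, inserting ``stop_aa`` (lowercase) at
    every stop.  All stops in one peptide receive the same letter."""
    if stop_aa is not None:
        su = stop_aa.upper()
        if su not in STOP_SUBSTITUTIONS:
            raise ValueError(
                f"stop substitution must be one of {STOP_SUBSTITUTIONS}, got {stop_aa!r}"
            )
        stop_aa = su
    return "".join(r.letter(stop_aa) for r in residues)


_IL = str.maketrans("Ii", "Ll")


def collapse_il(s: str) -> str:
    """Map I->L (and i->l), preserving case elsewhere."""
    return s.translate(_IL)


def mass_equivalent(a: str, b: str) -> bool:
    """True iff the sequences are indistinguishable by mass: equal after
    I->L collapse, ignoring case/stop flags."""
    return collapse_il(a.upper()) == collapse_il(b.upper())
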