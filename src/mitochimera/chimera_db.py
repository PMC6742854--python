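"""Theoretical chimeric peptide database.

A chimeric window covers, by default, 30 regular tricodons + 30 codons
expanded by k silent nucleotides + 30 regular tricodons, i.e. 300 nt for
tetracodons (k=1) and 330 nt for pentacodons (k=2), translated to a
90-residue peptide.  Windows slide by single nucleotides along both
strands of the (circular) genome, giving 2·L windows per expansion type.
Windows whose translation hits stop codons are expanded into 19 variants,
one per mass-distinguishable stop-substitution letter; the nominal
database size used for e-value normalisation counts every window 19
times: 2 · L · 19 (= 629,622 for the 16,569 bp human mitogenome).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple, Union

from .genome import Genome, StrandedLocus, BoundsError
from .translation import (
    STOP_SUBSTITUTIONS,
    GeneticCode,
    TranslatedResidue,
    default_code,
    substitute_stops,
    translate_expanded,
    translate_tricodons,
)

#: Placeholder used at stop positions in schematic (variant-free) renderings.
STOP_PLACEHOLDER = "*"

DEFAULT_SEG_CODONS = (30, 30, 30)

SEGMENT_LABELS = ("tri5", "exp", "tri3")


@dataclass(frozen=True)
class ChimericWindow:
    """A genomic window with tri5/expanded/tri3 segment structure."""

    strand: str
    start: int  # 0-based offset on the strand's 5'->3' sequence
    k: int
    seg_codons: Tuple[int, int, int] = DEFAULT_SEG_CODONS

    def __post_init__(self) -> None:
        if self.k not in (1, 2):
            raise ValueError("k must be 1 or 2")
        n1, n2, n3 = self.seg_codons
        if min(n1, n2, n3) < 1:
            raise ValueError("segment codon counts must be >= 1")
        if self.seg_codons == DEFAULT_SEG_CODONS:
            expected = 300 if self.k == 1 else 330
            assert self.nt_span == expected

    @property
    def nt_span(self) -> int:
        n1, n2, n3 = self.seg_codons
        return 3 * n1 + (3 + self.k) * n2 + 3 * n3

    @property
    def n_residues(self) -> int:
        return sum(self.seg_codons)

    @property
    def boundaries(self) -> Tuple[int, int]:
        """Residue indices of the tri5|exp and exp|tri3 junctions."""
        n1, n2, _ = self.seg_codons
        return n1, n1 + n2

    def segment_label(self, residue_index: int) -> str:
        b1, b2 = self.boundaries
        if residue_index < b1:
            return "tri5"
        if residue_index < b2:
            return "exp"
        return "tri3"

    def local_nt(self, residue_index: int) -> int:
        """Window-local nucleotide offset of the residue's codon start."""
        b1, b2 = self.boundaries
        if residue_index < b1:
            return 3 * residue_index
        if residue_index < b2:
            return 3 * b1 + (3 + self.k) * (residue_index - b1)
        return 3 * b1 + (3 + self.k) * (b2 - b1) + 3 * (residue_index - b2)

    def locus(self) -> StrandedLocus:
        return StrandedLocus(self.strand, self.start, self.nt_span)


@dataclass
class ChimericPeptide:
    """A translated window, optionally bound to one stop-substitution."""

    window: ChimericWindow
    residues: List[TranslatedResidue]
    stop_positions: Tuple[int, ...]
    stop_aa: Optional[str] = None  # set iff this record is a stop variant

    def __post_init__(self) -> None:
        if len(self.residues) != self.window.n_residues:
            raise ValueError("residue count does not match window")

    @property
    def schematic(self) -> str:
        """Sequence with stop positions as the placeholder character."""
        return "".join(
            STOP_PLACEHOLDER if r.from_stop else r.aa for r in self.residues
        )

    def rendered(self, stop_aa: Optional[str] = None) -> str:
        """90-letter string; stop positions lowercase of the chosen letter."""
        aa = stop_aa or self.stop_aa
        if self.stop_positions and aa is None:
            raise ValueError("peptide has stops but no substitution letter")
        return substitute_stops(self.residues, aa)


def enumerate_windows(
    g: Genome,
    k: int,
    seg_codons: Tuple[int, int, int] = DEFAULT_SEG_CODONS,
) -> Iterator[ChimericWindow]:
    """All single-nucleotide-step windows, + strand ascending start first,
    then - strand: exactly 2·L windows on a circular genome."""
    probe = ChimericWindow("+", 0, k, seg_codons)
    if not g.circular and g.length < probe.nt_span:
        raise BoundsError(
            f"linear genome of length {g.length} shorter than window span "
            f"{probe.nt_span}"
        )
    n_starts = g.length if g.circular else g.length - probe.nt_span + 1
    for strand in ("+", "-"):
        for start in range(n_starts):
            yield ChimericWindow(strand, start, k, seg_codons)


def translate_window(
    g: Genome, w: ChimericWindow, code: GeneticCode | None = None
) -> ChimericPeptide:
    """Translate the three segments of a window into 90 residues."""
    code = code or default_code()
    n1, n2, n3 = w.seg_codons
    nt = g.fetch(w.locus())
    a = 3 * n1
    b = a + (3 + w.k) * n2
    residues = (
        translate_tricodons(nt[:a], code)
        + translate_expanded(nt[a:b], w.k, code)
        + translate_tricodons(nt[b:], code)
    )
    # re-anchor offsets to window-local coordinates
    residues = [
        TranslatedResidue(
            aa=r.aa, from_stop=r.from_stop, offset=w.local_nt(i), mode=r.mode
        )
        for i, r in enumerate(residues)
    ]
    stops = tuple(i for i, r in enumerate(residues) if r.from_stop)
    return ChimericPeptide(window=w, residues=residues, stop_positions=stops)


def expand_stop_variants(
    p: ChimericPeptide, emit_stop_free_once: bool = True
) -> List[ChimericPeptide]:
    """The 19 stop-substitution variants of a stop-containing peptide.

    Stop-free peptides yield a single record by default; with
    ``emit_stop_free_once=False`` they are replicated 19 times to mirror
    the nominal bookkeeping exactly.
    """
    if not p.stop_positions:
        if emit_stop_free_once:
            return [p]
        return [
            ChimericPeptide(p.window, p.residues, p.stop_positions, stop_aa=None)
            for _ in STOP_SUBSTITUTIONS
        ]
    return [
        ChimericPeptide(p.window, p.residues, p.stop_positions, stop_aa=aa)
        for aa in STOP_SUBSTITUTIONS
    ]


def nominal_db_size(L_g: int, n_subs: int = len(STOP_SUBSTITUTIONS)) -> int:
    """Nominal peptide count for one expansion type: 2·L·n_subs.

    This is the normalisation constant used for e-values; it counts every
    window once per substitution letter regardless of stop content
    (2 × 16,569 × 19 = 629,622 for the human mitogenome).
    """
    if L_g < 1:
        raise ValueError("genome length must be >= 1")
    return 2 * L_g * n_subs


def record_header(genome_id: str, p: ChimericPeptide) -> str:
    w = p.window
    n1, n2, n3 = w.seg_codons
    stops = ",".join(str(i) for i in p.stop_positions) or "-"
    return (
        f"{genome_id}|s={w.strand}|p={w.start + 1}|k={w.k}"
        f"|stop={p.stop_aa or '-'}|seg={n1},{n2},{n3}|stops={stops}"
    )


def parse_header(header: str) -> Tuple[str, ChimericWindow, Optional[str]]:
    """Inverse of :func:`record_header`: (genome id, window, stop letter)."""
    fields = header.split("|")
    gid = fields[0]
    kv = dict(f.split("=", 1) for f in fields[1:])
    seg = tuple(int(x) for x in kv["seg"].split(","))
    w = ChimericWindow(kv["s"], int(kv["p"]) - 1, int(kv["k"]), seg)
    stop_aa = None if kv["stop"] == "-" else kv["stop"]
    return gid, w, stop_aa


def build_database(
    g: Genome,
    ks: Sequence[int] = (1,),
    seg_codons: Tuple[int, int, int] = DEFAULT_SEG_CODONS,
    code: GeneticCode | None = None,
    emit_stop_free_once: bool = True,
) -> Iterator[ChimericPeptide]:
    """Stream every stop-substitution variant of every window, for each k
    in ``ks``, in deterministic order."""
    code = code or default_code()
    for k in ks:
        for w in enumerate_windows(g, k, seg_codons):
            p = translate_window(g, w, code)
            yield from expand_stop_variants(p, emit_stop_free_once)


def write_db_fasta(
    peptides: Iterable[ChimericPeptide],
    path: Union[str, Path],
    genome_id: str = "genome",
    dedupe: bool = False,
    line_width: int = 90,
) -> int:
    """Write variant records to FASTA; returns the record count.

    With ``dedupe=True`` identical sequences are collapsed into one record
    whose header concatenates the provenance headers with ';'.
    """
    if dedupe:
        seen: dict = {}
        order: list = []
        for p in peptides:
            s = p.rendered()
            if s in seen:
                seen[s].append(record_header(genome_id, p))
            else:
                seen[s] = [record_header(genome_id, p)]
                order.append(s)
        n = 0
        with open(path, "w") as fh:
            for s in order:
                fh.write(">" + ";".join(seen[s]) + "\n")
                for i in range(0, len(s), line_width):
                    fh.write(s[i : i + line_width] + "\n")
                n += 1
        return n
    n = 0
    with open(path, "w") as fh:
        for p in peptides:
            s = p.rendered()
            fh.write(">" + record_header(genome_id, p) + "\n")
            for i in range(0, len(s), line_width):
                fh.write(s[i : i + line_width] + "\n")
            n += 1
    return n
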