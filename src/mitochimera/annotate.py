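"""Annotation of detected peptides against the chimeric template database.

Given peptide sequences reported by an MS search (vendor scores are
pass-through inputs, never recomputed), this module

1. finds every chimeric template containing the sequence (I and L are
   mass-equivalent and collapsed; a lowercase letter in a detected
   sequence claims a stop-translated position and matches only a stop
   position of a template variant carrying that same substitution);
2. infers the tricoded/expanded junction.  Residues adjacent to the
   junction that translate identically under the continued tricodon
   frame and under the expanded-codon frame are ambiguous and assigned
   parsimoniously to the tricoded side;
3. applies the chimera filter (>= 8 consecutive tricoded and >= 8
   consecutive expanded-coded residues, both configurable);
4. attaches the database-wide e-value N / 19^min_len;
5. maps the tricoded segment onto canonical proteins when it falls
   in-frame inside an annotated CDS on the same strand.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from itertools import accumulate
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .chimera_db import (
    STOP_PLACEHOLDER,
    ChimericPeptide,
    ChimericWindow,
    DEFAULT_SEG_CODONS,
    enumerate_windows,
    nominal_db_size,
    parse_header,
    translate_window,
)
from .genome import (
    Genome,
    StrandedLocus,
    frame_number,
    frame_translation_index,
)
from .translation import (
    AMINO_ACIDS,
    STOP_SUBSTITUTIONS,
    GeneticCode,
    collapse_il,
    default_code,
    translate_tricodons,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectedPeptide:
    """An observed peptide sequence; lowercase letters claim translated
    stops.  ``score`` and ``q`` are vendor outputs carried through."""

    sequence: str
    sample: str = ""
    score: Optional[float] = None
    q: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty detected peptide")
        for c in self.sequence:
            if c.upper() not in AMINO_ACIDS:
                raise ValueError(f"invalid amino acid {c!r} in {self.sequence!r}")


@dataclass(frozen=True)
class GeneRecord:
    """One canonical CDS: 1-based inclusive + strand coordinates."""

    name: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start > end")


@dataclass
class GeneTable:
    records: List[GeneRecord]

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(names) != len(set(names)):
            raise ValueError("gene names must be unique")
        self.records = sorted(self.records, key=lambda r: (r.start, r.name))

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_gene_table(path: Union[str, Path]) -> GeneTable:
    """Read a GeneTable from TSV (gene, start, end, strand; header
    optional) or from GFF3 CDS lines (gene name from gene=/Name=/ID=)."""
    path = Path(path)
    records = []
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("##gff") or first.count("\t") >= 7:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 8 or f[2] != "CDS":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                ) if len(f) > 8 else {}
                name = attrs.get("gene") or attrs.get("Name") or attrs.get("ID")
                records.append(GeneRecord(name, int(f[3]), int(f[4]), f[6]))
        else:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if f[0].lower() in ("gene", "name"):
                    continue
                records.append(GeneRecord(f[0], int(f[1]), int(f[2]), f[3]))
    return GeneTable(records)


# ---------------------------------------------------------------------------
# template database index
# ---------------------------------------------------------------------------

_SEP = "#"


def search_pattern(sequence: str) -> Tuple[Optional[str], Optional[str]]:
    """Convert a detected sequence into (pattern, stop letter).

    The pattern is I->L collapsed with every lowercase position replaced
    by the stop placeholder; all lowercase letters must agree on one
    substitution letter (one variant substitutes all stops identically),
    otherwise no template can match and (None, None) is returned.
    """
    s = collapse_il(sequence)
    letters = {c.upper() for c in s if c.islower()}
    if len(letters) > 1:
        return None, None
    stop_aa = letters.pop() if letters else None
    pattern = "".join(STOP_PLACEHOLDER if c.islower() else c for c in s)
    return pattern, stop_aa


class ChimeraDatabase:
    """Indexed collection of chimeric templates over one genome.

    Templates are stored once per window (not per stop variant); stop
    positions are held as a placeholder so that one substring scan covers
    all 19 substitution variants at once.
    """

    def __init__(
        self,
        genome: Genome,
        templates: Sequence[ChimericPeptide],
        code: GeneticCode | None = None,
    ):
        self.genome = genome
        self.code = code or default_code()
        self.templates = list(templates)
        self._keys = [collapse_il(t.schematic) for t in self.templates]
        starts = [0]
        starts.extend(accumulate(len(k) + 1 for k in self._keys))
        self._starts = starts[:-1]
        self._text = _SEP.join(self._keys)

    @classmethod
    def from_genome(
        cls,
        genome: Genome,
        ks: Sequence[int] = (1, 2),
        seg_codons: Tuple[int, int, int] = DEFAULT_SEG_CODONS,
        code: GeneticCode | None = None,
    ) -> "ChimeraDatabase":
        code = code or default_code()
        templates = [
            translate_window(genome, w, code)
            for k in ks
            for w in enumerate_windows(genome, k, seg_codons)
        ]
        return cls(genome, templates, code)

    @classmethod
    def from_fasta(
        cls, path: Union[str, Path], genome: Genome, code: GeneticCode | None = None
    ) -> "ChimeraDatabase":
        """Rebuild the template index from a database FASTA written by
        :func:`mitochimera.chimera_db.write_db_fasta` (stop variants of
        one window collapse back to a single template)."""
        code = code or default_code()
        from Bio import SeqIO

        seen = set()
        windows = []
        for rec in SeqIO.parse(str(path), "fasta"):
            for header in rec.description.split(";"):
                _gid, w, _stop = parse_header(header.lstrip(">").strip())
                if w not in seen:
                    seen.add(w)
                    windows.append(w)
        templates = [translate_window(genome, w, code) for w in windows]
        return cls(genome, templates, code)

    def __len__(self) -> int:
        return len(self.templates)

    def nominal_size(self) -> int:
        """Nominal per-expansion-type database size 2·L·19."""
        return nominal_db_size(self.genome.length)

    def lookup(self, pattern: str) -> List[Tuple[int, int]]:
        """(template index, residue offset) of every occurrence."""
        hits = []
        pos = self._text.find(pattern)
        while pos != -1:
            ti = bisect.bisect_right(self._starts, pos) - 1
            hits.append((ti, pos - self._starts[ti]))
            pos = self._text.find(pattern, pos + 1)
        return hits


def match_template(
    d: DetectedPeptide, db: ChimeraDatabase
) -> List[Tuple[ChimericPeptide, int]]:
    """Every (template variant, offset) whose rendering contains the
    detected sequence, in deterministic (+ strand, start, k) order."""
    pattern, stop_aa = search_pattern(d.sequence)
    if pattern is None:
        return []
    out = []
    for ti, off in db.lookup(pattern):
        t = db.templates[ti]
        out.append((replace_variant(t, stop_aa), off))
    out.sort(
        key=lambda h: (
            h[0].window.strand != "+",
            h[0].window.start,
            h[0].window.k,
            h[1],
        )
    )
    return out


def replace_variant(t: ChimericPeptide, stop_aa: Optional[str]) -> ChimericPeptide:
    """Bind a template to the stop-substitution claimed by the match."""
    return ChimericPeptide(
        window=t.window,
        residues=t.residues,
        stop_positions=t.stop_positions,
        stop_aa=stop_aa,
    )


# ---------------------------------------------------------------------------
# junction inference
# ---------------------------------------------------------------------------

@dataclass
class ChimeraAnnotation:
    """A detected peptide resolved against one chimeric template."""

    peptide: DetectedPeptide
    template: ChimericPeptide
    match_offset: int
    tri_len: int
    exp_len: int
    ambiguous_span: int
    junction_side: Optional[str]  # '5prime_noncanonical'/'3prime_noncanonical'
    junction: Optional[int]  # template residue index of the boundary used
    tri_locus: Optional[StrandedLocus]  # genomic span of the tricoded run
    frame: Optional[int] = None  # 1-6
    pos_start: Optional[int] = None  # 1-based aa index in frame translation
    pos_end: Optional[int] = None
    evalue: Optional[float] = None
    gene_hit: Optional[Tuple[str, Tuple[int, int]]] = None

    @property
    def rendered(self) -> str:
        """Detected sequence with '|' junction marks; when an ambiguous
        run exists it sits between two marks, e.g. 'ABC|X|DEF'."""
        s = self.peptide.sequence
        if self.junction is None:
            return s
        b = self.junction - self.match_offset
        if self.junction_side == "3prime_noncanonical":
            cuts = sorted({b, b + self.ambiguous_span})
        else:
            cuts = sorted({b - self.ambiguous_span, b})
        out, prev = [], 0
        for c in cuts:
            out.append(s[prev:c])
            prev = c
        out.append(s[prev:])
        return "|".join(out)


def _continuation_matches(
    g: Genome,
    code: GeneticCode,
    w: ChimericWindow,
    local_nt: int,
    residue,
) -> bool:
    """Does the tricodon read at window-local ``local_nt`` reproduce the
    expanded-codon residue?  Two stops are considered matching (any
    substitution letter fits both readings)."""
    codon = g.fetch(StrandedLocus(w.strand, (w.start + local_nt) % g.length, 3))
    aa, is_stop = code.decode(codon)
    if residue.from_stop:
        return is_stop
    if is_stop:
        return False
    return collapse_il(aa) == collapse_il(residue.aa)


def resolve_junction(
    d: DetectedPeptide,
    template: ChimericPeptide,
    offset: int,
    g: Genome,
    code: GeneticCode | None = None,
) -> ChimeraAnnotation:
    """Segment the matched peptide and apply the parsimony rule.

    When the match straddles both template junctions, the one yielding
    the more balanced chimera (larger min(tri_len, exp_len)) is kept.
    """
    code = code or default_code()
    w = template.window
    m = len(d.sequence)
    b1, b2 = w.boundaries
    end = offset + m

    candidates = []
    if offset < b1 < end:
        candidates.append(b1)
    if offset < b2 < end:
        candidates.append(b2)

    if not candidates:
        in_exp = b1 <= offset and end <= b2
        tri_len, exp_len = (0, m) if in_exp else (m, 0)
        tri_locus = None
        frame = pos_start = pos_end = None
        if tri_len:
            local = w.local_nt(offset)
            p = (w.start + local) % g.length
            tri_locus = StrandedLocus(w.strand, p, 3 * tri_len)
            fo = p % 3
            frame = frame_number(w.strand, fo)
            pos_start = frame_translation_index(fo, p, g.length)
            pos_end = pos_start + tri_len - 1
        return ChimeraAnnotation(
            peptide=d,
            template=template,
            match_offset=offset,
            tri_len=tri_len,
            exp_len=exp_len,
            ambiguous_span=0,
            junction_side=None,
            junction=None,
            tri_locus=tri_locus,
            frame=frame,
            pos_start=pos_start,
            pos_end=pos_end,
        )

    best = None
    for b in candidates:
        ann = _resolve_at(d, template, offset, b, g, code)
        if best is None or min(ann.tri_len, ann.exp_len) > min(
            best.tri_len, best.exp_len
        ):
            best = ann
    return best


def _resolve_at(
    d: DetectedPeptide,
    template: ChimericPeptide,
    offset: int,
    b: int,
    g: Genome,
    code: GeneticCode,
) -> ChimeraAnnotation:
    w = template.window
    m = len(d.sequence)
    b1, b2 = w.boundaries
    end = offset + m

    if b == b1:  # expanded run on the 3' side of the junction
        side = "3prime_noncanonical"
        exp_lo, exp_hi = b1, min(end, b2)
        tri_len0 = b1 - offset
        span = 0
        anchor = w.local_nt(b1)  # continued tricodon frame starts here
        while b1 + span < exp_hi and _continuation_matches(
            g, code, w, anchor + 3 * span, template.residues[b1 + span]
        ):
            span += 1
        tri_len = tri_len0 + span
        exp_len = (exp_hi - exp_lo) - span
        first_local = w.local_nt(offset)
    else:  # b == b2: expanded run on the 5' side
        side = "5prime_noncanonical"
        exp_lo, exp_hi = max(offset, b1), b2
        tri_len0 = end - b2 if end > b2 else 0
        # clip to the template end
        tri_len0 = min(tri_len0, w.n_residues - b2)
        span = 0
        anchor = w.local_nt(b2)  # tricodon frame extended backwards
        while b2 - 1 - span >= exp_lo and _continuation_matches(
            g, code, w, anchor - 3 * (span + 1), template.residues[b2 - 1 - span]
        ):
            span += 1
        tri_len = tri_len0 + span
        exp_len = (exp_hi - exp_lo) - span
        first_local = anchor - 3 * span

    p = (w.start + first_local) % g.length
    tri_locus = StrandedLocus(w.strand, p, 3 * tri_len) if tri_len else None
    fo = p % 3
    frame = frame_number(w.strand, fo) if tri_len else None
    pos_start = frame_translation_index(fo, p, g.length) if tri_len else None
    pos_end = pos_start + tri_len - 1 if tri_len else None
    return ChimeraAnnotation(
        peptide=d,
        template=template,
        match_offset=offset,
        tri_len=tri_len,
        exp_len=exp_len,
        ambiguous_span=span,
        junction_side=side,
        junction=b,
        tri_locus=tri_locus,
        frame=frame,
        pos_start=pos_start,
        pos_end=pos_end,
    )


def passes_filter(a: ChimeraAnnotation, min_len: int = 8) -> bool:
    """The chimera filter: at least ``min_len`` consecutive tricoded and
    ``min_len`` consecutive expanded-coded residues, adjacent runs."""
    return a.tri_len >= min_len and a.exp_len >= min_len


def evalue(db_size: int, min_len: int = 8) -> float:
    """Database-wide expectation of a chance run: db_size · 19^-min_len."""
    if db_size < 0:
        raise ValueError("db_size must be >= 0")
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return db_size * 19.0 ** (-min_len)


# ---------------------------------------------------------------------------
# canonical-protein mapping
# ---------------------------------------------------------------------------

def _gene_strand_offset(gene: GeneRecord, L: int) -> int:
    """0-based offset of the gene's 5' end on its own strand."""
    return gene.start - 1 if gene.strand == "+" else L - gene.end


def map_segment_to_gene(
    locus: StrandedLocus,
    segment_seq: str,
    genes: GeneTable,
    g: Genome,
    code: GeneticCode | None = None,
) -> Optional[Tuple[str, Tuple[int, int]]]:
    """Map a tricoded genomic segment onto a canonical protein.

    ``locus`` spans 3·n nucleotides on one strand; ``segment_seq`` is the
    n-residue detected sequence (lowercase = claimed stop translation).
    A hit requires same strand, full containment in the CDS, placement in
    the CDS reading frame, and sequence concordance (I/L collapsed;
    stop-claimed positions exempt).  Returns (gene, 1-based residue
    range) or None; near-frame placements are rejected and logged.
    """
    code = code or default_code()
    L = g.length
    p, span = locus.start, locus.span
    n_res = span // 3
    for gene in genes:
        if gene.strand != locus.strand:
            continue
        g0 = _gene_strand_offset(gene, L)
        glen = gene.end - gene.start + 1
        if not (g0 <= p and p + span <= g0 + glen):
            continue
        if (p - g0) % 3 != 0:
            logger.info(
                "gene %s overlaps but out of frame (offset %d)", gene.name, p - g0
            )
            continue
        residues = translate_tricodons(g.fetch(locus), code)
        ok = True
        for det_char, r in zip(segment_seq, residues):
            if det_char.islower():
                continue  # stop-substituted position, exempt
            if r.from_stop or collapse_il(r.aa) != collapse_il(det_char.upper()):
                ok = False
                break
        if not ok:
            logger.info("gene %s in frame but sequence discordant", gene.name)
            continue
        start_res = (p - g0) // 3 + 1
        return gene.name, (start_res, start_res + n_res - 1)
    return None


def map_to_gene(
    a: ChimeraAnnotation,
    genes: GeneTable,
    g: Genome,
    code: GeneticCode | None = None,
) -> Optional[Tuple[str, Tuple[int, int]]]:
    """Map the tricoded run of an annotation onto a canonical protein."""
    if a.tri_locus is None or a.tri_len == 0:
        return None
    return map_segment_to_gene(
        a.tri_locus, _tricoded_subsequence(a), genes, g, code
    )


def _tricoded_subsequence(a: ChimeraAnnotation) -> str:
    """The detected-peptide substring covering the tricoded run (after
    parsimony reassignment)."""
    s = a.peptide.sequence
    if a.junction is None:
        return s if a.tri_len else ""
    b = a.junction - a.match_offset
    if a.junction_side == "3prime_noncanonical":
        return s[: b + a.ambiguous_span]
    return s[b - a.ambiguous_span :]


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "sample", "peptide", "matched", "k", "strand", "window_start",
    "stop_aa", "frame", "pos_start", "pos_end", "rendered", "tri_len",
    "exp_len", "ambiguous_span", "junction_side", "evalue",
    "passes_filter", "multi_k", "gene", "gene_res_start", "gene_res_end",
    "score", "q",
]


def annotate_all(
    detected: Iterable[DetectedPeptide],
    db: ChimeraDatabase,
    genes: Optional[GeneTable] = None,
    min_len: int = 8,
    score_threshold: Optional[float] = None,
    q_threshold: Optional[float] = None,
) -> pd.DataFrame:
    """One row per (peptide, best template per expansion type k).

    The best template minimises the number of stop substitutions, then
    prefers the + strand, the lowest start, and the smallest k.  Vendor
    score/q thresholds, when given, filter the input rows (pass-through;
    nothing is rescored).  Peptides matching templates of more than one k
    are reported once per k with ``multi_k=True``.
    """
    ev = {k: evalue(nominal_db_size(db.genome.length), min_len) for k in (1, 2)}
    rows = []
    for d in detected:
        if score_threshold is not None and (d.score is None or d.score <= score_threshold):
            continue
        if q_threshold is not None and (d.q is None or d.q >= q_threshold):
            continue
        hits = match_template(d, db)
        if not hits:
            rows.append(_empty_row(d))
            continue
        by_k: dict = {}
        for t, off in hits:
            key = t.window.k
            rank = (
                len(t.stop_positions),
                t.window.strand != "+",
                t.window.start,
                off,
            )
            if key not in by_k or rank < by_k[key][0]:
                by_k[key] = (rank, t, off)
        multi_k = len(by_k) > 1
        for k in sorted(by_k):
            _rank, t, off = by_k[k]
            a = resolve_junction(d, t, off, db.genome, db.code)
            a.evalue = ev[k]
            if genes is not None:
                a.gene_hit = map_to_gene(a, genes, db.genome, db.code)
            rows.append(_row(d, a, min_len, multi_k))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def _empty_row(d: DetectedPeptide) -> dict:
    return {
        "sample": d.sample, "peptide": d.sequence, "matched": False,
        "k": pd.NA, "strand": pd.NA, "window_start": pd.NA, "stop_aa": pd.NA,
        "frame": pd.NA, "pos_start": pd.NA, "pos_end": pd.NA,
        "rendered": d.sequence, "tri_len": pd.NA, "exp_len": pd.NA,
        "ambiguous_span": pd.NA, "junction_side": pd.NA, "evalue": pd.NA,
        "passes_filter": False, "multi_k": False, "gene": pd.NA,
        "gene_res_start": pd.NA, "gene_res_end": pd.NA,
        "score": d.score, "q": d.q,
    }


def _row(d: DetectedPeptide, a: ChimeraAnnotation, min_len: int, multi_k: bool) -> dict:
    gene, res = (a.gene_hit or (pd.NA, (pd.NA, pd.NA)))
    return {
        "sample": d.sample,
        "peptide": d.sequence,
        "matched": True,
        "k": a.template.window.k,
        "strand": a.template.window.strand,
        "window_start": a.template.window.start + 1,
        "stop_aa": a.template.stop_aa or "-",
        "frame": a.frame if a.frame is not None else pd.NA,
        "pos_start": a.pos_start if a.pos_start is not None else pd.NA,
        "pos_end": a.pos_end if a.pos_end is not None else pd.NA,
        "rendered": a.rendered,
        "tri_len": a.tri_len,
        "exp_len": a.exp_len,
        "ambiguous_span": a.ambiguous_span,
        "junction_side": a.junction_side or pd.NA,
        "evalue": a.evalue,
        "passes_filter": passes_filter(a, min_len),
        "multi_k": multi_k,
        "gene": gene,
        "gene_res_start": res[0],
        "gene_res_end": res[1],
        "score": d.score,
        "q": d.q,
    }


# CDS coordinates of the 13 protein-coding genes of the human mitogenome
# (NC_012920, 1-based inclusive).  Only ND6 lies on the - strand.
_HUMAN_MITO_CDS = [
    ("ND1", 3307, 4262, "+"),
    ("ND2", 4470, 5511, "+"),
    ("CO1", 5904, 7445, "+"),
    ("CO2", 7586, 8269, "+"),
    ("AT8", 8366, 8572, "+"),
    ("AT6", 8527, 9207, "+"),
    ("CO3", 9207, 9990, "+"),
    ("ND3", 10059, 10404, "+"),
    ("ND4L", 10470, 10766, "+"),
    ("ND4", 10760, 12137, "+"),
    ("ND5", 12337, 14148, "+"),
    ("ND6", 14149, 14673, "-"),
    ("CytB", 14747, 15887, "+"),
]

HUMAN_MITO_LENGTH = 16569


def human_mito_gene_table() -> GeneTable:
    """The 13 canonical CDS records of the human mitogenome (NC_012920)."""
    return GeneTable([GeneRecord(*r) for r in _HUMAN_MITO_CDS])


def read_detected(path: Union[str, Path]) -> List[DetectedPeptide]:
    """Read detected peptides from TSV (sequence[, sample, score, q]) or
    bare one-sequence-per-line text."""
    path = Path(path)
    peptides = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        return []
    header = None
    first = lines[0].split("\t")
    if first[0].lower() in ("sequence", "peptide"):
        header = [h.lower() for h in first]
        lines = lines[1:]
    for ln in lines:
        f = ln.split("\t")
        if header:
            rec = dict(zip(header, f))
            peptides.append(
                DetectedPeptide(
                    sequence=rec.get("sequence") or rec.get("peptide"),
                    sample=rec.get("sample", ""),
                    score=float(rec["score"]) if rec.get("score") not in (None, "") else None,
                    q=float(rec["q"]) if rec.get("q") not in (None, "") else None,
                )
            )
        else:
            peptides.append(DetectedPeptide(sequence=f[0]))
    return peptides
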