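"""Seeded generators: random circular genomes and planted detections.

These emulate the role real MS datasets play downstream of the vendor
search: lists of observed peptide sequences.  A *plant* is a digestion
fragment of a known chimeric window that straddles a tricoded/expanded
junction with at least ``min_len`` residues on each side, so the whole
annotation pipeline (template matching, junction inference, chimera
filter) can be tested against recorded ground truth.  Noise peptides are
random sequences over the mass-distinguishable alphabet.

All randomness flows from one integer seed through a local
``numpy.random.Generator``; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .annotate import DetectedPeptide, passes_filter, resolve_junction
from .chimera_db import (
    DEFAULT_SEG_CODONS,
    ChimericWindow,
    translate_window,
)
from .digestion import CleavageRule, digest
from .genome import Genome
from .translation import STOP_SUBSTITUTIONS, GeneticCode, default_code

DEFAULT_GC = 0.44  # close to the human mitogenome's base composition


class PlantConfigError(ValueError):
    pass


def random_genome(L: int, seed: int, gc: float = DEFAULT_GC) -> Genome:
    """A circular genome of i.i.d. nucleotides at the given GC fraction."""
    if L < 1:
        raise ValueError("genome length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=L, p=p))
    return Genome(id=f"synthetic_L{L}_seed{seed}", seq=seq, circular=True)


@dataclass(frozen=True)
class PlantSpec:
    """Parameters for planting detectable chimeric fragments."""

    n_plants: int = 50
    k_mix: Tuple[float, float] = (0.5, 0.5)  # proportions of k=1, k=2
    stop_rate: Optional[float] = None  # None: natural stop content
    cleavage: CleavageRule = field(default_factory=lambda: CleavageRule("K", "carboxyl", 1))
    min_len: int = 8
    noise_peptides: int = 0
    seed: int = 0
    seg_codons: Tuple[int, int, int] = DEFAULT_SEG_CODONS
    max_retries: int = 500

    def __post_init__(self) -> None:
        if abs(sum(self.k_mix) - 1.0) > 1e-9:
            raise ValueError("k_mix proportions must sum to 1")
        if min(self.n_plants, self.noise_peptides) < 0:
            raise ValueError("counts must be >= 0")
        if self.min_len > min(self.seg_codons):
            raise PlantConfigError(
                f"min_len {self.min_len} exceeds the smallest segment "
                f"({min(self.seg_codons)} codons): no fragment can satisfy "
                "the junction-straddling requirement"
            )


TRUTH_COLUMNS = [
    "plant", "strand", "start", "k", "stop_aa", "frag_offset", "frag_len",
    "junction", "junction_side", "ambiguous_span", "sequence",
]


def _straddling_fragments(peptide_str, bounds, min_len):
    """(fragment, junction, side) for fragments with >= min_len residues
    on each side of a template junction."""
    b1, b2 = bounds
    out = []
    for frag in peptide_str:
        o, l = frag.offset, len(frag.sequence)
        if o + min_len <= b1 and o + l >= b1 + min_len:
            out.append((frag, b1, "3prime_noncanonical"))
        if o + min_len <= b2 and o + l >= b2 + min_len:
            out.append((frag, b2, "5prime_noncanonical"))
    return out


def plant_detections(
    g: Genome,
    spec: PlantSpec,
    code: GeneticCode | None = None,
) -> Tuple[List[DetectedPeptide], pd.DataFrame]:
    """Plant ``spec.n_plants`` junction-straddling fragments plus noise.

    For each plant a window and stop letter are drawn, the window is
    translated and digested with ``spec.cleavage``, and a fragment with
    at least ``spec.min_len`` residues on each side of a junction is
    selected (windows are resampled, with bounded retries, when digestion
    yields none).  Returns the detected-peptide list and a ground-truth
    table (window identity, stop letter, fragment offset, junction).
    """
    code = code or default_code()
    rng = np.random.default_rng(spec.seed)
    probe = ChimericWindow("+", 0, 2, spec.seg_codons)
    if g.length < probe.nt_span and not g.circular:
        raise PlantConfigError("genome too short for windows")

    detected: List[DetectedPeptide] = []
    truth_rows = []
    for plant_id in range(spec.n_plants):
        k = 1 if rng.random() < spec.k_mix[0] else 2
        chosen = None
        for _try in range(spec.max_retries):
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(0, g.length))
            w = ChimericWindow(strand, start, k, spec.seg_codons)
            p = translate_window(g, w, code)
            if spec.stop_rate is not None:
                want_stop = rng.random() < spec.stop_rate
                if bool(p.stop_positions) != want_stop:
                    continue
            stop_aa = (
                str(rng.choice(list(STOP_SUBSTITUTIONS)))
                if p.stop_positions
                else None
            )
            rendered = p.rendered(stop_aa) if p.stop_positions else p.rendered()
            frags = digest(rendered, spec.cleavage)
            cands = _straddling_fragments(frags, w.boundaries, spec.min_len)
            # keep only fragments that still satisfy the filter after the
            # parsimony reassignment at their own junction
            resolved = []
            for frag, junction, side in cands:
                ann = resolve_junction(
                    DetectedPeptide(frag.sequence, "synthetic"),
                    p, frag.offset, g, code,
                )
                if ann.junction == junction and passes_filter(ann, spec.min_len):
                    resolved.append((frag, ann))
            if not resolved:
                continue
            frag, ann = resolved[int(rng.integers(0, len(resolved)))]
            chosen = (w, stop_aa, frag, ann)
            break
        if chosen is None:
            raise PlantConfigError(
                f"no junction-straddling fragment found in {spec.max_retries} "
                "window draws; relax the cleavage rule or min_len"
            )
        w, stop_aa, frag, ann = chosen
        detected.append(
            DetectedPeptide(sequence=frag.sequence, sample="synthetic")
        )
        truth_rows.append(
            {
                "plant": plant_id,
                "strand": w.strand,
                "start": w.start,
                "k": w.k,
                "stop_aa": stop_aa or "-",
                "frag_offset": frag.offset,
                "frag_len": len(frag.sequence),
                "junction": ann.junction,
                "junction_side": ann.junction_side,
                "ambiguous_span": ann.ambiguous_span,
                "sequence": frag.sequence,
            }
        )

    lengths = [len(d.sequence) for d in detected] or [2 * spec.min_len]
    for _ in range(spec.noise_peptides):
        n = int(rng.choice(lengths))
        seq = "".join(rng.choice(list(STOP_SUBSTITUTIONS), size=n))
        detected.append(DetectedPeptide(sequence=seq, sample="noise"))

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return detected, truth
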