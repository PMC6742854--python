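# Methods

## Chimeric window model

A chimeric window is the concatenation, read 5′→3′ on one strand of a
circular genome, of `n1` tricodons, `n2` codons expanded by `k` silent
nucleotides, and `n3` tricodons (defaults `n1 = n2 = n3 = 30`,
`k ∈ {1, 2}`), spanning `3·n1 + (3+k)·n2 + 3·n3` nucleotides — 300 nt
for tetracodons and 330 nt for pentacodons at the defaults. Windows
start at every position of both strands, so a circular genome of length
`L` yields `2·L` windows per expansion type, enumerated + strand first
in ascending start order for reproducibility. Circularity is the
default (and is what makes the count exactly `2·L`); linear genomes are
supported with bounds checking. Internally all coordinates are 0-based
half-open; everything user-facing (FASTA headers, annotation tables) is
1-based inclusive. Frames are numbered 1–6 with frame = offset + 1 on
the + strand and offset + 4 on the reverse-complement strand read
5′→3′; the offset↔frame pairing within a strand is a convention this
package fixes and documents, since only the 1–3/4–6 split is standard.

## Translation

The genetic code is selectable by NCBI table id and defaults to the
vertebrate mitochondrial code (table 2: AGA/AGG stops, ATA→Met,
TGA→Trp), taken from Biopython's table data. Expanded codons carry
their silent nucleotides as a **trailing** tail: a (3+k)-group is
translated from its first three nucleotides. This makes expanded-codon
translation of a sequence identical to tricodon translation of the
"delRNA" transform (delete the 4th, or 4th and 5th, nucleotide after
each triplet) — an equivalence held by construction and enforced as a
tested invariant on seeded random sequences.

Only code-defined stops (AGA, AGG, TAA, TAG under table 2) are
substitutable; TGA is native Trp under the mitochondrial code and is
never treated as a stop. A peptide containing stops is emitted once per
substitution letter, the **same** letter at all of its stops, over the
19 mass-distinguishable amino acids (Leu/Ile merged — equal
monoisotopic mass). Stop-translated residues are rendered lowercase.
Stop-free windows are emitted once; the nominal size `2·L·19` used for
e-values still counts every window 19 times, so the written record
count is bounded above by, and generally close to, the nominal size
(random and mitochondrial-like sequence puts stops in nearly every
90-codon window). A flag restores literal 19-fold emission of stop-free
windows for exact nominal bookkeeping.

## Junction inference and parsimony

A detected peptide is located in templates by exact substring matching
after I→L collapse, with lowercase letters matching only stop positions
(and forcing one common substitution letter); because variants differ
only at stop positions, matching is done once per window against a
stop-placeholder rendering rather than once per variant.

The template's segment boundaries classify matched residues as tricoded
or expanded-coded. The boundary is then refined by the parsimony rule:
starting at the junction and moving into the expanded segment, a
residue is *ambiguous* if the continued tricodon frame (stepping 3 nt
per residue from the junction nucleotide) translates to the same amino
acid as the expanded reading; the ambiguous run is reassigned to the
tricoded side. Two geometric consequences are worth noting. At the
tri|expanded (5′) boundary, the first expanded codon reads the same
three nucleotides as the continued tricodon frame, so it is always
ambiguous when covered by the match; divergence begins with the second
continuation codon, which contains the first silent nucleotide. At the
expanded|tri (3′) boundary the backward continuation codon contains the
silent tail immediately, so the test is genuine from the first residue.
Stop-vs-stop comparisons count as matching (any substitution letter
fits both readings). When a long match straddles both boundaries, the
junction giving the larger `min(tri_len, exp_len)` is reported. The
chimera filter requires `tri_len ≥ m` and `exp_len ≥ m` with `m = 8` by
default, and the attached e-value is `N · 19⁻ᵐ` with `N = 2·L·19`; for
the human mitogenome this evaluates to `629,622/19⁸ ≈ 3.7·10⁻⁵`.

Among multiple matching templates the reported one minimises the stop
count, then prefers + strand, lower start, smaller k; peptides matching
templates of both expansion types are reported once per k and flagged
`multi_k`. Vendor scores (Xcorr, PLGS) and q-values arriving with
detected peptides are pass-through columns; optional thresholds
(defaults in the literature: Xcorr > 1.99, PLGS ≥ 6.49, q < 0.05)
filter rows without any rescoring.

## Canonical-protein mapping

A tricoded run maps to a canonical protein when its genomic span lies
on the same strand, fully inside the CDS, at an in-frame offset
(`offset mod 3 = 0`), and its sequence concords with the translated CDS
under I/L collapse, with stop-claimed (lowercase) positions exempt.
Near-frame placements are rejected and logged rather than fuzzily
accepted, since residue-index claims are only meaningful in-frame. The
13 CDS coordinate records of the human mitogenome (NC_012920) ship as a
built-in table; ND6 is the one − strand gene.

## Digestion and masses

Cleavage rules name one residue species in the 19-letter merged
alphabet and a side: carboxyl cuts after the residue, amino before it;
cuts falling on a terminus are no-ops, so no empty fragments arise.
"One missed cleavage" means ≤ 1 (with `s` internal sites the fragment
count is `(s+1) + s`). The per-sample search enumeration is the 38
configurations (19 residues × 2 sides, residues alphabetical, carboxyl
first). Monoisotopic masses are standard residue masses (pyteomics)
plus water (18.010565 Da) plus modification deltas; the default
modification set is fixed carbamidomethyl-C (+57.02146 Da), variable
oxidation-M (+15.99491 Da) and variable Lys→pyrrolysine (+109.05276 Da,
the Unimod delta — the community constant, configurable since vendor
documentation does not print it). Mass tests compare at 1e-4 Da.

## Decoys and q-values

Decoy records are full per-record sequence reversals, count-preserving.
The q-value of a hit is the minimum, over all score thresholds that
still accept it, of `#(decoys ≥ s) / max(1, #(targets ≥ s))`, computed
by suffix-minimum over the descending score list; ties share a q and
values are capped at 1. This is the plain target-decoy estimator:
semi-supervised rescoring of spectral features is out of scope, and on
synthetic score mixtures the estimator's empirical FDR at q < 0.05 is
verified to stay near the nominal level.

## Synthetic data

`random_genome` draws i.i.d. nucleotides at a configurable GC fraction
(default 0.44, near the human mitogenome's composition — cosmetic, it
affects only codon usage statistics). `plant_detections` draws windows
uniformly over strand × start × k, substitutes a random stop letter
when needed, digests the 90-mer with the configured cleavage rule, and
keeps a fragment only if it straddles a junction with at least
`min_len` residues on each side *after* the parsimony reassignment —
so planted fragments pass the chimera filter by construction, and the
truth table records the exact junction and ambiguous span the annotator
should infer. Windows with no qualifying fragment are resampled with
bounded retries. Noise peptides are uniform random sequences over the
19-letter alphabet with lengths drawn from the planted fragments. What
this emulates is the *sequence-level* output of an MS search; it does
not model spectra, intensities, retention times, or the vendor scoring
process, so passing recovery tests demonstrates the correctness of
database construction and annotation logic, not end-to-end MS
sensitivity on real data.

## Problem sizes and numerical choices

The test suite exercises the full-scale database build (16,569 bp, both
expansion types, ~629k records each), translation-equivalence on 1,000
seeded sequences per k, planted recovery with 200 fragments on a
5,000 bp genome, and FDR control with 1,000 target/decoy pairs; unit
tests run on 300–3,000 bp genomes. All randomness is seeded through
local `numpy` generators; identical seeds give byte-identical outputs.
Determinism of the database FASTA is asserted byte-for-byte.

## Known limitations

- One sequence per genome; no ambiguity codes.
- The e-value is the printed normalisation formula, not a calibrated
  statistic; it ignores composition bias and the actual emitted record
  count.
- Gene mapping requires exact in-frame containment; chimeric peptides
  whose tricoded part crosses a CDS boundary are not split.
- Real-genome accession checks in the test suite use a synthetic
  stand-in sequence of the correct length with the real CDS coordinate
  table, verifying the coordinate arithmetic and self-consistent
  concordance; runs against the true NC_012920 sequence require
  supplying that FASTA.
- Expansions beyond k = 2 and chimeric templates with more than one
  expanded segment are unsupported.
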