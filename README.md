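# mitochimera

Tools for building and interrogating databases of **chimeric peptides** —
peptides translated partly from regular trinucleotide codons and partly
from codons expanded by one or two silent nucleotides (tetracodons and
pentacodons) — from a circular genome such as the human mitogenome.

Frameshifting translation by tRNAs with expanded anticodons, or regular
translation of transcripts from which every 4th (or 4th and 5th)
nucleotide after each triplet has been deleted, can produce protein
stretches that match no reading frame of the genome under the standard
code. Proteogenomic searches for such products need a custom sequence
database. `mitochimera` generates that database and annotates the
peptides a search engine reports against it.

## The model

For expansion `k ∈ {1, 2}`, a **chimeric window** covers, 5′→3′ on one
strand,

```
30 tricodons  +  30 (3+k)-nt expanded codons  +  30 tricodons
= 90 + 120 + 90 = 300 nt   (tetracodons, k = 1)
= 90 + 150 + 90 = 330 nt   (pentacodons, k = 2)
```

and translates to a 90-residue peptide (expanded codons are read from
their first three nucleotides; the trailing `k` nucleotides are silent).
Windows step by single nucleotides along the complete circular genome on
both strands: `2·L` windows per expansion type (`2 × 16,569` for the
human mitogenome). Translation uses the vertebrate mitochondrial code
(NCBI table 2) by default. A window whose translation hits stop codons
is emitted as 19 variants, one per mass-distinguishable amino acid
substituted at *all* of its stops (Leu/Ile merged; stop-translated
residues are rendered lowercase). The nominal database size used for
e-value normalisation is

```
N = 2 · L · 19 = 2 · 16,569 · 19 = 629,622   per expansion type,
```

and a detected peptide is accepted as chimeric only if it carries at
least `m = 8` consecutive tricoded **and** 8 consecutive expanded-coded
residues, with chance expectation `E = N · 19⁻ᵐ` across the database.
Residues at the junction whose amino acid is identical under both
reading modes are assigned *parsimoniously to the tricoded side*.
Supporting machinery includes single-residue cleavage rules (carboxyl or
amino side, ≤1 missed cleavage; the `2 × 19 = 38` per-sample search
configurations), monoisotopic masses with the usual fixed/variable
modifications, reverse-decoy databases and plain target-decoy q-values.

## Worked example

Simulate a 2,500 bp genome with 10 planted chimeric fragments plus 5
noise peptides, build the tetracodon database, and annotate:

```bash
mitochimera simulate --length 2500 --plants 10 --noise 5 --seed 7 \
    --out-genome g.fa --out-peptides obs.tsv --out-truth truth.tsv
mitochimera build-db --genome g.fa --k 1 --out db.fa
mitochimera annotate --genome g.fa --peptides obs.tsv --min-len 8 --out anno.tsv
```

which logs

```
INFO mitochimera: planted 10 peptides (+5 noise) on synthetic_L2500_seed7
INFO mitochimera: genome synthetic_L2500_seed7 (L=2500): wrote 95000 records (nominal 95000 per k) to db.fa
INFO mitochimera: detected=15 annotated=10 filtered=10 gene-mapped=0
```

`95000 = 2 · 2500 · 19` records: on this random genome every window
contains a stop, so each is emitted 19 times. All 10 planted fragments
(and none of the noise peptides) are matched and pass the ≥8/≥8 filter.
The first annotation row reads

```
peptide        SLNAFsYSRAsAGFLIAPMsNSWHTREESRFSLTsLSNVMWLQSWSCIDFGsISVRSVPGGEVKMHAHSYHATLEEsCGLFRMDK
k=2  strand=-  window_start=1446  frame=6  pos_start=482
rendered       SLNAFsYSRAsAGFLIAPMsNSWHTREESR|F|SLTsLSNVMWLQSWSCIDFGs...
tri_len=31  exp_len=29  ambiguous_span=1  evalue=5.6e-06  passes_filter=True
```

i.e. a pentacoded (`k=2`) template on the − strand starting at genomic
position 1446; the tricoded part sits in frame 6 at amino-acid position
482 of that frame's translation; lowercase `s` marks Ser inserted at
stop codons; the residue between the two `|` marks translates
identically under both reading modes and is counted as tricoded
(`ambiguous_span=1`); the e-value is `2·2500·19 / 19⁸ ≈ 5.6e-06`.

With a real genome FASTA and a CDS table (TSV `gene  start  end  strand`
or GFF3; `--mito-genes` supplies the built-in NC_012920 table), tricoded
segments falling in-frame inside a CDS are reported with the canonical
protein name and 1-based residue range. `mitochimera qvalues` appends
target-decoy q-values to a scored hit list, and `mitochimera run
--config run.yaml` chains the stages and writes a `MANIFEST.json` of
stage counts.

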