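"""Template matching, junction parsimony, chimera filter, gene mapping."""

import numpy as np
import pandas as pd
import pytest

from mitochimera import (
    ChimeraDatabase,
    ChimericWindow,
    DetectedPeptide,
    GeneRecord,
    GeneTable,
    Genome,
    StrandedLocus,
    annotate_all,
    collapse_il,
    default_code,
    evalue,
    human_mito_gene_table,
    map_segment_to_gene,
    map_to_gene,
    match_template,
    passes_filter,
    random_genome,
    read_gene_table,
    resolve_junction,
    translate_tricodons,
    translate_window,
    substitute_stops,
)
from mitochimera.annotate import search_pattern
from mitochimera.synthetic import PlantSpec, plant_detections


@pytest.fixture(scope="module")
def toy_db():
    g = random_genome(300, seed=77)
    return ChimeraDatabase.from_genome(g, ks=(1, 2))


class TestMatchTemplate:
    def test_verbatim_substring_found_at_offset(self, toy_db):
        t = toy_db.templates[5]
        seq = t.rendered("Q") if t.stop_positions else t.rendered()
        d = DetectedPeptide(seq[25:45])
        hits = match_template(d, toy_db)
        assert any(
            h[0].window == t.window and h[1] == 25 for h in hits
        )

    def test_ile_matches_leu_template(self, toy_db):
        t = toy_db.templates[5]
        seq = (t.rendered("Q") if t.stop_positions else t.rendered())[25:45]
        assert "L" in seq  # fixture sanity
        d = DetectedPeptide(seq.replace("L", "I"))
        assert any(h[0].window == t.window for h in match_template(d, toy_db))

    def test_uppercase_does_not_match_stop_position(self, toy_db):
        t = next(p for p in toy_db.templates if p.stop_positions)
        i = t.stop_positions[0]
        lo, hi = max(0, i - 8), min(90, i + 8)
        seq = t.rendered("Q")[lo:hi]
        assert "q" in seq
        hits_upper = match_template(DetectedPeptide(seq.upper()), toy_db)
        assert not any(
            h[0].window == t.window and h[1] == lo for h in hits_upper
        )

    def test_absent_sequence_agrees_with_brute_force_scan(self, toy_db):
        rng = np.random.default_rng(4)
        for _ in range(10):
            pep = "".join(rng.choice(list("ACDEFGHKMNPQRSTVWY"), size=20))
            hits = match_template(DetectedPeptide(pep), toy_db)
            brute = [
                t
                for t in toy_db.templates
                if collapse_il(pep) in collapse_il(t.schematic)
            ]
            assert bool(hits) == bool(brute)

    def test_inconsistent_stop_letters_match_nothing(self, toy_db):
        # two different lowercase letters cannot come from one variant
        assert match_template(DetectedPeptide("AAAAwAAAAqAAAA"), toy_db) == []
        assert search_pattern("AwAqA") == (None, None)

    def test_deterministic_order(self, toy_db):
        d = DetectedPeptide("".join("K" for _ in range(3)))
        hits = match_template(d, toy_db)
        keys = [
            (h[0].window.strand != "+", h[0].window.start, h[0].window.k, h[1])
            for h in hits
        ]
        assert keys == sorted(keys)


class TestResolveJunction:
    """Fixtures built on genomes where both translation modes are known."""

    @pytest.fixture
    def mono(self, monomorphic_chimeric_genome):
        g = monomorphic_chimeric_genome
        t = translate_window(g, ChimericWindow("+", 0, 1))
        return g, t

    def test_forward_junction_first_expanded_codon_shared(self, mono):
        # the first expanded codon reads the same 3 nt as the continued
        # tricodon frame, so it is ambiguous and reassigned; the second
        # continuation codon includes the silent nt (AAT=N != M) and stops
        # the run
        g, t = mono
        d = DetectedPeptide(t.rendered()[20:40])
        a = resolve_junction(d, t, 20, g)
        assert a.junction == 30
        assert a.junction_side == "3prime_noncanonical"
        assert a.ambiguous_span == 1
        assert (a.tri_len, a.exp_len) == (11, 9)
        assert a.rendered == "M" * 10 + "|M|" + "M" * 9

    def test_backward_junction_silent_nt_disambiguates(self, mono):
        # tricodon continuation before tri3 reads TGA (Trp/stop context)
        # instead of ATG: different residue, so ambiguous_span = 0 and the
        # boundary stays at template position 60
        g, t = mono
        d = DetectedPeptide(t.rendered()[50:70])
        a = resolve_junction(d, t, 50, g)
        assert a.junction == 60
        assert a.junction_side == "5prime_noncanonical"
        assert a.ambiguous_span == 0
        assert (a.tri_len, a.exp_len) == (10, 10)

    def test_homopolymer_full_reassignment(self):
        # all-A genome: every reading gives Lys, the ambiguous run covers
        # the entire expanded overlap and exp_len collapses to 0
        g = Genome("polyA", "A" * 300)
        t = translate_window(g, ChimericWindow("+", 0, 1))
        d = DetectedPeptide(t.rendered()[22:38])
        a = resolve_junction(d, t, 22, g)
        assert a.ambiguous_span == 8
        assert (a.tri_len, a.exp_len) == (16, 0)

    def test_match_inside_tri5_has_no_junction(self, mono):
        g, t = mono
        d = DetectedPeptide(t.rendered()[2:20])
        a = resolve_junction(d, t, 2, g)
        assert a.junction is None
        assert (a.tri_len, a.exp_len) == (18, 0)
        assert a.frame == 1 and a.pos_start == 3 and a.pos_end == 20

    def test_match_inside_expanded_segment(self, mono):
        g, t = mono
        d = DetectedPeptide(t.rendered()[32:55])
        a = resolve_junction(d, t, 32, g)
        assert (a.tri_len, a.exp_len) == (0, 23)
        assert a.tri_locus is None

    def test_parsimony_monotonicity_on_random_windows(self):
        g = random_genome(800, seed=23)
        rng = np.random.default_rng(8)
        for _ in range(50):
            k = int(rng.integers(1, 3))
            w = ChimericWindow(
                "+" if rng.random() < 0.5 else "-", int(rng.integers(0, 800)), k
            )
            t = translate_window(g, w)
            s = t.rendered("Q") if t.stop_positions else t.rendered()
            off = int(rng.integers(10, 45))
            d = DetectedPeptide(s[off : off + 25])
            a = resolve_junction(d, t, off, g)
            assert a.ambiguous_span >= 0
            if a.junction == 30:
                assert a.tri_len >= 30 - off  # reassignment only grows tri
            assert a.tri_len + a.exp_len <= len(d.sequence)


class TestFilterAndEvalue:
    @pytest.mark.parametrize(
        "tri,exp,ok", [(8, 8, True), (30, 7, False), (7, 30, False)]
    )
    def test_filter_threshold(self, tri, exp, ok, monomorphic_chimeric_genome):
        g = monomorphic_chimeric_genome
        t = translate_window(g, ChimericWindow("+", 0, 1))
        a = resolve_junction(DetectedPeptide("M" * 16), t, 20, g)
        a.tri_len, a.exp_len = tri, exp
        assert passes_filter(a, min_len=8) is ok

    def test_filter_count_monotone_in_min_len(self):
        g = random_genome(2000, seed=31)
        det, _ = plant_detections(g, PlantSpec(n_plants=30, seed=2))
        db = ChimeraDatabase.from_genome(g)
        tab = annotate_all(det, db, min_len=1)
        counts = []
        for ml in (1, 5, 8, 12, 20):
            tab_ml = annotate_all(det, db, min_len=ml)
            counts.append(int(tab_ml["passes_filter"].sum()))
        assert counts == sorted(counts, reverse=True)

    def test_evalue_formula(self):
        assert evalue(629622, 8) == pytest.approx(629622 / 19**8)
        assert evalue(629622, 8) == pytest.approx(3.707e-5, rel=1e-3)
        assert evalue(1000, 0) == 1000
        assert evalue(0, 8) == 0


class TestGeneMapping:
    @pytest.fixture
    def gene_fixture(self):
        g = random_genome(200, seed=55)
        # 60-nt "gene" at 1-based 11..70 on the + strand
        genes = GeneTable([GeneRecord("toy", 11, 70, "+")])
        return g, genes

    def test_codons_4_to_12_recovered(self, gene_fixture):
        g, genes = gene_fixture
        p = 10 + 9  # codon 4 starts 9 nt into the CDS
        locus = StrandedLocus("+", p, 27)
        residues = translate_tricodons(g.fetch(locus))
        seq = substitute_stops(residues, "W")
        hit = map_segment_to_gene(locus, seq, genes, g)
        assert hit == ("toy", (4, 12))

    def test_out_of_frame_rejected(self, gene_fixture):
        g, genes = gene_fixture
        locus = StrandedLocus("+", 20, 27)  # offset 10 into CDS: not %3
        residues = translate_tricodons(g.fetch(locus))
        seq = substitute_stops(residues, "W")
        assert map_segment_to_gene(locus, seq, genes, g) is None

    def test_wrong_strand_rejected(self, gene_fixture):
        g, genes = gene_fixture
        locus = StrandedLocus("-", 19, 27)
        residues = translate_tricodons(g.fetch(locus))
        seq = substitute_stops(residues, "W")
        assert map_segment_to_gene(locus, seq, genes, g) is None

    def test_sequence_discordance_rejected(self, gene_fixture):
        g, genes = gene_fixture
        locus = StrandedLocus("+", 19, 27)
        seq = "W" * 9  # cannot concord with a random translation
        assert map_segment_to_gene(locus, seq, genes, g) is None

    def test_round_trip_every_codon_of_every_gene(self):
        """frame coordinate -> gene mapping recovers each residue index."""
        g = random_genome(400, seed=91)
        genes = GeneTable(
            [
                GeneRecord("gA", 11, 70, "+"),
                GeneRecord("gB", 101, 160, "+"),
                GeneRecord("gC", 201, 260, "-"),
            ]
        )
        L = g.length
        for gene in genes:
            g0 = gene.start - 1 if gene.strand == "+" else L - gene.end
            n_res = (gene.end - gene.start + 1) // 3
            for r in range(1, n_res + 1):
                locus = StrandedLocus(gene.strand, g0 + 3 * (r - 1), 3)
                residues = translate_tricodons(g.fetch(locus))
                seq = substitute_stops(residues, "W")
                hit = map_segment_to_gene(locus, seq, genes, g)
                assert hit == (gene.name, (r, r))


@pytest.fixture(scope="module")
def standin():
    from mitochimera import frame_translation_coordinate

    g = random_genome(16569, seed=12920)
    return g, human_mito_gene_table(), frame_translation_coordinate


class TestHumanMitoCoordinates:
    """Frame-translation positions printed for chimeric peptides whose
    tricoded part falls in canonical proteins (coordinate arithmetic on
    the NC_012920 annotation; genome sequence is a synthetic stand-in)."""

    @pytest.mark.parametrize(
        "offset,aa_start,n_res,gene,res_start",
        [
            (1, 5240, 9, "CytB", 325),  # positions 5240-5248 -> CytB 325-333
            (2, 1639, 20, "ND2", 150),  # positions 1639-1658 -> ND2 150-169
        ],
    )
    def test_frame_positions_map_into_gene(
        self, standin, offset, aa_start, n_res, gene, res_start
    ):
        g, genes, coord = standin
        first = coord("+", offset, aa_start, length=g.length)
        locus = StrandedLocus("+", first.start, 3 * n_res)
        seq = substitute_stops(translate_tricodons(g.fetch(locus)), "W")
        hit = map_segment_to_gene(locus, seq, genes, g)
        assert hit == (gene, (res_start, res_start + n_res - 1))

    def test_thirteen_genes(self):
        assert len(human_mito_gene_table()) == 13


class TestAnnotateAll:
    def test_empty_input_gives_empty_table_with_header(self, toy_db):
        tab = annotate_all([], toy_db)
        assert len(tab) == 0
        assert "passes_filter" in tab.columns

    def test_planted_peptides_all_pass_filter(self):
        g = random_genome(3000, seed=6)
        det, truth = plant_detections(g, PlantSpec(n_plants=25, seed=3))
        db = ChimeraDatabase.from_genome(g)
        tab = annotate_all(det, db)
        assert tab["passes_filter"].all()
        best = tab.drop_duplicates("peptide", keep="first")
        merged = truth.merge(
            best, left_on="sequence", right_on="peptide", suffixes=("_t", "")
        )
        assert (merged["start"] + 1 == merged["window_start"]).all()
        assert (merged["strand_t"] == merged["strand"]).all()
        assert (merged["k_t"] == merged["k"]).all()

    def test_multi_k_peptide_reported_for_both(self):
        g = Genome("polyA", "A" * 400)
        db = ChimeraDatabase.from_genome(g, ks=(1, 2))
        tab = annotate_all([DetectedPeptide("K" * 16)], db)
        assert sorted(tab["k"]) == [1, 2]
        assert tab["multi_k"].all()

    def test_vendor_thresholds_are_passthrough(self, toy_db):
        det = [
            DetectedPeptide("KKKK", score=2.5, q=0.01),
            DetectedPeptide("RRRR", score=1.5, q=0.01),
            DetectedPeptide("GGGG", score=2.5, q=0.2),
        ]
        tab = annotate_all(det, toy_db, score_threshold=1.99, q_threshold=0.05)
        assert list(tab["peptide"]) == ["KKKK"]


class TestGeneTableIO:
    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene\tstart\tend\tstrand\nA\t11\t70\t+\nB\t80\t100\t-\n")
        gt = read_gene_table(p)
        assert [r.name for r in gt] == ["A", "B"]
        assert gt.records[1].strand == "-"

    def test_gff3_cds_lines(self, tmp_path):
        p = tmp_path / "genes.gff"
        p.write_text(
            "##gff-version 3\n"
            "chr\tsrc\tgene\t1\t200\t.\t+\t.\tID=g1\n"
            "chr\tsrc\tCDS\t11\t70\t.\t+\t0\tID=c1;gene=A\n"
            "chr\tsrc\tCDS\t80\t100\t.\t-\t0\tgene=B\n"
        )
        gt = read_gene_table(p)
        assert [(r.name, r.start, r.end, r.strand) for r in gt] == [
            ("A", 11, 70, "+"),
            ("B", 80, 100, "-"),
        ]

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            GeneTable([GeneRecord("A", 1, 3, "+"), GeneRecord("A", 4, 6, "+")])
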