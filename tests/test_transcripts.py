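"""Isoform assembly, cis-element extraction, reporters and mutagenesis."""

import numpy as np
import pytest

from pcpa_screen.polya import ScreenParams
from pcpa_screen.seqio import find_motif
from pcpa_screen.synthetic import (
    SyntheticConfig,
    generate_toy_genome,
    generate_transcript_pool,
    truth_to_acceptor,
    truth_to_hit,
)
from pcpa_screen.transcripts import (
    Minigene,
    build_transcript,
    construct_to_reference,
    extract_cis_element,
    insert_cis_element,
    make_cat_reporter,
)


@pytest.fixture(scope="module")
def planted(cascade_fixture):
    cfg, genome, genes, manifest = cascade_fixture
    return genome, genes, manifest


def gene_truth_hit(genome, genes, manifest, idx=0):
    gene = genes[idx]
    truth = manifest.gene(gene.gene_id)
    return gene, truth, truth_to_hit(gene, truth)


class TestBuildTranscript:
    def test_mrna_is_concatenated_exons(self, planted):
        genome, genes, manifest = planted
        gene = genes[0]
        tx = build_transcript(gene, genome, "mRNA", tail_len=0)
        expected = "".join(
            genome.gene_seq(gene)[s:e] for s, e in gene.oriented_exons()
        )
        assert tx.seq == expected
        assert tx.polyadenylated is False

    @pytest.mark.parametrize("idx", [0, 1])  # one gene per strand
    def test_pcpa_length_arithmetic(self, planted, idx):
        genome, genes, manifest = planted
        gene, truth, hit = gene_truth_hit(genome, genes, manifest, idx)
        tx = build_transcript(
            gene, genome, "PCPA", pa_hit=hit, cleavage_offset=15, tail_len=30
        )
        exon1_len = gene.exons[0][1] - gene.exons[0][0]
        assert len(tx) == exon1_len + truth.polya.dist_from_5ss + 6 + 15 + 30
        assert tx.polyadenylated and tx.seq.endswith("A" * 30)

    @pytest.mark.parametrize("idx", [0, 1])
    def test_cspp_excision_identity(self, planted, idx):
        """len(CSPP) = len(PCPA) - (cryptic junction offset - 5'ss offset)."""
        genome, genes, manifest = planted
        gene, truth, hit = gene_truth_hit(genome, genes, manifest, idx)
        acc = truth_to_acceptor(truth, rank=1)
        pcpa = build_transcript(gene, genome, "PCPA", pa_hit=hit)
        cspp = build_transcript(gene, genome, "CSPP", pa_hit=hit, acceptor=acc)
        assert len(cspp) == len(pcpa) - acc.junction_offset
        # the hexamer lies upstream of the cleavage position in both
        assert "AATAAA" in pcpa.body[-60:]
        assert "AATAAA" in cspp.body[-60:]

    def test_read_through_not_polyadenylated(self, planted):
        genome, genes, manifest = planted
        gene, truth, hit = gene_truth_hit(genome, genes, manifest)
        tx = build_transcript(gene, genome, "read-through", pa_hit=hit)
        assert tx.polyadenylated is False
        assert tx.tail_len == 0

    def test_pcpa_requires_hit(self, planted):
        genome, genes, _ = planted
        with pytest.raises(ValueError, match="poly"):
            build_transcript(genes[0], genome, "PCPA")

    def test_cspp_requires_acceptor(self, planted):
        genome, genes, manifest = planted
        gene, truth, hit = gene_truth_hit(genome, genes, manifest)
        with pytest.raises(ValueError, match="acceptor"):
            build_transcript(gene, genome, "CSPP", pa_hit=hit)


class TestCisElement:
    def test_default_pads_give_214_nt_fragment(self, planted):
        genome, genes, manifest = planted
        gene, truth, hit = gene_truth_hit(genome, genes, manifest)
        element = extract_cis_element(gene, genome, hit)
        assert len(element.seq) == 157 + 6 + 51
        assert element.seq[157:163] == "AATAAA"

    def test_pad_exceeding_intron_boundary(self, planted):
        genome, genes, manifest = planted
        gene, truth, hit = gene_truth_hit(genome, genes, manifest)
        with pytest.raises(ValueError, match="pad"):
            extract_cis_element(gene, genome, hit, upstream_pad=truth.polya.dist_from_5ss + 1)

    def test_zero_pads_give_bare_hexamer(self, planted):
        genome, genes, manifest = planted
        gene, truth, hit = gene_truth_hit(genome, genes, manifest)
        element = extract_cis_element(gene, genome, hit, 0, 0)
        assert element.seq == "AATAAA"


class TestReporter:
    def test_intronic_insertion_recovers_intronic_signal(self, planted, params, matrices):
        genome, genes, manifest = planted
        gene, truth, hit = gene_truth_hit(genome, genes, manifest)
        element = extract_cis_element(gene, genome, hit)
        reporter = insert_cis_element(
            make_cat_reporter(seed=21), element, "intron", insertion_offset=250
        )
        rgenome, rgene = construct_to_reference(reporter)
        mg = Minigene(rgenome, rgene, params, *matrices)
        hits = [h for h in mg.scan().hits if h.intron.ordinal == 1]
        assert len(hits) == 1  # the element's hexamer, now intronic

    def test_exonic_insertion_with_neutralized_vector_pa(self, planted):
        genome, genes, manifest = planted
        gene, truth, hit = gene_truth_hit(genome, genes, manifest)
        element = extract_cis_element(gene, genome, hit)
        reporter = insert_cis_element(
            make_cat_reporter(seed=21), element, "three_prime_exon",
            neutralize_vector_pa=True,
        )
        assert find_motif(reporter.segment("vector_pa"), "AATAAA") == []
        assert "GGATCC" in reporter.segment("vector_pa")
        # the inserted element's own hexamer is intact in the 3' exon
        assert "AATAAA" in reporter.segment("three_prime_exon")

    def test_neutralize_without_vector_signal_is_identity(self):
        from pcpa_screen.transcripts import CisElement, ReporterConstruct

        base = make_cat_reporter(seed=22)
        clean = ReporterConstruct(
            name=base.name,
            segments=tuple(
                (lbl, s.replace("AATAAA", "GGATCC")) if lbl == "vector_pa" else (lbl, s)
                for lbl, s in base.segments
            ),
        )
        element = CisElement("x", 0, 0, "AATAAA")
        out = insert_cis_element(clean, element, "intron", neutralize_vector_pa=True)
        assert out.segment("vector_pa") == clean.segment("vector_pa")

    def test_unknown_site_rejected(self):
        from pcpa_screen.transcripts import CisElement

        with pytest.raises(ValueError, match="site"):
            insert_cis_element(
                make_cat_reporter(), CisElement("x", 0, 0, "AATAAA"), "promoter"
            )


class TestMutagenesis:
    @pytest.fixture()
    def minigene(self, planted, params, matrices):
        genome, genes, _ = planted
        return Minigene(genome, genes[0], params, *matrices)

    def test_polya_mutation_abolishes_all_calls(self, minigene):
        mutated, edit = minigene.apply_mutation("polya_signal")
        assert edit.before == "AATAAA" and edit.after == "GGATCC"
        result = mutated.scan()
        assert [h for h in result.hits if h.passes_stage1] == []
        assert result.best is None and result.acceptors == []

    def test_cryptic_site_cascade(self, minigene):
        """Masking site 1 promotes site 2; masking 1+2 promotes site 3."""
        base = minigene.scan()
        assert [a.dist_to_polya for a in base.acceptors] == [30, 120, 260]
        m1, _ = minigene.apply_mutation("cryptic_3ss", 1)
        r1 = m1.scan()
        assert [a.dist_to_polya for a in r1.acceptors] == [120, 260]
        assert r1.acceptors[0].rank == 1
        m2, _ = m1.apply_mutation("cryptic_3ss", 1)
        r2 = m2.scan()
        assert [a.dist_to_polya for a in r2.acceptors] == [260]

    def test_five_ss_mutation_blocks_cspp_not_pcpa(self, minigene):
        mutated, edit = minigene.apply_mutation("five_ss")
        assert (edit.before, edit.after) == ("GT", "GA")
        result = mutated.scan()
        assert result.best is not None  # PCPA signal still called
        pcpa = build_transcript(
            mutated.gene, mutated.genome, "PCPA", pa_hit=result.best
        )
        assert pcpa.polyadenylated
        with pytest.raises(ValueError, match="donor"):
            build_transcript(
                mutated.gene, mutated.genome, "CSPP",
                pa_hit=result.best, acceptor=result.acceptors[0],
            )

    def test_mutations_are_minimal_substitutions(self, minigene):
        for target in ("polya_signal", "five_ss", "cryptic_3ss"):
            mutated, edit = minigene.apply_mutation(target)
            before = minigene.genome.contigs[minigene.gene.contig]
            after = mutated.genome.contigs[minigene.gene.contig]
            assert len(before) == len(after)
            hamming = sum(a != b for a, b in zip(before, after))
            assert hamming <= len(edit.after)

    def test_missing_target_rejected(self, minigene):
        with pytest.raises(ValueError, match="rank"):
            minigene.apply_mutation("cryptic_3ss", site_index=9)


class TestPoolRoundTrip:
    def test_reporter_screen_matches_endogenous_calls(self, planted, params, matrices):
        """A cis-element moved into a reporter intron reproduces the
        endogenous acceptor calls that lie within the element."""
        genome, genes, manifest = planted
        gene, truth, hit = gene_truth_hit(genome, genes, manifest)
        element = extract_cis_element(gene, genome, hit)
        reporter = insert_cis_element(
            make_cat_reporter(seed=25), element, "intron", insertion_offset=250
        )
        rgenome, rgene = construct_to_reference(reporter)
        mg = Minigene(rgenome, rgene, params, *matrices)
        result = mg.scan()
        assert result.best is not None
        # sites within 157 nt of the hexamer travelled with the element
        endogenous = [a.dist_to_polya for a in Minigene(
            genome, gene, params, *matrices).scan().acceptors
            if a.dist_to_polya + 13 <= 157]
        moved = [a.dist_to_polya for a in result.acceptors
                 if a.dist_to_polya + 13 <= 157]
        assert moved == endogenous
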