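import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pcpa_screen.polya import ScreenParams
from pcpa_screen.scoring import default_matrices
from pcpa_screen.synthetic import SyntheticConfig, generate_toy_genome


@pytest.fixture(scope="session")
def matrices():
    """(branch 7-mer, acceptor 14-mer) shipped frequency matrices."""
    return default_matrices()


@pytest.fixture(scope="session")
def params():
    return ScreenParams()


@pytest.fixture(scope="session")
def cascade_fixture():
    """Scrubbed 4-gene genome with three planted cryptic sites per gene."""
    cfg = SyntheticConfig(
        n_genes=4, seed=11, cryptic_dists=(30, 120, 260), polya_dist=(330, 450)
    )
    return (cfg,) + generate_toy_genome(cfg)


@pytest.fixture(scope="session")
def default_fixture():
    """Scrubbed 10-gene genome with the default planting (two cryptic sites)."""
    cfg = SyntheticConfig(n_genes=10, seed=7)
    return (cfg,) + generate_toy_genome(cfg)


def to_oracle_gene(gene):
    return {
        "gene_id": gene.gene_id,
        "transcript_id": gene.transcript_id,
        "contig": gene.contig,
        "strand": gene.strand,
        "exons": [list(e) for e in gene.exons],
    }


def to_oracle_params(p: ScreenParams) -> dict:
    return {
        "signal_set": set(p.signal_set),
        "max_tss_dist": p.max_tss_dist,
        "allowed_intron_ordinals": set(p.allowed_intron_ordinals),
        "min_intron_len": p.min_intron_len,
        "max_5ss_dist": p.max_5ss_dist,
        "refined_max_5ss_dist": p.refined_max_5ss_dist,
        "acceptor_cv_threshold": p.acceptor_cv_threshold,
        "branch_cv_threshold": p.branch_cv_threshold,
    }


def oracle_screen(genome, genes, params, matrices):
    """Run the naive reference implementation on package-level objects."""
    from reference_impl import naive_screen

    bm, am = matrices
    return naive_screen(
        contigs=genome.contigs,
        genes=[to_oracle_gene(g) for g in genes],
        params=to_oracle_params(params),
        branch_rows=[dict(r) for r in bm.freqs],
        acceptor_rows=[dict(r) for r in am.freqs],
        acceptor_required=list(am.required_bases),
        spacing=params.branch_spacing,
    )


def production_as_tuples(genome, genes, params, matrices):
    """Production screen results flattened to the oracle's tuple format."""
    from pcpa_screen.polya import filter_promoter_proximal, find_intronic_polya_signals
    from pcpa_screen.scoring import rank_cryptic_sites, scan_cryptic_acceptors

    bm, am = matrices
    out = {}
    for gene in genes:
        hits = filter_promoter_proximal(
            find_intronic_polya_signals(gene, genome, params), params
        )
        tuples = [
            (h.intron.ordinal, h.dist_from_tss, h.dist_from_5ss, h.hexamer,
             h.passes_stage1, h.passes_refinement)
            for h in hits
        ]
        acceptors = []
        refined = [h for h in hits if h.passes_refinement]
        if refined:
            best = min(refined, key=lambda h: (h.dist_from_tss, h.intron.ordinal, h.dist_from_5ss))
            iseq = genome.gene_seq(gene)[
                best.intron.oriented_start : best.intron.oriented_end
            ]
            for acc in rank_cryptic_sites(
                scan_cryptic_acceptors(iseq, best.dist_from_5ss, params, bm, am)
            ):
                acceptors.append(
                    (acc.junction_offset, acc.dist_to_polya,
                     acc.acceptor.start, acc.acceptor.window, acc.acceptor.cv,
                     acc.branch.start, acc.branch.window, acc.branch.cv,
                     acc.rank)
                )
        out[gene.transcript_id] = {"hits": tuples, "acceptors": acceptors}
    return out
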