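"""End-to-end screen orchestration and result export.

The funnel mirrors the screen's staged narrowing: intronic poly(A) signals
passing the positional criteria (stage 1), the <500 bp refinement, then
cryptic 3' splice-site calling upstream of the refined signal. Counts are
reported both per intron (stage 1) and per gene (later stages); a gene counts
once however many passing introns it has, keeping the promoter-most (smallest
distance-from-TSS) hit as its best.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .polya import (
    IntronRecord,
    PolyASignalHit,
    ScreenParams,
    filter_promoter_proximal,
    find_intronic_polya_signals,
)
from .scoring import (
    CrypticAcceptor,
    FrequencyMatrix,
    SpliceSiteScore,
    default_matrices,
    rank_cryptic_sites,
    scan_cryptic_acceptors,
)
from .seqio import GeneModel, Genome

__all__ = [
    "CandidateRecord",
    "FunnelReport",
    "run_screen",
    "export_results",
    "read_candidates",
]

STAGES = ("stage1", "refined", "acceptor_positive")


@dataclass(frozen=True)
class CandidateRecord:
    """Per-transcript screen outcome: the best hit and its cryptic acceptors."""

    gene_id: str
    transcript_id: str
    best_hit: PolyASignalHit
    acceptors: tuple[CrypticAcceptor, ...]
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "acceptor_positive" and not self.acceptors:
            raise ValueError("acceptor_positive requires at least one cryptic acceptor")


@dataclass(frozen=True)
class FunnelReport:
    """Stage-by-stage tallies of the screen."""

    n_introns_stage1: int
    n_genes_stage1: int
    n_genes_refined: int
    n_genes_acceptor_positive: int
    n_genes_total: int
    fraction_genes_with_proximal_intronic_pA: float

    def __post_init__(self) -> None:
        counts = (
            self.n_introns_stage1,
            self.n_genes_stage1,
            self.n_genes_refined,
            self.n_genes_acceptor_positive,
            self.n_genes_total,
        )
        if any(c < 0 for c in counts):
            raise ValueError("funnel counts must be non-negative")
        if not (
            self.n_genes_acceptor_positive
            <= self.n_genes_refined
            <= self.n_genes_stage1
            <= self.n_genes_total
        ):
            raise ValueError("funnel counts must be monotone")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _best(hits: Sequence[PolyASignalHit]) -> PolyASignalHit:
    return min(hits, key=lambda h: (h.dist_from_tss, h.intron.ordinal, h.dist_from_5ss))


def run_screen(
    genome: Genome,
    gene_models: Sequence[GeneModel],
    params: ScreenParams | None = None,
    branch_matrix: FrequencyMatrix | None = None,
    acceptor_matrix: FrequencyMatrix | None = None,
) -> tuple[list[CandidateRecord], FunnelReport]:
    """Run the full funnel over ``gene_models``.

    Each transcript is screened independently; the report deduplicates at
    the gene level. The cryptic-acceptor scan runs on the best refined hit's
    intron, over the region between its 5' splice site and the hexamer. The
    fraction of genes with a promoter-proximal intronic poly(A) signal
    applies the TSS-distance criterion only, as a gene-level summary of how
    widespread proximal intronic signals are before the intron-level filters.
    """
    params = params or ScreenParams()
    if branch_matrix is None or acceptor_matrix is None:
        bm, am = default_matrices()
        branch_matrix = branch_matrix or bm
        acceptor_matrix = acceptor_matrix or am

    records: list[CandidateRecord] = []
    introns_stage1: set[tuple[str, int]] = set()
    genes_stage1: set[str] = set()
    genes_refined: set[str] = set()
    genes_acceptor: set[str] = set()
    genes_proximal: set[str] = set()
    all_genes = {g.gene_id for g in gene_models}

    for gene in gene_models:
        hits = filter_promoter_proximal(
            find_intronic_polya_signals(gene, genome, params), params
        )
        if any(h.dist_from_tss <= params.max_tss_dist for h in hits):
            genes_proximal.add(gene.gene_id)
        stage1 = [h for h in hits if h.passes_stage1]
        if not stage1:
            continue
        genes_stage1.add(gene.gene_id)
        for h in stage1:
            introns_stage1.add((gene.transcript_id, h.intron.ordinal))
        refined = [h for h in hits if h.passes_refinement]
        if not refined:
            records.append(
                CandidateRecord(
                    gene_id=gene.gene_id,
                    transcript_id=gene.transcript_id,
                    best_hit=_best(stage1),
                    acceptors=(),
                    stage="stage1",
                )
            )
            continue
        genes_refined.add(gene.gene_id)
        best = _best(refined)
        gene_seq = genome.gene_seq(gene)
        intron = best.intron
        iseq = gene_seq[intron.oriented_start : intron.oriented_end]
        acceptors = rank_cryptic_sites(
            scan_cryptic_acceptors(
                iseq, best.dist_from_5ss, params, branch_matrix, acceptor_matrix
            )
        )
        for acc in acceptors:
            acc.genomic_junction = gene.oriented_to_genomic(
                intron.oriented_start + acc.junction_offset
            )
        stage = "acceptor_positive" if acceptors else "refined"
        if acceptors:
            genes_acceptor.add(gene.gene_id)
        records.append(
            CandidateRecord(
                gene_id=gene.gene_id,
                transcript_id=gene.transcript_id,
                best_hit=best,
                acceptors=tuple(acceptors),
                stage=stage,
            )
        )

    records.sort(key=lambda r: (r.gene_id, r.transcript_id))
    report = FunnelReport(
        n_introns_stage1=len(introns_stage1),
        n_genes_stage1=len(genes_stage1),
        n_genes_refined=len(genes_refined),
        n_genes_acceptor_positive=len(genes_acceptor),
        n_genes_total=len(all_genes),
        fraction_genes_with_proximal_intronic_pA=(
            len(genes_proximal) / len(all_genes) if all_genes else 0.0
        ),
    )
    return records, report


_TSV_FIELDS = [
    "gene_id", "transcript_id", "stage", "contig", "strand",
    "intron_ordinal", "intron_genomic_start", "intron_genomic_end",
    "intron_oriented_start", "intron_oriented_end", "intron_five_ss",
    "intron_three_ss", "hexamer", "signal_start", "dist_from_tss",
    "dist_from_5ss", "passes_stage1", "passes_refinement", "acceptors",
]


def _record_to_row(rec: CandidateRecord) -> dict:
    hit = rec.best_hit
    intron = hit.intron
    acceptors = [
        {
            "branch_window": a.branch.window,
            "branch_start": a.branch.start,
            "branch_cv": a.branch.cv,
            "acceptor_window": a.acceptor.window,
            "acceptor_start": a.acceptor.start,
            "acceptor_cv": a.acceptor.cv,
            "junction_offset": a.junction_offset,
            "dist_to_polya": a.dist_to_polya,
            "rank": a.rank,
            "genomic_junction": a.genomic_junction,
        }
        for a in rec.acceptors
    ]
    return {
        "gene_id": rec.gene_id,
        "transcript_id": rec.transcript_id,
        "stage": rec.stage,
        "contig": intron.contig,
        "strand": intron.strand,
        "intron_ordinal": intron.ordinal,
        "intron_genomic_start": intron.genomic_start,
        "intron_genomic_end": intron.genomic_end,
        "intron_oriented_start": intron.oriented_start,
        "intron_oriented_end": intron.oriented_end,
        "intron_five_ss": intron.five_ss,
        "intron_three_ss": intron.three_ss,
        "hexamer": hit.hexamer,
        "signal_start": hit.signal_start,
        "dist_from_tss": hit.dist_from_tss,
        "dist_from_5ss": hit.dist_from_5ss,
        "passes_stage1": int(hit.passes_stage1),
        "passes_refinement": int(hit.passes_refinement),
        "acceptors": json.dumps(acceptors, sort_keys=True),
    }


def _row_to_record(row: Mapping[str, str]) -> CandidateRecord:
    intron = IntronRecord(
        gene_id=row["gene_id"],
        transcript_id=row["transcript_id"],
        contig=row["contig"],
        strand=row["strand"],
        ordinal=int(row["intron_ordinal"]),
        genomic_start=int(row["intron_genomic_start"]),
        genomic_end=int(row["intron_genomic_end"]),
        oriented_start=int(row["intron_oriented_start"]),
        oriented_end=int(row["intron_oriented_end"]),
        five_ss=int(row["intron_five_ss"]),
        three_ss=int(row["intron_three_ss"]),
    )
    hit = PolyASignalHit(
        intron=intron,
        hexamer=row["hexamer"],
        signal_start=int(row["signal_start"]),
        dist_from_tss=int(row["dist_from_tss"]),
        dist_from_5ss=int(row["dist_from_5ss"]),
        passes_stage1=bool(int(row["passes_stage1"])),
        passes_refinement=bool(int(row["passes_refinement"])),
    )
    acceptors = tuple(
        CrypticAcceptor(
            branch=SpliceSiteScore(a["branch_window"], a["branch_start"], a["branch_cv"]),
            acceptor=SpliceSiteScore(
                a["acceptor_window"], a["acceptor_start"], a["acceptor_cv"]
            ),
            junction_offset=a["junction_offset"],
            dist_to_polya=a["dist_to_polya"],
            rank=a["rank"],
            genomic_junction=a["genomic_junction"],
        )
        for a in json.loads(row["acceptors"])
    )
    return CandidateRecord(
        gene_id=row["gene_id"],
        transcript_id=row["transcript_id"],
        best_hit=hit,
        acceptors=acceptors,
        stage=row["stage"],
    )


def read_candidates(path: str | Path) -> list[CandidateRecord]:
    """Reconstruct :class:`CandidateRecord` objects from a candidates TSV."""
    with open(path, newline="") as fh:
        return [_row_to_record(row) for row in csv.DictReader(fh, delimiter="\t")]


def export_results(
    records: Sequence[CandidateRecord],
    report: FunnelReport,
    out_dir: str | Path,
    genome: Genome | None = None,
    gene_models: Sequence[GeneModel] | None = None,
    params: ScreenParams | None = None,
) -> dict[str, Path]:
    """Write candidates TSV, signal/acceptor BEDs, predicted transcripts
    (GTF + FASTA, when reference context is supplied) and the funnel JSON.

    The candidates TSV round-trips: :func:`read_candidates` reconstructs the
    in-memory records exactly.
    """
    from .transcripts import build_transcript  # local import to avoid a cycle

    params = params or ScreenParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["candidates"] = out / "candidates.tsv"
    with open(paths["candidates"], "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_TSV_FIELDS, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        for rec in records:
            writer.writerow(_record_to_row(rec))

    paths["signals_bed"] = out / "signals.bed"
    with open(paths["signals_bed"], "w") as fh:
        for rec in records:
            hit = rec.best_hit
            lo, hi = hit.genomic_interval
            name = f"{rec.gene_id}_intron{hit.intron.ordinal}_{hit.hexamer}"
            fh.write(
                f"{hit.intron.contig}\t{lo}\t{hi}\t{name}\t0\t{hit.intron.strand}\n"
            )

    paths["acceptors_bed"] = out / "acceptors.bed"
    with open(paths["acceptors_bed"], "w") as fh:
        for rec in records:
            strand = rec.best_hit.intron.strand
            for acc in rec.acceptors:
                if acc.genomic_junction is None:
                    continue
                g = acc.genomic_junction
                lo, hi = (g - 2, g) if strand == "+" else (g + 1, g + 3)
                fh.write(
                    f"{rec.best_hit.intron.contig}\t{lo}\t{hi}\t"
                    f"{rec.gene_id}_c3ss_rank{acc.rank}\t{acc.acceptor.cv:.2f}\t{strand}\n"
                )

    gene_by_tx = {g.transcript_id: g for g in gene_models or []}
    paths["transcripts_fasta"] = out / "transcripts.fa"
    paths["transcripts_gtf"] = out / "transcripts.gtf"
    with open(paths["transcripts_fasta"], "w") as fa, open(paths["transcripts_gtf"], "w") as gtf:
        for rec in records:
            gene = gene_by_tx.get(rec.transcript_id)
            if genome is None or gene is None or not rec.best_hit.passes_refinement:
                continue
            models = [
                build_transcript(
                    gene, genome, "PCPA", pa_hit=rec.best_hit,
                    cleavage_offset=params.cleavage_offset,
                    tail_len=params.polya_tail_len,
                )
            ]
            rank1 = next((a for a in rec.acceptors if a.rank == 1), None)
            if rank1 is not None:
                models.append(
                    build_transcript(
                        gene, genome, "CSPP", pa_hit=rec.best_hit, acceptor=rank1,
                        cleavage_offset=params.cleavage_offset,
                        tail_len=params.polya_tail_len,
                    )
                )
            for tx in models:
                tx_id = f"{rec.transcript_id}.{tx.kind}"
                fa.write(f">{tx_id}\n")
                for i in range(0, len(tx.seq), 60):
                    fa.write(tx.seq[i : i + 60] + "\n")
                for s, e in sorted(tx.segments):
                    attrs = f'gene_id "{rec.gene_id}"; transcript_id "{tx_id}"; kind "{tx.kind}";'
                    gtf.write(
                        "\t".join(
                            [
                                gene.contig, "pcpa_screen", "exon", str(s + 1), str(e),
                                ".", gene.strand, ".", attrs,
                            ]
                        )
                        + "\n"
                    )

    paths["funnel"] = out / "funnel.json"
    with open(paths["funnel"], "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
    return paths
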