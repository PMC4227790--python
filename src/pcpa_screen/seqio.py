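"""Reference-sequence and annotation I/O with strand-aware sequence primitives.

Coordinate conventions used throughout the package:

* internal coordinates are 0-based, half-open, genomic;
* written outputs follow each format's own convention (BED 0-based half-open,
  GTF 1-based closed);
* a gene's *oriented* coordinate system puts 0 at the transcription start site
  and increases along the direction of transcription, so every "downstream
  distance" in the screen is a transcript-direction distance, never a raw
  genomic delta. For minus-strand genes oriented sequences are reverse
  complements of the genomic top strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")
ALPHABET = frozenset("ACGTN")

__all__ = [
    "Genome",
    "GeneModel",
    "Primer",
    "load_reference",
    "reverse_complement",
    "verify_primer_pair",
    "find_motif",
]


def reverse_complement(seq: str) -> str:
    """Reverse complement of ``seq`` (alphabet ACGTN, case preserved)."""
    if not set(seq.upper()) <= ALPHABET:
        bad = sorted(set(seq.upper()) - ALPHABET)
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Primer:
    """An oligonucleotide written 5'->3'."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"primer {self.name!r} has empty sequence")
        if not set(self.seq.upper()) <= NUCLEOTIDES:
            raise ValueError(f"primer {self.name!r} contains non-ACGT characters")


def verify_primer_pair(fwd: Primer, rev: Primer) -> bool:
    """True iff ``rev`` is the exact reverse complement of ``fwd`` (case-insensitive).

    Site-directed mutagenesis primer pairs anneal to opposite strands over the
    same footprint, so a well-formed pair must satisfy this identity.
    """
    return rev.seq.upper() == reverse_complement(fwd.seq.upper())


def find_motif(seq: str, motif: str, allow_overlap: bool = True) -> list[int]:
    """All 0-based start offsets of exact ``motif`` occurrences in ``seq``.

    N never matches any motif position (the motif itself must be unambiguous
    ACGT). A motif longer than ``seq`` yields an empty list.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    if not set(motif) <= NUCLEOTIDES:
        raise ValueError("motif must be unambiguous ACGT")
    s = seq.upper()
    out: list[int] = []
    i = s.find(motif)
    while i != -1:
        out.append(i)
        i = s.find(motif, i + 1 if allow_overlap else i + len(motif))
    return out


class Genome:
    """Uppercase nucleotide sequences keyed by contig name."""

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("genome must contain at least one contig")
        norm: dict[str, str] = {}
        for name, seq in contigs.items():
            s = str(seq).upper()
            if not s:
                raise ValueError(f"contig {name!r} is empty")
            if not set(s) <= ALPHABET:
                bad = sorted(set(s) - ALPHABET)
                raise ValueError(f"contig {name!r} contains invalid characters {bad}")
            norm[name] = s
        self.contigs: dict[str, str] = norm

    @classmethod
    def from_fasta(cls, source: str | Path) -> "Genome":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(source), "fasta")}
        if not records:
            raise ValueError(f"no FASTA records found in {source}")
        return cls(records)

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        if contig not in self.contigs:
            raise KeyError(f"unknown contig {contig!r}")
        if start < 0 or end > len(self.contigs[contig]) or start > end:
            raise ValueError(
                f"interval [{start},{end}) outside contig {contig!r} "
                f"of length {len(self.contigs[contig])}"
            )
        return self.contigs[contig][start:end]

    def gene_seq(self, gene: "GeneModel") -> str:
        """Oriented sequence of the gene span (position 0 = TSS)."""
        s = self.fetch(gene.contig, gene.span[0], gene.span[1])
        return reverse_complement(s) if gene.strand == "-" else s

    def with_contig(self, name: str, seq: str) -> "Genome":
        new = dict(self.contigs)
        new[name] = seq
        return Genome(new)

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.contigs):
                fh.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class GeneModel:
    """A stranded, exon-structured gene model on a reference contig.

    ``exons`` are genomic half-open intervals listed in transcription order
    (ascending genomic coordinates on '+', descending on '-').
    """

    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: zero/negative-length exon [{s},{e})")
        genomic = sorted(exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if exons != tuple(expected):
            raise ValueError(f"{self.gene_id}: exons not in transcription order")
        object.__setattr__(self, "exons", exons)
        if not self.transcript_id:
            object.__setattr__(self, "transcript_id", f"{self.gene_id}.t1")

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start (strand-aware)."""
        first = self.exons[0]
        return first[0] if self.strand == "+" else first[1] - 1

    def oriented_exons(self) -> list[tuple[int, int]]:
        """Exons in gene-oriented coordinates (0 = TSS), ascending."""
        ss, se = self.span
        if self.strand == "+":
            return [(s - ss, e - ss) for s, e in self.exons]
        return [(se - e, se - s) for s, e in self.exons]

    def oriented_to_genomic(self, pos: int) -> int:
        """Map an oriented offset to the genomic coordinate of that base."""
        ss, se = self.span
        if not 0 <= pos <= self.span_length:
            raise ValueError(f"oriented position {pos} outside gene span")
        return ss + pos if self.strand == "+" else se - 1 - pos

    def oriented_interval_to_genomic(self, start: int, end: int) -> tuple[int, int]:
        """Map an oriented half-open interval to a genomic half-open interval."""
        ss, se = self.span
        if self.strand == "+":
            return ss + start, ss + end
        return se - end, se - start


def _bed12_gene_models(path: Path) -> list[GeneModel]:
    cols = [
        "contig", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count",
        "block_sizes", "block_starts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=cols, dtype=str)
    genes: list[GeneModel] = []
    for row in df.itertuples(index=False):
        start = int(row.start)
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        exons = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
        exons = [iv for iv in exons if iv[1] > iv[0]]
        if not exons:
            log.warning("skipping BED record %s: no non-empty blocks", row.name)
            continue
        if row.strand == "-":
            exons = exons[::-1]
        genes.append(
            GeneModel(
                gene_id=str(row.name),
                contig=str(row.contig),
                strand=str(row.strand),
                exons=tuple(exons),
                transcript_id=str(row.name),
            )
        )
    return genes


def _gff_gene_models(path: Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        attrs = exon.attributes
        tx = (attrs.get("transcript_id") or attrs.get("Parent") or [None])[0]
        if tx is None:
            log.warning("skipping exon without transcript_id/Parent at %s:%s", exon.seqid, exon.start)
            continue
        gene = (attrs.get("gene_id") or attrs.get("gene") or [tx])[0]
        start, end = exon.start - 1, exon.end  # GTF/GFF are 1-based closed
        if end <= start:
            log.warning("skipping zero-length exon of %s", tx)
            continue
        entry = by_tx.setdefault(
            tx, {"gene": gene, "contig": exon.seqid, "strand": exon.strand, "exons": []}
        )
        entry["exons"].append((start, end))
    genes = []
    for tx, entry in by_tx.items():
        exons = sorted(entry["exons"])
        if entry["strand"] == "-":
            exons = exons[::-1]
        genes.append(
            GeneModel(
                gene_id=entry["gene"],
                contig=entry["contig"],
                strand=entry["strand"],
                exons=tuple(exons),
                transcript_id=tx,
            )
        )
    genes.sort(key=lambda g: (g.contig, g.span[0], g.transcript_id))
    return genes


def load_reference(
    fasta_source: str | Path, annotation_source: str | Path
) -> tuple[Genome, list[GeneModel]]:
    """Load a FASTA reference plus gene models from GTF/GFF3 or BED12.

    Malformed exon records are skipped with a logged warning; a gene whose
    contig is absent from the FASTA is a hard error naming the gene.
    """
    genome = Genome.from_fasta(fasta_source)
    ann = Path(annotation_source)
    if ann.suffix.lower() in (".bed", ".bed12"):
        genes = _bed12_gene_models(ann)
    else:
        genes = _gff_gene_models(ann)
    for gene in genes:
        if gene.contig not in genome:
            raise ValueError(
                f"gene {gene.gene_id!r} references contig {gene.contig!r} "
                "absent from the FASTA"
            )
        if gene.span[1] > genome.length(gene.contig):
            raise ValueError(
                f"gene {gene.gene_id!r} extends past the end of contig {gene.contig!r}"
            )
    return genome, genes


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "pcpa_screen") -> None:
    """Write gene models as GTF exon features (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for gene in genes:
            for s, e in sorted(gene.exons):
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.transcript_id}";'
                fh.write(
                    "\t".join(
                        [
                            gene.contig, source, "exon", str(s + 1), str(e),
                            ".", gene.strand, ".", attrs,
                        ]
                    )
                    + "\n"
                )
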