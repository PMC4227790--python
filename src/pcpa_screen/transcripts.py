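"""Transcript isoform models, reporter constructs and in-silico mutagenesis.

Isoform kinds modelled here:

* ``mRNA`` — the fully spliced annotated product;
* ``pre-mRNA`` — the unspliced genomic span, not polyadenylated;
* ``PCPA`` — premature cleavage and polyadenylation at an intronic poly(A)
  signal: the transcript ends in a *composite terminal exon* made of the
  upstream exon plus the host-intron prefix up to the cleavage site;
* ``CSPP`` — the cryptically spliced product of PCPA: identical to PCPA
  except the interval from the authentic 5' splice site to a cryptic
  intronic 3' splice-site junction has been spliced out;
* ``read-through`` — RNA transcribed past the intronic poly(A) signal
  without cleavage, hence not polyadenylated there.

The cleavage site is placed a configurable offset downstream of the hexamer
end (default 15 nt, in the canonical 10-30 nt window); polyadenylated
transcripts carry a modelled homopolymer tail so that oligo-dT-primed 3' RACE
can be simulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .polya import (
    IntronRecord,
    PolyASignalHit,
    ScreenParams,
    enumerate_introns,
    filter_promoter_proximal,
    find_intronic_polya_signals,
)
from .scoring import (
    CrypticAcceptor,
    FrequencyMatrix,
    rank_cryptic_sites,
    scan_cryptic_acceptors,
)
from .seqio import GeneModel, Genome, find_motif, reverse_complement

TRANSCRIPT_KINDS = ("mRNA", "pre-mRNA", "PCPA", "CSPP", "read-through")

__all__ = [
    "TranscriptModel",
    "CisElement",
    "ReporterConstruct",
    "EditRecord",
    "Minigene",
    "ScanResult",
    "build_transcript",
    "extract_cis_element",
    "insert_cis_element",
    "make_cat_reporter",
    "construct_to_reference",
    "apply_mutation",
]


@dataclass(frozen=True)
class TranscriptModel:
    """An isoform as an ordered list of genomic segments joined 5'->3'."""

    kind: str
    gene_id: str
    segments: tuple[tuple[int, int], ...]
    seq: str
    polyadenylated: bool
    tail_len: int = 0
    cleavage_pos: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in TRANSCRIPT_KINDS:
            raise ValueError(f"unknown transcript kind {self.kind!r}")
        seg_len = sum(e - s for s, e in self.segments)
        if len(self.seq) != seg_len + self.tail_len:
            raise ValueError(
                f"{self.kind}: sequence length {len(self.seq)} != "
                f"segment total {seg_len} + tail {self.tail_len}"
            )

    @property
    def body(self) -> str:
        """Transcript sequence without the modelled poly(A) tail."""
        return self.seq[: len(self.seq) - self.tail_len] if self.tail_len else self.seq

    def __len__(self) -> int:
        return len(self.seq)


def _oriented_segments_to_genomic(
    gene: GeneModel, oriented: Sequence[tuple[int, int]]
) -> tuple[tuple[int, int], ...]:
    return tuple(gene.oriented_interval_to_genomic(s, e) for s, e in oriented)


def build_transcript(
    gene: GeneModel,
    genome: Genome,
    kind: str,
    pa_hit: PolyASignalHit | None = None,
    acceptor: CrypticAcceptor | None = None,
    cleavage_offset: int = 15,
    tail_len: int = 30,
    readthrough_extension: int = 200,
) -> TranscriptModel:
    """Assemble the requested isoform of ``gene``.

    ``PCPA``/``CSPP``/``read-through`` require ``pa_hit`` (the intronic
    poly(A) signal); ``CSPP`` additionally requires ``acceptor`` (a called
    cryptic 3' splice site upstream of the cleavage position) and an intact
    authentic donor GT at the host intron's 5' splice site, since the
    cryptically spliced product joins that donor to the cryptic acceptor.
    """
    if kind not in TRANSCRIPT_KINDS:
        raise ValueError(f"unknown transcript kind {kind!r}")
    gene_seq = genome.gene_seq(gene)
    oriented_exons = gene.oriented_exons()

    def materialize(oriented: list[tuple[int, int]], tail: int) -> TranscriptModel:
        body = "".join(gene_seq[s:e] for s, e in oriented)
        cleavage = None
        if kind in ("PCPA", "CSPP"):
            cleavage = gene.oriented_to_genomic(oriented[-1][1] - 1)
        return TranscriptModel(
            kind=kind,
            gene_id=gene.gene_id,
            segments=_oriented_segments_to_genomic(gene, oriented),
            seq=body + "A" * tail,
            polyadenylated=tail > 0,
            tail_len=tail,
            cleavage_pos=cleavage,
        )

    if kind == "mRNA":
        return materialize(oriented_exons, tail_len)
    if kind == "pre-mRNA":
        return materialize([(0, gene.span_length)], 0)

    if pa_hit is None:
        raise ValueError(f"{kind} requires a poly(A) signal hit")
    intron = pa_hit.intron
    k = intron.ordinal
    cleavage_oriented = intron.oriented_start + pa_hit.dist_from_5ss + 6 + cleavage_offset
    if cleavage_oriented > intron.oriented_end:
        raise ValueError("cleavage site extends past the host intron")

    if kind == "read-through":
        end = min(cleavage_oriented + readthrough_extension, intron.oriented_end)
        segs = oriented_exons[: k - 1] + [(oriented_exons[k - 1][0], end)]
        return materialize(segs, 0)

    if kind == "PCPA":
        # composite terminal exon: upstream exon fused to the intron prefix
        segs = oriented_exons[: k - 1] + [(oriented_exons[k - 1][0], cleavage_oriented)]
        return materialize(segs, tail_len)

    # CSPP
    if acceptor is None:
        raise ValueError("CSPP requires a called cryptic acceptor")
    junction = intron.oriented_start + acceptor.junction_offset
    if junction >= cleavage_oriented:
        raise ValueError("cryptic acceptor lies downstream of the cleavage position")
    donor = gene_seq[intron.oriented_start : intron.oriented_start + 2]
    if donor != "GT":
        raise ValueError(
            f"authentic 5' splice site of intron {k} is not GT (found {donor!r}); "
            "cryptic splicing requires an intact donor"
        )
    segs = oriented_exons[:k] + [(junction, cleavage_oriented)]
    return materialize(segs, tail_len)


@dataclass(frozen=True)
class CisElement:
    """A poly(A)-signal-centred intronic fragment for reporter insertion."""

    source_gene: str
    upstream_pad: int
    downstream_pad: int
    seq: str
    hexamer: str = "AATAAA"

    def __post_init__(self) -> None:
        if len(self.seq) != self.upstream_pad + len(self.hexamer) + self.downstream_pad:
            raise ValueError("cis-element length inconsistent with pads")
        at = self.seq.upper()[self.upstream_pad : self.upstream_pad + len(self.hexamer)]
        if at != self.hexamer.upper():
            raise ValueError(f"hexamer not found at offset {self.upstream_pad}")


def extract_cis_element(
    gene: GeneModel,
    genome: Genome,
    pa_hit: PolyASignalHit,
    upstream_pad: int = 157,
    downstream_pad: int = 51,
) -> CisElement:
    """Cut the fragment from ``upstream_pad`` nt before to ``downstream_pad``
    nt after the poly(A) hexamer, entirely within the host intron."""
    intron = pa_hit.intron
    d = pa_hit.dist_from_5ss
    if d < upstream_pad:
        raise ValueError(
            f"upstream pad {upstream_pad} exceeds the {d} nt available before the hexamer"
        )
    if d + 6 + downstream_pad > intron.length:
        raise ValueError(
            f"downstream pad {downstream_pad} extends past the intron boundary"
        )
    gene_seq = genome.gene_seq(gene)
    start = intron.oriented_start + d - upstream_pad
    end = intron.oriented_start + d + 6 + downstream_pad
    return CisElement(
        source_gene=gene.gene_id,
        upstream_pad=upstream_pad,
        downstream_pad=downstream_pad,
        seq=gene_seq[start:end],
        hexamer=pa_hit.hexamer,
    )


@dataclass(frozen=True)
class ReporterConstruct:
    """A labelled minigene reporter: exon1 - intron - 3' exon - vector poly(A)."""

    name: str
    segments: tuple[tuple[str, str], ...]
    insertions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        labels = [lbl for lbl, _ in self.segments]
        if len(labels) != len(set(labels)):
            raise ValueError("segment labels must be unique")

    @property
    def seq(self) -> str:
        return "".join(s for _, s in self.segments)

    def segment(self, label: str) -> str:
        for lbl, s in self.segments:
            if lbl == label:
                return s
        raise KeyError(f"no segment labelled {label!r}")

    def segment_offset(self, label: str) -> int:
        off = 0
        for lbl, s in self.segments:
            if lbl == label:
                return off
            off += len(s)
        raise KeyError(f"no segment labelled {label!r}")


_SITE_LABELS = {"intron": "intron", "three_prime_exon": "three_prime_exon"}


def insert_cis_element(
    construct: ReporterConstruct,
    element: CisElement,
    site: str,
    neutralize_vector_pa: bool = False,
    insertion_offset: int | None = None,
) -> ReporterConstruct:
    """Insert ``element`` into the named site of the reporter.

    ``site`` is ``"intron"`` or ``"three_prime_exon"``. When
    ``neutralize_vector_pa`` is set, every aataaa in the vector poly(A)
    segment is replaced by ggatcc, so the inserted element's signal is the
    only functional one nearby.
    """
    if site not in _SITE_LABELS:
        raise ValueError(f"unknown insertion site {site!r}")
    label = _SITE_LABELS[site]
    new_segments = []
    inserted = False
    for lbl, s in construct.segments:
        if lbl == label:
            at = len(s) // 2 if insertion_offset is None else insertion_offset
            if not 0 <= at <= len(s):
                raise ValueError("insertion offset outside segment")
            s = s[:at] + element.seq + s[at:]
            inserted = True
        if neutralize_vector_pa and lbl == "vector_pa":
            u = s.upper()
            while "AATAAA" in u:
                i = u.index("AATAAA")
                u = u[:i] + "GGATCC" + u[i + 6 :]
            s = u
        new_segments.append((lbl, s))
    if not inserted:
        raise ValueError(f"construct has no segment labelled {label!r}")
    return ReporterConstruct(
        name=construct.name,
        segments=tuple(new_segments),
        insertions=construct.insertions + ((element.source_gene, site),),
    )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_cat_reporter(
    seed: int = 0,
    exon1_len: int = 150,
    intron_len: int = 900,
    exon2_len: int = 150,
    vector_pa_len: int = 60,
    name: str = "CAT(In)",
) -> ReporterConstruct:
    """A deterministic intron-containing CAT-style reporter backbone.

    The intron carries canonical GT/AG boundaries and the vector poly(A)
    segment contains a single AATAAA; random background is scrubbed of any
    other AATAAA so that subsequent scans see only planted signals.
    """
    rng = np.random.default_rng(seed)

    def scrubbed(n: int) -> str:
        s = list(_random_seq(rng, n))
        for _ in range(100):
            hits = find_motif("".join(s), "AATAAA")
            if not hits:
                return "".join(s)
            for h in hits:
                s[h + rng.integers(0, 6)] = str(rng.choice(list("CG")))
        raise RuntimeError("could not scrub reporter background")

    exon1 = scrubbed(exon1_len)
    intron = "GT" + scrubbed(intron_len - 4) + "AG"
    exon2 = scrubbed(exon2_len)
    pa_core = scrubbed(vector_pa_len - 6)
    at = vector_pa_len // 3
    vector_pa = pa_core[:at] + "AATAAA" + pa_core[at:]
    return ReporterConstruct(
        name=name,
        segments=(
            ("exon1", exon1),
            ("intron", intron),
            ("three_prime_exon", exon2),
            ("vector_pa", vector_pa),
        ),
    )


def construct_to_reference(
    construct: ReporterConstruct, contig: str = "reporter"
) -> tuple[Genome, GeneModel]:
    """Express a reporter as a plus-strand single-gene reference for screening.

    The terminal exon spans the 3' exon and the vector poly(A) segment, so a
    cis-element inserted into the 3' exon is exonic while one inserted into
    the intron is intronic — mirroring the two insertion-site variants.
    """
    exon1 = construct.segment("exon1")
    intron = construct.segment("intron")
    e1 = (0, len(exon1))
    intron_end = len(exon1) + len(intron)
    e2 = (intron_end, len(construct.seq))
    gene = GeneModel(
        gene_id=construct.name,
        contig=contig,
        strand="+",
        exons=(e1, e2),
    )
    return Genome({contig: construct.seq}), gene


@dataclass(frozen=True)
class EditRecord:
    """A minimal substitution applied to a reference sequence."""

    target: str
    oriented_start: int
    genomic_interval: tuple[int, int]
    before: str
    after: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScanResult:
    """Output of a single-gene screen: flagged hits, the best refined hit, and
    ranked cryptic acceptors in its intron."""

    hits: list[PolyASignalHit]
    best: PolyASignalHit | None
    acceptors: list[CrypticAcceptor]


@dataclass(frozen=True)
class Minigene:
    """A single gene on a reference, bundled with screen parameters.

    Supports rescanning after in-silico mutagenesis, reproducing the
    mutate-and-reassay logic of minigene experiments: destroying the poly(A)
    hexamer abolishes PCPA calling, destroying a cryptic acceptor's AG
    promotes the next-ranked site, destroying the donor GT leaves PCPA
    intact but blocks CSPP construction.
    """

    genome: Genome
    gene: GeneModel
    params: ScreenParams
    branch_matrix: FrequencyMatrix
    acceptor_matrix: FrequencyMatrix

    def scan(self) -> ScanResult:
        hits = filter_promoter_proximal(
            find_intronic_polya_signals(self.gene, self.genome, self.params), self.params
        )
        refined = [h for h in hits if h.passes_refinement]
        best = min(refined, key=lambda h: h.dist_from_tss) if refined else None
        acceptors: list[CrypticAcceptor] = []
        if best is not None:
            gene_seq = self.genome.gene_seq(self.gene)
            iseq = gene_seq[best.intron.oriented_start : best.intron.oriented_end]
            acceptors = rank_cryptic_sites(
                scan_cryptic_acceptors(
                    iseq, best.dist_from_5ss, self.params,
                    self.branch_matrix, self.acceptor_matrix,
                )
            )
            for acc in acceptors:
                acc.genomic_junction = self.gene.oriented_to_genomic(
                    best.intron.oriented_start + acc.junction_offset
                )
        return ScanResult(hits=hits, best=best, acceptors=acceptors)

    def _edit(self, target: str, opos: int, replacement: str) -> tuple["Minigene", EditRecord]:
        gene_seq = self.genome.gene_seq(self.gene)
        before = gene_seq[opos : opos + len(replacement)]
        new_oriented = gene_seq[:opos] + replacement + gene_seq[opos + len(replacement) :]
        ss, se = self.gene.span
        block = new_oriented if self.gene.strand == "+" else reverse_complement(new_oriented)
        contig_seq = self.genome.contigs[self.gene.contig]
        new_contig = contig_seq[:ss] + block + contig_seq[se:]
        g_lo = min(self.gene.oriented_to_genomic(opos),
                   self.gene.oriented_to_genomic(opos + len(replacement) - 1))
        record = EditRecord(
            target=target,
            oriented_start=opos,
            genomic_interval=(g_lo, g_lo + len(replacement)),
            before=before,
            after=replacement,
        )
        return (
            dataclasses.replace(self, genome=self.genome.with_contig(self.gene.contig, new_contig)),
            record,
        )

    def apply_mutation(
        self, target: str, site_index: int = 1
    ) -> tuple["Minigene", EditRecord]:
        """Destroy a previously called element with a minimal substitution.

        ``target``: ``"polya_signal"`` (AATAAA -> GGATCC), ``"five_ss"``
        (donor GT -> GA) or ``"cryptic_3ss"`` (rank ``site_index`` acceptor's
        invariant AG -> AT).
        """
        result = self.scan()
        if result.best is None:
            raise ValueError("no passing poly(A) signal called; nothing to mutate")
        intron = result.best.intron
        if target == "polya_signal":
            opos = intron.oriented_start + result.best.dist_from_5ss
            return self._edit(target, opos, "GGATCC")
        if target == "five_ss":
            opos = intron.oriented_start
            gene_seq = self.genome.gene_seq(self.gene)
            if gene_seq[opos : opos + 2] != "GT":
                raise ValueError("donor GT not present at the 5' splice site")
            return self._edit(target, opos, "GA")
        if target == "cryptic_3ss":
            by_rank = {a.rank: a for a in result.acceptors}
            if site_index not in by_rank:
                raise ValueError(f"no cryptic acceptor with rank {site_index}")
            acc = by_rank[site_index]
            # the invariant AG occupies the two positions before the junction
            opos = intron.oriented_start + acc.junction_offset - 2
            return self._edit(f"cryptic_3ss_{site_index}", opos, "AT")
        raise ValueError(f"unknown mutation target {target!r}")


def apply_mutation(
    minigene: Minigene, target: str, site_index: int = 1
) -> tuple[Minigene, EditRecord]:
    """Functional wrapper over :meth:`Minigene.apply_mutation`."""
    return minigene.apply_mutation(target, site_index=site_index)
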