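"""Stage 1 of the screen: intronic poly(A)-signal discovery and positional filters.

A promoter-proximal intronic poly(A) signal is a hexamer (canonically AATAAA)
lying in a first or second intron of at least 1 kb, within 5 kb of the
transcription start site and within 1 kb of the intron's 5' splice site, all
distances measured along the direction of transcription. A refinement keeps
only signals strictly closer than 500 bp to the 5' splice site; those introns
are then scanned for cryptic 3' splice sites upstream of the signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .seqio import GeneModel, Genome, find_motif

__all__ = [
    "IntronRecord",
    "PolyASignalHit",
    "ScreenParams",
    "enumerate_introns",
    "find_intronic_polya_signals",
    "filter_promoter_proximal",
]


@dataclass(frozen=True)
class IntronRecord:
    """One intron of a transcript, in both genomic and oriented coordinates.

    ``five_ss`` is the genomic position of the first intronic base on the
    transcribed strand (donor side); ``three_ss`` the strand-aware position
    just past the last intronic base (acceptor side).
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    ordinal: int  # 1-based, transcription order
    genomic_start: int
    genomic_end: int
    oriented_start: int
    oriented_end: int
    five_ss: int
    three_ss: int

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise ValueError("intron ordinal must be >= 1")
        if self.length < 1:
            raise ValueError("intron must have length >= 1")

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start


@dataclass(frozen=True)
class PolyASignalHit:
    """An intronic poly(A) hexamer occurrence with the screen's three distances.

    ``signal_start`` is the genomic coordinate of the hexamer's first
    transcribed base (strand-aware); distances are transcript-direction
    distances to the hexamer's first base.
    """

    intron: IntronRecord
    hexamer: str
    signal_start: int
    dist_from_tss: int
    dist_from_5ss: int
    passes_stage1: bool = False
    passes_refinement: bool = False

    def __post_init__(self) -> None:
        if self.dist_from_5ss < 0:
            raise ValueError("dist_from_5ss must be >= 0")

    @property
    def genomic_interval(self) -> tuple[int, int]:
        """Genomic half-open interval occupied by the hexamer."""
        if self.intron.strand == "+":
            return self.signal_start, self.signal_start + 6
        return self.signal_start - 5, self.signal_start + 1


@dataclass(frozen=True)
class ScreenParams:
    """Operating point of the screen.

    Defaults implement the published operating point: signals within 5 kb of
    the TSS, in a first or second intron of >= 1 kb, within 1 kb of the 5'
    splice site (all inclusive), refined to < 500 bp (strict), with consensus
    value thresholds 39.41 (acceptor 14-mer) and 50.16 (branch 7-mer).
    """

    signal_set: frozenset[str] = frozenset({"AATAAA"})
    max_tss_dist: int = 5000
    allowed_intron_ordinals: frozenset[int] = frozenset({1, 2})
    min_intron_len: int = 1000
    max_5ss_dist: int = 1000
    refined_max_5ss_dist: int = 500
    acceptor_cv_threshold: float = 39.41
    branch_cv_threshold: float = 50.16
    branch_spacing: tuple[int, int] = (18, 44)
    cleavage_offset: int = 15
    polya_tail_len: int = 30

    def __post_init__(self) -> None:
        object.__setattr__(self, "signal_set", frozenset(h.upper() for h in self.signal_set))
        object.__setattr__(
            self, "allowed_intron_ordinals", frozenset(int(o) for o in self.allowed_intron_ordinals)
        )
        if min(self.max_tss_dist, self.min_intron_len, self.max_5ss_dist, self.refined_max_5ss_dist) <= 0:
            raise ValueError("all distance parameters must be positive")
        if self.refined_max_5ss_dist > self.max_5ss_dist:
            raise ValueError("refined_max_5ss_dist must be <= max_5ss_dist")
        for thr in (self.acceptor_cv_threshold, self.branch_cv_threshold):
            if not 0 <= thr <= 100:
                raise ValueError("consensus-value thresholds must lie in [0, 100]")
        lo, hi = self.branch_spacing
        if not (0 <= lo <= hi):
            raise ValueError("branch_spacing must be a nonnegative (lo, hi) with lo <= hi")

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenParams":
        kwargs = dict(d)
        if "signal_set" in kwargs:
            kwargs["signal_set"] = frozenset(kwargs["signal_set"])
        if "allowed_intron_ordinals" in kwargs:
            kwargs["allowed_intron_ordinals"] = frozenset(kwargs["allowed_intron_ordinals"])
        if "branch_spacing" in kwargs:
            kwargs["branch_spacing"] = tuple(kwargs["branch_spacing"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["signal_set"] = sorted(self.signal_set)
        d["allowed_intron_ordinals"] = sorted(self.allowed_intron_ordinals)
        d["branch_spacing"] = list(self.branch_spacing)
        return d


def enumerate_introns(gene: GeneModel) -> list[IntronRecord]:
    """Introns of ``gene`` in transcription order, ordinals 1..n-1.

    Single-exon genes have no introns.
    """
    oriented = gene.oriented_exons()
    records: list[IntronRecord] = []
    for i, ((_, e1), (s2, _)) in enumerate(zip(oriented, oriented[1:]), start=1):
        o_start, o_end = e1, s2
        g_start, g_end = gene.oriented_interval_to_genomic(o_start, o_end)
        records.append(
            IntronRecord(
                gene_id=gene.gene_id,
                transcript_id=gene.transcript_id,
                contig=gene.contig,
                strand=gene.strand,
                ordinal=i,
                genomic_start=g_start,
                genomic_end=g_end,
                oriented_start=o_start,
                oriented_end=o_end,
                five_ss=gene.oriented_to_genomic(o_start),
                three_ss=gene.oriented_to_genomic(o_end - 1)
                + (1 if gene.strand == "+" else -1),
            )
        )
    return records


def find_intronic_polya_signals(
    gene: GeneModel, genome: Genome, params: ScreenParams
) -> list[PolyASignalHit]:
    """All intronic poly(A)-hexamer occurrences of ``gene`` with their distances.

    One hit per (intron, hexamer occurrence); pass/fail flags are left unset
    (filtering is a separate, order-preserving step). Exonic occurrences and
    hexamers straddling an exon/intron boundary are not reported: only
    windows fully inside the extracted intron sequence count as intronic.
    """
    span_start, span_end = gene.span
    if span_start < 0 or span_end > genome.length(gene.contig):
        raise ValueError(f"gene {gene.gene_id!r} lies outside contig bounds")
    gene_seq = genome.gene_seq(gene)
    hits: list[PolyASignalHit] = []
    for intron in enumerate_introns(gene):
        iseq = gene_seq[intron.oriented_start : intron.oriented_end]
        for hexamer in sorted(params.signal_set):
            for off in find_motif(iseq, hexamer):
                oriented_pos = intron.oriented_start + off
                hits.append(
                    PolyASignalHit(
                        intron=intron,
                        hexamer=hexamer,
                        signal_start=gene.oriented_to_genomic(oriented_pos),
                        dist_from_tss=oriented_pos,
                        dist_from_5ss=off,
                    )
                )
    hits.sort(key=lambda h: (h.intron.ordinal, h.dist_from_5ss, h.hexamer))
    return hits


def filter_promoter_proximal(
    hits: Sequence[PolyASignalHit], params: ScreenParams
) -> list[PolyASignalHit]:
    """Apply the positional criteria, returning flagged copies in input order.

    Stage 1 requires (inclusive bounds, matching "within"): distance from the
    TSS <= ``max_tss_dist``; intron ordinal in ``allowed_intron_ordinals``
    with intron length >= ``min_intron_len``; distance from the 5' splice
    site <= ``max_5ss_dist``. The refinement additionally requires the strict
    bound dist_from_5ss < ``refined_max_5ss_dist``.
    """
    out: list[PolyASignalHit] = []
    for hit in hits:
        stage1 = (
            hit.dist_from_tss <= params.max_tss_dist
            and hit.intron.ordinal in params.allowed_intron_ordinals
            and hit.intron.length >= params.min_intron_len
            and hit.dist_from_5ss <= params.max_5ss_dist
        )
        refined = stage1 and hit.dist_from_5ss < params.refined_max_5ss_dist
        out.append(
            dataclasses.replace(hit, passes_stage1=stage1, passes_refinement=refined)
        )
    return out
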