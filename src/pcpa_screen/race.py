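"""In-silico 3' RACE: oligo-dT/adaptor reverse transcription, first-round PCR
with a gene- or vector-specific forward primer and the adaptor primer, then
nested PCR with a chimeric poly(A)-junction primer.

The chimeric nested primer carries a run of Ts (default 12) followed by
residues complementary to the template immediately upstream of the cleavage
site, so it only primes cDNAs whose body ends at that exact cleavage point —
this is what discriminates PCPA/CSPP products (shared terminus, different
internal structure) from read-through RNA, which carries no poly(A) tail at
the intronic site and yields nothing.

PCR cycle numbers (first round >35; nested 10/15/20 for mRNA/PCPA/CSPP
detection) are detection-sensitivity settings in the bench protocol; the
simulator records amplicons deterministically and treats cycles as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .polya import PolyASignalHit
from .scoring import CrypticAcceptor
from .seqio import GeneModel, Genome, Primer, reverse_complement
from .transcripts import TranscriptModel

__all__ = [
    "ChimericPrimer",
    "Amplicon",
    "design_chimeric_primer",
    "simulate_3race",
    "classify_amplicon",
    "make_junction_probes",
    "DEFAULT_ADAPTOR",
]

# Opaque stand-in for the oligo-dT/adaptor RT primer tag; the bench adaptor's
# exact sequence is a protocol detail and is configurable at call sites.
DEFAULT_ADAPTOR = Primer("XbaKpnBam_adaptor", "TCTAGAGGTACCGGATCC")


@dataclass(frozen=True)
class ChimericPrimer:
    """A nested reverse primer: ``t_run`` Ts then a cleavage-site anchor, 5'->3'."""

    name: str
    anchor: str
    t_run: int = 12

    def __post_init__(self) -> None:
        if self.t_run < 1:
            raise ValueError("t_run must be >= 1")
        if not self.anchor:
            raise ValueError("anchor must be non-empty")

    @property
    def seq(self) -> str:
        return "T" * self.t_run + self.anchor


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on a tagged cDNA template."""

    fwd_primer: str
    rev_primer: str
    template_kind: str
    start: int
    end: int
    round: str  # "first" | "nested"
    seq: str
    cycles: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("amplicon end must exceed start")
        if self.round not in ("first", "nested"):
            raise ValueError("round must be 'first' or 'nested'")

    @property
    def length(self) -> int:
        return self.end - self.start


def design_chimeric_primer(
    transcript: TranscriptModel,
    anchor_len: int = 8,
    t_run: int = 12,
    name: str | None = None,
) -> ChimericPrimer:
    """Design the nested reverse primer for ``transcript``'s poly(A) junction.

    The anchor is the reverse complement of the ``anchor_len`` bases
    immediately 5' of the cleavage site, so the primer anneals exactly across
    the tail/body junction of its own transcript (and of any transcript
    sharing that terminus).
    """
    if not transcript.polyadenylated:
        raise ValueError("chimeric RACE primers require a polyadenylated transcript")
    if anchor_len < 4:
        raise ValueError("anchor_len must be >= 4")
    body = transcript.body
    if len(body) < anchor_len:
        raise ValueError("transcript body shorter than the requested anchor")
    anchor = reverse_complement(body[-anchor_len:]).upper()
    return ChimericPrimer(
        name=name or f"{transcript.gene_id}_{transcript.kind}_nested",
        anchor=anchor,
        t_run=t_run,
    )


def _tagged_cdna(transcript: TranscriptModel, adaptor: Primer) -> str:
    """Sense-strand template after oligo-dT/adaptor reverse transcription."""
    return transcript.seq.upper() + reverse_complement(adaptor.seq.upper())


def simulate_3race(
    pool: Sequence[TranscriptModel],
    fwd: Primer,
    adaptor: Primer = DEFAULT_ADAPTOR,
    nested_rev: ChimericPrimer | None = None,
    mismatch_tolerance: int = 0,
    first_round_cycles: int = 36,
    nested_cycles: int = 15,
) -> list[Amplicon]:
    """Predict first-round and nested amplicons from a transcript pool.

    Only polyadenylated transcripts are reverse transcribed (the adaptor
    anneals to the oligo-dT-tagged tail), so read-through and pre-mRNA
    templates yield nothing. The first round amplifies every tagged cDNA
    containing the forward primer; the nested round requires the chimeric
    primer's anchor to match the tail-adjacent terminus exactly. Lengths are
    measured between primer 5' ends. Only exact matching is implemented;
    ``mismatch_tolerance`` must currently be 0.
    """
    if mismatch_tolerance != 0:
        raise NotImplementedError("only exact primer matching is supported")
    fseq = fwd.seq.upper()
    amplicons: list[Amplicon] = []
    for tx in pool:
        if not tx.polyadenylated:
            continue
        template = _tagged_cdna(tx, adaptor)
        fpos = template.find(fseq)
        if fpos == -1:
            continue
        amplicons.append(
            Amplicon(
                fwd_primer=fwd.name,
                rev_primer=adaptor.name,
                template_kind=tx.kind,
                start=fpos,
                end=len(template),
                round="first",
                seq=template[fpos:],
                cycles=first_round_cycles,
            )
        )
        if nested_rev is None:
            continue
        body = tx.body.upper()
        anchor_site = reverse_complement(nested_rev.anchor)
        if not body.endswith(anchor_site):
            continue
        if tx.tail_len < nested_rev.t_run:
            continue
        rev_end = len(body) + nested_rev.t_run  # 5' end of the chimeric primer
        if fpos + len(fseq) > rev_end:
            continue
        amplicons.append(
            Amplicon(
                fwd_primer=fwd.name,
                rev_primer=nested_rev.name,
                template_kind=tx.kind,
                start=fpos,
                end=rev_end,
                round="nested",
                seq=template[fpos:rev_end],
                cycles=nested_cycles,
            )
        )
    return amplicons


def make_junction_probes(
    gene: GeneModel,
    genome: Genome,
    pa_hit: PolyASignalHit,
    acceptor: CrypticAcceptor | None = None,
    k: int = 8,
) -> dict[str, str]:
    """Diagnostic junction k-mer pairs distinguishing the isoform classes.

    * ``PCPA`` — the unspliced exon/intron boundary at the host intron's 5'
      splice site (present only when the intron prefix is retained);
    * ``CSPP`` — the chimeric junction of the upstream exon joined to the
      cryptic 3' splice site;
    * ``mRNA`` — the authentic exon-exon junction across the host intron.
    """
    gene_seq = genome.gene_seq(gene)
    intron = pa_hit.intron
    exon_end = intron.oriented_start
    if exon_end < k:
        raise ValueError("upstream exon shorter than probe half-width")
    left = gene_seq[exon_end - k : exon_end]
    probes = {
        "PCPA": left + gene_seq[exon_end : exon_end + k],
        "mRNA": left + gene_seq[intron.oriented_end : intron.oriented_end + k],
    }
    if acceptor is not None:
        j = intron.oriented_start + acceptor.junction_offset
        probes["CSPP"] = left + gene_seq[j : j + k]
    return probes


def classify_amplicon(amplicon: Amplicon, probes: Mapping[str, str]) -> str:
    """Assign an amplicon to an isoform class by its junction content.

    An amplicon containing the unspliced 5'ss interval is PCPA; one spanning
    the cryptic junction with that interval absent is CSPP; one spanning the
    authentic exon-exon junction is mRNA; anything else is ambiguous.
    """
    seq = amplicon.seq.upper()
    for kind in ("PCPA", "CSPP", "mRNA"):
        probe = probes.get(kind)
        if probe and probe.upper() in seq:
            return kind
    return "ambiguous"
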