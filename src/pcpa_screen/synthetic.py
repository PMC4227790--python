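"""Seeded synthetic genomes with planted PCPA elements and a truth manifest.

Each generated gene is multi-exon, strand-alternating, with canonical GT/AG
intron boundaries and, by default, a planted intronic AATAAA at a controlled
distance from the 5' splice site plus branch/acceptor motif pairs sampled at
controlled consensus-value bands upstream of it. The manifest records every
planted element with exact coordinates and the pass/fail flags the default
screen parameters imply, so recovery against the screen is exact-set testable.

When ``scrub_spurious`` is on, the background is rejection-regenerated until
the transcribed gene sequence contains no unplanted AATAAA and the scanned
region of the host intron contains no unplanted above-threshold acceptor
call (verified by internal rescan). Scrubbing never touches planted
elements, so the stated background composition is preserved except at
offending windows.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .polya import (
    IntronRecord,
    PolyASignalHit,
    ScreenParams,
    enumerate_introns,
)
from .scoring import (
    BASES,
    CrypticAcceptor,
    FrequencyMatrix,
    SpliceSiteScore,
    consensus_value,
    default_matrices,
    scan_cryptic_acceptors,
)
from .seqio import GeneModel, Genome, find_motif, reverse_complement, write_gtf
from .transcripts import TranscriptModel, build_transcript

__all__ = [
    "SyntheticConfig",
    "PlantedPolyA",
    "PlantedAcceptor",
    "GeneTruth",
    "TruthManifest",
    "generate_toy_genome",
    "sample_motif_with_cv",
    "generate_transcript_pool",
    "truth_to_hit",
    "truth_to_acceptor",
    "write_fixture_dir",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; fixed seed implies byte-identical output."""

    n_genes: int = 10
    seed: int = 0
    n_exons: tuple[int, int] = (3, 3)
    exon_len: tuple[int, int] = (150, 300)
    host_intron_len: tuple[int, int] = (1200, 1800)
    other_intron_len: tuple[int, int] = (1000, 1400)
    plant_polya: bool = True
    polya_ordinal: int = 1
    polya_dist: tuple[int, int] = (200, 450)
    cryptic_dists: tuple[int, ...] = (30, 120)
    acceptor_cv_band: tuple[float, float] = (70.0, 95.0)
    branch_cv_band: tuple[float, float] = (70.0, 95.0)
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    scrub_spurious: bool = True
    intergenic: int = 200
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("n_exons", "exon_len", "host_intron_len", "other_intron_len", "polya_dist"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} must be a non-empty positive range")
        if abs(sum(self.background) - 1.0) > 1e-6 or any(p < 0 for p in self.background):
            raise ValueError("background composition must be a probability vector")
        if len(set(self.cryptic_dists)) != len(self.cryptic_dists):
            raise ValueError("cryptic_dists must be distinct")
        if self.polya_ordinal < 1:
            raise ValueError("polya_ordinal must be >= 1")


@dataclass(frozen=True)
class PlantedPolyA:
    intron_ordinal: int
    dist_from_5ss: int
    dist_from_tss: int
    oriented_offset: int  # gene-oriented offset of the hexamer start
    hexamer: str
    expect_stage1: bool
    expect_refined: bool


@dataclass(frozen=True)
class PlantedAcceptor:
    junction_offset: int  # intron-relative, exonic side of the cryptic junction
    dist_to_polya: int
    acceptor_window: str
    branch_window: str
    acceptor_start: int  # intron-relative
    branch_start: int  # intron-relative
    acceptor_cv: float
    branch_cv: float
    expect_called: bool
    expected_rank: int  # 0 when not expected to be called


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic, transcription order
    polya: PlantedPolyA | None
    acceptors: tuple[PlantedAcceptor, ...]


@dataclass(frozen=True)
class TruthManifest:
    seed: int
    genes: tuple[GeneTruth, ...]

    def gene(self, gene_id: str) -> GeneTruth:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            raw = json.load(fh)
        genes = []
        for g in raw["genes"]:
            polya = PlantedPolyA(**g["polya"]) if g["polya"] else None
            accs = tuple(PlantedAcceptor(**a) for a in g["acceptors"])
            genes.append(
                GeneTruth(
                    gene_id=g["gene_id"],
                    transcript_id=g["transcript_id"],
                    contig=g["contig"],
                    strand=g["strand"],
                    exons=tuple(tuple(iv) for iv in g["exons"]),
                    polya=polya,
                    acceptors=accs,
                )
            )
        return cls(seed=raw["seed"], genes=tuple(genes))


def sample_motif_with_cv(
    matrix: FrequencyMatrix,
    cv_band: tuple[float, float],
    rng: np.random.Generator,
    max_attempts: int = 200,
) -> str:
    """Draw a window whose consensus value lies inside ``cv_band``.

    Constructive randomized search: positions are filled left to right,
    restricting each choice to bases for which a completion inside the band
    remains achievable by the suffix min/max bounds, then verifying the
    realized CV. Required (invariant) bases are always respected. Raises
    when the band lies outside [0, 100] or no window is found.
    """
    lo, hi = cv_band
    if not (0.0 <= lo <= hi <= 100.0):
        raise ValueError(f"cv band {cv_band} must lie within [0, 100]")
    span = matrix.s_max - matrix.s_min
    s_lo = matrix.s_min + lo / 100.0 * span
    s_hi = matrix.s_min + hi / 100.0 * span
    required = dict(matrix.required_bases)
    n = matrix.width
    eff_min = [matrix.freqs[i][required[i]] if i in required else min(matrix.freqs[i].values())
               for i in range(n)]
    eff_max = [matrix.freqs[i][required[i]] if i in required else max(matrix.freqs[i].values())
               for i in range(n)]
    suf_min = [0.0] * (n + 1)
    suf_max = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suf_min[i] = suf_min[i + 1] + eff_min[i]
        suf_max[i] = suf_max[i + 1] + eff_max[i]
    tol = 1e-9
    for _ in range(max_attempts):
        s = 0.0
        bases: list[str] = []
        ok = True
        for i in range(n):
            if i in required:
                cand = [required[i]]
            else:
                row = matrix.freqs[i]
                cand = [
                    b
                    for b in BASES
                    if s + row[b] + suf_min[i + 1] <= s_hi + tol
                    and s + row[b] + suf_max[i + 1] >= s_lo - tol
                ]
            if not cand:
                ok = False
                break
            b = cand[int(rng.integers(0, len(cand)))]
            s += matrix.freqs[i][b]
            bases.append(b)
        if not ok:
            continue
        window = "".join(bases)
        cv = consensus_value(window, matrix)
        if lo - 1e-6 <= cv <= hi + 1e-6:
            return window
    raise ValueError(f"cv band {cv_band} unreachable for matrix {matrix.name!r}")


def _branch_shift_safe(b_win: str, matrix: FrequencyMatrix, threshold: float) -> bool:
    """True when no shifted self-overlap of ``b_win`` can reach ``threshold``.

    A window planted to stay below the branch threshold must not be
    rescuable through a shifted registration that reuses its high-frequency
    bases: positions outside the overlap are assumed scrub-mutable to C, the
    one base every scrub edit writes (C can create neither AATAAA nor AG and
    makes repeated edits idempotent).
    """
    rows = matrix.freqs
    n = matrix.width
    s_thr = matrix.s_min + threshold / 100.0 * (matrix.s_max - matrix.s_min)
    for k in range(-(n - 1), n):
        if k == 0:
            continue
        s = 0.0
        for p in range(n):
            src = k + p
            s += rows[p][b_win[src]] if 0 <= src < n else rows[p]["C"]
        if s >= s_thr - 1e-9:
            return False
    return True


def _expectations(
    o_offset: int, d: int, ordinal: int, intron_len: int, params: ScreenParams
) -> tuple[bool, bool]:
    stage1 = (
        o_offset <= params.max_tss_dist
        and ordinal in params.allowed_intron_ordinals
        and intron_len >= params.min_intron_len
        and d <= params.max_5ss_dist
    )
    return stage1, stage1 and d < params.refined_max_5ss_dist


def _plant_window(
    seq: list[str],
    abs_start: int,
    window: str,
    occupied: list[tuple[int, int]],
    gene_id: str,
    what: str,
) -> None:
    lo, hi = abs_start, abs_start + len(window)
    if lo < 0 or hi > len(seq):
        raise ValueError(f"{gene_id}: planted {what} falls outside the gene")
    for a, b in occupied:
        if lo < b and a < hi:
            raise ValueError(f"{gene_id}: planted {what} overlaps another planted element")
    seq[lo:hi] = list(window)
    occupied.append((lo, hi))


def _scrub_gene(
    seq: list[str],
    occupied: list[tuple[int, int]],
    host_bounds: tuple[int, int] | None,
    polya_abs: int | None,
    planted_acceptors: dict[int, bool],  # junction -> expect_called
    polya_dist: int,
    params: ScreenParams,
    branch_matrix: FrequencyMatrix,
    acceptor_matrix: FrequencyMatrix,
    rng: np.random.Generator,
    gene_id: str,
) -> None:
    def protected(pos: int) -> bool:
        return any(a <= pos < b for a, b in occupied)

    for _ in range(400):
        s = "".join(seq)
        offenders: list[tuple[int, int, str]] = []
        for off in find_motif(s, "AATAAA"):
            if polya_abs is not None and off == polya_abs:
                continue
            offenders.append((off, off + 6, "hexamer"))
        if host_bounds is not None:
            h_lo, h_hi = host_bounds
            iseq = s[h_lo:h_hi]
            for call in scan_cryptic_acceptors(
                iseq, polya_dist, params, branch_matrix, acceptor_matrix
            ):
                j = call.junction_offset
                if planted_acceptors.get(j, False):
                    continue  # planted and expected to be called
                a = h_lo + call.acceptor.start
                if j in planted_acceptors:
                    # planted acceptor meant to stay silent: a spurious
                    # above-threshold branch rescued it — kill that branch
                    b = h_lo + call.branch.start
                    offenders.append((b, b + branch_matrix.width, "branch"))
                else:
                    offenders.append((a, a + acceptor_matrix.width, "acceptor"))
        if not offenders:
            return
        for lo, hi, kind in offenders:
            free = [p for p in range(lo, hi) if not protected(p)]
            if kind == "acceptor":
                # kill the window's invariant AG; planted windows are sampled
                # AG-free internally, so one of its two bases is always free.
                g_pos = lo + acceptor_matrix.width - 2
                if not protected(g_pos):
                    seq[g_pos] = "C"
                elif not protected(g_pos - 1):
                    seq[g_pos - 1] = "C"
                else:
                    raise RuntimeError(
                        f"{gene_id}: spurious acceptor AG lies inside planted elements"
                    )
                continue
            if not free:
                raise RuntimeError(
                    f"{gene_id}: spurious {kind} overlaps planted elements and cannot be scrubbed"
                )
            if kind == "branch":
                # flatten every free position to C; idempotent, so repeated
                # passes over overlapping registrations cannot oscillate
                for p in free:
                    seq[p] = "C"
                continue
            # C can create neither AATAAA nor AG
            non_c = [p for p in free if seq[p] != "C"]
            p = non_c[int(rng.integers(0, len(non_c)))] if non_c else free[0]
            seq[p] = "C"
    raise RuntimeError(f"{gene_id}: background scrubbing did not converge")


def generate_toy_genome(
    config: SyntheticConfig,
    params: ScreenParams | None = None,
    branch_matrix: FrequencyMatrix | None = None,
    acceptor_matrix: FrequencyMatrix | None = None,
) -> tuple[Genome, list[GeneModel], TruthManifest]:
    """Generate a deterministic toy genome, annotation and truth manifest.

    One gene per contig; strands alternate when ``both_strands`` is set.
    Infeasible configurations (an intron too short for its planted elements)
    raise a :class:`ValueError` naming the gene.
    """
    params = params or ScreenParams()
    if branch_matrix is None or acceptor_matrix is None:
        bm, am = default_matrices()
        branch_matrix = branch_matrix or bm
        acceptor_matrix = acceptor_matrix or am

    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    truths: list[GeneTruth] = []
    base_arr = np.array(list("ACGT"))
    for i in range(config.n_genes):
        rng = np.random.default_rng([config.seed, i])
        gene_id = f"g{i + 1:03d}"
        contig = f"chr{i + 1}"
        strand = "+" if (i % 2 == 0 or not config.both_strands) else "-"
        n_ex = int(rng.integers(config.n_exons[0], config.n_exons[1] + 1))
        if n_ex < 2 and config.plant_polya:
            raise ValueError(f"{gene_id}: planting a poly(A) signal needs >= 2 exons")
        if config.plant_polya and config.polya_ordinal > n_ex - 1:
            raise ValueError(
                f"{gene_id}: polya_ordinal {config.polya_ordinal} exceeds intron count {n_ex - 1}"
            )
        exon_lens = [
            int(rng.integers(config.exon_len[0], config.exon_len[1] + 1)) for _ in range(n_ex)
        ]
        intron_lens = []
        for k in range(1, n_ex):
            lo, hi = (
                config.host_intron_len
                if k == config.polya_ordinal
                else config.other_intron_len
            )
            intron_lens.append(int(rng.integers(lo, hi + 1)))
        # oriented layout: exon1 intron1 exon2 ... tiling [0, L)
        bounds: list[tuple[str, int, int]] = []
        pos = 0
        for k in range(n_ex):
            bounds.append(("exon", pos, pos + exon_lens[k]))
            pos += exon_lens[k]
            if k < n_ex - 1:
                bounds.append(("intron", pos, pos + intron_lens[k]))
                pos += intron_lens[k]
        L = pos
        seq = list(
            base_arr[rng.choice(4, size=L, p=np.asarray(config.background))]
        )
        introns_oriented = [(a, b) for kind, a, b in bounds if kind == "intron"]
        occupied: list[tuple[int, int]] = []
        for a, b in introns_oriented:
            _plant_window(seq, a, "GT", occupied, gene_id, "donor GT")
            _plant_window(seq, b - 2, "AG", occupied, gene_id, "acceptor AG")

        polya_truth: PlantedPolyA | None = None
        acceptor_truths: list[PlantedAcceptor] = []
        host_bounds: tuple[int, int] | None = None
        polya_abs: int | None = None
        d = 0
        if config.plant_polya:
            h_lo, h_hi = introns_oriented[config.polya_ordinal - 1]
            host_bounds = (h_lo, h_hi)
            host_len = h_hi - h_lo
            d = int(rng.integers(config.polya_dist[0], config.polya_dist[1] + 1))
            if d + 6 + params.cleavage_offset > host_len - 2:
                raise ValueError(
                    f"{gene_id}: host intron ({host_len} nt) too short for a poly(A) "
                    f"signal at {d} nt plus the cleavage offset"
                )
            polya_abs = h_lo + d
            _plant_window(seq, polya_abs, "AATAAA", occupied, gene_id, "poly(A) hexamer")
            stage1, refined = _expectations(
                polya_abs, d, config.polya_ordinal, host_len, params
            )
            polya_truth = PlantedPolyA(
                intron_ordinal=config.polya_ordinal,
                dist_from_5ss=d,
                dist_from_tss=polya_abs,
                oriented_offset=polya_abs,
                hexamer="AATAAA",
                expect_stage1=stage1,
                expect_refined=refined,
            )
            spacing_lo, spacing_hi = params.branch_spacing
            for dist in config.cryptic_dists:
                j = d - dist  # intron-relative junction
                a_start = j - (acceptor_matrix.width - 1)
                if a_start < 2 or j > d:
                    raise ValueError(
                        f"{gene_id}: cryptic site at dist_to_polya {dist} does not fit "
                        "between the 5' splice site and the hexamer"
                    )
                gap = int(rng.integers(spacing_lo, spacing_hi + 1))
                b_start = j - gap - branch_matrix.width
                if b_start < 2:
                    raise ValueError(
                        f"{gene_id}: branch window for dist_to_polya {dist} "
                        "falls before the intron start"
                    )
                ag_at = acceptor_matrix.width - 3  # the invariant AG's A position
                for _ in range(500):
                    a_win = sample_motif_with_cv(acceptor_matrix, config.acceptor_cv_band, rng)
                    b_win = sample_motif_with_cv(branch_matrix, config.branch_cv_band, rng)
                    # windows must not smuggle in extra signals: no AATAAA, and
                    # no AG outside the invariant registration, so scrubbing can
                    # always reach every spurious acceptor's AG
                    if "AATAAA" in a_win or "AATAAA" in b_win or "AG" in b_win:
                        continue
                    if consensus_value(
                        b_win, branch_matrix
                    ) < params.branch_cv_threshold and not _branch_shift_safe(
                        b_win, branch_matrix, params.branch_cv_threshold
                    ):
                        continue
                    if any(
                        a_win[i : i + 2] == "AG"
                        for i in range(len(a_win) - 1)
                        if i != ag_at
                    ):
                        continue
                    break
                else:
                    raise RuntimeError(f"{gene_id}: could not sample clean motif windows")
                _plant_window(seq, h_lo + a_start, a_win, occupied, gene_id, "acceptor 14-mer")
                _plant_window(seq, h_lo + b_start, b_win, occupied, gene_id, "branch 7-mer")
                acv = consensus_value(a_win, acceptor_matrix)
                bcv = consensus_value(b_win, branch_matrix)
                acceptor_truths.append(
                    PlantedAcceptor(
                        junction_offset=j,
                        dist_to_polya=dist,
                        acceptor_window=a_win,
                        branch_window=b_win,
                        acceptor_start=a_start,
                        branch_start=b_start,
                        acceptor_cv=acv,
                        branch_cv=bcv,
                        expect_called=(
                            acv >= params.acceptor_cv_threshold
                            and bcv >= params.branch_cv_threshold
                        ),
                        expected_rank=0,
                    )
                )
            called = sorted(
                (a for a in acceptor_truths if a.expect_called),
                key=lambda a: a.dist_to_polya,
            )
            ranks = {a.junction_offset: r for r, a in enumerate(called, start=1)}
            acceptor_truths = [
                dataclasses.replace(a, expected_rank=ranks.get(a.junction_offset, 0))
                for a in acceptor_truths
            ]

        if config.scrub_spurious:
            _scrub_gene(
                seq,
                occupied,
                host_bounds,
                polya_abs,
                {a.junction_offset: a.expect_called for a in acceptor_truths},
                d,
                params,
                branch_matrix,
                acceptor_matrix,
                rng,
                gene_id,
            )

        oriented = "".join(seq)
        pad_l = "".join(base_arr[rng.choice(4, size=config.intergenic, p=np.asarray(config.background))])
        pad_r = "".join(base_arr[rng.choice(4, size=config.intergenic, p=np.asarray(config.background))])
        block = oriented if strand == "+" else reverse_complement(oriented)
        contigs[contig] = pad_l + block + pad_r
        off = len(pad_l)
        exon_oriented = [(a, b) for kind, a, b in bounds if kind == "exon"]
        if strand == "+":
            exons = tuple((off + a, off + b) for a, b in exon_oriented)
        else:
            exons = tuple((off + L - b, off + L - a) for a, b in exon_oriented)
        gene = GeneModel(
            gene_id=gene_id,
            contig=contig,
            strand=strand,
            exons=exons,
            transcript_id=f"{gene_id}.t1",
        )
        genes.append(gene)
        truths.append(
            GeneTruth(
                gene_id=gene_id,
                transcript_id=gene.transcript_id,
                contig=contig,
                strand=strand,
                exons=exons,
                polya=polya_truth,
                acceptors=tuple(acceptor_truths),
            )
        )
    return Genome(contigs), genes, TruthManifest(seed=config.seed, genes=tuple(truths))


def truth_to_hit(gene: GeneModel, truth: GeneTruth) -> PolyASignalHit:
    """Reconstruct the planted poly(A) hit of ``gene`` from the manifest."""
    if truth.polya is None:
        raise ValueError(f"{gene.gene_id}: no poly(A) signal planted")
    introns = enumerate_introns(gene)
    intron = introns[truth.polya.intron_ordinal - 1]
    return PolyASignalHit(
        intron=intron,
        hexamer=truth.polya.hexamer,
        signal_start=gene.oriented_to_genomic(truth.polya.oriented_offset),
        dist_from_tss=truth.polya.dist_from_tss,
        dist_from_5ss=truth.polya.dist_from_5ss,
        passes_stage1=truth.polya.expect_stage1,
        passes_refinement=truth.polya.expect_refined,
    )


def truth_to_acceptor(truth: GeneTruth, rank: int = 1) -> CrypticAcceptor:
    """Reconstruct the planted cryptic acceptor of the given expected rank."""
    for a in truth.acceptors:
        if a.expected_rank == rank:
            return CrypticAcceptor(
                branch=SpliceSiteScore(a.branch_window, a.branch_start, a.branch_cv),
                acceptor=SpliceSiteScore(a.acceptor_window, a.acceptor_start, a.acceptor_cv),
                junction_offset=a.junction_offset,
                dist_to_polya=a.dist_to_polya,
                rank=rank,
            )
    raise ValueError(f"no planted acceptor with expected rank {rank}")


def generate_transcript_pool(
    gene: GeneModel,
    genome: Genome,
    truth: GeneTruth,
    kinds: Sequence[str],
    params: ScreenParams | None = None,
) -> list[TranscriptModel]:
    """One transcript per requested kind, built from the planted ground truth."""
    params = params or ScreenParams()
    pool: list[TranscriptModel] = []
    for kind in kinds:
        if kind in ("mRNA", "pre-mRNA"):
            pool.append(
                build_transcript(gene, genome, kind, tail_len=params.polya_tail_len)
            )
            continue
        if truth.polya is None:
            raise ValueError(f"{gene.gene_id}: kind {kind} needs a planted poly(A) signal")
        hit = truth_to_hit(gene, truth)
        acceptor = None
        if kind == "CSPP":
            if not any(a.expect_called for a in truth.acceptors):
                raise ValueError(f"{gene.gene_id}: CSPP requested but no acceptor planted")
            acceptor = truth_to_acceptor(truth, rank=1)
        pool.append(
            build_transcript(
                gene,
                genome,
                kind,
                pa_hit=hit,
                acceptor=acceptor,
                cleavage_offset=params.cleavage_offset,
                tail_len=params.polya_tail_len,
            )
        )
    return pool


def write_fixture_dir(
    genome: Genome,
    genes: Iterable[GeneModel],
    manifest: TruthManifest,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write genome.fa, genes.gtf and truth.json under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "gtf": out / "genes.gtf",
        "truth": out / "truth.json",
    }
    genome.write_fasta(paths["fasta"])
    write_gtf(genes, paths["gtf"])
    manifest.to_json(paths["truth"])
    return paths
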