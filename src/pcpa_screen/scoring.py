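"""Consensus-value scoring of branch/acceptor motifs and cryptic 3'ss calling.

The consensus value (CV) of a window under a per-position base-frequency
matrix follows the Shapiro-Senapathy normalisation::

    CV = 100 * (S - S_min) / (S_max - S_min)

where ``S`` sums the frequency of the observed base at each position and
``S_min``/``S_max`` sum the per-position minimum/maximum frequencies. CV is
100 for the consensus window, 0 for the anti-consensus window, and lies in
[0, 100] for every window.

Stage 2 of the screen slides a 14-mer acceptor window (13 intronic positions
ending in the invariant AG, plus one exonic position) over the region between
an intron's 5' splice site and a passing poly(A) hexamer, keeping windows
whose CV clears the acceptor threshold and that are preceded, at a
branch-point-like spacing, by a 7-mer branch window clearing the branch
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

from .polya import ScreenParams

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

__all__ = [
    "FrequencyMatrix",
    "SpliceSiteScore",
    "CrypticAcceptor",
    "load_matrix",
    "default_matrices",
    "consensus_value",
    "scan_cryptic_acceptors",
    "rank_cryptic_sites",
]


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position base frequencies with optional fixed (required) bases."""

    name: str
    freqs: tuple[dict[str, float], ...]
    required_bases: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        for i, row in enumerate(self.freqs):
            if set(row) != set(BASES):
                raise ValueError(f"{self.name}: position {i} must map all of ACGT")
            if any(v < 0 for v in row.values()):
                raise ValueError(f"{self.name}: negative frequency at position {i}")
            if abs(sum(row.values()) - 1.0) > 1e-6:
                raise ValueError(f"{self.name}: frequencies at position {i} do not sum to 1")
        for pos, base in self.required_bases:
            if not 0 <= pos < self.width:
                raise ValueError(f"{self.name}: required position {pos} out of range")
            if base not in BASES:
                raise ValueError(f"{self.name}: required base must be one of ACGT")

    @property
    def width(self) -> int:
        return len(self.freqs)

    @property
    def s_min(self) -> float:
        return sum(min(row.values()) for row in self.freqs)

    @property
    def s_max(self) -> float:
        return sum(max(row.values()) for row in self.freqs)

    def consensus_window(self) -> str:
        """Window picking the max-frequency base at every position."""
        return "".join(max(BASES, key=lambda b: row[b]) for row in self.freqs)

    def anti_consensus_window(self) -> str:
        """Window picking the min-frequency base at every position."""
        return "".join(min(BASES, key=lambda b: row[b]) for row in self.freqs)

    def matches_required(self, window: str) -> bool:
        w = window.upper()
        return all(w[pos] == base for pos, base in self.required_bases)


def load_matrix(path: str | Path) -> FrequencyMatrix:
    """Read a plain-text frequency matrix.

    Format: optional ``#`` comment lines (``# name: ...`` and
    ``# required: POS=BASE ...`` are honoured), then a header naming the base
    order, then one row of tab-separated frequencies per position.
    """
    name = Path(path).stem
    required: list[tuple[int, str]] = []
    rows: list[dict[str, float]] = []
    order: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("name:"):
                    name = body.split(":", 1)[1].strip()
                elif body.lower().startswith("required:"):
                    for tok in body.split(":", 1)[1].split():
                        pos, base = tok.split("=")
                        required.append((int(pos), base.upper()))
                continue
            fields = line.split("\t")
            if order is None:
                order = [f.strip().upper() for f in fields]
                if sorted(order) != sorted(BASES):
                    raise ValueError(f"{path}: header must name the four bases")
                continue
            rows.append({b: float(v) for b, v in zip(order, fields)})
    if order is None or not rows:
        raise ValueError(f"{path}: no matrix rows found")
    return FrequencyMatrix(name=name, freqs=tuple(rows), required_bases=tuple(required))


def default_matrices() -> tuple[FrequencyMatrix, FrequencyMatrix]:
    """The shipped (branch 7-mer, acceptor 14-mer) frequency matrices."""
    data = resources.files("pcpa_screen").joinpath("data/matrices")
    with resources.as_file(data.joinpath("branch7.tsv")) as p:
        branch = load_matrix(p)
    with resources.as_file(data.joinpath("acceptor14.tsv")) as p:
        acceptor = load_matrix(p)
    return branch, acceptor


def consensus_value(window: str, matrix: FrequencyMatrix) -> float:
    """Shapiro-Senapathy consensus value of ``window`` under ``matrix``, in [0, 100]."""
    w = window.upper()
    if len(w) != matrix.width:
        raise ValueError(f"window length {len(w)} != matrix width {matrix.width}")
    if any(b not in BASES for b in w):
        raise ValueError(f"window {window!r} contains non-ACGT characters")
    s = sum(row[b] for row, b in zip(matrix.freqs, w))
    return 100.0 * (s - matrix.s_min) / (matrix.s_max - matrix.s_min)


@dataclass
class SpliceSiteScore:
    """A scored motif window at an intron-relative start offset."""

    window: str
    start: int
    cv: float


@dataclass
class CrypticAcceptor:
    """A called (branch 7-mer, acceptor 14-mer) pair inside a PCPA-prone intron.

    Offsets are intron-relative (0 = first intronic base, i.e. the 5' splice
    site); ``junction_offset`` is the exonic side of the cryptic junction —
    the first base retained downstream of the spliced-out region. The
    pipeline decorates calls with ``genomic_junction`` when gene context is
    available.
    """

    branch: SpliceSiteScore
    acceptor: SpliceSiteScore
    junction_offset: int
    dist_to_polya: int
    rank: int = 0
    genomic_junction: int | None = None

    def __post_init__(self) -> None:
        if self.dist_to_polya < 0:
            raise ValueError("dist_to_polya must be >= 0")


def scan_cryptic_acceptors(
    intron_seq: str,
    polya_offset: int,
    params: ScreenParams,
    branch_matrix: FrequencyMatrix,
    acceptor_matrix: FrequencyMatrix,
) -> list[CrypticAcceptor]:
    """Call cryptic acceptors between the 5' splice site and the poly(A) hexamer.

    ``intron_seq`` is the oriented intron sequence; ``polya_offset`` the
    hexamer's start offset within it. A call requires the acceptor window's
    fixed bases (the invariant AG), acceptor CV >= ``acceptor_cv_threshold``,
    and a branch window whose last base ends ``branch_spacing`` nt upstream
    of the junction with CV >= ``branch_cv_threshold``; each qualifying
    acceptor is paired with its best branch (highest CV, ties to the 5'-most
    window). Windows containing N are skipped. Results are sorted by
    position. A region shorter than the matrix width yields no calls.
    """
    seq = intron_seq.upper()
    if not 0 <= polya_offset <= len(seq):
        raise ValueError("polya_offset outside intron sequence")
    aw, bw = acceptor_matrix.width, branch_matrix.width
    spacing_lo, spacing_hi = params.branch_spacing
    # junction offset = start + (width - 1): one exonic position trails the AG
    junction_delta = aw - 1
    calls: list[CrypticAcceptor] = []
    for start in range(0, len(seq) - aw + 1):
        junction = start + junction_delta
        if junction > polya_offset:
            break
        window = seq[start : start + aw]
        if "N" in window:
            log.debug("skipping acceptor window with N at offset %d", start)
            continue
        if not acceptor_matrix.matches_required(window):
            continue
        acv = consensus_value(window, acceptor_matrix)
        if acv < params.acceptor_cv_threshold:
            continue
        best: SpliceSiteScore | None = None
        for gap in range(spacing_lo, spacing_hi + 1):
            b_end = junction - gap
            b_start = b_end - bw
            if b_start < 0:
                continue
            bwin = seq[b_start:b_end]
            if "N" in bwin:
                continue
            bcv = consensus_value(bwin, branch_matrix)
            if bcv < params.branch_cv_threshold:
                continue
            if best is None or bcv > best.cv or (bcv == best.cv and b_start < best.start):
                best = SpliceSiteScore(window=bwin, start=b_start, cv=bcv)
        if best is None:
            continue
        calls.append(
            CrypticAcceptor(
                branch=best,
                acceptor=SpliceSiteScore(window=window, start=start, cv=acv),
                junction_offset=junction,
                dist_to_polya=polya_offset - junction,
            )
        )
    calls.sort(key=lambda c: c.junction_offset)
    return calls


def rank_cryptic_sites(sites: Sequence[CrypticAcceptor]) -> list[CrypticAcceptor]:
    """Assign ranks: 1 = nearest the cleavage region (smallest dist_to_polya).

    Ties break toward the higher acceptor CV, then the 5'-most position.
    Returns the sites sorted by rank; input objects are updated in place.
    """
    ordered = sorted(
        sites, key=lambda c: (c.dist_to_polya, -c.acceptor.cv, c.junction_offset)
    )
    for i, site in enumerate(ordered, start=1):
        site.rank = i
    return ordered
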