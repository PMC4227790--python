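# Methods

## The screening model

The screen treats premature cleavage and polyadenylation (PCPA) as a purely
positional and motif-level phenomenon. A gene model is a stranded, ordered
list of exons; everything between consecutive exons is intron. All
"downstream" distances are measured along the direction of transcription
(gene-oriented coordinates with 0 at the TSS), never as raw genomic deltas,
so plus- and minus-strand genes are treated identically. Internally all
coordinates are 0-based half-open genomic; written outputs use each format's
native convention (BED 0-based half-open, GTF 1-based closed).

Stage 1 keeps an intronic poly(A) hexamer when (i) its first base lies
within 5 000 nt of the TSS along the transcript path, (ii) it sits in intron
1 or 2 and that intron is at least 1 000 nt, and (iii) its first base lies
within 1 000 nt of the intron's 5' splice site. The first two bounds are
inclusive ("within"); the refinement that gates the splice-site scan is
strict (< 500 nt from the 5' splice site) — the two phrasings are
deliberately different and both are honored exactly. Distances always refer
to the hexamer's first base; a hexamer straddling an exon/intron boundary is
not intronic. The hexamer set defaults to {AATAAA} alone — the canonical
signal, and the one destroyed by the standard aataaa→ggatcc mutagenesis —
with variants (ATTAAA, …) available through `ScreenParams.signal_set`.

When a transcript has several refined signals, the gene is summarized by the
hit with the smallest distance from the TSS (promoter-proximality being the
organizing principle of the screen), and the cryptic-site scan runs in that
hit's intron. Annotations with several transcripts per gene are screened per
transcript; funnel counts deduplicate per gene.

## Consensus-value scoring

Splice-signal strength uses the Shapiro–Senapathy normalisation
`CV = 100·(S − S_min)/(S_max − S_min)` with `S` the sum of observed
per-position base frequencies. CV is 100 at the per-position argmax window,
0 at the argmin window, and lies in [0, 100] always; it is monotone in the
frequency of any observed base and invariant under joint position
permutation — all of which the test suite asserts.

Two matrices ship as plain-text data files (`data/matrices/*.tsv`, one row
per position, tab-separated frequencies, header naming the base order,
`# required:` comment for invariant bases):

* **acceptor14** — a 14-position 3' splice-site window laid out as 13
  intronic positions ending in the invariant AG plus one exonic position;
  the cryptic junction is the boundary after the AG.
* **branch7** — a 7-position branch-site window with the branch adenosine at
  position 6 (strongly preferred, not invariant).

The frequencies are compiled from the standard published human consensus
compositions for these elements. The exact table a given web scorer uses is
a configuration detail, which is why matrices are data files: any
alternative table in the same format drops in without code changes. The
operating thresholds default to CV ≥ 39.41 (acceptor) and ≥ 50.16 (branch),
treated as raw consensus values. Polypyrimidine-tract content is captured
only through the acceptor matrix; there is no separate PPT rule.

A cryptic acceptor call requires the invariant AG, an acceptor CV at
threshold, and a branch window whose last base ends 18–44 nt upstream of the
junction (the canonical metazoan branch-point spacing; configurable). Each
qualifying acceptor is paired with its best branch (highest CV, ties to the
5'-most window). Calls are ranked by distance to the poly(A) hexamer —
rank 1 nearest the cleavage region — with ties broken by higher acceptor CV,
then 5'-most position. Windows containing N are skipped (N never matches
anything, a conservative choice).

## Transcript models

Five isoform kinds are assembled from genomic segments joined 5'→3':

* **mRNA** — spliced exons;
* **pre-mRNA** — the unspliced span, no poly(A) tail;
* **PCPA** — upstream exons plus the host-intron prefix ending at the
  cleavage site: the composite terminal exon. The cleavage site is placed
  `cleavage_offset` nt after the hexamer end (default 15 nt, the middle of
  the canonical 10–30 nt window; configurable because the true site is
  gene-specific);
* **CSPP** — the PCPA transcript with the interval from the authentic 5'
  splice site to the cryptic junction spliced out, giving the length
  identity `len(CSPP) = len(PCPA) − junction_offset`. CSPP construction
  requires an intact donor GT: destroying the 5' splice site blocks CSPP
  while leaving PCPA available, matching the mutant-minigene logic;
* **read-through** — upstream exons plus intron sequence continuing past the
  cleavage site (default 200 nt beyond), not polyadenylated at the intronic
  site.

Polyadenylated kinds carry a modelled 30-A tail so oligo-dT-primed reverse
transcription can be simulated. In-silico mutagenesis uses minimal
substitutions: AATAAA→GGATCC for the poly(A) signal, GT→GA for the donor,
AG→AT for a cryptic acceptor, each returned with an edit record. Reporter
constructs (exon1 / intron / 3' exon / vector poly(A)) accept a
cis-element — the fragment from 157 nt upstream to 51 nt downstream of a
poly(A) hexamer — inserted into the intron or the 3' exon, optionally with
every vector AATAAA neutralized to GGATCC.

## 3' RACE simulation

Reverse transcription tags every polyadenylated transcript with an adaptor
behind the tail (the adaptor sequence is an opaque configurable tag). The
first PCR round amplifies any tagged cDNA containing the forward primer;
the nested round uses a chimeric primer of 12 Ts plus an anchor
reverse-complementary to the bases immediately upstream of the cleavage
site, so it primes only transcripts ending at that exact terminus. Lengths
are measured between primer 5' ends. Non-polyadenylated templates
(read-through, pre-mRNA) are never amplified. Amplicons are classified by
junction content: containing the unspliced 5'ss boundary → PCPA; the
exon–cryptic-junction chimera → CSPP; the authentic exon–exon junction →
mRNA; otherwise ambiguous. Matching is exact; PCR cycle numbers and
annealing temperatures are metadata, not simulated kinetics — cycle counts
control detection sensitivity at the bench, which a deterministic simulator
cannot meaningfully reproduce.

## Synthetic genomes

The generator emulates exactly the structure the screen assumes: multi-exon
genes on alternating strands (one per contig), canonical GT/AG intron
boundaries, uniform background composition by default, a planted AATAAA at a
controlled distance from the 5' splice site of a chosen intron, and
branch/acceptor pairs sampled inside requested CV bands at controlled
distances from the hexamer. Motif sampling is a constructive randomized
search: positions are filled left to right among bases that keep the target
CV band reachable by suffix min/max bounds, then verified — exact for point
bands like [100, 100] and fast for narrow near-threshold bands.

With `scrub_spurious` on (the default), the transcribed gene sequence is
rejection-edited until it contains no unplanted AATAAA and the scanned
region of the host intron yields no unplanted acceptor call. Every scrub
edit writes the base C: C can create neither AATAAA nor an AG, and repeated
passes are idempotent, so edits across overlapping window registrations
cannot oscillate. Spurious acceptor calls lose their invariant AG; a
deliberately sub-threshold planted site that a spurious background branch
would rescue loses that branch (its background positions flattened to C).
Planted windows are themselves sampled free of internal AATAAA/AG, and
sub-threshold branch windows are additionally required to be *shift-safe* —
no shifted registration reusing their bases can clear the branch threshold
once surrounding background is C. The truth manifest records every planted
element with exact coordinates, the stage flags its distances imply, and the
expected cryptic-site ranks; recovery tests assert exact set equality
against it.

What the generator does not emulate: realistic base composition, repeats,
codon structure, real splice-site strength at the authentic junctions
beyond the GT/AG dinucleotides, multiple poly(A) signals per intron, or
read-level noise. Passing recovery tests therefore demonstrates correctness
of the screen's logic and arithmetic, not calibration of the CV thresholds
on real genomes — the genome-wide funnel counts depend on the annotation
version and are out of scope by design.

## Numerical and degenerate-input choices

* Filters are pure flag-setters; order is preserved, and refinement passes
  imply stage-1 passes structurally.
* Ranking and branch selection are fully deterministic, with documented tie
  breaks (distance, then CV, then 5'-most).
* Matrix validation requires per-position frequencies to sum to 1 ± 1e-6;
  CV comparisons in sampling use 1e-6 slack so band endpoints are honest.
* Empty inputs yield empty outputs with zeroed reports; a region shorter
  than a matrix width yields no calls; a motif longer than its target yields
  no hits. Missing contigs and infeasible planting configurations are hard
  errors naming the offending gene.
* Fixture generation derives one child RNG per gene from (seed, index), so
  output is byte-identical across runs and genes are independent of
  `n_genes`.

## Problem sizes

The shipped tests and the acceptance script use 10-gene genomes of roughly
40 kb (100 genes across 10 seeds for oracle equivalence, 20 seeds for
recovery, 5 seeds × 4 bands for threshold sharpness, 10⁴ random windows for
the CV contract). These sizes give exact set-level assertions with
comfortable margins while keeping the whole suite in the seconds range; the
screen itself is linear in genome length and runs unchanged on larger
inputs.
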