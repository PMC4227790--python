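# pcpa-screen

A toolkit for studying **premature cleavage and polyadenylation (PCPA)** in
promoter-proximal introns. Many human genes carry an AATAAA poly(A) signal in
their first or second intron, close enough to the promoter that 3'-end
processing there truncates the transcript into a *composite terminal exon* —
a terminal exon made of upstream exon plus retained intron sequence. Some of
these truncated transcripts are subsequently spliced at a *cryptic* intronic
3' splice site, yielding a cryptically spliced product of PCPA (CSPP). This
package implements the in-silico side of that biology for computational
biologists and RNA labs:

* a genome screen for promoter-proximal intronic poly(A) signals,
* consensus-value scoring of candidate branch/acceptor motifs upstream of
  those signals and ranking of cryptic 3' splice sites,
* construction of the isoforms the assay discriminates (mRNA, PCPA, CSPP,
  read-through) and of reporter minigenes with in-silico mutagenesis,
* a deterministic 3' RACE / nested PCR simulator, and
* a seeded synthetic-genome generator with a ground-truth manifest so the
  entire pipeline is testable without any downloads.

## The screen

A poly(A) hexamer (default AATAAA) in an intron passes **stage 1** when, with
all distances measured along the direction of transcription:

1. it lies within 5 kb downstream of the transcription start site,
2. it sits in the first or second intron, and that intron is ≥ 1 kb, and
3. it lies within 1 kb downstream of the intron's 5' splice site.

A **refinement** keeps signals strictly closer than 500 bp to the 5' splice
site. In refined introns the region between the 5' splice site and the
hexamer is scanned for a cryptic 3' splice site: a 14-mer acceptor window
(13 intronic bases ending in the invariant AG, plus one exonic base)
preceded at branch-point spacing (18–44 nt) by a 7-mer branch window. Both
windows are scored with the Shapiro–Senapathy consensus value

```
CV = 100 · (S − S_min) / (S_max − S_min),   S = Σ_i f_i(base_i)
```

where `f_i` are per-position base frequencies; calls require CV ≥ 39.41
(acceptor) and ≥ 50.16 (branch). Called sites are ranked by proximity to the
poly(A) signal; masking the rank-1 AG in silico re-ranks the next site, the
cascade seen in minigene mutagenesis experiments.

## Worked example

```sh
pcpa-screen make-fixtures --seed 3 --out-dir fx
pcpa-screen run --fasta fx/genome.fa --annotation fx/genes.gtf --out out
```

The second command prints the funnel report (here for the 10-gene synthetic
default, where every gene carries one planted passing signal and two planted
cryptic sites):

```json
{
 "fraction_genes_with_proximal_intronic_pA": 1.0,
 "n_genes_acceptor_positive": 10,
 "n_genes_refined": 10,
 "n_genes_stage1": 10,
 "n_genes_total": 10,
 "n_introns_stage1": 10
}
```

`n_introns_stage1` counts introns with a stage-1 signal; the gene-level
counts deduplicate (a gene counts once however many passing introns it has);
the fraction applies the TSS-distance criterion alone, a gene-level summary
of how widespread proximal intronic signals are before the intron filters.
`out/` contains `candidates.tsv` (one row per transcript with the best hit,
its three distances and the ranked cryptic acceptors — it round-trips via
`pcpa_screen.read_candidates`), `signals.bed`, `acceptors.bed`, predicted
PCPA/CSPP transcripts as `transcripts.fa`/`transcripts.gtf`, and
`funnel.json`.

From Python, the same screen plus the downstream assay:

```python
from pcpa_screen import Primer, run_screen, simulate_3race, design_chimeric_primer
from pcpa_screen.synthetic import (SyntheticConfig, generate_toy_genome,
                                   generate_transcript_pool)

genome, genes, truth = generate_toy_genome(SyntheticConfig(seed=3))
records, report = run_screen(genome, genes)
pool = generate_transcript_pool(genes[0], genome, truth.genes[0],
                                ["mRNA", "PCPA", "CSPP", "read-through"])
fwd = Primer("fwd", genome.gene_seq(genes[0])[20:40])
nested = design_chimeric_primer([t for t in pool if t.kind == "PCPA"][0])
for amp in simulate_3race(pool, fwd, nested_rev=nested):
    print(amp.template_kind, amp.round, amp.length)
```

which prints one first-round amplicon per polyadenylated template and nested
amplicons only from the templates sharing the PCPA cleavage terminus
(PCPA and CSPP, never read-through) — the discrimination logic of the
chimeric 12-T primer anchored immediately upstream of the cleavage site.

## Layout

| module | contents |
| --- | --- |
| `pcpa_screen.seqio` | FASTA/GTF/BED12 loading, strand-aware `Genome`/`GeneModel`, reverse complement, motif search, primer checks |
| `pcpa_screen.polya` | intron enumeration, poly(A) hit discovery, positional filters, `ScreenParams` |
| `pcpa_screen.scoring` | frequency matrices, consensus value, cryptic acceptor scan and ranking |
| `pcpa_screen.transcripts` | isoform assembly, cis-element extraction, reporter constructs, in-silico mutagenesis |
| `pcpa_screen.race` | chimeric primer design, 3' RACE simulation, amplicon classification |
| `pcpa_screen.synthetic` | seeded toy genomes with planted elements and a truth manifest |
| `pcpa_screen.pipeline` | the full funnel, candidate records, exports |

See `docs/methods.md` for the model, parameter and design notes.
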