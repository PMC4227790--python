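"""Naive single-file reference implementation of the whole screen.

Used as an independent oracle in tests: plain nested loops, manual reverse
complementation and window arithmetic, no imports from the package under
test. Everything is recomputed from scratch from the raw contig strings and
exon lists.
"""

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_rc(s):
    out = []
    for ch in reversed(s.upper()):
        out.append(COMP[ch])
    return "".join(out)


def naive_cv(window, rows):
    s = 0.0
    smin = 0.0
    smax = 0.0
    for i, row in enumerate(rows):
        s += row[window[i]]
        lo = min(row.values())
        hi = max(row.values())
        smin += lo
        smax += hi
    return 100.0 * (s - smin) / (smax - smin)


def naive_gene_layout(contig_seq, exons, strand):
    """Oriented sequence plus oriented exon intervals in transcription order."""
    lo = min(s for s, _ in exons)
    hi = max(e for _, e in exons)
    block = contig_seq[lo:hi].upper()
    oriented = block if strand == "+" else naive_rc(block)
    o_exons = []
    for s, e in exons:  # already in transcription order
        if strand == "+":
            o_exons.append((s - lo, e - lo))
        else:
            o_exons.append((hi - e, hi - s))
    return oriented, o_exons


def naive_screen(contigs, genes, params, branch_rows, acceptor_rows,
                 acceptor_required, spacing):
    """Screen every gene; returns per-transcript hit and acceptor tuples.

    genes: list of dicts with gene_id, transcript_id, contig, strand,
    exons (transcription order, genomic half-open).
    params: dict with signal_set, max_tss_dist, allowed_intron_ordinals,
    min_intron_len, max_5ss_dist, refined_max_5ss_dist,
    acceptor_cv_threshold, branch_cv_threshold.
    """
    out = {}
    for gene in genes:
        oriented, o_exons = naive_gene_layout(
            contigs[gene["contig"]], gene["exons"], gene["strand"]
        )
        introns = []
        for i in range(len(o_exons) - 1):
            introns.append((i + 1, o_exons[i][1], o_exons[i + 1][0]))
        hits = []
        for ordinal, a, b in introns:
            iseq = oriented[a:b]
            for hexamer in sorted(params["signal_set"]):
                w = len(hexamer)
                for i in range(len(iseq) - w + 1):
                    if iseq[i : i + w] != hexamer:
                        continue
                    dist_5ss = i
                    dist_tss = a + i
                    stage1 = (
                        dist_tss <= params["max_tss_dist"]
                        and ordinal in params["allowed_intron_ordinals"]
                        and (b - a) >= params["min_intron_len"]
                        and dist_5ss <= params["max_5ss_dist"]
                    )
                    refined = stage1 and dist_5ss < params["refined_max_5ss_dist"]
                    hits.append(
                        (ordinal, dist_tss, dist_5ss, hexamer, stage1, refined)
                    )
        hits.sort(key=lambda h: (h[0], h[2], h[3]))
        refined_hits = [h for h in hits if h[5]]
        acceptors = []
        if refined_hits:
            best = min(refined_hits, key=lambda h: (h[1], h[0], h[2]))
            ordinal, _, d, _, _, _ = best
            a, b = [(x, y) for o, x, y in introns if o == ordinal][0]
            iseq = oriented[a:b]
            aw = len(acceptor_rows)
            bw = len(branch_rows)
            raw = []
            for start in range(0, len(iseq) - aw + 1):
                junction = start + aw - 1
                if junction > d:
                    continue
                window = iseq[start : start + aw]
                if "N" in window:
                    continue
                if any(window[p] != base for p, base in acceptor_required):
                    continue
                acv = naive_cv(window, acceptor_rows)
                if acv < params["acceptor_cv_threshold"]:
                    continue
                best_branch = None
                for gap in range(spacing[0], spacing[1] + 1):
                    b_end = junction - gap
                    b_start = b_end - bw
                    if b_start < 0:
                        continue
                    bwin = iseq[b_start:b_end]
                    if "N" in bwin:
                        continue
                    bcv = naive_cv(bwin, branch_rows)
                    if bcv < params["branch_cv_threshold"]:
                        continue
                    if (
                        best_branch is None
                        or bcv > best_branch[2]
                        or (bcv == best_branch[2] and b_start < best_branch[0])
                    ):
                        best_branch = (b_start, bwin, bcv)
                if best_branch is None:
                    continue
                raw.append(
                    (junction, d - junction, start, window, acv) + best_branch
                )
            ranked = sorted(raw, key=lambda r: (r[1], -r[4], r[0]))
            for rank, r in enumerate(ranked, start=1):
                acceptors.append(r + (rank,))
        out[gene["transcript_id"]] = {"hits": hits, "acceptors": acceptors}
    return out
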