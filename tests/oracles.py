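"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: FASTQ parsing goes
through Bio.SeqIO, anchor search is an explicit positional scan, and interval
queries are quadratic loops.
"""
import gzip
from pathlib import Path

from Bio import SeqIO

ANCHOR = "GTTTAAGAGCTATGCTGGAA"


def naive_count(fastq_by_sample, library):
    """Per-read substring scan quantification.

    Returns (counts, audit) as plain dicts: counts[sample][guide_id],
    audit[sample] = dict with total_reads/anchored/matched/ambiguous/unmatched.
    """
    keys = {g.guide_id: g.spacer[-15:] for g in library}
    counts, audit = {}, {}
    for sample, paths in fastq_by_sample.items():
        if isinstance(paths, (str, Path)):
            paths = [paths]
        c = {g.guide_id: 0 for g in library}
        a = dict.fromkeys(["total_reads", "anchored", "matched", "ambiguous", "unmatched"], 0)
        for path in paths:
            path = Path(path)
            opener = gzip.open if path.suffix == ".gz" else open
            with opener(path, "rt") as fh:
                for rec in SeqIO.parse(fh, "fastq"):
                    seq = str(rec.seq)
                    a["total_reads"] += 1
                    # explicit positional scan for the first anchor occurrence
                    pos = next(
                        (i for i in range(len(seq) - len(ANCHOR) + 1)
                         if seq[i : i + len(ANCHOR)] == ANCHOR),
                        None,
                    )
                    if pos is None or pos < 15:
                        continue
                    a["anchored"] += 1
                    key = seq[pos - 15 : pos]
                    hits = [gid for gid, k in keys.items() if k == key]
                    if len(hits) == 1:
                        a["matched"] += 1
                        c[hits[0]] += 1
                    elif len(hits) > 1:
                        a["ambiguous"] += 1
                    else:
                        a["unmatched"] += 1
        counts[sample], audit[sample] = c, a
    return counts, audit


def brute_nearest_tss(mid, tss_list):
    """tss_list: (pos, name) pairs. Returns (name, distance)."""
    best = min(tss_list, key=lambda t: abs(t[0] - mid))
    return best[1], abs(best[0] - mid)


def brute_overlap(item, peaks):
    chrom, s, e = item
    return any(pc == chrom and ps < e and s < pe for pc, ps, pe in peaks)


def brute_nearest_distance(chrom, pos, peaks):
    ds = [
        max(ps - pos, pos - (pe - 1), 0)
        for pc, ps, pe in peaks
        if pc == chrom
    ]
    return min(ds) if ds else None


def brute_domain_overlap(a, b):
    """Venn counts via explicit component expansion over (chrom,start,end)."""
    def inter(x, y):
        return x[0] == y[0] and x[1] < y[2] and y[1] < x[2]

    nodes = [("a", i) for i in range(len(a))] + [("b", j) for j in range(len(b))]
    seen = set()
    only_a = only_b = shared = 0
    a_hit = [any(inter(x, y) for y in b) for x in a]
    b_hit = [any(inter(y, x) for x in a) for y in b]
    only_a = a_hit.count(False)
    only_b = b_hit.count(False)
    for start in nodes:
        if start in seen:
            continue
        comp, frontier = {start}, [start]
        while frontier:
            side, i = frontier.pop()
            me = a[i] if side == "a" else b[i]
            others = b if side == "a" else a
            oside = "b" if side == "a" else "a"
            for j, o in enumerate(others):
                if inter(me, o) and (oside, j) not in comp:
                    comp.add((oside, j))
                    frontier.append((oside, j))
        seen |= comp
        sides = {s for s, _ in comp}
        if sides == {"a", "b"}:
            shared += 1
    return {"only_a": only_a, "shared": shared, "only_b": only_b}
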