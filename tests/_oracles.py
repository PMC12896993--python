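"""Brute-force reference implementations used only by tests.

These deliberately re-derive results from first principles (explicit interval
expansion, exhaustive scans, full enumeration) so they stay independent of
the library code paths they check.
"""
from __future__ import annotations

from itertools import permutations

import numpy as np

_PRECEDENCE = [
    "exonic",
    "splicing",
    "UTR5",
    "UTR3",
    "intronic",
    "ncRNA",
    "upstream",
    "downstream",
    "intergenic",
]


def expand_intervals(genes, flank=1000, splice_window=2):
    """Explicit (chrom, start, end, category, gene_id) list for every gene."""
    out = []
    for g in genes:
        if g.strand == "+":
            out.append((g.chrom, g.start - flank, g.start - 1, "upstream", g.gene_id))
            out.append((g.chrom, g.end + 1, g.end + flank, "downstream", g.gene_id))
        else:
            out.append((g.chrom, g.start - flank, g.start - 1, "downstream", g.gene_id))
            out.append((g.chrom, g.end + 1, g.end + flank, "upstream", g.gene_id))
        if g.biotype == "ncRNA":
            out.append((g.chrom, g.start, g.end, "ncRNA", g.gene_id))
            continue
        for f in g.features:
            if f.kind == "exon_cds":
                out.append((g.chrom, f.start, f.end, "exonic", g.gene_id))
            elif f.kind in ("UTR5", "UTR3"):
                out.append((g.chrom, f.start, f.end, f.kind, g.gene_id))
            else:  # intron: splice-adjacent edges then the interior
                w = splice_window
                left_end = min(f.start + w - 1, f.end)
                right_start = max(f.end - w + 1, f.start)
                out.append((g.chrom, f.start, left_end, "splicing", g.gene_id))
                out.append((g.chrom, right_start, f.end, "splicing", g.gene_id))
                if f.start + w <= f.end - w:
                    out.append((g.chrom, f.start + w, f.end - w, "intronic", g.gene_id))
    return out


def brute_force_classify(chrom, pos, genes, flank=1000, splice_window=2):
    """Scan every expanded interval; resolve by precedence then gene_id."""
    hits = [
        (cat, gid)
        for (c, s, e, cat, gid) in expand_intervals(genes, flank, splice_window)
        if c == chrom and s <= pos <= e
    ]
    if not hits:
        return "intergenic", None
    return min(hits, key=lambda h: (_PRECEDENCE.index(h[0]), h[1]))


def any_pair_overlaps(genes) -> bool:
    """All-pairs interval overlap test, O(n^2)."""
    gl = list(genes)
    for i in range(len(gl)):
        for j in range(i + 1, len(gl)):
            a, b = gl[i], gl[j]
            if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
                return True
    return False


def brute_force_ks_d(a, b) -> float:
    """sup over all observed points of |ECDF_a - ECDF_b|."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for t in np.concatenate([a, b]):
        d = abs((a <= t).mean() - (b <= t).mean())
        best = max(best, d)
    return best


def _rank(v):
    """Mid-ranks, derived by explicit tie-group averaging."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def brute_force_spearman(x, y):
    """(rho, two-sided exact permutation p) by literal enumeration."""
    rx, ry = _rank(x), _rank(y)

    def corr(u, v):
        u = u - u.mean()
        v = v - v.mean()
        return float((u * v).sum() / np.sqrt((u * u).sum() * (v * v).sum()))

    rho = corr(rx, ry)
    n = len(rx)
    hits = total = 0
    for perm in permutations(range(n)):
        total += 1
        if abs(corr(rx, ry[list(perm)])) >= abs(rho) - 1e-12:
            hits += 1
    return rho, hits / total
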