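"""Naive, independent reference implementations used as test oracles.

Everything here favours directness over speed: literal character
counting, per-base scans, exhaustive enumeration.
"""

from __future__ import annotations

import math
import re


def fisher_two_tail(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    denom = math.comb(n, c1)

    def pmf(k):
        return math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom

    p_obs = pmf(a)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, total)


def bh_adjust(pvals):
    """Benjamini-Hochberg by literal sort-and-scan."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


def _segment_ok(seq: str) -> bool:
    L = len(seq)
    if L < 201 or "N" in seq:
        return False
    c, g = seq.count("C"), seq.count("G")
    if (c + g) / L <= 0.5:
        return False
    exp = c * g / L
    return exp > 0 and seq.count("CG") / exp > 0.6


def cgi_calls(seq: str):
    """Island intervals by naive window scan, merge and exhaustive trim."""
    wins = []
    for i in range(len(seq) - 199):
        w = seq[i:i + 200]
        if "N" in w:
            continue
        c, g = w.count("C"), w.count("G")
        if (c + g) / 200 <= 0.5:
            continue
        exp = c * g / 200
        if exp > 0 and w.count("CG") / exp > 0.6:
            wins.append((i, i + 200))
    merged = []
    for s, e in wins:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    out = []
    for s, e in merged:
        found = None
        for L in range(e - s, 200, -1):
            for st in range(s, e - L + 1):
                if _segment_ok(seq[st:st + L]):
                    found = (st, st + L)
                    break
            if found:
                break
        if found:
            out.append(found)
    return out


def msp1_fragments(seq: str, lo: int, hi: int):
    """Size-selected MspI fragments via regex cut-site scan."""
    cuts = [m.start() + 1 for m in re.finditer("CCGG", seq)]
    return [
        (s, e) for s, e in zip(cuts[:-1], cuts[1:]) if lo <= e - s <= hi
    ]


def genic_label(pos0: int, genes, flank: int = 5000) -> str:
    """Five-way label for one 0-based position by per-gene scan."""
    for pick, test in (
        ("exon", lambda g: any(s <= pos0 < e for s, e in g.exons)),
        ("intron", lambda g: g.start <= pos0 < g.end),
        ("upstream", lambda g: (
            g.start - flank <= pos0 < g.start if g.strand == "+"
            else g.end <= pos0 < g.end + flank)),
        ("downstream", lambda g: (
            g.end <= pos0 < g.end + flank if g.strand == "+"
            else g.start - flank <= pos0 < g.start)),
    ):
        if any(test(g) for g in genes):
            return pick
    return "intergenic"


def cgi_label(pos0: int, annotation, chrom: str) -> str:
    for name, table in (("island", annotation.islands),
                        ("shore", annotation.shores),
                        ("shelf", annotation.shelves)):
        for s, e in table.get(chrom, []):
            if s <= pos0 < e:
                return name
    return "open_sea"


def pearson_r(x, y) -> float:
    """Textbook sample correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
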