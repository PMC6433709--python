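"""CpG-island detection and shore/shelf derivation.

An island is a maximal segment longer than 200 bp with GC fraction
strictly above 0.5 and an observed/expected CpG ratio strictly above
0.6, where expected CpG = (#C x #G) / length.  Shores are the 2 kb
flanks outside islands; shelves the next 2 kb beyond the shores, with
precedence island > shore > shelf when neighbouring islands collide.

Detection scans 200-bp windows stepped by 1 bp, merges qualifying
windows, and replaces each merged candidate (padded by one window on
each side) with its longest sub-segment that still meets all three
criteria.  Runs of N break candidates; N bases count toward segment
length but not composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import clip, merge, subtract

MIN_LENGTH = 201  # ">200 bp" read strictly
MIN_GC = 0.5
MIN_OE = 0.6
WINDOW = 200
FLANK = 2000


class SequenceError(ValueError):
    """Raised for sequences outside the ACGTN alphabet."""


@dataclass
class CgiRecord:
    chrom: str
    start: int  # 0-based half-open
    end: int
    gc_fraction: float
    obs_cpg: int
    exp_cpg: float
    oe_ratio: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CgiAnnotation:
    """Islands with derived shore/shelf intervals, per chromosome."""

    islands: dict = field(default_factory=dict)   # chrom -> [(s, e)]
    shores: dict = field(default_factory=dict)
    shelves: dict = field(default_factory=dict)


def _encode(segment: str) -> np.ndarray:
    arr = np.frombuffer(segment.upper().encode("ascii"), dtype=np.uint8)
    bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if bad.any():
        pos = int(np.nonzero(bad)[0][0])
        raise SequenceError(
            f"non-ACGTN symbol {segment[pos]!r} at offset {pos}"
        )
    return arr


def score_segment(segment: str):
    """Return (gc_fraction, obs_cpg, exp_cpg, oe_ratio) for one segment.

    N bases count toward the length but not toward C/G/CpG counts; the
    O/E ratio is defined as 0 when the expected CpG count is 0.
    """
    if not segment:
        raise SequenceError("empty segment")
    arr = _encode(segment)
    n = arr.size
    n_c = int((arr == ord("C")).sum())
    n_g = int((arr == ord("G")).sum())
    obs = int(((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).sum())
    gc = (n_c + n_g) / n
    exp = n_c * n_g / n
    oe = obs / exp if exp > 0 else 0.0
    return gc, obs, exp, oe


def _window_stats(arr: np.ndarray, w: int):
    """Per-start C, G, CpG and N counts for every length-w window."""
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_n = (arr == ord("N")).astype(np.int64)
    is_cg = np.zeros_like(is_c)
    is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))

    def windowed(x, width):
        c = np.concatenate([[0], np.cumsum(x)])
        return c[width:] - c[:-width]

    # CpG dinucleotides fully inside the window: starts 0..w-2 relative
    return (
        windowed(is_c, w),
        windowed(is_g, w),
        windowed(is_cg[: arr.size - 1], w - 1) if arr.size >= w else
        np.zeros(0, dtype=np.int64),
        windowed(is_n, w),
    )


def _qualifies(n_c, n_g, obs, length):
    if length < MIN_LENGTH:
        return False
    gc = (n_c + n_g) / length
    exp = n_c * n_g / length
    if gc <= MIN_GC or exp <= 0:
        return False
    return obs / exp > MIN_OE


def _longest_qualifying(arr: np.ndarray, lo: int, hi: int):
    """Longest (leftmost on ties) sub-segment of arr[lo:hi] meeting all
    criteria, or None.  Exhaustive over (start, length)."""
    sub = arr[lo:hi]
    n = sub.size
    if n < MIN_LENGTH:
        return None
    is_c = np.concatenate([[0], np.cumsum(sub == ord("C"))])
    is_g = np.concatenate([[0], np.cumsum(sub == ord("G"))])
    cg = np.zeros(n, dtype=np.int64)
    cg[:-1] = (sub[:-1] == ord("C")) & (sub[1:] == ord("G"))
    is_cg = np.concatenate([[0], np.cumsum(cg)])
    is_n = np.concatenate([[0], np.cumsum(sub == ord("N"))])
    for length in range(n, MIN_LENGTH - 1, -1):
        starts = np.arange(0, n - length + 1)
        ends = starts + length
        n_c = is_c[ends] - is_c[starts]
        n_g = is_g[ends] - is_g[starts]
        obs = is_cg[ends - 1] - is_cg[starts]
        n_n = is_n[ends] - is_n[starts]
        gc_ok = (n_c + n_g) > MIN_GC * length
        exp = n_c * n_g / length
        with np.errstate(divide="ignore", invalid="ignore"):
            oe_ok = np.where(exp > 0, obs > MIN_OE * exp, False)
        ok = gc_ok & oe_ok & (n_n == 0)
        if ok.any():
            s = int(starts[np.argmax(ok)])
            return lo + s, lo + s + length
    return None


def call_cgis(sequence: str, chrom: str = "chr") -> list[CgiRecord]:
    """Detect CpG islands on one chromosome sequence.

    Returns sorted, non-overlapping :class:`CgiRecord` objects; an empty
    list when nothing qualifies.
    """
    if not sequence:
        raise SequenceError("empty sequence")
    arr = _encode(sequence)
    if arr.size < MIN_LENGTH:
        return []
    n_c, n_g, obs, n_n = _window_stats(arr, WINDOW)
    m = min(n_c.size, obs.size)
    n_c, n_g, obs, n_n = n_c[:m], n_g[:m], obs[:m], n_n[:m]
    gc_ok = (n_c + n_g) > MIN_GC * WINDOW
    exp = n_c * n_g / WINDOW
    with np.errstate(divide="ignore", invalid="ignore"):
        oe_ok = np.where(exp > 0, obs > MIN_OE * exp, False)
    ok = gc_ok & oe_ok & (n_n == 0)
    starts = np.nonzero(ok)[0]
    if starts.size == 0:
        return []
    # candidate = union of qualifying windows; no padding, so flanking
    # low-GC sequence cannot dilute its way into an island
    candidates = merge((int(s), int(s) + WINDOW) for s in starts)
    records = []
    for lo, hi in candidates:
        hit = _longest_qualifying(arr, lo, hi)
        if hit is None:
            continue
        s, e = hit
        gc, ob, ex, oe = score_segment(sequence[s:e])
        records.append(CgiRecord(chrom, s, e, gc, ob, ex, oe))
    records.sort(key=lambda r: r.start)
    return records


def derive_shores_shelves(islands_by_chrom: dict, chrom_lengths: dict,
                          flank: int = FLANK) -> CgiAnnotation:
    """Derive shore (+/- ``flank``) and shelf (next ``flank``) intervals.

    ``islands_by_chrom`` maps chrom -> sorted (start, end) intervals.
    Precedence island > shore > shelf; everything clipped to chromosome
    bounds.  Raises ValueError for islands outside those bounds.
    """
    ann = CgiAnnotation()
    for chrom, islands in islands_by_chrom.items():
        length = chrom_lengths[chrom]
        islands = merge(islands)
        for s, e in islands:
            if s < 0 or e > length:
                raise ValueError(
                    f"island ({s}, {e}) outside chromosome {chrom} "
                    f"of length {length}"
                )
        near = clip(merge((s - flank, e + flank) for s, e in islands),
                    0, length)
        far = clip(merge((s - 2 * flank, e + 2 * flank) for s, e in islands),
                   0, length)
        shores = subtract(near, islands)
        shelves = subtract(subtract(far, near), islands)
        ann.islands[chrom] = islands
        ann.shores[chrom] = shores
        ann.shelves[chrom] = shelves
    return ann
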