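"""Differential methylation calling between pubertal-stage groups.

Site level (DMC for CpG, DMH for CpH): reads are pooled across the
replicates of each group, a two-tail Fisher's exact test is applied to
the 2x2 table of methylated/unmethylated pooled reads, p-values are
Benjamini-Hochberg adjusted within each context x comparison stratum,
and a site is called DM when q <= 0.05 *and* the pooled level
difference exceeds 0.20 in absolute value (strictly).  Polarity marks
the group with the higher level.

Region level (DMI for CpG islands, DMG for genes +/- 5 kb): regions
covered by at least 20 sites of the tested context are compared by a
classical two-sample Student's t test (pooled variance; Welch optional)
on the three per-replicate region means, BH-adjusted within each
kind x context x comparison stratum, DM when q <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate import FeatureIndex
from .core import SiteMatrix

COMPARISONS = {
    "PreVsIn": ("Pre", "In"),
    "InVsPost": ("In", "Post"),
    "PreVsPost": ("Pre", "Post"),
}

DELTA_MIN = 0.20
Q_MAX = 0.05
MIN_SITES = 20


@dataclass(frozen=True)
class Comparison:
    name: str
    group_a: str
    group_b: str

    def __post_init__(self):
        if self.group_a == self.group_b:
            raise ValueError("comparison groups must differ")


def get_comparison(name: str) -> Comparison:
    a, b = COMPARISONS[name]
    return Comparison(name, a, b)


def fisher_exact_two_tail(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.
    Returns 1.0 when a margin is empty.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative count")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]])[1])


def fisher_exact_two_tail_many(a, b, c, d) -> np.ndarray:
    """Vectorized two-sided Fisher over parallel count arrays.

    Same statistic as :func:`fisher_exact_two_tail` (including the
    small relative tolerance when comparing table probabilities),
    computed by summing hypergeometric pmf values per table.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    n = a + b + c + d
    r1 = a + b          # first-row margin
    c1 = a + c          # first-column margin
    p = np.ones(a.shape, dtype=float)
    valid = (r1 > 0) & (n - r1 > 0) & (c1 > 0) & (n - c1 > 0)
    idx = np.nonzero(valid)[0]
    if idx.size == 0:
        return p
    kmax = np.minimum(r1, c1)
    kmin = np.maximum(0, r1 + c1 - n)
    # chunk over sites; vectorize over the hypergeometric support
    chunk = max(1, int(2_000_000 // max(1, int((kmax - kmin).max() + 1))))
    for lo in range(0, idx.size, chunk):
        rows = idx[lo:lo + chunk]
        width = int((kmax[rows] - kmin[rows]).max()) + 1
        k = kmin[rows][:, None] + np.arange(width)[None, :]
        support = k <= kmax[rows][:, None]
        pmf = stats.hypergeom.pmf(
            np.where(support, k, 0),
            n[rows][:, None], c1[rows][:, None], r1[rows][:, None],
        )
        obs = stats.hypergeom.pmf(a[rows], n[rows], c1[rows], r1[rows])
        take = support & (pmf <= obs[:, None] * (1 + 1e-7))
        p[rows] = np.minimum(1.0, np.where(take, pmf, 0.0).sum(axis=1))
    return p


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dm_site_test(matrix: SiteMatrix, comparison: str,
                 delta_min: float = DELTA_MIN,
                 q_max: float = Q_MAX) -> pd.DataFrame:
    """Per-site Fisher + FDR + delta-threshold DM calls.

    Returns one row per site and context with pooled group levels,
    delta (A - B), p, q, ``is_dm`` and ``polarity``.  FDR is adjusted
    within each context separately.
    """
    comp = get_comparison(comparison)
    ma, ta = matrix.pooled_counts(comp.group_a)
    mb, tb = matrix.pooled_counts(comp.group_b)
    if (ta == 0).any() or (tb == 0).any():
        raise ValueError("site with empty group after filtering")
    level_a = ma / ta
    level_b = mb / tb
    delta = level_a - level_b
    p = fisher_exact_two_tail_many(ma, ta - ma, mb, tb - mb)
    out = matrix.sites.copy()
    out["comparison"] = comp.name
    out["level_a"] = level_a
    out["level_b"] = level_b
    out["delta"] = delta
    out["p"] = p
    q = np.empty_like(p)
    for ctx in out["context"].unique():
        m = (out["context"] == ctx).to_numpy()
        q[m] = bh_fdr(p[m])
    out["q"] = q
    out["is_dm"] = (out["q"] <= q_max) & (np.abs(delta) > delta_min)
    polarity = np.full(len(out), "none", dtype=object)
    polarity[(out["is_dm"] & (delta > 0)).to_numpy()] = "hyper_in_a"
    polarity[(out["is_dm"] & (delta < 0)).to_numpy()] = "hyper_in_b"
    out["polarity"] = polarity
    return out


def student_t_two_sample(a, b, welch: bool = False):
    """Two-tailed two-sample t test on small replicate groups.

    Classical pooled-variance Student's t by default (df = n_a+n_b-2).
    Degenerate zero-variance groups: equal means -> p = 1; unequal
    means -> p = 0 (flagged upstream).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.var(a) == 0 and np.var(b) == 0:
        return (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def dm_region_test(regions, matrix: SiteMatrix, comparison: str,
                   context: str = "CpG", min_sites: int = MIN_SITES,
                   q_max: float = Q_MAX, welch: bool = False) -> pd.DataFrame:
    """Region-level differential methylation (DMI / DMG).

    ``regions``: iterable of (region_id, kind, chrom, start, end) with
    0-based half-open coordinates.  Regions with fewer than
    ``min_sites`` covered sites of ``context`` are reported untested
    (p, q = NaN).  FDR is adjusted across tested regions only.
    """
    comp = get_comparison(comparison)
    ctx = matrix.context_subset(context)
    lev = ctx.levels()
    cols_a = ctx.sample_columns(comp.group_a)
    cols_b = ctx.sample_columns(comp.group_b)
    by_chrom = {
        chrom: (sub["pos"].to_numpy() - 1,
                ctx.sites.index.get_indexer(sub.index))
        for chrom, sub in ctx.sites.groupby("chrom", sort=False)
    }
    rows = []
    for region_id, kind, chrom, start, end in regions:
        if chrom in by_chrom:
            pos0, ridx = by_chrom[chrom]
            lo = np.searchsorted(pos0, start)
            hi = np.searchsorted(pos0, end)
            sel = ridx[lo:hi]
        else:
            sel = np.array([], dtype=int)
        n = sel.size
        if n < min_sites:
            rows.append((region_id, kind, chrom, start, end, n,
                         np.nan, np.nan, np.nan, np.nan, False, False))
            continue
        reps_a = lev[np.ix_(sel, cols_a)].mean(axis=0)
        reps_b = lev[np.ix_(sel, cols_b)].mean(axis=0)
        _, p = student_t_two_sample(reps_a, reps_b, welch=welch)
        rows.append((region_id, kind, chrom, start, end, n,
                     float(reps_a.mean()), float(reps_b.mean()),
                     p, np.nan, True, False))
    out = pd.DataFrame(rows, columns=[
        "region_id", "kind", "chrom", "start", "end", "n_sites",
        "mean_a", "mean_b", "p", "q", "tested", "is_dm",
    ])
    out["comparison"] = comp.name
    out["context"] = context
    tested = out["tested"].to_numpy()
    if tested.any():
        q = bh_fdr(out.loc[tested, "p"].to_numpy())
        out.loc[tested, "q"] = q
        out.loc[tested, "is_dm"] = q <= q_max
    return out


def dm_regarding_genes(dm_sites: pd.DataFrame,
                       index: FeatureIndex) -> set[str]:
    """Genes whose body +/- 5 kb contains at least one DM site."""
    genes: set[str] = set()
    hits = dm_sites.loc[dm_sites["is_dm"], ["chrom", "pos"]]
    for chrom, pos in hits.itertuples(index=False):
        genes |= index.genes_for_site(chrom, int(pos))
    return genes


def dmi_regarding_genes(dmis: pd.DataFrame, models,
                        flank: int = 5000) -> set[str]:
    """Genes whose body +/- flank overlaps at least one DM island."""
    calls = dmis.loc[dmis["is_dm"]]
    genes: set[str] = set()
    for m in models:
        s, e = m.extended_span(flank)
        sub = calls[calls["chrom"] == m.chrom]
        if ((sub["start"] < e) & (sub["end"] > s)).any():
            genes.add(m.gene_id)
    return genes
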