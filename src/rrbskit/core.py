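"""Filtered multi-sample site matrix and descriptive methylation statistics.

The central object is :class:`SiteMatrix`: per-cytosine methylated and
total read counts across samples, restricted to sites covered by at
least ``min_cov`` reads in *every* sample (co-existence rule).  Strands
are never merged: the C on the plus strand and the G-position C on the
minus strand of one CpG dinucleotide are distinct sites.

Level arithmetic follows the conventions of RRBS pipelines:

* site level      = methylated reads / total reads,
* group level     = unweighted mean of the replicate site levels
                    (not a pooled-read ratio),
* region level    = mean of the group levels of sites in the region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STAGES = ("Pre", "In", "Post")
DEFAULT_MIN_COV = 5

GENE_SCHEME = {"up_bins": 20, "body_bins": 40, "down_bins": 20, "flank": 5000}
CGI_SCHEME = {"up_bins": 20, "body_bins": 20, "down_bins": 20, "flank": 2000}


@dataclass
class SiteMatrix:
    """Sites x samples count matrix with sample metadata.

    ``sites`` has columns chrom, pos (1-based), strand, context
    ('CpG'/'CpH'); ``meth`` and ``total`` are int arrays of shape
    (n_sites, n_samples); ``samples`` has columns name, stage,
    replicate aligned with the matrix columns.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self):
        if (self.meth > self.total).any():
            raise ValueError("methylated count exceeds total count")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_columns(self, stage: str) -> np.ndarray:
        return np.nonzero((self.samples["stage"] == stage).to_numpy())[0]

    def levels(self) -> np.ndarray:
        """Per-site per-sample methylation levels."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.meth / self.total

    def group_levels(self, stage: str) -> np.ndarray:
        """Per-site mean of replicate levels for one stage."""
        cols = self.sample_columns(stage)
        return self.levels()[:, cols].mean(axis=1)

    def pooled_counts(self, stage: str):
        """Reads pooled across a stage's replicates (site Fisher test)."""
        cols = self.sample_columns(stage)
        return self.meth[:, cols].sum(axis=1), self.total[:, cols].sum(axis=1)

    def subset(self, mask) -> "SiteMatrix":
        mask = np.asarray(mask)
        return SiteMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            self.meth[mask], self.total[mask], self.samples,
        )

    def context_subset(self, context: str) -> "SiteMatrix":
        return self.subset((self.sites["context"] == context).to_numpy())


def load_and_filter(sample_frames: dict, sample_meta: pd.DataFrame,
                    min_cov: int = DEFAULT_MIN_COV) -> SiteMatrix:
    """Intersect per-sample CGmap frames and apply the coverage filter.

    Parameters
    ----------
    sample_frames : dict of name -> DataFrame
        Frames as returned by :func:`rrbskit.io.read_cgmap` (columns
        chrom, pos, strand, context, dinuc, meth, total).
    sample_meta : DataFrame
        Columns name, stage, replicate; row order fixes matrix columns.
    min_cov : int
        Minimum total reads required in every sample.

    Only sites present with ``total >= min_cov`` in *all* samples are
    retained.
    """
    if len(sample_meta) < 2:
        raise ValueError("need at least two samples")
    names = list(sample_meta["name"])
    indexed = {}
    for name in names:
        df = sample_frames[name]
        key = pd.MultiIndex.from_frame(df[["chrom", "pos"]])
        if key.duplicated().any():
            dup = df.loc[key.duplicated(), ["chrom", "pos"]].iloc[0]
            raise ValueError(
                f"duplicate site {dup['chrom']}:{dup['pos']} in sample {name}"
            )
        indexed[name] = df.set_index(key)
    common = indexed[names[0]].index
    for name in names[1:]:
        common = common.intersection(indexed[name].index)
    common = common.sortlevel()[0]
    first = indexed[names[0]].loc[common]
    sites = first[["chrom", "pos", "strand", "context"]].reset_index(drop=True)
    meth = np.empty((len(common), len(names)), dtype=np.int64)
    total = np.empty_like(meth)
    for j, name in enumerate(names):
        sub = indexed[name].loc[common]
        meth[:, j] = sub["meth"].to_numpy()
        total[:, j] = sub["total"].to_numpy()
    keep = (total >= min_cov).all(axis=1)
    return SiteMatrix(
        sites.loc[keep].reset_index(drop=True),
        meth[keep], total[keep], sample_meta.reset_index(drop=True),
    )


def site_level(methylated: int, total: int) -> float:
    """Methylated reads / total reads."""
    if total <= 0:
        raise ValueError("site level undefined for zero coverage")
    if methylated > total:
        raise ValueError("methylated exceeds total")
    return methylated / total


def group_level(replicate_levels) -> float:
    """Unweighted mean of replicate site levels."""
    return float(np.mean(np.asarray(replicate_levels, dtype=float)))


def region_level(region, matrix: SiteMatrix, context: str, stage: str):
    """Mean group level over sites of ``context`` inside ``region``.

    ``region`` is (chrom, start, end), 0-based half-open.  Returns
    (level | None, n_sites).
    """
    chrom, start, end = region
    pos0 = matrix.sites["pos"].to_numpy() - 1
    mask = (
        (matrix.sites["chrom"] == chrom).to_numpy()
        & (matrix.sites["context"] == context).to_numpy()
        & (pos0 >= start) & (pos0 < end)
    )
    n = int(mask.sum())
    if n == 0:
        return None, 0
    return float(matrix.group_levels(stage)[mask].mean()), n


@dataclass
class ProfileMatrix:
    """Binned metagene/meta-CGI profile: mean level and site count per bin."""

    scheme: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # table columns: bin (1-based), section, stage, mean, n


def _bin_of(pos0, start, end, up_bins, body_bins, down_bins, flank):
    """Global bin index (0-based) for 0-based positions around one
    plus-oriented region [start, end); -1 when outside the span."""
    pos0 = np.asarray(pos0, dtype=np.int64)
    out = np.full(pos0.shape, -1, dtype=np.int64)
    up_w = flank / up_bins
    down_w = flank / down_bins
    body_w = (end - start) / body_bins
    up = (pos0 >= start - flank) & (pos0 < start)
    out[up] = (pos0[up] - (start - flank)) // up_w
    body = (pos0 >= start) & (pos0 < end)
    out[body] = up_bins + np.minimum(
        ((pos0[body] - start) / body_w).astype(np.int64), body_bins - 1
    )
    down = (pos0 >= end) & (pos0 < end + flank)
    out[down] = up_bins + body_bins + (pos0[down] - end) // down_w
    return out


def binned_profile(regions, matrix: SiteMatrix, scheme: str, stage: str,
                   context: str = "CpG") -> ProfileMatrix:
    """Average methylation profile across binned region instances.

    ``scheme`` is 'gene' (20 upstream / 40 body / 20 downstream bins,
    5 kb flanks, minus-strand regions orientation-flipped so bin 1 is
    always 5'-most) or 'cgi' (20/20/20, 2 kb flanks, unstranded).
    ``regions`` are GeneModel objects for 'gene', (chrom, start, end)
    tuples for 'cgi'.  A site overlapped by several regions contributes
    to each of their profiles.
    """
    p = GENE_SCHEME if scheme == "gene" else CGI_SCHEME
    n_bins = p["up_bins"] + p["body_bins"] + p["down_bins"]
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    ctx = (matrix.sites["context"] == context).to_numpy()
    glev = matrix.group_levels(stage)
    by_chrom = {
        chrom: (sub["pos"].to_numpy() - 1,
                matrix.sites.index.get_indexer(sub.index))
        for chrom, sub in matrix.sites.loc[ctx].groupby("chrom", sort=False)
    }
    for region in regions:
        if scheme == "gene":
            chrom, start, end, strand = (region.chrom, region.start,
                                         region.end, region.strand)
        else:
            chrom, start, end = region
            strand = "+"
        if end - start < p["body_bins"]:
            warnings.warn(
                f"region {chrom}:{start}-{end} shorter than "
                f"{p['body_bins']} body bins; skipped"
            )
            continue
        if chrom not in by_chrom:
            continue
        pos0, rows = by_chrom[chrom]
        lo = np.searchsorted(pos0, start - p["flank"])
        hi = np.searchsorted(pos0, end + p["flank"])
        sel_pos, sel_rows = pos0[lo:hi], rows[lo:hi]
        if strand == "-":
            # reflect within the padded span so bin 1 stays 5'-most
            sel_pos = (start - p["flank"]) + (end + p["flank"] - 1) - sel_pos
        bins = _bin_of(sel_pos, start, end, p["up_bins"], p["body_bins"],
                       p["down_bins"], p["flank"])
        ok = bins >= 0
        np.add.at(sums, bins[ok], glev[sel_rows[ok]])
        np.add.at(counts, bins[ok], 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    sections = (
        ["upstream"] * p["up_bins"] + ["body"] * p["body_bins"]
        + ["downstream"] * p["down_bins"]
    )
    table = pd.DataFrame({
        "bin": np.arange(1, n_bins + 1),
        "section": sections,
        "stage": stage,
        "mean": means,
        "n": counts,
    })
    return ProfileMatrix(scheme=scheme, table=table)


def window_track(chroms, positions, chrom_lengths: dict,
                 width: int = 1_000_000, mode: str = "density",
                 values=None) -> pd.DataFrame:
    """Tile each chromosome into fixed windows and quantify per window.

    ``mode='density'`` counts items; ``mode='mean_level'`` averages
    ``values`` (windows without items get NaN).  Interval inputs should
    be reduced to midpoints by the caller.  Window grids depend only on
    ``chrom_lengths`` and ``width``, so tracks from one genome align.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    chroms = np.asarray(chroms, dtype=object)
    pos0 = np.asarray(positions, dtype=np.int64) - 1
    rows = []
    for chrom in sorted(chrom_lengths):
        n_win = max(1, -(-chrom_lengths[chrom] // width))
        sel = chroms == chrom
        win = pos0[sel] // width
        if mode == "density":
            val = np.bincount(win, minlength=n_win).astype(float)
        else:
            v = np.asarray(values, dtype=float)[sel]
            s = np.bincount(win, weights=v, minlength=n_win)
            c = np.bincount(win, minlength=n_win)
            with np.errstate(invalid="ignore"):
                val = np.where(c > 0, s / np.maximum(c, 1), np.nan)
        for i in range(n_win):
            rows.append((chrom, i, val[i]))
    return pd.DataFrame(rows, columns=["chrom", "window", "value"])


def interval_midpoints(intervals):
    """Midpoint (1-based) of each 0-based half-open interval."""
    return [(s + e) // 2 + 1 for s, e in intervals]


def pearson(x, y):
    """Sample Pearson correlation with a two-sided t-distribution p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
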