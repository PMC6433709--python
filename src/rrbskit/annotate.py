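"""Genic, CGI-related and QTL annotation of cytosine sites.

The genome is partitioned into five genic features — upstream (5 kb
before the TSS, strand-aware), exon, intron, downstream (5 kb past the
TES), intergenic — with precedence exon > intron > upstream >
downstream > intergenic so that overlapping genes and intruding flanks
still yield exactly one label per site.  CGI-related labels (island /
shore / shelf / open sea) are an independent classification carried
alongside, as is QTL membership.

Site positions are 1-based (CGmap convention); intervals are 0-based
half-open internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .cgi import CgiAnnotation
from .intervals import MembershipIndex, merge

UPSTREAM_FLANK = 5000
GENIC_LABELS = ("upstream", "exon", "intron", "downstream", "intergenic")
CGI_LABELS = ("island", "shore", "shelf", "open_sea")


@dataclass
class GeneModel:
    """One gene: body [start, end) on ``strand`` with exon intervals."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int   # 0-based half-open gene body
    end: int
    exons: list  # [(start, end)] within the body

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"exon ({s}, {e}) outside body of {self.gene_id}"
                )

    @property
    def tss(self) -> int:
        """Transcription start, as a 0-based position."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def upstream_interval(self, flank: int = UPSTREAM_FLANK):
        if self.strand == "+":
            return (self.start - flank, self.start)
        return (self.end, self.end + flank)

    def downstream_interval(self, flank: int = UPSTREAM_FLANK):
        if self.strand == "+":
            return (self.end, self.end + flank)
        return (self.start - flank, self.start)

    def extended_span(self, flank: int = UPSTREAM_FLANK):
        """Gene body plus ``flank`` on both sides (DM-regarding-gene rule)."""
        return (self.start - flank, self.end + flank)


class FeatureIndex:
    """Precomputed per-chromosome membership indexes for fast labelling."""

    def __init__(self, models: list[GeneModel], flank: int = UPSTREAM_FLANK):
        self.flank = flank
        by_chrom: dict[str, dict[str, list]] = {}
        for m in models:
            d = by_chrom.setdefault(
                m.chrom, {"exon": [], "body": [], "up": [], "down": []}
            )
            d["exon"].extend(m.exons)
            d["body"].append((m.start, m.end))
            d["up"].append(m.upstream_interval(flank))
            d["down"].append(m.downstream_interval(flank))
        self._idx = {
            chrom: {k: MembershipIndex(v) for k, v in d.items()}
            for chrom, d in by_chrom.items()
        }
        self._span_trees: dict[str, IntervalTree] = {}
        for m in models:
            s, e = m.extended_span(flank)
            self._span_trees.setdefault(m.chrom, IntervalTree()).addi(
                s, e, m.gene_id
            )

    def genic_labels(self, chrom: str, positions) -> np.ndarray:
        """Vectorized five-way labels for 1-based ``positions``."""
        pos0 = np.asarray(positions, dtype=np.int64) - 1
        out = np.full(pos0.shape, "intergenic", dtype=object)
        idx = self._idx.get(chrom)
        if idx is None:
            warnings.warn(f"unknown chromosome {chrom!r}; labelling intergenic")
            return out
        # precedence: exon > intron > upstream > downstream
        down = idx["down"].contains(pos0)
        out[down] = "downstream"
        up = idx["up"].contains(pos0)
        out[up] = "upstream"
        body = idx["body"].contains(pos0)
        out[body] = "intron"
        exon = idx["exon"].contains(pos0)
        out[exon] = "exon"
        return out

    def genes_for_site(self, chrom: str, pos: int) -> set[str]:
        """IDs of genes whose body +/- flank contains the 1-based site."""
        tree = self._span_trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos - 1)}


def assign_genic_feature(site, models_or_index) -> str:
    """Label one (chrom, 1-based pos) site; see module docstring."""
    idx = (models_or_index if isinstance(models_or_index, FeatureIndex)
           else FeatureIndex(models_or_index))
    chrom, pos = site
    return str(idx.genic_labels(chrom, [pos])[0])


class CgiIndex:
    """island/shore/shelf/open_sea labelling from a CgiAnnotation."""

    def __init__(self, ann: CgiAnnotation):
        chroms = set(ann.islands) | set(ann.shores) | set(ann.shelves)
        self._idx = {
            chrom: {
                "island": MembershipIndex(ann.islands.get(chrom, [])),
                "shore": MembershipIndex(ann.shores.get(chrom, [])),
                "shelf": MembershipIndex(ann.shelves.get(chrom, [])),
            }
            for chrom in chroms
        }

    def cgi_labels(self, chrom: str, positions) -> np.ndarray:
        pos0 = np.asarray(positions, dtype=np.int64) - 1
        out = np.full(pos0.shape, "open_sea", dtype=object)
        idx = self._idx.get(chrom)
        if idx is None:
            return out
        out[idx["shelf"].contains(pos0)] = "shelf"
        out[idx["shore"].contains(pos0)] = "shore"
        out[idx["island"].contains(pos0)] = "island"
        return out


def assign_cgi_feature(site, annotation: CgiAnnotation) -> str:
    chrom, pos = site
    return str(CgiIndex(annotation).cgi_labels(chrom, [pos])[0])


def genes_for_site(site, models_or_index) -> set[str]:
    idx = (models_or_index if isinstance(models_or_index, FeatureIndex)
           else FeatureIndex(models_or_index))
    chrom, pos = site
    return idx.genes_for_site(chrom, pos)


class QtlIndex:
    """Membership against merged QTL intervals (overlaps counted once)."""

    def __init__(self, qtls_by_chrom: dict):
        self._idx = {
            chrom: MembershipIndex(merge(ivs))
            for chrom, ivs in qtls_by_chrom.items()
        }

    def contains(self, chrom: str, positions) -> np.ndarray:
        pos0 = np.asarray(positions, dtype=np.int64) - 1
        idx = self._idx.get(chrom)
        if idx is None:
            return np.zeros(pos0.shape, dtype=bool)
        return idx.contains(pos0)


def overlaps_qtl(site, qtls_by_chrom: dict) -> bool:
    chrom, pos = site
    return bool(QtlIndex(qtls_by_chrom).contains(chrom, [pos])[0])


def annotate_sites(sites: pd.DataFrame, index: FeatureIndex,
                   cgi_index: CgiIndex | None = None,
                   qtl_index: QtlIndex | None = None) -> pd.DataFrame:
    """Annotate a frame with ``chrom``/``pos`` columns in place of loops.

    Adds ``genic`` always, plus ``cgi`` and ``qtl`` when the matching
    index is given.
    """
    out = sites.copy()
    genic = np.empty(len(out), dtype=object)
    cgi = np.empty(len(out), dtype=object) if cgi_index is not None else None
    qtl = np.zeros(len(out), dtype=bool) if qtl_index is not None else None
    for chrom, sub in out.groupby("chrom", sort=False):
        loc = out.index.get_indexer(sub.index)
        genic[loc] = index.genic_labels(chrom, sub["pos"].to_numpy())
        if cgi is not None:
            cgi[loc] = cgi_index.cgi_labels(chrom, sub["pos"].to_numpy())
        if qtl is not None:
            qtl[loc] = qtl_index.contains(chrom, sub["pos"].to_numpy())
    out["genic"] = genic
    if cgi is not None:
        out["cgi"] = cgi
    if qtl is not None:
        out["qtl"] = qtl
    return out
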