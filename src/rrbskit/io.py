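"""Readers and writers for the pipeline's plain-text formats.

CGmap dialect (8 tab-separated columns): chrom, reference base (C for
plus-strand sites, G for minus), 1-based position, context class
(CG/CHG/CHH), strand-local dinucleotide, methylation level, methylated
reads, total reads.  The level column is advisory and recomputed from
the counts on read; a mismatch above 0.01 triggers a warning.

Sites are 1-based; intervals use BED 0-based half-open coordinates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .annotate import GeneModel

CGMAP_COLUMNS = ["chrom", "base", "pos", "cls", "dinuc",
                 "level", "meth", "total"]


class FormatError(ValueError):
    """Malformed input row, with file and line context."""


def read_cgmap(path) -> pd.DataFrame:
    """Parse one CGmap-style file into the internal site-count frame.

    Returns columns chrom, pos, strand, context ('CpG'/'CpH'), cls,
    dinuc, meth, total.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=CGMAP_COLUMNS,
            dtype={"chrom": str, "base": str, "cls": str, "dinuc": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        line = int(df.isna().any(axis=1).idxmax()) + 1
        raise FormatError(f"{path}:{line}: missing or non-numeric field")
    for col in ("pos", "meth", "total"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 1
            raise FormatError(f"{path}:{line}: non-numeric {col}")
        df[col] = vals.astype(np.int64)
    bad = df["meth"] > df["total"]
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise FormatError(f"{path}:{line}: methylated > total")
    if not df["base"].isin(["C", "G"]).all():
        line = int((~df["base"].isin(["C", "G"])).idxmax()) + 1
        raise FormatError(f"{path}:{line}: reference base must be C or G")
    with np.errstate(invalid="ignore"):
        recomputed = df["meth"] / df["total"].replace(0, np.nan)
    drift = (recomputed - pd.to_numeric(df["level"])).abs()
    if (drift > 0.01).any():
        warnings.warn(f"{path}: level column disagrees with counts "
                      f"(max drift {drift.max():.3f}); counts used")
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["pos"],
        "strand": np.where(df["base"] == "C", "+", "-"),
        "context": np.where(df["cls"] == "CG", "CpG", "CpH"),
        "cls": df["cls"],
        "dinuc": df["dinuc"],
        "meth": df["meth"],
        "total": df["total"],
    })
    return out


def write_cgmap(frame: pd.DataFrame, path) -> None:
    """Inverse of :func:`read_cgmap` (level emitted to 4 d.p.)."""
    out = pd.DataFrame({
        "chrom": frame["chrom"],
        "base": np.where(frame["strand"] == "+", "C", "G"),
        "pos": frame["pos"],
        "cls": frame["cls"],
        "dinuc": frame["dinuc"],
        "level": (frame["meth"] / frame["total"]).round(4),
        "meth": frame["meth"],
        "total": frame["total"],
    })
    out.to_csv(path, sep="\t", header=False, index=False,
               float_format="%.4f")


def read_bed(path) -> dict:
    """BED (>= 3 columns) -> chrom -> sorted [(start, end)]."""
    out: dict[str, list] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{i}: fewer than 3 BED columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{i}: non-integer interval") from exc
            if e < s:
                raise FormatError(f"{path}:{i}: end < start")
            out.setdefault(parts[0], []).append((s, e))
    for chrom in out:
        out[chrom].sort()
    return out


def write_bed(intervals_by_chrom: dict, path, name: str = ".",
              scores=None) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals_by_chrom):
            for j, (s, e) in enumerate(intervals_by_chrom[chrom]):
                score = scores[chrom][j] if scores else 0
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score}\t.\n")


def write_cgi_bed(annotation, path) -> None:
    """Islands, shores and shelves as one BED6 (name = class,
    score = round(1000 x O/E) for islands, 0 otherwise)."""
    rows = []
    for chrom in sorted(set(annotation.islands) | set(annotation.shores)
                        | set(annotation.shelves)):
        for s, e in annotation.islands.get(chrom, []):
            rows.append((chrom, s, e, "island", 0))
        for s, e in annotation.shores.get(chrom, []):
            rows.append((chrom, s, e, "shore", 0))
        for s, e in annotation.shelves.get(chrom, []):
            rows.append((chrom, s, e, "shelf", 0))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, s, e, name, score in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score}\t.\n")


def read_cgi_bed(path):
    """Read a BED of islands (and optionally shores/shelves) back into
    per-class interval dicts; unlabeled rows count as islands."""
    from .cgi import CgiAnnotation
    ann = CgiAnnotation()
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{i}: fewer than 3 BED columns")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            cls = parts[3] if len(parts) > 3 else "island"
            table = {"island": ann.islands, "shore": ann.shores,
                     "shelf": ann.shelves}.get(cls, ann.islands)
            table.setdefault(chrom, []).append((s, e))
    for d in (ann.islands, ann.shores, ann.shelves):
        for chrom in d:
            d[chrom].sort()
    return ann


def write_gene_bed12(models, path) -> None:
    """GeneModel list -> BED12."""
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda g: (g.chrom, g.start)):
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            starts = ",".join(str(s - m.start) for s, e in m.exons) + ","
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.gene_id}\t0\t{m.strand}"
                f"\t{m.start}\t{m.end}\t0\t{len(m.exons)}\t{sizes}\t{starts}\n"
            )


def read_gene_table(path) -> list:
    """Read gene models from BED12 or the 6-column TSV dialect
    (gene_id, chrom, strand, start, end, comma-separated exon pairs)."""
    models = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            try:
                if len(parts) >= 12:  # BED12
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    gene_id, strand = parts[3], parts[5]
                    n = int(parts[9])
                    sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                    offs = [int(x) for x in parts[11].rstrip(",").split(",")]
                    if len(sizes) != n or len(offs) != n:
                        raise ValueError("block count mismatch")
                    exons = [(start + o, start + o + sz)
                             for o, sz in zip(offs, sizes)]
                elif len(parts) == 6:
                    gene_id, chrom, strand = parts[0], parts[1], parts[2]
                    start, end = int(parts[3]), int(parts[4])
                    exons = []
                    for pair in parts[5].split(","):
                        if pair:
                            s, e = pair.split("-")
                            exons.append((int(s), int(e)))
                else:
                    raise ValueError(f"{len(parts)} columns")
            except ValueError as exc:
                raise FormatError(f"{path}:{i}: {exc}") from exc
            models.append(GeneModel(gene_id=gene_id, chrom=chrom,
                                    strand=strand, start=start, end=end,
                                    exons=exons))
    return models


def write_fasta(sequences: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sequences):
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict:
    """chrom -> sequence, via pyfaidx."""
    from pyfaidx import Fasta
    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_window_track(track: pd.DataFrame, path,
                       width: int = 1_000_000) -> None:
    """WindowTrack frame -> bedGraph."""
    with open(path, "w") as fh:
        for chrom, win, value in track.itertuples(index=False):
            if np.isnan(value):
                continue
            fh.write(f"{chrom}\t{win * width}\t{(win + 1) * width}"
                     f"\t{value:.6g}\n")
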