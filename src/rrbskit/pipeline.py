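"""End-to-end pipeline driver: filter -> annotate -> profiles/windows ->
differential calls -> gene sets -> enrichment, with a reproducibility
manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import CgiIndex, FeatureIndex, QtlIndex, annotate_sites
from .cgi import derive_shores_shelves
from .core import (CGI_SCHEME, GENE_SCHEME, STAGES, SiteMatrix,
                   binned_profile, interval_midpoints, load_and_filter,
                   window_track)
from .differential import (COMPARISONS, dm_regarding_genes, dm_region_test,
                           dm_site_test, dmi_regarding_genes)
from .enrichment import enrichment_report, enrichment_table

log = logging.getLogger("rrbskit")


@dataclass
class PipelineConfig:
    """Paths, thresholds and bookkeeping for one pipeline run."""

    genome: str | None = None
    genes: str | None = None
    cgi: str | None = None
    qtl: str | None = None
    sample_table: str | None = None      # TSV: name, stage, replicate, path
    outdir: str = "rrbskit_out"
    min_cov: int = 5
    delta_min: float = 0.20
    q_max: float = 0.05
    min_sites: int = 20
    window: int = 1_000_000
    flank_gene: int = 5000
    flank_cgi: int = 2000
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_cov", "min_sites", "window",
                     "flank_gene", "flank_cgi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("delta_min", "q_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PipelineResult:
    matrix: SiteMatrix
    annotated: pd.DataFrame
    dm_sites: dict = field(default_factory=dict)      # (comp) -> frame
    dm_regions: dict = field(default_factory=dict)    # (kind, ctx, comp)
    gene_sets: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)    # context -> frame
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, sample_frames: dict | None = None,
                 sample_meta: pd.DataFrame | None = None,
                 models=None, cgi_annotation=None, qtls=None,
                 chrom_lengths: dict | None = None) -> PipelineResult:
    """Execute every stage and write TSV outputs plus a manifest.

    Inputs may be given as paths in ``config`` or directly as in-memory
    objects (the simulator's output), which takes precedence.
    """
    from . import io as rio

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_times = {}
    warnings_count = 0

    def tick(name):
        stage_times[name] = round(time.time() - t0, 3)
        log.info("stage %s done at %.1fs", name, stage_times[name])

    try:
        if sample_frames is None:
            meta = pd.read_csv(config.sample_table, sep="\t")
            sample_meta = meta[["name", "stage", "replicate"]]
            sample_frames = {
                row["name"]: rio.read_cgmap(row["path"])
                for _, row in meta.iterrows()
            }
        stages = set(sample_meta["stage"])
        if stages != set(STAGES):
            raise ValueError(f"sample table must define stages {STAGES}")
        if sample_meta.groupby("stage").size().min() < 2:
            raise ValueError("need >= 2 replicates per stage")
        if models is None:
            models = rio.read_gene_table(config.genes)
        if qtls is None:
            qtls = rio.read_bed(config.qtl) if config.qtl else {}
        if cgi_annotation is None:
            islands = rio.read_bed(config.cgi)
            if chrom_lengths is None:
                seqs = rio.read_fasta(config.genome)
                chrom_lengths = {c: len(s) for c, s in seqs.items()}
            cgi_annotation = derive_shores_shelves(islands, chrom_lengths)
        if chrom_lengths is None:
            seqs = rio.read_fasta(config.genome)
            chrom_lengths = {c: len(s) for c, s in seqs.items()}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'inputs' failed: {exc}") from exc

    result = PipelineResult(matrix=None, annotated=None)

    # --- filtering -----------------------------------------------------
    try:
        matrix = load_and_filter(sample_frames, sample_meta,
                                 min_cov=config.min_cov)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'filter' failed: {exc}") from exc
    result.matrix = matrix
    tick("filter")

    # --- annotation ----------------------------------------------------
    findex = FeatureIndex(models, flank=config.flank_gene)
    cindex = CgiIndex(cgi_annotation)
    qindex = QtlIndex(qtls)
    annotated = annotate_sites(matrix.sites, findex, cindex, qindex)
    result.annotated = annotated
    annotated.to_csv(outdir / "sites_annotated.tsv", sep="\t", index=False)
    tick("annotate")

    # --- profiles and window tracks ------------------------------------
    island_regions = [
        (chrom, s, e)
        for chrom in sorted(cgi_annotation.islands)
        for s, e in cgi_annotation.islands[chrom]
    ]
    profiles = []
    for context in ("CpG", "CpH"):
        for stage in STAGES:
            for scheme, regions in (("gene", models),
                                    ("cgi", island_regions)):
                prof = binned_profile(regions, matrix, scheme, stage,
                                      context=context)
                tab = prof.table.copy()
                tab["context"] = context
                tab["scheme"] = scheme
                profiles.append(tab)
    profile_table = pd.concat(profiles, ignore_index=True)
    profile_table.to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    tick("profiles")

    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    for context in ("CpG", "CpH"):
        m = (matrix.sites["context"] == context).to_numpy()
        track = window_track(chroms[m], pos[m], chrom_lengths,
                             width=config.window, mode="density")
        rio.write_window_track(track, outdir / f"density_{context}.bedGraph",
                               width=config.window)
    tick("windows")

    # --- differential calls --------------------------------------------
    region_specs = {
        "CGI": [(f"cgi_{i + 1}", "CGI", c, s, e)
                for i, (c, s, e) in enumerate(island_regions)],
        "gene": [(m.gene_id, "gene",) + (m.chrom,) + m.extended_span(
            config.flank_gene) for m in models],
    }
    dm_masks: dict[str, dict] = {"CpG": {}, "CpH": {}}
    for comp in COMPARISONS:
        sites_res = dm_site_test(matrix, comp, delta_min=config.delta_min,
                                 q_max=config.q_max)
        result.dm_sites[comp] = sites_res
        sites_res.to_csv(outdir / f"dm_sites_{comp}.tsv", sep="\t",
                         index=False)
        for context in ("CpG", "CpH"):
            m = (sites_res["context"] == context).to_numpy()
            dm_masks[context][comp] = sites_res["is_dm"].to_numpy()[m]
        for context in ("CpG", "CpH"):
            for kind, regs in region_specs.items():
                res = dm_region_test(regs, matrix, comp, context=context,
                                     min_sites=config.min_sites,
                                     q_max=config.q_max)
                result.dm_regions[(kind, context, comp)] = res
                res.to_csv(
                    outdir / f"dm_regions_{kind}_{context}_{comp}.tsv",
                    sep="\t", index=False)
        # gene sets
        dmc = sites_res[sites_res["context"] == "CpG"]
        dmh = sites_res[sites_res["context"] == "CpH"]
        gene_sets = {
            "DMC_genes": sorted(dm_regarding_genes(dmc, findex)),
            "DMH_genes": sorted(dm_regarding_genes(dmh, findex)),
            "DMI_genes": sorted(dmi_regarding_genes(
                result.dm_regions[("CGI", "CpG", comp)], models,
                flank=config.flank_gene)),
        }
        result.gene_sets[comp] = gene_sets
        for name, ids in gene_sets.items():
            pd.Series(ids, dtype=str).to_csv(
                outdir / f"{name}_{comp}.tsv", sep="\t",
                index=False, header=False)
    tick("differential")

    # --- enrichment ----------------------------------------------------
    for context in ("CpG", "CpH"):
        m = (annotated["context"] == context).to_numpy()
        table = enrichment_table(annotated.loc[m].reset_index(drop=True),
                                 dm_masks[context], context)
        result.enrichment[context] = table
        table.to_csv(outdir / f"enrichment_{context}.tsv", sep="\t",
                     index=False)
        enrichment_report(table).to_csv(
            outdir / f"enrichment_report_{context}.tsv", sep="\t",
            index=False)
    tick("enrichment")

    # --- manifest ------------------------------------------------------
    outputs = sorted(p for p in outdir.iterdir()
                     if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_cov": config.min_cov, "delta_min": config.delta_min,
            "q_max": config.q_max, "min_sites": config.min_sites,
            "window": config.window, "flank_gene": config.flank_gene,
            "flank_cgi": config.flank_cgi,
        },
        "n_sites": int(matrix.n_sites),
        "n_samples": int(len(sample_meta)),
        "warnings": warnings_count,
        "stage_seconds": stage_times,
        "outputs": {
            p.name: {"sha256": _sha256(p),
                     "rows": sum(1 for _ in open(p))}
            for p in outputs
        },
    }
    # checksum stability: timing varies run to run, keep it out of the
    # reproducibility fingerprint
    fingerprint = {k: v for k, v in manifest.items()
                   if k != "stage_seconds"}
    manifest["fingerprint"] = hashlib.sha256(
        json.dumps(fingerprint, sort_keys=True).encode()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    result.manifest = manifest
    return result
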