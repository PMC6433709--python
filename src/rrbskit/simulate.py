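"""Synthetic RRBS methylome generator with known ground truth.

Builds a small random genome with planted CpG islands, gene models and
QTL intervals, restricts coverage to MspI fragments passing the
110-220 bp size selection (the defining RRBS property), and draws
per-cytosine read counts for a 3-stage x 3-replicate design:

* coverage per site ~ negative binomial (gamma-Poisson mixture),
* methylated reads ~ binomial with a per-site probability composed of
  a bimodal base level (low in islands, high in open sea for CpG;
  ~0.7% for CpH), a small monotone stage decrease Pre -> In -> Post,
  a planted differential effect, and replicate-level beta
  overdispersion,
* probabilities clipped to [0, 1]; the recorded truth uses the
  post-clipping per-stage probabilities.

Everything is deterministic given the seed: the same configuration
reproduces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import GeneModel

STAGES = ("Pre", "In", "Post")
_COMPS = (("Pre", "In"), ("In", "Post"), ("Pre", "Post"))
_COMP_NAMES = ("PreVsIn", "InVsPost", "PreVsPost")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class SimSizeError(ValueError):
    """Requested features do not fit in the genome."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic methylome.

    Defaults mirror the study design this package targets: a
    3 x 3 RRBS experiment with 110-220 bp MspI fragments, bimodal CpG
    methylation averaging roughly 53%, very low CpH methylation
    (~0.7%) and a small monotone global decrease across the pubertal
    stages.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 3_000_000
    n_genes: int = 60
    n_cgis: int = 80
    n_qtls: int = 8
    frag_min: int = 110
    frag_max: int = 220
    mean_coverage: float = 30.0
    coverage_dispersion: float = 0.3
    cpg_level_island: float = 0.10
    cpg_level_open: float = 0.68
    cph_level: float = 0.007
    stage_deltas: tuple = (0.0, -0.006, -0.012)
    beta_binomial_rho: float = 0.005
    dm_site_fraction: float = 0.05
    dm_effect: float = 0.5
    dm_region_count: int = 6

    def validate(self) -> None:
        if self.frag_min >= self.frag_max:
            raise ValueError("frag_min must be < frag_max")
        fracs = (self.cpg_level_island, self.cpg_level_open, self.cph_level,
                 self.beta_binomial_rho, self.dm_site_fraction,
                 self.dm_effect)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        d = self.stage_deltas
        if len(d) != 3 or not (d[0] >= d[1] >= d[2]):
            raise ValueError(
                "stage_deltas must be monotone non-increasing Pre->In->Post"
            )
        if min(self.n_chrom, self.chrom_length, self.n_genes,
               self.n_cgis, self.n_qtls) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class SimTruth:
    """Planted ground truth for the synthetic dataset."""

    cgi_intervals: dict = field(default_factory=dict)   # chrom -> [(s, e)]
    qtl_intervals: dict = field(default_factory=dict)
    genes: list = field(default_factory=list)           # GeneModel
    dm_sites: pd.DataFrame | None = None
    # columns: chrom, pos (1-based), context, comparison, effect (A - B)
    dm_regions: pd.DataFrame | None = None
    # columns: region_id, kind, chrom, start, end, comparison, effect


@dataclass
class SimData:
    """In-memory bundle: genome, annotations, sites and count frames."""

    config: SimConfig
    sequences: dict              # chrom -> str
    fragments: dict              # chrom -> [(s, e)]
    genes: list
    qtls: dict
    truth: SimTruth
    sites: pd.DataFrame          # chrom, pos, strand, context, cls, dinuc
    stage_probs: np.ndarray      # n_sites x 3 planted probabilities
    samples: pd.DataFrame        # name, stage, replicate

    def sample_frame(self, stage: str, replicate: int) -> pd.DataFrame:
        return simulate_counts(self, stage, replicate)


def msp1_digest(sequence: str, frag_min: int = 110,
                frag_max: int = 220) -> list:
    """In-silico MspI digest with size selection.

    MspI cuts C^CGG; fragments are the intervals between consecutive
    cut positions, retained when frag_min <= length <= frag_max.
    Returned 0-based half-open, sorted, non-overlapping.  End pieces
    (before the first / after the last cut) are discarded, as they
    are in a real library.
    """
    if not sequence:
        raise ValueError("empty sequence")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    if arr.size < 4:
        return []
    hit = (
        (arr[:-3] == ord("C")) & (arr[1:-2] == ord("C"))
        & (arr[2:-1] == ord("G")) & (arr[3:] == ord("G"))
    )
    cuts = np.nonzero(hit)[0] + 1  # cut between C and CGG
    if cuts.size < 2:
        return []
    starts, ends = cuts[:-1], cuts[1:]
    lengths = ends - starts
    keep = (lengths >= frag_min) & (lengths <= frag_max)
    return [(int(s), int(e)) for s, e in zip(starts[keep], ends[keep])]


def _random_sequence(rng, length, p_acgt):
    return rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p_acgt
    )


def _place_intervals(rng, n, lengths, chrom_length, margin, occupied):
    """Place n non-overlapping intervals of given lengths, away from
    ``occupied`` intervals; raises SimSizeError when space runs out."""
    placed = []
    taken = sorted(occupied)
    for i in range(n):
        length = int(lengths[i])
        for _ in range(200):
            s = int(rng.integers(margin, chrom_length - margin - length))
            e = s + length
            if all(e <= ts or s >= te for ts, te in taken):
                placed.append((s, e))
                taken.append((s, e))
                taken.sort()
                break
        else:
            raise SimSizeError(
                f"could not place interval {i + 1}/{n} of length {length}"
            )
    return placed


def generate_genome(config: SimConfig):
    """Build sequences, gene models, QTLs and the truth scaffold.

    Returns (sequences, genes, qtls, truth).  Island segments are
    CG-enriched (GC ~ 0.7, O/E ~ 1) against an AT-biased background
    (GC ~ 0.4) so the UCSC-style CGI criteria hold inside planted
    islands and fail outside.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 11])
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]

    def split(n):
        base, extra = divmod(n, len(chroms))
        return {c: base + (1 if i < extra else 0)
                for i, c in enumerate(chroms)}

    n_cgi = split(config.n_cgis)
    n_gene = split(config.n_genes)
    n_qtl = split(config.n_qtls)

    sequences, genes, qtls = {}, [], {}
    truth = SimTruth()
    for chrom in chroms:
        L = config.chrom_length
        arr = _random_sequence(rng, L, [0.30, 0.20, 0.20, 0.30])
        gene_lengths = rng.integers(4_000, 16_000, size=n_gene[chrom])
        bodies = _place_intervals(rng, n_gene[chrom], gene_lengths, L,
                                  margin=12_000, occupied=[])
        bodies.sort()
        chrom_genes = []
        for k, (s, e) in enumerate(bodies):
            strand = "+" if rng.integers(2) == 0 else "-"
            n_exon = int(rng.integers(2, 6))
            # carve exons from an even partition of the body
            edges = np.linspace(s, e, 2 * n_exon + 1).astype(int)
            exons = [(int(edges[2 * j]), int(edges[2 * j + 1]))
                     for j in range(n_exon)]
            chrom_genes.append(GeneModel(
                gene_id=f"{chrom}_g{k + 1}", chrom=chrom, strand=strand,
                start=s, end=e, exons=exons,
            ))
        genes.extend(chrom_genes)
        # islands: about half promoter-anchored (biased upstream of the
        # TSS, the usual location of mammalian promoter CGIs), the rest
        # placed randomly
        cgi_lengths = rng.integers(900, 1700, size=n_cgi[chrom])
        islands: list[tuple[int, int]] = []
        n_prom = min(n_cgi[chrom] // 2, len(chrom_genes))
        prom_genes = list(rng.choice(len(chrom_genes), size=n_prom,
                                     replace=False))
        for j, gi in enumerate(prom_genes):
            g = chrom_genes[gi]
            gl = int(cgi_lengths[j])
            up = int(0.8 * gl)
            if g.strand == "+":
                s = g.start - up
            else:
                s = g.end - (gl - up)
            s = max(0, min(s, L - gl))
            e = s + gl
            if all(e <= ts or s >= te for ts, te in islands):
                islands.append((s, e))
        n_random = n_cgi[chrom] - len(islands)
        if n_random > 0:
            islands.extend(_place_intervals(
                rng, n_random, cgi_lengths[len(islands):], L,
                margin=10_000, occupied=islands))
        for s, e in islands:
            arr[s:e] = _random_sequence(rng, e - s,
                                        [0.15, 0.35, 0.35, 0.15])
        islands.sort()
        q_lengths = rng.integers(100_000, 400_000, size=n_qtl[chrom])
        q_ivs = []
        for ql in q_lengths:
            s = int(rng.integers(0, max(1, L - int(ql))))
            q_ivs.append((s, s + int(ql)))
        qtls[chrom] = sorted(q_ivs)
        sequences[chrom] = arr.tobytes().decode("ascii")
        truth.cgi_intervals[chrom] = islands
    truth.qtl_intervals = qtls
    truth.genes = genes
    return sequences, genes, qtls, truth


def enumerate_sites(sequence: str, fragments) -> pd.DataFrame:
    """All cytosines (both strands) inside retained fragments.

    Returns a frame with 1-based ``pos``, ``strand``, ``context``
    ('CpG'/'CpH'), CGmap context class ('CG'/'CHG'/'CHH') and the
    strand-local dinucleotide.
    """
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    pad = np.full(arr.size + 4, ord("N"), dtype=np.uint8)
    pad[2:-2] = arr
    mask = np.zeros(arr.size, dtype=bool)
    for s, e in fragments:
        mask[s:e] = True
    C, G = ord("C"), ord("G")
    rows = []
    for strand in "+-":
        if strand == "+":
            here = (arr == C) & mask
            pos0 = np.nonzero(here)[0]
            nxt1 = pad[pos0 + 3]   # base at pos0+1
            nxt2 = pad[pos0 + 4]
        else:
            here = (arr == G) & mask
            pos0 = np.nonzero(here)[0]
            # strand-local "next" base is the complement of the
            # preceding reference base
            comp = np.full(256, ord("N"), dtype=np.uint8)
            for x, y in _COMPLEMENT.items():
                comp[ord(x)] = ord(y)
            nxt1 = comp[pad[pos0 + 1]]  # base at pos0-1 on the reference
            nxt2 = comp[pad[pos0]]      # base at pos0-2
        is_cg = nxt1 == G
        cls = np.where(is_cg, "CG", np.where(nxt2 == G, "CHG", "CHH"))
        dinuc = np.char.add("C", np.frombuffer(
            nxt1.tobytes(), dtype="S1").astype("U1"))
        rows.append(pd.DataFrame({
            "pos": pos0 + 1,
            "strand": strand,
            "context": np.where(is_cg, "CpG", "CpH"),
            "cls": cls,
            "dinuc": dinuc,
        }))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values("pos", kind="stable").reset_index(drop=True)


def _comp_index(name: str) -> tuple:
    i = _COMP_NAMES.index(name)
    return (_COMPS[i][0], _COMPS[i][1])


def simulate_methylome(config: SimConfig) -> SimData:
    """Generate genome, fragment-restricted sites, planted effects and
    the per-stage probability matrix; counts are drawn lazily per
    sample by :func:`simulate_counts`."""
    config.validate()
    sequences, genes, qtls, truth = generate_genome(config)
    fragments = {
        chrom: msp1_digest(seq, config.frag_min, config.frag_max)
        for chrom, seq in sequences.items()
    }
    site_frames = []
    for chrom in sorted(sequences):
        df = enumerate_sites(sequences[chrom], fragments[chrom])
        df.insert(0, "chrom", chrom)
        site_frames.append(df)
    sites = pd.concat(site_frames, ignore_index=True)

    # base level: bimodal CpG (island vs open sea), flat low CpH
    n = len(sites)
    base = np.full(n, config.cph_level)
    is_cpg = (sites["context"] == "CpG").to_numpy()
    base[is_cpg] = config.cpg_level_open
    from .intervals import MembershipIndex
    for chrom, ivs in truth.cgi_intervals.items():
        idx = MembershipIndex(ivs)
        in_chrom = (sites["chrom"] == chrom).to_numpy()
        pos0 = sites.loc[in_chrom, "pos"].to_numpy() - 1
        in_island = np.zeros(n, dtype=bool)
        in_island[in_chrom] = idx.contains(pos0)
        base[in_island & is_cpg] = config.cpg_level_island

    probs = np.clip(
        base[:, None] + np.asarray(config.stage_deltas)[None, :], 0.0, 1.0
    )
    probs0 = probs.copy()  # pre-planting baseline, for the truth record

    rng = np.random.default_rng([int(config.seed), 23])
    region_rows = []
    region_member = np.zeros(n, dtype=bool)
    # region-level planting: whole planted CGIs shifted in one stage
    if config.dm_region_count > 0 and config.dm_effect > 0:
        all_regions = [
            (chrom, s, e)
            for chrom in sorted(truth.cgi_intervals)
            for s, e in truth.cgi_intervals[chrom]
        ]
        k = min(config.dm_region_count, len(all_regions))
        pick = rng.choice(len(all_regions), size=k, replace=False)
        for r, ridx in enumerate(sorted(pick)):
            chrom, s, e = all_regions[ridx]
            comp = _COMP_NAMES[r % 3]
            ga, gb = _comp_index(comp)
            bi = STAGES.index(gb)
            in_r = (
                (sites["chrom"] == chrom).to_numpy()
                & (sites["pos"].to_numpy() - 1 >= s)
                & (sites["pos"].to_numpy() - 1 < e)
                & is_cpg
            )
            if not in_r.any():
                continue
            sign = 1.0 if base[in_r].mean() >= 0.5 else -1.0
            probs[in_r, bi] = np.clip(
                probs[in_r, bi] - sign * config.dm_effect, 0.0, 1.0
            )
            region_member |= in_r
            region_rows.append((f"dmr_{r + 1}", "CGI", chrom, s, e, comp,
                                sign * config.dm_effect))

    # site-level planting, outside planted regions
    if config.dm_site_fraction > 0 and config.dm_effect > 0:
        for ctx_mask in (is_cpg, ~is_cpg):
            pool = np.nonzero(ctx_mask & ~region_member)[0]
            k = int(round(config.dm_site_fraction * pool.size))
            if k == 0:
                continue
            chosen = rng.choice(pool, size=k, replace=False)
            comps = rng.integers(0, 3, size=k)
            signs = rng.choice([-1.0, 1.0], size=k)
            for s_idx, ci, sign in zip(chosen, comps, signs):
                b = base[s_idx]
                # keep the full effect representable after clipping
                if b - sign * config.dm_effect < 0 or \
                        b - sign * config.dm_effect > 1:
                    sign = -sign
                ga, gb = _COMPS[ci]
                bi = STAGES.index(gb)
                probs[s_idx, bi] = np.clip(
                    probs[s_idx, bi] - sign * config.dm_effect, 0.0, 1.0
                )

    # record realized per-comparison truth from the planted probabilities,
    # relative to the unplanted (stage-delta only) baseline
    frames = []
    for comp, (ga, gb) in zip(_COMP_NAMES, _COMPS):
        ai, bi = STAGES.index(ga), STAGES.index(gb)
        eff = probs[:, ai] - probs[:, bi]
        eff0 = probs0[:, ai] - probs0[:, bi]
        planted = np.abs(eff - eff0) > 1e-9
        frames.append(pd.DataFrame({
            "chrom": sites["chrom"].to_numpy()[planted],
            "pos": sites["pos"].to_numpy()[planted],
            "context": sites["context"].to_numpy()[planted],
            "comparison": comp,
            "effect": eff[planted],
        }))
    truth.dm_sites = pd.concat(frames, ignore_index=True)
    truth.dm_regions = pd.DataFrame(
        region_rows, columns=["region_id", "kind", "chrom", "start", "end",
                              "comparison", "effect"]
    )

    samples = pd.DataFrame([
        {"name": f"{stage}_{rep}", "stage": stage, "replicate": rep}
        for stage in STAGES for rep in (1, 2, 3)
    ])
    return SimData(config=config, sequences=sequences, fragments=fragments,
                   genes=genes, qtls=qtls, truth=truth, sites=sites,
                   stage_probs=probs, samples=samples)


def simulate_counts(sim: SimData, stage: str, replicate: int) -> pd.DataFrame:
    """Draw one sample's per-site counts (CGmap-shaped frame).

    Coverage ~ negative binomial; methylated reads ~ binomial with a
    per-replicate beta-perturbed probability.  Sites drawing zero
    coverage are omitted, as an aligner would omit them.
    """
    config = sim.config
    si = STAGES.index(stage)
    rng = np.random.default_rng(
        [int(config.seed), 101, si, int(replicate)]
    )
    n = len(sim.sites)
    mu = config.mean_coverage
    disp = config.coverage_dispersion
    if disp > 1e-9:
        lam = rng.gamma(shape=1.0 / disp, scale=mu * disp, size=n)
        total = rng.poisson(lam)
    else:
        total = rng.poisson(mu, size=n)
    p = sim.stage_probs[:, si].copy()
    rho = config.beta_binomial_rho
    if rho > 1e-9:
        interior = (p > 0) & (p < 1)
        a = p[interior] * (1 - rho) / rho
        b = (1 - p[interior]) * (1 - rho) / rho
        p[interior] = rng.beta(a, b)
    meth = rng.binomial(total, p)
    keep = total > 0
    df = sim.sites.loc[keep, ["chrom", "pos", "strand", "context",
                              "cls", "dinuc"]].copy()
    df["meth"] = meth[keep]
    df["total"] = total[keep]
    df["level"] = df["meth"] / df["total"]
    return df.reset_index(drop=True)


def simulate_sample_frames(sim: SimData) -> dict:
    """name -> CGmap-shaped frame for every sample in the design."""
    return {
        row["name"]: simulate_counts(sim, row["stage"], row["replicate"])
        for _, row in sim.samples.iterrows()
    }


def write_dataset(sim: SimData, outdir) -> dict:
    """Write genome FASTA, BED annotations, per-sample CGmap files and
    truth tables; returns the path map."""
    from pathlib import Path

    from . import io as rio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["genome"] = outdir / "genome.fa"
    rio.write_fasta(sim.sequences, paths["genome"])
    paths["genes"] = outdir / "genes.bed"
    rio.write_gene_bed12(sim.genes, paths["genes"])
    paths["qtls"] = outdir / "qtls.bed"
    rio.write_bed(sim.qtls, paths["qtls"], name="qtl")
    paths["cgis"] = outdir / "truth_cgi.bed"
    rio.write_bed(sim.truth.cgi_intervals, paths["cgis"], name="island")
    for _, row in sim.samples.iterrows():
        frame = simulate_counts(sim, row["stage"], row["replicate"])
        p = outdir / f"{row['name']}.cgmap.tsv"
        rio.write_cgmap(frame, p)
        paths[row["name"]] = p
    paths["truth_dm_sites"] = outdir / "truth_dm_sites.tsv"
    sim.truth.dm_sites.to_csv(paths["truth_dm_sites"], sep="\t", index=False)
    paths["truth_dm_regions"] = outdir / "truth_dm_regions.tsv"
    sim.truth.dm_regions.to_csv(paths["truth_dm_regions"], sep="\t",
                                index=False)
    sample_rows = sim.samples.copy()
    sample_rows["path"] = [str(paths[n]) for n in sample_rows["name"]]
    paths["sample_table"] = outdir / "samples.tsv"
    sample_rows.to_csv(paths["sample_table"], sep="\t", index=False)
    return paths


def config_from_dict(d: dict) -> SimConfig:
    known = {f.name for f in dataclasses.fields(SimConfig)}
    bad = set(d) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    if "stage_deltas" in d:
        d = dict(d, stage_deltas=tuple(d["stage_deltas"]))
    return SimConfig(**d)
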