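# Methods

`rrbskit` re-implements, as a tested library, the downstream analysis
of a reduced representation bisulfite sequencing (RRBS) experiment
comparing hypothalamic methylomes across three pubertal stages (Pre,
In, Post) in gilts, with three biological replicates per stage.  The
upstream steps — read trimming, bisulfite alignment, methylation
calling — are out of scope; the pipeline starts from per-cytosine
count files (CGmap dialect) and genome/annotation inputs, or from the
bundled synthetic generator.

## Site model and filtering

Every cytosine is a site; the two strands of a CpG dinucleotide are
two distinct sites, matching per-cytosine caller output.  A site's
context is CpG when the next base on the same strand is G, otherwise
CpH (H = A, C or T).  Sites are retained when covered by at least
`min_cov = 5` reads in **every** sample (the co-existence rule); the
retained set with its count matrix is the `SiteMatrix`.

Level arithmetic, in order of aggregation:

* site level = methylated / total reads;
* group level = unweighted mean of the replicate site levels — not the
  pooled-read ratio.  The two differ when coverages differ (e.g.
  replicates 1/100, 9/10, 5/10: mean 0.47, pooled 0.125);
* region level = mean of group levels over sites in the region.

Pooled-read ratios appear in exactly one place: inside the site-level
Fisher test, where a 2×2 table of reads is the test's sampling unit.

## CpG islands, shores, shelves

Islands follow the classic composition criteria: length > 200 bp
(strict, i.e. ≥ 201), G+C fraction > 0.5, observed/expected CpG ratio
> 0.6, with expected CpG = (#C × #G) / length.  Detection slides a
200 bp window by 1 bp, merges qualifying windows, and replaces each
merged candidate with its longest sub-segment that still meets all
three criteria (exhaustive within the candidate).  The candidate is
*not* padded: against a moderately GC-rich background the criteria
are weak enough that a maximal qualifying segment can legitimately
extend hundreds of bases past a CG-dense core by dilution, so padding
systematically over-extends calls.  Runs of N break candidates; N
counts toward segment length but not composition.  Exactness relative
to an exhaustive-substring search is asserted on ≤ 2 kb test inputs;
on long sequences the window scan is a heuristic in exactly the way
classical island finders are.

Shores are the ±2 kb flanks outside islands; shelves the next ±2 kb,
with precedence island > shore > shelf and clipping to chromosome
bounds.  Islands ∪ shores ∪ shelves ∪ open sea partitions the genome.

In a real analysis islands are typically supplied as a downloaded BED
(the annotator accepts one); the caller exists so synthetic genomes
are self-contained.

## Genic annotation

Five features partition the genome: upstream (5 kb before the TSS,
strand-aware), exon, intron (gene body minus exons), downstream (5 kb
past the TES, strand-aware), intergenic.  Overlaps are resolved by the
precedence exon > intron > upstream > downstream > intergenic, which
makes the five per-feature site counts sum exactly to the total — the
property the published count tables exhibit.  Whether the original
flank definition was strand-aware is not documented; strand-aware is
the standard TSS-anchored reading and is what the generator's truth
uses.  For "DM-regarding-gene" rules a gene's span is its body ± 5 kb;
a site may belong to several genes' spans.  QTL intervals are merged
before membership tests so overlapping QTLs count a site once.

## Differential methylation

Comparisons: Pre vs In, In vs Post, Pre vs Post.

**Site level (DMC/DMH).**  Reads are pooled across the three
replicates of each group; the 2×2 table
[[meth_A, unmeth_A], [meth_B, unmeth_B]] gets a two-tail Fisher's
exact test (sum of hypergeometric probabilities ≤ that of the observed
table).  P-values are Benjamini–Hochberg adjusted within each
context × comparison stratum.  A site is DM iff q ≤ 0.05 (inclusive)
**and** |Δ| > 0.20 (strict), where Δ is the pooled-level difference
A − B; polarity (hyper-methylated in A or B) follows the sign of Δ.
Pooling replicates is the only way a 2×2 Fisher applies to a
3-vs-3 design; it treats reads as exchangeable within a group, so it
is anticonservative when between-replicate variance is large (see the
generator's `beta_binomial_rho` below).  At scale the test runs
through a vectorized hypergeometric-summation path that matches the
scalar routine (and an exhaustive enumeration oracle) to 1e−12.

**Region level (DMI/DMG).**  Regions are CpG islands or gene bodies
± 5 kb.  A region is tested only when it contains ≥ 20 sites of the
tested context.  Each replicate contributes its mean site level in the
region; groups are compared with the classical pooled-variance
two-sample Student's t (df = 4 for 3 vs 3; Welch available behind a
flag), BH-adjusted within kind × context × comparison, DM iff
q ≤ 0.05.  Degenerate zero-variance inputs: equal means → p = 1,
unequal means → p = 0.

**Gene sets.**  DMC/DMH-regarding genes contain ≥ 1 DM site in their
extended span; DMI-regarding genes overlap ≥ 1 DM island by ≥ 1 bp.

## Enrichment

Each feature class (island, shore, shelf, the five genic features,
QTL) is tested against its complement with a two-tail Fisher on
[[dm_in, dm_out], [nondm_in, nondm_out]].  The reported enrichment is
the proportion ratio (dm_in/dm_total)/(sites_in/sites_total); this
reading exactly reproduces all six published QTL-row enrichment
values from the published counts, which is why it is the primary
statistic (the sample odds ratio is emitted alongside).  The published
enrichment values for some island/exon/intron rows are reproduced by
neither the proportion ratio nor the odds ratio computed from the
printed counts alone, so those rows are treated as worked examples
for counts only, not for the enrichment column.

## Synthetic methylome generator

The generator exists so every downstream stage can be tested against
known truth without any download.  What it emulates, and the defaults:

* **Genome**: `n_chrom = 2` chromosomes of 3 Mb, AT-biased background
  (GC ≈ 0.40).  `n_cgis = 80` islands of 0.9–1.7 kb with GC ≈ 0.70 and
  O/E ≈ 1, about half anchored at gene TSSs (biased 80% upstream of
  the TSS, where mammalian promoter CGIs sit) and half placed
  randomly; `n_genes = 60` non-overlapping genes of 4–16 kb with 2–5
  exons and random strand; `n_qtls = 8` intervals of 0.1–0.4 Mb.
* **RRBS coverage restriction**: an in-silico MspI digest (cut C^CGG)
  with 110–220 bp size selection; only cytosines inside retained
  fragments are observed.  With these compositions islands are
  roughly ten-fold covered relative to background, the defining
  enrichment of RRBS, and the default genome yields ≈ 2.7 × 10⁴ CpG
  and ≈ 8.7 × 10⁴ CpH sites (the real experiment's 1.3 M/5.9 M totals
  are deliberately not matched).
* **Methylation levels**: bimodal CpG base level — 0.10 inside truth
  islands, 0.68 in open sea — giving a genome average near the
  published ≈ 53%; flat CpH level 0.007 (≈ 0.7%).  Stage deltas
  (0, −0.006, −0.012) impose a small monotone Pre > In > Post
  decrease.  The published real-data decrease (53.57 → 53.50 →
  53.01%) is smaller than the Monte-Carlo resolution of a genome this
  size, so the default is chosen to make the ordering a property of
  the conditions rather than of one lucky draw (≈ 8 standard errors
  at the default site count).
* **Counts**: per-site coverage is negative binomial
  (gamma–Poisson, mean 30, dispersion 0.3) independently per
  site and sample; methylated reads are binomial with a per-replicate
  probability drawn from a beta distribution with mean equal to the
  site's stage probability and correlation parameter
  `beta_binomial_rho = 0.005`.  The rho term exists to give the
  region-level t test genuine between-replicate variance.  It is kept
  small on purpose: the replicates it emulates are littermate gilts
  reared identically, and the site-level caller pools reads across
  replicates, a design that presumes small between-replicate
  variance — at rho ≈ 0.02 the pooled Fisher test's realized
  false-discovery proportion against planted truth degrades to ≈ 0.27,
  while at 0.005 it stays below 0.1.  This is a documented limitation
  of pooling-based callers, not of the simulation.
* **Planted differentials**: a fraction `dm_site_fraction = 0.05` of
  sites per context receives a ± `dm_effect = 0.5` shift applied to
  the later stage of one randomly chosen comparison (sign flipped
  when clipping to [0, 1] would truncate the effect), and
  `dm_region_count = 6` whole islands are shifted the same way.
  Because the three stages share members across comparisons, an
  effect planted for one comparison can also separate another pair of
  stages; the recorded truth therefore stores the *realized*
  per-comparison probability difference, post-clipping, for every
  perturbed site.
* **Determinism**: all randomness flows from `SimConfig.seed` through
  independent named streams (genome, planting, each sample), so a
  configuration reproduces byte-identical output files.

What the generator does **not** emulate: read-level artifacts
(bisulfite conversion failure, mapping bias, SNP-induced miscalls),
fragment-end coverage structure, correlated methylation of
neighbouring sites, and chromosome-scale features such as the
published telomeric DM enrichment.  Passing tests therefore validate
the arithmetic and the calling rules, and the statistical behaviour
under beta-binomial noise — not robustness to alignment-level error
modes in real libraries.

## Numerical choices

* Two-sided Fisher ties: tables with probability ≤ observed × (1 +
  1e−7) are summed, the convention of the scipy routine the scalar
  path delegates to; the vectorized path reproduces it to 1e−12.
* Bin assignment uses half-open bins with floor semantics; gene and
  island flank bins are fixed-width (250 bp and 100 bp); body bins are
  length/40 (genes) or length/20 (islands); minus-strand genes are
  reflected so bin 1 is always 5′-most; regions shorter than their
  body bin count are skipped with a warning; flank bins that run off a
  chromosome end simply collect no sites.
* Window tracks tile from coordinate 0 with a fixed width (1 Mb
  default), so all tracks of one genome share a grid; intervals are
  counted by midpoint.
* BH adjustment delegates to the standard step-up implementation and
  is checked against a naive sort-and-scan oracle.
* Thresholds are configuration, not constants: `min_cov = 5`,
  `delta_min = 0.20` (strict), `q_max = 0.05` (inclusive),
  `min_sites = 20`, flanks 5 kb (genes) and 2 kb (islands).

## Known limitations

* The site-level caller inherits the pooling fallacy: with strongly
  overdispersed replicates its FDR control is nominal-only.  The
  honest fix (beta-binomial or logistic site models) is explicitly
  out of scope.
* The island caller guarantees exactness only at oracle-checkable
  scales; merged-candidate trimming is exhaustive per candidate but
  the window scan itself can miss qualifying segments that contain no
  qualifying 200 bp window.
* Real-data headline numbers (1.3 M retained CpGs, stage means of
  53.5%, DM counts near 10⁵) require the original sequencing deposit
  and are not reproducible from this repository; the package
  reproduces their arithmetic relationships and the qualitative
  patterns on synthetic data.
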