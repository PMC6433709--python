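"""Published reference counts for worked examples.

Site and differential-methylation counts printed by the porcine
hypothalamus RRBS study this pipeline re-implements (three pubertal
stages, three replicates each, Sscrofa 11.1).  They are inputs for
arithmetic checks — percentage-of-detected-sites and QTL relative
enrichment — not outputs of this package.

Keys of the per-feature tables: ``detected`` is the number of retained
sites falling in the feature; each comparison maps to the number of DM
sites in the feature.
"""

COMPARISONS = ("PreVsIn", "InVsPost", "PreVsPost")

# CpG context: 1,320,853 detected sites
CPG_TABLE = {
    "Total": {"detected": 1_320_853,
              "PreVsIn": 85_726, "InVsPost": 92_914, "PreVsPost": 100_421},
    "CGI": {"detected": 628_028,
            "PreVsIn": 26_422, "InVsPost": 28_834, "PreVsPost": 29_862},
    "CGI shores": {"detected": 259_488,
                   "PreVsIn": 20_572, "InVsPost": 22_559,
                   "PreVsPost": 25_014},
    "CGI shelves": {"detected": 86_548,
                    "PreVsIn": 7_621, "InVsPost": 8_489, "PreVsPost": 9_131},
    "Upstream": {"detected": 220_380,
                 "PreVsIn": 7_557, "InVsPost": 7_797, "PreVsPost": 8_716},
    "Exon": {"detected": 290_064,
             "PreVsIn": 13_384, "InVsPost": 14_895, "PreVsPost": 15_729},
    "Intron": {"detected": 419_870,
               "PreVsIn": 31_840, "InVsPost": 35_490, "PreVsPost": 38_123},
    "Downstream": {"detected": 75_956,
                   "PreVsIn": 5_644, "InVsPost": 5_912, "PreVsPost": 6_714},
    "Intergenic": {"detected": 314_583,
                   "PreVsIn": 27_301, "InVsPost": 28_820,
                   "PreVsPost": 31_139},
    "QTL": {"detected": 57_332,
            "PreVsIn": 3_930, "InVsPost": 4_387, "PreVsPost": 4_691},
}

# CpH context: 5,884,256 detected sites
CPH_TABLE = {
    "Total": {"detected": 5_884_256,
              "PreVsIn": 15_940, "InVsPost": 14_804, "PreVsPost": 16_893},
    "CGI": {"detected": 1_611_528,
            "PreVsIn": 2_686, "InVsPost": 2_456, "PreVsPost": 2_992},
    "CGI shores": {"detected": 1_528_834,
                   "PreVsIn": 4_378, "InVsPost": 4_102, "PreVsPost": 4_620},
    "CGI shelves": {"detected": 507_135,
                    "PreVsIn": 1_620, "InVsPost": 1_518, "PreVsPost": 1_788},
    "Upstream": {"detected": 773_667,
                 "PreVsIn": 1_099, "InVsPost": 997, "PreVsPost": 1_281},
    "Exon": {"detected": 944_488,
             "PreVsIn": 1_538, "InVsPost": 1_387, "PreVsPost": 1_690},
    "Intron": {"detected": 2_130_322,
               "PreVsIn": 6_661, "InVsPost": 6_251, "PreVsPost": 7_034},
    "Downstream": {"detected": 371_205,
                   "PreVsIn": 1_063, "InVsPost": 876, "PreVsPost": 1_102},
    "Intergenic": {"detected": 1_664_574,
                   "PreVsIn": 5_579, "InVsPost": 5_293, "PreVsPost": 5_786},
    "QTL": {"detected": 251_222,
            "PreVsIn": 796, "InVsPost": 788, "PreVsPost": 826},
}

GENIC_FEATURES = ("Upstream", "Exon", "Intron", "Downstream", "Intergenic")


def dm_percentages(table: dict) -> dict:
    """DM sites as a percentage of detected sites, per comparison."""
    total = table["Total"]
    return {c: 100.0 * total[c] / total["detected"] for c in COMPARISONS}


def genic_partition_total(table: dict) -> int:
    """Sum of the five genic-feature detected-site counts (should equal
    the detected total when the genic labels partition all sites)."""
    return sum(table[f]["detected"] for f in GENIC_FEATURES)
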