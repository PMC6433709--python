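"""Feature enrichment of differentially methylated sites.

Each feature class (CGI, shores, shelves, the five genic features,
QTL) is tested against its complement with a two-tail Fisher's exact
test on [[dm_in, dm_out], [nondm_in, nondm_out]].  The reported
"relative enrichment" is the proportion ratio

    (dm_in / dm_total) / (sites_in / sites_total),

with the sample odds ratio emitted alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import fisher_exact_two_tail


@dataclass
class EnrichmentResult:
    feature: str
    comparison: str
    context: str
    dm_in: int
    dm_total: int
    sites_in: int
    sites_total: int
    relative_enrichment: float
    odds_ratio: float
    p: float
    defined: bool = True


def enrichment_from_counts(dm_in: int, dm_total: int, sites_in: int,
                           sites_total: int, feature: str = "",
                           comparison: str = "", context: str = "",
                           ) -> EnrichmentResult:
    """Enrichment statistics from the four counts of one feature row."""
    if not (0 <= dm_in <= min(dm_total, sites_in)):
        raise ValueError("inconsistent counts")
    if dm_total == 0 or sites_in == 0 or sites_in == sites_total:
        return EnrichmentResult(feature, comparison, context, dm_in,
                                dm_total, sites_in, sites_total,
                                np.nan, np.nan, np.nan, defined=False)
    dm_out = dm_total - dm_in
    nondm_in = sites_in - dm_in
    nondm_out = sites_total - sites_in - dm_out
    rel = (dm_in / dm_total) / (sites_in / sites_total)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (dm_in * nondm_out) / (dm_out * nondm_in) \
            if dm_out * nondm_in > 0 else np.inf
    p = fisher_exact_two_tail(dm_in, dm_out, nondm_in, nondm_out)
    return EnrichmentResult(feature, comparison, context, dm_in, dm_total,
                            sites_in, sites_total, rel, float(odds), p)


def feature_enrichment(dm_mask, feature_mask, feature: str = "",
                       comparison: str = "", context: str = "",
                       ) -> EnrichmentResult:
    """Enrichment of DM sites in one feature class.

    ``dm_mask`` and ``feature_mask`` are parallel booleans over all
    tested sites.
    """
    dm_mask = np.asarray(dm_mask, dtype=bool)
    feature_mask = np.asarray(feature_mask, dtype=bool)
    if dm_mask.shape != feature_mask.shape:
        raise ValueError("mask length mismatch")
    return enrichment_from_counts(
        int((dm_mask & feature_mask).sum()), int(dm_mask.sum()),
        int(feature_mask.sum()), int(dm_mask.size),
        feature, comparison, context,
    )


def enrichment_table(annotated: pd.DataFrame, dm_by_comparison: dict,
                     context: str) -> pd.DataFrame:
    """One row per feature class x comparison, Table-style.

    ``annotated`` must carry ``genic``, ``cgi`` and ``qtl`` columns for
    every tested site of ``context``; ``dm_by_comparison`` maps
    comparison name -> boolean DM mask aligned with ``annotated``.
    """
    features = {
        "CGI": (annotated["cgi"] == "island").to_numpy(),
        "CGI shores": (annotated["cgi"] == "shore").to_numpy(),
        "CGI shelves": (annotated["cgi"] == "shelf").to_numpy(),
        "Upstream": (annotated["genic"] == "upstream").to_numpy(),
        "Exon": (annotated["genic"] == "exon").to_numpy(),
        "Intron": (annotated["genic"] == "intron").to_numpy(),
        "Downstream": (annotated["genic"] == "downstream").to_numpy(),
        "Intergenic": (annotated["genic"] == "intergenic").to_numpy(),
        "QTL": annotated["qtl"].to_numpy(),
    }
    rows = []
    for feat, mask in features.items():
        for comp, dm in dm_by_comparison.items():
            r = feature_enrichment(dm, mask, feat, comp, context)
            rows.append(r)
    return pd.DataFrame([vars(r) for r in rows])


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (report display)."""
    factor = 10 ** decimals
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


def enrichment_report(table: pd.DataFrame) -> pd.DataFrame:
    """Wide report: one row per feature, per-comparison DM count,
    enrichment (2 d.p., half-up) and p."""
    out = []
    for feat, sub in table.groupby("feature", sort=False):
        row = {"feature": feat, "detected_sites": int(sub["sites_in"].iloc[0])}
        for _, r in sub.iterrows():
            c = r["comparison"]
            row[f"{c}_n"] = int(r["dm_in"])
            row[f"{c}_enrichment"] = (
                round_half_up(r["relative_enrichment"])
                if r["defined"] else np.nan
            )
            row[f"{c}_p"] = r["p"]
        out.append(row)
    return pd.DataFrame(out)
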