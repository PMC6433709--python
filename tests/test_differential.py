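"""Site- and region-level differential methylation calling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rrbskit.annotate import GeneModel
from rrbskit.differential import (Comparison, bh_fdr, dm_regarding_genes,
                                  dm_region_test, dm_site_test,
                                  dmi_regarding_genes, fisher_exact_two_tail,
                                  fisher_exact_two_tail_many,
                                  student_t_two_sample)

from .conftest import make_matrix
from .oracles import bh_adjust, fisher_two_tail


class TestFisher:
    def test_extreme_table_equals_enumeration(self):
        # [[20,0],[0,20]]: only the two extreme tables are as unlikely
        want = 2 / math.comb(40, 20)
        assert fisher_exact_two_tail(20, 0, 0, 20) == \
            pytest.approx(want, rel=1e-9)

    def test_balanced_table_is_one(self):
        assert fisher_exact_two_tail(5, 5, 5, 5) == 1.0

    def test_empty_margin_convention(self):
        assert fisher_exact_two_tail(0, 0, 3, 4) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_tail(-1, 2, 3, 4)

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        tables = rng.integers(0, 15, size=(500, 4))
        p_vec = fisher_exact_two_tail_many(*tables.T)
        for (a, b, c, d), p in zip(tables, p_vec):
            want = fisher_two_tail(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(want, abs=1e-12)

    def test_scalar_and_vectorized_agree(self):
        rng = np.random.default_rng(1)
        tables = rng.integers(0, 40, size=(100, 4))
        p_vec = fisher_exact_two_tail_many(*tables.T)
        for (a, b, c, d), p in zip(tables, p_vec):
            assert p == pytest.approx(
                fisher_exact_two_tail(int(a), int(b), int(c), int(d)),
                abs=1e-10)


class TestBhFdr:
    def test_stepup_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03] * 3)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_empty_input(self):
        assert len(bh_fdr([])) == 0

    def test_matches_sort_and_scan_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 200)))
            assert bh_fdr(p) == pytest.approx(bh_adjust(list(p)), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def _matrix_from_pools(pool_a, pool_b):
    """One CpG site whose group pools equal the given (meth, total)."""
    def split(m, t):
        base_t, rem_t = divmod(t, 3)
        totals = [base_t + (1 if i < rem_t else 0) for i in range(3)]
        meths = []
        left = m
        for tt in totals:
            take = min(left, tt)
            meths.append(take)
            left -= take
        return list(zip(meths, totals))

    counts = split(*pool_a) + split(*pool_b) + split(*pool_b)
    return make_matrix([("c", 100, "+", "CpG")], [counts])


class TestDmSiteTest:
    def test_total_difference_called_hyper_in_a(self):
        mat = _matrix_from_pools((60, 60), (0, 60))
        res = dm_site_test(mat, "PreVsIn")
        row = res.iloc[0]
        assert row["is_dm"] and row["polarity"] == "hyper_in_a"
        assert row["delta"] == pytest.approx(1.0)
        assert row["q"] < 1e-20

    def test_small_delta_never_dm(self):
        mat = _matrix_from_pools((550, 1000), (450, 1000))
        res = dm_site_test(mat, "PreVsIn")
        row = res.iloc[0]
        assert row["delta"] == pytest.approx(0.10)
        assert row["p"] < 0.05 and not row["is_dm"]

    def test_delta_exactly_20_percent_not_dm(self):
        mat = _matrix_from_pools((700, 1000), (500, 1000))
        res = dm_site_test(mat, "PreVsIn")
        row = res.iloc[0]
        assert row["delta"] == pytest.approx(0.20)
        assert row["q"] <= 0.05 and not row["is_dm"]

    def test_group_swap_symmetry(self, small_matrix):
        res = dm_site_test(small_matrix, "PreVsIn")
        swapped_meta = small_matrix.samples.copy()
        swapped_meta["stage"] = swapped_meta["stage"].map(
            {"Pre": "In", "In": "Pre", "Post": "Post"})
        from rrbskit.core import SiteMatrix
        swapped = SiteMatrix(small_matrix.sites, small_matrix.meth,
                             small_matrix.total, swapped_meta)
        res2 = dm_site_test(swapped, "PreVsIn")
        assert np.allclose(res["delta"], -res2["delta"])
        assert np.allclose(res["p"], res2["p"])
        assert np.allclose(res["q"], res2["q"])
        flip = {"hyper_in_a": "hyper_in_b", "hyper_in_b": "hyper_in_a",
                "none": "none"}
        assert list(res2["polarity"]) == [flip[x] for x in res["polarity"]]

    def test_comparison_requires_distinct_groups(self):
        with pytest.raises(ValueError):
            Comparison("bad", "Pre", "Pre")


class TestStudentT:
    def test_identical_groups_p_one(self):
        t, p = student_t_two_sample([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert (t, p) == (0.0, 1.0)

    def test_separated_groups_significant(self):
        a = [0.8, 0.82, 0.81]
        b = [0.2, 0.22, 0.21]
        t, p = student_t_two_sample(a, b)
        # pooled-variance oracle, df = 4
        ma, mb = np.mean(a), np.mean(b)
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t_want = (ma - mb) / math.sqrt(sp2 * (2 / 3))
        p_want = 2 * stats.t.sf(abs(t_want), df=4)
        assert t == pytest.approx(t_want)
        assert p == pytest.approx(p_want) and p < 0.001

    def test_zero_variance_unequal_means(self):
        _, p = student_t_two_sample([0.5] * 3, [0.6] * 3)
        assert p == 0.0


class TestDmRegionTest:
    def _matrix(self, n_sites, level_a, level_b, cov=50):
        rows = [("c", 100 + 10 * i, "+", "CpG") for i in range(n_sites)]
        counts = []
        for _ in range(n_sites):
            per = [(round(level_a * cov), cov)] * 3 \
                + [(round(level_b * cov), cov)] * 3 \
                + [(round(level_b * cov), cov)] * 3
            counts.append(per)
        return make_matrix(rows, counts)

    def test_region_under_20_sites_untested(self):
        mat = self._matrix(19, 0.9, 0.1)
        res = dm_region_test([("r1", "CGI", "c", 0, 10_000)], mat, "PreVsIn")
        row = res.iloc[0]
        assert not row["tested"] and not row["is_dm"]
        assert np.isnan(row["p"])

    def test_identical_groups_not_dm(self):
        mat = self._matrix(25, 0.5, 0.5)
        res = dm_region_test([("r1", "CGI", "c", 0, 10_000)], mat, "PreVsIn")
        row = res.iloc[0]
        assert row["tested"] and not row["is_dm"]

    def test_planted_regions_recovered(self, default_sim, default_matrix):
        regions = [
            (f"cgi_{i}", "CGI", c, s, e)
            for i, (c, s, e) in enumerate(
                (c, s, e) for c in sorted(default_sim.truth.cgi_intervals)
                for s, e in default_sim.truth.cgi_intervals[c])
        ]
        planted = default_sim.truth.dm_regions
        for comp in ("PreVsIn", "InVsPost", "PreVsPost"):
            res = dm_region_test(regions, default_matrix, comp)
            called = set(zip(res.loc[res["is_dm"], "chrom"],
                             res.loc[res["is_dm"], "start"]))
            want = planted[planted["comparison"] == comp]
            assert set(zip(want["chrom"], want["start"])) <= called


class TestDmRegardingGenes:
    def _genes(self):
        return [
            GeneModel("gA", "c", "+", 20_000, 30_000, [(20_000, 24_000)]),
            GeneModel("gB", "c", "+", 60_000, 70_000, [(60_000, 64_000)]),
        ]

    def test_site_in_downstream_flank_counts(self):
        from rrbskit.annotate import FeatureIndex
        dm = pd.DataFrame({"chrom": ["c"], "pos": [33_000],
                           "is_dm": [True]})
        got = dm_regarding_genes(dm, FeatureIndex(self._genes()))
        assert got == {"gA"}

    def test_isolated_site_contributes_nothing(self):
        from rrbskit.annotate import FeatureIndex
        dm = pd.DataFrame({"chrom": ["c"], "pos": [45_000],
                           "is_dm": [True]})
        assert dm_regarding_genes(dm, FeatureIndex(self._genes())) == set()

    def test_matches_bruteforce(self, small_sim):
        from rrbskit.annotate import FeatureIndex
        rng = np.random.default_rng(5)
        pos = rng.integers(1, 400_001, size=200)
        dm = pd.DataFrame({"chrom": "chr1", "pos": pos, "is_dm": True})
        got = dm_regarding_genes(dm, FeatureIndex(small_sim.genes))
        want = {g.gene_id for g in small_sim.genes
                if any(g.start - 5_000 <= p - 1 < g.end + 5_000
                       for p in pos)}
        assert got == want

    def test_dmi_straddling_flank_boundary_counts(self):
        dmis = pd.DataFrame({
            "chrom": ["c", "c"],
            "start": [14_500, 45_000],
            "end": [15_500, 46_000],
            "is_dm": [True, True],
        })
        got = dmi_regarding_genes(dmis, self._genes())
        assert got == {"gA"}  # first DMI overlaps gA's upstream flank edge
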