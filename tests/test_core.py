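"""Site matrix filtering, level arithmetic, profiles and windows."""

import numpy as np
import pandas as pd
import pytest

from rrbskit.annotate import GeneModel
from rrbskit.core import (SiteMatrix, binned_profile, group_level,
                          load_and_filter, pearson, region_level, site_level,
                          window_track)

from .conftest import make_matrix
from .oracles import pearson_r


def _frames_from_counts(per_sample):
    """per_sample: name -> list of (chrom, pos, meth, total)."""
    out = {}
    for name, rows in per_sample.items():
        out[name] = pd.DataFrame(
            [(c, p, "+", "CpG", "CG", m, t) for c, p, m, t in rows],
            columns=["chrom", "pos", "strand", "context", "dinuc",
                     "meth", "total"],
        )
    return out


META3 = pd.DataFrame({
    "name": ["Pre_1", "In_1", "Post_1"],
    "stage": ["Pre", "In", "Post"],
    "replicate": [1, 1, 1],
})


class TestLoadAndFilter:
    def test_coverage_boundary_at_five(self):
        frames = _frames_from_counts({
            "Pre_1": [("c", 10, 3, 5), ("c", 20, 2, 4)],
            "In_1": [("c", 10, 1, 5), ("c", 20, 2, 5)],
            "Post_1": [("c", 10, 0, 9), ("c", 20, 1, 5)],
        })
        mat = load_and_filter(frames, META3)
        assert list(mat.sites["pos"]) == [10]  # pos 20 has one total of 4

    def test_site_absent_from_one_sample_dropped(self):
        frames = _frames_from_counts({
            "Pre_1": [("c", 10, 3, 6), ("c", 20, 2, 6)],
            "In_1": [("c", 10, 1, 6)],
            "Post_1": [("c", 10, 0, 9), ("c", 20, 1, 6)],
        })
        mat = load_and_filter(frames, META3)
        assert list(mat.sites["pos"]) == [10]

    def test_duplicate_site_rejected(self):
        frames = _frames_from_counts({
            "Pre_1": [("c", 10, 3, 6), ("c", 10, 2, 6)],
            "In_1": [("c", 10, 1, 6)],
            "Post_1": [("c", 10, 0, 9)],
        })
        with pytest.raises(ValueError, match="duplicate"):
            load_and_filter(frames, META3)

    def test_matches_bruteforce_intersection(self):
        rng = np.random.default_rng(3)
        names = ["Pre_1", "In_1", "Post_1"]
        per = {}
        all_pos = rng.choice(500, size=60, replace=False) + 1
        for name in names:
            keep = rng.random(60) < 0.8
            totals = rng.integers(0, 12, size=60)
            per[name] = [("c", int(p), int(min(t, rng.integers(0, t + 1))), int(t))
                         for p, k, t in zip(all_pos, keep, totals) if k]
        frames = _frames_from_counts(per)
        mat = load_and_filter(frames, META3)
        # naive oracle
        want = []
        maps = {n: {p: t for _, p, _, t in rows} for n, rows in per.items()}
        for p in sorted(all_pos):
            if all(p in maps[n] and maps[n][p] >= 5 for n in names):
                want.append(p)
        assert list(mat.sites["pos"]) == want

    def test_raising_min_cov_never_adds_sites(self):
        rng = np.random.default_rng(4)
        per = {n: [("c", int(p), 0, int(rng.integers(0, 15)))
                   for p in range(1, 80)]
               for n in ["Pre_1", "In_1", "Post_1"]}
        frames = _frames_from_counts(per)
        prev = None
        for cov in (1, 3, 5, 8):
            got = set(load_and_filter(frames, META3,
                                      min_cov=cov).sites["pos"])
            if prev is not None:
                assert got <= prev
            prev = got


class TestLevels:
    def test_site_level_examples(self):
        assert site_level(3, 5) == 0.6
        assert site_level(0, 7) == 0.0
        assert site_level(7, 7) == 1.0

    def test_site_level_errors(self):
        with pytest.raises(ValueError):
            site_level(1, 0)
        with pytest.raises(ValueError):
            site_level(8, 7)

    def test_group_level_is_mean_of_replicates(self):
        assert group_level([0.2, 0.4, 0.6]) == pytest.approx(0.4)
        assert group_level([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_group_level_differs_from_pooled_ratio(self):
        # replicate ratios 1/100, 9/10, 5/10
        levels = [1 / 100, 9 / 10, 5 / 10]
        assert group_level(levels) == pytest.approx(0.47, abs=0.005)
        pooled = (1 + 9 + 5) / (100 + 10 + 10)
        assert pooled == pytest.approx(0.125)
        assert abs(group_level(levels) - pooled) > 0.3

    def test_region_level_mean_and_empty(self):
        mat = make_matrix(
            [("c", 100, "+", "CpG"), ("c", 200, "+", "CpG")],
            [[(1, 10)] * 9, [(3, 10)] * 9],
        )
        level, n = region_level(("c", 0, 300), mat, "CpG", "Pre")
        assert (level, n) == (pytest.approx(0.2), 2)
        level, n = region_level(("c", 500, 600), mat, "CpG", "Pre")
        assert level is None and n == 0


class TestBinnedProfile:
    def test_body_bin_width_is_length_over_40(self):
        g = GeneModel("g", "c", "+", 10_000, 14_000, [(10_000, 14_000)])
        # site in 1-based 10_101 -> 0-based 10_100 -> body bin 2 (100 bp bins)
        mat = make_matrix([("c", 10_101, "+", "CpG")], [[(5, 10)] * 9])
        prof = binned_profile([g], mat, "gene", "Pre").table
        assert prof["n"].sum() == 1
        assert int(prof.loc[prof["n"] > 0, "bin"].iloc[0]) == 22  # 20 up + 2

    def test_minus_strand_site_before_tss_hits_last_upstream_bin(self):
        g = GeneModel("g", "c", "-", 10_000, 14_000, [(10_000, 14_000)])
        # TSS at 0-based 13_999; 100 bp upstream (transcription sense)
        # is 0-based 14_099 -> 1-based 14_100
        mat = make_matrix([("c", 14_100, "+", "CpG")], [[(5, 10)] * 9])
        prof = binned_profile([g], mat, "gene", "Pre").table
        assert int(prof.loc[prof["n"] > 0, "bin"].iloc[0]) == 20

    def test_short_region_skipped_with_warning(self):
        g = GeneModel("g", "c", "+", 100, 130, [(100, 130)])
        mat = make_matrix([("c", 110, "+", "CpG")], [[(5, 10)] * 9])
        with pytest.warns(UserWarning, match="skipped"):
            prof = binned_profile([g], mat, "gene", "Pre").table
        assert prof["n"].sum() == 0

    def test_matches_bruteforce_binning(self, small_sim, small_matrix):
        prof = binned_profile(small_sim.genes, small_matrix, "gene",
                              "Pre").table
        # naive per-site, per-gene assignment
        sums = np.zeros(80)
        counts = np.zeros(80, dtype=int)
        glev = small_matrix.group_levels("Pre")
        cpg = small_matrix.sites["context"].to_numpy() == "CpG"
        for g in small_sim.genes:
            if g.end - g.start < 40:
                continue
            for i in np.nonzero(
                    (small_matrix.sites["chrom"].to_numpy() == g.chrom)
                    & cpg)[0]:
                p = int(small_matrix.sites["pos"].iat[i]) - 1
                if not (g.start - 5_000 <= p < g.end + 5_000):
                    continue
                if g.strand == "-":
                    p = (g.start - 5_000) + (g.end + 5_000 - 1) - p
                if p < g.start:
                    b = (p - (g.start - 5_000)) // 250
                elif p < g.end:
                    w = (g.end - g.start) / 40
                    b = 20 + min(int((p - g.start) / w), 39)
                else:
                    b = 60 + (p - g.end) // 250
                sums[b] += glev[i]
                counts[b] += 1
        assert list(prof["n"]) == list(counts)
        got = prof["mean"].to_numpy()
        want = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        assert np.allclose(got, want, equal_nan=True)

    def test_cgi_scheme_has_60_bins(self, small_sim, small_matrix):
        regions = [("chr1", s, e)
                   for s, e in small_sim.truth.cgi_intervals["chr1"]]
        prof = binned_profile(regions, small_matrix, "cgi", "In").table
        assert len(prof) == 60
        assert prof["n"].sum() > 0
        means = prof.loc[prof["n"] > 0, "mean"]
        assert ((means >= 0) & (means <= 1)).all()


class TestWindowTrack:
    def test_density_counts(self):
        track = window_track(
            ["c"] * 4, [10, 20, 999_999, 1_000_001], {"c": 2_000_000})
        assert list(track["value"]) == [3.0, 1.0]

    def test_empty_input_all_zero(self):
        track = window_track([], [], {"c": 3_500_000})
        assert list(track["value"]) == [0.0, 0.0, 0.0, 0.0]

    def test_mean_level_mode_matches_naive(self):
        rng = np.random.default_rng(8)
        pos = rng.integers(1, 5_000_001, size=300)
        vals = rng.random(300)
        track = window_track(["c"] * 300, pos, {"c": 5_000_000},
                             mode="mean_level", values=vals)
        for w in range(5):
            m = (pos - 1) // 1_000_000 == w
            want = vals[m].mean() if m.any() else np.nan
            got = track.loc[track["window"] == w, "value"].iloc[0]
            assert got == pytest.approx(want, nan_ok=True)

    def test_same_genome_same_grid(self):
        lengths = {"c1": 2_500_000, "c2": 1_000_000}
        t1 = window_track(["c1"], [5], lengths)
        t2 = window_track(["c2"], [5], lengths)
        assert list(t1[["chrom", "window"]].itertuples(index=False)) == \
            list(t2[["chrom", "window"]].itertuples(index=False))


class TestPearson:
    def test_perfect_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_ten_point_fixture_matches_hand_formula(self):
        rng = np.random.default_rng(9)
        x = rng.random(10)
        y = 0.5 * x + rng.random(10)
        r, p = pearson(x, y)
        assert r == pytest.approx(pearson_r(list(x), list(y)), abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
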