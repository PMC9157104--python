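import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscan.errors import ConfigError, ValidationError
from poolscan.poolio import SiteBlock
from poolscan.scan import (
    Region,
    SnpRecord,
    call_biallelic,
    candidate_regions,
    compute_afd,
    lower_median,
    passes_filters,
    run_scan,
    smooth_windows,
    top_snps,
)

from conftest import make_site


# ---------------------------------------------------------------------------
# compute_afd


class TestComputeAfd:
    def test_fixed_difference_is_one(self):
        assert compute_afd((1, 0), (0, 1)) == 1.0

    def test_identical_vectors_are_zero(self):
        assert compute_afd((0.3, 0.7), (0.3, 0.7)) == 0.0

    def test_half_l1(self):
        assert compute_afd((0.75, 0.25), (0.25, 0.75)) == pytest.approx(0.5)

    def test_unequal_length_rejected(self):
        with pytest.raises(ValidationError):
            compute_afd((1, 0), (0.5, 0.25, 0.25))

    def test_not_summing_to_one_rejected(self):
        with pytest.raises(ValidationError):
            compute_afd((0.5, 0.4), (0.5, 0.5))

    @given(
        st.lists(st.floats(0.001, 1.0), min_size=2, max_size=5),
        st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_range_and_self_zero(self, raw1, data):
        raw2 = data.draw(
            st.lists(
                st.floats(0.001, 1.0), min_size=len(raw1), max_size=len(raw1)
            )
        )
        f1 = np.array(raw1) / np.sum(raw1)
        f2 = np.array(raw2) / np.sum(raw2)
        a = compute_afd(f1, f2)
        assert 0.0 <= a <= 1.0 + 1e-12
        assert a == compute_afd(f2, f1)
        assert compute_afd(f1, f1) == 0.0


# ---------------------------------------------------------------------------
# call_biallelic


class TestCallBiallelic:
    def test_fixed_difference(self):
        site = make_site(pools=[{"A": 50}, {"G": 50}])
        snp = call_biallelic(site)
        assert snp is not None
        assert {snp.major, snp.minor} == {"A", "G"}
        # minor-allele (G) frequency: absent in pool 1, fixed in pool 2
        assert (snp.freq_1, snp.freq_2) == (0.0, 1.0)
        assert snp.afd == 1.0

    def test_monomorphic_site_returns_none(self):
        site = make_site(pools=[{"A": 40}, {"A": 60}])
        assert call_biallelic(site) is None

    def test_triallelic_rejected_above_error_floor(self):
        # combined A=60, G=35, T=5: third allele 5/100 > 1%
        site = make_site(pools=[{"A": 30, "G": 20, "T": 5}, {"A": 30, "G": 15}])
        assert call_biallelic(site, error_floor=0.01) is None

    def test_third_allele_within_floor_tolerated(self):
        site = make_site(pools=[{"A": 60, "G": 35}, {"A": 60, "G": 44, "T": 1}])
        snp = call_biallelic(site, error_floor=0.01)
        assert snp is not None
        # non-retained T reads discarded from depths
        assert snp.depth_1 == 95 and snp.depth_2 == 104

    def test_all_zero_counts_return_none(self):
        assert call_biallelic(make_site(pools=[{}, {}])) is None

    def test_pool_without_retained_reads_returns_none(self):
        site = make_site(pools=[{"A": 50, "G": 50}, {}])
        assert call_biallelic(site) is None

    def test_bad_error_floor_rejected(self):
        with pytest.raises(ConfigError):
            call_biallelic(make_site(pools=[{"A": 5}, {"G": 5}]), error_floor=0.2)


# ---------------------------------------------------------------------------
# passes_filters


def snp(depth_1=80, depth_2=80, freq_1=0.5, freq_2=0.5):
    return SnpRecord(
        chrom="chrI",
        pos=1,
        major="A",
        minor="G",
        depth_1=depth_1,
        depth_2=depth_2,
        freq_1=freq_1,
        freq_2=freq_2,
        afd=abs(freq_1 - freq_2),
    )


class TestPassesFilters:
    def test_below_lower_depth_bound_fails(self):
        assert not passes_filters(snp(depth_1=39, depth_2=80, freq_1=0.3, freq_2=0.3), 40, 130, 0.2)

    def test_bounds_inclusive(self):
        assert passes_filters(snp(depth_1=40, depth_2=130, freq_1=0.2, freq_2=0.2), 40, 130, 0.2)

    def test_combined_maf_from_summed_counts(self):
        # pools (A=30,G=10) and (A=33,G=7): combined MAF 17/80 = 0.2125
        s = snp(depth_1=40, depth_2=40, freq_1=10 / 40, freq_2=7 / 40)
        assert passes_filters(s, 40, 130, 0.2)
        assert not passes_filters(s, 40, 130, 0.22)

    def test_above_upper_depth_bound_fails(self):
        assert not passes_filters(snp(depth_2=131, freq_1=0.4, freq_2=0.4), 40, 130, 0.2)

    def test_bad_bounds_config_error(self):
        with pytest.raises(ConfigError):
            passes_filters(snp(), 130, 40, 0.2)

    def test_filter_order_invariance(self, rng):
        # depth-then-MAF equals MAF-then-depth on random records
        for _ in range(200):
            d1, d2 = rng.integers(1, 200, size=2)
            m1, m2 = rng.integers(0, d1 + 1), rng.integers(0, d2 + 1)
            s = snp(int(d1), int(d2), m1 / d1, m2 / d2)
            depth_ok = 40 <= d1 <= 130 and 40 <= d2 <= 130
            maf_ok = (m1 + m2) / (d1 + d2) >= 0.2
            assert passes_filters(s, 40, 130, 0.2) == (depth_ok and maf_ok)


# ---------------------------------------------------------------------------
# run_scan


class TestRunScan:
    def test_matches_scalar_pipeline_on_random_sites(self, random_sites):
        result = run_scan(random_sites, depth_min=40, depth_max=130, maf_min=0.2)
        expected = []
        for site in random_sites:
            rec = call_biallelic(site, error_floor=0.01)
            if rec is not None and passes_filters(rec, 40, 130, 0.2):
                expected.append(rec)
        assert len(result.snps) == len(expected)
        for row, rec in zip(result.snps.itertuples(), expected):
            assert (row.chrom, row.pos, row.major, row.minor) == (
                rec.chrom,
                rec.pos,
                rec.major,
                rec.minor,
            )
            assert (row.depth_1, row.depth_2) == (rec.depth_1, rec.depth_2)
            assert row.freq_1 == pytest.approx(rec.freq_1)
            assert row.afd == pytest.approx(rec.afd)
        if expected:
            afds = sorted(r.afd for r in expected)
            assert result.median_afd == pytest.approx(afds[(len(afds) - 1) // 2])

    def test_toy_stream_survivors(self):
        # designed: sites 2 and 4 survive; others fail depth, MAF or calling
        sites = [
            make_site(pos=10, pools=[{"A": 30}, {"A": 9, "G": 30}]),  # pool1 depth 30 < 40
            make_site(pos=20, pools=[{"A": 30, "G": 20}, {"A": 40, "G": 10}]),  # ok
            make_site(pos=30, pools=[{"A": 70}, {"A": 66, "G": 4}]),  # MAF 4/140 < 0.2
            make_site(pos=40, pools=[{"A": 25, "C": 25}, {"C": 50}]),  # ok
            make_site(pos=50, pools=[{"T": 50}, {"T": 60}]),  # monomorphic
        ]
        result = run_scan(sites, depth_min=40, depth_max=130, maf_min=0.2)
        assert result.snps["pos"].tolist() == [20, 40]

    def test_empty_stream(self):
        result = run_scan([])
        assert len(result.snps) == 0 and result.median_afd is None

    def test_all_monomorphic_stream(self):
        sites = [make_site(pos=p, pools=[{"A": 50}, {"A": 50}]) for p in (1, 2, 3)]
        result = run_scan(sites)
        assert len(result.snps) == 0

    def test_unsorted_input_names_position(self):
        sites = [
            make_site(pos=100, pools=[{"A": 50}, {"G": 50}]),
            make_site(pos=90, pools=[{"A": 50}, {"G": 50}]),
        ]
        with pytest.raises(ValidationError, match="90"):
            run_scan(sites)

    def test_chromosome_reappearance_rejected(self):
        sites = [
            make_site(chrom="chrI", pos=10, pools=[{"A": 5}, {"G": 5}]),
            make_site(chrom="chrII", pos=10, pools=[{"A": 5}, {"G": 5}]),
            make_site(chrom="chrI", pos=20, pools=[{"A": 5}, {"G": 5}]),
        ]
        with pytest.raises(ValidationError, match="chrI"):
            run_scan(sites)

    def test_afd_in_unit_interval(self, random_sites):
        result = run_scan(random_sites, depth_min=1, depth_max=10_000, maf_min=0.0)
        afd = result.snps["afd"].to_numpy()
        assert ((afd >= 0) & (afd <= 1)).all()


# ---------------------------------------------------------------------------
# smooth_windows


def brute_force_windows(snps, width, step, min_snps):
    rows = []
    for chrom in snps["chrom"].unique():
        sub = snps[snps["chrom"] == chrom]
        start = 1
        while start <= sub["pos"].max():
            end = start + width - 1
            inside = sub[(sub["pos"] >= start) & (sub["pos"] <= end)]
            if len(inside) >= min_snps:
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "n_snps": len(inside),
                        "mean_afd": inside["afd"].mean(),
                    }
                )
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "mean_afd"])


def random_snp_table(rng, n=200, chroms=("chrI", "chrII")):
    frames = []
    for chrom in chroms:
        pos = np.sort(rng.choice(np.arange(1, 200_001), size=n // len(chroms), replace=False))
        frames.append(
            pd.DataFrame({"chrom": chrom, "pos": pos, "afd": rng.random(len(pos))})
        )
    return pd.concat(frames, ignore_index=True)


class TestSmoothWindows:
    def test_window_below_min_snps_omitted(self):
        snps = pd.DataFrame({"chrom": "chrI", "pos": np.arange(1, 6) * 100, "afd": 0.5})
        out = smooth_windows(snps, width=40_000, step=20_000, min_snps=6)
        assert len(out) == 0

    def test_six_equal_snps_mean(self):
        snps = pd.DataFrame({"chrom": "chrI", "pos": np.arange(1, 7) * 100, "afd": 0.5})
        out = smooth_windows(snps, width=40_000, step=20_000, min_snps=6)
        first = out.iloc[0]
        assert first["n_snps"] == 6 and first["mean_afd"] == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self, rng):
        snps = random_snp_table(rng)
        fast = smooth_windows(snps, width=40_000, step=20_000, min_snps=6)
        slow = brute_force_windows(snps, 40_000, 20_000, 6)
        pd.testing.assert_frame_equal(
            fast.reset_index(drop=True).astype({"n_snps": "int64", "start": "int64", "end": "int64"}),
            slow.astype({"n_snps": "int64", "start": "int64", "end": "int64"}),
        )

    def test_each_snp_in_width_over_step_windows(self, rng):
        # away from chromosome start, each SNP falls in width/step windows
        snps = pd.DataFrame({"chrom": "chrI", "pos": [100_000], "afd": [0.5]})
        out = smooth_windows(snps, width=40_000, step=20_000, min_snps=1)
        assert len(out) == 2

    def test_width_not_multiple_of_step_rejected(self):
        snps = pd.DataFrame({"chrom": "chrI", "pos": [10], "afd": [0.5]})
        with pytest.raises(ConfigError):
            smooth_windows(snps, width=30_000, step=20_000)

    def test_width_below_step_rejected(self):
        snps = pd.DataFrame({"chrom": "chrI", "pos": [10], "afd": [0.5]})
        with pytest.raises(ConfigError):
            smooth_windows(snps, width=10_000, step=20_000)


# ---------------------------------------------------------------------------
# top_snps


class TestTopSnps:
    def make_table(self, afds, chrom="chrI"):
        return pd.DataFrame(
            {
                "chrom": chrom,
                "pos": np.arange(1, len(afds) + 1) * 10,
                "afd": afds,
            }
        )

    def test_descending_order(self):
        table = self.make_table([0.49, 0.541, 0.50, 0.1])
        out = top_snps(table, k=3)
        assert out["afd"].tolist() == [0.541, 0.50, 0.49]

    def test_sort_oracle(self, rng):
        table = self.make_table(rng.random(50))
        out = top_snps(table, k=10)
        expected = sorted(table["afd"], reverse=True)[:10]
        assert out["afd"].tolist() == pytest.approx(expected)

    def test_all_equal_takes_genomic_order(self):
        table = self.make_table([0.5] * 6)
        out = top_snps(table, k=3)
        assert out["pos"].tolist() == [10, 20, 30]

    def test_k_one_is_maximum(self):
        table = self.make_table([0.2, 0.9, 0.4])
        assert top_snps(table, k=1)["afd"].iloc[0] == 0.9

    def test_exactly_k_on_boundary_tie(self, caplog):
        table = self.make_table([0.9, 0.5, 0.5, 0.5])
        with caplog.at_level("INFO", logger="poolscan.scan"):
            out = top_snps(table, k=2)
        assert len(out) == 2
        assert out["pos"].tolist() == [10, 20]

    def test_k_above_table_size_returns_all_with_warning(self, caplog):
        table = self.make_table([0.1, 0.2])
        with caplog.at_level("WARNING", logger="poolscan.scan"):
            out = top_snps(table, k=10)
        assert len(out) == 2

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ConfigError):
            top_snps(self.make_table([0.5]), k=0)


# ---------------------------------------------------------------------------
# candidate_regions


def anchors(positions, chrom="chrI"):
    return pd.DataFrame({"chrom": chrom, "pos": positions, "afd": 0.5})


class TestCandidateRegions:
    def test_single_snp_centering(self):
        (region,) = candidate_regions(anchors([500_000]))
        assert (region.start, region.end, region.anchor_pos) == (410_000, 590_000, 500_000)

    def test_lower_clip(self):
        (region,) = candidate_regions(anchors([50_000]))
        assert (region.start, region.end) == (1, 140_000)

    def test_four_snp_cluster_merges_to_one(self):
        (region,) = candidate_regions(anchors([100_000, 101_000, 102_000, 103_000]))
        assert region.anchor_pos == (100_000 + 103_000) // 2

    def test_distant_anchors_stay_separate(self):
        regions = candidate_regions(anchors([100_000, 800_000]))
        assert len(regions) == 2

    def test_overlapping_regions_merged(self):
        # 30 kb apart: beyond cluster_gap but regions overlap
        (region,) = candidate_regions(anchors([500_000, 550_000]))
        assert region.start == 410_000 and region.end == 640_000

    def test_chromosomes_kept_apart(self):
        table = pd.concat([anchors([100_000], "chrI"), anchors([100_000], "chrII")])
        regions = candidate_regions(table)
        assert {r.chrom for r in regions} == {"chrI", "chrII"}

    def test_empty_input(self):
        assert candidate_regions(anchors([])) == []


class TestLowerMedian:
    def test_odd(self):
        assert lower_median(np.array([3.0, 1.0, 2.0])) == 2.0

    def test_even_takes_lower(self):
        assert lower_median(np.array([4.0, 1.0, 3.0, 2.0])) == 2.0
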