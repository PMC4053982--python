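"""The generative model's expectations, determinism, and the dilution mixture."""

import numpy as np
import pandas as pd
import pytest

from ascn import simulate
from ascn.simulate import (
    SimulationConfig,
    allele_fraction,
    arms_from_profile,
    default_tumor_profile,
    dilute_reads,
    simulate_het_snps,
    simulate_windows,
)
from ascn.simulate import _mixture_weight


def mean_within_3se(counts, expected):
    counts = np.asarray(counts, dtype=float)
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    return abs(counts.mean() - expected) <= 3 * se


class TestWindowCounts:
    def test_copy_neutral_pure_tumor_matches_mean_coverage(self, uniform_profile, flat_bias):
        cfg = SimulationConfig(purity=1.0, mean_coverage=20.0, gc_bias=flat_bias, seed=3)
        tumor, normal = simulate_windows(uniform_profile, cfg)
        assert mean_within_3se(tumor["count"], 20.0)
        assert mean_within_3se(normal["count"], 20.0)

    def test_half_purity_tetraploid_region_expectation(self, flat_bias):
        profile = pd.DataFrame(
            [("chr1", "p", 0, 2_000_000, 4, 2)],
            columns=["chrom", "arm", "start", "end", "total_cn", "minor_cn"],
        )
        cfg = SimulationConfig(purity=0.5, mean_coverage=20.0, gc_bias=flat_bias, seed=4)
        tumor, _ = simulate_windows(profile, cfg)
        # (0.5*4 + 0.5*2)/2 = 1.5 times the diploid coverage
        assert mean_within_3se(tumor["count"], 30.0)

    def test_zero_purity_tumor_indistinguishable_from_normal(self, small_profile, flat_bias):
        cfg = SimulationConfig(purity=0.0, mean_coverage=15.0, gc_bias=flat_bias, seed=5)
        tumor, normal = simulate_windows(small_profile, cfg)
        assert mean_within_3se(tumor["count"], 15.0)
        assert abs(tumor["count"].mean() - normal["count"].mean()) < 0.2

    def test_gc_bias_modulates_expectation(self, uniform_profile):
        cfg = SimulationConfig(purity=1.0, mean_coverage=50.0, seed=6)
        tumor, _ = simulate_windows(uniform_profile, cfg)
        lo = tumor[tumor["gc"] < 0.40]["count"]
        mid = tumor[(tumor["gc"] > 0.43) & (tumor["gc"] < 0.47)]["count"]
        assert lo.mean() < mid.mean()

    def test_same_seed_bit_identical(self, small_profile):
        cfg = SimulationConfig(purity=0.7, mean_coverage=10.0, seed=11)
        t1, n1 = simulate_windows(small_profile, cfg)
        t2, n2 = simulate_windows(small_profile, cfg)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(n1, n2)

    def test_uncovered_window_rejected_with_location(self):
        gapped = pd.DataFrame(
            [("chr1", "p", 0, 1000, 2, 1), ("chr1", "p", 2000, 3000, 2, 1)],
            columns=["chrom", "arm", "start", "end", "total_cn", "minor_cn"],
        )
        cfg = SimulationConfig(seed=0)
        with pytest.raises(ValueError, match=r"chr1:1[0-9]00"):
            simulate_windows(gapped, cfg)

    def test_invalid_minor_copy_rejected(self):
        bad = pd.DataFrame(
            [("chr1", "p", 0, 1000, 3, 2)],
            columns=["chrom", "arm", "start", "end", "total_cn", "minor_cn"],
        )
        with pytest.raises(ValueError, match="minor"):
            simulate_windows(bad, SimulationConfig(seed=0))


class TestAlleleFractions:
    @pytest.mark.parametrize(
        "purity,total,allele_cn,expected",
        [
            (1.0, 2, 1, 0.5),      # balanced heterozygote
            (1.0, 3, 1, 1 / 3),    # minor homolog of 3m1
            (1.0, 3, 2, 2 / 3),    # major homolog of 3m1
            (0.5, 2, 2, 0.75),     # major homolog of 2m0 at half purity
            (0.5, 2, 0, 0.25),     # lost homolog of 2m0 at half purity
        ],
    )
    def test_allele_fraction_formula(self, purity, total, allele_cn, expected):
        assert allele_fraction(purity, total, allele_cn) == pytest.approx(expected)

    def test_het_snps_split_between_homolog_fractions(self):
        profile = pd.DataFrame(
            [("chr1", "p", 0, 5_000_000, 3, 1)],
            columns=["chrom", "arm", "start", "end", "total_cn", "minor_cn"],
        )
        cfg = SimulationConfig(purity=1.0, mean_coverage=200.0, snp_density=1.0, seed=7)
        snps = simulate_het_snps(profile, cfg)
        frac = snps["countA"] / (snps["countA"] + snps["countB"])
        # allele A sits on the major (f=2/3) or minor (f=1/3) homolog
        assert ((frac - 1 / 3).abs() < 0.12).sum() + ((frac - 2 / 3).abs() < 0.12).sum() \
            == len(snps)
        near_major = ((frac - 2 / 3).abs() < 0.12).mean()
        assert 0.4 < near_major < 0.6

    def test_het_snp_positions_inside_segments_and_deterministic(self, small_profile):
        cfg = SimulationConfig(purity=0.8, mean_coverage=30.0, seed=8)
        s1 = simulate_het_snps(small_profile, cfg)
        s2 = simulate_het_snps(small_profile, cfg)
        pd.testing.assert_frame_equal(s1, s2)
        for _, seg in small_profile.iterrows():
            sel = s1[(s1["pos"] - 1 >= seg["start"]) & (s1["pos"] - 1 < seg["end"])]
            assert (sel["true_total"] == seg["total_cn"]).all()


class TestDilution:
    @pytest.mark.parametrize(
        "purity,ploidy,expected_w",
        [
            (1.0, 4.0, 1.0),
            (0.5, 4.0, 2 / 3),   # half tetraploid cells hold 2/3 of the DNA
            (0.3, 2.0, 0.3),     # diploid tumor: DNA fraction = cell fraction
        ],
    )
    def test_mixture_weight(self, purity, ploidy, expected_w):
        assert _mixture_weight(purity, ploidy) == pytest.approx(expected_w)

    def test_total_coverage_preserved_and_tumor_share_correct(self):
        n = 40_000
        tumor = pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 200,
                              "end": np.arange(1, n + 1) * 200,
                              "count": np.full(n, 40)})
        normal = tumor.copy()
        normal["count"] = 60
        mixed = dilute_reads(tumor, normal, target_purity=0.5, tumor_ploidy=4.0, seed=1)
        assert mixed["count"].mean() == pytest.approx(40.0, rel=0.01)

    def test_pure_target_returns_tumor_unchanged(self):
        tumor = pd.DataFrame({"chrom": "chr1", "start": [0, 200], "end": [200, 400],
                              "count": [17, 25]})
        normal = tumor.copy()
        mixed = dilute_reads(tumor, normal, target_purity=1.0, tumor_ploidy=3.0, seed=0)
        assert list(mixed["count"]) == [17, 25]

    def test_snp_allele_counts_diluted_per_allele(self):
        n = 20_000
        tumor = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, n + 1),
                              "countA": np.full(n, 30), "countB": np.full(n, 10)})
        normal = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, n + 1),
                               "countA": np.full(n, 20), "countB": np.full(n, 20)})
        mixed = dilute_reads(tumor, normal, target_purity=0.5, tumor_ploidy=4.0, seed=2)
        # w=2/3 of tumor (A:B = 3:1) plus 1/3 of normal (1:1), at tumor depth 40
        assert (mixed["countA"] + mixed["countB"]).mean() == pytest.approx(40, rel=0.02)
        assert mixed["countA"].mean() == pytest.approx(40 * (2 / 3 * 0.75 + 1 / 3 * 0.5),
                                                       rel=0.02)

    def test_insufficient_normal_reports_max_achievable_purity(self):
        n = 1000
        tumor = pd.DataFrame({"chrom": "c", "start": np.arange(n), "end": np.arange(n) + 1,
                              "count": np.full(n, 100)})
        normal = tumor.copy()
        normal["count"] = 5
        with pytest.raises(ValueError, match="maximum achievable purity"):
            dilute_reads(tumor, normal, target_purity=0.1, tumor_ploidy=2.0, seed=0)


def test_default_profile_structure():
    profile = default_tumor_profile()
    simulate.validate_profile(profile)
    length = profile["end"] - profile["start"]
    assert length.sum() == 300_000_000
    states = set(zip(profile["total_cn"], profile["minor_cn"]))
    assert states == {(1, 0), (2, 0), (2, 1), (3, 0), (3, 1), (4, 1), (4, 2)}
    assert (length >= 5_000_000).all()
    arms = arms_from_profile(profile)
    assert set(arms["chrom"]) == set(profile["chrom"])
    assert (arms["centromere_start"] == arms["centromere_end"]).all()
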