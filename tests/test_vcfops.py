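import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheatscan import vcfops
from wheatscan.vcfops import (
    hard_filter,
    pairwise_diversity,
    snp_density,
    wc_fst_per_site,
    window_fst,
    window_pi,
)

from conftest import make_table


# ---------------------------------------------------------------- oracles
def pi_oracle(gt_rows, width):
    """Brute force: enumerate all sample pairs per site (het/missing skipped)."""
    total = 0.0
    for row in gt_rows:
        calls = [g for g in row if g in (0, 1)]
        n = len(calls)
        if n < 2:
            continue
        pairs = list(itertools.combinations(calls, 2))
        total += sum(1 for x, y in pairs if x != y) / len(pairs)
    return total / width


def wc_oracle(x1, x2):
    """One-way ANOVA theta from raw haploid indicator values."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    n1, n2 = len(x1), len(x2)
    ntot = n1 + n2
    p1, p2 = x1.mean(), x2.mean()
    pbar = (x1.sum() + x2.sum()) / ntot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # df = r - 1 = 1
    msg = (((x1 - p1) ** 2).sum() + ((x2 - p2) ** 2).sum()) / (ntot - 2)
    nc = ntot - (n1**2 + n2**2) / ntot
    denom = msp + (nc - 1) * msg
    return (msp - msg) / denom if denom != 0 else float("nan")


# ------------------------------------------------------------- hard_filter
class TestHardFilter:
    def test_cluster_of_three_within_10bp_removed(self):
        t = make_table(
            [
                ("1A", 100, "A", "G", [0, 1]),
                ("1A", 105, "C", "T", [0, 1]),
                ("1A", 109, "G", "A", [0, 1]),
            ],
            ["s1", "s2"],
            dp=8,
        )
        assert len(hard_filter(t)) == 0

    def test_two_close_snps_retained(self):
        t = make_table(
            [("1A", 100, "A", "G", [0, 1]), ("1A", 105, "C", "T", [0, 1])],
            ["s1", "s2"],
            dp=8,
        )
        assert len(hard_filter(t)) == 2

    def test_exactly_10bp_span_not_a_cluster(self):
        # positions 100..110 span 10 bp (11 positions): outside "within 10 bp"
        t = make_table(
            [
                ("1A", 100, "A", "G", [0, 1]),
                ("1A", 105, "C", "T", [0, 1]),
                ("1A", 110, "G", "A", [0, 1]),
            ],
            ["s1", "s2"],
            dp=8,
        )
        assert len(hard_filter(t)) == 3

    def test_enumerated_toy_table(self):
        # 6 records; one has mean DP 20 (> 15) and is removed
        dp = [8, 8, 20, 8, 8, 8]
        t = make_table(
            [
                ("1A", 100, "A", "G", [0, 1]),
                ("1A", 500, "C", "T", [0, 1]),
                ("1A", 900, "G", "A", [0, 1]),
                ("1A", 1300, "T", "C", [0, 1]),
                ("2A", 100, "A", "C", [0, 1]),
                ("2A", 500, "G", "T", [0, 1]),
            ],
            ["s1", "s2"],
            dp=np.array(dp),
        )
        out = hard_filter(t)
        assert len(out) == 5
        assert 900 not in out.sites["pos"].tolist()

    def test_depth_bounds_inclusive(self):
        t = make_table(
            [
                ("1A", 100, "A", "G", [0, 1]),
                ("1A", 500, "C", "T", [0, 1]),
                ("1A", 900, "G", "A", [0, 1]),
            ],
            ["s1", "s2"],
            dp=np.array([4, 15, 3]),
        )
        out = hard_filter(t)
        assert out.sites["pos"].tolist() == [100, 500]

    def test_empty_table(self):
        t = make_table([], ["s1"])
        assert len(hard_filter(t)) == 0


# --------------------------------------------------------------- window_pi
class TestWindowPi:
    def test_monomorphic_window_zero(self):
        t = make_table([("1A", 5, "A", "G", [0, 0, 0])], ["a", "b", "c"])
        track = window_pi(t, width=10_000, chrom_lengths={"1A": 10_000})
        assert track.values[0] == 0.0

    def test_single_snp_two_samples(self):
        t = make_table([("1A", 5, "A", "G", [0, 1])], ["a", "b"])
        track = window_pi(t, width=10_000, chrom_lengths={"1A": 10_000})
        assert track.values[0] == pytest.approx(1.0e-4, abs=1e-15)

    def test_four_samples_split(self):
        t = make_table([("1A", 5, "A", "G", [0, 0, 1, 1])], ["a", "b", "c", "d"])
        track = window_pi(t, width=10_000, chrom_lengths={"1A": 10_000})
        expected = (2 * 2 / 6) / 1e4  # brute force over the 6 pairs
        assert track.values[0] == pytest.approx(expected, abs=1e-15)

    def test_rejects_bad_width(self):
        t = make_table([("1A", 5, "A", "G", [0, 1])], ["a", "b"])
        with pytest.raises(ValueError):
            window_pi(t, width=0)

    @given(st.lists(
        st.lists(st.sampled_from([-1, 0, 1, 2]), min_size=4, max_size=4),
        min_size=1, max_size=20,
    ))
    @settings(max_examples=50, deadline=None)
    def test_oracle_equivalence(self, gt_rows):
        records = [("1A", i * 7 + 1, "A", "G", row) for i, row in enumerate(gt_rows)]
        t = make_table(records, ["a", "b", "c", "d"])
        track = window_pi(t, width=1000, chrom_lengths={"1A": 1000})
        assert track.values[0] == pytest.approx(pi_oracle(gt_rows, 1000), abs=1e-12)


# ------------------------------------------------------ pairwise_diversity
class TestPairwiseDiversity:
    def _table(self):
        return make_table(
            [
                ("1A", 10, "A", "G", [0, 1, 0]),
                ("1A", 20, "C", "T", [1, 1, -1]),
                ("1A", 1500, "G", "A", [0, 1, 1]),
            ],
            ["x", "y", "z"],
        )

    def test_self_comparison_zero(self):
        track = pairwise_diversity(self._table(), "x", "x", width=1000,
                                   chrom_lengths={"1A": 2000})
        assert np.all(track.values == 0.0)

    def test_direct_count(self):
        track = pairwise_diversity(self._table(), "x", "y", width=1000,
                                   chrom_lengths={"1A": 2000})
        assert track.values[0] == pytest.approx(1 / 1000)
        assert track.values[1] == pytest.approx(1 / 1000)
        assert track.frame["n_sites"].tolist() == [2, 1]

    def test_no_overlap_is_nan(self):
        t = make_table([("1A", 10, "A", "G", [0, -1])], ["x", "z"])
        track = pairwise_diversity(t, "x", "z", width=1000,
                                   chrom_lengths={"1A": 1000})
        assert np.isnan(track.values[0])
        assert track.frame["n_sites"].iloc[0] == 0

    def test_symmetry(self):
        a = pairwise_diversity(self._table(), "x", "y", width=1000,
                               chrom_lengths={"1A": 2000})
        b = pairwise_diversity(self._table(), "y", "x", width=1000,
                               chrom_lengths={"1A": 2000})
        np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            pairwise_diversity(self._table(), "x", "nope")


# -------------------------------------------------------------- window_fst
class TestWindowFst:
    def test_fixed_difference_is_one(self):
        t = make_table(
            [
                ("1A", 10, "A", "G", [0, 0, 1, 1]),
                ("1A", 20, "C", "T", [0, 0, 1, 1]),
            ],
            ["a1", "a2", "b1", "b2"],
        )
        track = window_fst(t, ["a1", "a2"], ["b1", "b2"], width=1000,
                           chrom_lengths={"1A": 1000})
        assert track.values[0] == pytest.approx(1.0)

    def test_hand_computed_single_site(self):
        # group1: 10 ref / 0 alt; group2: 5 ref / 5 alt
        g1 = [0] * 10
        g2 = [0] * 5 + [1] * 5
        t = make_table([("1A", 10, "A", "G", g1 + g2)],
                       [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)])
        track = window_fst(t, [f"a{i}" for i in range(10)],
                           [f"b{i}" for i in range(10)], width=1000,
                           chrom_lengths={"1A": 1000})
        expected = wc_oracle(g1, g2)
        assert track.values[0] == pytest.approx(expected, abs=1e-12)
        assert wc_fst_per_site(
            np.array([10]), np.array([0]), np.array([5]), np.array([5])
        )[0] == pytest.approx(expected, abs=1e-12)

    def test_null_panmictic_mean_near_zero(self, rng):
        n_sites = 10_000
        freqs = rng.uniform(0.1, 0.9, size=n_sites)
        g1 = (rng.random((n_sites, 8)) < freqs[:, None]).astype(np.int8)
        g2 = (rng.random((n_sites, 8)) < freqs[:, None]).astype(np.int8)
        records = [
            ("1A", i + 1, "A", "G", list(g1[i]) + list(g2[i]))
            for i in range(n_sites)
        ]
        t = make_table(records, [f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)])
        # the per-site ratio has an O(1/n) negative bias under the null, so
        # the unbiasedness check uses the ratio-of-sums form; its standard
        # error follows from the delta method on the per-site numerators
        track = window_fst(t, [f"a{i}" for i in range(8)], [f"b{i}" for i in range(8)],
                           width=n_sites + 1, chrom_lengths={"1A": n_sites + 1},
                           mode="ratio")
        a1, b1 = (g1 == 0).sum(1), (g1 == 1).sum(1)
        a2, b2 = (g2 == 0).sum(1), (g2 == 1).sum(1)
        n1, n2 = a1 + b1, a2 + b2
        ntot = n1 + n2
        p1, p2, pbar = b1 / n1, b2 / n2, (b1 + b2) / ntot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
        nc = ntot - (n1**2 + n2**2) / ntot
        num, den = msp - msg, msp + (nc - 1) * msg
        se = np.std(num) / np.sqrt(len(num)) / np.mean(den)
        assert abs(track.values[0]) < 4 * se

    def test_mean_mode_matches_per_site_mean(self, rng):
        n_sites = 500
        freqs = rng.uniform(0.1, 0.9, size=n_sites)
        g1 = (rng.random((n_sites, 6)) < freqs[:, None]).astype(np.int8)
        g2 = (rng.random((n_sites, 6)) < freqs[:, None]).astype(np.int8)
        records = [
            ("1A", i + 1, "A", "G", list(g1[i]) + list(g2[i]))
            for i in range(n_sites)
        ]
        t = make_table(records, [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)])
        track = window_fst(t, [f"a{i}" for i in range(6)], [f"b{i}" for i in range(6)],
                           width=n_sites + 1, chrom_lengths={"1A": n_sites + 1})
        theta = wc_fst_per_site(
            (g1 == 0).sum(1), (g1 == 1).sum(1), (g2 == 0).sum(1), (g2 == 1).sum(1)
        )
        fixed = ((g1 == 1).sum(1) + (g2 == 1).sum(1) == 0) | (
            (g1 == 0).sum(1) + (g2 == 0).sum(1) == 0
        )
        expected = np.nanmean(theta[~fixed])
        assert track.values[0] == pytest.approx(expected, abs=1e-12)

    @given(st.lists(
        st.lists(st.sampled_from([0, 1]), min_size=8, max_size=8),
        min_size=1, max_size=20,
    ))
    @settings(max_examples=50, deadline=None)
    def test_oracle_equivalence(self, gt_rows):
        samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        records = [("1A", i * 3 + 1, "A", "G", row) for i, row in enumerate(gt_rows)]
        t = make_table(records, samples)
        track = window_fst(t, samples[:4], samples[4:], width=1000,
                           chrom_lengths={"1A": 1000})
        thetas = [
            wc_oracle(row[:4], row[4:])
            for row in gt_rows
            if 0 < sum(row) < 8  # skip sites fixed across both groups
        ]
        thetas = [x for x in thetas if not np.isnan(x)]
        if thetas:
            assert track.values[0] == pytest.approx(np.mean(thetas), abs=1e-12)
        else:
            assert np.isnan(track.values[0])

    def test_group_overlap_rejected(self):
        t = make_table([("1A", 10, "A", "G", [0, 1, 0, 1])], ["a", "b", "c", "d"])
        with pytest.raises(ValueError):
            window_fst(t, ["a", "b"], ["b", "c"])


# ------------------------------------------------------------- snp_density
class TestSnpDensity:
    def test_empty_table(self):
        t = make_table([], ["s1"])
        track = snp_density(t, width=1000, chrom_lengths={"1A": 3000})
        assert np.all(track.values == 0.0)

    def test_direct_count(self):
        records = [("1A", 1001 + i, "A", "G", [0]) for i in range(7)]
        t = make_table(records, ["s1"])
        track = snp_density(t, width=1000, chrom_lengths={"1A": 3000})
        assert track.values.tolist() == [0.0, 7.0, 0.0]

    def test_conservation(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 50_000), size=200, replace=False))
        records = [("1A", int(p), "A", "G", [0]) for p in pos]
        t = make_table(records, ["s1"])
        track = snp_density(t, width=7_000, chrom_lengths={"1A": 50_000})
        assert track.values.sum() == 200


class TestAnnotationFilter:
    def test_thresholds_and_missing_pass(self):
        t = make_table(
            [
                ("1A", 10, "A", "G", [0]),
                ("1A", 20, "C", "T", [0]),
                ("1A", 30, "G", "A", [0]),
            ],
            ["s1"],
        )
        t.sites["QD"] = [1.0, 5.0, np.nan]
        out = vcfops.annotation_filter(t, {"QD": ("<", 2.0)})
        assert out.sites["pos"].tolist() == [20, 30]
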