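"""SNP hard filtering and windowed population statistics.

Genotypes are haploid-coded for the inbred accessions this package targets;
heterozygous calls are treated as missing by default in pi and Fst (set
``het_policy="both"`` to count both alleles of a het call).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from wheatscan.core.variants import GT_ALT, GT_HET, GT_REF, VariantTable
from wheatscan.core.windows import WindowTrack, assign_windows, make_windows


@dataclass
class FilterThresholds:
    """Hard-filter knobs: SNP clusters and across-sample mean depth."""

    cluster_n: int = 3
    cluster_bp: int = 10
    min_mean_dp: float = 4.0
    max_mean_dp: float = 15.0


def hard_filter(table: VariantTable, thresholds: FilterThresholds | None = None) -> VariantTable:
    """Remove clustered SNPs and SNPs with extreme mean depth.

    A SNP is clustered when it belongs to a run of >= ``cluster_n`` SNPs
    spanning < ``cluster_bp`` bp on one chromosome; all members of such a
    run are removed. Mean depth is the across-sample average of DP; SNPs
    with mean < ``min_mean_dp`` or > ``max_mean_dp`` are removed. Records
    with a non-single-base ref/alt are dropped. Order is preserved.
    """
    t = thresholds or FilterThresholds()
    if len(table) == 0:
        return table
    keep = np.ones(len(table), dtype=bool)

    # biallelic single-base records only
    ref = table.sites["ref"].str.len().to_numpy()
    alt = table.sites["alt"].str.len().to_numpy()
    keep &= (ref == 1) & (alt == 1)

    # cluster rule
    chroms = table.sites["chrom"].to_numpy()
    pos = table.sites["pos"].to_numpy()
    n = t.cluster_n
    clustered = np.zeros(len(table), dtype=bool)
    for c in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == c)
        p = pos[idx]
        if len(p) < n:
            continue
        span = p[n - 1:] - p[: len(p) - n + 1]
        starts = np.flatnonzero(span < t.cluster_bp)
        for s in starts:
            clustered[idx[s:s + n]] = True
    keep &= ~clustered

    # depth rule
    if table.dp is not None:
        mean_dp = table.dp.mean(axis=1)
        keep &= (mean_dp >= t.min_mean_dp) & (mean_dp <= t.max_mean_dp)
    return table.subset_sites(keep)


def _allele_counts(
    gt: np.ndarray, het_policy: str = "missing"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (ref count, alt count) from haploid-coded genotypes.

    het_policy="missing" ignores het calls; "both" adds one ref and one
    alt allele per het call (doubling the weight of homozygous calls so
    every sample contributes two alleles).
    """
    if het_policy == "missing":
        a = (gt == GT_REF).sum(axis=1)
        b = (gt == GT_ALT).sum(axis=1)
    elif het_policy == "both":
        het = (gt == GT_HET).sum(axis=1)
        a = 2 * (gt == GT_REF).sum(axis=1) + het
        b = 2 * (gt == GT_ALT).sum(axis=1) + het
    else:
        raise ValueError(f"unknown het_policy {het_policy!r}")
    return a.astype(np.int64), b.astype(np.int64)


def _window_frame(table: VariantTable, chrom_lengths: dict[str, int] | None, width: int, step: int | None):
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(table.sites.loc[table.sites["chrom"] == c, "pos"].max())
            for c in table.chroms()
        }
    return make_windows(chrom_lengths, width, step)


def window_pi(
    table: VariantTable,
    samples: list[str] | None = None,
    width: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
    step: int | None = None,
    het_policy: str = "missing",
) -> WindowTrack:
    """Windowed nucleotide diversity.

    Per site with a ref alleles and b alt alleles among non-missing calls
    (n = a + b >= 2), the contribution is a*b / C(n, 2); window value is
    the sum of contributions divided by the window's true width (including
    invariant sites; partial final windows use their residual width).
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    sub = table if samples is None else table.subset_samples(samples)
    a, b = _allele_counts(sub.gt, het_policy)
    n = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(n >= 2, a * b / (n * (n - 1) / 2.0), 0.0)
    informative = n >= 2

    windows = _window_frame(table, chrom_lengths, width, step)
    idx = assign_windows(windows, sub.sites["chrom"].to_numpy(), sub.sites["pos"].to_numpy() - 1)
    ok = idx >= 0
    sums = np.zeros(len(windows))
    counts = np.zeros(len(windows), dtype=np.int64)
    np.add.at(sums, idx[ok], contrib[ok])
    np.add.at(counts, idx[ok], informative[ok].astype(np.int64))
    widths = (windows["end"] - windows["start"]).to_numpy()
    frame = windows.copy()
    frame["value"] = sums / widths
    frame["n_sites"] = counts
    return WindowTrack(frame, width=width)


def pairwise_diversity(
    table: VariantTable,
    sample_x: str,
    sample_y: str,
    width: int = 1_000_000,
    chrom_lengths: dict[str, int] | None = None,
) -> WindowTrack:
    """Per-window fraction of sites at which two samples differ.

    Value = (# sites with different non-missing alleles) / window width;
    n_sites = # sites where both samples are non-missing. Windows with no
    informative site are NaN.
    """
    gx = table.gt[:, table.sample_index(sample_x)]
    gy = table.gt[:, table.sample_index(sample_y)]
    informative = (gx != -1) & (gy != -1)
    differs = informative & (gx != gy)

    windows = _window_frame(table, chrom_lengths, width, None)
    idx = assign_windows(windows, table.sites["chrom"].to_numpy(), table.sites["pos"].to_numpy() - 1)
    ok = idx >= 0
    diffs = np.zeros(len(windows))
    counts = np.zeros(len(windows), dtype=np.int64)
    np.add.at(diffs, idx[ok], differs[ok].astype(float))
    np.add.at(counts, idx[ok], informative[ok].astype(np.int64))
    widths = (windows["end"] - windows["start"]).to_numpy()
    frame = windows.copy()
    frame["value"] = np.where(counts > 0, diffs / widths, np.nan)
    frame["n_sites"] = counts
    return WindowTrack(frame, width=width)


def wc_fst_per_site(
    a1: np.ndarray, b1: np.ndarray, a2: np.ndarray, b2: np.ndarray
) -> np.ndarray:
    """Weir-Cockerham theta per site from haploid allele counts.

    ANOVA estimator for haploid data over r = 2 populations with sample
    sizes n_i and alt-allele frequencies p_i:

        MSP = sum n_i (p_i - pbar)^2 / (r - 1)
        MSG = sum n_i p_i (1 - p_i) / sum (n_i - 1)
        n_c = (n_tot - sum n_i^2 / n_tot) / (r - 1)
        theta = (MSP - MSG) / (MSP + (n_c - 1) MSG)

    Returns NaN where undefined (a group with no calls, or a site fixed
    across both groups, where the denominator vanishes).
    """
    n1 = a1 + b1
    n2 = a2 + b2
    ntot = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = b1 / n1
        p2 = b2 / n2
        pbar = (b1 + b2) / ntot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
        nc = (ntot - (n1**2 + n2**2) / ntot)
        denom = msp + (nc - 1) * msg
        theta = np.where(denom != 0, (msp - msg) / denom, np.nan)
    bad = (n1 < 1) | (n2 < 1) | (ntot < 3)
    return np.where(bad, np.nan, theta)


def window_fst(
    table: VariantTable,
    group1_samples: list[str],
    group2_samples: list[str],
    width: int = 1_000_000,
    chrom_lengths: dict[str, int] | None = None,
    het_policy: str = "missing",
    mode: str = "mean",
) -> WindowTrack:
    """Windowed Weir-Cockerham Fst between two sample groups.

    Sites fixed across both groups are skipped. ``mode="mean"`` averages
    per-site estimates (negative values retained); ``mode="ratio"`` uses
    the ratio-of-sums form (sum numerators / sum denominators).
    """
    overlap = set(group1_samples) & set(group2_samples)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group1_samples) < 2 or len(group2_samples) < 2:
        raise ValueError("both groups need >= 2 samples")
    g1 = table.subset_samples(group1_samples)
    g2 = table.subset_samples(group2_samples)
    a1, b1 = _allele_counts(g1.gt, het_policy)
    a2, b2 = _allele_counts(g2.gt, het_policy)

    fixed = ((b1 + b2) == 0) | ((a1 + a2) == 0)
    theta = wc_fst_per_site(a1, b1, a2, b2)
    usable = ~fixed & ~np.isnan(theta)

    windows = _window_frame(table, chrom_lengths, width, None)
    idx = assign_windows(windows, table.sites["chrom"].to_numpy(), table.sites["pos"].to_numpy() - 1)
    ok = (idx >= 0) & usable
    frame = windows.copy()
    counts = np.zeros(len(windows), dtype=np.int64)
    np.add.at(counts, idx[ok], 1)
    if mode == "mean":
        sums = np.zeros(len(windows))
        np.add.at(sums, idx[ok], theta[ok])
        with np.errstate(invalid="ignore"):
            frame["value"] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    elif mode == "ratio":
        n1 = a1 + b1
        n2 = a2 + b2
        ntot = n1 + n2
        with np.errstate(divide="ignore", invalid="ignore"):
            p1 = b1 / n1
            p2 = b2 / n2
            pbar = (b1 + b2) / ntot
            msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
            msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
            nc = ntot - (n1**2 + n2**2) / ntot
            num = msp - msg
            den = msp + (nc - 1) * msg
        nums = np.zeros(len(windows))
        dens = np.zeros(len(windows))
        np.add.at(nums, idx[ok], num[ok])
        np.add.at(dens, idx[ok], den[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            frame["value"] = np.where(dens != 0, nums / dens, np.nan)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    frame["n_sites"] = counts
    return WindowTrack(frame, width=width)


def snp_density(
    table: VariantTable,
    width: int = 1_000_000,
    chrom_lengths: dict[str, int] | None = None,
) -> WindowTrack:
    """SNP count per window."""
    windows = _window_frame(table, chrom_lengths, width, None)
    idx = assign_windows(windows, table.sites["chrom"].to_numpy(), table.sites["pos"].to_numpy() - 1)
    counts = np.zeros(len(windows), dtype=np.int64)
    np.add.at(counts, idx[idx >= 0], 1)
    frame = windows.copy()
    frame["value"] = counts.astype(float)
    frame["n_sites"] = counts
    return WindowTrack(frame, width=width)


def annotation_filter(table: VariantTable, rules: dict[str, tuple[str, float]]) -> VariantTable:
    """Generic per-record numeric thresholds on optional annotation columns.

    ``rules`` maps column name -> (op, threshold) with op in {"<", ">",
    "<=", ">="}; a record failing any rule is removed. Records lacking the
    column (NaN) pass.
    """
    ops = {
        "<": np.less, ">": np.greater, "<=": np.less_equal, ">=": np.greater_equal,
    }
    keep = np.ones(len(table), dtype=bool)
    for col, (op, thr) in rules.items():
        if col not in table.sites:
            continue
        vals = pd.to_numeric(table.sites[col], errors="coerce").to_numpy(dtype=float)
        fails = ops[op](vals, thr)
        keep &= ~np.where(np.isnan(vals), False, fails)
    return table.subset_sites(keep)
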