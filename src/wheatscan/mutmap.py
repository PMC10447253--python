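"""Bulked-segregant SNP-index mapping of a recessive EMS mutation.

Works on allele-depth tables (chrom, pos, ref, alt, depth, alt_depth) from
a mutant bulk. The SNP index is alt_depth/depth; indices >= 0.9 are called
homozygous, < 0.3 are removed, the rest are heterozygous-class. Window
averaging (default 100 kb) of surviving indices localizes the causal SNP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from wheatscan.core.segments import Segment
from wheatscan.core.windows import WindowTrack, assign_windows, make_windows

HOMOZYGOUS_MIN_INDEX = 0.9
REMOVAL_INDEX = 0.3


@dataclass
class BulkFilterThresholds:
    """Removal conditions on optional per-record annotation columns."""

    min_qual: float = 30.0     # remove QUAL < 30
    max_fs: float = 40.0       # remove FS > 40
    min_mq: float = 40.0       # remove MQ < 40
    min_dp: int = 3            # remove DP <= 3
    min_gq: float = 20.0       # remove GQ < 20
    indel_proximity: int = 10  # remove SNPs within 10 bp of an indel


def filter_bulk_variants(
    raw_table: pd.DataFrame,
    thresholds: BulkFilterThresholds | None = None,
    indel_positions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply bulk SNP hard filters.

    ``raw_table`` needs chrom/pos/ref/alt and may carry qual, fs, mq, gq
    columns plus an ``is_indel`` flag; absent annotations pass (logged via
    warning). ``indel_positions`` (chrom, pos) supplements is_indel rows as
    the indel proximity reference.
    """
    t = thresholds or BulkFilterThresholds()
    df = raw_table.reset_index(drop=True)
    keep = np.ones(len(df), dtype=bool)

    is_indel = (
        df["is_indel"].fillna(False).to_numpy(dtype=bool)
        if "is_indel" in df
        else np.zeros(len(df), dtype=bool)
    )
    # biallelic single-base SNPs only
    snp_like = (
        df["ref"].astype(str).str.len().eq(1)
        & df["alt"].astype(str).str.len().eq(1)
        & ~df["alt"].astype(str).str.contains(",")
    ).to_numpy()
    keep &= snp_like & ~is_indel

    absent = []
    rules = [
        ("qual", lambda v: v < t.min_qual),
        ("fs", lambda v: v > t.max_fs),
        ("mq", lambda v: v < t.min_mq),
        ("depth", lambda v: v <= t.min_dp),
        ("gq", lambda v: v < t.min_gq),
    ]
    for col, fails in rules:
        if col not in df:
            absent.append(col)
            continue
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        keep &= ~np.where(np.isnan(vals), False, fails(vals))
    if absent:
        warnings.warn(
            f"annotation columns absent, treated as passing: {absent}",
            stacklevel=2,
        )

    # indel proximity
    indels = []
    if is_indel.any():
        indels.append(df.loc[is_indel, ["chrom", "pos"]])
    if indel_positions is not None and len(indel_positions):
        indels.append(indel_positions[["chrom", "pos"]])
    if indels:
        ind = pd.concat(indels, ignore_index=True)
        for chrom, grp in ind.groupby("chrom", sort=False):
            ipos = np.sort(grp["pos"].to_numpy())
            sel = (df["chrom"] == chrom).to_numpy() & keep
            pos = df["pos"].to_numpy()[sel]
            j = np.searchsorted(ipos, pos)
            near = np.zeros(len(pos), dtype=bool)
            left_ok = j > 0
            near[left_ok] |= pos[left_ok] - ipos[j[left_ok] - 1] <= t.indel_proximity
            right_ok = j < len(ipos)
            near[right_ok] |= ipos[j[right_ok]] - pos[right_ok] <= t.indel_proximity
            idxs = np.flatnonzero(sel)
            keep[idxs[near]] = False
    return df[keep].reset_index(drop=True)


def remove_varietal(bulk_table: pd.DataFrame, parent_table: pd.DataFrame) -> pd.DataFrame:
    """Drop bulk records whose (chrom, pos, alt) also appears in the parent
    control — shared background ("varietal") variants, not EMS-induced."""
    if len(parent_table) == 0:
        return bulk_table.reset_index(drop=True)
    parent_keys = set(
        zip(parent_table["chrom"], parent_table["pos"], parent_table["alt"])
    )
    mask = [
        (c, p, a) not in parent_keys
        for c, p, a in zip(bulk_table["chrom"], bulk_table["pos"], bulk_table["alt"])
    ]
    return bulk_table[mask].reset_index(drop=True)


def ems_filter(table: pd.DataFrame) -> pd.DataFrame:
    """Retain only EMS-type transitions on the reference strand:
    G->A and C->T."""
    keep = ((table["ref"] == "G") & (table["alt"] == "A")) | (
        (table["ref"] == "C") & (table["alt"] == "T")
    )
    return table[keep].reset_index(drop=True)


def is_ems_type(ref: str, alt: str) -> bool:
    return (ref, alt) in {("G", "A"), ("C", "T")}


def snp_index_scan(
    table: pd.DataFrame,
    width: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, WindowTrack]:
    """Per-record SNP indices and their windowed means.

    Records with depth <= 0 are rejected with a warning. Indices < 0.3 are
    classed "removed" and excluded from window averaging; >= 0.9 are
    "homozygous"; the rest "heterozygous". Window value = mean index of
    surviving records (NaN when none).
    """
    df = table.reset_index(drop=True).copy()
    bad = df["depth"].to_numpy() <= 0
    if bad.any():
        warnings.warn(f"rejecting {int(bad.sum())} records with depth <= 0",
                      stacklevel=2)
        df = df[~bad].reset_index(drop=True)
    idx = df["alt_depth"].to_numpy() / df["depth"].to_numpy()
    if (idx < 0).any() or (idx > 1).any():
        raise ValueError("alt_depth must lie in [0, depth]")
    df["snp_index"] = idx
    df["ems_type"] = [
        is_ems_type(r, a) for r, a in zip(df["ref"], df["alt"])
    ]
    df["class"] = np.select(
        [idx >= HOMOZYGOUS_MIN_INDEX, idx < REMOVAL_INDEX],
        ["homozygous", "removed"],
        "heterozygous",
    )

    if chrom_lengths is None:
        chrom_lengths = {
            c: int(df.loc[df["chrom"] == c, "pos"].max())
            for c in dict.fromkeys(df["chrom"])
        }
    windows = make_windows(chrom_lengths, width)
    surviving = (df["class"] != "removed").to_numpy()
    widx = assign_windows(
        windows, df["chrom"].to_numpy(), df["pos"].to_numpy() - 1
    )
    ok = surviving & (widx >= 0)
    sums = np.zeros(len(windows))
    counts = np.zeros(len(windows), dtype=np.int64)
    np.add.at(sums, widx[ok], idx[ok])
    np.add.at(counts, widx[ok], 1)
    frame = windows.copy()
    with np.errstate(invalid="ignore"):
        frame["value"] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    frame["n_sites"] = counts
    return df, WindowTrack(frame, width=width)


def plot_snp_index(track: WindowTrack, path, causal: tuple[str, int] | None = None) -> None:
    """Per-chromosome windowed SNP-index panels (PNG/PDF via matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = track.chroms()
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 2.2 * len(chroms)),
                             squeeze=False, sharey=True)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = track.frame[track.frame["chrom"] == chrom]
        mid = (sub["start"] + sub["end"]) / 2e6
        ax.plot(mid, sub["value"], ".", ms=3)
        ax.axhline(HOMOZYGOUS_MIN_INDEX, ls="--", lw=0.8, color="grey")
        if causal is not None and causal[0] == chrom:
            ax.axvline(causal[1] / 1e6, color="red", lw=0.8)
        ax.set_ylabel("SNP index")
        ax.set_title(chrom, fontsize=9)
        ax.set_ylim(0, 1.05)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def candidate_interval(
    windows: WindowTrack,
    records: pd.DataFrame,
    index_threshold: float = 0.9,
) -> tuple[Segment | None, pd.DataFrame]:
    """Longest run of contiguous windows with mean index >= threshold.

    NaN windows are tolerated inside a run but do not extend its ends.
    Returns the interval (None when no window qualifies) and the
    homozygous EMS-type records inside it.
    """
    frame = windows.frame
    chroms = frame["chrom"].to_numpy()
    starts = frame["start"].to_numpy()
    ends = frame["end"].to_numpy()
    vals = windows.values
    best: tuple[int, str, int, int] | None = None  # (n_pass, chrom, lo, hi)
    for chrom in windows.chroms():
        cidx = np.flatnonzero(chroms == chrom)
        v = vals[cidx]
        defined = ~np.isnan(v)
        passing = np.where(defined, v >= index_threshold, False)
        i, n = 0, len(cidx)
        while i < n:
            if passing[i]:
                j = i
                last = i
                n_pass = 0
                while j < n and (not defined[j] or passing[j]):
                    if passing[j]:
                        last = j
                        n_pass += 1
                    j += 1
                if best is None or n_pass > best[0]:
                    best = (n_pass, str(chrom), int(starts[cidx[i]]), int(ends[cidx[last]]))
                i = j
            else:
                i += 1
    if best is None:
        return None, records.iloc[0:0]
    _, chrom, lo, hi = best
    seg = Segment(chrom, lo, hi, label="candidate_interval")
    inside = (
        (records["chrom"] == chrom)
        & (records["pos"] - 1 >= lo)
        & (records["pos"] - 1 < hi)
        & (records["class"] == "homozygous")
        & records["ems_type"]
    )
    return seg, records[inside].reset_index(drop=True)
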