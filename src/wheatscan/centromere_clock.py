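"""Centromere boundaries from enrichment-peak density and LTR insertion ages.

Peak density is the clipped-union covered fraction per 100 kb bin; the
longest above-threshold run per chromosome (with gap tolerance) is the
functional centromere. Insertion age of an LTR retrotransposon follows
from the divergence of its two LTRs, identical at insertion time:
Jukes-Cantor K = -(3/4) ln(1 - 4p/3), age = K / (2 * rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from wheatscan.core.segments import Segment
from wheatscan.core.windows import WindowTrack, make_windows


def peak_density(
    peaks: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_width: int = 100_000,
) -> WindowTrack:
    """Fraction of each bin covered by the union of peak intervals.

    ``peaks`` columns: chrom, start, end (0-based half-open; BED-style).
    Overlapping peaks are unioned before coverage is measured.
    """
    windows = make_windows(chrom_lengths, bin_width)
    covered = np.zeros(len(windows))
    for chrom, length in chrom_lengths.items():
        sub = peaks[peaks["chrom"] == chrom].sort_values("start")
        if len(sub) == 0:
            continue
        # clipped union of intervals
        merged: list[list[int]] = []
        for s, e in zip(sub["start"], sub["end"]):
            s, e = max(0, int(s)), min(length, int(e))
            if e <= s:
                continue
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cidx = np.flatnonzero((windows["chrom"] == chrom).to_numpy())
        starts = windows["start"].to_numpy()[cidx]
        ends = windows["end"].to_numpy()[cidx]
        for s, e in merged:
            first = np.searchsorted(ends, s, side="right")
            last = np.searchsorted(starts, e, side="left")
            for w in range(first, last):
                covered[cidx[w]] += min(e, ends[w]) - max(s, starts[w])
    frame = windows.copy()
    widths = (windows["end"] - windows["start"]).to_numpy()
    frame["value"] = covered / widths
    frame["n_sites"] = (covered > 0).astype(np.int64)
    return WindowTrack(frame, width=bin_width)


def call_centromere(
    density: WindowTrack,
    threshold: float = 0.1,
    merge_gap_bins: int = 5,
) -> dict[str, Segment | None]:
    """Longest above-threshold run per chromosome (with gap tolerance).

    Bins with density >= threshold are grouped, allowing up to
    ``merge_gap_bins`` consecutive below-threshold bins inside a run; the
    longest run per chromosome is reported with its mean density as score.
    Chromosomes with no passing bin map to None.
    """
    frame = density.frame
    chroms = frame["chrom"].to_numpy()
    starts = frame["start"].to_numpy()
    ends = frame["end"].to_numpy()
    vals = density.values
    out: dict[str, Segment | None] = {}
    for chrom in density.chroms():
        cidx = np.flatnonzero(chroms == chrom)
        passing = vals[cidx] >= threshold
        best = None
        i, n = 0, len(cidx)
        while i < n:
            if passing[i]:
                j = i
                last = i
                gap = 0
                while j + 1 < n:
                    if passing[j + 1]:
                        j += 1
                        last = j
                        gap = 0
                    elif gap + 1 <= merge_gap_bins:
                        j += 1
                        gap += 1
                    else:
                        break
                length = last - i + 1
                if best is None or length > best[0]:
                    best = (length, i, last)
                i = last + 1
            else:
                i += 1
        if best is None:
            out[str(chrom)] = None
        else:
            _, lo, hi = best
            run = cidx[lo:hi + 1]
            out[str(chrom)] = Segment(
                str(chrom), int(starts[run[0]]), int(ends[run[-1]]),
                label="centromere", score=float(np.mean(vals[run])),
            )
    return out


@dataclass
class LtrDivergence:
    p: float                 # raw mismatch proportion over aligned columns
    k: float                 # Jukes-Cantor corrected distance (NaN if saturated)
    n_columns: int           # aligned non-gap, non-N columns
    saturated: bool


def ltr_divergence(ltr5: str, ltr3: str) -> LtrDivergence:
    """Divergence between the two LTRs of one element.

    Equal-length sequences are compared positionally; otherwise a global
    alignment with unit mismatch/gap costs is computed first. Gap columns
    and columns containing N are excluded. p >= 0.75 saturates the
    Jukes-Cantor correction and is flagged (K = NaN).
    """
    a, b = ltr5.upper(), ltr3.upper()
    if not a or not b:
        raise ValueError("empty LTR sequence")
    if len(a) != len(b):
        a, b = _global_align(a, b)
    pairs = [
        (x, y)
        for x, y in zip(a, b)
        if x not in "-N" and y not in "-N"
    ]
    if not pairs:
        raise ValueError("no alignable columns between LTRs")
    n = len(pairs)
    mism = sum(1 for x, y in pairs if x != y)
    p = mism / n
    if p >= 0.75:
        return LtrDivergence(p, float("nan"), n, True)
    k = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return LtrDivergence(p, k, n, False)


def _global_align(a: str, b: str) -> tuple[str, str]:
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def insertion_age(k: float, rate: float) -> float:
    """Insertion age in years: K / (2 * rate).

    ``rate`` is substitutions/site/year per LTR; the factor 2 accounts for
    both LTRs diverging independently since insertion. A NaN (saturated) K
    propagates.
    """
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    return k / (2.0 * rate)


def age_table(
    pairs: dict[str, tuple[str, str]], rate: float
) -> pd.DataFrame:
    """Per-element TSV-ready table (id, p, K, age) for LTR pairs."""
    rows = []
    for elem_id, (ltr5, ltr3) in pairs.items():
        d = ltr_divergence(ltr5, ltr3)
        rows.append(
            {
                "element": elem_id,
                "p": d.p,
                "K": d.k,
                "age": insertion_age(d.k, rate) if not d.saturated else float("nan"),
                "saturated": d.saturated,
            }
        )
    return pd.DataFrame(rows, columns=["element", "p", "K", "age", "saturated"])


def read_ltr_pairs_fasta(path) -> dict[str, tuple[str, str]]:
    """Read LTR pairs from FASTA with ids suffixed _5LTR / _3LTR."""
    from Bio import SeqIO

    five: dict[str, str] = {}
    three: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id.endswith("_5LTR"):
            five[rec.id[:-5]] = str(rec.seq)
        elif rec.id.endswith("_3LTR"):
            three[rec.id[:-5]] = str(rec.seq)
    out = {}
    for elem in five:
        if elem in three:
            out[elem] = (five[elem], three[elem])
    return out
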