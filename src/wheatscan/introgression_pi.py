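"""Diversity-reduction introgression calling from pairwise-diversity tracks.

A candidate segment is a run of consecutive windows in which diversity
between a target accession and the putative donor falls well below the
genome-wide background. Three criteria must hold: (1) the run spans at
least ``min_span``; (2) the same region is NOT reduced against a control
(outgroup) accession; (3) the reduction is not explained by missing data
(informative-site or depth proxy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from wheatscan.core.segments import Segment, merge_segments
from wheatscan.core.windows import WindowTrack


@dataclass
class PiCallParams:
    reduction_factor: float = 0.25  # "reduced" = value < factor x genome median
    min_span: int = 10_000_000      # minimum total qualifying span, bp
    min_coverage_frac: float = 0.5  # criterion-3 floor vs coverage genome median


def _runs_of(qualifies: np.ndarray, defined: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of qualifying windows; NaN (undefined) windows neither
    break a run nor count toward it. Returns [start_idx, end_idx) pairs
    trimmed to defined qualifying windows at both ends."""
    runs = []
    i, n = 0, len(qualifies)
    while i < n:
        if defined[i] and qualifies[i]:
            j = i
            last_good = i
            while j < n and (not defined[j] or qualifies[j]):
                if defined[j]:
                    last_good = j
                j += 1
            runs.append((i, last_good + 1))
            i = j
        else:
            i += 1
    return runs


def call_pi_introgressions(
    target_track: WindowTrack,
    control_track: WindowTrack,
    coverage_track: WindowTrack | None = None,
    params: PiCallParams | None = None,
    label: str = "introgression",
) -> list[Segment]:
    """Call introgression segments from a target pairwise-diversity track.

    ``coverage_track`` defaults to the ``n_sites`` channel of the target
    track (informative sites as a mapped-read proxy).
    """
    p = params or PiCallParams()
    target_track.require_same_windows(control_track)
    if coverage_track is None:
        frame = target_track.frame[["chrom", "start", "end"]].copy()
        frame["value"] = target_track.frame["n_sites"].astype(float)
        frame["n_sites"] = target_track.frame["n_sites"]
        coverage_track = WindowTrack(frame, width=target_track.width)
    else:
        target_track.require_same_windows(coverage_track)

    tgt = target_track.values
    ctl = control_track.values
    cov = coverage_track.values
    tgt_median = target_track.genome_median()
    ctl_median = control_track.genome_median()
    cov_median = coverage_track.genome_median()
    threshold = p.reduction_factor * tgt_median

    frame = target_track.frame
    segments: list[Segment] = []
    for chrom in target_track.chroms():
        sel = (frame["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(sel)
        vals = tgt[idx]
        defined = ~np.isnan(vals)
        qualifies = np.where(defined, vals < threshold, False)
        starts = frame["start"].to_numpy()[idx]
        ends = frame["end"].to_numpy()[idx]
        widths = ends - starts
        for lo, hi in _runs_of(qualifies, defined):
            run = slice(lo, hi)
            span = int(widths[run][qualifies[run] & defined[run]].sum())
            if span < p.min_span:
                continue
            crit2 = bool(
                np.nanmedian(ctl[idx][run]) >= p.reduction_factor * ctl_median
            ) if np.any(~np.isnan(ctl[idx][run])) else False
            crit3 = bool(
                np.nanmedian(cov[idx][run]) >= p.min_coverage_frac * cov_median
            ) if np.any(~np.isnan(cov[idx][run])) else False
            if not (crit2 and crit3):
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = float(np.nanmean(vals[run]) / tgt_median) if tgt_median > 0 else 0.0
            segments.append(
                Segment(
                    chrom,
                    int(starts[lo]),
                    int(ends[hi - 1]),
                    label=label,
                    score=ratio,
                    evidence={"span": True, "control": crit2, "coverage": crit3},
                )
            )
    return segments


def genome_fraction(segments: list[Segment], genome_length: int) -> float:
    """Fraction of the genome covered by merged, non-overlapping segments."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    merged = merge_segments(segments, gap=-1)
    for a, b in zip(merged, merged[1:]):
        if a.overlaps(b):
            raise RuntimeError("segments overlap after merge")
    return sum(s.length for s in merged) / genome_length


def fraction_summary(
    segments_by_accession: dict[str, list[Segment]], genome_length: int
) -> pd.DataFrame:
    """Per-accession genome fractions plus panel mean/min/max rows."""
    rows = [
        {"accession": acc, "fraction": genome_fraction(segs, genome_length)}
        for acc, segs in segments_by_accession.items()
    ]
    df = pd.DataFrame(rows, columns=["accession", "fraction"])
    if len(df):
        stats = pd.DataFrame(
            {
                "accession": ["panel_mean", "panel_min", "panel_max"],
                "fraction": [df["fraction"].mean(), df["fraction"].min(), df["fraction"].max()],
            }
        )
        df = pd.concat([df, stats], ignore_index=True)
    return df
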