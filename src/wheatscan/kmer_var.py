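"""Identity-by-state variation scores against query k-mer databases.

For each fixed window of a reference genome, the variation score counts
maximal runs of consecutive k-mer start positions whose canonical k-mer is
absent from a query accession's k-mer set (a point substitution produces
one absent-run of length k, hence one variation). Windows identical by
state to the query score <= the IBS cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from wheatscan.core.seqs import SequenceSet
from wheatscan.core.segments import Segment
from wheatscan.core.windows import WindowTrack, make_windows
from wheatscan.kmer_map import KmerSet, scan_genome


def window_variations(
    reference: SequenceSet,
    query_kmers: KmerSet,
    k: int = 31,
    width: int = 50_000,
    query_id: str = "",
) -> WindowTrack:
    """Variation count per window of the reference against one query set.

    A variation is a maximal run of consecutive reference positions whose
    canonical k-mer is absent from the query; the run is attributed to the
    window containing its start. ``n_sites`` reports absent positions per
    window.
    """
    if query_kmers.k != k:
        raise ValueError(f"query k-mer set has k={query_kmers.k}, expected {k}")
    matches = scan_genome(reference, query_kmers)
    windows = make_windows(reference.lengths(), width)
    values = np.zeros(len(windows))
    n_sites = np.zeros(len(windows), dtype=np.int64)
    for chrom in reference:
        member = matches[chrom]
        absent = ~member
        if len(absent) == 0:
            continue
        run_start = absent & ~np.concatenate([[False], absent[:-1]])
        sel = (windows["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(sel)
        starts = windows["start"].to_numpy()[idx]
        ends = windows["end"].to_numpy()[idx]
        bins = np.append(starts, ends[-1])
        values[idx] = np.histogram(np.flatnonzero(run_start), bins=bins)[0]
        n_sites[idx] = np.histogram(np.flatnonzero(absent), bins=bins)[0]
    frame = windows.copy()
    frame["value"] = values
    frame["n_sites"] = n_sites
    if query_id:
        frame["query"] = query_id
    return WindowTrack(frame, width=width)


@dataclass
class IbsParams:
    cutoff: int = 30
    merge_gap_windows: int = 1  # tolerated interior failing windows
    min_windows: int = 2


def ibs_segments(
    track: WindowTrack,
    cutoff: int = 30,
    merge_gap_windows: int = 1,
    min_windows: int = 2,
    label: str = "ibs",
) -> list[Segment]:
    """Maximal runs of windows with variation score <= cutoff.

    Up to ``merge_gap_windows`` consecutive failing windows inside a run
    are tolerated; runs with fewer than ``min_windows`` passing windows
    are dropped.
    """
    frame = track.frame
    chroms = frame["chrom"].to_numpy()
    starts = frame["start"].to_numpy()
    ends = frame["end"].to_numpy()
    vals = track.values
    passing = vals <= cutoff
    segments: list[Segment] = []
    for chrom in track.chroms():
        idx = np.flatnonzero(chroms == chrom)
        p = passing[idx]
        i, n = 0, len(idx)
        while i < n:
            if p[i]:
                j = i
                last_pass = i
                n_pass = 1
                gap = 0
                while j + 1 < n:
                    if p[j + 1]:
                        j += 1
                        last_pass = j
                        n_pass += 1
                        gap = 0
                    elif gap + 1 <= merge_gap_windows:
                        j += 1
                        gap += 1
                    else:
                        break
                if n_pass >= min_windows:
                    lo, hi = idx[i], idx[last_pass]
                    segments.append(
                        Segment(
                            chrom, int(starts[lo]), int(ends[hi]),
                            label=label,
                            score=float(np.mean(vals[idx[i]:idx[last_pass] + 1])),
                        )
                    )
                i = last_pass + 1
            else:
                i += 1
    return segments


def min_consensus(tracks: list[WindowTrack], track_ids: list[str] | None = None) -> WindowTrack:
    """Per-window minimum across tracks, with argmin provenance.

    The returned track carries an ``argmin`` column listing the id(s) of
    the track(s) attaining the minimum in each window (comma-joined on
    ties).
    """
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        first.require_same_windows(t)
    ids = track_ids or [str(i) for i in range(len(tracks))]
    if len(ids) != len(tracks):
        raise ValueError("track_ids length mismatch")
    mat = np.vstack([t.values for t in tracks])
    mins = mat.min(axis=0)
    argmin = [
        ",".join(ids[j] for j in np.flatnonzero(mat[:, i] == mins[i]))
        for i in range(mat.shape[1])
    ]
    frame = first.frame[["chrom", "start", "end"]].copy()
    frame["value"] = mins
    frame["n_sites"] = np.vstack([t.frame["n_sites"].to_numpy() for t in tracks]).min(axis=0)
    frame["argmin"] = argmin
    return WindowTrack(frame, width=first.width)


def assign_donor_group(
    segment: Segment,
    tracks_by_group: dict[str, list[WindowTrack]],
    cutoff: int = 30,
    majority: float = 0.75,
) -> str:
    """Assign a donor group to an IBS segment, or "unassigned".

    For each group, the per-window minimum across its tracks is taken over
    the segment's windows; the group's support is the fraction of windows
    with minimum <= cutoff. The top group is assigned only if its support
    is >= ``majority`` and strictly exceeds every other group's.
    """
    fractions: dict[str, float] = {}
    for group, tracks in tracks_by_group.items():
        cons = min_consensus(tracks) if len(tracks) > 1 else tracks[0]
        frame = cons.frame
        in_seg = (
            (frame["chrom"] == segment.chrom)
            & (frame["start"] < segment.end)
            & (frame["end"] > segment.start)
        ).to_numpy()
        if not in_seg.any():
            raise ValueError(
                f"segment {segment.chrom}:{segment.start}-{segment.end} has no "
                f"windows in group {group!r} track"
            )
        vals = cons.values[in_seg]
        fractions[group] = float(np.mean(vals <= cutoff))
    best = max(fractions, key=fractions.get)
    best_frac = fractions[best]
    if best_frac < majority:
        return "unassigned"
    if any(f >= best_frac for g, f in fractions.items() if g != best):
        return "unassigned"
    return best
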