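"""Fixed-width per-chromosome window tracks.

Windows are 0-based half-open and tile each chromosome (tumbling) unless a
step < width is configured; the final window of a chromosome may be partial.
Values are NaN-coded where the statistic is undefined (n_sites = 0).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

COLUMNS = ["chrom", "start", "end", "value", "n_sites"]


def make_windows(
    chrom_lengths: dict[str, int], width: int, step: int | None = None
) -> pd.DataFrame:
    """Window frame (chrom, start, end) tiling each chromosome."""
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    step = width if step is None else step
    if step <= 0 or step > width:
        raise ValueError(f"step must be in (0, width], got {step}")
    frames = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(frames, ignore_index=True)


class WindowTrack:
    """Per-chromosome fixed-width windows each carrying one numeric value."""

    def __init__(self, frame: pd.DataFrame, width: int | None = None):
        missing = [c for c in ("chrom", "start", "end", "value") if c not in frame]
        if missing:
            raise ValueError(f"window frame missing columns: {missing}")
        frame = frame.reset_index(drop=True).copy()
        if "n_sites" not in frame:
            frame["n_sites"] = 0
        self.frame = frame[COLUMNS + [c for c in frame.columns if c not in COLUMNS]]
        if width is None and len(frame):
            width = int((frame["end"] - frame["start"]).max())
        self.width = width

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy()

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    def same_windows(self, other: "WindowTrack") -> bool:
        a, b = self.frame, other.frame
        return (
            len(a) == len(b)
            and (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
            and (a["end"].to_numpy() == b["end"].to_numpy()).all()
        )

    def require_same_windows(self, other: "WindowTrack") -> None:
        if not self.same_windows(other):
            raise ValueError("window tracks do not share the same windowing")

    def genome_mean(self) -> float:
        """Mean of window values over defined (non-NaN) windows."""
        return float(np.nanmean(self.values)) if len(self) else float("nan")

    def genome_median(self) -> float:
        return float(np.nanmedian(self.values)) if len(self) else float("nan")

    def with_values(self, values: np.ndarray, n_sites: np.ndarray | None = None) -> "WindowTrack":
        frame = self.frame[["chrom", "start", "end"]].copy()
        frame["value"] = values
        frame["n_sites"] = self.frame["n_sites"] if n_sites is None else n_sites
        return WindowTrack(frame, width=self.width)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path: str | Path) -> "WindowTrack":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame)

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NaN")

    def __repr__(self) -> str:
        return f"WindowTrack({len(self)} windows, width={self.width})"


def assign_windows(
    windows: pd.DataFrame, chrom: np.ndarray, pos0: np.ndarray
) -> np.ndarray:
    """Index of the tumbling window containing each 0-based position.

    Assumes tumbling windows (step == width); returns -1 for positions on
    chromosomes absent from the frame or beyond the last window.
    """
    out = np.full(len(pos0), -1, dtype=np.int64)
    pos0 = np.asarray(pos0, dtype=np.int64)
    chrom = np.asarray(chrom)
    for c, grp in windows.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        sel = chrom == c
        if not sel.any():
            continue
        idx = np.searchsorted(starts, pos0[sel], side="right") - 1
        valid = (idx >= 0) & (pos0[sel] < ends[np.clip(idx, 0, len(ends) - 1)])
        res = np.where(valid, grp.index.to_numpy()[np.clip(idx, 0, len(ends) - 1)], -1)
        out[sel] = res
    return out
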