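"""Labelled genomic intervals with score and per-criterion evidence."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class Segment:
    """Genomic interval, 0-based half-open, with a label and a score."""

    chrom: str
    start: int
    end: int
    label: str = ""
    score: float = 0.0
    evidence: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"segment end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Segment") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_segments(segments: list[Segment], gap: int = 0) -> list[Segment]:
    """Merge same-chromosome segments separated by <= gap bp.

    Labels of merged members are preserved on the first member; scores are
    length-weighted means.
    """
    out: list[Segment] = []
    for seg in sorted(segments, key=lambda s: (s.chrom, s.start, s.end)):
        if out and seg.chrom == out[-1].chrom and seg.start - out[-1].end <= gap:
            prev = out[-1]
            total = prev.length + seg.length
            prev.score = (prev.score * prev.length + seg.score * seg.length) / total
            prev.end = max(prev.end, seg.end)
        else:
            out.append(
                Segment(seg.chrom, seg.start, seg.end, seg.label, seg.score,
                        dict(seg.evidence))
            )
    return out


def write_bed(segments: list[Segment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            name = seg.label if seg.label else "."
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{name}\t{seg.score:g}\n")


def read_bed(path: str | Path) -> list[Segment]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 and parts[3] != "." else ""
            score = float(parts[4]) if len(parts) > 4 else 0.0
            out.append(Segment(chrom, start, end, label, score))
    return out
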