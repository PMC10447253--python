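"""Simulation configuration and planted ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from wheatscan.core.segments import Segment, read_bed, write_bed


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generator.

    A single ``seed`` fixes every source of randomness; stage-local
    generators are derived deterministically from it.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"1A": 1_000_000})
    # substitutions/site expected on each population branch of the fixed
    # ((alpha),(beta,dom),(gamma)) topology
    mutation_rate_per_branch: float = 1e-4
    # substitutions/site on each accession's terminal branch (None -> rate/4)
    terminal_rate: float | None = None
    pop_sizes: dict[str, int] = field(
        default_factory=lambda: {"alpha": 4, "beta": 2, "dom": 4, "gamma": 2}
    )
    # (target accession, chrom, start, end, donor population[, donor accession])
    introgression_spec: list[tuple] = field(default_factory=list)
    ril_count: int = 50
    crossovers_per_chrom: float = 2.0
    obs_rate: float = 0.5
    obs_error_rate: float = 0.0
    bulk_size: int = 30
    depth: int = 10
    morgans_per_bp: float = 1e-8

    def __post_init__(self):
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} length must be > 0")
        if not 0 <= self.mutation_rate_per_branch < 1:
            raise ValueError("mutation_rate_per_branch must be in [0, 1)")
        if self.terminal_rate is not None and not 0 <= self.terminal_rate < 1:
            raise ValueError("terminal_rate must be in [0, 1)")
        for spec in self.introgression_spec:
            _target, chrom, start, end = spec[:4]
            if chrom not in self.chrom_lengths:
                raise ValueError(f"introgression on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(
                    f"introgression interval {chrom}:{start}-{end} out of bounds"
                )

    @property
    def effective_terminal_rate(self) -> float:
        if self.terminal_rate is not None:
            return self.terminal_rate
        return self.mutation_rate_per_branch / 4.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "introgression_spec" in raw:
            raw["introgression_spec"] = [tuple(x) for x in raw["introgression_spec"]]
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "seed": self.seed,
            "chrom_lengths": dict(self.chrom_lengths),
            "mutation_rate_per_branch": self.mutation_rate_per_branch,
            "terminal_rate": self.terminal_rate,
            "pop_sizes": dict(self.pop_sizes),
            "introgression_spec": [list(x) for x in self.introgression_spec],
            "ril_count": self.ril_count,
            "crossovers_per_chrom": self.crossovers_per_chrom,
            "obs_rate": self.obs_rate,
            "obs_error_rate": self.obs_error_rate,
            "bulk_size": self.bulk_size,
            "depth": self.depth,
            "morgans_per_bp": self.morgans_per_bp,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class TruthSet:
    """Planted ground truth emitted alongside every simulated artifact."""

    introgression_segments: list[Segment] = field(default_factory=list)
    crossover_positions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    causal_snp: tuple[str, int] | None = None
    ltr_ages: dict[str, float] = field(default_factory=dict)
    # which parent (0/1) each RIL chromosome starts with, keyed ril -> chrom
    start_parents: dict[str, dict[str, int]] = field(default_factory=dict)

    def validate(self, chrom_lengths: dict[str, int]) -> None:
        for seg in self.introgression_segments:
            if seg.chrom not in chrom_lengths or seg.end > chrom_lengths[seg.chrom]:
                raise ValueError(f"truth segment outside simulated genome: {seg}")
        for ril, pts in self.crossover_positions.items():
            by_chrom: dict[str, int] = {}
            for chrom, pos in pts:
                if chrom in by_chrom and pos <= by_chrom[chrom]:
                    raise ValueError(
                        f"crossovers not strictly increasing for {ril} on {chrom}"
                    )
                by_chrom[chrom] = pos

    def write_bed(self, path: str | Path) -> None:
        write_bed(self.introgression_segments, path)

    @staticmethod
    def read_bed(path: str | Path) -> list[Segment]:
        return read_bed(path)
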