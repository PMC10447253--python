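"""Named chromosome sequences (haploid representation of an inbred genotype)."""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

# base <-> 2-bit code tables; 255 marks non-ACGT
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


class SequenceSet(Mapping):
    """Ordered mapping of chromosome id -> uppercase DNA sequence (str).

    Sequences are over {A, C, G, T, N}; coordinates throughout the package
    are 0-based half-open unless a format dictates otherwise.
    """

    def __init__(self, sequences: Mapping[str, str] | None = None):
        self._seqs: dict[str, str] = {}
        if sequences:
            for name, seq in sequences.items():
                self[name] = seq

    def __setitem__(self, name: str, seq: str) -> None:
        self._seqs[name] = str(seq).upper()

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def codes(self, name: str) -> np.ndarray:
        """2-bit codes (A=0 C=1 G=2 T=3, 255 for non-ACGT) as uint8 array."""
        raw = np.frombuffer(self._seqs[name].encode("ascii"), dtype=np.uint8)
        return _CODE[raw]

    @staticmethod
    def from_codes(codes_by_chrom: Mapping[str, np.ndarray]) -> "SequenceSet":
        out = SequenceSet()
        for name, codes in codes_by_chrom.items():
            out[name] = _BASE[codes].tobytes().decode("ascii")
        return out

    def reverse_complement(self) -> "SequenceSet":
        return SequenceSet(
            {n: s.translate(_COMPLEMENT)[::-1] for n, s in self._seqs.items()}
        )

    @classmethod
    def read_fasta(cls, path: str | Path) -> "SequenceSet":
        out = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            out[rec.id] = str(rec.seq)
        return out

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        records = (
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self._seqs.items()
        )
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)

    def __repr__(self) -> str:
        body = ", ".join(f"{n}:{len(s)}bp" for n, s in self._seqs.items())
        return f"SequenceSet({body})"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving map)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform-random sequence over {A, C, G, T}."""
    if length <= 0:
        raise ValueError(f"sequence length must be positive, got {length}")
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return _BASE[codes].tobytes().decode("ascii")
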