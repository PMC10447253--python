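"""Species-specific canonical k-mer sets and genome scanning.

"Mapping full-length k-mers with no mismatches" is implemented as exact
canonical-membership lookup: a genome position matches when the canonical
form of the k-mer starting there is in the set. K-mers are packed into
fixed-width byte keys (4 bases per byte, memcmp-ordered) so set algebra
and membership run as vectorized numpy operations on byte strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from wheatscan.core.seqs import SequenceSet, reverse_complement
from wheatscan.core.segments import Segment, merge_segments
from wheatscan.core.windows import WindowTrack, make_windows

def key_dtype(k: int) -> str:
    """Fixed-width byte-string dtype packing k 2-bit bases, 4 per byte.

    Bases are left-aligned within each byte and the final partial byte is
    zero-padded, so memcmp order of keys equals lexicographic order of the
    k-mer strings (A < C < G < T).
    """
    return f"S{(k + 3) // 4}"


def _pack_strand(codes: np.ndarray, k: int, m: int) -> np.ndarray:
    """Packed keys for all m start positions of one strand's code array."""
    # 4-base byte lattice over the whole sequence, computed once
    b = (
        (codes[:-3].astype(np.uint16) << 6)
        | (codes[1:-2].astype(np.uint16) << 4)
        | (codes[2:-1].astype(np.uint16) << 2)
        | codes[3:].astype(np.uint16)
    ).astype(np.uint8)
    nbytes = (k + 3) // 4
    out = np.zeros((m, nbytes), dtype=np.uint8)
    full = k // 4
    for t in range(full):
        out[:, t] = b[4 * t: 4 * t + m]
    r = k % 4
    if r:
        # partial final byte: top r bases only, zero-padded (the 4-base
        # lattice would leak bases beyond the k-mer, so build it directly)
        tail = np.zeros(m, dtype=np.uint8)
        for j in range(r):
            tail |= (codes[4 * full + j: 4 * full + j + m].astype(np.uint8)
                     << (6 - 2 * j)).astype(np.uint8)
        out[:, full] = tail
    return np.ascontiguousarray(out).view(key_dtype(k)).reshape(m)


def _pack_positions(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical packed keys for every k-mer start position of a sequence.

    Returns (keys, valid); positions whose window spans a non-ACGT symbol
    are invalid and carry an arbitrary key.
    """
    n = len(codes)
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=key_dtype(k)), np.empty(0, dtype=bool)
    invalid = (codes == 255).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(invalid)])
    valid = (cum[k:] - cum[:-k]) == 0
    safe = np.where(codes == 255, 0, codes).astype(np.uint8)

    fwd = _pack_strand(safe, k, m)
    # position i of the forward strand is position n-k-i of the reverse
    # complement, so the RC keys are the RC-strand keys reversed
    rc_codes = (3 - safe[::-1]).astype(np.uint8)
    rev = _pack_strand(rc_codes, k, m)[::-1]
    keys = np.where(fwd <= rev, fwd, rev)
    return keys, valid


def _keys_to_strings(keys: np.ndarray, k: int) -> list[str]:
    from wheatscan.core.seqs import _BASE

    nbytes = (k + 3) // 4
    mat = np.frombuffer(b"".join(key.ljust(nbytes, b"\0") for key in keys),
                        dtype=np.uint8).reshape(len(keys), nbytes)
    digits = np.empty((len(keys), nbytes * 4), dtype=np.uint8)
    for j in range(4):
        digits[:, j::4] = (mat >> (6 - 2 * j)) & 3
    chars = np.ascontiguousarray(_BASE[digits[:, :k]])
    return [s.decode("ascii") for s in chars.view(f"S{k}").reshape(len(keys))]


def canonical_kmer(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    kmer = kmer.upper()
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _validate_k(k: int) -> None:
    # recommended operating range is 15-63; small odd k allowed for toys
    if k < 1 or k > 63 or k % 2 == 0:
        raise ValueError(f"k must be odd and in [1, 63], got {k}")


@dataclass
class KmerSet:
    """Canonical k-mer membership structure with fixed k.

    ``keys`` is a sorted, unique array of byte-packed k-mers (see
    :func:`key_dtype`); byte order of keys equals lexicographic order of
    k-mer strings, so searchsorted-based membership is exact.
    """

    k: int
    keys: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        _validate_k(self.k)
        if self.keys is None:
            self.keys = np.empty(0, dtype=key_dtype(self.k))
        else:
            self.keys = np.asarray(self.keys, dtype=key_dtype(self.k))

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            return False
        codes = SequenceSet({"q": kmer}).codes("q")
        keys, valid = _pack_positions(codes, self.k)
        if not valid[0]:
            return False
        return bool(self.membership(keys)[0])

    def membership(self, keys: np.ndarray) -> np.ndarray:
        """Vectorized membership for an array of packed keys."""
        if len(self.keys) == 0:
            return np.zeros(len(keys), dtype=bool)
        idx = np.searchsorted(self.keys, keys)
        idx = np.minimum(idx, len(self.keys) - 1)
        return self.keys[idx] == keys

    def to_strings(self) -> list[str]:
        return _keys_to_strings(self.keys, self.k)

    # -- set algebra -------------------------------------------------------
    def _require_same_k(self, other: "KmerSet") -> None:
        if self.k != other.k:
            raise ValueError(f"k mismatch: {self.k} vs {other.k}")

    def difference(self, other: "KmerSet") -> "KmerSet":
        self._require_same_k(other)
        return KmerSet(self.k, np.setdiff1d(self.keys, other.keys, assume_unique=True),
                       label=self.label)

    def intersection(self, other: "KmerSet") -> "KmerSet":
        self._require_same_k(other)
        return KmerSet(self.k, np.intersect1d(self.keys, other.keys, assume_unique=True),
                       label=self.label)

    def union(self, other: "KmerSet") -> "KmerSet":
        self._require_same_k(other)
        return KmerSet(self.k, np.union1d(self.keys, other.keys), label=self.label)

    # -- I/O ---------------------------------------------------------------
    def write_text(self, path: str | Path) -> None:
        """Interoperable export: one k-mer per line after a # header."""
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\tcount={len(self)}\tlabel={self.label}\n")
            for s in self.to_strings():
                fh.write(s + "\n")

    @classmethod
    def read_text(cls, path: str | Path) -> "KmerSet":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            fields = dict(
                item.split("=", 1) for item in header.lstrip("#").split("\t")
            )
            k = int(fields["k"])
            kmers = [line.strip() for line in fh if line.strip()]
        return count_kmers(kmers, k, label=fields.get("label", ""))

    def write_binary(self, path: str | Path) -> None:
        """Packed binary: one text header line then raw packed keys."""
        with open(path, "wb") as fh:
            fh.write(f"#k={self.k}\tcount={len(self)}\tlabel={self.label}\n".encode())
            fh.write(self.keys.tobytes())

    @classmethod
    def read_binary(cls, path: str | Path) -> "KmerSet":
        with open(path, "rb") as fh:
            header = fh.readline().decode().rstrip("\n")
            fields = dict(
                item.split("=", 1) for item in header.lstrip("#").split("\t")
            )
            k = int(fields["k"])
            keys = np.frombuffer(fh.read(), dtype=key_dtype(k))
        return cls(k, keys.copy(), label=fields.get("label", ""))


def _iter_sequences(source) -> list[str]:
    if isinstance(source, SequenceSet):
        return [source[c] for c in source]
    if isinstance(source, (str, Path)):
        path = Path(source)
        fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
        from Bio import SeqIO

        return [str(r.seq) for r in SeqIO.parse(str(path), fmt)]
    return [str(s) for s in source]


def count_kmers(source, k: int = 51, label: str = "") -> KmerSet:
    """Distinct canonical k-mers over all input sequences.

    ``source`` may be a SequenceSet, a FASTA/FASTQ path, or an iterable of
    sequence strings (reads). K-mers spanning non-ACGT symbols are skipped;
    sequences shorter than k contribute nothing. One representative per
    k-mer is retained.
    """
    _validate_k(k)
    chunks = []
    for seq in _iter_sequences(source):
        codes = SequenceSet({"q": seq}).codes("q") if not isinstance(seq, np.ndarray) else seq
        keys, valid = _pack_positions(codes, k)
        if len(keys):
            chunks.append(keys[valid])
    if not chunks:
        return KmerSet(k, label=label)
    return KmerSet(k, np.unique(np.concatenate(chunks)), label=label)


def specific_kmers(set_a: KmerSet, set_b: KmerSet) -> KmerSet:
    """K-mers of a not present in b (a \\ b)."""
    out = set_a.difference(set_b)
    out.label = f"{set_a.label}-specific" if set_a.label else "specific"
    return out


def scan_genome(genome: SequenceSet, kmer_set: KmerSet) -> dict[str, np.ndarray]:
    """Boolean match array per chromosome: position i is True when the
    canonical k-mer starting at i is a member."""
    out = {}
    for chrom in genome:
        codes = genome.codes(chrom)
        keys, valid = _pack_positions(codes, kmer_set.k)
        member = np.zeros(len(keys), dtype=bool)
        if len(keys):
            member[valid] = kmer_set.membership(keys[valid])
        out[chrom] = member
    return out


def window_specific_coverage(
    genome: SequenceSet,
    kmer_set: KmerSet,
    width: int = 1_000_000,
    count_mode: str = "depth",
) -> WindowTrack:
    """Mean per-base depth of matched k-mers in fixed windows.

    Each matching k-mer start adds 1 to the depth of the k bases it covers;
    window value = total covered depth / window width. ``count_mode=
    "starts"`` counts match starts per window instead.
    """
    if count_mode not in {"depth", "starts"}:
        raise ValueError(f"unknown count_mode {count_mode!r}")
    k = kmer_set.k
    matches = scan_genome(genome, kmer_set)
    windows = make_windows(genome.lengths(), width)
    values = np.zeros(len(windows))
    n_sites = np.zeros(len(windows), dtype=np.int64)
    for chrom, length in genome.lengths().items():
        member = matches[chrom]
        sel = (windows["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(sel)
        starts = windows["start"].to_numpy()[idx]
        ends = windows["end"].to_numpy()[idx]
        starts_hit = np.flatnonzero(member)
        if count_mode == "depth":
            diff = np.zeros(length + 1, dtype=np.int64)
            np.add.at(diff, starts_hit, 1)
            np.add.at(diff, np.minimum(starts_hit + k, length), -1)
            depth = np.cumsum(diff[:-1])
            cs = np.concatenate([[0], np.cumsum(depth)])
            values[idx] = (cs[ends] - cs[starts]) / (ends - starts)
        else:
            values[idx] = np.histogram(starts_hit, bins=np.append(starts, ends[-1]))[0]
        counts = np.histogram(starts_hit, bins=np.append(starts, ends[-1]))[0]
        n_sites[idx] = counts
    frame = windows.copy()
    frame["value"] = values
    frame["n_sites"] = n_sites
    return WindowTrack(frame, width=width)


@dataclass
class KmerCallParams:
    min_donor_cov: float = 5.0   # donor-specific mean depth floor
    max_other_cov: float = 1.0   # competing-species depth ceiling
    merge_gap: int = 1_000_000   # merge segments no more than this far apart
    min_len: int = 50_000


def call_kmer_segments(
    donor_track: WindowTrack,
    other_track: WindowTrack,
    params: KmerCallParams | None = None,
    label: str = "kmer_introgression",
) -> list[Segment]:
    """Segments of elevated donor-specific and depleted other-specific k-mers.

    Windows with donor coverage >= min_donor_cov AND other coverage <=
    max_other_cov are grouped; groups separated by <= merge_gap bp are
    merged; merged segments shorter than min_len are dropped.
    """
    p = params or KmerCallParams()
    donor_track.require_same_windows(other_track)
    frame = donor_track.frame
    qualifies = (donor_track.values >= p.min_donor_cov) & (
        other_track.values <= p.max_other_cov
    )
    raw: list[Segment] = []
    chroms = frame["chrom"].to_numpy()
    starts = frame["start"].to_numpy()
    ends = frame["end"].to_numpy()
    vals = donor_track.values
    i, n = 0, len(frame)
    while i < n:
        if qualifies[i]:
            j = i
            while (
                j + 1 < n
                and qualifies[j + 1]
                and chroms[j + 1] == chroms[i]
                and starts[j + 1] == ends[j]
            ):
                j += 1
            raw.append(
                Segment(
                    str(chroms[i]), int(starts[i]), int(ends[j]),
                    label=label, score=float(np.mean(vals[i:j + 1])),
                )
            )
            i = j + 1
        else:
            i += 1
    merged = merge_segments(raw, gap=p.merge_gap)
    return [s for s in merged if s.length >= p.min_len]
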