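import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheatscan.core.segments import Segment
from wheatscan.core.seqs import SequenceSet, reverse_complement
from wheatscan.core.windows import WindowTrack, make_windows
from wheatscan.kmer_map import (
    KmerCallParams,
    KmerSet,
    call_kmer_segments,
    canonical_kmer,
    count_kmers,
    specific_kmers,
    window_specific_coverage,
)
from wheatscan.simgen import make_ancestor, plant_introgressions
from wheatscan.simgen.generate import diverge_genome

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


# ---------------------------------------------------------------- oracles
def brute_kmers(seqs, k):
    out = set()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            win = seq[i:i + k]
            if set(win) <= set("ACGT"):
                out.add(canonical_kmer(win))
    return out


def brute_coverage(genome, kmer_strings, k, width):
    """Per-window mean depth by per-position membership and base painting."""
    values = {}
    for chrom in genome:
        seq = genome[chrom]
        depth = np.zeros(len(seq), dtype=int)
        for i in range(len(seq) - k + 1):
            win = seq[i:i + k]
            if set(win) <= set("ACGT") and canonical_kmer(win) in kmer_strings:
                depth[i:i + k] += 1
        for start in range(0, len(seq), width):
            end = min(start + width, len(seq))
            values[(chrom, start)] = depth[start:end].sum() / (end - start)
    return values


class TestCountKmers:
    def test_enumerated_example(self):
        ks = count_kmers(["ACGTACGT"], 5)
        # 4 positions: ACGTA, CGTAC, GTACG, TACGT; canonical forms collapse
        expected = brute_kmers(["ACGTACGT"], 5)
        assert set(ks.to_strings()) == expected
        assert len(ks) <= 4

    def test_reverse_complement_same_set(self):
        seq = "ACCGTTAGGCATT"
        a = count_kmers([seq], 7)
        b = count_kmers([reverse_complement(seq)], 7)
        assert set(a.to_strings()) == set(b.to_strings())

    def test_n_masks_overlapping_kmers(self):
        ks = count_kmers(["ACNGTACGTT"], 3)
        assert set(ks.to_strings()) == brute_kmers(["ACNGTACGTT"], 3)
        assert not any("N" in s for s in ks.to_strings())

    def test_short_sequence_contributes_nothing(self):
        assert len(count_kmers(["ACG"], 5)) == 0

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            count_kmers(["ACGTACGT"], 4)

    @given(dna)
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, seq):
        ks = count_kmers([seq], 7)
        assert set(ks.to_strings()) == brute_kmers([seq], 7)

    def test_canonical_invariant(self):
        ks = count_kmers(["ACGTAGGCTA"], 5)
        for s in ks.to_strings():
            assert s == canonical_kmer(s)

    def test_text_round_trip(self, tmp_path):
        ks = count_kmers(["ACGTAGGCTAGGAT"], 5, label="toy")
        path = tmp_path / "k.txt"
        ks.write_text(path)
        back = KmerSet.read_text(path)
        assert back.k == 5 and back.label == "toy"
        assert set(back.to_strings()) == set(ks.to_strings())

    def test_binary_round_trip(self, tmp_path):
        ks = count_kmers(["ACGTAGGCTAGGAT"], 5, label="toy")
        path = tmp_path / "k.bin"
        ks.write_binary(path)
        back = KmerSet.read_binary(path)
        assert back.k == 5
        assert np.array_equal(back.keys, ks.keys)


class TestSpecificKmers:
    def test_identical_sets_empty(self):
        a = count_kmers(["ACGTAGGCTA"], 5)
        assert len(specific_kmers(a, a)) == 0

    def test_disjoint_sets_unchanged(self):
        a = count_kmers(["AAAAAAA"], 5)
        b = count_kmers(["CCCCCCC"], 5)
        assert set(specific_kmers(a, b).to_strings()) == set(a.to_strings())

    def test_partition_identity(self):
        a = count_kmers(["ACGTAGGCTAGGATCCA"], 5)
        b = count_kmers(["TAGGCTAGGAACCTT"], 5)
        assert len(specific_kmers(a, b)) + len(a.intersection(b)) == len(a)

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError):
            specific_kmers(count_kmers(["ACGTACG"], 5), count_kmers(["ACGTACG"], 7))

    def test_specific_count_grows_with_divergence(self):
        base = make_ancestor({"1A": 30_000}, seed=42)
        sizes = []
        for d in (0.002, 0.01, 0.05):
            other = diverge_genome(base, d, seed=7)
            a = count_kmers(base, 21)
            b = count_kmers(other, 21)
            sizes.append(len(specific_kmers(a, b)))
        assert sizes[0] < sizes[1] < sizes[2]


class TestWindowSpecificCoverage:
    def test_self_coverage_near_k(self):
        k = 11
        genome = make_ancestor({"1A": 5_000}, seed=3)
        ks = count_kmers(genome, k)
        track = window_specific_coverage(genome, ks, width=5_000)
        # every internal base covered by ~k matches, edges shallower
        assert track.values[0] == pytest.approx(k, rel=0.02)

    def test_empty_set_zero_track(self):
        genome = make_ancestor({"1A": 2_000}, seed=3)
        track = window_specific_coverage(genome, KmerSet(11), width=500)
        assert np.all(track.values == 0.0)

    def test_exact_against_brute_force(self, rng):
        k, width = 9, 1_000
        genome = make_ancestor({"1A": 7_000, "2B": 3_500}, seed=5)
        source = make_ancestor({"x": 4_000}, seed=6)
        # half-overlapping k-mer source: some matches, some not
        mixed = SequenceSet({"x": source["x"][:2000] + genome["1A"][:2000]})
        ks = count_kmers(mixed, k)
        track = window_specific_coverage(genome, ks, width=width)
        expected = brute_coverage(genome, set(ks.to_strings()), k, width)
        for row in track.frame.itertuples():
            assert row.value == pytest.approx(expected[(row.chrom, row.start)], abs=1e-12)

    def test_strand_invariance_mirror_track(self):
        k, width = 7, 500
        genome = make_ancestor({"1A": 3_000}, seed=8)
        ks = count_kmers(make_ancestor({"d": 1_500}, seed=9), k)
        fwd = window_specific_coverage(genome, ks, width=width, count_mode="starts")
        rev = window_specific_coverage(genome.reverse_complement(), ks, width=width,
                                       count_mode="starts")
        # a match starting at i covers the k-mer whose RC starts at L-k-i;
        # start counts per window mirror up to the k-1 bp window-edge shift
        total_fwd = fwd.values.sum()
        total_rev = rev.values.sum()
        assert total_fwd == total_rev

    def test_planted_segment_elevates_only_its_windows(self):
        k = 21
        recipient = make_ancestor({"1A": 100_000}, seed=10)
        donor = diverge_genome(recipient, 0.02, seed=11)
        planted, _ = plant_introgressions(
            recipient, donor, [Segment("1A", 40_000, 60_000)]
        )
        donor_specific = specific_kmers(count_kmers(donor, k), count_kmers(recipient, k))
        track = window_specific_coverage(planted, donor_specific, width=10_000)
        vals = track.values
        inside = vals[4:6]
        outside = np.concatenate([vals[:4], vals[6:]])
        assert inside.min() > 5
        assert outside.max() < 1


class TestCallKmerSegments:
    def _tracks(self, donor_vals, other_vals, width=100_000):
        frame = make_windows({"1A": width * len(donor_vals)}, width)
        d = frame.copy()
        d["value"] = donor_vals
        o = frame.copy()
        o["value"] = other_vals
        return WindowTrack(d, width=width), WindowTrack(o, width=width)

    def test_merge_within_one_mb(self):
        # qualifying windows 0-1 and then 7-8: gap 0.5 Mb <= 1 Mb merges
        donor = [9, 9, 0, 0, 0, 0, 0, 9, 9, 0]
        other = [0.0] * 10
        d, o = self._tracks(donor, other)
        segs = call_kmer_segments(d, o)
        assert [(s.start, s.end) for s in segs] == [(0, 900_000)]

    def test_gap_exactly_merge_gap_merges(self):
        width = 500_000
        donor = [9, 0, 0, 9]  # gap = 2 windows = 1 Mb exactly
        d, o = self._tracks(donor, [0.0] * 4, width=width)
        segs = call_kmer_segments(d, o, KmerCallParams(min_len=100_000))
        assert [(s.start, s.end) for s in segs] == [(0, 2_000_000)]

    def test_gap_above_merge_gap_stays_split(self):
        width = 550_000
        donor = [9, 0, 0, 9]  # gap = 1.1 Mb > 1 Mb
        d, o = self._tracks(donor, [0.0] * 4, width=width)
        segs = call_kmer_segments(d, o, KmerCallParams(min_len=100_000))
        assert len(segs) == 2

    def test_coverage_threshold_boundary(self):
        d, o = self._tracks([4.99, 0, 5.0, 0], [0.0] * 4)
        segs = call_kmer_segments(d, o, KmerCallParams(min_len=1))
        assert [(s.start, s.end) for s in segs] == [(200_000, 300_000)]

    def test_depleted_other_required(self):
        d, o = self._tracks([9, 9], [0.0, 2.0])
        segs = call_kmer_segments(d, o, KmerCallParams(min_len=1, merge_gap=0))
        assert [(s.start, s.end) for s in segs] == [(0, 100_000)]

    def test_no_qualifying_windows(self):
        d, o = self._tracks([1, 2], [0.0, 0.0])
        assert call_kmer_segments(d, o) == []

    def test_min_len_filter(self):
        d, o = self._tracks([9, 0, 0, 0], [0.0] * 4)
        segs = call_kmer_segments(d, o, KmerCallParams(min_len=200_000))
        assert segs == []


class TestBoundaryRecovery:
    def test_planted_boundaries_within_k_minus_one(self):
        k = 21
        recipient = make_ancestor({"1A": 50_000}, seed=20)
        donor = diverge_genome(recipient, 0.05, seed=21)
        truth = Segment("1A", 20_000, 30_000)
        planted, _ = plant_introgressions(recipient, donor, [truth])
        donor_specific = specific_kmers(
            count_kmers(donor, k), count_kmers(recipient, k)
        )
        recipient_specific = specific_kmers(
            count_kmers(recipient, k), count_kmers(donor, k)
        )
        dtrack = window_specific_coverage(planted, donor_specific, width=1_000)
        otrack = window_specific_coverage(planted, recipient_specific, width=1_000)
        segs = call_kmer_segments(
            dtrack, otrack, KmerCallParams(min_donor_cov=5, max_other_cov=1,
                                           merge_gap=1_000, min_len=2_000)
        )
        assert len(segs) == 1
        assert abs(segs[0].start - truth.start) <= max(k - 1, 1_000)
        assert abs(segs[0].end - truth.end) <= max(k - 1, 1_000)
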