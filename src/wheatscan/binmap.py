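"""Skim-sequencing bin genotyping of RIL populations.

Sparse parental-allele observations are aggregated into fixed 1 Mb bins;
each bin is coded P1/P2 when one parent's observations reach the consensus
proportion (default 0.7 of informative observations), H otherwise, and NA
with no (or too few) observations. Breakpoints are reported as intervals
between consecutive informative bins with different codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from wheatscan.core.segments import Segment
from wheatscan.core.variants import GT_ALT, GT_REF, VariantTable
from wheatscan.core.windows import assign_windows, make_windows

P1, P2, H, NA = "P1", "P2", "H", "NA"
_EXCHANGE = {P1: "A", P2: "B", H: "H", NA: "-"}


def discover_parent_markers(
    parents: VariantTable,
    parent1: str,
    parent2: str,
    min_dp: int = 6,
    max_dp: int = 100,
    min_allele_dp: int = 3,
) -> VariantTable:
    """Sites usable as parental markers.

    Keeps sites where both parents are homozygous and non-missing, carry
    different alleles, have depth within [min_dp, max_dp] and supporting
    allele depth >= min_allele_dp.
    """
    i1 = parents.sample_index(parent1)
    i2 = parents.sample_index(parent2)
    g1, g2 = parents.gt[:, i1], parents.gt[:, i2]
    keep = (
        np.isin(g1, (GT_REF, GT_ALT))
        & np.isin(g2, (GT_REF, GT_ALT))
        & (g1 != g2)
    )
    if parents.dp is not None:
        keep &= (parents.dp[:, i1] >= min_dp) & (parents.dp[:, i1] <= max_dp)
        keep &= (parents.dp[:, i2] >= min_dp) & (parents.dp[:, i2] <= max_dp)
    if parents.ad_ref is not None and parents.ad_alt is not None:
        sup1 = np.where(g1 == GT_REF, parents.ad_ref[:, i1], parents.ad_alt[:, i1])
        sup2 = np.where(g2 == GT_REF, parents.ad_ref[:, i2], parents.ad_alt[:, i2])
        keep &= (sup1 >= min_allele_dp) & (sup2 >= min_allele_dp)
    out = parents.subset_sites(keep)
    if len(out) == 0:
        import warnings

        warnings.warn("no sites pass parental marker filters", stacklevel=2)
    return out


def markers_frame(markers: VariantTable, parent1: str, parent2: str) -> pd.DataFrame:
    """Marker table (chrom, pos, allele_p1, allele_p2) from a filtered
    two-parent VariantTable."""
    i1 = markers.sample_index(parent1)
    i2 = markers.sample_index(parent2)
    ref = markers.sites["ref"].to_numpy()
    alt = markers.sites["alt"].to_numpy()
    return pd.DataFrame(
        {
            "chrom": markers.sites["chrom"],
            "pos": markers.sites["pos"],
            "allele_p1": np.where(markers.gt[:, i1] == GT_REF, ref, alt),
            "allele_p2": np.where(markers.gt[:, i2] == GT_REF, ref, alt),
        }
    )


@dataclass
class BinGenotypeMatrix:
    """RIL x 1 Mb bin consensus codes with per-cell support counts."""

    bins: pd.DataFrame              # chrom, start, end
    rils: list[str]
    codes: np.ndarray               # object array of P1/P2/H/NA, (n_rils, n_bins)
    n_p1_obs: np.ndarray
    n_p2_obs: np.ndarray
    collapsed: dict[int, list[int]] | None = None  # kept bin -> duplicate bins

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{c}:{s}-{e}"
            for c, s, e in self.bins[["chrom", "start", "end"]].itertuples(index=False)
        ]
        return pd.DataFrame(self.codes, index=self.rils, columns=cols)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="ril")

    def write_exchange(self, path) -> None:
        """One-letter codes (A/B/H/-) for linkage-mapping import."""
        frame = self.to_frame().replace(_EXCHANGE)
        frame.to_csv(path, sep="\t", index_label="ril")

    @classmethod
    def read_tsv(cls, path) -> "BinGenotypeMatrix":
        """Round-trip of :meth:`write_tsv` (support counts not preserved)."""
        frame = pd.read_csv(path, sep="\t", index_col="ril")
        bins = []
        for col in frame.columns:
            chrom, span = col.rsplit(":", 1)
            start, end = span.split("-")
            bins.append((chrom, int(start), int(end)))
        codes = frame.to_numpy(dtype=object)
        zeros = np.zeros_like(codes, dtype=np.int64)
        return cls(
            pd.DataFrame(bins, columns=["chrom", "start", "end"]),
            [str(r) for r in frame.index],
            codes, zeros, zeros,
        )


def genotype_bins(
    observations: pd.DataFrame,
    markers: pd.DataFrame,
    chrom_lengths: dict[str, int],
    width: int = 1_000_000,
    ratio: float = 0.7,
    min_obs: int = 1,
) -> BinGenotypeMatrix:
    """Consensus bin genotypes from sparse observations.

    ``observations`` columns: ril, chrom, pos (1-based), allele.
    ``markers`` columns: chrom, pos, allele_p1, allele_p2. Observations at
    positions not in the marker table, or with an allele matching neither
    parent, are ignored. Per bin: p1/(p1+p2) >= ratio -> P1;
    p2/(p1+p2) >= ratio -> P2; else H; fewer than min_obs observations -> NA.
    """
    if ratio <= 0.5:
        raise ValueError(f"consensus ratio must exceed 0.5, got {ratio}")
    if min_obs < 1:
        raise ValueError("min_obs must be >= 1")
    bins = make_windows(chrom_lengths, width)
    rils = sorted(observations["ril"].unique()) if len(observations) else []
    n_bins = len(bins)
    n_p1 = np.zeros((len(rils), n_bins), dtype=np.int64)
    n_p2 = np.zeros((len(rils), n_bins), dtype=np.int64)

    if len(observations):
        obs = observations.merge(markers, on=["chrom", "pos"], how="inner")
        is_p1 = (obs["allele"] == obs["allele_p1"]).to_numpy()
        is_p2 = (obs["allele"] == obs["allele_p2"]).to_numpy()
        obs = obs[is_p1 | is_p2]
        is_p1 = (obs["allele"] == obs["allele_p1"]).to_numpy()
        bin_idx = assign_windows(
            bins, obs["chrom"].to_numpy(), obs["pos"].to_numpy() - 1
        )
        ril_idx = pd.Categorical(obs["ril"], categories=rils).codes
        ok = bin_idx >= 0
        np.add.at(n_p1, (ril_idx[ok & is_p1], bin_idx[ok & is_p1]), 1)
        np.add.at(n_p2, (ril_idx[ok & ~is_p1], bin_idx[ok & ~is_p1]), 1)

    total = n_p1 + n_p2
    with np.errstate(divide="ignore", invalid="ignore"):
        frac1 = np.where(total > 0, n_p1 / np.maximum(total, 1), 0.0)
    codes = np.full((len(rils), n_bins), H, dtype=object)
    codes[frac1 >= ratio] = P1
    codes[(1 - frac1 >= ratio) & (total > 0)] = P2
    codes[total < min_obs] = NA
    return BinGenotypeMatrix(bins, rils, codes, n_p1, n_p2)


def find_breakpoints(
    matrix: BinGenotypeMatrix,
    observations: pd.DataFrame | None = None,
    markers: pd.DataFrame | None = None,
    treat_h_as_na: bool = False,
) -> dict[str, list[Segment]]:
    """Breakpoint intervals per RIL.

    Between every consecutive pair of informative bins with different
    codes, an interval from the end of the left informative bin to the
    start of the right one is emitted (intervening NA bins widen the
    interval; adjacent bins give a minimal 1 bp interval at the shared
    boundary). With ``treat_h_as_na`` the H code is uncertain rather than
    informative, so a P1-H-P2 run yields one widened P1>P2 interval.

    When ``observations`` and ``markers`` are supplied, each interval is
    refined to marker resolution: it then runs from just after the last
    observation supporting the left code through the first observation
    supporting the right code, scanning from the left bin's start to the
    right bin's end. The true exchange point is guaranteed to lie inside a
    refined interval when observations are error-free.
    """
    out: dict[str, list[Segment]] = {}
    chroms = matrix.bins["chrom"].to_numpy()
    starts = matrix.bins["start"].to_numpy()
    ends = matrix.bins["end"].to_numpy()
    refine = observations is not None and markers is not None
    if refine:
        obs = observations.merge(markers, on=["chrom", "pos"], how="inner")
        obs_by_ril = dict(tuple(obs.groupby("ril", sort=False)))
    uninformative = {NA, H} if treat_h_as_na else {NA}
    for r, ril in enumerate(matrix.rils):
        row = matrix.codes[r]
        segs: list[Segment] = []
        for chrom in dict.fromkeys(chroms):
            idx = np.flatnonzero(chroms == chrom)
            informative = idx[[c not in uninformative for c in row[idx]]]
            for left, right in zip(informative, informative[1:]):
                if row[left] == row[right]:
                    continue
                lo = int(ends[left])
                hi = int(starts[right]) if starts[right] > ends[left] else lo + 1
                if refine:
                    lo, hi = _refine_interval(
                        obs_by_ril.get(ril), str(chrom),
                        int(starts[left]), int(ends[right]),
                        str(row[left]), str(row[right]), lo, hi,
                    )
                segs.append(
                    Segment(str(chrom), lo, hi, label=f"{row[left]}>{row[right]}")
                )
        out[ril] = segs
    return out


def _refine_interval(
    ril_obs: pd.DataFrame | None,
    chrom: str,
    span_start: int,
    span_end: int,
    left_code: str,
    right_code: str,
    default_lo: int,
    default_hi: int,
) -> tuple[int, int]:
    if ril_obs is None:
        return default_lo, default_hi
    sub = ril_obs[
        (ril_obs["chrom"] == chrom)
        & (ril_obs["pos"] - 1 >= span_start)
        & (ril_obs["pos"] - 1 < span_end)
    ].sort_values("pos")
    if len(sub) == 0:
        return default_lo, default_hi
    which = np.where(
        sub["allele"].to_numpy() == sub["allele_p1"].to_numpy(), P1, P2
    )
    pos0 = sub["pos"].to_numpy() - 1
    left_hits = pos0[which == left_code]
    right_hits = pos0[which == right_code]
    if len(left_hits) == 0 or len(right_hits) == 0:
        return default_lo, default_hi
    last_left = int(left_hits.max())
    first_right = int(right_hits[right_hits > last_left].min()) if (
        right_hits > last_left
    ).any() else None
    if first_right is None:
        return default_lo, default_hi
    return last_left + 1, first_right + 1


def filter_marker_matrix(
    matrix: BinGenotypeMatrix, max_missing: float = 0.30
) -> BinGenotypeMatrix:
    """Drop bins with > max_missing NA fraction, then deduplicate bins with
    identical code vectors (first of each group kept; membership recorded
    in ``collapsed``)."""
    n_rils = len(matrix.rils)
    na_frac = (matrix.codes == NA).sum(axis=0) / max(n_rils, 1)
    keep = np.flatnonzero(na_frac <= max_missing)

    seen: dict[tuple, int] = {}
    collapsed: dict[int, list[int]] = {}
    kept: list[int] = []
    for j in keep:
        key = tuple(matrix.codes[:, j])
        if key in seen:
            collapsed.setdefault(seen[key], []).append(int(j))
        else:
            seen[key] = int(j)
            kept.append(int(j))
    return BinGenotypeMatrix(
        matrix.bins.iloc[kept].reset_index(drop=True),
        matrix.rils,
        matrix.codes[:, kept],
        matrix.n_p1_obs[:, kept],
        matrix.n_p2_obs[:, kept],
        collapsed=collapsed,
    )
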