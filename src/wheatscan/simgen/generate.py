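"""Generators for every synthetic input used by the analysis stages.

All coordinates are 0-based half-open internally; emitted variant tables
use 1-based positions (VCF convention). Mutation placement is
infinite-sites: colliding positions are redrawn so every emitted record
stays biallelic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from wheatscan.core.seqs import SequenceSet, random_sequence
from wheatscan.core.segments import Segment
from wheatscan.core.variants import GT_ALT, VariantTable
from wheatscan.simgen.config import SimConfig, TruthSet

#: fixed population topology ((alpha),(beta,dom),(gamma)); maps population
#: id to the branches on its root-to-tip path
POPULATIONS: dict[str, tuple[str, ...]] = {
    "alpha": ("alpha",),
    "beta": ("betadom", "beta"),
    "dom": ("betadom", "dom"),
    "gamma": ("gamma",),
}

_OTHER_BASES = {
    "A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG",
}


def make_ancestor(chrom_lengths: dict[str, int], seed: int) -> SequenceSet:
    """Uniform-random ancestral genome; identical bytes for identical seed."""
    rng = np.random.default_rng(seed)
    out = SequenceSet()
    for chrom, length in chrom_lengths.items():
        out[chrom] = random_sequence(length, rng)
    return out


def _draw_positions(
    n: int, chrom_lengths: dict[str, int], rng: np.random.Generator,
    used: set[tuple[str, int]],
) -> list[tuple[str, int]]:
    """n distinct (chrom, pos0) uniform over the genome, avoiding `used`."""
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)
    total = lengths.sum()
    bounds = np.cumsum(lengths)
    out: list[tuple[str, int]] = []
    while len(out) < n:
        flat = rng.integers(0, total, size=n - len(out))
        idx = np.searchsorted(bounds, flat, side="right")
        offs = flat - (bounds[idx] - lengths[idx])
        for i, o in zip(idx, offs):
            key = (chroms[i], int(o))
            if key not in used:
                used.add(key)
                out.append(key)
    return out


def evolve_panel(
    ancestor: SequenceSet, config: SimConfig
) -> tuple[VariantTable, TruthSet]:
    """Evolve a diversity panel on the fixed ((alpha),(beta,dom),(gamma)) tree.

    Each population branch and each accession's terminal branch accumulates
    Poisson(rate x genome length) substitutions at uniform positions.
    Accessions are fully inbred: genotypes are haploid-coded 0/1.
    Domesticated accessions listed in ``config.introgression_spec`` have
    their genotypes overwritten with the donor accession's alleles across
    the specified intervals.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chrom_lengths = ancestor.lengths()
    total_len = sum(chrom_lengths.values())

    accessions: list[str] = []
    acc_pop: dict[str, str] = {}
    for pop, size in config.pop_sizes.items():
        if pop not in POPULATIONS:
            raise ValueError(f"unknown population {pop!r}; expected {list(POPULATIONS)}")
        for i in range(1, size + 1):
            acc = f"{pop}{i}"
            accessions.append(acc)
            acc_pop[acc] = pop

    # branches carrying mutations: population branches present in the panel,
    # then one terminal branch per accession
    branch_rate: dict[str, float] = {}
    branch_members: dict[str, list[int]] = {}
    present = {p for p, n in config.pop_sizes.items() if n > 0}
    pop_branches: list[str] = []
    for pop in present:
        for br in POPULATIONS[pop]:
            if br not in pop_branches:
                pop_branches.append(br)
    for br in pop_branches:
        branch_rate[br] = config.mutation_rate_per_branch
        branch_members[br] = [
            i for i, acc in enumerate(accessions) if br in POPULATIONS[acc_pop[acc]]
        ]
    for i, acc in enumerate(accessions):
        branch_rate[f"t:{acc}"] = config.effective_terminal_rate
        branch_members[f"t:{acc}"] = [i]

    used: set[tuple[str, int]] = set()
    site_rows: list[tuple[str, int]] = []
    site_branch: list[str] = []
    for br, rate in branch_rate.items():
        n_mut = int(rng.poisson(rate * total_len))
        for key in _draw_positions(n_mut, chrom_lengths, rng, used):
            site_rows.append(key)
            site_branch.append(br)

    order = sorted(range(len(site_rows)), key=lambda i: site_rows[i])
    site_rows = [site_rows[i] for i in order]
    site_branch = np.array([site_branch[i] for i in order], dtype=object)
    n_sites = len(site_rows)

    gt = np.zeros((n_sites, len(accessions)), dtype=np.int8)
    for br, members in branch_members.items():
        on_branch = np.flatnonzero(site_branch == br)
        if len(on_branch):
            gt[np.ix_(on_branch, members)] = GT_ALT

    site_chrom = np.array([c for c, _ in site_rows], dtype=object)
    site_pos0 = np.array([p for _, p in site_rows], dtype=np.int64)
    ref_codes = np.zeros(n_sites, dtype=np.uint8)
    for chrom in chrom_lengths:
        sel = site_chrom == chrom
        if sel.any():
            ref_codes[sel] = ancestor.codes(chrom)[site_pos0[sel]]
    alt_codes = (ref_codes + 1 + rng.integers(0, 3, size=n_sites)) % 4
    bases = np.array(list("ACGT"))
    sites = pd.DataFrame(
        {
            "chrom": site_chrom,
            "pos": site_pos0 + 1,
            "ref": bases[ref_codes],
            "alt": bases[alt_codes],
        }
    )

    # planted gamma-lineage introgressions overwrite target genotypes
    truth = TruthSet()
    per_target: dict[str, list[tuple[int, int, str]]] = {}
    acc_index = {acc: i for i, acc in enumerate(accessions)}
    for spec in config.introgression_spec:
        target, chrom, start, end, donor_pop = spec[:5]
        donor_acc = spec[5] if len(spec) > 5 else f"{donor_pop}1"
        if target not in acc_index:
            raise ValueError(f"unknown target accession {target!r}")
        if donor_acc not in acc_index:
            raise ValueError(f"unknown donor accession {donor_acc!r}")
        for s, e, c in per_target.get(target, []):
            if c == chrom and s < end and start < e:
                raise ValueError(
                    f"overlapping introgression intervals on {target}: "
                    f"{chrom}:{start}-{end} vs {chrom}:{s}-{e}"
                )
        per_target.setdefault(target, []).append((start, end, chrom))
        in_iv = (
            (sites["chrom"] == chrom)
            & (sites["pos"] - 1 >= start)
            & (sites["pos"] - 1 < end)
        ).to_numpy()
        gt[in_iv, acc_index[target]] = gt[in_iv, acc_index[donor_acc]]
        truth.introgression_segments.append(
            Segment(chrom, start, end, label=f"{target}:{donor_pop}")
        )

    dp_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    dp = dp_rng.poisson(max(config.depth, 1), size=gt.shape).astype(np.int32)
    ad_alt = np.where(gt == GT_ALT, dp, 0).astype(np.int32)
    ad_ref = (dp - ad_alt).astype(np.int32)

    table = VariantTable(sites, gt, accessions, dp=dp, ad_ref=ad_ref, ad_alt=ad_alt)
    truth.validate(chrom_lengths)
    return table, truth


def simulate_ril(
    parent1_alleles: pd.DataFrame,
    parent2_alleles: pd.DataFrame,
    config: SimConfig,
    het_intervals: list[tuple[str, str, int, int]] | None = None,
) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate a RIL population observed at very low coverage.

    Parameters
    ----------
    parent1_alleles, parent2_alleles
        DataFrames with columns ``chrom``, ``pos`` (1-based), ``allele``.
        Only markers present in both and with differing alleles are used.
    config
        ``ril_count``, ``crossovers_per_chrom``, ``obs_rate``,
        ``obs_error_rate`` and ``chrom_lengths`` are consumed.
    het_intervals
        Optional residual-heterozygosity intervals (ril, chrom, start, end);
        observations inside report either parent with probability 1/2 and
        the mosaic is coded heterozygous there.

    Returns
    -------
    observations : DataFrame with columns ril, chrom, pos, allele, parent
        (parent in {0, 1} = which parent the reported allele matches).
    truth : TruthSet with exact crossover positions per RIL.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    markers = parent1_alleles.merge(
        parent2_alleles, on=["chrom", "pos"], suffixes=("_p1", "_p2")
    )
    markers = markers[markers["allele_p1"] != markers["allele_p2"]].reset_index(drop=True)
    het_by_ril: dict[str, list[tuple[str, int, int]]] = {}
    for ril, chrom, start, end in het_intervals or []:
        het_by_ril.setdefault(ril, []).append((chrom, start, end))

    truth = TruthSet()
    obs_rows = []
    for r in range(1, config.ril_count + 1):
        ril = f"RIL{r:04d}"
        truth.crossover_positions[ril] = []
        truth.start_parents[ril] = {}
        for chrom, length in config.chrom_lengths.items():
            sub = markers[markers["chrom"] == chrom]
            n_co = int(rng.poisson(config.crossovers_per_chrom))
            breaks = np.sort(rng.integers(1, length, size=n_co))
            breaks = np.unique(breaks)
            start_parent = int(rng.integers(0, 2))
            truth.start_parents[ril][chrom] = start_parent
            truth.crossover_positions[ril].extend((chrom, int(b)) for b in breaks)
            if len(sub) == 0:
                continue
            pos0 = sub["pos"].to_numpy() - 1
            parent = (start_parent + np.searchsorted(breaks, pos0, side="right")) % 2
            observed = rng.random(len(sub)) < config.obs_rate
            flip = rng.random(len(sub)) < config.obs_error_rate
            reported = np.where(flip, 1 - parent, parent)
            for chrom_h, hs, he in het_by_ril.get(ril, []):
                if chrom_h != chrom:
                    continue
                in_h = (pos0 >= hs) & (pos0 < he)
                reported = np.where(
                    in_h, rng.integers(0, 2, size=len(sub)), reported
                )
            alle = np.where(
                reported == 0, sub["allele_p1"].to_numpy(), sub["allele_p2"].to_numpy()
            )
            for i in np.flatnonzero(observed):
                obs_rows.append(
                    (ril, chrom, int(sub["pos"].iloc[i]), alle[i], int(reported[i]))
                )
    obs = pd.DataFrame(obs_rows, columns=["ril", "chrom", "pos", "allele", "parent"])
    truth.validate(config.chrom_lengths)
    return obs, truth


def haldane_c(distance_bp: float, morgans_per_bp: float) -> float:
    """Recombination fraction from physical distance (Haldane, capped 0.5)."""
    d = distance_bp * morgans_per_bp
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def simulate_bulk(
    reference: SequenceSet,
    n_ems: int,
    causal_pos: tuple[str, int],
    bulk_size: int,
    depth: int,
    seed: int,
    morgans_per_bp: float = 1e-8,
) -> tuple[pd.DataFrame, TruthSet]:
    """Allele depths of a recessive-mutant bulk with one causal EMS SNP.

    Every planted SNP is a G->A or C->T transition on the reference strand.
    The bulk is homozygous mutant at the causal site; at another site with
    recombination fraction c from it, each of the 2 x bulk_size sampled
    chromosomes carries the mutant allele with probability 1 - c, and the
    observed alt depth is Binomial(depth, realized bulk frequency).

    ``causal_pos`` uses a 1-based position whose reference base must be G
    or C (so the causal change is itself EMS-type).
    """
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    if n_ems < 1:
        raise ValueError("n_ems must be >= 1")
    chrom_c, pos_c = causal_pos
    if chrom_c not in reference:
        raise ValueError(f"causal chromosome {chrom_c!r} not in reference")
    if not 1 <= pos_c <= len(reference[chrom_c]):
        raise ValueError(f"causal position {pos_c} outside {chrom_c}")
    if reference[chrom_c][pos_c - 1] not in "GC":
        raise ValueError("causal position must carry a G or C reference base")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    chroms = list(reference)
    lengths = reference.lengths()

    # draw EMS sites at G/C reference bases, distinct, including the causal one
    sites: set[tuple[str, int]] = {(chrom_c, pos_c)}
    lens = np.array([lengths[c] for c in chroms], dtype=np.int64)
    bounds = np.cumsum(lens)
    while len(sites) < n_ems:
        flat = rng.integers(0, lens.sum(), size=n_ems - len(sites) + 8)
        idx = np.searchsorted(bounds, flat, side="right")
        offs = flat - (bounds[idx] - lens[idx])
        for i, o in zip(idx, offs):
            chrom, pos = chroms[i], int(o) + 1
            if reference[chrom][pos - 1] in "GC":
                sites.add((chrom, pos))
                if len(sites) == n_ems:
                    break

    rows = []
    for chrom, pos in sorted(sites):
        ref = reference[chrom][pos - 1]
        alt = "A" if ref == "G" else "T"
        if (chrom, pos) == (chrom_c, pos_c):
            freq = 1.0
        else:
            c = haldane_c(abs(pos - pos_c), morgans_per_bp) if chrom == chrom_c else 0.5
            mutant_chroms = rng.binomial(2 * bulk_size, 1.0 - c)
            freq = mutant_chroms / (2 * bulk_size)
        alt_depth = int(rng.binomial(depth, freq))
        rows.append((chrom, pos, ref, alt, depth, alt_depth))
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "depth", "alt_depth"]
    )
    truth = TruthSet(causal_snp=(chrom_c, pos_c))
    return table, truth


def plant_introgressions(
    recipient: SequenceSet, donor: SequenceSet, segments: list[Segment]
) -> tuple[SequenceSet, TruthSet]:
    """Copy donor sequence into the recipient across the given intervals."""
    out = SequenceSet({c: s for c, s in recipient.items()})
    for seg in segments:
        if seg.chrom not in recipient or seg.chrom not in donor:
            raise ValueError(f"chromosome {seg.chrom!r} missing from a genome")
        if seg.end > len(recipient[seg.chrom]) or seg.end > len(donor[seg.chrom]):
            raise ValueError(f"segment beyond chromosome end: {seg}")
        s = out[seg.chrom]
        out[seg.chrom] = s[: seg.start] + donor[seg.chrom][seg.start:seg.end] + s[seg.end:]
    truth = TruthSet(introgression_segments=[
        Segment(s.chrom, s.start, s.end, s.label or "planted") for s in segments
    ])
    return out, truth


def diverge_genome(
    genome: SequenceSet, rate: float, seed: int
) -> SequenceSet:
    """A copy of ``genome`` with Poisson(rate x length) substitutions."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    out = SequenceSet()
    for chrom in genome:
        out[chrom] = _mutate(genome[chrom], rate, rng)
    return out


def _mutate(seq: str, expected_per_site: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = rng.poisson(expected_per_site * len(arr))
    pos = rng.integers(0, len(arr), size=n)
    for p in pos:  # events with replacement: a proper Jukes-Cantor chain
        others = _OTHER_BASES[chr(arr[p])]
        arr[p] = ord(others[rng.integers(0, 3)])
    return arr.tobytes().decode("ascii")


def diverge_ltr_pair(
    length: int, age_years: float, rate: float, seed: int
) -> tuple[str, str, float]:
    """Two LTR copies, identical at insertion, each mutated for ``age_years``.

    ``rate`` is substitutions/site/year on each copy (Jukes-Cantor process);
    returns (ltr5, ltr3, true age).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if age_years < 0:
        raise ValueError("age must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    ancestral = random_sequence(length, rng)
    expected = rate * age_years
    ltr5 = _mutate(ancestral, expected, rng)
    ltr3 = _mutate(ancestral, expected, rng)
    return ltr5, ltr3, age_years
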