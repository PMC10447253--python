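"""Driver that materializes a full synthetic dataset on disk."""

from __future__ import annotations

from pathlib import Path

from wheatscan.simgen.config import SimConfig
from wheatscan.simgen.generate import (
    evolve_panel,
    make_ancestor,
    simulate_bulk,
    simulate_ril,
)


def simulate_dataset(config: SimConfig, outdir: str | Path) -> list[Path]:
    """Generate panel, RIL and bulk artifacts with truth files.

    Writes: ancestor.fasta, panel.vcf, truth_introgressions.bed,
    ril_observations.tsv, ril_crossovers.tsv, bulk.tsv, bulk_truth.tsv and
    an echo of the configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    ancestor = make_ancestor(config.chrom_lengths, config.seed)
    fasta = outdir / "ancestor.fasta"
    ancestor.write_fasta(fasta)
    outputs.append(fasta)

    panel, truth = evolve_panel(ancestor, config)
    vcf = outdir / "panel.vcf"
    panel.write_vcf(vcf)
    outputs.append(vcf)
    bed = outdir / "truth_introgressions.bed"
    truth.write_bed(bed)
    outputs.append(bed)

    if config.ril_count > 0 and len(panel):
        from wheatscan.binmap import markers_frame

        # first two accessions act as RIL parents
        p1, p2 = panel.samples[0], panel.samples[-1]
        informative = panel.gt[:, panel.sample_index(p1)] != panel.gt[
            :, panel.sample_index(p2)
        ]
        markers = markers_frame(panel.subset_sites(informative), p1, p2)
        obs, ril_truth = simulate_ril(
            markers.rename(columns={"allele_p1": "allele"})[["chrom", "pos", "allele"]],
            markers.rename(columns={"allele_p2": "allele"})[["chrom", "pos", "allele"]],
            config,
        )
        obs_path = outdir / "ril_observations.tsv"
        obs.to_csv(obs_path, sep="\t", index=False)
        outputs.append(obs_path)
        co_path = outdir / "ril_crossovers.tsv"
        with open(co_path, "w") as fh:
            fh.write("ril\tchrom\tpos\n")
            for ril, pts in ril_truth.crossover_positions.items():
                for chrom, pos in pts:
                    fh.write(f"{ril}\t{chrom}\t{pos}\n")
        outputs.append(co_path)

    if config.bulk_size > 0:
        chrom = next(iter(config.chrom_lengths))
        seq = ancestor[chrom]
        causal = next(
            (i + 1 for i in range(len(seq) // 2, len(seq)) if seq[i] in "GC"),
            None,
        )
        if causal is not None:
            bulk, bulk_truth = simulate_bulk(
                ancestor,
                n_ems=max(config.depth, 50),
                causal_pos=(chrom, causal),
                bulk_size=config.bulk_size,
                depth=max(config.depth, 1),
                seed=config.seed,
                morgans_per_bp=config.morgans_per_bp,
            )
            bulk_path = outdir / "bulk.tsv"
            bulk.to_csv(bulk_path, sep="\t", index=False)
            outputs.append(bulk_path)
            truth_path = outdir / "bulk_truth.tsv"
            with open(truth_path, "w") as fh:
                fh.write("chrom\tpos\n")
                fh.write(f"{bulk_truth.causal_snp[0]}\t{bulk_truth.causal_snp[1]}\n")
            outputs.append(truth_path)

    cfg_path = outdir / "sim_config.yaml"
    config.to_yaml(cfg_path)
    outputs.append(cfg_path)
    return outputs
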